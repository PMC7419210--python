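"""Permutation enrichment of GC and repeat content at duplication donors.

Simulates a repeat-annotated genome whose SINEs favour high-GC blocks,
plants 80 duplication-donor segments with a known SINE enrichment of 1.5x,
and asks the permutation engine to recover it. The E column is observed /
mean of random length-matched placements; SINE/LINE p values come from the
Z-score transform of the permutation null, GC from a two-sample KS test.
"""

from dupliconevo import (
    DuplicationSimConfig,
    LandscapeSimConfig,
    PermutationConfig,
    results_table,
    run_enrichment,
    simulate_duplication_history,
    simulate_landscape,
)

landscape, _ = simulate_landscape(
    LandscapeSimConfig(
        n_chroms=8, chrom_length_bp=5_000_000, gc_block_bp=50_000,
        sine_gc_coupling=5.0, seed=11,
    )
)
history = simulate_duplication_history(
    landscape,
    DuplicationSimConfig(
        n_blocks=80, block_size_range_kbp=(20, 20),
        donor_enrichment_E=1.5, junction_alu_prob=0.0, seed=12,
    ),
)
results = run_enrichment(
    landscape,
    {"donors": history["donors"]},
    PermutationConfig(n_permutations=2000, seed=13),
)
print(results_table(results).to_string(index=False, float_format=lambda x: f"{x:.4g}"))
print(
    "\nPlanted SINE enrichment was 1.5x; the SINE row's E should be close to"
    " it, GC is mildly enriched (donors favour high-GC blocks), LINE is null."
)
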