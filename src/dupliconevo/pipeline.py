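"""Seeded end-to-end runs: simulate -> enrich -> junctions -> selection ->
phylogeny -> timing, with a JSON run-manifest for reproducibility.

The pipeline is a convenience wrapper over the library modules; every
stage is importable and usable on its own. All randomness flows from the
single run seed through named substreams, so re-running an identical
configuration reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .dnds import NeiGojoboriConfig, group_selection_scan
from .enrichment import PermutationConfig, results_table, run_enrichment
from .junctions import boundary_summary, classify_boundary, deletion_summary
from .phylo import DEFAULT_CALIBRATIONS_MYA, bootstrap_support, calibrate_rate, duplication_time, k2p_distance
from .simulate import (
    CodonSimConfig,
    DuplicationSimConfig,
    LandscapeSimConfig,
    simulate_codon_family,
    simulate_duplication_history,
    simulate_landscape,
)

DEMO_CONFIG = {
    "landscape.n_chroms": 2,
    "landscape.chrom_length_bp": 1_000_000,
    "landscape.gc_block_bp": 20_000,
    "landscape.sine_gc_coupling": 5.0,
    "duplication.n_blocks": 20,
    "duplication.block_size_kbp": 10.0,
    "duplication.donor_enrichment_E": 1.5,
    "enrich.n_permutations": 500,
    "codons.n_codons": 200,
    "codons.branch_length": 0.1,
    "codons.omega.HSA": 3.0,
    "codons.omega.OWM": 0.2,
    "phylo.bootstrap_replicates": 200,
}


def parse_config(path) -> dict:
    """Plain-text ``key = value`` configuration, '#' comments allowed."""
    cfg: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (t.strip() for t in line.split("=", 1))
            try:
                cfg[key] = json.loads(val)
            except json.JSONDecodeError:
                cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir, seed: int = 0) -> dict:
    """Run the requested stages in dependency order; returns the manifest."""
    cfg = dict(DEMO_CONFIG)
    cfg.update(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    sub = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(
            ("landscape", "duplication", "enrich", "codons", "phylo"), ss.spawn(5)
        )
    }
    manifest: dict = {
        "tool_version": __version__,
        "seed": seed,
        "substream_seeds": sub,
        "config": {k: v for k, v in cfg.items()},
        "stages": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(outputs: dict):
            manifest["stages"][name] = {
                "wall_time_s": round(time.perf_counter() - t0, 3),
                "outputs": {
                    k: {"path": str(p), "sha256": _sha256(Path(p))}
                    for k, p in outputs.items()
                },
            }

        return done

    # simulate
    done = stage("simulate")
    land_cfg = LandscapeSimConfig(
        n_chroms=int(cfg["landscape.n_chroms"]),
        chrom_length_bp=int(cfg["landscape.chrom_length_bp"]),
        gc_block_bp=int(cfg["landscape.gc_block_bp"]),
        sine_gc_coupling=float(cfg["landscape.sine_gc_coupling"]),
        seed=sub["landscape"],
    )
    landscape, _ = simulate_landscape(land_cfg)
    size_kbp = float(cfg["duplication.block_size_kbp"])
    dup_cfg = DuplicationSimConfig(
        n_blocks=int(cfg["duplication.n_blocks"]),
        block_size_range_kbp=(size_kbp, size_kbp),
        donor_enrichment_E=float(cfg["duplication.donor_enrichment_E"]),
        seed=sub["duplication"],
    )
    history = simulate_duplication_history(landscape, dup_cfg)
    donors_bed = out / "donors.bed"
    from .intervals import write_bed

    write_bed(history["donors"], donors_bed)
    done({"donors_bed": donors_bed})

    # enrichment
    done = stage("enrich")
    enr = run_enrichment(
        landscape,
        {"donors": history["donors"]},
        PermutationConfig(
            n_permutations=int(cfg["enrich.n_permutations"]), seed=sub["enrich"]
        ),
    )
    enr_path = out / "enrichment.tsv"
    results_table(enr).to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
    done({"enrichment_table": enr_path})

    # junctions
    done = stage("junctions")
    calls = [
        classify_boundary(j["chrom"], j["breakpoint"], landscape.repeats)
        for j in history["junctions"]
    ]
    jn = boundary_summary(calls)
    jn.update({f"deletion_{k}": v for k, v in deletion_summary(history["pre_integration"]).items()})
    jn_path = out / "junctions.json"
    jn_path.write_text(json.dumps(jn, indent=2, default=float))
    done({"junction_summary": jn_path})

    # selection
    done = stage("dnds")
    omegas = {
        k.split(".")[-1]: float(v) for k, v in cfg.items() if k.startswith("codons.omega.")
    }
    codon_cfg = CodonSimConfig(
        group_sizes={g: 3 for g in omegas},
        omega_per_group=omegas,
        n_codons=int(cfg["codons.n_codons"]),
        branch_length=float(cfg["codons.branch_length"]),
        seed=sub["codons"],
    )
    aln, _ = simulate_codon_family(codon_cfg)
    scan = group_selection_scan(aln, NeiGojoboriConfig())
    scan_path = out / "selection_scan.tsv"
    scan.to_csv(scan_path, sep="\t", index=False, float_format="%.6g")
    done({"selection_scan": scan_path})

    # phylogeny + timing
    done = stage("phylo")
    tree = bootstrap_support(
        aln.sequences,
        n_replicates=int(cfg["phylo.bootstrap_replicates"]),
        seed=sub["phylo"],
    )
    tree_path = out / "tree.nwk"
    tree_path.write_text(tree.newick(with_supports=True) + "\n")
    # date the deepest between-group pair with the deep-split calibration
    labels = [n for n, _ in aln.sequences]
    k_pairs = [
        k2p_distance(aln.sequences[i][1], aln.sequences[j][1]).K
        for i in range(len(labels))
        for j in range(i + 1, len(labels))
        if aln.group[labels[i]] != aln.group[labels[j]]
    ]
    timing = {}
    if k_pairs:
        K_deep = max(k_pairs)
        T_cal = DEFAULT_CALIBRATIONS_MYA["owm_nwm_split"][0]
        rate = calibrate_rate(K_deep, T_cal)
        timing = {
            "calibration_T_mya": T_cal,
            "rate_per_site_per_mya": rate,
            "shallowest_pair_T_mya": duplication_time(min(k_pairs), rate),
        }
    timing_path = out / "timing.json"
    timing_path.write_text(json.dumps(timing, indent=2))
    done({"tree": tree_path, "timing": timing_path})

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
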