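"""Synthetic data with known ground truth for every pipeline stage.

Three generators: ``simulate_landscape`` builds a repeat-annotated genome
with blockwise GC heterogeneity and (optionally GC-coupled) SINE/LINE
densities; ``simulate_duplication_history`` plants duplication donors with
a known SINE enrichment coefficient, junction Alus with known probability,
and pre-integration deletions with a known lognormal size distribution;
``simulate_codon_family`` evolves codon paralog families under per-group
omega with transition/transversion bias kappa. Every generator is
deterministic under its seed and returns a truth record holding the
planted parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dnds import BASES, GENETIC_CODE, SENSE_CODONS, CodonAlignment, is_transition
from .intervals import (
    GenomeLandscape,
    GenomicInterval,
    RegionSet,
    RepeatAnnotation,
    allowed_space,
    merge_intervals,
)
from .junctions import (
    PreIntegrationRecord,
    load_clone_screen_table,
    load_pre_integration_table,
)
from .phylo import TreeNode


# ---------------------------------------------------------------------------
# Genome landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeSimConfig:
    """Desk-scale genome landscape parameters.

    Densities are elements per Mbp; defaults approximate the euchromatic
    human genome (Alu-class SINEs ~350/Mbp, L1-class LINEs ~150/Mbp, mean
    GC ~0.41 with isochore-like blockwise spread). ``sine_gc_coupling`` is
    an odds multiplier for SINE placement in blocks whose GC is above the
    genome median; 1.0 means no coupling.
    """

    n_chroms: int = 4
    chrom_length_bp: int = 3_000_000
    gc_block_bp: int = 50_000
    gc_base: float = 0.41
    gc_block_sd: float = 0.05
    sine_density: float = 350.0
    line_density: float = 150.0
    ltr_density: float = 85.0
    sine_len: int = 300
    line_len: int = 1_000  # most genomic L1 copies are heavily 5'-truncated
    ltr_len: int = 500
    sine_gc_coupling: float = 1.0
    exclusion_fraction: float = 0.08
    min_element_gap: int = 0  # elements may not overlap by more than this
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.gc_base < 1:
            raise ValueError("gc_base must be in (0,1)")
        if min(self.sine_density, self.line_density, self.ltr_density) < 0:
            raise ValueError("densities must be >= 0")
        if not 0 <= self.exclusion_fraction < 1:
            raise ValueError("exclusion_fraction must be in [0,1)")
        if self.chrom_length_bp % self.gc_block_bp:
            raise ValueError("chrom_length_bp must be a multiple of gc_block_bp")


def simulate_landscape(config: LandscapeSimConfig) -> tuple[GenomeLandscape, dict]:
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length_bp for c in chroms}
    n_blocks = config.chrom_length_bp // config.gc_block_bp

    gc_track: dict[str, np.ndarray] = {}
    for c in chroms:
        gc = rng.normal(config.gc_base, config.gc_block_sd, size=n_blocks)
        gc_track[c] = np.clip(gc, 0.05, 0.95)
    all_gc = np.concatenate([gc_track[c] for c in chroms])
    gc_median = float(np.median(all_gc))

    # per-block SINE intensity, normalised so the genome-wide density is kept
    coupling = config.sine_gc_coupling
    weights = {c: np.where(gc_track[c] > gc_median, coupling, 1.0) for c in chroms}
    mean_w = float(np.mean(np.concatenate([weights[c] for c in chroms])))
    sine_intensity = {c: config.sine_density * weights[c] / mean_w for c in chroms}

    repeats: list[RepeatAnnotation] = []
    truth_counts: dict[str, dict] = {}
    for c in chroms:
        placed: list[tuple[int, int, str, str]] = []
        for cls, dens, length, fam in (
            ("SINE", None, config.sine_len, "AluS"),
            ("LINE", config.line_density, config.line_len, "L1"),
            ("LTR", config.ltr_density, config.ltr_len, "ERV"),
        ):
            if cls == "SINE":
                lam = sine_intensity[c] * config.gc_block_bp / 1e6
            else:
                lam = np.full(n_blocks, dens * config.gc_block_bp / 1e6)
            counts = rng.poisson(lam)
            for b in range(n_blocks):
                if not counts[b]:
                    continue
                starts = rng.integers(
                    b * config.gc_block_bp, (b + 1) * config.gc_block_bp, size=counts[b]
                )
                for s in starts:
                    e = min(int(s) + length, sizes[c])
                    if e - int(s) >= 1:
                        placed.append((int(s), e, cls, fam))
        # Matérn-style thinning: drop elements overlapping a kept one by
        # more than the configured tolerance
        placed.sort()
        kept: list[tuple[int, int, str, str]] = []
        last_end = -1
        for s, e, cls, fam in placed:
            if s >= last_end - config.min_element_gap:
                kept.append((s, e, cls, fam))
                last_end = e
        for s, e, cls, fam in kept:
            repeats.append(
                RepeatAnnotation(GenomicInterval(c, s, e), repeat_class=cls, family=fam)
            )
        truth_counts[c] = {"n_placed": len(placed), "n_kept": len(kept)}

    # exclusion mask: a few uniformly placed segments per chromosome
    mask_ivs: list[GenomicInterval] = []
    n_seg = 4
    seg_len = int(config.exclusion_fraction * config.chrom_length_bp / n_seg)
    for c in chroms:
        if seg_len < 1:
            break
        starts = rng.integers(0, config.chrom_length_bp - seg_len, size=n_seg)
        for s in starts:
            mask_ivs.append(GenomicInterval(c, int(s), int(s) + seg_len))
    exclusion = merge_intervals(RegionSet(mask_ivs)) if mask_ivs else RegionSet()

    landscape = GenomeLandscape(
        chrom_sizes=sizes,
        repeats=repeats,
        gc_track=gc_track,
        gc_window=config.gc_block_bp,
        exclusion_mask=exclusion,
    )
    truth = {
        "config": config,
        "gc_median": gc_median,
        "sine_intensity_per_mbp": sine_intensity,
        "counts": truth_counts,
    }
    return landscape, truth


# ---------------------------------------------------------------------------
# Duplication history
# ---------------------------------------------------------------------------

@dataclass
class DuplicationSimConfig:
    """Duplication-block history parameters.

    ``donor_enrichment_E`` is the planted enrichment coefficient: the
    expected SINE density at donor positions divided by the allowed-space
    average, the quantity the permutation engine estimates.
    ``block_size_range_kbp`` defaults to the observed span of real
    duplication blocks; desk-scale runs pass a smaller range.
    """

    n_blocks: int = 14
    block_size_range_kbp: tuple[float, float] = (150.02, 379.3)
    donor_enrichment_E: float = 1.0
    junction_alu_prob: float = 9.0 / 14.0
    deletion_lognormal: tuple[float, float] = (math.log(5.8), 1.0)  # (mu, sigma) kbp
    p_no_deletion: float = 1.0 / 13.0
    junction_window_bp: int = 50
    alu_len: int = 300
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.junction_alu_prob <= 1:
            raise ValueError("junction_alu_prob must be in [0,1]")
        if self.block_size_range_kbp[0] <= 0:
            raise ValueError("block sizes must be > 0")
        if self.donor_enrichment_E <= 0:
            raise ValueError("donor_enrichment_E must be > 0")


def _block_eligible_positions(
    landscape: GenomeLandscape, L: int
) -> tuple[list[tuple[str, int, int, int]], np.ndarray, np.ndarray]:
    """Placement slots entirely inside one GC block and one allowed segment.

    Returns (slots, eligible position counts, block GC values); each slot is
    (chrom, slot_start, n_positions, block_index_within_chrom).
    """
    w = landscape.gc_window
    allowed = allowed_space(landscape)
    slots: list[tuple[str, int, int, int]] = []
    gcs: list[float] = []
    for iv in allowed:
        b0, b1 = iv.start // w, (iv.end - 1) // w
        for b in range(b0, b1 + 1):
            s = max(iv.start, b * w)
            e = min(iv.end, (b + 1) * w)
            n_pos = e - s - L + 1
            if n_pos > 0:
                slots.append((iv.chrom, s, n_pos, b))
                gcs.append(float(landscape.gc_track[iv.chrom][b]))
    if not slots:
        raise ValueError(f"no allowed GC block can hold a region of length {L}")
    return slots, np.array([t[2] for t in slots], dtype=np.int64), np.array(gcs)


def _realized_block_density(landscape: GenomeLandscape, cls: str) -> dict[tuple[str, int], float]:
    """Realized per-(chrom, block) element density (per bp), by element start."""
    w = landscape.gc_window
    counts: dict[tuple[str, int], int] = {}
    for rep in landscape.repeats:
        if rep.repeat_class != cls:
            continue
        key = (rep.interval.chrom, rep.interval.start // w)
        counts[key] = counts.get(key, 0) + 1
    return {k: v / w for k, v in counts.items()}


def simulate_duplication_history(
    landscape: GenomeLandscape,
    config: DuplicationSimConfig,
) -> dict:
    """Plant donors, acceptor junctions, and pre-integration deletions.

    Donors are placed so that the expected SINE density at donor positions
    is ``donor_enrichment_E`` times the allowed-space average, by mixing
    uniform placement with placement restricted to above-median-GC blocks
    (mixing weight solved from the realized per-block densities). Each of
    the ``n_blocks`` insertions contributes two junctions; an AluS element
    is planted overlapping the +/-50 bp junction window with probability
    ``junction_alu_prob``. Planted junction repeats are appended to the
    landscape's annotation.
    """
    rng = np.random.default_rng(config.seed)
    lo_bp = int(config.block_size_range_kbp[0] * 1000)
    hi_bp = int(config.block_size_range_kbp[1] * 1000)
    L_ref = (lo_bp + hi_bp) // 2
    slots, n_pos, gcs = _block_eligible_positions(landscape, L_ref)
    dens_map = _realized_block_density(landscape, "SINE")
    slot_dens = np.array(
        [dens_map.get((c, b), 0.0) for c, _, _, b in slots], dtype=float
    )
    gc_median = float(np.median(np.concatenate(list(landscape.gc_track.values()))))
    high = gcs > gc_median
    lam_all = float(np.average(slot_dens, weights=n_pos))
    if not high.any() or lam_all <= 0:
        raise ValueError("landscape has no high-GC blocks or no SINEs")
    lam_high = float(np.average(slot_dens[high], weights=n_pos[high]))
    E = config.donor_enrichment_E
    if abs(E - 1.0) < 1e-12:
        alpha = 0.0
    else:
        if lam_high <= lam_all:
            raise ValueError("cannot plant enrichment: high-GC blocks not SINE-denser")
        alpha = (E - 1.0) * lam_all / (lam_high - lam_all)
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(
                f"requested enrichment E={E} infeasible (needs mixing weight {alpha:.2f})"
            )

    cum_all = np.cumsum(n_pos)
    cum_high = np.cumsum(np.where(high, n_pos, 0))

    def draw_slot(use_high: bool) -> tuple[str, int]:
        cum = cum_high if use_high else cum_all
        u = int(rng.integers(cum[-1]))
        k = int(np.searchsorted(cum, u, side="right"))
        prev = int(cum[k - 1]) if k else 0
        chrom, s, _, _ = slots[k]
        return chrom, s + (u - prev)

    donors: list[GenomicInterval] = []
    for i in range(config.n_blocks):
        use_high = bool(rng.random() < alpha)
        chrom, start = draw_slot(use_high)
        donors.append(
            GenomicInterval(chrom, start, start + L_ref, name=f"donor{i}", role="donor")
        )

    # insertions: acceptor junctions + pre-integration deletions. On the
    # derived genome the inserted block separates the two transition
    # junctions by its own length, so their +/-50 bp windows are disjoint.
    # Insertion points are drawn in unique sequence: both junction windows
    # must be free of pre-existing SINEs, so that the SINE-positive rate at
    # junctions is the planted probability and nothing else.
    allowed = allowed_space(landscape)
    allowed_list = [iv for iv in allowed if len(iv) > L_ref]
    if not allowed_list:
        raise ValueError("no allowed segment can hold an insertion")
    alens = np.array([len(iv) - L_ref for iv in allowed_list], dtype=np.int64)
    acum = np.cumsum(alens)
    sine_bounds: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in landscape.chrom_sizes:
        ivs = sorted(
            (r.interval.start, r.interval.end)
            for r in landscape.repeats
            if r.repeat_class == "SINE" and r.interval.chrom == c
        )
        arr = np.asarray(ivs, dtype=np.int64).reshape(-1, 2)
        ends_cummax = np.maximum.accumulate(arr[:, 1]) if len(arr) else arr[:, 1]
        sine_bounds[c] = (arr[:, 0], ends_cummax)

    def window_clear(chrom: str, bp: int) -> bool:
        starts, ends_cummax = sine_bounds[chrom]
        lo, hi = bp - config.junction_window_bp, bp + config.junction_window_bp
        k = np.searchsorted(starts, hi, side="right")
        return k == 0 or ends_cummax[k - 1] <= lo

    junctions: list[dict] = []
    records: list[PreIntegrationRecord] = []
    planted_repeats: list[RepeatAnnotation] = []
    mu, sigma = config.deletion_lognormal
    for i in range(config.n_blocks):
        for _attempt in range(1000):
            u = int(rng.integers(acum[-1]))
            k = int(np.searchsorted(acum, u, side="right"))
            prev = int(acum[k - 1]) if k else 0
            seg = allowed_list[k]
            point = seg.start + (u - prev)
            if window_clear(seg.chrom, point) and window_clear(seg.chrom, point + L_ref):
                break
        else:
            raise ValueError("could not find a SINE-free insertion site")
        for side, bp in (("left", point), ("right", point + L_ref)):
            planted = bool(rng.random() < config.junction_alu_prob)
            if planted:
                w = config.junction_window_bp
                s = int(rng.integers(bp - w - config.alu_len + 1, bp + w + 1))
                s = max(s, 0)
                rep = RepeatAnnotation(
                    GenomicInterval(seg.chrom, s, s + config.alu_len),
                    repeat_class="SINE",
                    family="AluS",
                )
                planted_repeats.append(rep)
            junctions.append(
                {"chrom": seg.chrom, "breakpoint": bp, "side": side,
                 "insertion": i, "alu_planted": planted}
            )
        if rng.random() < config.p_no_deletion:
            deletion_kbp = 0.0
        else:
            deletion_kbp = round(float(rng.lognormal(mu, sigma)), 1)
        records.append(
            PreIntegrationRecord(
                species="synthetic",
                chrom=seg.chrom,
                anchor_start=point,
                anchor_end=point + int(round(deletion_kbp * 1000)),
                deletion_kbp=deletion_kbp,
                insertion_kbp=L_ref / 1000.0,
            )
        )
    landscape.repeats.extend(planted_repeats)

    truth = {
        "config": config,
        "alpha": alpha,
        "lambda_all": lam_all,
        "lambda_high": lam_high,
        "target_E": E,
        "n_alu_planted": sum(j["alu_planted"] for j in junctions),
        "n_junctions": len(junctions),
    }
    return {
        "donors": RegionSet(donors, role="donor"),
        "junctions": junctions,
        "pre_integration": records,
        "planted_repeats": planted_repeats,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# Codon families
# ---------------------------------------------------------------------------

@dataclass
class CodonSimConfig:
    """Codon-family evolution parameters.

    Each group evolves star-like from a shared root sequence: every member
    accumulates ``branch_length`` expected substitutions per codon site on
    its own lineage under the group's omega. One branch-length unit is one
    expected substitution per codon, averaged over the 61 sense codons
    under the configured (omega, kappa).
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {"HSA": 3, "OWM": 3})
    omega_per_group: dict[str, float] = field(default_factory=lambda: {"HSA": 1.0, "OWM": 1.0})
    kappa: float = 2.0
    n_codons: int = 300
    branch_length: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        for g, w in self.omega_per_group.items():
            if w <= 0:
                raise ValueError(f"omega for group {g} must be > 0")


def _rate_table(omega: float, kappa: float) -> dict[str, tuple[list[str], np.ndarray, float]]:
    """codon -> (neighbors, move rates, total rate), stop moves excluded."""
    table: dict[str, tuple[list[str], np.ndarray, float]] = {}
    for codon in SENSE_CODONS:
        aa = GENETIC_CODE[codon]
        neigh: list[str] = []
        rates: list[float] = []
        for i in range(3):
            for b in BASES:
                if b == codon[i]:
                    continue
                alt = codon[:i] + b + codon[i + 1 :]
                if GENETIC_CODE[alt] == "*":
                    continue
                r = kappa if is_transition(codon[i], b) else 1.0
                if GENETIC_CODE[alt] != aa:
                    r *= omega
                neigh.append(alt)
                rates.append(r)
        arr = np.asarray(rates)
        table[codon] = (neigh, arr, float(arr.sum()))
    return table


def _evolve_sequence(
    codons: list[str],
    t: float,
    table: dict[str, tuple[list[str], np.ndarray, float]],
    scale: float,
    rng: np.random.Generator,
) -> tuple[list[str], int]:
    out = []
    n_subs = 0
    for c in codons:
        cur = c
        time = 0.0
        while True:
            _, rates, total = table[cur]
            wait = rng.exponential(1.0 / (scale * total))
            time += wait
            if time > t:
                break
            neigh, rates, total = table[cur]
            k = int(rng.choice(len(neigh), p=rates / total))
            cur = neigh[k]
            n_subs += 1
        out.append(cur)
    return out, n_subs


def simulate_codon_family(config: CodonSimConfig) -> tuple[CodonAlignment, dict]:
    """Evolve a codon paralog family; never emits stop codons."""
    rng = np.random.default_rng(config.seed)
    root = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=config.n_codons)]
    sequences: list[tuple[str, str]] = []
    group_map: dict[str, str] = {}
    total_subs: dict[str, int] = {}
    for gname in sorted(config.group_sizes):
        k = config.group_sizes[gname]
        omega = config.omega_per_group.get(gname, 1.0)
        table = _rate_table(omega, config.kappa)
        mean_rate = float(np.mean([table[c][2] for c in SENSE_CODONS]))
        scale = 1.0 / mean_rate  # one unit branch = one expected sub per codon
        subs = 0
        for m in range(k):
            codons, ns = _evolve_sequence(root, config.branch_length, table, scale, rng)
            label = f"{gname}_{m + 1}"
            sequences.append((label, "".join(codons)))
            group_map[label] = gname
            subs += ns
        total_subs[gname] = subs
    aln = CodonAlignment(sequences=sequences, group=group_map)
    truth = {
        "config": config,
        "root": "".join(root),
        "substitutions_per_group": total_subs,
    }
    return aln, truth


# ---------------------------------------------------------------------------
# Nucleotide alignments on a fixed tree (for distance/bootstrap checks)
# ---------------------------------------------------------------------------

def simulate_nucleotide_alignment(
    tree: TreeNode,
    n_sites: int,
    kappa: float = 2.0,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """Evolve nucleotide sequences down a tree under the K2P model.

    Branch lengths are expected substitutions per site. Returns
    (label, sequence) pairs in leaf order.
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    base_idx = {b: i for i, b in enumerate("ACGT")}
    # transition partner index for each base: A<->G, C<->T
    ts_partner = np.array([base_idx["G"], base_idx["T"], base_idx["A"], base_idx["C"]])

    def p_matrix(t: float) -> np.ndarray:
        e1 = math.exp(-4.0 * beta * t)
        e2 = math.exp(-2.0 * (alpha + beta) * t)
        p_same = 0.25 + 0.25 * e1 + 0.5 * e2
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        p_tv = 0.25 - 0.25 * e1
        P = np.full((4, 4), p_tv)
        for i in range(4):
            P[i, i] = p_same
            P[i, ts_partner[i]] = p_ts
        return P

    root_states = rng.integers(4, size=n_sites)
    out: list[tuple[str, str]] = []

    def walk(node: TreeNode, states: np.ndarray) -> None:
        if node.is_leaf():
            out.append((node.name, "".join("ACGT"[s] for s in states)))
            return
        for child, blen in node.children:
            P = p_matrix(blen)
            u = rng.random(n_sites)
            cdf = np.cumsum(P, axis=1)
            child_states = (u[:, None] > cdf[states]).sum(axis=1)
            walk(child, child_states)

    walk(tree, root_states)
    return out


def table_fixtures() -> dict:
    """The packaged, checksummed summary-table fixtures."""
    return {
        "clone_screen": load_clone_screen_table(),
        "pre_integration": load_pre_integration_table(),
        "pre_integration_all_rows": load_pre_integration_table(include_flagged=True),
    }
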