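"""Modified Nei-Gojobori dN/dS estimation and the D = dN - dS Z-test.

The estimator counts, for every codon, how many of its three positions are
potentially synonymous versus nonsynonymous (weighting single-base changes
by a transition/transversion ratio R; R = 0.5 recovers the original
unweighted method), and classifies observed codon differences by averaging
over all orderings of single-base steps, excluding pathways through stop
codons. Positive selection in a pair of paralogs is tested one-tailed with
Z = (dN - dS) / sigma, sigma from the analytic large-sample variances (a
codon-bootstrap sigma is available by flag). ``group_selection_scan``
applies the test per paralog group and per exon of a partitioned codon
alignment, emitting both a pooled-count Z and the mean of pairwise Z.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import stats

BASES = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _codon_table() -> dict[str, str]:
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code

GENETIC_CODE = _codon_table()
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))


def is_transition(b1: str, b2: str) -> bool:
    return (b1, b2) in _TRANSITIONS


@dataclass
class NeiGojoboriConfig:
    """Estimator knobs.

    ``ts_tv_ratio_R`` weights potential sites (0.5 = original unweighted
    method). ``correction`` is the multiple-hit correction applied to the
    proportions: ``proportion`` (none) or ``jukes_cantor``.
    """

    ts_tv_ratio_R: float = 0.5
    correction: str = "jukes_cantor"
    gap_handling: str = "pairwise_deletion"
    direction: str = "positive"  # alternative dN > dS; "purifying" tests dS > dN
    sigma: str = "analytic"  # or "bootstrap"
    bootstrap_reps: int = 1000
    bootstrap_seed: int | None = None

    def __post_init__(self) -> None:
        if self.ts_tv_ratio_R <= 0:
            raise ValueError("ts_tv_ratio_R must be > 0")
        if self.correction not in ("proportion", "jukes_cantor"):
            raise ValueError("correction must be 'proportion' or 'jukes_cantor'")


@dataclass
class PairwiseDnDs:
    pair: tuple[str, str]
    n_codons: int
    N_sites: float
    S_sites: float
    Nd: float
    Sd: float
    dN: float
    dS: float
    var_dN: float
    var_dS: float
    D: float
    Z: float
    p_one_tailed: float
    saturated: bool = False
    skipped_codons: int = 0


@lru_cache(maxsize=None)
def potential_sites(codon: str, R: float = 0.5) -> tuple[float, float]:
    """Potential (nonsynonymous, synonymous) site counts of one codon.

    Each position contributes one site, apportioned between synonymous and
    nonsynonymous according to the weighted fractions of its single-base
    changes; transitions weigh R/(R+1), each transversion (1-R/(R+1))/2,
    renormalized per position after excluding changes to stop codons.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    aa = GENETIC_CODE[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no potential sites")
    w_ts = R / (R + 1.0)
    w_tv = (1.0 - w_ts) / 2.0
    n_syn = 0.0
    for i in range(3):
        wsum = 0.0
        wsyn = 0.0
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if GENETIC_CODE[alt] == "*":
                continue
            w = w_ts if is_transition(codon[i], b) else w_tv
            wsum += w
            if GENETIC_CODE[alt] == aa:
                wsyn += w
        if wsum > 0:
            n_syn += wsyn / wsum
    return 3.0 - n_syn, n_syn


@lru_cache(maxsize=None)
def pairwise_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) difference counts.

    Multi-difference codon pairs are averaged over all orderings of single
    steps, excluding pathways that pass through a stop codon. Raises if no
    stop-free pathway exists (callers skip and flag such codons).
    """
    c1, c2 = codon1.upper(), codon2.upper()
    for c in (c1, c2):
        if len(c) != 3 or any(b not in BASES for b in c):
            raise ValueError(f"invalid codon {c!r}")
        if GENETIC_CODE[c] == "*":
            raise ValueError(f"stop codon {c} in comparison")
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    total_n = total_s = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        path_n = path_s = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if GENETIC_CODE[nxt] == "*":
                ok = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                path_s += 1.0
            else:
                path_n += 1.0
            cur = nxt
        if ok:
            total_n += path_n
            total_s += path_s
            n_paths += 1
    if n_paths == 0:
        raise ValueError(f"no stop-free pathway between {c1} and {c2}")
    return total_n / n_paths, total_s / n_paths


def _usable_codons(seq1: str, seq2: str) -> tuple[list[tuple[str, str]], int]:
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    if len(seq1) % 3:
        raise ValueError("aligned length must be divisible by 3")
    used: list[tuple[str, str]] = []
    skipped = 0
    for i in range(0, len(seq1), 3):
        a, b = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if any(ch not in BASES for ch in a + b):
            skipped += 1
            continue
        if GENETIC_CODE[a] == "*" or GENETIC_CODE[b] == "*":
            skipped += 1
            continue
        used.append((a, b))
    return used, skipped


def _correct(p: float, n: float, correction: str) -> tuple[float, float]:
    """(distance, variance) for a proportion p over n sites."""
    if n <= 0:
        return float("nan"), float("nan")
    if correction == "proportion":
        return p, p * (1.0 - p) / n
    if p >= 0.75:
        return float("nan"), float("nan")  # saturated under Jukes-Cantor
    d = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    var = p * (1.0 - p) / (n * (1.0 - 4.0 * p / 3.0) ** 2)
    return d, var


def dn_ds(
    seq1: str,
    seq2: str,
    config: NeiGojoboriConfig | None = None,
    pair: tuple[str, str] = ("seq1", "seq2"),
) -> PairwiseDnDs:
    """Pairwise dN/dS with the D = dN - dS one-tailed Z-test."""
    cfg = config or NeiGojoboriConfig()
    used, skipped = _usable_codons(seq1, seq2)
    if not used:
        raise ValueError("no comparable codons after gap/ambiguity handling")
    N, S, Nd, Sd = _count_pair(used, cfg.ts_tv_ratio_R)
    dN, var_dN = _correct(Nd / N, N, cfg.correction)
    dS, var_dS = _correct(Sd / S, S, cfg.correction)
    saturated = math.isnan(dS) or math.isnan(dN)
    if saturated:
        D = Z = p = float("nan")
    else:
        D = dN - dS
        if cfg.sigma == "bootstrap":
            sigma = _bootstrap_sigma(used, cfg)
        else:
            sigma = math.sqrt(var_dN + var_dS)
        if sigma > 0:
            Z = D / sigma
        else:
            Z = 0.0
        p = float(stats.norm.sf(Z) if cfg.direction == "positive" else stats.norm.cdf(Z))
    return PairwiseDnDs(
        pair=pair,
        n_codons=len(used),
        N_sites=N,
        S_sites=S,
        Nd=Nd,
        Sd=Sd,
        dN=dN,
        dS=dS,
        var_dN=var_dN,
        var_dS=var_dS,
        D=D,
        Z=Z,
        p_one_tailed=p,
        saturated=saturated,
        skipped_codons=skipped,
    )


def _count_pair(used: list[tuple[str, str]], R: float) -> tuple[float, float, float, float]:
    N1 = S1 = N2 = S2 = Nd = Sd = 0.0
    for a, b in used:
        n1, s1 = potential_sites(a, R)
        n2, s2 = potential_sites(b, R)
        N1 += n1
        S1 += s1
        N2 += n2
        S2 += s2
        try:
            nd, sd = pairwise_differences(a, b)
        except ValueError:
            continue  # all pathways through stops: codon flagged and skipped
        Nd += nd
        Sd += sd
    return (N1 + N2) / 2.0, (S1 + S2) / 2.0, Nd, Sd


def _bootstrap_sigma(used: list[tuple[str, str]], cfg: NeiGojoboriConfig) -> float:
    rng = np.random.default_rng(cfg.bootstrap_seed)
    n = len(used)
    Ds = []
    for _ in range(cfg.bootstrap_reps):
        idx = rng.integers(n, size=n)
        sample = [used[i] for i in idx]
        N, S, Nd, Sd = _count_pair(sample, cfg.ts_tv_ratio_R)
        dN, _ = _correct(Nd / N, N, cfg.correction)
        dS, _ = _correct(Sd / S, S, cfg.correction)
        if not (math.isnan(dN) or math.isnan(dS)):
            Ds.append(dN - dS)
    return float(np.std(Ds, ddof=1)) if len(Ds) > 1 else 0.0


# ---------------------------------------------------------------------------
# Codon alignments and the per-group / per-exon scan
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame aligned codon sequences with group and exon metadata.

    ``exon_partition`` maps exon labels to half-open codon index ranges.
    """

    sequences: list[tuple[str, str]]
    group: dict[str, str] = field(default_factory=dict)
    exon_partition: list[tuple[str, tuple[int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("all sequences must have equal aligned length")
        L = lengths.pop() if lengths else 0
        if L % 3:
            raise ValueError("aligned length must be divisible by 3")
        self.length_codons = L // 3
        used = [False] * self.length_codons
        for label, (a, b) in self.exon_partition:
            if not (0 <= a < b <= self.length_codons):
                raise ValueError(f"exon {label!r} range ({a},{b}) out of bounds")
            for i in range(a, b):
                if used[i]:
                    raise ValueError(f"exon {label!r} overlaps another exon")
                used[i] = True
        for name, seq in self.sequences:
            for i in range(0, max(L - 3, 0), 3):  # internal codons only
                codon = seq[i : i + 3].upper()
                if all(b in BASES for b in codon) and GENETIC_CODE[codon] == "*":
                    raise ValueError(f"internal stop codon in {name} at codon {i // 3}")

    def labels(self) -> list[str]:
        return [name for name, _ in self.sequences]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for name, _ in self.sequences:
            out.setdefault(self.group.get(name, "ungrouped"), []).append(name)
        return out

    def slice_codons(self, a: int, b: int) -> dict[str, str]:
        return {name: seq[3 * a : 3 * b] for name, seq in self.sequences}


def read_codon_alignment(fasta_path, group_tsv=None, exon_tsv=None) -> CodonAlignment:
    """Load an aligned multi-FASTA plus optional group / exon tables.

    The group table is two-column ``label<TAB>group``; the exon table is
    three-column ``exon<TAB>start_codon<TAB>end_codon`` (half-open).
    """
    from Bio import SeqIO

    seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(fasta_path), "fasta")]
    group: dict[str, str] = {}
    if group_tsv:
        with open(group_tsv) as fh:
            for line in fh:
                if line.strip():
                    label, tag = line.split()[:2]
                    group[label] = tag
    exons: list[tuple[str, tuple[int, int]]] = []
    if exon_tsv:
        with open(exon_tsv) as fh:
            for line in fh:
                if line.strip():
                    label, a, b = line.split()[:3]
                    exons.append((label, (int(a), int(b))))
    return CodonAlignment(sequences=seqs, group=group, exon_partition=exons)


def group_selection_scan(
    alignment: CodonAlignment,
    config: NeiGojoboriConfig | None = None,
    exclude_exons: set[str] = frozenset({"exon 8"}),
):
    """Per (group x exon) positive-selection summary of pairwise D tests.

    For each paralog group with >= 2 members and each non-excluded exon,
    all within-group pairwise dN/dS comparisons are computed on the exon's
    codon range. Two summaries are emitted per row: a Z-test on pooled
    difference/site counts (``Z_pooled``, ``p_pooled``) and the mean of the
    pairwise Z values (``mean_Z``). Groups with fewer than two members are
    skipped.
    """
    import pandas as pd

    cfg = config or NeiGojoboriConfig()
    partition = alignment.exon_partition or [("all", (0, alignment.length_codons))]
    rows = []
    for exon_label, (a, b) in partition:
        if exon_label in exclude_exons:
            continue
        sliced = alignment.slice_codons(a, b)
        for gname, members in sorted(alignment.groups().items()):
            if len(members) < 2:
                continue
            pair_results = []
            for x, y in itertools.combinations(sorted(members), 2):
                try:
                    pair_results.append(dn_ds(sliced[x], sliced[y], cfg, pair=(x, y)))
                except ValueError:
                    continue
            usable = [r for r in pair_results if not r.saturated]
            if not usable:
                continue
            N = sum(r.N_sites for r in usable)
            S = sum(r.S_sites for r in usable)
            Nd = sum(r.Nd for r in usable)
            Sd = sum(r.Sd for r in usable)
            dN, var_dN = _correct(Nd / N, N, cfg.correction)
            dS, var_dS = _correct(Sd / S, S, cfg.correction)
            if math.isnan(dN) or math.isnan(dS):
                continue
            D = dN - dS
            sigma = math.sqrt(var_dN + var_dS)
            Z = D / sigma if sigma > 0 else 0.0
            p = float(
                stats.norm.sf(Z) if cfg.direction == "positive" else stats.norm.cdf(Z)
            )
            rows.append(
                {
                    "group": gname,
                    "exon": exon_label,
                    "n_pairs": len(usable),
                    "mean_dN": float(np.mean([r.dN for r in usable])),
                    "mean_dS": float(np.mean([r.dS for r in usable])),
                    "mean_D": float(np.mean([r.D for r in usable])),
                    "mean_Z": float(np.mean([r.Z for r in usable])),
                    "dN_pooled": dN,
                    "dS_pooled": dS,
                    "D_pooled": D,
                    "Z_pooled": Z,
                    "p_pooled": p,
                }
            )
    return pd.DataFrame(rows)
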