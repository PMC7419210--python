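"""Distance phylogenetics: K2P distances, neighbor-joining trees with
bootstrap supports, Tajima's relative rate test, and rate-calibrated
duplication timing (R = K/2T).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = "ACGT"


@dataclass
class K2PResult:
    K: float
    SE: float
    P: float  # transition proportion
    Q: float  # transversion proportion
    n_sites: int
    saturated: bool = False


def k2p_distance(seq1: str, seq2: str) -> K2PResult:
    """Kimura two-parameter distance with delta-method standard error.

    Sites where either sequence has a gap or ambiguity are excluded
    (pairwise deletion). With P and Q the transition and transversion
    proportions, K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)). A pair is flagged
    saturated when either logarithm argument is non-positive.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        n += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites after gap handling")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(float("nan"), float("nan"), P, Q, n, saturated=True)
    K = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    c1, c2 = 1.0 / w1, 1.0 / w2
    c3 = (c1 + c2) / 2.0
    var = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / n
    return K2PResult(K, math.sqrt(max(var, 0.0)), P, Q, n)


def p_distance(seq1: str, seq2: str) -> K2PResult:
    """Uncorrected proportion of differing sites (comparison baseline)."""
    r = k2p_distance(seq1, seq2)  # reuse site bookkeeping
    p = r.P + r.Q
    n = r.n_sites
    se = math.sqrt(p * (1 - p) / n) if n else float("nan")
    return K2PResult(p, se, r.P, r.Q, n)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray  # symmetric, zero diagonal
    model: str = "K2P"
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = m[np.isfinite(m)]
        if finite.size and (finite < -1e-12).any():
            raise ValueError("distances must be nonnegative")
        self.matrix = m


def build_distance_matrix(
    sequences: list[tuple[str, str]], model: str = "K2P"
) -> DistanceMatrix:
    labels = [name for name, _ in sequences]
    n = len(labels)
    m = np.zeros((n, n))
    saturated = []
    dist = k2p_distance if model == "K2P" else p_distance
    for i in range(n):
        for j in range(i + 1, n):
            r = dist(sequences[i][1], sequences[j][1])
            if r.saturated:
                saturated.append((labels[i], labels[j]))
            m[i, j] = m[j, i] = r.K
    return DistanceMatrix(labels=labels, matrix=m, model=model, saturated_pairs=saturated)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str = ""
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root for traversal.

    ``supports`` maps internal bipartitions (canonical frozensets of leaf
    labels) to bootstrap support fractions in [0, 1].
    """

    root: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)
    negative_branches_clamped: int = 0

    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial leaf bipartitions, one canonical frozenset per edge."""
        all_leaves = frozenset(self.root.leaves())
        out: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf():
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(_canonical(side, all_leaves))
                below = below | side
            return below

        walk(self.root)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic leaf-to-leaf path lengths (additivity oracle hook)."""
        labels = self.leaf_labels()
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        m = np.zeros((n, n))

        def walk(node: TreeNode, dist_to_leaves: dict[str, float]):
            # returns distances from `node` to all leaves below it
            if node.is_leaf():
                return {node.name: 0.0}
            sub = []
            for child, blen in node.children:
                d = walk(child, dist_to_leaves)
                sub.append({k: v + blen for k, v in d.items()})
            for a in range(len(sub)):
                for b in range(a + 1, len(sub)):
                    for la, da in sub[a].items():
                        for lb, db in sub[b].items():
                            m[idx[la], idx[lb]] = m[idx[lb], idx[la]] = da + db
            merged: dict[str, float] = {}
            for d in sub:
                merged.update(d)
            return merged

        walk(self.root, {})
        return DistanceMatrix(labels=labels, matrix=m, model="patristic")

    def newick(self, with_supports: bool = False) -> str:
        all_leaves = frozenset(self.root.leaves())

        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(f"{fmt(c)}:{b:.6g}" for c, b in node.children)
            label = ""
            if with_supports:
                side = frozenset(node.leaves())
                key = _canonical(side, all_leaves)
                if key in self.supports:
                    label = f"{self.supports[key]:.3g}"
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def _canonical(side: frozenset, universe: frozenset) -> frozenset:
    comp = universe - side
    if len(side) != len(comp):
        return side if len(side) < len(comp) else comp
    return side if tuple(sorted(side)) < tuple(sorted(comp)) else comp


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining with deterministic tie-breaking.

    Ties in the Q criterion resolve to the lexicographically smallest
    (label, label) pair, where an internal node carries the smallest leaf
    label beneath it. Negative branch lengths are clamped to zero and
    counted on the returned tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor-joining requires at least 3 taxa")
    if not np.all(np.isfinite(dm.matrix)):
        bad = [
            (dm.labels[i], dm.labels[j])
            for i in range(n)
            for j in range(i + 1, n)
            if not np.isfinite(dm.matrix[i, j])
        ]
        raise ValueError(f"non-finite (saturated) distances for pairs: {bad}")
    D = dm.matrix.astype(float).copy()
    nodes = [TreeNode(name=l) for l in dm.labels]
    sort_keys = list(dm.labels)  # smallest leaf label beneath each active node
    clamped = 0

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                key = (q, *sorted((sort_keys[i], sort_keys[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        bi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = D[i, j] - bi
        if bi < 0:
            clamped += 1
            bi = 0.0
        if bj < 0:
            clamped += 1
            bj = 0.0
        new = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        new_key = min(sort_keys[i], sort_keys[j])
        d_new = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        sort_keys = [sort_keys[k] for k in keep] + [new_key]

    # resolve the final 3-star with exact branch lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    b0 = (d01 + d02 - d12) / 2.0
    b1 = (d01 + d12 - d02) / 2.0
    b2 = (d02 + d12 - d01) / 2.0
    lens = []
    for b in (b0, b1, b2):
        if b < 0:
            clamped += 1
            b = 0.0
        lens.append(b)
    root = TreeNode(children=list(zip(nodes, lens)))
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch length(s) to 0")
    return PhyloTree(root=root, negative_branches_clamped=clamped)


def bootstrap_support(
    sequences: list[tuple[str, str]],
    n_replicates: int = 500,
    seed: int | None = None,
    model: str = "K2P",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement per replicate, the K2P + NJ
    pipeline is rebuilt, and each internal bipartition of the full-data
    tree receives the fraction of replicate trees containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    L = len(sequences[0][1])
    if L < 1:
        raise ValueError("alignment must have at least one column")
    labels = [name for name, _ in sequences]
    arrs = [np.frombuffer(s.upper().encode(), dtype=np.uint8) for _, s in sequences]
    full = nj_tree(build_distance_matrix(sequences, model=model))
    target = full.bipartitions()
    hits = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    n_effective = 0
    for _ in range(n_replicates):
        cols = rng.integers(L, size=L)
        boot = [
            (labels[i], arrs[i][cols].tobytes().decode()) for i in range(len(labels))
        ]
        try:
            tree = nj_tree(build_distance_matrix(boot, model=model))
        except ValueError:
            continue  # saturated replicate
        n_effective += 1
        reps = tree.bipartitions()
        for bp in target:
            if bp in reps:
                hits[bp] += 1
    if n_effective == 0:
        raise ValueError("all bootstrap replicates were saturated")
    full.supports = {bp: hits[bp] / n_effective for bp in target}
    return full


# ---------------------------------------------------------------------------
# Tajima relative rate test and duplication timing
# ---------------------------------------------------------------------------

@dataclass
class TajimaRRTResult:
    m1: int  # sites where only seqA differs from the other two
    m2: int  # sites where only seqB differs
    chi2: float
    p: float
    undefined: bool = False


def tajima_rrt(seqA: str, seqB: str, outgroup: str) -> TajimaRRTResult:
    """Tajima's relative rate test for equal rates on two ingroup lineages.

    m1 counts sites where A is the odd one out (B equals the outgroup),
    m2 where B is; under rate equality chi2 = (m1-m2)^2/(m1+m2) is
    chi-square with 1 df. With m1 + m2 = 0 the test is undefined.
    """
    if not (len(seqA) == len(seqB) == len(outgroup)):
        raise ValueError("all three sequences must be aligned to equal length")
    m1 = m2 = 0
    for a, b, o in zip(seqA.upper(), seqB.upper(), outgroup.upper()):
        if any(c not in _VALID for c in (a, b, o)):
            continue
        if a != b and b == o:
            m1 += 1
        elif a != b and a == o:
            m2 += 1
    if m1 + m2 == 0:
        return TajimaRRTResult(0, 0, 0.0, 1.0, undefined=True)
    chi2 = (m1 - m2) ** 2 / (m1 + m2)
    return TajimaRRTResult(m1, m2, chi2, float(stats.chi2.sf(chi2, df=1)))


DEFAULT_CALIBRATIONS_MYA = {
    "chimpanzee": (6.0, 7.0),
    "orangutan": (15.0, 15.0),
    "macaque": (25.0, 25.0),
    "owm_nwm_split": (35.0, 35.0),
}


def calibrate_rate(K_calibration: float, T_mya: float) -> float:
    """Substitution rate per site per million years: R = K / 2T."""
    if K_calibration < 0:
        raise ValueError("K must be >= 0")
    if T_mya <= 0:
        raise ValueError("calibration time must be > 0")
    return K_calibration / (2.0 * T_mya)


def duplication_time(K_pair: float, rate: float) -> float:
    """Divergence time in Mya for a pair at distance K: T = K / 2R."""
    if K_pair < 0:
        raise ValueError("K must be >= 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    return K_pair / (2.0 * rate)
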