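"""Genomic interval data model, file I/O, and interval algebra.

Coordinates are 0-based half-open throughout, BED style. The user-facing
objects are thin dataclasses: :class:`GenomicInterval` (one region with a
role label), :class:`RegionSet` (an ordered collection sharing a role),
:class:`RepeatAnnotation` (one RepeatMasker element), and
:class:`GenomeLandscape` (chromosome sizes + GC track or sequence + repeats
+ exclusion/unique masks) — the universe in which permutation tests and
simulations run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

ROLES = ("donor", "acceptor", "pre_integration", "block", "other")
REPEAT_CLASSES = ("SINE", "LINE", "LTR", "DNA", "other")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with a role label."""

    chrom: str
    start: int
    end: int
    name: str = ""
    role: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end (zero-length intervals forbidden)"
            )
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class RegionSet:
    """An ordered collection of intervals sharing a role label.

    ``n_regions`` is the *n* that enters the binomial standard-error formula
    for permutation p-values.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    role: str = "other"

    @property
    def n_regions(self) -> int:
        return len(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def lengths(self) -> list[int]:
        return [len(iv) for iv in self.intervals]


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat element. Classes outside the enum map to ``other``."""

    interval: GenomicInterval
    repeat_class: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"repeat_class {self.repeat_class!r} not in {REPEAT_CLASSES}; "
                "use normalize_repeat_class() on raw RepeatMasker strings"
            )


def normalize_repeat_class(raw: str) -> str:
    """Map a RepeatMasker class string (e.g. ``SINE/Alu``, ``L1``) to the enum."""
    head = raw.split("/")[0].strip().upper()
    if head in ("SINE", "LINE", "LTR", "DNA"):
        return head
    return "other"


@dataclass
class GenomeLandscape:
    """Chromosome sizes plus feature tracks: the permutation-test universe.

    Either ``sequence`` (chrom -> nucleotide string) or ``gc_track``
    (chrom -> per-window GC fractions, with ``gc_window`` bp per window)
    must be provided for GC queries. ``exclusion_mask`` is the union of
    regions never used for null placements (SDs, centromeres, telomeres,
    assembly gaps); ``unique_mask`` marks non-duplicated sequence used when
    walking out acceptor flanks.
    """

    chrom_sizes: dict[str, int]
    repeats: list[RepeatAnnotation] = field(default_factory=list)
    sequence: dict[str, str] | None = None
    gc_track: dict[str, np.ndarray] | None = None
    gc_window: int = 1000
    exclusion_mask: RegionSet = field(default_factory=RegionSet)
    unique_mask: RegionSet | None = None

    def __post_init__(self) -> None:
        for rep in self.repeats:
            self._check_bounds(rep.interval, "repeat")
        for iv in self.exclusion_mask:
            self._check_bounds(iv, "exclusion mask")

    def _check_bounds(self, iv: GenomicInterval, what: str) -> None:
        size = self.chrom_sizes.get(iv.chrom)
        if size is None:
            raise ValueError(f"{what} interval on unknown chromosome {iv.chrom!r}")
        if iv.end > size:
            raise ValueError(
                f"{what} interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {size}"
            )

    def gc_fraction(self, iv: GenomicInterval) -> float:
        """GC fraction of one interval, from sequence or the windowed track."""
        if self.sequence is not None:
            seg = self.sequence[iv.chrom][iv.start : iv.end]
            if not seg:
                raise ValueError(f"empty sequence slice for {iv}")
            gc = sum(1 for c in seg.upper() if c in "GCS")
            return gc / len(seg)
        if self.gc_track is not None:
            track = self.gc_track[iv.chrom]
            return _windowed_mean(track, self.gc_window, iv.start, iv.end)
        raise ValueError("landscape has neither sequence nor gc_track")


def _windowed_mean(track: np.ndarray, window: int, start: int, end: int) -> float:
    """Length-weighted mean of a per-window track over [start, end)."""
    if end <= start:
        raise ValueError("empty interval")
    i0, i1 = start // window, (end - 1) // window
    if i0 == i1:
        return float(track[i0])
    total = 0.0
    # partial first and last windows, full windows between
    total += track[i0] * ((i0 + 1) * window - start)
    total += track[i1] * (end - i1 * window)
    if i1 - i0 > 1:
        total += float(np.sum(track[i0 + 1 : i1])) * window
    return total / (end - start)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_bed(path, role: str = "other", one_based: bool = False) -> RegionSet:
    """Read a 3-6 column BED file into a RegionSet.

    ``one_based=True`` accepts 1-based inclusive coordinates (genome-browser
    style, as printed in the source tables) and converts them on read.
    Input order is preserved and chromosome names are taken verbatim.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if one_based:
                start -= 1
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start >= end "
                    f"({start} >= {end}); zero-length intervals forbidden"
                )
            name = parts[3] if len(parts) > 3 else ""
            intervals.append(GenomicInterval(chrom, start, end, name=name, role=role))
    return RegionSet(intervals=intervals, role=role)


def write_bed(regions: RegionSet, path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column ``chrom<TAB>length`` file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def read_repeatmasker(path) -> list[RepeatAnnotation]:
    """Read a RepeatMasker ``.out``-style whitespace table.

    Tolerates the two header lines and blank lines. Expects the standard
    column order: score, divergence x3, query, begin, end, (left), strand,
    repeat name, class/family, ... Coordinates in .out files are 1-based
    inclusive and are converted to 0-based half-open.
    """
    repeats: list[RepeatAnnotation] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 11 or not parts[0].lstrip("-").isdigit():
                continue  # header / blank
            chrom, begin, end = parts[4], int(parts[5]), int(parts[6])
            family = parts[9]
            rclass = normalize_repeat_class(parts[10])
            repeats.append(
                RepeatAnnotation(
                    GenomicInterval(chrom, begin - 1, end),
                    repeat_class=rclass,
                    family=family,
                )
            )
    return repeats


def read_fasta_sequences(path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence} via Biopython."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def merge_intervals(regions: RegionSet) -> RegionSet:
    """Coalesce overlapping or abutting intervals per chromosome.

    This is the "redundant sites merged to nonredundant regions" step:
    output covers exactly the union of input coverage, sorted by
    (chrom, start). Abutting intervals (end == next start) are merged.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or abut
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, role=regions.role))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end, role=regions.role))
    return RegionSet(intervals=merged, role=regions.role)


def complement(regions: RegionSet, chrom_sizes: Mapping[str, int]) -> RegionSet:
    """Per-chromosome complement of a (possibly unmerged) region set."""
    merged = merge_intervals(regions) if regions.n_regions else regions
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        pos = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > pos:
                out.append(GenomicInterval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < size:
            out.append(GenomicInterval(chrom, pos, size))
    return RegionSet(intervals=out, role="other")


def allowed_space(landscape: GenomeLandscape) -> RegionSet:
    """Genome minus the exclusion mask; errors if nothing remains."""
    out = complement(landscape.exclusion_mask, landscape.chrom_sizes)
    if out.total_bases() == 0:
        raise ValueError("exclusion mask covers the entire genome")
    return out


def intersect_lengths(a: RegionSet, b: RegionSet) -> int:
    """Total bases shared between two region sets (each merged first)."""
    am, bm = merge_intervals(a) if len(a) else a, merge_intervals(b) if len(b) else b
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in bm:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    total = 0
    for iv in am:
        for other in by_chrom.get(iv.chrom, []):
            lo, hi = max(iv.start, other.start), min(iv.end, other.end)
            if hi > lo:
                total += hi - lo
    return total


def flanking_unique(
    block: GenomicInterval,
    landscape: GenomeLandscape,
    flank_len: int = 10_000,
) -> RegionSet:
    """Nearest ``flank_len`` bp of unique sequence on each side of a block.

    Walks base-by-base outward from each block edge, skipping duplicated
    (non-unique) sequence, concatenating unique bases until ``flank_len``
    are collected; the collected bases are returned as maximal intervals.
    A side is truncated (interval named with a ``truncated`` suffix) when
    the chromosome end or exhausted unique space intervenes.
    """
    size = landscape.chrom_sizes[block.chrom]
    if landscape.unique_mask is not None:
        uniq = [
            (iv.start, iv.end)
            for iv in merge_intervals(landscape.unique_mask)
            if iv.chrom == block.chrom
        ]
    else:
        uniq = [(0, size)]
    out: list[GenomicInterval] = []

    def collect(segments: list[tuple[int, int]], side: str) -> None:
        got = 0
        pieces: list[tuple[int, int]] = []
        for s, e in segments:
            take = min(e - s, flank_len - got)
            if take <= 0:
                break
            if side == "left":  # walking leftward: take the rightmost bases
                pieces.append((e - take, e))
            else:
                pieces.append((s, s + take))
            got += take
            if got >= flank_len:
                break
        suffix = "" if got >= flank_len else ".truncated"
        for i, (s, e) in enumerate(pieces):
            out.append(
                GenomicInterval(
                    block.chrom, s, e,
                    name=f"{block.name or 'block'}.{side}{suffix}",
                    role="acceptor",
                )
            )

    left = [(s, min(e, block.start)) for s, e in uniq if s < block.start]
    left = [(s, e) for s, e in left if e > s]
    collect(list(reversed(left)), "left")
    right = [(max(s, block.end), e) for s, e in uniq if e > block.end]
    right = [(s, e) for s, e in right if e > s]
    collect(right, "right")
    out.sort(key=lambda iv: iv.start)
    return RegionSet(intervals=out, role="acceptor")


def overlap_elements(
    regions: RegionSet,
    repeats: Sequence[RepeatAnnotation],
    repeat_class: str,
) -> int:
    """Count distinct repeat elements of one class overlapping a region set.

    Each element counts once even if it spans two regions (distinct-element
    rule of the retrotransposon enrichment statistic).
    """
    if repeat_class not in REPEAT_CLASSES:
        raise ValueError(f"repeat_class {repeat_class!r} not in {REPEAT_CLASSES}")
    count = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for rep in repeats:
        if rep.repeat_class != repeat_class:
            continue
        r = rep.interval
        for iv in by_chrom.get(r.chrom, []):
            if r.start < iv.end and iv.start < r.end:
                count += 1
                break
    return count
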