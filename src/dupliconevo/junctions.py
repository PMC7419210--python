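"""Breakpoint-level accounting: junction repeat classification,
pre-integration deletion sizing, and clone-library copy-number screens.

Three small analyses live here. ``classify_boundary`` asks whether a
duplication transition junction has a repeat element (in particular a SINE
such as AluS) mapping within +/-50 bp of the breakpoint.
``pre_integration_deletion`` / ``deletion_summary`` size the sequence lost
at the orthologous outgroup locus when a duplication integrated.
``estimate_copy_number`` turns a count of positively hybridizing BAC clones
and an average library coverage into a copy-number range. The two published
summary tables this package reanalyses ship as checksummed TSV fixtures.
"""

from __future__ import annotations

import hashlib
import statistics
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from .intervals import RepeatAnnotation

_FIXTURE_SHA256 = {
    "table1_clone_screen.tsv": "aa9e084d255ee1c3666c490ea521db97b84d987b3e216ccc43db5e1199404eed",
    "table4_pre_integration.tsv": "855f55ce0d4d5bfe80f2c0929ab0fde61dae338f7c10db737b37a514bb488bac",
}


@dataclass
class JunctionCall:
    chrom: str
    breakpoint: int
    window_bp: int
    repeat_hits: list[tuple[str, str, int]] = field(default_factory=list)
    verdict: str = "unique"  # SINE_positive | other_repeat | unique


@dataclass
class PreIntegrationRecord:
    species: str
    chrom: str
    anchor_start: int
    anchor_end: int
    deletion_kbp: float | None = None
    repeat_pct: float | None = None
    ltr_pct: float | None = None
    line_pct: float | None = None
    sine_pct: float | None = None
    unique_pct: float | None = None
    insertion_kbp: float | None = None
    build: str = ""
    flag: str = ""


@dataclass
class ScreenEstimate:
    library: str
    n_clones: int
    coverage_lo: float
    coverage_hi: float
    copy_lo: float
    copy_hi: float
    copy_point: int


def classify_boundary(
    chrom: str,
    breakpoint: int,
    repeats: Sequence[RepeatAnnotation],
    window_bp: int = 50,
) -> JunctionCall:
    """Classify one junction by repeat content within +/-window_bp.

    The window is closed: an element touching either boundary base counts.
    A single SINE hit makes the verdict ``SINE_positive`` regardless of
    other hits; any other repeat gives ``other_repeat``; else ``unique``.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    lo, hi = breakpoint - window_bp, breakpoint + window_bp  # closed on bases lo..hi
    hits: list[tuple[str, str, int]] = []
    for rep in repeats:
        iv = rep.interval
        if iv.chrom != chrom:
            continue
        if iv.start <= hi and iv.end - 1 >= lo:
            hits.append((rep.repeat_class, rep.family, iv.start - breakpoint))
    if any(h[0] == "SINE" for h in hits):
        verdict = "SINE_positive"
    elif hits:
        verdict = "other_repeat"
    else:
        verdict = "unique"
    return JunctionCall(chrom, breakpoint, window_bp, repeat_hits=hits, verdict=verdict)


def boundary_summary(calls: Sequence[JunctionCall]) -> dict:
    """Fraction of junctions with a SINE at the breakpoint (with counts)."""
    if not calls:
        raise ValueError("boundary_summary requires at least one junction call")
    n_pos = sum(1 for c in calls if c.verdict == "SINE_positive")
    return {
        "n_sine_positive": n_pos,
        "n_junctions": len(calls),
        "fraction_sine_positive": n_pos / len(calls),
    }


def pre_integration_deletion(anchor_start: int, anchor_end: int) -> float:
    """Deleted span between outgroup anchors, in kbp rounded to 0.1."""
    if anchor_end < anchor_start:
        raise ValueError("anchor_end must be >= anchor_start")
    return round((anchor_end - anchor_start) / 1000.0, 1)


def deletion_summary(records: Sequence[PreIntegrationRecord]) -> dict:
    """Summary statistics of pre-integration deletions.

    The median is taken over all records, with an absent deletion treated
    as 0 (a precise integration); min/max are over records with loss.
    ``median_kbp_with_loss`` is the alternative median restricted to loci
    that lost sequence. ``mean_repeat_pct`` averages composition over the
    records that report it.
    """
    if not records:
        raise ValueError("deletion_summary requires at least one record")
    dels = [r.deletion_kbp if r.deletion_kbp is not None else 0.0 for r in records]
    with_loss = [d for d in dels if d > 0]
    reps = [r.repeat_pct for r in records if r.repeat_pct is not None]
    return {
        "n_records": len(records),
        "median_kbp": statistics.median(dels),
        "median_kbp_with_loss": statistics.median(with_loss) if with_loss else None,
        "min_kbp": min(with_loss) if with_loss else None,
        "max_kbp": max(with_loss) if with_loss else None,
        "n_with_loss": len(with_loss),
        "pct_with_loss": 100.0 * len(with_loss) / len(records),
        "mean_repeat_pct": sum(reps) / len(reps) if reps else None,
    }


def estimate_copy_number(
    n_clones: int,
    coverage_lo: float,
    coverage_hi: float,
    library: str = "",
) -> ScreenEstimate:
    """Copy-number range from a BAC-library hybridization screen.

    ``n_clones`` positively hybridizing clones at an average library
    coverage between ``coverage_lo`` and ``coverage_hi`` fold imply between
    n/coverage_hi and n/coverage_lo copies; the integer point estimate is
    the rounded midpoint.
    """
    if n_clones < 0:
        raise ValueError("n_clones must be >= 0")
    if not (0 < coverage_lo <= coverage_hi):
        raise ValueError("require 0 < coverage_lo <= coverage_hi")
    lo = n_clones / coverage_hi
    hi = n_clones / coverage_lo
    return ScreenEstimate(
        library=library,
        n_clones=n_clones,
        coverage_lo=coverage_lo,
        coverage_hi=coverage_hi,
        copy_lo=lo,
        copy_hi=hi,
        copy_point=round((lo + hi) / 2),
    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_text(name: str) -> str:
    data = resources.files("dupliconevo.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise RuntimeError(f"fixture {name} checksum mismatch: {digest}")
    return data.decode()


def _opt_float(tok: str) -> float | None:
    return None if tok in (".", "") else float(tok)


def load_pre_integration_table(include_flagged: bool = False) -> list[PreIntegrationRecord]:
    """The 14-row integration-site composition fixture.

    By default the one locus flagged as a cytogenetic rearrangement between
    chromosomes is dropped, leaving the 13 analyzed loci.
    """
    lines = _fixture_text("table4_pre_integration.tsv").splitlines()
    header = lines[0].split("\t")
    out: list[PreIntegrationRecord] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        tok = dict(zip(header, line.split("\t")))
        rec = PreIntegrationRecord(
            species=tok["species"],
            build=tok["build"],
            chrom=tok["chrom"],
            anchor_start=int(tok["anchor_start"]),
            anchor_end=int(tok["anchor_end"]),
            deletion_kbp=_opt_float(tok["deletion_kbp"]),
            repeat_pct=_opt_float(tok["repeat_pct"]),
            ltr_pct=_opt_float(tok["ltr_pct"]),
            line_pct=_opt_float(tok["line_pct"]),
            sine_pct=_opt_float(tok["sine_pct"]),
            unique_pct=_opt_float(tok["unique_pct"]),
            insertion_kbp=_opt_float(tok["insertion_kbp"]),
            flag=tok.get("flag", "") or "",
        )
        if rec.flag and not include_flagged:
            continue
        out.append(rec)
    return out


def load_clone_screen_table() -> list[dict]:
    """The clone-library copy-number screen fixture (one dict per lineage)."""
    lines = _fixture_text("table1_clone_screen.tsv").splitlines()
    header = lines[0].split("\t")
    rows = []
    for line in lines[1:]:
        if not line.strip():
            continue
        tok = dict(zip(header, line.split("\t")))
        rows.append(
            {
                "lineage": tok["lineage"],
                "library": tok["library"],
                "coverage_lo": _opt_float(tok["coverage_lo"]),
                "coverage_hi": _opt_float(tok["coverage_hi"]),
                "n_clones": None if tok["n_clones"] == "." else int(tok["n_clones"]),
                "copy_number": tok["copy_number"],
                "previously_reported": tok.get("previously_reported", "") == "*",
            }
        )
    return rows
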