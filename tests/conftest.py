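import numpy as np
import pytest

from dupliconevo import (
    GenomeLandscape,
    GenomicInterval,
    RegionSet,
    RepeatAnnotation,
)


@pytest.fixture
def toy_landscape():
    """1 Mb + 0.5 Mb genome with a handful of repeats and a small mask."""
    sizes = {"chr1": 1_000_000, "chr2": 500_000}
    rng = np.random.default_rng(42)
    repeats = []
    for chrom, size in sizes.items():
        for s in rng.integers(0, size - 400, size=60):
            repeats.append(
                RepeatAnnotation(
                    GenomicInterval(chrom, int(s), int(s) + 300), "SINE", "AluS"
                )
            )
        for s in rng.integers(0, size - 1200, size=25):
            repeats.append(
                RepeatAnnotation(
                    GenomicInterval(chrom, int(s), int(s) + 1000), "LINE", "L1"
                )
            )
    gc = {
        "chr1": np.full(1000, 0.41),
        "chr2": np.full(500, 0.41),
    }
    mask = RegionSet(
        [GenomicInterval("chr1", 200_000, 250_000), GenomicInterval("chr2", 0, 20_000)]
    )
    return GenomeLandscape(
        chrom_sizes=sizes,
        repeats=repeats,
        gc_track=gc,
        gc_window=1000,
        exclusion_mask=mask,
    )


def brute_force_overlap_count(regions, repeats, repeat_class):
    """O(n*m) oracle: distinct elements of a class overlapping any region."""
    n = 0
    for rep in repeats:
        if rep.repeat_class != repeat_class:
            continue
        iv = rep.interval
        if any(
            iv.chrom == r.chrom and iv.start < r.end and r.start < iv.end
            for r in regions
        ):
            n += 1
    return n
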