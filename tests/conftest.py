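"""Shared fixtures and independent oracles.

The per-base boolean-mask oracle re-derives interval arithmetic from first
principles (one boolean per genomic base) and is the reference for every
interval-level operation.
"""

from __future__ import annotations

import numpy as np
import pytest

from haplotx.intervals import GenomeLayout, GenomicInterval, IntervalSet


def base_mask(intervals, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """One boolean per base: True where any interval covers it."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in layout.chrom_sizes.items()}
    for iv in intervals:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def mask_to_intervals(masks: dict[str, np.ndarray]) -> list[GenomicInterval]:
    """Runs of True in the mask, as intervals (brute-force merge)."""
    out = []
    for chrom in sorted(masks):
        m = masks[chrom]
        padded = np.concatenate(([False], m, [False]))
        diff = np.diff(padded.astype(int))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]
        out.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def random_interval_set(
    rng: np.random.Generator, layout: GenomeLayout, n: int, max_len: int = 2000
) -> IntervalSet:
    chroms = list(layout.chrom_sizes)
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = layout.chrom_sizes[chrom]
        length = int(rng.integers(1, max_len + 1))
        start = int(rng.integers(0, size - length))
        out.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(out)


@pytest.fixture
def toy_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 10_000, "chr2": 8_000})
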