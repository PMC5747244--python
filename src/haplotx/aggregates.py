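"""Aggregate (metaplot) profiles around transcript 5' ends, promoter
occupancy by peak tracks, matched controls, and bidirectional-promoter
calling.

A metaplot counts peak elements (CAGE clusters, histone-mark peaks) by
their midpoint offset from each transcript's 5' end, oriented by strand
(negative offsets are upstream), summed over transcripts expressed in the
track's condition and divided by the number of those transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .transcripts import ExpressionMatrix, TranscriptModel


@dataclass
class PeakTrack:
    """Peak calls / CAGE clusters per mark for one tissue condition."""

    marks: dict[str, IntervalSet]
    condition: str


@dataclass
class AggregateProfile:
    """Normalized per-bin counts around 5' ends.

    bin_edges has len(normalized_counts) + 1 entries; bin k covers
    [bin_edges[k], bin_edges[k+1]) in strand-oriented offset space.
    raw_counts are the integer peak counts before division by n_transcripts.
    """

    bin_edges: np.ndarray
    normalized_counts: np.ndarray
    raw_counts: np.ndarray
    n_transcripts: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.bin_edges[:-1],
                "normalized_count": self.normalized_counts,
                "raw_count": self.raw_counts,
            }
        )


def _expressed(
    transcripts: Sequence[TranscriptModel],
    expr: ExpressionMatrix | None,
    condition: str | None,
    min_expr: float,
) -> list[TranscriptModel]:
    if expr is None or condition is None:
        return list(transcripts)
    col = expr.fpkm[condition]
    return [m for m in transcripts if col.get(m.transcript_id, 0.0) > min_expr]


def aggregate_profile(
    transcripts: Sequence[TranscriptModel],
    peaks: IntervalSet,
    flank_bp: int = 5000,
    bin_bp: int = 100,
    expr: ExpressionMatrix | None = None,
    condition: str | None = None,
    min_expr: float = 0.0,
) -> AggregateProfile:
    """Metaplot of peak midpoints around 5' ends of expressed transcripts.

    Only transcripts with FPKM > min_expr in `condition` are included when
    an expression matrix is supplied.  Peaks land in the bin containing
    their midpoint's strand-oriented offset; counts are normalized by the
    number of included transcripts.
    """
    included = _expressed(transcripts, expr, condition, min_expr)
    if not included:
        raise ValueError("no transcript passes the expression filter")
    n_bins = (2 * flank_bp) // bin_bp
    edges = np.arange(-flank_bp, -flank_bp + (n_bins + 1) * bin_bp, bin_bp)
    raw = np.zeros(n_bins, dtype=np.int64)
    pc = peaks.per_chrom()
    mids_by_chrom = {
        c: (arr[:, 0] + arr[:, 1]) // 2 for c, arr in pc.items()
    }
    for m in included:
        mids = mids_by_chrom.get(m.chrom)
        if mids is None or len(mids) == 0:
            continue
        p = m.five_prime_pos
        offsets = (mids - p) if m.strand == "+" else (p - mids)
        inside = (offsets >= -flank_bp) & (offsets < -flank_bp + n_bins * bin_bp)
        idx = (offsets[inside] + flank_bp) // bin_bp
        np.add.at(raw, idx.astype(int), 1)
    return AggregateProfile(edges, raw / len(included), raw, len(included))


def promoter_occupancy(
    transcripts: Sequence[TranscriptModel],
    track: PeakTrack | Mapping[str, IntervalSet],
    flank_bp: int = 500,
    expr: ExpressionMatrix | None = None,
    min_expr: float = 0.0,
) -> dict[str, float]:
    """Fraction of transcript promoters (5' end +/- flank) touched by >= 1
    peak, per mark."""
    marks = track.marks if isinstance(track, PeakTrack) else dict(track)
    condition = track.condition if isinstance(track, PeakTrack) else None
    included = _expressed(transcripts, expr, condition, min_expr)
    out: dict[str, float] = {}
    for mark, peaks in marks.items():
        if not included:
            out[mark] = 0.0
            continue
        n_hit = 0
        for m in included:
            p = m.five_prime_pos
            window = GenomicInterval(m.chrom, max(0, p - flank_bp), p + flank_bp)
            if peaks.overlaps_interval(window):
                n_hit += 1
        out[mark] = n_hit / len(included)
    return out


def matched_lnc_control(
    candidate_medians: pd.Series, target_median: float, size: int
) -> pd.Index:
    """Size-matched control set of candidates with median expression nearest
    the target median.  Returns all candidates (with an implicit warning
    semantics) when fewer than `size` exist."""
    if candidate_medians.empty:
        raise ValueError("no control candidates supplied")
    ranked = (candidate_medians - target_median).abs().sort_values(kind="stable")
    return ranked.index[: min(size, len(ranked))]


def call_bidirectional(
    transcripts: Sequence[TranscriptModel], extend_bp: int = 500
) -> tuple[pd.Series, float]:
    """Flag transcripts whose 5'-extended span overlaps the 5'-extended span
    of an opposite-strand transcript (symmetric by construction)."""
    spans = []
    for m in transcripts:
        s = m.span
        if m.strand == "+":
            spans.append(GenomicInterval(s.chrom, max(0, s.start - extend_bp), s.end, "+"))
        else:
            spans.append(GenomicInterval(s.chrom, s.start, s.end + extend_bp, "-"))
    flags = pd.Series(False, index=[m.transcript_id for m in transcripts])
    by_chrom: dict[str, list[int]] = {}
    for i, sp in enumerate(spans):
        by_chrom.setdefault(sp.chrom, []).append(i)
    for idxs in by_chrom.values():
        idxs = sorted(idxs, key=lambda i: spans[i].start)
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                if spans[j].start >= spans[i].end:
                    break
                if spans[i].strand != spans[j].strand:
                    flags.iloc[i] = True
                    flags.iloc[j] = True
    frac = float(flags.mean()) if len(flags) else 0.0
    return flags, frac
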