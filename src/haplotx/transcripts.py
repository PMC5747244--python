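"""Transcript models, expression normalization, retention filters, and
haploblock occupancy.

Expression handling follows the usual count-matrix workflow: raw
per-condition read counts are depth-normalized with median-of-ratios size
factors, converted to FPKM (fragments per kilobase of transcript per
million mapped fragments) using the transcript's exonic length, and
filtered.  A transcript is *retained* when it is multi-exonic, overlaps the
capture target space by at least one exonic base, reaches FPKM above the
threshold in at least one condition, and contributes more than the minimum
isoform fraction of its locus's expression.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet


@dataclass
class TranscriptModel:
    """A stranded, possibly multi-exonic transcript model.

    Exons are stored sorted and non-overlapping.  The 5' end is the first
    exon's start on the + strand and the last exon's final base on the −
    strand.
    """

    transcript_id: str
    exons: list[GenomicInterval]
    strand: str
    locus_id: str | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be + or -, got {self.strand!r}")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes {chroms}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"transcript {self.transcript_id} has overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def length_nt(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_multi_exonic(self) -> bool:
        return len(self.exons) >= 2

    @property
    def five_prime_pos(self) -> int:
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def three_prime_pos(self) -> int:
        if self.strand == "+":
            return self.exons[-1].end - 1
        return self.exons[0].start

    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive exons."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def exon_set(self) -> IntervalSet:
        return IntervalSet(self.exons)


def assign_loci(models: Sequence[TranscriptModel], prefix: str = "LOC") -> None:
    """Cluster transcripts sharing >= 1 exonic base on the same strand into loci.

    Clustering is transitive (mirrors assembler locus merging) and writes
    locus_id in place.
    """
    order = sorted(range(len(models)), key=lambda i: (models[i].chrom, models[i].strand,
                                                      models[i].span.start))
    parent = list(range(len(models)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    # sweep per (chrom, strand): overlap of exonic bases, transitively
    by_group: dict[tuple[str, str], list[int]] = {}
    for i in order:
        by_group.setdefault((models[i].chrom, models[i].strand), []).append(i)
    for idxs in by_group.values():
        for a_pos, i in enumerate(idxs):
            set_i = models[i].exon_set()
            for j in idxs[a_pos + 1:]:
                if models[j].span.start >= models[i].span.end:
                    break
                if set_i.overlap_bases(models[j].exon_set()) > 0:
                    union(i, j)
    roots = sorted({find(i) for i in range(len(models))},
                   key=lambda r: (models[r].chrom, models[r].span.start, models[r].strand))
    label = {r: f"{prefix}{k + 1:05d}" for k, r in enumerate(roots)}
    for i, m in enumerate(models):
        m.locus_id = label[find(i)]


# ---------------------------------------------------------------------------
# Expression: size factors and FPKM
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth normalization factors, one per condition.

    For transcripts with positive counts in every condition, each count is
    divided by the transcript's geometric mean across conditions; the
    factor of a condition is the median of those ratios.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors need at least 2 conditions")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError(
            "no transcript has positive counts in all conditions; "
            "add a pseudocount or provide factors explicitly"
        )
    gm = np.exp(np.log(positive).mean(axis=1))
    ratios = positive.div(gm, axis=0)
    return ratios.median(axis=0).rename("size_factor")


def fpkm(counts: pd.DataFrame, lengths: pd.Series, factors: pd.Series) -> pd.DataFrame:
    """FPKM matrix from counts, transcript lengths (nt), and size factors.

    fpkm_ij = (count_ij / factor_j) / ((length_i / 1e3) * (normalized
    column total_j / 1e6)).
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("all transcript lengths must be positive")
    norm = counts.div(factors, axis=1)
    totals = norm.sum(axis=0)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero normalized column total for conditions {bad}")
    return norm.div(lengths / 1e3, axis=0).div(totals / 1e6, axis=1)


class ExpressionMatrix:
    """Counts, size factors, and derived FPKM for a set of transcripts."""

    def __init__(
        self,
        counts: pd.DataFrame,
        lengths: pd.Series,
        factors: pd.Series | None = None,
    ):
        if (counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        self.lengths = lengths.reindex(counts.index)
        self.size_factors = size_factors(counts) if factors is None else factors
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")
        self.fpkm = fpkm(counts, self.lengths, self.size_factors)

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns)

    def max_fpkm(self) -> pd.Series:
        return self.fpkm.max(axis=1)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# Retention filters / tiers / occupancy
# ---------------------------------------------------------------------------

def isoform_fractions(
    models: Sequence[TranscriptModel], expr: ExpressionMatrix
) -> pd.Series:
    """Each isoform's share of its locus's expression.

    The share is computed in the condition where the locus's summed FPKM is
    maximal, so a dominant tissue defines the isoform mix.
    """
    for m in models:
        if m.locus_id is None:
            raise ValueError(f"transcript {m.transcript_id} has no locus assignment")
    locus_of = {m.transcript_id: m.locus_id for m in models}
    fr = pd.Series(0.0, index=[m.transcript_id for m in models])
    fpkm_m = expr.fpkm.loc[fr.index]
    groups = fpkm_m.groupby([locus_of[t] for t in fr.index])
    for _, sub in groups:
        totals = sub.sum(axis=0)
        if totals.max() <= 0:
            continue
        best = totals.idxmax()
        fr.loc[sub.index] = sub[best] / totals[best]
    return fr


def retain_transcripts(
    models: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    target_regions: IntervalSet,
    fpkm_min: float = 1.0,
    isoform_min_frac: float = 0.01,
) -> list[TranscriptModel]:
    """Apply the conjunction of retention filters.

    Retained iff multi-exonic AND >= 1 exonic base overlaps the capture
    target regions AND max FPKM across conditions exceeds fpkm_min AND the
    isoform's share of its locus's expression exceeds isoform_min_frac.
    """
    shares = isoform_fractions(models, expr)
    max_f = expr.max_fpkm()
    retained = []
    for m in models:
        if not m.is_multi_exonic:
            continue
        if max_f.get(m.transcript_id, 0.0) <= fpkm_min:
            continue
        if shares[m.transcript_id] <= isoform_min_frac:
            continue
        if m.exon_set().overlap_bases(target_regions) == 0:
            continue
        retained.append(m)
    return retained


TIERS = ("low", "medium", "high")


def expression_tiers(
    retained: Sequence[TranscriptModel], expr: ExpressionMatrix
) -> pd.Series:
    """Partition retained transcripts into low/medium/high max-FPKM tertiles.

    Values at a boundary go to the lower tier.
    """
    if not retained:
        raise ValueError("no retained transcripts to tier")
    ids = [m.transcript_id for m in retained]
    vals = expr.max_fpkm().loc[ids]
    q1, q2 = np.quantile(vals, [1 / 3, 2 / 3])
    tier = pd.Series("high", index=ids, name="tier")
    tier[vals <= q2] = "medium"
    tier[vals <= q1] = "low"
    return tier


@dataclass
class OccupancyResult:
    """Per-block transcription flags and the overall occupied fraction."""

    per_block_flag: dict[str, bool]
    fraction_occupied: float


def occupancy(
    blocks: Mapping[str, GenomicInterval] | Sequence[GenomicInterval],
    retained: Sequence[TranscriptModel],
    expr: ExpressionMatrix,
    fpkm_min: float = 1.0,
) -> OccupancyResult:
    """Fraction of blocks containing >= 1 retained transcript above fpkm_min.

    A block is occupied when a qualifying transcript has at least one
    exonic base inside it.
    """
    if not isinstance(blocks, Mapping):
        blocks = {f"block{i + 1:04d}": b for i, b in enumerate(blocks)}
    max_f = expr.max_fpkm()
    qualifying = IntervalSet(
        e
        for m in retained
        if max_f.get(m.transcript_id, 0.0) > fpkm_min
        for e in m.exons
    ).merge()
    flags = {
        name: qualifying.overlaps_interval(iv) for name, iv in blocks.items()
    }
    frac = float(np.mean(list(flags.values()))) if flags else 0.0
    return OccupancyResult(flags, frac)


# ---------------------------------------------------------------------------
# GTF I/O (1-based inclusive at the file boundary)
# ---------------------------------------------------------------------------

def read_transcripts_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read transcript models (exon features) from a GTF file."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes["transcript_id"][0]
        rec = by_tx.setdefault(
            tid,
            {
                "exons": [],
                "strand": exon.strand,
                "gene_id": exon.attributes.get("gene_id", [None])[0],
            },
        )
        rec["exons"].append(
            GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        )
    return [
        TranscriptModel(tid, rec["exons"], rec["strand"], gene_id=rec["gene_id"])
        for tid, rec in sorted(by_tx.items())
    ]


def write_transcripts_gtf(
    models: Sequence[TranscriptModel], path: str | Path, source: str = "haplotx"
) -> None:
    with open(path, "w") as fh:
        for m in models:
            gene = m.gene_id or m.locus_id or m.transcript_id
            attrs = f'gene_id "{gene}"; transcript_id "{m.transcript_id}";'
            span = m.span
            fh.write(
                f"{m.chrom}\t{source}\ttranscript\t{span.start + 1}\t{span.end}\t.\t"
                f"{m.strand}\t.\t{attrs}\n"
            )
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
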