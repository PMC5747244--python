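"""Capture-space construction: haploblock exclusions, exon removal, and
control-region selection.

The capture space is the genomic target of the hybridization probes: the
union of retained haploblocks with every annotated protein-coding or
lincRNA exon removed, so that sequencing effort goes to unannotated
transcription.  Control classes (random intronic windows, a gene desert,
known exons) quantify background transcriptional noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .haploblocks import Haploblock
from .intervals import GenomicInterval, IntervalSet
from .transcripts import TranscriptModel

CODING_TYPES = ("protein_coding",)
EXCLUDED_EXON_TYPES = ("protein_coding", "lincRNA")


@dataclass
class AnnotationSet:
    """Gene annotation: gene records with gene_type, and per-transcript exons.

    genes: DataFrame with columns gene_id, chrom, start, end, strand, gene_type.
    exons: DataFrame with columns gene_id, transcript_id, chrom, start, end, strand.
    Coordinates are 0-based half-open (converted from GTF on read).
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    @classmethod
    def from_gtf(cls, path: str | Path) -> "AnnotationSet":
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
        gene_rows, exon_rows = [], []
        for g in db.features_of_type("gene"):
            gene_rows.append(
                {
                    "gene_id": g.attributes["gene_id"][0],
                    "chrom": g.seqid,
                    "start": g.start - 1,
                    "end": g.end,
                    "strand": g.strand,
                    "gene_type": g.attributes.get("gene_type", ["unknown"])[0],
                }
            )
        gene_type = {r["gene_id"]: r["gene_type"] for r in gene_rows}
        for e in db.features_of_type("exon"):
            gid = e.attributes.get("gene_id", [None])[0]
            exon_rows.append(
                {
                    "gene_id": gid,
                    "transcript_id": e.attributes.get("transcript_id", [None])[0],
                    "chrom": e.seqid,
                    "start": e.start - 1,
                    "end": e.end,
                    "strand": e.strand,
                    "gene_type": gene_type.get(gid, "unknown"),
                }
            )
        genes = pd.DataFrame(
            gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"]
        )
        exons = pd.DataFrame(
            exon_rows,
            columns=["gene_id", "transcript_id", "chrom", "start", "end", "strand", "gene_type"],
        )
        return cls(genes, exons)

    def exon_set(self, gene_types: Sequence[str] | None = None) -> IntervalSet:
        """Union of exons, optionally restricted to the given gene types."""
        df = self.exons
        if gene_types is not None:
            df = df[df["gene_type"].isin(gene_types)]
        return IntervalSet(
            GenomicInterval(c, s, e)
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ).merge()

    def tss_windows(self, flank_bp: int = 500) -> IntervalSet:
        """Strand-aware promoter windows (TSS +/- flank) for every transcript."""
        out = []
        for (tid,), grp in self.exons.groupby(["transcript_id"]):
            strand = grp["strand"].iloc[0]
            chrom = grp["chrom"].iloc[0]
            tss = grp["start"].min() if strand == "+" else grp["end"].max() - 1
            out.append(
                GenomicInterval(chrom, max(0, tss - flank_bp), tss + flank_bp)
            )
        return IntervalSet(out).merge()

    def padded_exon_set(self, pad_bp: int) -> IntervalSet:
        df = self.exons
        return IntervalSet(
            GenomicInterval(c, max(0, s - pad_bp), e + pad_bp)
            for c, s, e in zip(df["chrom"], df["start"], df["end"])
        ).merge()


@dataclass
class CaptureSpace:
    """Target regions plus the control classes of the probe design."""

    target_regions: IntervalSet
    control_introns: IntervalSet = field(default_factory=IntervalSet)
    control_desert: IntervalSet = field(default_factory=IntervalSet)
    control_exons: IntervalSet = field(default_factory=IntervalSet)

    def write_beds(self, out_dir: str | Path) -> None:
        from .intervals import write_bed

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_bed(self.target_regions, out_dir / "targets.bed")
        write_bed(self.control_introns, out_dir / "control_introns.bed")
        write_bed(self.control_desert, out_dir / "control_desert.bed")
        write_bed(self.control_exons, out_dir / "control_exons.bed")


def exclude_blocks(
    blocks: Sequence[Haploblock] | Sequence[GenomicInterval],
    annotation: AnnotationSet,
    min_len_bp: int = 3000,
    extra_coding_exons: IntervalSet | None = None,
) -> list:
    """Drop blocks that touch a coding exon or are shorter than min_len_bp.

    A single base of coding-exon overlap disqualifies a block.  A second
    annotation source (e.g. RefSeq) may contribute additional coding exons
    through extra_coding_exons.
    """
    coding = annotation.exon_set(CODING_TYPES)
    if extra_coding_exons is not None:
        coding = IntervalSet(list(coding) + list(extra_coding_exons)).merge()
    kept = []
    for blk in blocks:
        region = blk.region if isinstance(blk, Haploblock) else blk
        if region.length < min_len_bp:
            continue
        if coding.overlaps_interval(region):
            continue
        kept.append(blk)
    return kept


def build_capture_space(
    blocks: IntervalSet, annotation: AnnotationSet
) -> CaptureSpace:
    """Subtract protein-coding and lincRNA exons from the block union."""
    excluded = annotation.exon_set(EXCLUDED_EXON_TYPES)
    targets = blocks.merge().subtract(excluded)
    if targets.is_empty:
        raise ValueError(
            "capture space is empty: blocks and annotation do not overlap sensibly"
        )
    return CaptureSpace(target_regions=targets)


def pick_intron_controls(
    loci: Sequence[TranscriptModel],
    repeats: IntervalSet,
    rng_seed: int,
    length_range: tuple[int, int] = (200, 1000),
    repeat_max_frac: float = 0.75,
) -> tuple[IntervalSet, list[str]]:
    """One random intronic window per locus, avoiding repeat-rich targets.

    Introns of a locus are tried in random order; a window of uniform
    random length in length_range is placed uniformly inside the intron and
    accepted when its repeat-covered base fraction is <= repeat_max_frac.
    Loci with no acceptable intron are skipped and reported.

    Returns (controls, skipped_locus_ids).  Deterministic under rng_seed.
    """
    rng = np.random.default_rng(rng_seed)
    lo, hi = length_range
    seen_loci: set[str] = set()
    controls: list[GenomicInterval] = []
    skipped: list[str] = []
    for model in loci:
        locus = model.locus_id or model.transcript_id
        if locus in seen_loci:
            continue
        seen_loci.add(locus)
        introns = [i for i in model.introns() if i.length >= lo]
        if not introns:
            if model.introns():
                skipped.append(locus)
            continue
        order = rng.permutation(len(introns))
        chosen = None
        for k in order:
            intron = introns[k]
            max_len = min(hi, intron.length)
            length = int(rng.integers(lo, max_len + 1))
            start = int(rng.integers(intron.start, intron.end - length + 1))
            cand = GenomicInterval(intron.chrom, start, start + length)
            rep = IntervalSet([cand]).overlap_bases(repeats)
            if rep / cand.length <= repeat_max_frac:
                chosen = cand
                break
        if chosen is None:
            skipped.append(locus)
        else:
            controls.append(chosen)
    return IntervalSet(controls), skipped
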