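"""Synthetic-data generation with controllable ground truth.

Every pipeline input can be emulated on a coordinate-only toy genome
(default: 2 chromosomes x 2 Mb): proxy-SNP panels with a decaying LD
profile, recombination hotspots, gene annotation and repeats, transcript
models with planted block occupancy and tissue-specificity profiles, peak
tracks with planted promoter enrichment, SNP catalogs with a planted
element odds ratio, and allele-specific read counts with planted
imbalance.  Truth tables record what was planted so recovery can be
checked without re-deriving it.

LD is generated as a deterministic decay profile r2(d) = exp(-d /
ld_decay_bp) plus bounded noise rather than by coalescent simulation:
block-construction correctness needs only an r2 field per SNP, not
population-genetic realism.  A configurable fraction of index SNPs sit on
an LD "plateau" (r2 near 0.9 at every tabulated proxy), which exercises
the hotspot-extension branch of block construction.

All generators are deterministic under the configured seed; stage seeds
are spawned from it, so stages can also be used independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .capture import AnnotationSet
from .haploblocks import Hotspot, SnpRecord
from .intervals import GenomeLayout, GenomicInterval, IntervalSet, write_bed
from .transcripts import TranscriptModel, assign_loci

MARKS = ("CAGE", "H3K4me3", "H3K27ac", "H3K4me1")


@dataclass
class SimConfig:
    """All knobs of the generator, with defaults matching the study design
    being emulated (21 tissue conditions, ~85% block occupancy, ~81%
    single-condition expression profiles)."""

    seed: int = 0
    # genome shape
    n_chroms: int = 2
    chrom_len_bp: int = 2_000_000
    # LD panel
    n_index_snps: int = 20
    ld_decay_bp: int = 15_000
    ld_noise: float = 0.05
    proxy_spacing_bp: int = 1_000
    proxy_span_bp: int = 60_000
    plateau_frac: float = 0.15
    hotspot_spacing_bp: int = 40_000
    # annotation
    n_genes: int = 30
    n_repeats: int = 200
    # transcriptome
    n_conditions: int = 21
    isoforms_per_locus: int = 2
    exons_per_transcript: int = 3
    occupancy_frac: float = 0.85
    tau_profile: float = 0.81
    bidirectional_frac: float = 0.34
    n_housekeeping: int = 5
    # marks and SNPs
    promoter_mark_frac: float = 0.6
    background_mark_rate: float = 2e-6  # peaks per base
    peak_width_bp: int = 200
    gwas_element_or: float = 2.0
    n_gwas_snps: int = 300
    n_common_snps: int = 3000
    # allele-specific expression
    ai_effect: float = 0.8
    ai_frac: float = 0.3
    snps_per_transcript: int = 5
    depth_mean: float = 50.0
    min_depth: int = 1

    def __post_init__(self) -> None:
        fracs = {
            "plateau_frac": self.plateau_frac,
            "occupancy_frac": self.occupancy_frac,
            "tau_profile": self.tau_profile,
            "promoter_mark_frac": self.promoter_mark_frac,
            "bidirectional_frac": self.bidirectional_frac,
            "ai_frac": self.ai_frac,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.ai_effect < 1.0):
            raise ValueError(f"ai_effect must lie in (0, 1), got {self.ai_effect}")
        if self.ld_decay_bp >= self.chrom_len_bp:
            raise ValueError("ld_decay_bp must be smaller than the chromosome length")
        if self.background_mark_rate * self.peak_width_bp > 1.0:
            raise ValueError("background mark rate implies more than full genome coverage")
        for name in ("n_chroms", "chrom_len_bp", "n_index_snps", "n_conditions",
                     "isoforms_per_locus", "exons_per_transcript"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def genome_layout(config: SimConfig) -> GenomeLayout:
    return GenomeLayout(
        {f"chr{i + 1}": config.chrom_len_bp for i in range(config.n_chroms)}
    )


def _stage_rngs(config: SimConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(config.seed)
    names = ["ld", "annotation", "transcriptome", "marks", "ase"]
    return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


# ---------------------------------------------------------------------------
# LD panel
# ---------------------------------------------------------------------------

@dataclass
class LdPanel:
    index_snps: list[SnpRecord]
    proxies: pd.DataFrame  # index_snp_id, proxy_snp_id, chrom, pos, r2
    hotspots: list[Hotspot]
    truth_blocks: pd.DataFrame  # block_id, chrom, start, end, left_rule, right_rule

    def block_intervals(self) -> dict[str, GenomicInterval]:
        return {
            str(r.block_id): GenomicInterval(str(r.chrom), int(r.start), int(r.end))
            for r in self.truth_blocks.itertuples()
        }


def _scan_truth_boundary(
    index_pos: int,
    side: list[tuple[int, float]],
    hotspot_pos: list[int],
    direction: int,
    r2_extend: float,
    r2_sufficient: float,
    side_cap: int,
) -> tuple[int, str]:
    """Literal per-SNP walk used to emit ground-truth boundaries (main
    rules), written independently of the block-construction module."""
    boundary = index_pos
    rule = "proxy_extent"
    for pos, r2 in side:
        if r2 > r2_extend:
            if direction < 0 and pos < boundary:
                boundary = pos
            if direction > 0 and pos > boundary:
                boundary = pos
    cap = index_pos + direction * side_cap
    if (direction < 0 and boundary < cap) or (direction > 0 and boundary > cap):
        boundary = cap
        rule = "cap"
    in_cap = [r2 for pos, r2 in side if abs(pos - index_pos) <= side_cap]
    sufficient = any(r2 < r2_sufficient for r2 in in_cap)
    if not sufficient:
        beyond = [
            h for h in hotspot_pos if (h < boundary if direction < 0 else h > boundary)
        ]
        if beyond:
            boundary = max(beyond) if direction < 0 else min(beyond)
            rule = "hotspot"
    return boundary, rule


def simulate_ld_panel(config: SimConfig, rng: np.random.Generator | None = None) -> LdPanel:
    """Proxy-SNP tables, hotspots, and ground-truth block boundaries."""
    if rng is None:
        rng = _stage_rngs(config)["ld"]
    layout = genome_layout(config)
    chroms = list(layout.chrom_sizes)
    n_per = -(-config.n_index_snps // len(chroms))  # ceil
    index_snps: list[SnpRecord] = []
    k = 0
    for chrom in chroms:
        length = layout.chrom_sizes[chrom]
        margin = config.proxy_span_bp + config.hotspot_spacing_bp
        positions = np.linspace(margin, length - margin, n_per).astype(int)
        for pos in positions:
            if k >= config.n_index_snps:
                break
            k += 1
            index_snps.append(SnpRecord(f"rs{k:05d}", chrom, int(pos), None, "index"))

    hotspots: list[Hotspot] = []
    for chrom in chroms:
        length = layout.chrom_sizes[chrom]
        grid = np.arange(config.hotspot_spacing_bp, length, config.hotspot_spacing_bp)
        jitter = rng.integers(
            -config.hotspot_spacing_bp // 5, config.hotspot_spacing_bp // 5 + 1, len(grid)
        )
        for p in np.clip(grid + jitter, 1, length - 1):
            hotspots.append(Hotspot(chrom, int(p)))

    offsets = np.arange(
        config.proxy_spacing_bp, config.proxy_span_bp + 1, config.proxy_spacing_bp
    )
    rows = []
    truth_rows = []
    plateau = rng.random(len(index_snps)) < config.plateau_frac
    for i, idx in enumerate(index_snps):
        rows.append(
            {"index_snp_id": idx.snp_id, "proxy_snp_id": idx.snp_id,
             "chrom": idx.chrom, "pos": idx.pos, "r2": 1.0}
        )
        side_snps = {-1: [], 1: []}
        for direction in (-1, 1):
            for j, d in enumerate(offsets):
                pos = idx.pos + direction * int(d)
                if pos < 0 or pos >= layout.chrom_sizes[idx.chrom]:
                    continue
                if plateau[i]:
                    base = 0.9
                else:
                    base = float(np.exp(-d / config.ld_decay_bp))
                r2 = float(
                    np.clip(base + rng.uniform(-config.ld_noise, config.ld_noise), 0.0, 1.0)
                )
                pid = f"{idx.snp_id}_{'l' if direction < 0 else 'r'}{j + 1:03d}"
                rows.append(
                    {"index_snp_id": idx.snp_id, "proxy_snp_id": pid,
                     "chrom": idx.chrom, "pos": pos, "r2": r2}
                )
                side_snps[direction].append((pos, r2))
        hpos = [h.pos for h in hotspots if h.chrom == idx.chrom]
        left, lrule = _scan_truth_boundary(
            idx.pos, side_snps[-1], hpos, -1, 0.5, 0.6, 500_000
        )
        right, rrule = _scan_truth_boundary(
            idx.pos, side_snps[1], hpos, 1, 0.5, 0.6, 500_000
        )
        truth_rows.append(
            {"block_id": idx.snp_id, "chrom": idx.chrom, "start": max(0, left),
             "end": right + 1, "left_rule": lrule, "right_rule": rrule,
             "plateau": bool(plateau[i])}
        )
    proxies = pd.DataFrame(rows, columns=["index_snp_id", "proxy_snp_id", "chrom", "pos", "r2"])
    truth = pd.DataFrame(truth_rows)
    return LdPanel(index_snps, proxies, hotspots, truth)


# ---------------------------------------------------------------------------
# Annotation and repeats
# ---------------------------------------------------------------------------

GENE_TYPES = ("protein_coding", "lincRNA", "pseudogene")
GENE_TYPE_PROBS = (0.6, 0.3, 0.1)


def simulate_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[AnnotationSet, IntervalSet]:
    """A toy gene annotation (with gene_type labels) and a repeat track."""
    if rng is None:
        rng = _stage_rngs(config)["annotation"]
    layout = genome_layout(config)
    chroms = list(layout.chrom_sizes)
    gene_rows, exon_rows = [], []
    for g in range(config.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        gtype = rng.choice(GENE_TYPES, p=GENE_TYPE_PROBS)
        n_ex = int(rng.integers(2, 5))
        exon_len = int(rng.integers(100, 300))
        intron_len = int(rng.integers(500, 2000))
        span = n_ex * exon_len + (n_ex - 1) * intron_len
        start = int(rng.integers(0, layout.chrom_sizes[chrom] - span))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"GENE{g + 1:04d}"
        tid = f"{gid}.1"
        gene_rows.append(
            {"gene_id": gid, "chrom": chrom, "start": start, "end": start + span,
             "strand": strand, "gene_type": gtype}
        )
        pos = start
        for _ in range(n_ex):
            exon_rows.append(
                {"gene_id": gid, "transcript_id": tid, "chrom": chrom,
                 "start": pos, "end": pos + exon_len, "strand": strand,
                 "gene_type": gtype}
            )
            pos += exon_len + intron_len
    genes = pd.DataFrame(gene_rows)
    exons = pd.DataFrame(exon_rows)
    repeats = []
    for _ in range(config.n_repeats):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(100, 1000))
        start = int(rng.integers(0, layout.chrom_sizes[chrom] - length))
        repeats.append(GenomicInterval(chrom, start, start + length))
    return AnnotationSet(genes, exons), IntervalSet(repeats)


def write_annotation_gtf(annotation: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in annotation.genes.itertuples():
            attrs = f'gene_id "{r.gene_id}"; gene_type "{r.gene_type}";'
            fh.write(
                f"{r.chrom}\thaplotx_sim\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )
        for r in annotation.exons.itertuples():
            attrs = (
                f'gene_id "{r.gene_id}"; transcript_id "{r.transcript_id}"; '
                f'gene_type "{r.gene_type}";'
            )
            fh.write(
                f"{r.chrom}\thaplotx_sim\texon\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Transcriptome with planted occupancy and tau profiles
# ---------------------------------------------------------------------------

@dataclass
class Transcriptome:
    models: list[TranscriptModel]
    counts: pd.DataFrame
    truth_transcripts: pd.DataFrame
    truth_blocks: pd.DataFrame

    @property
    def lengths(self) -> pd.Series:
        return pd.Series(
            {m.transcript_id: m.length_nt for m in self.models}, name="length"
        )


def _exon_chain(
    chrom: str, start: int, n_exons: int, rng: np.random.Generator, strand: str
) -> list[GenomicInterval]:
    exons = []
    pos = start
    for _ in range(n_exons):
        exon_len = int(rng.integers(120, 300))
        exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
        pos += exon_len + int(rng.integers(500, 1500))
    return exons


def simulate_transcriptome(
    config: SimConfig,
    blocks: Mapping[str, GenomicInterval],
    rng: np.random.Generator | None = None,
) -> Transcriptome:
    """Plant transcripts into blocks with known occupancy and tau classes.

    An occupancy_frac fraction of blocks receives a qualifying locus
    (multi-exonic isoforms, max FPKM comfortably above 1); the rest receive
    decoys that every retention filter must remove (single-exon transcripts
    with reads, or silent multi-exon models).  Housekeeping loci expressed
    in every condition are placed outside the blocks so size factors are
    well defined.
    """
    if rng is None:
        rng = _stage_rngs(config)["transcriptome"]
    layout = genome_layout(config)
    conditions = [f"tissue{i + 1:02d}" for i in range(config.n_conditions)]
    models: list[TranscriptModel] = []
    counts_rows: dict[str, np.ndarray] = {}
    truth_tx = []
    truth_blocks = []
    max_span = (
        config.exons_per_transcript * 300 + (config.exons_per_transcript - 1) * 1500 + 200
    )
    tx_n = 0
    for b_i, (block_id, region) in enumerate(blocks.items()):
        if region.length < max_span:
            raise ValueError(
                f"block {block_id} ({region.length} bp) too small for the requested "
                f"exon structure (needs ~{max_span} bp)"
            )
        occupied = bool(rng.random() < config.occupancy_frac)
        truth_blocks.append({"block_id": block_id, "occupied": occupied})
        strand = "+" if rng.random() < 0.5 else "-"
        anchor = int(rng.integers(region.start, region.end - max_span))
        if occupied:
            locus = f"SIG{b_i + 1:04d}"
            # optionally plant a divergent (head-to-head) partner locus
            bidir = bool(rng.random() < config.bidirectional_frac)
            lo_anchor = region.start + max_span + 800
            hi_anchor = region.end - 2 * max_span - 800
            if bidir and lo_anchor < hi_anchor:
                anchor = int(rng.integers(lo_anchor, hi_anchor))
            else:
                bidir = False
            single = bool(rng.random() < config.tau_profile)
            cond = conditions[int(rng.integers(config.n_conditions))]
            total = int(rng.integers(500, 3000))
            base = _exon_chain(region.chrom, anchor, config.exons_per_transcript, rng, strand)
            n_iso = config.isoforms_per_locus
            main_frac = float(rng.uniform(0.6, 0.9)) if n_iso > 1 else 1.0
            fracs = [main_frac] + [(1 - main_frac) / (n_iso - 1)] * (n_iso - 1) if n_iso > 1 else [1.0]
            for iso in range(n_iso):
                tx_n += 1
                tid = f"TX{tx_n:05d}"
                exons = [GenomicInterval(e.chrom, e.start, e.end, strand) for e in base]
                if iso > 0:
                    last = exons[-1]
                    exons[-1] = GenomicInterval(
                        last.chrom, last.start, min(last.end + 50 * iso, region.end), strand
                    )
                models.append(TranscriptModel(tid, exons, strand, locus_id=locus))
                if single:
                    row = np.zeros(config.n_conditions)
                    row[conditions.index(cond)] = round(total * fracs[iso])
                else:
                    lam = max(total * fracs[iso] / config.n_conditions, 1.0)
                    row = rng.poisson(lam, config.n_conditions).astype(float)
                counts_rows[tid] = row
                truth_tx.append(
                    {"transcript_id": tid, "locus_id": locus, "block_id": block_id,
                     "role": "signal", "single_condition": single,
                     "condition": cond if single else "", "isoform_frac": fracs[iso],
                     "bidirectional": bidir}
                )
            if bidir:
                tx_n += 1
                tid = f"TX{tx_n:05d}"
                p_strand = "-" if strand == "+" else "+"
                gap = int(rng.integers(150, 700))
                exon_lens = [int(rng.integers(120, 300)) for _ in range(config.exons_per_transcript)]
                intron_lens = [int(rng.integers(500, 1500)) for _ in range(config.exons_per_transcript - 1)]
                span = sum(exon_lens) + sum(intron_lens)
                main_5p = anchor if strand == "+" else base[-1].end - 1
                if p_strand == "-":
                    p_start = main_5p - gap + 1 - span
                else:
                    p_start = main_5p + gap
                exons, pos2 = [], p_start
                for k, el in enumerate(exon_lens):
                    exons.append(GenomicInterval(region.chrom, pos2, pos2 + el, p_strand))
                    if k < len(intron_lens):
                        pos2 += el + intron_lens[k]
                p_locus = f"BID{b_i + 1:04d}"
                models.append(TranscriptModel(tid, exons, p_strand, locus_id=p_locus))
                p_single = bool(rng.random() < config.tau_profile)
                p_cond = conditions[int(rng.integers(config.n_conditions))]
                p_total = int(rng.integers(500, 3000))
                if p_single:
                    row = np.zeros(config.n_conditions)
                    row[conditions.index(p_cond)] = p_total
                else:
                    row = rng.poisson(
                        max(p_total / config.n_conditions, 1.0), config.n_conditions
                    ).astype(float)
                counts_rows[tid] = row
                truth_tx.append(
                    {"transcript_id": tid, "locus_id": p_locus, "block_id": block_id,
                     "role": "bidirectional_partner", "single_condition": p_single,
                     "condition": p_cond if p_single else "", "isoform_frac": 1.0,
                     "bidirectional": True}
                )
        else:
            tx_n += 1
            tid = f"TX{tx_n:05d}"
            if rng.random() < 0.5:
                # single-exon decoy with real reads: removed by the spliced-only rule
                exon = GenomicInterval(region.chrom, anchor, anchor + int(rng.integers(300, 800)), strand)
                models.append(TranscriptModel(tid, [exon], strand, locus_id=f"DEC{b_i + 1:04d}"))
                row = rng.poisson(30.0, config.n_conditions).astype(float)
                role = "decoy_single_exon"
            else:
                # silent multi-exon decoy: removed by the expression filter
                exons = _exon_chain(region.chrom, anchor, config.exons_per_transcript, rng, strand)
                models.append(TranscriptModel(tid, exons, strand, locus_id=f"DEC{b_i + 1:04d}"))
                row = np.zeros(config.n_conditions)
                role = "decoy_silent"
            counts_rows[tid] = row
            truth_tx.append(
                {"transcript_id": tid, "locus_id": f"DEC{b_i + 1:04d}", "block_id": block_id,
                 "role": role, "single_condition": False, "condition": "",
                 "isoform_frac": 1.0, "bidirectional": False}
            )
    # housekeeping loci outside the blocks keep every condition's library
    # non-degenerate (positive counts in all conditions)
    block_set = IntervalSet(blocks.values()).merge()
    free = layout.as_interval_set().subtract(block_set)
    gaps = [iv for iv in free if iv.length > max_span + 2]
    for h in range(config.n_housekeeping):
        gap = gaps[int(rng.integers(len(gaps)))]
        anchor = int(rng.integers(gap.start, gap.end - max_span))
        strand = "+" if rng.random() < 0.5 else "-"
        tx_n += 1
        tid = f"TX{tx_n:05d}"
        exons = _exon_chain(gap.chrom, anchor, config.exons_per_transcript, rng, strand)
        models.append(TranscriptModel(tid, exons, strand, locus_id=f"HK{h + 1:03d}"))
        counts_rows[tid] = rng.poisson(200.0, config.n_conditions).astype(float) + 1.0
        truth_tx.append(
            {"transcript_id": tid, "locus_id": f"HK{h + 1:03d}", "block_id": "",
             "role": "housekeeping", "single_condition": False, "condition": "",
             "isoform_frac": 1.0, "bidirectional": False}
        )
    counts = pd.DataFrame.from_dict(counts_rows, orient="index", columns=conditions)
    counts.index.name = "transcript_id"
    return Transcriptome(
        models, counts, pd.DataFrame(truth_tx), pd.DataFrame(truth_blocks)
    )


# ---------------------------------------------------------------------------
# Peak tracks and SNP catalogs
# ---------------------------------------------------------------------------

@dataclass
class MarksAndSnps:
    marks: dict[str, IntervalSet]
    snps: pd.DataFrame  # chrom, pos, snp_id, class in {gwas, common}
    elements: dict[str, IntervalSet]  # disjoint: promoters / exons / introns
    truth: dict
    # one row per locus: representative transcript + per-mark planted flags
    truth_loci: pd.DataFrame = field(default_factory=pd.DataFrame)


def _sample_positions(s: IntervalSet, n: int, rng: np.random.Generator) -> list[tuple[str, int]]:
    """n positions uniform over the bases covered by s."""
    entries = [
        (chrom, int(a), int(b))
        for chrom, arr in sorted(s.per_chrom().items())
        for a, b in arr
    ]
    lengths = np.array([b - a for _, a, b in entries], dtype=float)
    if lengths.sum() == 0:
        raise ValueError("cannot sample positions from an empty interval set")
    probs = lengths / lengths.sum()
    picks = rng.choice(len(entries), size=n, p=probs)
    out = []
    for k in picks:
        chrom, a, b = entries[k]
        out.append((chrom, int(rng.integers(a, b))))
    return out


def transcript_elements(models: Sequence[TranscriptModel], promoter_bp: int = 500) -> dict[str, IntervalSet]:
    """Disjoint promoter/exon/intron element classes from transcript models.

    Promoters are the strand-aware upstream windows of 5' ends; introns and
    promoters are trimmed of any exonic overlap so each base belongs to one
    class.
    """
    exons = IntervalSet(e for m in models for e in m.exons).merge()
    introns = IntervalSet(i for m in models for i in m.introns()).merge().subtract(exons)
    promoters = []
    for m in models:
        p = m.five_prime_pos
        if m.strand == "+":
            promoters.append(GenomicInterval(m.chrom, max(0, p - promoter_bp), max(1, p)))
        else:
            promoters.append(GenomicInterval(m.chrom, p + 1, p + 1 + promoter_bp))
    prom = IntervalSet(promoters).merge().subtract(exons).subtract(introns)
    return {"promoters": prom, "exons": exons, "introns": introns}


def simulate_marks_and_snps(
    config: SimConfig,
    models: Sequence[TranscriptModel],
    rng: np.random.Generator | None = None,
) -> MarksAndSnps:
    """Peak tracks with planted promoter-mark fractions, and SNP catalogs
    realizing the configured GWAS element odds ratio in expectation."""
    if rng is None:
        rng = _stage_rngs(config)["marks"]
    layout = genome_layout(config)
    half = config.peak_width_bp // 2
    # Marks are planted per promoter *site*: isoforms share a promoter, and
    # divergent (head-to-head) loci share one bidirectional promoter region,
    # so one planting decision is made per cluster of overlapping 5'+-500
    # windows.  The planted fraction is then recoverable from one
    # representative transcript per site.
    locus_reps: list[TranscriptModel] = []
    seen: set[str] = set()
    for m in models:
        locus = m.locus_id or m.transcript_id
        if locus not in seen:
            seen.add(locus)
            locus_reps.append(m)
    windows = sorted(
        locus_reps,
        key=lambda m: (m.chrom, m.five_prime_pos),
    )
    reps: list[TranscriptModel] = []
    for m in windows:
        if (
            reps
            and reps[-1].chrom == m.chrom
            and abs(reps[-1].five_prime_pos - m.five_prime_pos) <= 1_000
        ):
            continue  # same promoter site as the previous representative
        reps.append(m)
    marks: dict[str, IntervalSet] = {}
    planted_frac: dict[str, float] = {}
    loci_rows = {
        "locus_id": [m.locus_id or m.transcript_id for m in reps],
        "transcript_id": [m.transcript_id for m in reps],
    }
    for mark in MARKS:
        chosen = rng.random(len(reps)) < config.promoter_mark_frac
        loci_rows[f"planted_{mark}"] = list(map(bool, chosen))
        peaks = []
        for m, hit in zip(reps, chosen):
            if not hit:
                continue
            center = m.five_prime_pos + int(rng.integers(-50, 51))
            start = max(0, center - half)
            peaks.append(
                GenomicInterval(
                    m.chrom, start, min(start + config.peak_width_bp, layout.chrom_sizes[m.chrom])
                )
            )
        n_bg = rng.poisson(config.background_mark_rate * layout.total_bases)
        for chrom, pos in _sample_positions(layout.as_interval_set(), int(n_bg), rng):
            start = max(0, pos - half)
            peaks.append(
                GenomicInterval(chrom, start, min(start + config.peak_width_bp,
                                                  layout.chrom_sizes[chrom]))
            )
        marks[mark] = IntervalSet(peaks)
        planted_frac[mark] = float(np.mean(chosen)) if len(reps) else 0.0
    elements = transcript_elements(models)
    class_names = ["promoters", "exons", "introns"]
    bases = np.array([elements[c].total_bases() for c in class_names], dtype=float)
    if (bases == 0).any():
        raise ValueError("an element class is empty; need transcripts with introns")
    odds = np.array([config.gwas_element_or, config.gwas_element_or, 1.0])
    snp_rows = []
    common_share = bases / bases.sum()
    gwas_share = bases * odds / (bases * odds).sum()
    for klass, n, share in (
        ("common", config.n_common_snps, common_share),
        ("gwas", config.n_gwas_snps, gwas_share),
    ):
        counts = rng.multinomial(n, share)
        i = 0
        for cname, k in zip(class_names, counts):
            if k == 0:
                continue
            for chrom, pos in _sample_positions(elements[cname], int(k), rng):
                i += 1
                snp_rows.append(
                    {"chrom": chrom, "pos": pos, "snp_id": f"{klass}_{i:05d}", "class": klass}
                )
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "snp_id", "class"])
    truth = {
        "promoter_mark_frac": config.promoter_mark_frac,
        "planted_frac_realized": planted_frac,
        "gwas_element_or": config.gwas_element_or,
    }
    return MarksAndSnps(marks, snps, elements, truth, pd.DataFrame(loci_rows))


# ---------------------------------------------------------------------------
# Allele-specific counts
# ---------------------------------------------------------------------------

def simulate_ase(
    config: SimConfig,
    transcript_ids: Sequence[str],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Allele-specific read counts with a planted imbalanced subset.

    Null transcripts draw reference reads Binomial(depth, 0.5); planted
    ones Binomial(depth, ai_effect).  Depths are Poisson(depth_mean) with a
    configurable floor.
    """
    if rng is None:
        rng = _stage_rngs(config)["ase"]
    rows, truth_rows = [], []
    for t_i, tid in enumerate(transcript_ids):
        planted = bool(rng.random() < config.ai_frac)
        p = config.ai_effect if planted else 0.5
        for s in range(config.snps_per_transcript):
            depth = max(config.min_depth, int(rng.poisson(config.depth_mean)))
            ref = int(rng.binomial(depth, p))
            rows.append(
                {"transcript_id": tid, "snp_id": f"{tid}_snp{s + 1}",
                 "chrom": "chr1", "pos": 1000 * t_i + s,
                 "ref_reads": ref, "alt_reads": depth - ref}
            )
        truth_rows.append({"transcript_id": tid, "planted_imbalance": planted})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    config: SimConfig
    layout: GenomeLayout
    panel: LdPanel
    annotation: AnnotationSet
    repeats: IntervalSet
    transcriptome: Transcriptome
    marks_snps: MarksAndSnps
    ase: pd.DataFrame
    ase_truth: pd.DataFrame


def simulate_all(config: SimConfig, out_dir: str | Path | None = None) -> SimBundle:
    """Generate every pipeline input; optionally write the full fixture tree."""
    rngs = _stage_rngs(config)
    layout = genome_layout(config)
    panel = simulate_ld_panel(config, rngs["ld"])
    annotation, repeats = simulate_annotation(config, rngs["annotation"])
    blocks = panel.block_intervals()
    txome = simulate_transcriptome(config, blocks, rngs["transcriptome"])
    ms = simulate_marks_and_snps(config, txome.models, rngs["marks"])
    signal_ids = txome.truth_transcripts.query("role == 'signal'")["transcript_id"].tolist()
    ase, ase_truth = simulate_ase(config, signal_ids, rngs["ase"])
    bundle = SimBundle(config, layout, panel, annotation, repeats, txome, ms, ase, ase_truth)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> None:
    from .transcripts import write_transcripts_gtf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.layout.to_tsv(out / "genome.sizes.tsv")
    bundle.panel.proxies.to_csv(out / "proxies.tsv", sep="\t", index=False)
    with open(out / "hotspots.bed", "w") as fh:
        for h in bundle.panel.hotspots:
            fh.write(f"{h.chrom}\t{h.pos}\t{h.pos + 1}\n")
    bundle.panel.truth_blocks.to_csv(out / "truth_blocks.tsv", sep="\t", index=False)
    write_annotation_gtf(bundle.annotation, out / "annotation.gtf")
    write_bed(bundle.repeats, out / "repeats.bed")
    write_transcripts_gtf(bundle.transcriptome.models, out / "transcripts.gtf")
    counts = bundle.transcriptome.counts.astype(int)
    counts.to_csv(out / "counts.tsv", sep="\t")
    bundle.transcriptome.truth_transcripts.to_csv(
        out / "truth_transcripts.tsv", sep="\t", index=False
    )
    bundle.transcriptome.truth_blocks.to_csv(
        out / "truth_occupancy.tsv", sep="\t", index=False
    )
    for mark, peaks in bundle.marks_snps.marks.items():
        write_bed(peaks, out / f"peaks_{mark}.bed")
    for cname, s in bundle.marks_snps.elements.items():
        write_bed(s, out / f"elements_{cname}.bed")
    bundle.marks_snps.snps.to_csv(out / "snps.tsv", sep="\t", index=False)
    bundle.marks_snps.truth_loci.to_csv(out / "truth_marks.tsv", sep="\t", index=False)
    bundle.ase.to_csv(out / "ase.tsv", sep="\t", index=False)
    bundle.ase_truth.to_csv(out / "truth_ase.tsv", sep="\t", index=False)
    bundle.config.to_yaml(out / "config.resolved.yaml")
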