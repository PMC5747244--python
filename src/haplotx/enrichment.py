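"""Nucleotide- and SNP-level enrichment statistics.

The core object is a 2x2 contingency table over genomic bases: for a
region of interest R and an annotation A,

    a = bases covered by both R and A
    b = bases of A outside R
    c = bases of R outside A
    d = bases of the (effective) genome in neither

The odds ratio is (a/b)/(c/d); the standard error of log OR is
sqrt(1/a + 1/b + 1/c + 1/d) and the 95% CI is log OR +/- 1.96 SE.  P values
come from the chi-square test on the table, with Yates continuity
correction by default (matching the conventional 2x2 behaviour of standard
statistical software).  Exclusion zones (e.g. annotated promoters and
exons) are subtracted from R, A, and the genome total before counting.

Randomized-placement controls re-place the ROI intervals uniformly at
random in the allowed genome, preserving lengths and chromosome
assignment, and recompute the statistic per replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeLayout, GenomicInterval, IntervalSet
from .transcripts import TranscriptModel

Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d base (or SNP) counts; cells may be half-integral after the
    Haldane-Anscombe correction."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> "ContingencyTable":
        """Haldane-Anscombe +0.5 on every cell (for OR/CI with zero cells)."""
        return ContingencyTable(self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)


@dataclass
class EnrichmentResult:
    log_or: float
    ci_low: float
    ci_high: float
    p_value: float
    table: ContingencyTable
    n_randomizations: int = 0
    p_adj: float | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)


def contingency(
    roi: IntervalSet,
    annotation: IntervalSet,
    genome: GenomeLayout,
    exclusions: IntervalSet | None = None,
) -> ContingencyTable:
    """Build the base-count table after removing exclusion zones everywhere.

    Cells sum to the effective genome size (total bases minus excluded
    bases).
    """
    if exclusions is None:
        exclusions = IntervalSet()
    effective = genome.total_bases - exclusions.merge().total_bases()
    if effective <= 0:
        raise ValueError("exclusions cover the entire genome")
    roi_x = roi.subtract(exclusions)
    ann_x = annotation.subtract(exclusions)
    a = roi_x.overlap_bases(ann_x)
    b = ann_x.total_bases() - a
    c = roi_x.total_bases() - a
    d = effective - a - b - c
    return ContingencyTable(a, b, c, d)


def chi_square_2x2(
    table: ContingencyTable,
    yates: bool = True,
    alternative: str = "two-sided",
) -> float:
    """Chi-square p value for the 2x2 table.

    alternative="greater" halves the two-sided p when the observed odds
    ratio exceeds 1 (and takes the complement-half otherwise), the usual
    one-sided reading of the chi-square on one degree of freedom.
    """
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if obs.sum() == 0:
        raise ValueError("empty contingency table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        # a degenerate margin carries no evidence of association
        p_two = 1.0
    else:
        res = stats.chi2_contingency(obs, correction=yates)
        p_two = float(res.pvalue)
    if alternative == "two-sided":
        return p_two
    if alternative == "greater":
        with np.errstate(divide="ignore", invalid="ignore"):
            or_gt_1 = table.a * table.d > table.b * table.c
        return p_two / 2 if or_gt_1 else 1 - p_two / 2
    raise ValueError(f"unknown alternative {alternative!r}")


def odds_ratio(
    table: ContingencyTable,
    haldane: bool = False,
    yates: bool = True,
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Odds ratio (a/b)/(c/d) with normal-approximation CI on the log scale.

    The chi-square p value is always computed on the uncorrected counts;
    the Haldane-Anscombe correction applies to the OR and CI only.
    """
    work = table
    if min(table.a, table.b, table.c, table.d) == 0:
        if not haldane:
            raise ValueError(
                "zero contingency cell: enable the Haldane-Anscombe correction "
                "(haldane=True) to compute a finite odds ratio"
            )
        work = table.corrected()
    log_or = math.log((work.a / work.b) / (work.c / work.d))
    se = math.sqrt(1 / work.a + 1 / work.b + 1 / work.c + 1 / work.d)
    p = chi_square_2x2(table, yates=yates, alternative=alternative)
    return EnrichmentResult(log_or, log_or - Z_95 * se, log_or + Z_95 * se, p, table)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    from statsmodels.stats.multitest import multipletests

    if len(p_values) == 0:
        return np.array([])
    return multipletests(p_values, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Randomized-placement controls
# ---------------------------------------------------------------------------

def _allowed_gaps(genome: GenomeLayout, exclusions: IntervalSet) -> dict[str, np.ndarray]:
    allowed = genome.as_interval_set().subtract(exclusions)
    return allowed.per_chrom()


def place_randomly(
    roi: IntervalSet,
    genome: GenomeLayout,
    exclusions: IntervalSet,
    rng: np.random.Generator,
    cross_chromosome: bool = False,
) -> IntervalSet:
    """Place length-preserved copies of the ROI intervals uniformly at random
    in the allowed genome (outside exclusions, inside chromosomes).

    By default intervals stay on their own chromosome; cross_chromosome
    pools gaps genome-wide.
    """
    gaps_by_chrom = _allowed_gaps(genome, exclusions)
    placed: list[GenomicInterval] = []
    for iv in roi.merge():
        length = iv.length
        if cross_chromosome:
            pool = [
                (chrom, s, e)
                for chrom, arr in gaps_by_chrom.items()
                for s, e in arr
                if e - s >= length
            ]
        else:
            arr = gaps_by_chrom.get(iv.chrom, np.zeros((0, 2), dtype=np.int64))
            pool = [(iv.chrom, s, e) for s, e in arr if e - s >= length]
        if not pool:
            raise ValueError(
                f"no allowed gap can host an interval of length {length} "
                f"({'genome-wide' if cross_chromosome else iv.chrom})"
            )
        weights = np.array([e - s - length + 1 for _, s, e in pool], dtype=float)
        k = rng.choice(len(pool), p=weights / weights.sum())
        chrom, s, e = pool[k]
        start = int(rng.integers(s, e - length + 1))
        placed.append(GenomicInterval(chrom, start, start + length))
    return IntervalSet(placed)


def randomized_control(
    roi: IntervalSet,
    annotation: IntervalSet,
    genome: GenomeLayout,
    exclusions: IntervalSet | None = None,
    n_rand: int = 100,
    seed: int = 0,
    haldane: bool = True,
    cross_chromosome: bool = False,
) -> list[EnrichmentResult]:
    """Enrichment statistics for n_rand random re-placements of the ROI."""
    if n_rand < 1:
        raise ValueError("n_rand must be >= 1")
    if exclusions is None:
        exclusions = IntervalSet()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_rand):
        fake = place_randomly(roi, genome, exclusions, rng, cross_chromosome)
        table = contingency(fake, annotation, genome, exclusions)
        res = odds_ratio(table, haldane=haldane)
        res.n_randomizations = n_rand
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# TSS enrichment (5' ends +/- flank) and element-level SNP enrichment
# ---------------------------------------------------------------------------

def tss_windows(
    transcripts: Sequence[TranscriptModel],
    flank_bp: int = 500,
    genome: GenomeLayout | None = None,
) -> IntervalSet:
    """Strand-aware windows of +/- flank around transcript 5' ends."""
    out = []
    for m in transcripts:
        p = m.five_prime_pos
        start = max(0, p - flank_bp)
        end = p + flank_bp
        if genome is not None:
            end = min(end, genome.chrom_sizes[m.chrom])
        out.append(GenomicInterval(m.chrom, start, end))
    return IntervalSet(out)


def tss_enrichment(
    transcripts: Sequence[TranscriptModel],
    annotation: IntervalSet,
    genome: GenomeLayout,
    gencode,
    flank_bp: int = 500,
    promoter_excl_bp: int = 500,
    exon_pad_bp: int = 200,
    n_rand: int = 0,
    seed: int = 0,
    haldane: bool = False,
) -> tuple[EnrichmentResult, list[EnrichmentResult]]:
    """Enrichment of an annotation (e.g. CAGE clusters) at transcript starts.

    The ROI is the set of 5'-end windows; exclusions are annotated promoter
    windows (+/- promoter_excl_bp around annotated TSSs) plus annotated
    exons padded by exon_pad_bp.  `gencode` is the AnnotationSet supplying
    those exclusions.  Optionally computes randomized-placement controls.
    """
    roi = tss_windows(transcripts, flank_bp, genome)
    exclusions = IntervalSet(
        list(gencode.tss_windows(promoter_excl_bp))
        + list(gencode.padded_exon_set(exon_pad_bp))
    ).merge()
    table = contingency(roi, annotation, genome, exclusions)
    result = odds_ratio(table, haldane=haldane)
    controls: list[EnrichmentResult] = []
    if n_rand > 0:
        controls = randomized_control(
            roi, annotation, genome, exclusions, n_rand=n_rand, seed=seed
        )
    return result, controls


def element_snp_enrichment(
    elements: Mapping[str, IntervalSet],
    gwas_snps: pd.DataFrame,
    common_snps: pd.DataFrame,
    reference_class: str = "introns",
    haldane: bool = False,
) -> dict[str, EnrichmentResult]:
    """Per-element enrichment of GWAS SNPs relative to the intronic reference.

    For each element class e (promoters, exons, 3' UTRs, ...), the table
    counts SNPs: {GWAS, common} x {in e, in reference introns}.  SNP frames
    need columns chrom and pos.  P values are one-sided ("greater");
    Benjamini-Hochberg adjusted p values are attached across classes.
    """
    if reference_class not in elements:
        raise ValueError(f"elements must include the reference class {reference_class!r}")
    ref = elements[reference_class]
    if ref.total_bases() == 0:
        raise ValueError("reference (intron) class is empty")

    def count_in(snps: pd.DataFrame, s: IntervalSet) -> int:
        return int(s.contains_points(snps["chrom"].tolist(), snps["pos"].tolist()).sum())

    g_ref = count_in(gwas_snps, ref)
    c_ref = count_in(common_snps, ref)
    results: dict[str, EnrichmentResult] = {}
    for name, s in elements.items():
        if name == reference_class:
            continue
        table = ContingencyTable(
            count_in(gwas_snps, s), g_ref, count_in(common_snps, s), c_ref
        )
        results[name] = odds_ratio(table, haldane=haldane, alternative="greater")
    names = list(results)
    q = bh_adjust([results[n].p_value for n in names])
    for n, qv in zip(names, q):
        results[n].p_adj = float(qv)
    return results


def results_to_frame(results: Mapping[str, EnrichmentResult]) -> pd.DataFrame:
    rows = []
    for name, r in results.items():
        rows.append(
            {
                "name": name,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "log_or": r.log_or,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_value,
                "p_adj": r.p_adj,
            }
        )
    return pd.DataFrame(rows)
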