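"""Allelic-imbalance calling from allele-specific read counts.

Given heterozygous-site read counts per transcript, each SNP with
sufficient depth (default >= 30 reads) is tested against a balanced null
(reference-allele fraction 0.5, configurable for mapping-bias-adjusted
nulls) with a two-sided exact binomial test; per-transcript evidence is
combined across SNPs with Fisher's method.  The imbalance magnitude is
reported as |0.5 - median allelic ratio|, in [0, 0.5].  Transcripts are
flagged at a Benjamini-Hochberg FDR threshold (default 0.1).

This is a deliberately simple per-SNP model: haplotype phase is ignored
and SNPs are treated as independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust


@dataclass(frozen=True)
class AllelicCount:
    transcript_id: str
    snp_id: str
    ref_reads: int
    alt_reads: int

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def ratio(self) -> float:
        return self.ref_reads / self.total


@dataclass
class AllelicResult:
    transcript_id: str
    ai_measure: float  # |0.5 - median allelic ratio|, in [0, 0.5]
    median_ratio: float
    n_snps_used: int
    p_value: float
    q_value: float | None = None
    flag: bool = False


def filter_snps(counts: Iterable[AllelicCount], min_reads: int = 30) -> list[AllelicCount]:
    """Keep SNPs with total depth >= min_reads (inclusive)."""
    return [c for c in counts if c.total >= min_reads]


def transcript_ai(
    counts: Sequence[AllelicCount], null_ratio: float = 0.5
) -> AllelicResult:
    """Imbalance measure and combined p value for one transcript's SNPs.

    Per-SNP two-sided exact binomial p against null_ratio; the transcript p
    is Fisher's combination (-2 sum ln p ~ chi2 with 2k df).
    """
    if not counts:
        raise ValueError("transcript_ai needs at least one surviving SNP")
    tid = counts[0].transcript_id
    ratios = np.array([c.ratio for c in counts])
    pvals = [
        stats.binomtest(c.ref_reads, c.total, null_ratio, alternative="two-sided").pvalue
        for c in counts
    ]
    stat = -2.0 * np.sum(np.log(np.clip(pvals, np.finfo(float).tiny, 1.0)))
    p_comb = float(stats.chi2.sf(stat, df=2 * len(pvals)))
    med = float(np.median(ratios))
    return AllelicResult(
        transcript_id=tid,
        ai_measure=abs(0.5 - med),
        median_ratio=med,
        n_snps_used=len(counts),
        p_value=p_comb,
    )


def ai_fdr(results: Sequence[AllelicResult], fdr_threshold: float = 0.1) -> list[AllelicResult]:
    """Attach Benjamini-Hochberg q-values across transcripts and flag
    q < fdr_threshold."""
    q = bh_adjust([r.p_value for r in results])
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        r.flag = bool(qv < fdr_threshold)
    return list(results)


def call_allelic_imbalance(
    counts: Iterable[AllelicCount],
    min_reads: int = 30,
    fdr_threshold: float = 0.1,
    null_ratio: float = 0.5,
) -> tuple[list[AllelicResult], list[str]]:
    """Full pipeline: depth filter, per-transcript testing, FDR flagging.

    Returns (results, transcript ids omitted for lack of surviving SNPs).
    """
    surviving = filter_snps(counts, min_reads)
    by_tx: dict[str, list[AllelicCount]] = {}
    all_tx: set[str] = set()
    for c in counts if isinstance(counts, list) else list(counts):
        all_tx.add(c.transcript_id)
    for c in surviving:
        by_tx.setdefault(c.transcript_id, []).append(c)
    results = [transcript_ai(v, null_ratio) for _, v in sorted(by_tx.items())]
    omitted = sorted(all_tx - set(by_tx))
    return ai_fdr(results, fdr_threshold), omitted


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

ASE_COLUMNS = ["transcript_id", "snp_id", "chrom", "pos", "ref_reads", "alt_reads"]


def read_ase_tsv(path: str | Path) -> list[AllelicCount]:
    df = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "snp_id", "ref_reads", "alt_reads"} - set(df.columns)
    if missing:
        raise ValueError(f"ASE table missing columns: {sorted(missing)}")
    return [
        AllelicCount(str(r.transcript_id), str(r.snp_id), int(r.ref_reads), int(r.alt_reads))
        for r in df.itertuples()
    ]


def results_to_frame(results: Sequence[AllelicResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [r.transcript_id for r in results],
            "n_snps": [r.n_snps_used for r in results],
            "median_ratio": [r.median_ratio for r in results],
            "ai_measure": [r.ai_measure for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "flag": [r.flag for r in results],
        }
    )
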