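"""Enrichment statistics: formula fidelity, exclusions, randomization."""

import math

import numpy as np
import pytest
from scipy import stats

from haplotx.capture import AnnotationSet
from haplotx.enrichment import (
    ContingencyTable,
    bh_adjust,
    chi_square_2x2,
    contingency,
    element_snp_enrichment,
    odds_ratio,
    place_randomly,
    randomized_control,
    tss_enrichment,
    tss_windows,
)
from haplotx.intervals import GenomeLayout, GenomicInterval, IntervalSet
from haplotx.transcripts import TranscriptModel

from conftest import base_mask, random_interval_set

import pandas as pd


def yates_chi2_p(a, b, c, d):
    """Textbook 2x2 chi-square with continuity correction (independent of
    the implementation's scipy call)."""
    n = a + b + c + d
    expected = [
        (a + b) * (a + c) / n,
        (a + b) * (b + d) / n,
        (c + d) * (a + c) / n,
        (c + d) * (b + d) / n,
    ]
    observed = [a, b, c, d]
    stat = sum(
        (abs(o - e) - 0.5) ** 2 / e if abs(o - e) > 0.5 else 0.0
        for o, e in zip(observed, expected)
    )
    return float(stats.chi2.sf(stat, df=1))


class TestContingency:
    def test_simple_partition(self):
        layout = GenomeLayout({"chr1": 10_000})
        roi = IntervalSet([GenomicInterval("chr1", 0, 1_000)])
        ann = IntervalSet([GenomicInterval("chr1", 500, 1_500)])
        t = contingency(roi, ann, layout)
        assert (t.a, t.b, t.c, t.d) == (500, 500, 500, 8_500)
        assert t.total == 10_000

    def test_identical_sets_zero_off_cells(self):
        layout = GenomeLayout({"chr1": 10_000})
        s = IntervalSet([GenomicInterval("chr1", 100, 600)])
        t = contingency(s, s, layout)
        assert (t.b, t.c) == (0, 0)

    def test_random_fixtures_with_exclusions_match_mask_oracle(self, toy_layout):
        rng = np.random.default_rng(31)
        for _ in range(100):
            roi = random_interval_set(rng, toy_layout, int(rng.integers(1, 30)))
            ann = random_interval_set(rng, toy_layout, int(rng.integers(1, 30)))
            excl = random_interval_set(rng, toy_layout, int(rng.integers(0, 10)))
            t = contingency(roi, ann, toy_layout, excl)
            mr, ma, mx = (base_mask(s, toy_layout) for s in (roi, ann, excl))
            a = b = c = d = 0
            for chrom in mr:
                keep = ~mx[chrom]
                r, an = mr[chrom][keep], ma[chrom][keep]
                a += int((r & an).sum())
                b += int((~r & an).sum())
                c += int((r & ~an).sum())
                d += int((~r & ~an).sum())
            assert (t.a, t.b, t.c, t.d) == (a, b, c, d)
            assert t.total == toy_layout.total_bases - sum(
                int(m.sum()) for m in mx.values()
            )

    def test_total_exclusion_raises(self, toy_layout):
        full = toy_layout.as_interval_set()
        with pytest.raises(ValueError, match="entire genome"):
            contingency(full, full, toy_layout, full)


class TestOddsRatio:
    def test_symmetric_table_is_null(self):
        r = odds_ratio(ContingencyTable(100, 100, 100, 100))
        assert r.log_or == 0.0
        assert np.isclose(r.ci_low, -r.ci_high)
        assert np.isclose(r.p_value, 1.0)

    def test_printed_formulas_match_hand_evaluation(self):
        a, b, c, d = 150, 850, 1000, 9000
        r = odds_ratio(ContingencyTable(a, b, c, d))
        expected_or = (a / b) / (c / d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert np.isclose(r.odds_ratio, expected_or, rtol=1e-12)
        assert np.isclose(r.ci_low, math.log(expected_or) - 1.96 * se, rtol=1e-12)
        assert np.isclose(r.ci_high, math.log(expected_or) + 1.96 * se, rtol=1e-12)
        assert np.isclose(r.p_value, yates_chi2_p(a, b, c, d), rtol=1e-10)

    def test_zero_cell_requires_correction(self):
        t = ContingencyTable(0, 100, 50, 1000)
        with pytest.raises(ValueError, match="Haldane"):
            odds_ratio(t)
        r = odds_ratio(t, haldane=True)
        assert math.isfinite(r.log_or)
        # corrected cells are the original + 0.5
        assert np.isclose(
            r.odds_ratio, (0.5 / 100.5) / (50.5 / 1000.5), rtol=1e-12
        )

    def test_scale_invariance_of_odds_ratio(self):
        base = odds_ratio(ContingencyTable(30, 10, 10, 30))
        scaled = odds_ratio(ContingencyTable(300, 100, 100, 300))
        assert np.isclose(base.log_or, scaled.log_or)

    def test_ci_always_brackets_estimate(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            cells = rng.integers(1, 10_000, 4)
            r = odds_ratio(ContingencyTable(*cells))
            assert r.ci_low <= r.log_or <= r.ci_high


class TestChiSquare:
    def test_balanced_table_statistic_zero(self):
        assert chi_square_2x2(ContingencyTable(50, 50, 50, 50)) == 1.0

    @pytest.mark.parametrize(
        "cells",
        [(30, 10, 10, 30), (150, 850, 1000, 9000), (7, 3, 11, 19), (200, 5, 40, 60)],
    )
    def test_matches_textbook_continuity_corrected_formula(self, cells):
        p = chi_square_2x2(ContingencyTable(*cells))
        assert np.isclose(p, yates_chi2_p(*cells), rtol=1e-10)

    def test_p_decreases_with_imbalance_at_fixed_margins(self):
        ps = [
            chi_square_2x2(ContingencyTable(50 + k, 50 - k, 50 - k, 50 + k))
            for k in range(0, 45, 5)
        ]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_one_sided_alternative_halves_p_in_the_right_direction(self):
        enriched = ContingencyTable(30, 10, 10, 30)
        depleted = ContingencyTable(10, 30, 30, 10)
        p_two = chi_square_2x2(enriched)
        assert np.isclose(chi_square_2x2(enriched, alternative="greater"), p_two / 2)
        assert chi_square_2x2(depleted, alternative="greater") > 0.5


class TestBH:
    def test_step_up_hand_computation(self):
        p = [0.001, 0.02, 0.8]
        q = bh_adjust(p)
        assert np.allclose(q, [0.003, 0.03, 0.8])

    def test_single_p_is_its_own_q(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)


class TestRandomizedControl:
    def test_deterministic_under_seed(self, toy_layout):
        rng = np.random.default_rng(0)
        roi = random_interval_set(rng, toy_layout, 5, max_len=300)
        ann = random_interval_set(rng, toy_layout, 10, max_len=300)
        a = randomized_control(roi, ann, toy_layout, n_rand=3, seed=99)
        b = randomized_control(roi, ann, toy_layout, n_rand=3, seed=99)
        assert [r.log_or for r in a] == [r.log_or for r in b]

    def test_placements_avoid_exclusions_and_preserve_lengths(self, toy_layout):
        rng = np.random.default_rng(1)
        roi = IntervalSet([GenomicInterval("chr1", 0, 500), GenomicInterval("chr2", 0, 250)])
        excl = IntervalSet([GenomicInterval("chr1", 2_000, 6_000)])
        placed = place_randomly(roi, toy_layout, excl, rng)
        assert sorted(i.length for i in placed) == [250, 500]
        assert placed.overlap_bases(excl) == 0
        toy_layout.validate(placed)

    def test_oversized_interval_raises(self, toy_layout):
        roi = IntervalSet([GenomicInterval("chr1", 0, 9_999)])
        excl = IntervalSet([GenomicInterval("chr1", 5_000, 5_001)])
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="no allowed gap"):
            place_randomly(roi, toy_layout, excl, rng)

    def test_independent_annotation_gives_null_centered_log_or(self):
        # annotation scattered uniformly, ROI re-placed 100 times: the mean
        # log OR must sit within 3 standard errors of zero
        layout = GenomeLayout({"chr1": 200_000})
        rng = np.random.default_rng(12)
        roi = IntervalSet(
            [GenomicInterval("chr1", int(s), int(s) + 400) for s in rng.integers(0, 199_000, 15)]
        )
        positions = rng.choice(200_000, size=4_000, replace=False)
        ann = IntervalSet([GenomicInterval("chr1", int(p), int(p) + 1) for p in positions])
        controls = randomized_control(roi, ann, layout, n_rand=100, seed=7)
        lors = np.array([r.log_or for r in controls])
        se = lors.std(ddof=1) / math.sqrt(len(lors))
        assert abs(lors.mean()) < 3 * se


class TestTssEnrichment:
    def test_window_coordinates_respect_strand(self):
        plus = TranscriptModel(
            "p", [GenomicInterval("chr1", 10_000, 10_200, "+")], "+"
        )
        minus = TranscriptModel(
            "m", [GenomicInterval("chr1", 19_800, 20_000, "-")], "-"
        )
        w = list(tss_windows([plus, minus], 500))
        assert (w[0].start, w[0].end) == (9_500, 10_500)
        # minus-strand 5' end is base 19,999; window centered there
        assert (w[1].start, w[1].end) == (19_499, 20_499)

    def test_planted_cage_signal_is_recovered(self):
        layout = GenomeLayout({"chr1": 1_000_000})
        rng = np.random.default_rng(3)
        transcripts = []
        peaks = []
        for i in range(50):
            start = 2_000 + i * 15_000
            transcripts.append(
                TranscriptModel(
                    f"t{i}",
                    [
                        GenomicInterval("chr1", start, start + 200, "+"),
                        GenomicInterval("chr1", start + 1_000, start + 1_200, "+"),
                    ],
                    "+",
                )
            )
            if rng.random() < 0.6:
                peaks.append(GenomicInterval("chr1", start - 50, start + 50))
        for p in rng.integers(0, 999_000, 10):  # sparse background
            peaks.append(GenomicInterval("chr1", int(p), int(p) + 100))
        gencode = AnnotationSet(
            pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "strand", "gene_type"]),
            pd.DataFrame(
                columns=["gene_id", "transcript_id", "chrom", "start", "end", "strand", "gene_type"]
            ),
        )
        result, _ = tss_enrichment(
            transcripts, IntervalSet(peaks), layout, gencode, haldane=True
        )
        assert result.log_or > 0
        assert result.ci_low > 0  # CI excludes the null


class TestElementSnpEnrichment:
    def _elements(self):
        return {
            "exons": IntervalSet([GenomicInterval("chr1", 0, 10_000)]),
            "introns": IntervalSet([GenomicInterval("chr1", 20_000, 120_000)]),
        }

    @staticmethod
    def _snps(n_exon, n_intron, prefix):
        rows = [
            {"chrom": "chr1", "pos": 5 + i, "snp_id": f"{prefix}e{i}", "class": prefix}
            for i in range(n_exon)
        ] + [
            {"chrom": "chr1", "pos": 20_005 + i, "snp_id": f"{prefix}i{i}", "class": prefix}
            for i in range(n_intron)
        ]
        return pd.DataFrame(rows)

    def test_direct_arithmetic_example(self):
        res = element_snp_enrichment(
            self._elements(), self._snps(20, 80, "gwas"), self._snps(200, 1800, "common")
        )
        assert np.isclose(res["exons"].odds_ratio, (20 / 80) / (200 / 1800))
        assert res["exons"].p_adj is not None

    def test_identical_distributions_give_unit_odds(self):
        res = element_snp_enrichment(
            self._elements(), self._snps(100, 900, "gwas"), self._snps(100, 900, "common")
        )
        assert np.isclose(res["exons"].log_or, 0.0)

    def test_zero_gwas_in_class_with_correction_is_depleted(self):
        res = element_snp_enrichment(
            self._elements(),
            self._snps(0, 100, "gwas"),
            self._snps(500, 500, "common"),
            haldane=True,
        )
        assert res["exons"].odds_ratio < 1
        assert math.isfinite(res["exons"].log_or)

    def test_missing_reference_class_raises(self):
        with pytest.raises(ValueError, match="introns"):
            element_snp_enrichment(
                {"exons": IntervalSet([GenomicInterval("chr1", 0, 100)])},
                self._snps(1, 1, "gwas"),
                self._snps(1, 1, "common"),
            )
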