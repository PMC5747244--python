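"""Expression normalization, retention filters, tiers, and occupancy."""

import numpy as np
import pandas as pd
import pytest

from haplotx.intervals import GenomicInterval, IntervalSet
from haplotx.transcripts import (
    ExpressionMatrix,
    TranscriptModel,
    assign_loci,
    expression_tiers,
    fpkm,
    occupancy,
    read_transcripts_gtf,
    retain_transcripts,
    size_factors,
    write_transcripts_gtf,
)


def tx(tid, spans, strand="+", chrom="chr1", locus=None):
    return TranscriptModel(
        tid, [GenomicInterval(chrom, s, e, strand) for s, e in spans], strand, locus_id=locus
    )


class TestTranscriptModel:
    def test_five_prime_end_respects_strand(self):
        spans = [(100, 200), (300, 400)]
        assert tx("a", spans, "+").five_prime_pos == 100
        assert tx("a", spans, "-").five_prime_pos == 399

    def test_introns_are_exact_gaps(self):
        m = tx("a", [(0, 100), (200, 300), (450, 500)])
        assert [(i.start, i.end) for i in m.introns()] == [(100, 200), (300, 450)]
        assert m.length_nt == 100 + 100 + 50

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            tx("a", [(0, 100), (50, 150)])


class TestAssignLoci:
    def test_shared_exonic_base_same_strand_clusters(self):
        models = [tx("a", [(0, 100)], "+"), tx("b", [(99, 300), (400, 500)], "+")]
        assign_loci(models)
        assert models[0].locus_id == models[1].locus_id

    def test_opposite_strands_never_cluster(self):
        models = [tx("a", [(0, 100)], "+"), tx("b", [(0, 100)], "-")]
        assign_loci(models)
        assert models[0].locus_id != models[1].locus_id

    def test_clustering_is_transitive_through_chains(self):
        models = [
            tx("a", [(0, 100)], "+"),
            tx("b", [(90, 200)], "+"),
            tx("c", [(190, 300)], "+"),
        ]
        assign_loci(models)
        assert len({m.locus_id for m in models}) == 1


class TestSizeFactors:
    def test_identical_columns_get_equal_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        f = size_factors(counts)
        assert np.allclose(f, [1.0, 1.0])

    def test_doubled_column_factor_is_doubled(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        f = size_factors(counts)
        assert np.isclose(f["b"] / f["a"], 2.0)

    def test_random_matrix_matches_stepwise_median_of_ratios(self):
        rng = np.random.default_rng(8)
        counts = pd.DataFrame(
            rng.integers(1, 500, (50, 4)), columns=list("abcd")
        )
        f = size_factors(counts)
        # independent step-by-step computation
        arr = counts.to_numpy(dtype=float)
        gm = np.exp(np.log(arr).mean(axis=1))
        expected = np.median(arr / gm[:, None], axis=0)
        assert np.allclose(f.to_numpy(), expected)

    def test_no_all_positive_transcript_raises(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="pseudocount"):
            size_factors(counts)


class TestFpkm:
    def test_direct_arithmetic(self):
        counts = pd.DataFrame({"a": [100, 10 ** 6 - 100]}, index=["t1", "t2"])
        lengths = pd.Series([1_000, 10 ** 9], index=["t1", "t2"])
        factors = pd.Series([1.0], index=["a"])
        out = fpkm(counts, lengths, factors)
        assert np.isclose(out.loc["t1", "a"], 100.0)

    def test_zero_count_gives_zero_and_length_halves(self):
        counts = pd.DataFrame({"a": [0, 100, 100]}, index=["t0", "t1", "t2"])
        lengths = pd.Series([500, 1_000, 2_000], index=["t0", "t1", "t2"])
        out = fpkm(counts, lengths, pd.Series([1.0], index=["a"]))
        assert out.loc["t0", "a"] == 0
        assert np.isclose(out.loc["t2", "a"], out.loc["t1", "a"] / 2)

    def test_invariance_to_consistent_scaling(self):
        # multiplying a condition's counts and its size factor together
        # leaves FPKM unchanged
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(1, 100, (10, 2)), columns=["a", "b"])
        lengths = pd.Series(rng.integers(200, 2000, 10), index=counts.index)
        f = pd.Series([1.0, 1.0], index=["a", "b"])
        base = fpkm(counts, lengths, f)
        scaled = counts.copy()
        scaled["b"] *= 7
        f2 = pd.Series([1.0, 7.0], index=["a", "b"])
        assert np.allclose(base, fpkm(scaled, lengths, f2))


def filter_fixture():
    """Three equal-length isoforms with shares 0.98 / 0.015 / 0.005, plus a
    single-exon transcript and one outside the capture space."""
    models = [
        tx("iso1", [(1_000, 2_000), (3_000, 4_000)], locus="L1"),
        tx("iso2", [(1_000, 2_000), (3_500, 4_500)], locus="L1"),
        tx("iso3", [(1_000, 2_000), (3_900, 4_900)], locus="L1"),
        tx("mono", [(10_000, 12_000)], locus="L2"),
        tx("outside", [(50_000, 51_000), (52_000, 53_000)], locus="L3"),
    ]
    shares = {"iso1": 0.98, "iso2": 0.015, "iso3": 0.005}
    col = [
        round(100_000 * shares["iso1"]),
        round(100_000 * shares["iso2"]),
        round(100_000 * shares["iso3"]),
        50_000,
        10_000,
    ]
    counts = pd.DataFrame(
        {"t1": col, "t2": col},
        index=["iso1", "iso2", "iso3", "mono", "outside"],
    )
    lengths = pd.Series(
        {m.transcript_id: m.length_nt for m in models}
    )
    expr = ExpressionMatrix(counts, lengths, pd.Series([1.0, 1.0], index=["t1", "t2"]))
    capture = IntervalSet([GenomicInterval("chr1", 0, 20_000)])
    return models, expr, capture


class TestRetainTranscripts:
    def test_isoform_share_threshold_is_strict(self):
        models, expr, capture = filter_fixture()
        retained = {m.transcript_id for m in retain_transcripts(models, expr, capture)}
        # iso3 contributes 0.5% < 1%; mono is single-exon; outside misses capture
        assert retained == {"iso1", "iso2"}

    def test_filters_are_conjunctive(self):
        models, expr, capture = filter_fixture()
        full = {m.transcript_id for m in retain_transcripts(models, expr, capture)}
        # relaxing each filter individually can only add transcripts back
        no_iso = {
            m.transcript_id
            for m in retain_transcripts(models, expr, capture, isoform_min_frac=0.0)
        }
        everywhere = IntervalSet([GenomicInterval("chr1", 0, 100_000)])
        no_capture = {
            m.transcript_id for m in retain_transcripts(models, expr, everywhere)
        }
        assert full <= no_iso and full <= no_capture

    def test_missing_locus_assignment_raises(self):
        models, expr, capture = filter_fixture()
        models[0].locus_id = None
        with pytest.raises(ValueError, match="locus"):
            retain_transcripts(models, expr, capture)


class TestExpressionTiers:
    def test_three_transcripts_span_all_tiers(self):
        models = [
            tx("lo", [(0, 100), (200, 300)], locus="L1"),
            tx("mid", [(1000, 1100), (1200, 1300)], locus="L2"),
            tx("hi", [(2000, 2100), (2200, 2300)], locus="L3"),
        ]
        counts = pd.DataFrame(
            {"t1": [2, 20, 200], "t2": [2, 20, 200]}, index=["lo", "mid", "hi"]
        )
        lengths = pd.Series(1000, index=counts.index)
        expr = ExpressionMatrix(counts, lengths, pd.Series([1.0, 1.0], index=["t1", "t2"]))
        tiers = expression_tiers(models, expr)
        assert tiers.tolist() == ["low", "medium", "high"]

    def test_ties_break_to_lower_tier(self):
        models = [tx(f"t{i}", [(i * 1000, i * 1000 + 100), (i * 1000 + 200, i * 1000 + 300)],
                     locus=f"L{i}") for i in range(3)]
        counts = pd.DataFrame({"a": [5, 5, 5], "b": [5, 5, 5]},
                              index=[m.transcript_id for m in models])
        expr = ExpressionMatrix(counts, pd.Series(1000, index=counts.index),
                                pd.Series([1.0, 1.0], index=["a", "b"]))
        tiers = expression_tiers(models, expr)
        assert set(tiers) == {"low"}

    def test_tier_boundaries_match_quantile_oracle(self):
        rng = np.random.default_rng(2)
        n = 300
        ids = [f"t{i}" for i in range(n)]
        models = [
            tx(t, [(i * 5000, i * 5000 + 100), (i * 5000 + 200, i * 5000 + 300)], locus=t)
            for i, t in enumerate(ids)
        ]
        vals = rng.lognormal(2, 1, n)
        counts = pd.DataFrame({"a": vals, "b": vals}, index=ids)
        expr = ExpressionMatrix(counts, pd.Series(1000, index=ids),
                                pd.Series([1.0, 1.0], index=["a", "b"]))
        tiers = expression_tiers(models, expr)
        maxf = expr.max_fpkm()
        q1, q2 = np.quantile(maxf, [1 / 3, 2 / 3])
        for t in ids:
            v = maxf[t]
            expected = "low" if v <= q1 else ("medium" if v <= q2 else "high")
            assert tiers[t] == expected


class TestOccupancy:
    def _expr(self, ids, values):
        counts = pd.DataFrame({"a": values, "b": values}, index=ids)
        return ExpressionMatrix(
            counts, pd.Series(1000, index=ids), pd.Series([1.0, 1.0], index=["a", "b"])
        )

    def test_no_transcripts_means_zero(self):
        blocks = [GenomicInterval("chr1", 0, 1000)]
        expr = self._expr(["x"], [10])
        assert occupancy(blocks, [], expr).fraction_occupied == 0.0

    def test_every_block_occupied_gives_one(self):
        blocks = [GenomicInterval("chr1", 0, 10_000), GenomicInterval("chr1", 20_000, 30_000)]
        models = [
            tx("a", [(100, 200), (300, 400)], locus="L1"),
            tx("b", [(21_000, 21_200), (22_000, 22_200)], locus="L2"),
        ]
        expr = self._expr(["a", "b"], [1000, 1000])
        result = occupancy(blocks, models, expr)
        assert result.fraction_occupied == 1.0

    def test_subthreshold_transcript_does_not_occupy(self):
        blocks = [GenomicInterval("chr1", 0, 10_000)]
        models = [tx("a", [(100, 200), (300, 400)], locus="L1")]
        counts = pd.DataFrame({"a": [1, 10 ** 7], "b": [1, 10 ** 7]}, index=["a", "filler"])
        expr = ExpressionMatrix(
            counts, pd.Series(1000, index=counts.index),
            pd.Series([1.0, 1.0], index=["a", "b"]),
        )
        result = occupancy(blocks, models, expr, fpkm_min=1.0)
        assert result.fraction_occupied == 0.0


class TestGtfRoundTrip:
    def test_models_survive_gtf_io(self, tmp_path):
        models = [
            tx("a", [(100, 200), (300, 400)], "+"),
            tx("b", [(1_000, 1_500)], "-", chrom="chr2"),
        ]
        path = tmp_path / "tx.gtf"
        write_transcripts_gtf(models, path)
        back = read_transcripts_gtf(path)
        assert [(m.transcript_id, m.strand, [(e.start, e.end) for e in m.exons]) for m in back] == [
            ("a", "+", [(100, 200), (300, 400)]),
            ("b", "-", [(1_000, 1_500)]),
        ]
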