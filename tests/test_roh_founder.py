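"""Genotype QC, ROH calling, shared segments, genetic map, age estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from startloss.roh_founder import (
    AgeEstimate,
    GeneticMap,
    GenotypeRecord,
    NoSharedSegmentError,
    ROHParams,
    ROHSegment,
    UnsortedInputError,
    allele_frequency,
    call_roh,
    estimate_generations,
    filter_genotypes,
    inbreeding_from_roh,
    interval_cM,
    shared_roh,
    simulate_shared_lengths,
    years_from_generations,
)


def _rec(pos, gt, dp=30, gq=99, sample="P1", contig="chr2"):
    return GenotypeRecord(sample=sample, contig=contig, pos=pos, genotype=gt,
                          depth=dp, gq=gq)


class TestFilterGenotypes:
    @pytest.mark.parametrize("dp,gq,kept", [
        (10, 50, True),  # thresholds are inclusive ("at least")
        (9, 99, False),
        (30, 49, False),
    ])
    def test_thresholds(self, dp, gq, kept):
        out, _ = filter_genotypes([_rec(1, "hom_ref", dp=dp, gq=gq)])
        assert bool(out) == kept

    def test_missing_format_and_genotype_tallied(self):
        records = [_rec(1, "hom_ref", dp=-1), _rec(2, "missing")]
        kept, tally = filter_genotypes(records)
        assert kept == []
        assert tally["missing_format"] == 1 and tally["missing_genotype"] == 1


def _brute_force_roh(genotypes, positions, params):
    """Enumerate every maximal run satisfying the four constraints."""
    runs = []
    cur = []
    for gt, pos in zip(genotypes, positions):
        if gt == "het":
            runs.append(cur)
            cur = []
            continue
        if gt == "missing":
            continue
        if cur and pos - cur[-1] > params.max_gap_kb * 1000:
            runs.append(cur)
            cur = []
        cur.append(pos)
    runs.append(cur)
    return [(r[0], r[-1], len(r)) for r in runs
            if len(r) >= params.min_snp
            and (r[-1] - r[0]) / 1000 >= params.min_kb]


class TestCallRoh:
    def test_six_hom_calls_over_150kb(self):
        records = [_rec(1 + 30_000 * i, "hom_alt") for i in range(6)]
        (seg,) = call_roh(records)
        assert seg.n_snps == 6 and seg.span_kb == pytest.approx(150.0)

    def test_too_few_snps_rejected(self):
        records = [_rec(1 + 66_000 * i, "hom_ref") for i in range(4)]  # 200 kb span
        assert call_roh(records) == []

    def test_het_breaks_run(self):
        positions = [1 + 30_000 * i for i in range(10)]
        gts = ["hom_ref"] * 5 + ["het"] + ["hom_alt"] * 4
        records = [_rec(p, g) for p, g in zip(positions, gts)]
        segs = call_roh(records)
        assert len(segs) == 1 and segs[0].n_snps == 5  # the 4-run fails min_snp

    def test_gap_splits_candidate_runs(self):
        cluster1 = [_rec(1 + 30_000 * i, "hom_ref") for i in range(6)]
        cluster2 = [_rec(12_200_001 + 30_000 * i, "hom_ref") for i in range(6)]
        segs = call_roh(cluster1 + cluster2)
        assert len(segs) == 2

    def test_unsorted_input_is_an_error(self):
        with pytest.raises(UnsortedInputError):
            call_roh([_rec(200, "hom_ref"), _rec(100, "hom_ref")])

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.sampled_from(["hom_ref", "het", "hom_alt", "missing"]),
                  st.integers(1, 60_000)),
        min_size=0, max_size=200))
    def test_equals_brute_force_enumeration(self, items):
        """Caller ≡ exhaustive maximal-run oracle on random genotype strings."""
        params = ROHParams(min_snp=3, min_kb=50, max_gap_kb=100)
        positions = np.cumsum([gap for _, gap in items]).tolist()
        genotypes = [gt for gt, _ in items]
        records = [_rec(p, g) for p, g in zip(positions, genotypes)]
        got = [(s.start_pos, s.end_pos, s.n_snps) for s in call_roh(records, params)]
        assert got == _brute_force_roh(genotypes, positions, params)


class TestSharedRoh:
    def _seg(self, sample, start, end):
        return ROHSegment(sample=sample, contig="chr2", start_pos=start,
                          end_pos=end, n_snps=10)

    def test_max_of_starts_min_of_ends(self):
        segs = {"a": [self._seg("a", 100, 200)], "b": [self._seg("b", 120, 260)],
                "c": [self._seg("c", 90, 210)]}
        shared = shared_roh(segs, "chr2", 150)
        assert (shared.start_pos, shared.end_pos) == (120, 200)

    def test_identical_segments_returned_as_is(self):
        segs = {s: [self._seg(s, 100, 200)] for s in "abc"}
        shared = shared_roh(segs, "chr2", 150)
        assert (shared.start_pos, shared.end_pos) == (100, 200)

    def test_missing_focal_roh_names_samples(self):
        segs = {"a": [self._seg("a", 100, 200)], "b": [self._seg("b", 300, 400)]}
        with pytest.raises(NoSharedSegmentError) as exc:
            shared_roh(segs, "chr2", 150)
        assert exc.value.samples == ["b"]

    def test_idempotent_under_covering_sample(self):
        segs = {"a": [self._seg("a", 100, 200)], "b": [self._seg("b", 120, 260)]}
        base = shared_roh(segs, "chr2", 150)
        segs["c"] = [self._seg("c", base.start_pos - 50, base.end_pos + 50)]
        again = shared_roh(segs, "chr2", 150)
        assert (again.start_pos, again.end_pos) == (base.start_pos, base.end_pos)


class TestGeneticMap:
    def _map(self):
        return GeneticMap({"chr2": (np.array([0.0, 10e6]), np.array([0.0, 12.0]))})

    def test_linear_interpolation(self):
        assert interval_cM(self._map(), "chr2", 2_000_000, 7_000_000) \
            == pytest.approx(6.0)

    def test_zero_length_interval(self):
        assert interval_cM(self._map(), "chr2", 5_000_000, 5_000_000) == 0.0

    def test_additivity_across_panels(self):
        gmap = GeneticMap({"chr2": (np.array([0.0, 2e6, 5e6, 10e6]),
                                    np.array([0.0, 1.0, 7.0, 9.5]))})
        a, b, c = 500_000, 3_200_000, 8_700_000
        assert interval_cM(gmap, "chr2", a, b) + interval_cM(gmap, "chr2", b, c) \
            == pytest.approx(interval_cM(gmap, "chr2", a, c))

    def test_absent_contig_errors(self):
        with pytest.raises(KeyError):
            interval_cM(self._map(), "chrX", 0, 100)

    def test_tsv_round_trip(self, tmp_path):
        gmap = self._map()
        gmap.to_tsv(tmp_path / "map.tsv")
        back = GeneticMap.from_tsv(tmp_path / "map.tsv")
        assert interval_cM(back, "chr2", 1_000_000, 4_000_000) \
            == pytest.approx(interval_cM(gmap, "chr2", 1_000_000, 4_000_000))


class TestAgeEstimation:
    def test_point_estimate_formula(self):
        est = estimate_generations(4.0, n_paths=10, seed=0, n_boot=100)
        assert est.generations == pytest.approx(5.0)

    def test_inverse_proportionality(self):
        a = estimate_generations(4.0, n_paths=10, seed=0, n_boot=100)
        b = estimate_generations(2.0, n_paths=10, seed=0, n_boot=100)
        assert b.generations == pytest.approx(2 * a.generations)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_generations(0.0, n_paths=10)
        with pytest.raises(ValueError):
            estimate_generations(1.0, n_paths=0)

    def test_ci_brackets_point_estimate(self):
        est = estimate_generations(0.77, n_paths=10, seed=3)
        assert est.ci_low < est.generations < est.ci_high

    def test_median_recovery_matches_closed_form(self):
        """median(ĝ)/g equals the Gamma(2) factor 2/1.6783 ≈ 1.192: the
        method-of-moments point estimate is median-biased upward by a known,
        derivable constant under the erosion model."""
        # closed form: L ~ Gamma(2, θ); median(L) = θ·m with (1+m)e^{-m} = 1/2
        from scipy.optimize import brentq

        m = brentq(lambda x: (1 + x) * np.exp(-x) - 0.5, 0.1, 5.0)
        factor = 2.0 / m
        rng = np.random.default_rng(0)
        for g in (5, 26, 100):
            lengths = simulate_shared_lengths(g, 10, 2000, rng)
            med = np.median(200.0 / (10 * lengths))
            assert med / g == pytest.approx(factor, rel=0.08)

    def test_median_recovery_within_40_percent(self):
        """Median estimate across replicates is within ±40% of the truth for
        g ∈ {5, 26, 100}."""
        rng = np.random.default_rng(1)
        for g in (5, 26, 100):
            lengths = simulate_shared_lengths(g, 10, 2000, rng)
            med = float(np.median(200.0 / (10 * lengths)))
            assert abs(med - g) / g <= 0.40

    def test_summary_mentions_key_fields(self):
        est = estimate_generations(1.0, n_paths=8, seed=5, n_boot=200)
        text = est.summary()
        assert "generations" in text and "95% CI" in text


class TestWorkedArithmetic:
    def test_generations_to_years(self):
        assert years_from_generations(26, 23) == pytest.approx(598)
        assert years_from_generations(10, 25) == pytest.approx(250)
        with pytest.raises(ValueError):
            years_from_generations(0)

    def test_allele_frequency(self):
        assert allele_frequency(15, 280_902) == pytest.approx(5.340e-5, rel=1e-3)
        with pytest.raises(ValueError):
            allele_frequency(5, 0)

    def test_inbreeding_coefficient_from_total_roh(self):
        # ~50 Mb of ROH against a 3.2 Gb genome is 1/64
        assert inbreeding_from_roh(50e6) == pytest.approx(1 / 64)
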