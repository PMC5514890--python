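"""Step 3 statistics: exact 2-means, error pooling, binomial test and power.

Independent oracles: the binomial tail is recomputed as an explicit sum of
exact-integer binomial coefficients times float powers; the 1-D 2-means
optimum is recomputed by naive enumeration of contiguous sorted splits.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelsnv import (
    ContractViolation,
    ControlObservation,
    ControlTable,
    FilterConfig,
    GenomicSite,
    RawCandidate,
    SiteErrorModel,
    SiteObservation,
    binomial_power,
    binomial_pvalue,
    bonferroni,
    estimate_error_rate,
    flag_recurrent_germline,
    judge_variants,
    kmeans_1d_two_clusters,
    power_filter,
    split_controls,
)

CFG = FilterConfig()
SITE = GenomicSite("chr1", 100, "C", "A")


# -- oracles -----------------------------------------------------------------

def tail_sum_oracle(X: int, n: int, p: float) -> float:
    """P[Binom(n,p) >= X] as an explicit sum, smallest terms first."""
    total = 0.0
    for k in range(n, X - 1, -1):
        total += math.comb(n, k) * p**k * (1.0 - p) ** (n - k)
    return min(total, 1.0)


def two_means_oracle(values):
    """Naive enumeration of all contiguous splits of the sorted values."""
    s = sorted(values)
    n = len(s)
    best_k, best_wss = None, None
    for k in range(1, n):
        lo, hi = s[:k], s[k:]
        mlo, mhi = sum(lo) / k, sum(hi) / (n - k)
        wss = sum((x - mlo) ** 2 for x in lo) + sum((x - mhi) ** 2 for x in hi)
        if best_wss is None or wss < best_wss - 1e-15:
            best_k, best_wss = k, wss
    return best_k, best_wss


# -- exact 1-D two-means -----------------------------------------------------

class TestKMeans1D:
    def test_germline_cluster_geometry(self):
        values = [0.35] * 5 + [0.02] * 130
        part = kmeans_1d_two_clusters(values)
        assert len(part.upper) == 5 and len(part.lower) == 130
        assert part.upper_mean == pytest.approx(0.35)
        assert part.lower_mean == pytest.approx(0.02)

    def test_two_points_split_trivially(self):
        part = kmeans_1d_two_clusters([0.0, 1.0])
        assert part.lower == [0] and part.upper == [1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ContractViolation):
            kmeans_1d_two_clusters([0.5])
        with pytest.raises(ContractViolation):
            kmeans_1d_two_clusters([0.3, 0.3, 0.3])

    @given(st.lists(st.floats(0, 1, width=32), min_size=2, max_size=40)
           .filter(lambda v: len(set(v)) > 1))
    @settings(max_examples=200, derandomize=True)
    def test_matches_split_enumeration_oracle(self, values):
        part = kmeans_1d_two_clusters(values)
        _, best_wss = two_means_oracle(values)
        assert part.within_ss == pytest.approx(best_wss, abs=1e-9)
        assert part.lower_mean <= part.upper_mean

    def test_matches_sklearn_on_spot_checks(self):
        sklearn = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(7)
        for _ in range(5):
            vals = rng.random(30)
            part = kmeans_1d_two_clusters(vals)
            km = sklearn.KMeans(n_clusters=2, n_init=50, random_state=0).fit(
                vals.reshape(-1, 1))
            assert km.inertia_ == pytest.approx(part.within_ss, rel=1e-6)


# -- control splitting and error rate ---------------------------------------

def _table(afs_and_depths):
    obs = [
        ControlObservation(sample_id=f"c{i}", site=SITE,
                           alt_count=a, total_count=t)
        for i, (a, t) in enumerate(afs_and_depths)
    ]
    return ControlTable(site=SITE, observations=obs)


class TestSplitControls:
    def test_low_af_panel_pools_everyone(self):
        table = _table([(2, 100), (0, 80), (5, 100)])
        model = split_controls(table, CFG)
        assert not model.clustering_triggered
        assert model.germline_samples == []
        assert (model.pooled_alt, model.pooled_total) == (7, 280)

    def test_high_af_carriers_excluded_from_pool(self):
        carriers = [(35, 100)] * 5
        errors = [(2, 100)] * 130
        model = split_controls(_table(carriers + errors), CFG)
        assert model.clustering_triggered
        assert len(model.germline_samples) == 5
        assert len(model.error_samples) == 130
        assert model.pooled_alt == 260 and model.pooled_total == 13000
        assert flag_recurrent_germline(model, CFG)

    def test_single_covered_control_forms_the_pool(self):
        model = split_controls(_table([(0, 60)]), CFG)
        assert model.error_samples == ["c0"] and not model.clustering_triggered

    def test_single_high_af_control_falls_back_to_threshold(self):
        model = split_controls(_table([(30, 60)]), CFG)
        assert model.clustering_triggered
        assert model.germline_samples == ["c0"]
        assert model.pooled_total == 0

    def test_uncovered_controls_carry_no_information(self):
        table = _table([(1, 100), (0, 0), (0, 0)])
        model = split_controls(table, CFG)
        assert model.covered_count == 1
        assert model.pooled_total == 100


class TestRecurrenceFlag:
    def test_boundary_of_default_threshold(self):
        m1 = SiteErrorModel(SITE, ["g1"], ["e1"], 0, 100, True)
        m2 = SiteErrorModel(SITE, ["g1", "g2"], ["e1"], 0, 100, True)
        assert not flag_recurrent_germline(m1, CFG)
        assert flag_recurrent_germline(m2, CFG)

    def test_untriggered_clustering_never_flags(self):
        m = SiteErrorModel(SITE, [], ["e1"], 0, 100, False)
        assert not flag_recurrent_germline(m, CFG)


class TestErrorRate:
    def test_pooled_ratio(self):
        m = SiteErrorModel(SITE, [], ["a", "b"], 3, 200, False)
        assert estimate_error_rate(m) == pytest.approx(0.015)

    def test_zero_alt_pool_floored_by_depth(self):
        m = SiteErrorModel(SITE, [], ["a"], 0, 5000, False)
        assert estimate_error_rate(m) == pytest.approx(1 / 5001)
        # the floor keeps the p-value informative and decreasing in depth
        shallow = estimate_error_rate(SiteErrorModel(SITE, [], ["a"], 0, 50, False))
        assert shallow > estimate_error_rate(m)
        assert binomial_pvalue(3, 100, estimate_error_rate(m)) < 1.0

    def test_empty_pool_is_undefined(self):
        m = SiteErrorModel(SITE, [], [], 0, 0, False)
        assert estimate_error_rate(m) is None


# -- binomial test -----------------------------------------------------------

class TestBinomialPValue:
    def test_zero_support_spans_whole_distribution(self):
        assert binomial_pvalue(0, 50, 0.3) == 1.0

    def test_single_trial(self):
        assert binomial_pvalue(1, 1, 0.3) == pytest.approx(0.3)

    def test_low_af_example_matches_tail_sum(self):
        assert binomial_pvalue(5, 94, 0.005) == pytest.approx(
            tail_sum_oracle(5, 94, 0.005), abs=1e-12)

    def test_zero_error_rate_is_a_contract_violation(self):
        with pytest.raises(ContractViolation):
            binomial_pvalue(3, 10, 0.0)

    @given(st.integers(1, 60), st.floats(1e-4, 0.5))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_support_and_error_rate(self, n, p):
        pv = [binomial_pvalue(x, n, p) for x in range(n + 1)]
        assert all(a >= b for a, b in zip(pv, pv[1:]))
        assert binomial_pvalue(min(3, n), n, p) <= binomial_pvalue(
            min(3, n), n, min(1.0, p * 2))


class TestBonferroni:
    def test_single_test_unchanged(self):
        adj, sig = bonferroni([0.01], alpha=0.05)
        assert adj == [0.01] and sig == [True]

    def test_two_tests_scale_and_cap(self):
        adj, sig = bonferroni([1e-6, 0.04], alpha=0.05)
        assert adj == pytest.approx([2e-6, 0.08])
        assert sig == [True, False]

    def test_closed_form_at_scale(self):
        adj, sig = bonferroni([4e-4] * 100, alpha=0.05)
        assert all(a == pytest.approx(0.04) for a in adj)
        assert all(sig)

    def test_empty_input(self):
        assert bonferroni([], alpha=0.05) == ([], [])


# -- power -------------------------------------------------------------------

class TestBinomialPower:
    def test_zero_coverage_has_zero_power(self):
        assert binomial_power(0, 0.01, 0.3, 1e-6) == 0.0

    def test_power_saturates_with_depth(self):
        powers = [binomial_power(n, 0.001, 0.3, 1e-4)
                  for n in (10, 50, 200, 1000)]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_example_matches_enumeration_oracle(self):
        n, p_err, detect, alpha = 100, 0.01, 0.30, 1e-6
        k_star = next(k for k in range(n + 2)
                      if tail_sum_oracle(k, n, p_err) < alpha)
        expected = tail_sum_oracle(k_star, n, detect)
        assert binomial_power(n, p_err, detect, alpha) == pytest.approx(
            expected, abs=1e-12)

    def test_invalid_detect_af_is_a_contract_violation(self):
        with pytest.raises(ContractViolation):
            binomial_power(100, 0.4, 0.3, 0.01)


class TestPowerFilter:
    def _model(self, alt, total):
        return SiteErrorModel(SITE, [], ["c"], alt, total, False)

    def test_zero_tumor_coverage_fails(self):
        assert not power_filter(0, 100, self._model(1, 1000), CFG, 0.01)

    def test_saturated_depths_pass(self):
        assert power_filter(10000, 10000, self._model(10, 10000), CFG, 0.01)

    def test_single_crossing_in_tumor_depth(self):
        model = self._model(10, 10000)  # p = 1e-3
        verdicts = [power_filter(n, 200, model, CFG, 0.01)
                    for n in range(0, 160, 5)]
        flips = sum(1 for a, b in zip(verdicts, verdicts[1:]) if a != b)
        assert flips == 1 and verdicts[0] is False and verdicts[-1] is True

    def test_undefined_error_rate_fails(self):
        assert not power_filter(100, 100, self._model(0, 0), CFG, 0.01)


# -- judgements --------------------------------------------------------------

def _candidate(site, t_alt, t_total, n_alt=0, n_total=100):
    return RawCandidate(
        site=site,
        tumor=SiteObservation(site, "t", [], t_alt, t_total),
        normal=SiteObservation(site, "n", [], n_alt, n_total),
        filter_trace=[],
    )


def _control_table(site, pairs):
    return ControlTable(site=site, observations=[
        ControlObservation(f"c{i}", site, a, t) for i, (a, t) in enumerate(pairs)
    ])


class TestJudgeVariants:
    def test_strong_variant_over_clean_panel_is_real(self):
        cand = _candidate(SITE, 16, 92)
        table = _control_table(SITE, [(0, 2500)] * 4)  # pooled 0/10000 -> floor
        (call,) = judge_variants([cand], [table], CFG)
        assert call.judgement == "real"
        assert call.test.p_value < 1e-10

    def test_recurrent_panel_carriers_judged_germline(self):
        cand = _candidate(SITE, 40, 100)
        table = _control_table(SITE, [(35, 100)] * 5 + [(2, 100)] * 130)
        (call,) = judge_variants([cand], [table], CFG)
        assert call.judgement == "germline"
        assert call.test is None

    def test_weak_variant_at_noisy_site_rejected(self):
        cand = _candidate(SITE, 2, 92)
        table = _control_table(SITE, [(25, 1000)] * 4)  # p = 0.025
        (call,) = judge_variants([cand], [table], CFG)
        assert call.judgement == "reject"
        assert call.test.p_value > 0.05

    def test_uncovered_panel_judged_low_power(self):
        cand = _candidate(SITE, 5, 90)
        table = _control_table(SITE, [(0, 0)] * 3)
        (call,) = judge_variants([cand], [table], CFG)
        assert call.judgement == "low_power"

    def test_bonferroni_m_counts_only_tested_sites(self):
        sites = [GenomicSite("chr1", 100 + i, "C", "A") for i in range(3)]
        cands = [_candidate(sites[0], 10, 100),
                 _candidate(sites[1], 40, 100),
                 _candidate(sites[2], 5, 90)]
        tables = [
            _control_table(sites[0], [(0, 2500)] * 4),
            _control_table(sites[1], [(35, 100)] * 5),      # germline
            _control_table(sites[2], [(0, 0)] * 4),          # low power
        ]
        calls = judge_variants(cands, tables, CFG)
        judged = {c.site.pos: c.judgement for c in calls}
        assert judged == {100: "real", 101: "germline", 102: "low_power"}
        tested = [c for c in calls if c.test is not None]
        assert len(tested) == 1
        # m = 1: adjusted equals raw
        assert tested[0].test.p_adjusted == pytest.approx(tested[0].test.p_value)

    def test_misaligned_inputs_are_a_contract_violation(self):
        other = GenomicSite("chr2", 5, "T", "G")
        with pytest.raises(ContractViolation):
            judge_variants([_candidate(SITE, 5, 50)],
                           [_control_table(other, [(0, 10)])], CFG)

    def test_output_sorted_by_position(self):
        sites = [GenomicSite("chr1", p, "C", "A") for p in (300, 100, 200)]
        cands = [_candidate(s, 10, 100) for s in sites]
        tables = [_control_table(s, [(0, 1000)] * 3) for s in sites]
        calls = judge_variants(cands, tables, CFG)
        assert [c.site.pos for c in calls] == [100, 200, 300]
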