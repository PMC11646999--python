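"""Survival machinery tests: benefit labeling, Kaplan-Meier conventions,
log-rank against independent oracles, Cox against lifelines, and the
maximally selected cutpoint against an exhaustive scan."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test

from ctdx import ValidationError, cox_fit, dcb_label, km_fit, logrank_test, optimal_cutpoint
from ctdx.survival import (
    INDETERMINATE,
    cox_partial_loglik,
    cox_score_test,
    two_group_logrank_z,
)


class TestDcbLabel:
    @pytest.mark.parametrize(
        "t, event, expected",
        [
            (7.2, True, "DCB"),
            (4.0, True, "NDB"),
            (6.0, True, "DCB"),          # "at least 6 months" is inclusive
            (4.0, False, INDETERMINATE),  # censored before the window
            (6.0, False, "DCB"),
        ],
    )
    def test_rule(self, t, event, expected):
        assert dcb_label(t, event) == expected

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValidationError):
            dcb_label(0.0, True)


class TestKaplanMeier:
    def test_no_censoring_median(self):
        curve = km_fit([2, 4, 6, 8, 10], [1, 1, 1, 1, 1])
        assert curve.median == 6  # S(6) = 0.4 <= 0.5

    def test_all_censored_median_undefined(self):
        assert km_fit([3, 5, 7], [0, 0, 0]).median is None

    def test_single_event(self):
        curve = km_fit([3], [1])
        assert curve.median == 3
        assert curve.survival[-1] == 0.0

    def test_curve_monotone_in_unit_interval(self, default_cohort):
        c = default_cohort.cohort
        curve = km_fit(c["pfs_months"], c["progressed"].astype(bool))
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival.min() >= 0 and curve.survival.max() <= 1


def _brute_force_logrank(time, event, groups):
    """Independent O-E/V tabulation walked time by time."""
    time = np.asarray(time, float)
    event = np.asarray(event, bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    O = np.zeros(labels.size)
    E = np.zeros(labels.size)
    V = np.zeros((labels.size, labels.size))
    for td in sorted(set(time[event])):
        at_risk = time >= td
        deaths = event & (time == td)
        R = at_risk.sum()
        D = deaths.sum()
        for a, la in enumerate(labels):
            ra = (at_risk & (groups == la)).sum()
            O[a] += (deaths & (groups == la)).sum()
            E[a] += ra * D / R
            for b, lb in enumerate(labels):
                rb = (at_risk & (groups == lb)).sum()
                if R > 1:
                    V[a, b] += D * (R - D) / (R - 1) * (ra / R) * ((a == b) - rb / R)
    v = (O - E)[:-1]
    return float(v @ np.linalg.pinv(V[:-1, :-1]) @ v)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = [1, 2, 3, 4, 5]
        e = [1, 1, 0, 1, 1]
        res = logrank_test(t + t, e + e, [0] * 5 + [1] * 5)
        assert res.chi_square == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_tabulated_oracle(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 1, 1, 1, 1, 1]
        g = [0, 0, 0, 1, 1, 1]
        res = logrank_test(t, e, g)
        assert res.chi_square == pytest.approx(_brute_force_logrank(t, e, g), rel=1e-12)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_lifelines_on_random_data(self, rng, k):
        n = 60
        t = rng.exponential(1.0, n) + 0.01
        e = rng.random(n) < 0.8
        g = rng.integers(0, k, n)
        while np.unique(g).size < k:
            g = rng.integers(0, k, n)
        res = logrank_test(t, e, g)
        ll = multivariate_logrank_test(t, g, e)
        assert res.chi_square == pytest.approx(ll.test_statistic, rel=1e-9)
        assert res.degrees_of_freedom == k - 1

    def test_label_swap_invariance(self, rng):
        t = rng.exponential(1.0, 40) + 0.01
        e = rng.random(40) < 0.7
        g = (rng.random(40) < 0.5).astype(int)
        assert logrank_test(t, e, g).chi_square == pytest.approx(
            logrank_test(t, e, 1 - g).chi_square, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCox:
    def _sim(self, rng, n=400, beta=0.7):
        x = rng.normal(size=n)
        T = rng.exponential(np.exp(-beta * x))
        C = rng.exponential(1.5, n)
        return np.minimum(T, C) + 1e-9, T <= C, x

    def test_null_covariate_ci_covers_zero(self, rng):
        t, e, x = self._sim(rng, n=2000, beta=0.0)
        res = cox_fit(t, e, pd.DataFrame({"x": x}))
        assert res.ci_lower[0] < 1.0 < res.ci_upper[0]
        assert abs(res.coef[0]) < 0.1

    @pytest.mark.parametrize("tie_method", ["efron", "breslow"])
    def test_matches_lifelines(self, rng, tie_method):
        t, e, x = self._sim(rng)
        t = np.ceil(t * 20) / 20  # force ties
        df = pd.DataFrame({"x": x, "t": t, "e": e.astype(int)})
        mine = cox_fit(t, e, pd.DataFrame({"x": x}), tie_method=tie_method)
        if tie_method == "efron":
            cph = CoxPHFitter().fit(df, "t", "e")
            assert mine.coef[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)
            assert mine.hr[0] == pytest.approx(np.exp(cph.params_.iloc[0]), rel=1e-4)
        # hazard ratio / CI structural invariants
        assert mine.hr[0] == pytest.approx(np.exp(mine.coef[0]))
        assert mine.ci_lower[0] <= mine.hr[0] <= mine.ci_upper[0]

    def test_finite_difference_gradient_vanishes_at_optimum(self, rng):
        t, e, x = self._sim(rng, n=50)
        res = cox_fit(t, e, pd.DataFrame({"x": x}))
        h = 1e-5
        g = (cox_partial_loglik(res.coef + h, t, e, x.reshape(-1, 1))
             - cox_partial_loglik(res.coef - h, t, e, x.reshape(-1, 1))) / (2 * h)
        assert abs(g) < 1e-6

    def test_score_test_equals_logrank_for_binary_covariate(self, rng):
        """With one binary covariate and no tied event times, the Cox score
        chi-square at β = 0 is algebraically the log-rank chi-square."""
        n = 80
        t = rng.exponential(1.0, n) + rng.random(n) * 1e-6
        e = rng.random(n) < 0.8
        g = (rng.random(n) < 0.5).astype(int)
        sc = cox_score_test(t, e, g.astype(float).reshape(-1, 1), tie_method="breslow")
        lr = logrank_test(t, e, g)
        assert sc == pytest.approx(lr.chi_square, abs=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            cox_fit([1, 2, 3], [1, 1, 1], pd.DataFrame({"x": [1.0, 1.0, 1.0]}))


def _brute_force_cutpoint(values, t, e, minprop):
    """Exhaustive scan using the standalone two-group statistic."""
    best = None
    n = len(values)
    for c in np.unique(values)[:-1]:
        low = values <= c
        if low.sum() < minprop * n or (n - low.sum()) < minprop * n:
            continue
        z = abs(two_group_logrank_z(t, e, ~low))
        if best is None or z > best[1]:
            best = (c, z)
    return best


class TestOptimalCutpoint:
    def test_separable_construction(self):
        """Subjects with covariate <= 5 all progress by month 2, the rest
        after month 12; the scan must split exactly at 5."""
        values = np.arange(1, 11, dtype=float)
        t = np.where(values <= 5, 2.0, 12.0) - 0.1 * values / 10
        e = np.ones(10, dtype=bool)
        res = optimal_cutpoint(values, t, e, minprop=0.1)
        assert res.cutpoint == 5.0
        assert res.n_low == 5 and res.n_high == 5

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValidationError):
            optimal_cutpoint([2.0] * 5, [1, 2, 3, 4, 5], [1] * 5)

    def test_matches_exhaustive_oracle_on_random_data(self, rng):
        for _ in range(25):
            n = int(rng.integers(15, 50))
            values = np.round(rng.normal(size=n), 2)
            t = rng.exponential(1.0, n) + 0.01
            e = rng.random(n) < 0.8
            if np.unique(values).size < 2:
                continue
            try:
                res = optimal_cutpoint(values, t, e, minprop=0.1)
            except ValidationError:
                continue
            c, z = _brute_force_cutpoint(values, t, e, 0.1)
            assert res.statistic == pytest.approx(z, rel=1e-12)

    def test_monotone_transform_invariance(self, rng):
        n = 40
        values = rng.normal(size=n)
        t = rng.exponential(1.0, n) + 0.01
        e = rng.random(n) < 0.8
        a = optimal_cutpoint(values, t, e)
        b = optimal_cutpoint(np.exp(values), t, e)
        # same subjects on each side of the split
        assert a.n_low == b.n_low
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
        assert b.cutpoint == pytest.approx(np.exp(a.cutpoint))

    def test_minprop_respected(self, default_cohort):
        c = default_cohort.cohort
        res = optimal_cutpoint(
            c["btmb"].to_numpy(), c["pfs_months"].to_numpy(),
            c["progressed"].to_numpy(dtype=bool), minprop=0.2)
        n = len(c)
        assert res.n_low >= 0.2 * n and res.n_high >= 0.2 * n
        assert (res.scan["z"].abs().max()) == pytest.approx(res.statistic)
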