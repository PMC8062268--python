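"""Kaplan-Meier, log-rank, Cox regression, and the minimum-p cut-off scan."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as ll_logrank
from scipy import stats

from flora.survival import (
    _two_group_logrank_chi2,
    cox_fit,
    km_estimate,
    logrank_test,
    optimal_cutoff,
)


def _records(times, events, **covs):
    idx = [f"s{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events}, index=idx)
    for k, v in covs.items():
        df[k] = v
    return df


def _km_oracle(times, events):
    """Brute-force product-limit estimator over distinct event times."""
    order = np.argsort(times)
    t, e = np.asarray(times)[order], np.asarray(events)[order]
    out = {}
    s = 1.0
    for ti in np.unique(t):
        at_risk = np.sum(t >= ti)
        d = np.sum((t == ti) & (e == 1))
        if d > 0:
            s *= 1 - d / at_risk
        out[ti] = s
    return out


class TestKaplanMeier:
    def test_no_events_gives_unit_survival(self):
        res = km_estimate(_records([5, 8, 12], [0, 0, 0]))
        assert np.allclose(res["all"]["survival"], 1.0)

    def test_hand_computed_four_subject_curve(self):
        res = km_estimate(_records([1, 2, 3, 4], [1, 1, 0, 0]))["all"]
        by_time = dict(zip(res["time"], res["survival"]))
        assert by_time[1.0] == pytest.approx(0.75)
        assert by_time[2.0] == pytest.approx(0.5)

    def test_matches_brute_force_on_random_small_datasets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            times = rng.integers(1, 8, size=n).astype(float)  # force ties
            events = rng.integers(0, 2, size=n)
            if events.sum() == 0:
                continue
            res = km_estimate(_records(times, events))["all"]
            oracle = _km_oracle(times, events)
            for t, s in zip(res["time"], res["survival"]):
                if t in oracle:
                    assert s == pytest.approx(oracle[t])

    def test_negative_time_is_error(self):
        with pytest.raises(ValueError):
            km_estimate(_records([1, -2], [1, 1]))

    def test_grouped_curves_are_per_group(self):
        res = km_estimate(
            _records([1, 2, 3, 4], [1, 1, 1, 1], arm=["a", "a", "b", "b"]), "arm"
        )
        assert set(res) == {"a", "b"}


def _logrank_oracle(times, events, groups):
    """O-E with hypergeometric variance, two groups, direct summation."""
    times, events = np.asarray(times, float), np.asarray(events)
    g = np.asarray(groups)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at = times >= t
        n, n1 = at.sum(), (at & (g == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (g == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_worked_ten_subject_dataset(self):
        times = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 1, 0]
        groups = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
        chi2, df, p = logrank_test(
            _records(times, events, arm=groups), "arm"
        )
        expected = _logrank_oracle(times, events, groups)
        assert df == 1
        assert chi2 == pytest.approx(expected, rel=1e-6)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-6)

    def test_matches_oracle_on_random_small_datasets(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            times = rng.integers(1, 9, size=n).astype(float)
            events = rng.integers(0, 2, size=n)
            groups = rng.integers(0, 2, size=n)
            if events.sum() == 0 or len(set(groups)) < 2:
                continue
            denom_ok = _has_variance(times, events, groups)
            if not denom_ok:
                continue
            chi2, _, _ = logrank_test(_records(times, events, arm=groups), "arm")
            assert chi2 == pytest.approx(
                _logrank_oracle(times, events, groups), rel=1e-6, abs=1e-9
            )

    def test_duplicated_groups_give_zero_statistic(self):
        times = [1, 2, 3, 4, 5]
        events = [1, 1, 0, 1, 1]
        rec = _records(times + times, events + events, arm=[0] * 5 + [1] * 5)
        chi2, _, p = logrank_test(rec, "arm")
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_power_against_threefold_hazard(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 120
        for _ in range(reps):
            t1 = rng.exponential(1.0, 100)
            t2 = rng.exponential(1 / 3, 100)
            c = rng.uniform(0, 5, 200)
            times = np.concatenate([t1, t2])
            events = (times <= c).astype(int)
            times = np.minimum(times, c)
            _, _, p = logrank_test(
                _records(times, events, arm=[0] * 100 + [1] * 100), "arm"
            )
            rejections += p < 0.05
        assert rejections / reps >= 0.9

    def test_multivariate_mode_crosses_two_factors(self):
        rng = np.random.default_rng(3)
        n = 80
        rec = _records(
            rng.exponential(10, n),
            rng.integers(0, 2, n),
            arm=rng.integers(0, 2, n),
            hist=rng.choice(["int", "dif"], n),
        )
        chi2, df, p = logrank_test(rec, "arm", multivariate_with="hist")
        assert df == 3  # 2x2 cross-classification

    def test_internal_fast_scan_statistic_matches_lifelines(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = 40
            times = np.round(rng.exponential(10, n), 1) + 0.1
            events = rng.integers(0, 2, n)
            mask = rng.integers(0, 2, n).astype(bool)
            if events.sum() == 0 or mask.all() or not mask.any():
                continue
            order = np.argsort(times)
            chi2 = _two_group_logrank_chi2(
                times[order], events[order].astype(bool), mask[order]
            )
            ref = ll_logrank(
                times[mask], times[~mask], events[mask], events[~mask]
            ).test_statistic
            assert chi2 == pytest.approx(ref, rel=1e-6, abs=1e-9)


def _has_variance(times, events, groups):
    return _safe_oracle(times, events, groups) is not None


def _safe_oracle(times, events, groups):
    try:
        v = _logrank_oracle(times, events, groups)
        return v if np.isfinite(v) else None
    except ZeroDivisionError:
        return None


class TestCox:
    def test_recovers_planted_log_hazard_ratio(self):
        rng = np.random.default_rng(5)
        n, beta = 300, 0.7
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-beta * x) / 0.05)
        c = rng.uniform(0, 60, n)
        rec = _records(np.minimum(t, c).clip(1e-3), (t <= c).astype(int), x=x)
        fit = cox_fit(rec, ["x"])
        assert fit.converged
        se = (np.log(fit.table.loc["x", "ci_high"]) - np.log(fit.table.loc["x", "hr"])) / 1.96
        assert abs(fit.table.loc["x", "coef"] - beta) <= 3 * se

    def test_ci_bounds_bracket_hazard_ratio(self):
        rng = np.random.default_rng(6)
        n = 100
        rec = _records(
            rng.exponential(10, n), rng.integers(0, 2, n), x=rng.normal(size=n)
        )
        fit = cox_fit(rec, ["x"])
        row = fit.table.loc["x"]
        assert row["ci_low"] <= row["hr"] <= row["ci_high"]
        assert row["hr"] > 0

    def test_affine_rescaling_rescales_coefficient_exactly(self):
        rng = np.random.default_rng(7)
        n = 120
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x) / 0.05)
        rec = _records(t.clip(1e-3), np.ones(n, dtype=int), x=x)
        fit1 = cox_fit(rec, ["x"])
        rec2 = rec.copy()
        rec2["x"] = 10 * rec2["x"] + 3
        fit2 = cox_fit(rec2, ["x"])
        assert fit2.table.loc["x", "coef"] == pytest.approx(
            fit1.table.loc["x", "coef"] / 10, rel=1e-4
        )

    def test_constant_covariate_is_error(self):
        rec = _records([1, 2, 3, 4], [1, 1, 1, 1], x=[1, 1, 1, 1])
        with pytest.raises(ValueError):
            cox_fit(rec, ["x"])

    def test_score_identity_with_logrank_for_binary_covariate(self):
        # at beta=0 the Cox score test equals the log-rank statistic; with a
        # fitted model the Wald and log-rank p agree to leading order
        rng = np.random.default_rng(8)
        n = 200
        g = rng.integers(0, 2, n)
        t = rng.exponential(np.exp(-0.8 * g) / 0.05)
        c = rng.uniform(0, 80, n)
        rec = _records(np.minimum(t, c).clip(1e-3), (t <= c).astype(int), g=g)
        fit = cox_fit(rec, ["g"])
        _, _, p_lr = logrank_test(rec, "g")
        p_wald = fit.table.loc["g", "p"]
        assert np.sign(np.log(p_wald) - np.log(p_lr)) in (-1, 0, 1)
        assert abs(np.log10(p_wald) - np.log10(p_lr)) < 1.0


class TestOptimalCutoff:
    def test_two_distinct_values_cut_falls_between(self):
        rng = np.random.default_rng(9)
        n = 40
        x = np.array([1.0] * 20 + [5.0] * 20)
        t = rng.exponential(np.where(x > 3, 5, 20), n)
        rec = _records(t.clip(1e-3), np.ones(n, dtype=int))
        res = optimal_cutoff(rec, pd.Series(x, index=rec.index), min_group_frac=0.3)
        assert 1.0 < res["cutoff"] < 5.0
        assert set(res["groups"].unique()) == {"high", "low"}

    def test_constant_expression_is_error(self):
        rec = _records([1, 2, 3, 4], [1, 1, 1, 1])
        with pytest.raises(ValueError):
            optimal_cutoff(rec, pd.Series(2.0, index=rec.index))

    def test_planted_threshold_recovered(self):
        # cohort sized like a large tumor expression study
        rng = np.random.default_rng(10)
        hits = 0
        reps = 40
        for _ in range(reps):
            n = 375
            x = rng.normal(size=n)
            thr = np.quantile(x, 0.7)
            t = rng.exponential(np.where(x > thr, 1 / 0.09, 1 / 0.03))
            c = rng.uniform(0, 60, n)
            rec = _records(np.minimum(t, c).clip(1e-3), (t <= c).astype(int))
            res = optimal_cutoff(rec, pd.Series(x, index=rec.index))
            pct = stats.percentileofscore(x, res["cutoff"])
            hits += abs(pct - 70) <= 5
        assert hits / reps >= 0.8

    def test_null_minimum_p_is_anticonservative(self):
        # the scan's minimum p is stochastically smaller than uniform
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(60):
            n = 80
            t = rng.exponential(20, n)
            c = rng.uniform(0, 40, n)
            rec = _records(np.minimum(t, c).clip(1e-3), (t <= c).astype(int))
            res = optimal_cutoff(rec, pd.Series(rng.normal(size=n), index=rec.index))
            ps.append(res["p_logrank"])
        assert np.median(ps) < 0.5

    def test_reported_p_not_larger_than_median_cut_p(self):
        rng = np.random.default_rng(12)
        n = 100
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x) * 20)
        rec = _records(t.clip(1e-3), np.ones(n, dtype=int))
        res = optimal_cutoff(rec, pd.Series(x, index=rec.index))
        med = np.median(x)
        order = np.argsort(rec["time"].to_numpy())
        chi2_med = _two_group_logrank_chi2(
            rec["time"].to_numpy()[order],
            rec["event"].to_numpy()[order].astype(bool),
            (x > med)[order],
        )
        p_med = stats.chi2.sf(chi2_med, 1)
        assert res["p_logrank"] <= p_med + 1e-12
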