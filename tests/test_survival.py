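"""Cox engine, endpoint construction, and the descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform

import hazardcut as hc
from hazardcut.survival import efron_newton


def efron_loglik_bruteforce(time, event, x, beta):
    """Independent Efron partial log-likelihood by explicit risk-set
    enumeration (single covariate)."""
    ll = 0.0
    for ut in np.unique(time[event == 1]):
        D = (time == ut) & (event == 1)
        R = time >= ut
        wR = np.exp(beta * x[R]).sum()
        wD = np.exp(beta * x[D]).sum()
        d = int(D.sum())
        ll += beta * x[D].sum()
        for l in range(d):
            ll -= np.log(wR - l / d * wD)
    return ll


def grid_argmax(time, event, x, lo=-5.0, hi=5.0, step=1e-4):
    grid = np.arange(lo, hi + step / 2, step)
    ll = np.zeros_like(grid)
    for ut in np.unique(time[event == 1]):
        D = (time == ut) & (event == 1)
        R = time >= ut
        d = int(D.sum())
        wR = np.exp(np.outer(grid, x[R])).sum(axis=1)
        wD = np.exp(np.outer(grid, x[D])).sum(axis=1)
        ll += grid * x[D].sum()
        for l in range(d):
            ll -= np.log(wR - l / d * wD)
    return grid[np.nanargmax(ll)]


class TestCoxFit:
    def test_eight_subject_toy_matches_grid_oracle(self):
        # group coded 1 fails mostly earlier (interleaved so the maximum
        # partial-likelihood estimate stays finite)
        time = np.arange(1.0, 9.0)
        event = np.ones(8, dtype=int)
        x = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = hc.fit_cox(df, "time", "event", ["x"])
        oracle = grid_argmax(time, event, x)
        assert fit.converged
        assert abs(fit.terms.loc["x", "coef"] - oracle) < 1e-4

    def test_matches_lifelines_with_and_without_ties(self, two_group_frame):
        from lifelines import CoxPHFitter

        for frame in (two_group_frame, two_group_frame.assign(time=np.ceil(two_group_frame.time * 4) / 4)):
            fit = hc.fit_cox(frame, "time", "event", ["x", "g"])
            cph = CoxPHFitter().fit(frame[["time", "event", "x", "g"]], "time", "event")
            assert np.allclose(fit.terms["coef"].to_numpy(), cph.params_.to_numpy(), atol=1e-5)
            assert np.isclose(fit.loglik, cph.log_likelihood_, atol=1e-8)
            assert np.allclose(fit.terms["se"].to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-4)

    def test_engines_agree(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            n = int(rng.integers(20, 120))
            p = int(rng.integers(1, 4))
            K = int(rng.integers(1, 6))
            X = rng.standard_normal((K, n, p))
            t = np.ceil(rng.exponential(5, n) * 2) / 2  # forced ties
            e = rng.integers(0, 2, n)
            e[0] = 1
            for ties in ("efron", "breslow"):
                a = efron_newton(t, e, X, ties=ties, engine="numba")
                b = efron_newton(t, e, X, ties=ties, engine="numpy")
                assert (a.converged == b.converged).all()
                assert (a.failed == b.failed).all()
                ok = a.converged
                if ok.any():
                    assert np.abs(a.beta[ok] - b.beta[ok]).max() < 1e-6
                    assert np.abs(a.loglik[ok] - b.loglik[ok]).max() < 1e-7
                    assert np.abs(a.info[ok] - b.info[ok]).max() < 1e-5

    def test_exponential_simulation_recovers_rate_ratio(self):
        rng = np.random.default_rng(3)
        n = 2000
        g = (rng.uniform(size=n) > 0.5).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(np.log(3.0) * g)))
        c = rng.exponential(10, n)
        df = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int), "g": g})
        fit = hc.fit_cox(df, "time", "event", ["g"])
        # closed-form oracle under exponential hazards: events / person-time
        rate1 = df.event[g == 1].sum() / df.time[g == 1].sum()
        rate0 = df.event[g == 0].sum() / df.time[g == 0].sum()
        assert abs(fit.hr("g") / (rate1 / rate0) - 1) < 0.10

    def test_constant_covariate_is_nonidentifiable(self):
        df = pd.DataFrame(
            {"time": np.arange(1.0, 11.0), "event": 1, "x": 1.0}
        )
        with pytest.raises(ValueError, match="non-identifiable"):
            hc.fit_cox(df, "time", "event", ["x"])

    def test_zero_events_is_an_error(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "event": 0, "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="vent"):
            hc.fit_cox(df, "time", "event", ["x"])

    def test_separation_is_flagged_not_silent(self):
        # perfectly separating covariate: all early failures in one group
        df = pd.DataFrame(
            {
                "time": np.arange(1.0, 13.0),
                "event": 1,
                "x": [1.0] * 6 + [0.0] * 6,
            }
        )
        fit = hc.fit_cox(df, "time", "event", ["x"])
        assert not fit.converged

    def test_categorical_reference_is_most_frequent_level(self):
        rng = np.random.default_rng(5)
        n = 120
        df = pd.DataFrame(
            {
                "time": rng.exponential(5, n),
                "event": rng.integers(0, 2, n),
                "site": rng.choice(["oro", "hypo", "larynx"], n, p=[0.5, 0.3, 0.2]),
            }
        )
        df.loc[0, "event"] = 1
        fit = hc.fit_cox(df, "time", "event", ["site"])
        assert fit.references["site"] == "oro"
        assert set(fit.terms.index) == {"site=hypo", "site=larynx"}

    def test_time_origin_and_covariate_scale_invariance(self, two_group_frame):
        fit = hc.fit_cox(two_group_frame, "time", "event", ["x", "g"])
        shifted = two_group_frame.assign(time=two_group_frame.time + 7.0)
        fit_s = hc.fit_cox(shifted, "time", "event", ["x", "g"])
        assert np.allclose(fit.terms["coef"], fit_s.terms["coef"], atol=1e-12)
        scaled = two_group_frame.assign(x=two_group_frame.x * 4.0)
        fit_c = hc.fit_cox(scaled, "time", "event", ["x", "g"])
        assert np.isclose(fit_c.terms.loc["x", "coef"], fit.terms.loc["x", "coef"] / 4.0, atol=1e-6)

    def test_newton_matches_grid_on_random_small_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(8, 21))
            x = rng.standard_normal(n).round(1)
            t = np.ceil(rng.exponential(3, n) * 4) / 4
            e = rng.integers(0, 2, n)
            e[int(rng.integers(0, n))] = 1
            if np.ptp(x) == 0 or np.unique(t[e == 1]).size < 2:
                continue
            res = efron_newton(t, e, x[:, None])
            if not res.converged[0]:
                continue
            oracle = grid_argmax(t, e, x)
            if abs(oracle) > 4.9:
                continue
            assert abs(res.beta[0, 0] - oracle) < 1e-3


class TestSignificance:
    def test_threshold_is_strict(self, two_group_frame):
        fit = hc.fit_cox(two_group_frame, "time", "event", ["x", "g"])
        fit.terms.loc["x", "p"] = 0.049
        assert hc.significance(fit, "x")
        fit.terms.loc["x", "p"] = 0.05
        assert not hc.significance(fit, "x")

    def test_zero_coefficient_is_never_significant(self, two_group_frame):
        fit = hc.fit_cox(two_group_frame, "time", "event", ["x", "g"])
        fit.terms.loc["g", "coef"] = 0.0
        fit.terms.loc["g", "p"] = 1.0
        assert not hc.significance(fit, "g")

    def test_matches_likelihood_ratio_direction_on_toy_data(self):
        # a moderate-effect instance: Wald and likelihood-ratio tests are
        # different statistics, so agreement is only expected away from the
        # alpha boundary
        time = np.arange(1.0, 9.0)
        event = np.ones(8, dtype=int)
        x = np.array([1, 1, 0, 1, 0, 1, 0, 0], dtype=float)
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        fit = hc.fit_cox(df, "time", "event", ["x"])
        bhat = grid_argmax(time, event, x)
        lr = 2 * (efron_loglik_bruteforce(time, event, x, bhat) - efron_loglik_bruteforce(time, event, x, 0.0))
        from scipy.stats import chi2

        lr_reject = lr > chi2.ppf(0.95, 1)
        assert hc.significance(fit, "x") == lr_reject


class TestEndpoints:
    def test_death_censors_lrc_and_dm(self):
        raw = pd.DataFrame(
            {"treatment_start": [0.0], "last_followup": [3.0], "death_date": [2.0]}
        )
        out = hc.build_endpoints(raw)
        assert out.loc[0, "time_LRC"] == 2.0 and out.loc[0, "event_LRC"] == 0
        assert out.loc[0, "time_OS"] == 2.0 and out.loc[0, "event_OS"] == 1
        assert out.loc[0, "time_PFS"] == 2.0 and out.loc[0, "event_PFS"] == 1

    def test_pfs_is_earliest_component(self):
        raw = pd.DataFrame(
            {
                "treatment_start": [0.0],
                "last_followup": [2.5],
                "death_date": [2.0],
                "lrc_date": [1.0],
            }
        )
        out = hc.build_endpoints(raw)
        assert out.loc[0, "time_PFS"] == 1.0 and out.loc[0, "event_PFS"] == 1
        assert out.loc[0, "time_LRC"] == 1.0 and out.loc[0, "event_LRC"] == 1
        assert out.loc[0, "time_OS"] == 2.0 and out.loc[0, "event_OS"] == 1

    def test_event_before_treatment_start_is_an_error(self):
        raw = pd.DataFrame(
            {"treatment_start": [1.0], "last_followup": [3.0], "lrc_date": [0.5]}
        )
        with pytest.raises(ValueError, match="treatment_start"):
            hc.build_endpoints(raw)

    def test_datetime_input(self):
        raw = pd.DataFrame(
            {
                "treatment_start": pd.to_datetime(["2015-01-01"]),
                "last_followup": pd.to_datetime(["2018-01-01"]),
                "death_date": pd.to_datetime(["2017-01-01"]),
            }
        )
        out = hc.build_endpoints(raw)
        assert abs(out.loc[0, "time_OS"] - 2.0) < 0.01


class TestDescriptiveStats:
    def test_spearman_hand_example(self):
        # d^2 = (1,1,1,1,0), sum = 4 -> r = 1 - 6*4/(5*24) = 0.8
        r, _ = hc.spearman_corr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert np.isclose(r, 0.8)

    def test_spearman_extremes_and_errors(self):
        x = np.arange(10.0)
        assert np.isclose(hc.spearman_corr(x, x)[0], 1.0)
        assert np.isclose(hc.spearman_corr(x, x[::-1])[0], -1.0)
        with pytest.raises(ValueError, match="constant"):
            hc.spearman_corr(x, np.ones(10))

    def test_vif_closed_form(self):
        rng = np.random.default_rng(0)
        n = 20000
        a = rng.standard_normal(n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        v = hc.vif(np.column_stack([a, b]))
        assert np.allclose(v, 1 / (1 - 0.8**2), atol=0.1)

    def test_vif_orthogonal_and_collinear(self):
        X = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
        assert np.allclose(hc.vif(X), 1.0, atol=1e-8)
        Y = np.column_stack([X[:, 0], X[:, 0]])
        assert np.isinf(hc.vif(Y)).all()

    def test_cluster_identical_markers_merge_first(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "a": rng.standard_normal(30),
                "c": rng.standard_normal(30),
                "d": rng.standard_normal(30),
            }
        )
        df["b"] = df["a"]
        res = hc.cluster_markers(df[["a", "b", "c", "d"]], log_columns=())
        link = res["marker_linkage"]
        assert link[0, 2] == 0.0  # first merge at distance zero
        order = res["marker_order"]
        assert abs(order.index("a") - order.index("b")) == 1

    def test_cluster_two_anticorrelated_blocks(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(50)
        df = pd.DataFrame(
            {
                "m1": base + 0.1 * rng.standard_normal(50),
                "m2": base + 0.1 * rng.standard_normal(50),
                "m3": -base + 0.1 * rng.standard_normal(50),
                "m4": -base + 0.1 * rng.standard_normal(50),
            }
        )
        res = hc.cluster_markers(df, log_columns=())
        # cut the tree at two clusters: blocks must separate
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(res["marker_linkage"], 2, criterion="maxclust")
        cols = list(df.columns)
        assert labels[cols.index("m1")] == labels[cols.index("m2")]
        assert labels[cols.index("m3")] == labels[cols.index("m4")]
        assert labels[cols.index("m1")] != labels[cols.index("m3")]
        # merge heights match a brute-force complete-linkage oracle
        Z = (df - df.mean()) / df.std(ddof=0)
        D = squareform(
            np.sqrt(((Z.to_numpy().T[:, None, :] - Z.to_numpy().T[None, :, :]) ** 2).sum(-1)),
            checks=False,
        )
        coph = cophenet(res["marker_linkage"])
        assert coph.max() <= np.max(squareform(D, checks=False)) + 1e-9

    def test_cluster_single_sample_is_an_error(self):
        with pytest.raises(ValueError):
            hc.cluster_markers(pd.DataFrame({"a": [1.0], "b": [2.0]}))

    def test_kaplan_meier_product_limit_by_hand(self):
        times, surv, median = hc.kaplan_meier([1, 2, 3, 4], [1, 1, 1, 1])
        assert np.allclose(surv[-4:], [0.75, 0.5, 0.25, 0.0])
        assert median == 2.0

    def test_kaplan_meier_all_censored(self):
        _, surv, median = hc.kaplan_meier([1, 2, 3], [0, 0, 0])
        assert np.allclose(surv, 1.0)
        assert np.isnan(median)

    def test_kaplan_meier_mixed_hand_table(self):
        # events at 1, 3, 5; censored at 2, 4, 6
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 0, 1, 0, 1, 0]
        times, surv, _ = hc.kaplan_meier(t, e)
        # S(1)=5/6; S(3)=5/6*3/4=0.625; S(5)=0.625*1/2=0.3125
        lookup = dict(zip(times, surv))
        assert np.isclose(lookup[1.0], 5 / 6)
        assert np.isclose(lookup[3.0], 5 / 6 * 3 / 4)
        assert np.isclose(lookup[5.0], 5 / 6 * 3 / 4 * 1 / 2)
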