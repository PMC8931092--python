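"""KM/log-rank/Cox engines, screening, validation, CLL-IPI, WaW score."""

import numpy as np
import pandas as pd
import pytest

from protosig import rppa, survival as sv
from protosig.rppa import DataError


def brute_force_logrank_2group(times, events, groups):
    """Independent two-group log-rank from the at-risk table."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    U = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == g0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == g0)).sum()
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    from scipy import stats
    chi2 = U ** 2 / V
    return chi2, stats.chi2.sf(chi2, df=1)


def _expr(rng, n, proteins):
    ids = [f"s{i}" for i in range(n)]
    vals = pd.DataFrame(rng.normal(size=(n, len(proteins))), index=ids,
                        columns=proteins)
    return rppa.ExpressionMatrix(vals)


def _clin(index, t, e, endpoint="OS"):
    return pd.DataFrame({f"{endpoint}_time": t, f"{endpoint}_event": e}, index=index)


class TestKM:
    def test_hand_product_limit_example(self):
        res = sv.km_fit([1, 2, 3, 4], [1, 1, 1, 1])
        assert res.median == 2.0
        for t, s in [(1, 0.75), (2, 0.5), (3, 0.25), (4, 0.0)]:
            assert np.isclose(res.survival_at(t), s)

    def test_all_censored_median_undefined(self):
        res = sv.km_fit([5.0, 6.0, 7.0], [0, 0, 0])
        assert np.isnan(res.median)
        assert res.survival_at(7.0) == 1.0

    def test_negative_times_rejected(self):
        with pytest.raises(DataError):
            sv.km_fit([-1.0, 2.0], [1, 1])

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        t = rng.exponential(5, size=200)
        res = sv.km_fit(t, np.ones(200, int))
        for q in [0.25, 0.5, 0.75]:
            tq = np.quantile(t, q)
            emp = (t > tq).mean()
            assert abs(res.survival_at(tq) - emp) < 0.01


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2, 3, 4, 1, 2, 3, 4]
        e = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        res = sv.logrank(t, e, g)
        assert np.isclose(res.statistic, 0.0, atol=1e-12)
        assert np.isclose(res.p, 1.0)

    def test_matches_at_risk_table_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 40))
            t = rng.random(n) * 10
            e = (rng.random(n) < 0.7).astype(int)
            g = (rng.random(n) < 0.5).astype(int)
            if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
                continue
            chi2, p = brute_force_logrank_2group(t, e, g)
            res = sv.logrank(t, e, g)
            assert abs(res.statistic - chi2) / max(chi2, 1e-12) < 1e-6
            assert abs(res.p - p) / max(p, 1e-12) < 1e-6

    def test_single_group_rejected(self):
        with pytest.raises(DataError):
            sv.logrank([1, 2], [1, 1], [0, 0])

    def test_pairwise_table_bh(self, rng):
        n = 120
        t = rng.exponential(5, n)
        g = rng.integers(0, 3, n)
        res = sv.logrank(t, np.ones(n, int), g)
        assert res.pairwise is not None and len(res.pairwise) == 3
        assert (res.pairwise["q"] >= res.pairwise["p"] - 1e-12).all()

    def test_null_p_approximately_uniform(self, rng):
        from scipy import stats
        ps = []
        t = rng.exponential(5, 60)
        e = np.ones(60, int)
        for _ in range(300):
            g = rng.permutation(np.repeat([0, 1], 30))
            ps.append(sv.logrank(t, e, g).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCox:
    def test_planted_log_hr_recovered(self, rng):
        n = 600
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.7 * x))
        res = sv.cox_fit(pd.DataFrame({"x": x}), t, np.ones(n, int))
        assert res.ok
        loghr = np.log(res.summary["HR"].iloc[0])
        se = (np.log(res.summary["ci_upper"].iloc[0])
              - np.log(res.summary["ci_lower"].iloc[0])) / (2 * 1.96)
        assert abs(loghr - 0.7) < 3 * se
        assert res.c_index > 0.6

    def test_collinear_covariates_flagged(self, rng):
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        res = sv.cox_fit(X, rng.exponential(5, 50), np.ones(50, int))
        assert not res.ok and "collinear" in res.flagged

    def test_constant_covariate_flagged(self, rng):
        X = pd.DataFrame({"a": np.ones(30)})
        res = sv.cox_fit(X, rng.exponential(5, 30), np.ones(30, int))
        assert not res.ok and "constant" in res.flagged

    def test_no_events_flagged(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        res = sv.cox_fit(X, rng.exponential(5, 20), np.zeros(20, int))
        assert not res.ok and "no events" in res.flagged


class TestProteinScreen:
    def test_planted_prognostic_protein_detected(self, rng):
        n = 400
        m = _expr(rng, n, ["hit", "noise1", "noise2", "noise3"])
        lam = 0.1 * np.exp(1.0 * m.values["hit"])
        t = rng.exponential(1 / lam)
        clin = _clin(m.values.index, t, np.ones(n, int))
        res = sv.protein_screen(m, clin, "OS")
        by_id = {r.protein_id: r for r in res}
        assert by_id["hit"].q <= 0.05
        assert by_id["hit"].best_form == "continuous"

    def test_constant_protein_skipped(self, rng):
        m = _expr(rng, 50, ["a", "b"])
        m.values["a"] = 1.0
        clin = _clin(m.values.index, rng.exponential(5, 50), np.ones(50, int))
        res = sv.protein_screen(m, clin, "OS")
        flags = {r.protein_id: r.flagged for r in res}
        assert flags["a"] == "constant expression" and flags["b"] is None

    def test_all_censored_non_estimable(self, rng):
        m = _expr(rng, 30, ["a"])
        clin = _clin(m.values.index, rng.exponential(5, 30), np.zeros(30, int))
        res = sv.protein_screen(m, clin, "OS")
        assert all("non-estimable" in r.flagged for r in res)

    def test_q_at_least_p(self, rng):
        m = _expr(rng, 100, [f"p{i}" for i in range(10)])
        clin = _clin(m.values.index, rng.exponential(5, 100), np.ones(100, int))
        res = sv.protein_screen(m, clin, "OS")
        for r in res:
            if np.isfinite(r.q):
                assert r.q >= r.p - 1e-12


class TestIterativeValidation:
    def test_deterministic_given_seed(self, rng):
        m = _expr(rng, 150, ["x"])
        clin = _clin(m.values.index, rng.exponential(5, 150), np.ones(150, int))
        f1, h1 = sv.iterative_validation(m, clin, "OS", "x", n_iter=20, seed=4)
        f2, h2 = sv.iterative_validation(m, clin, "OS", "x", n_iter=20, seed=4)
        assert f1 == f2
        pd.testing.assert_frame_equal(h1, h2)

    def test_threshold_effect_prefers_median_form(self, rng):
        n = 400
        m = _expr(rng, n, ["x"])
        x = m.values["x"]
        lam = np.where(x < x.median(), 0.05, 0.4)
        t = rng.exponential(1 / lam)
        clin = _clin(m.values.index, t, np.ones(n, int))
        frac, hist = sv.iterative_validation(m, clin, "OS", "x", n_iter=40, seed=2)
        done = hist[~hist["skipped"]]
        # a step effect at the median validates strongly; with c-index form
        # selection tied grouped predictors hold no systematic edge over the
        # continuous form, so we assert validation rather than the chosen form
        assert frac > 0.70
        assert set(done["form"]) <= set(sv.FORMS)

    def test_skips_low_event_iterations(self, rng):
        n = 60
        m = _expr(rng, n, ["x"])
        e = np.zeros(n, int)
        e[:6] = 1  # extremely few events -> most test splits under threshold
        clin = _clin(m.values.index, rng.exponential(5, n), e)
        frac, hist = sv.iterative_validation(m, clin, "OS", "x", n_iter=10, seed=0)
        assert hist["skipped"].any()


class TestCLLIPI:
    def test_all_favorable_is_low(self):
        clin = pd.DataFrame({"age": [60.0], "rai_stage": [0], "ighv": ["mutated"],
                             "b2m": [2.0], "del17p": [False]}, index=["p"])
        out = sv.cll_ipi(clin)
        assert out.loc["p", "points"] == 0 and out.loc["p", "risk_group"] == "low"

    def test_missing_component_excluded(self):
        clin = pd.DataFrame({"age": [60.0], "rai_stage": [0], "ighv": ["mutated"],
                             "b2m": [np.nan], "del17p": [False]}, index=["p"])
        out = sv.cll_ipi(clin)
        assert "b2m" in out.loc["p", "excluded"]
        assert pd.isna(out.loc["p", "risk_group"])

    @pytest.mark.parametrize("points,group", [
        (0, "low"), (1, "low"), (2, "intermediate"), (3, "intermediate"),
        (4, "high"), (5, "high"), (6, "high"),
        (7, "very high"), (8, "very high"), (9, "very high"), (10, "very high")])
    def test_group_boundaries(self, points, group):
        assert sv.ipi_group(points) == group


class TestNestedStratification:
    def test_sg_effect_without_stage_effect(self, rng):
        n = 400
        sg = pd.Series(rng.choice(["G1", "G2"], n), index=[f"s{i}" for i in range(n)])
        stage = pd.Series(rng.choice(["0", "I"], n), index=sg.index)
        lam = np.where(sg == "G1", 0.05, 0.4)
        clin = _clin(sg.index, rng.exponential(1 / lam), np.ones(n, int))
        tab = sv.nested_stratification(stage, sg, clin, "OS")
        within_stage = tab[(tab["direction"] == "B_within_A") & (tab["status"] == "ok")]
        within_sg = tab[(tab["direction"] == "A_within_B") & (tab["status"] == "ok")]
        assert (within_stage["p"] < 0.01).all()       # SG separates inside stages
        assert (within_sg["p"] > 0.01).all()          # stage is null inside SGs

    def test_confounded_grouping_flagged(self, rng):
        n = 60
        g = pd.Series(rng.choice(["a", "b"], n), index=[f"s{i}" for i in range(n)])
        clin = _clin(g.index, rng.exponential(5, n), np.ones(n, int))
        tab = sv.nested_stratification(g, g, clin, "OS")
        assert (tab["status"] == "insufficient").all()


class TestWaW:
    def test_definitional_truth_table(self):
        expr = pd.DataFrame({"ANXA1": [1.0, -1.0], "TFRC": [1.0, -1.0],
                             "SMAD2.p245": [-1.0, 1.0]}, index=["good", "bad"])
        medians = pd.Series({"ANXA1": 0.0, "TFRC": 0.0, "SMAD2.p245": 0.0})
        res = sv.waw_score(expr, medians)
        assert res.adverse_count["good"] == 0 and res.risk_group["good"] == "0-1"
        assert res.adverse_count["bad"] == 3 and res.risk_group["bad"] == "2-3"

    def test_at_median_boundary_convention(self):
        expr = pd.DataFrame({"ANXA1": [0.0], "TFRC": [0.0], "SMAD2.p245": [0.0]},
                            index=["edge"])
        medians = pd.Series({"ANXA1": 0.0, "TFRC": 0.0, "SMAD2.p245": 0.0})
        res = sv.waw_score(expr, medians)
        # low markers use strict <, high marker uses >= : exactly one adverse
        assert res.adverse_count["edge"] == 1
        assert res.risk_group["edge"] == "0-1"

    def test_missing_marker_excludes_patient(self):
        expr = pd.DataFrame({"ANXA1": [np.nan, 1.0], "TFRC": [1.0, 1.0],
                             "SMAD2.p245": [0.0, 0.0]}, index=["m", "ok"])
        res = sv.waw_score(expr)
        assert "m" in res.excluded and "ok" in res.adverse_count.index
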