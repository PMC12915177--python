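"""Time-dependent ROC, Youden cutoffs, KM/log-rank, Cox and group tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter

from graftmac.survival import (
    ROCResult,
    administrative_censor,
    cox_fit,
    group_tests,
    infiltration_score,
    km_logrank,
    km_survival_at,
    lesion_correlation,
    schoenfeld_check,
    td_roc,
    youden_cutoff,
)


def surv_table(time, event, **covs):
    return pd.DataFrame({"time_days": time, "event": event, **covs})


# ---------------------------------------------------------------------------
# product-limit helper vs lifelines
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_km_survival_matches_lifelines(seed):
    rng = np.random.default_rng(seed)
    n = 60
    t = rng.exponential(100, n).round()  # ties on purpose
    e = rng.integers(0, 2, n)
    t = np.maximum(t, 1)
    for tau in (20.0, 80.0, 200.0):
        km = KaplanMeierFitter().fit(t, e)
        want = float(km.predict(tau))
        assert km_survival_at(t, e, tau) == pytest.approx(want, abs=1e-12)


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------

class TestTdROC:
    def test_uncensored_reduces_to_classical_roc(self):
        """Without censoring the KM-based sens/spec equal empirical ones."""
        rng = np.random.default_rng(5)
        n = 150
        x = rng.normal(size=n)
        t = np.where(x + rng.normal(scale=0.8, size=n) > 0, 100.0, 900.0)
        e = np.ones(n, dtype=int)
        tab = surv_table(t, e, marker=x)
        roc = td_roc(tab, "marker", tau=365.0)
        died = t <= 365.0
        for i, c in enumerate(roc.cutoffs):
            sens = ((x > c) & died).sum() / died.sum()
            spec = ((x <= c) & ~died).sum() / (~died).sum()
            assert roc.sensitivity[i] == pytest.approx(sens, abs=1e-12)
            assert roc.specificity[i] == pytest.approx(spec, abs=1e-12)
        # AUC agrees with the classical ROC of the binary outcome
        from sklearn.metrics import roc_auc_score
        assert roc.auc == pytest.approx(roc_auc_score(died, x), abs=0.02)

    def test_perfect_marker(self):
        tab = surv_table([50] * 10 + [800] * 10, [1] * 20,
                         marker=[1.0] * 10 + [0.0] * 10)
        roc = td_roc(tab, "marker", tau=365.0)
        cutoff, j = youden_cutoff(roc)
        assert roc.auc == pytest.approx(1.0)
        assert j == pytest.approx(1.0)
        assert cutoff == pytest.approx(0.0)  # smallest maximizing cutoff

    def test_independent_marker_auc_half(self):
        rng = np.random.default_rng(9)
        n = 4000
        tab = surv_table(rng.exponential(300, n), np.ones(n, dtype=int),
                         marker=rng.normal(size=n))
        roc = td_roc(tab, "marker", tau=365.0)
        assert roc.auc == pytest.approx(0.5, abs=0.03)

    def test_no_events_before_tau_rejected(self):
        tab = surv_table([400, 500], [1, 1], marker=[1.0, 2.0])
        with pytest.raises(ValueError, match="no event"):
            td_roc(tab, "marker", tau=365.0)


class TestYouden:
    def test_hand_arithmetic(self):
        roc = ROCResult(tau=365.0, cutoffs=np.array([1.0]),
                        sensitivity=np.array([0.8]),
                        specificity=np.array([0.9]), auc=0.85)
        _, j = youden_cutoff(roc)
        assert j == pytest.approx(0.7)

    def test_tie_takes_smallest_cutoff(self):
        roc = ROCResult(tau=365.0, cutoffs=np.array([1.0, 2.0, 3.0]),
                        sensitivity=np.array([0.7, 0.8, 0.6]),
                        specificity=np.array([0.8, 0.7, 0.9]), auc=0.8)
        cutoff, j = youden_cutoff(roc)
        assert cutoff == 1.0 and j == pytest.approx(0.5)

    def test_recovers_simulated_group_cutoff(self):
        rng = np.random.default_rng(3)
        n = 500
        x = rng.uniform(0, 1, n)
        hazard = np.where(x > 0.6, 5e-3, 5e-4)
        t = rng.exponential(1.0 / hazard)
        tab = surv_table(np.maximum(t, 1e-3), np.ones(n, dtype=int),
                         marker=x)
        roc = td_roc(tab, "marker", tau=365.0)
        cutoff, _ = youden_cutoff(roc)
        below = x[x <= 0.6].max()
        above = x[x > 0.6].min()
        assert below - 0.05 <= cutoff <= above + 0.05


# ---------------------------------------------------------------------------
# KM curves + log-rank
# ---------------------------------------------------------------------------

def logrank_chi2(time, event, group):
    """Module's log-rank statistic for a 2-group table (via km_logrank)."""
    tab = surv_table(time, event)
    _, chi2, p = km_logrank(tab, pd.Series(group), censor_horizon=np.inf)
    return chi2, p


class TestKMLogrank:
    def test_identical_groups_null(self):
        t = [10, 20, 30, 40, 50, 60] * 2
        e = [1, 1, 0, 1, 0, 1] * 2
        g = ["a"] * 6 + ["b"] * 6
        chi2, p = logrank_chi2(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_event_after_horizon_becomes_censored(self):
        tab = surv_table([100.0, 2000.0], [1, 1])
        out = administrative_censor(tab, 1825.0)
        assert out.loc[1, "time_days"] == 1825.0
        assert out.loc[1, "event"] == 0
        assert out.loc[0, "event"] == 1

    def test_matches_exhaustive_permutation(self):
        """Permutation p of the observed chi2 agrees with the chi-square p."""
        time = np.array([5, 8, 12, 16, 23, 27, 30, 34, 40, 45], dtype=float)
        event = np.ones(10, dtype=int)
        group = np.array(list("aaabbababb"))
        chi2_obs, p_asym = logrank_chi2(time, event, group)
        n_a = (group == "a").sum()
        count = total = 0
        for idx in itertools.combinations(range(10), n_a):
            g = np.array(["b"] * 10)
            g[list(idx)] = "a"
            chi2, _ = logrank_chi2(time, event, g)
            count += chi2 >= chi2_obs - 1e-12
            total += 1
        p_perm = count / total
        assert abs(p_perm - p_asym) < 0.1

    def test_curves_are_valid_survival_functions(self, celltype_data):
        rng = np.random.default_rng(0)
        n = 80
        tab = surv_table(rng.exponential(400, n) + 1,
                         rng.integers(0, 2, n))
        groups = pd.Series(np.where(np.arange(n) % 2 == 0, "hi", "lo"))
        curves, chi2, p = km_logrank(tab, groups)
        for c in curves.values():
            vals = c.iloc[:, 0].to_numpy()
            assert vals[0] <= 1.0 + 1e-12
            assert np.all(np.diff(vals) <= 1e-12)  # non-increasing


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

def partial_loglik(beta, time, event, x):
    """Breslow partial log-likelihood (no ties in the fixtures used)."""
    order = np.argsort(time)
    t, e, xv = time[order], event[order], x[order]
    ll = 0.0
    for i in range(len(t)):
        if e[i] == 1:
            risk = xv[i:]  # all with time >= t[i]
            ll += beta * xv[i] - np.log(np.sum(np.exp(beta * risk)))
    return ll


class TestCox:
    fixture = surv_table([1.0, 2.0, 3.0, 4.0], [1, 1, 0, 1],
                         x=[1.0, 0.0, 1.0, 0.0])

    def test_four_subject_closed_form(self):
        fit = cox_fit(self.fixture, ["x"], right_censor=None)
        assert fit.summary.loc["x", "beta"] == pytest.approx(
            np.log(np.sqrt(2)), abs=1e-3)
        assert fit.summary.loc["x", "hr"] == pytest.approx(np.sqrt(2),
                                                           abs=2e-3)

    def test_matches_grid_search_oracle(self):
        grid = np.linspace(-2, 2, 40001)
        ll = [partial_loglik(b, self.fixture["time_days"].to_numpy(),
                             self.fixture["event"].to_numpy(),
                             self.fixture["x"].to_numpy()) for b in grid]
        beta_grid = grid[int(np.argmax(ll))]
        fit = cox_fit(self.fixture, ["x"], right_censor=None)
        assert fit.summary.loc["x", "beta"] == pytest.approx(beta_grid,
                                                             abs=1e-3)

    def test_constant_covariate_flagged(self):
        tab = surv_table([1.0, 2.0, 3.0], [1, 1, 1], x=[2.0, 2.0, 2.0])
        fit = cox_fit(tab, ["x"], right_censor=None)
        assert fit.summary.loc["x", "beta"] == 0.0
        assert "x" in fit.flagged

    def test_right_censoring_applied(self):
        rng = np.random.default_rng(1)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(np.where(x > 0, 100, 400))
        tab = surv_table(np.maximum(t, 1e-3), np.ones(n, dtype=int), x=x)
        fit = cox_fit(tab, ["x"], right_censor=365.0)
        assert int(fit.data["event"].sum()) < n
        assert fit.summary.loc["x", "beta"] > 0.5


class TestSchoenfeld:
    def test_no_events_rejected(self):
        from graftmac.survival import CoxResult
        tab = surv_table([10.0, 20.0, 30.0], [1, 0, 1], x=[1.0, 0.0, 1.0])
        fit = cox_fit(tab, ["x"], right_censor=None)
        starved = CoxResult(summary=fit.summary, fitter=fit.fitter,
                            data=fit.data.assign(event=0))
        with pytest.raises(ValueError, match="no events"):
            schoenfeld_check(starved)

    def test_detects_time_varying_effect(self):
        rng = np.random.default_rng(4)
        n = 500
        x = rng.integers(0, 2, n).astype(float)
        # effect reverses over time: early harm, late protection
        t_early = rng.exponential(np.where(x > 0, 30, 100))
        t_late = 200 + rng.exponential(np.where(x > 0, 400, 80))
        t = np.where(rng.uniform(size=n) < 0.5, t_early, t_late)
        tab = surv_table(np.maximum(t, 1e-3), np.ones(n, dtype=int), x=x)
        fit = cox_fit(tab, ["x"], right_censor=None)
        out = schoenfeld_check(fit)
        assert out.loc["x", "p"] < 0.05

    def test_ph_data_rarely_rejected(self):
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 150
            x = rng.integers(0, 2, n).astype(float)
            t = rng.exponential(np.where(x > 0, 100, 200))
            tab = surv_table(np.maximum(t, 1e-3), np.ones(n, dtype=int),
                             x=x)
            fit = cox_fit(tab, ["x"], right_censor=None)
            rejections += schoenfeld_check(fit).loc["x", "p"] < 0.05
        assert rejections <= 4  # ~nominal 5% of 20


# ---------------------------------------------------------------------------
# composition statistics
# ---------------------------------------------------------------------------

class TestComposition:
    def test_infiltration_equal_proportions(self):
        rej = pd.Series({"mac": 0.2}, name="r")
        no = pd.Series({"mac": 0.2})
        out = infiltration_score(rej, no, eps=0.0)
        assert out.loc["mac", "infiltration_ratio"] == pytest.approx(1.0)

    def test_infiltration_fivefold(self):
        rej = pd.Series({"mac": 0.064})
        no = pd.Series({"mac": 0.0128})
        out = infiltration_score(rej, no)
        assert out.loc["mac", "infiltration_ratio"] == pytest.approx(
            5.0, rel=0.02)

    def test_infiltration_zero_denominator_flagged(self):
        out = infiltration_score(pd.Series({"mac": 0.1}),
                                 pd.Series({"mac": 0.0}))
        assert np.isfinite(out.loc["mac", "infiltration_ratio"])
        assert bool(out.loc["mac", "denominator_zero"])

    def test_lesion_correlation_linear(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 4, 40)
        tab = pd.DataFrame({"g": g, "ptc": g, "i": g, "t": g,
                            "frac": 4.0 * g + 1.0})
        out = lesion_correlation(tab, "frac")
        assert out["r"] > 0.999
        assert out["ci_low"] <= out["r"] <= out["ci_high"]

    def test_lesion_correlation_independent(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({
            "g": rng.integers(0, 4, 3000), "ptc": rng.integers(0, 4, 3000),
            "i": rng.integers(0, 4, 3000), "t": rng.integers(0, 4, 3000),
            "frac": rng.normal(size=3000)})
        out = lesion_correlation(tab, "frac")
        assert abs(out["r"]) < 0.05

    def test_lesion_correlation_needs_three(self):
        tab = pd.DataFrame({"g": [1, 2], "ptc": [0, 1], "i": [0, 0],
                            "t": [1, 1], "frac": [0.1, 0.2]})
        with pytest.raises(ValueError, match="at least 3"):
            lesion_correlation(tab, "frac")


class TestGroupTests:
    def test_identical_groups_unit_p(self):
        out = group_tests([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert out["p"] == pytest.approx(1.0)

    def test_mann_whitney_exact_enumeration(self):
        """U=0 for complete separation; exact two-sided p = 2/C(6,3) = 0.1."""
        out = group_tests([1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3)
        assert out["statistic"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(0.1)

    def test_three_identical_groups_kruskal_null(self):
        vals = [1, 2, 3, 4] * 3
        groups = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        out = group_tests(vals, groups)
        assert out["test"] == "kruskal-wallis"
        assert out["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert {"group_a", "group_b", "z", "p", "p_bh"} <= \
            set(out["dunn"].columns)

    def test_dunn_flags_the_shifted_group(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 1, 30),
                               rng.normal(3, 1, 30)])
        groups = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
        out = group_tests(vals, groups)
        dunn = out["dunn"].set_index(["group_a", "group_b"])
        assert dunn.loc[("a", "c"), "p_bh"] < 0.01
        assert dunn.loc[("b", "c"), "p_bh"] < 0.01
        assert dunn.loc[("a", "b"), "p"] > 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            group_tests([1, 2, 3], ["a", "a", "a"])
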