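"""Survival stratification and composition statistics for deconvolved cohorts.

Covers the clinical-consequence arm of the pipeline: time-dependent ROC of a
continuous marker (cell fraction) at a fixed horizon with the Kaplan-Meier
estimator, Youden-index cutoff selection, Kaplan-Meier curves with the
log-rank test under administrative censoring, Cox proportional-hazards
models (Efron ties) with a Schoenfeld-residual check, and the
composition-level statistics: infiltration ratios, Banff lesion-sum
correlation, and Mann-Whitney / Kruskal-Wallis + Dunn group tests.

The time-dependent ROC uses the cumulative/dynamic definition:
``Sens(c) = P(X > c | T <= tau)`` and ``Spec(c) = P(X <= c | T > tau)``,
estimated under censoring by applying the product-limit (Kaplan-Meier)
survival estimate inside each marker stratum.  Without censoring this
reduces exactly to the classical empirical ROC of the binary outcome
``1[T <= tau]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import (
    logrank_test,
    multivariate_logrank_test,
    proportional_hazard_test,
)

from .containers import LESION_COLUMNS, validate_survival_table


def km_survival_at(times: np.ndarray, events: np.ndarray, tau: float) -> float:
    """Product-limit survival estimate S(tau).

    Small internal implementation used per marker stratum inside the
    time-dependent ROC (hundreds of strata per curve); it is verified
    against the lifelines Kaplan-Meier fitter in the test suite.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        return 1.0
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    n_at_risk = times.size
    surv = 1.0
    i = 0
    while i < t.size and t[i] <= tau:
        j = i
        d = 0
        while j < t.size and t[j] == t[i]:
            d += e[j]
            j += 1
        if d:
            surv *= 1.0 - d / n_at_risk
        n_at_risk -= j - i
        i = j
    return float(surv)


@dataclass
class ROCResult:
    """Time-dependent ROC at horizon tau: cutoffs, sens/spec, Youden J."""

    tau: float
    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def td_roc(table: pd.DataFrame, marker: str, tau: float = 365.0) -> ROCResult:
    """Cumulative/dynamic time-dependent ROC with the KM estimator.

    Candidate cutoffs are the observed marker values.  Raises when no event
    occurs before the horizon (sensitivity undefined).
    """
    validate_survival_table(table)
    x = table[marker].to_numpy(dtype=float)
    t = table["time_days"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    if not np.any((t <= tau) & (e == 1)):
        raise ValueError(
            f"no event observed before tau={tau}; sensitivity is undefined"
        )
    s_tau = km_survival_at(t, e, tau)
    cutoffs = np.unique(x)
    sens = np.empty(cutoffs.size)
    spec = np.empty(cutoffs.size)
    for i, c in enumerate(cutoffs):
        above = x > c
        p_above = above.mean()
        s_above = km_survival_at(t[above], e[above], tau) if above.any() else 1.0
        s_below = km_survival_at(t[~above], e[~above], tau) if (~above).any() else 1.0
        denom_event = 1.0 - s_tau
        sens[i] = np.clip(p_above * (1.0 - s_above) / denom_event, 0.0, 1.0) \
            if denom_event > 0 else 0.0
        spec[i] = np.clip((1.0 - p_above) * s_below / s_tau, 0.0, 1.0) \
            if s_tau > 0 else 0.0
    fpr = 1.0 - spec
    order = np.lexsort((sens, fpr))
    xs = np.concatenate([[0.0], fpr[order], [1.0]])
    ys = np.concatenate([[0.0], sens[order], [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return ROCResult(tau=tau, cutoffs=cutoffs, sensitivity=sens,
                     specificity=spec, auc=auc)


def youden_cutoff(roc: ROCResult) -> tuple[float, float]:
    """Cutoff maximizing J = sensitivity + specificity - 1; ties take the smallest."""
    j = roc.youden
    best = int(np.argmax(j))  # argmax returns the first (smallest cutoff) tie
    return float(roc.cutoffs[best]), float(j[best])


def administrative_censor(
    table: pd.DataFrame, horizon: float
) -> pd.DataFrame:
    """Right-censor a survival table at ``horizon`` days."""
    out = table.copy()
    out["time_days"] = out["time_days"].astype(float)
    out["event"] = out["event"].astype(int)
    late = out["time_days"] > horizon
    out.loc[late, "time_days"] = horizon
    out.loc[late, "event"] = 0
    return out


def km_logrank(
    table: pd.DataFrame,
    groups: str | pd.Series,
    censor_horizon: float = 1825.0,
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """KM curves per group and the log-rank test, censored at the horizon.

    Returns (curves, chi2, p); curves map group label to the survival
    function table of the product-limit estimator.
    """
    validate_survival_table(table)
    g = table[groups] if isinstance(groups, str) else groups
    data = administrative_censor(table, censor_horizon)
    curves = {}
    for label in sorted(pd.unique(g)):
        on = (g == label).to_numpy()
        km = KaplanMeierFitter()
        km.fit(data.loc[on, "time_days"], data.loc[on, "event"], label=str(label))
        curves[str(label)] = km.survival_function_
    labels = sorted(pd.unique(g))
    if len(labels) == 2:
        a = (g == labels[0]).to_numpy()
        res = logrank_test(
            data.loc[a, "time_days"], data.loc[~a, "time_days"],
            data.loc[a, "event"], data.loc[~a, "event"],
        )
    else:
        res = multivariate_logrank_test(data["time_days"], g, data["event"])
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    """Per-covariate Cox estimates plus the fitter for residual diagnostics."""

    summary: pd.DataFrame
    fitter: CoxPHFitter | None
    data: pd.DataFrame
    flagged: list[str] = field(default_factory=list)


def cox_fit(
    table: pd.DataFrame,
    covariates: list[str],
    right_censor: float | None = 365.0,
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs.

    Constant covariates carry no information and are reported with beta 0
    and a flag instead of entering the optimization.  Monotone-likelihood
    (complete separation) fits are flagged via the convergence warning and
    the capped coefficient is returned.
    """
    if ties != "efron":
        raise ValueError("only the Efron tie correction is supported")
    validate_survival_table(table)
    data = table[["time_days", "event", *covariates]].copy()
    if right_censor is not None:
        data = administrative_censor(data, right_censor)
    flagged = [c for c in covariates if data[c].nunique() <= 1]
    active = [c for c in covariates if c not in flagged]

    rows = []
    fitter = None
    if active:
        fitter = CoxPHFitter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fitter.fit(
                data[["time_days", "event", *active]],
                duration_col="time_days", event_col="event",
            )
        for w in caught:
            if "convergence" in str(w.message).lower() or \
                    "monotone" in str(w.message).lower():
                flagged.append(f"convergence: {w.message}")
        s = fitter.summary
        for c in active:
            beta, se = float(s.loc[c, "coef"]), float(s.loc[c, "se(coef)"])
            # clip before exponentiating: monotone-likelihood fits produce
            # huge capped coefficients whose CI would overflow
            lo, hi = np.clip([beta - 1.96 * se, beta + 1.96 * se], -700, 700)
            rows.append({
                "covariate": c,
                "beta": beta,
                "hr": float(s.loc[c, "exp(coef)"]),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "se": se,
                "p": float(s.loc[c, "p"]),
            })
    for c in covariates:
        if c in flagged:
            rows.append({"covariate": c, "beta": 0.0, "hr": 1.0,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "se": np.inf, "p": np.nan})
    summary = pd.DataFrame(rows).set_index("covariate").loc[
        [c for c in covariates if c in flagged or c in active]
    ]
    return CoxResult(summary=summary, fitter=fitter, data=data, flagged=flagged)


def schoenfeld_check(fit: CoxResult) -> pd.DataFrame:
    """Proportional-hazards test from scaled Schoenfeld residuals vs time."""
    if fit.fitter is None:
        raise ValueError("no fitted covariates to check")
    if int(fit.data["event"].sum()) == 0:
        raise ValueError("no events: Schoenfeld residuals are undefined")
    res = proportional_hazard_test(fit.fitter, fit.data, time_transform="rank")
    out = res.summary.copy()
    out.index = out.index.get_level_values(0)
    return out


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

def infiltration_score(
    prop_rejection: pd.Series,
    prop_no_rejection: pd.Series,
    eps: float = 1e-4,
) -> pd.DataFrame:
    """Per-type infiltration ratio: rejection share over no-rejection share.

    ``eps`` is a pseudocount on the proportion scale guarding against empty
    no-rejection populations; rows where the raw denominator was zero are
    flagged because their ratio is governed by the pseudocount.
    """
    idx = prop_rejection.index.union(prop_no_rejection.index)
    num = prop_rejection.reindex(idx, fill_value=0.0)
    den = prop_no_rejection.reindex(idx, fill_value=0.0)
    ratio = num / (den + eps)
    return pd.DataFrame({
        "infiltration_ratio": ratio,
        "denominator_zero": den == 0.0,
    })


def lesion_correlation(
    table: pd.DataFrame,
    fraction_col: str,
    lesion_cols: tuple[str, ...] = LESION_COLUMNS,
) -> dict[str, float]:
    """Pearson correlation of a cell fraction with the summed lesion scores.

    The acute-rejection lesion burden is the sum of the glomerulitis (g),
    peritubular capillaritis (ptc), interstitial inflammation (i) and
    tubulitis (t) scores.  Returns r, a Fisher-z 95% CI and the two-sided p.
    """
    lesion_sum = table[list(lesion_cols)].sum(axis=1).to_numpy(dtype=float)
    y = table[fraction_col].to_numpy(dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 samples for a correlation")
    r, p = scipy.stats.pearsonr(lesion_sum, y)
    r = float(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    z = np.arctanh(r)
    half = 1.96 / np.sqrt(n - 3)
    return {
        "r": r, "p": float(p),
        "ci_low": float(np.tanh(z - half)),
        "ci_high": float(np.tanh(z + half)),
        "n": n,
        "lesion_sum_mean": float(lesion_sum.mean()),
    }


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks after Kruskal-Wallis, with tie correction."""
    ranks = scipy.stats.rankdata(values)
    n = len(values)
    ties = pd.Series(values).value_counts().to_numpy()
    tie_term = (ties ** 3 - ties).sum() / (12.0 * (n - 1))
    labels = sorted(pd.unique(groups))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ra, rb = ranks[groups == a], ranks[groups == b]
            var = (n * (n + 1) / 12.0 - tie_term) * (1 / len(ra) + 1 / len(rb))
            z = (ra.mean() - rb.mean()) / np.sqrt(max(var, 1e-300))
            rows.append({
                "group_a": a, "group_b": b, "z": float(z),
                "p": float(2 * scipy.stats.norm.sf(abs(z))),
            })
    out = pd.DataFrame(rows)
    from .trajde import bh_adjust
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


def group_tests(values, groups) -> dict:
    """Nonparametric group comparison chosen by the number of groups.

    Two groups: two-sided Mann-Whitney U (exact for <= 8 per group without
    ties, normal approximation with tie correction otherwise).  Three or
    more: Kruskal-Wallis with tie correction plus Dunn pairwise z-tests,
    reported both unadjusted and BH-adjusted.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if len(labels) == 2:
        a = values[groups == labels[0]]
        b = values[groups == labels[1]]
        res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="auto")
        return {"test": "mann-whitney", "statistic": float(res.statistic),
                "p": float(min(res.pvalue, 1.0))}
    samples = [values[groups == l] for l in labels]
    h, p = scipy.stats.kruskal(*samples)
    return {"test": "kruskal-wallis", "statistic": float(h), "p": float(p),
            "dunn": _dunn_pairwise(values, groups)}
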