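"""Time-to-event machinery and the covariate conventions of the pipeline.

Expression enters survival models either dichotomised at the cohort median
(Kaplan–Meier display, univariate Cox) or as a continuous covariate ranked
and normalised to [0, 1] — which makes the fitted model invariant to any
strictly monotone transform of the raw values. Multivariate Cox models are
reduced by stepwise backward likelihood-ratio selection with the gene under
study protected, and a two-gene stratification is tested with a Helmert
contrast isolating the double-overexpressing group.

Kaplan–Meier, log-rank and Cox partial-likelihood maximisation (Efron tie
handling) are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .io_config import ExpressionMatrix, logger

GROUP_LEVELS = ("-/-", "+/-", "-/+", "+/+")


def median_dichotomize(values) -> np.ndarray:
    """Split at the median: "high" iff value > median, ties go to "low"."""
    x = np.asarray(values, dtype=float)
    x_ok = x[~np.isnan(x)]
    if len(x_ok) < 2:
        raise ValueError("need >= 2 non-missing values to dichotomise")
    med = np.median(x_ok)
    if np.nanmin(x) == np.nanmax(x):
        raise ValueError("all values identical: degenerate median split")
    out = np.where(x > med, "high", "low").astype(object)
    out[np.isnan(x)] = None
    return out


def rank_normalize(values) -> np.ndarray:
    """Average ranks rescaled to [0, 1]: (rank − 1)/(n − 1).

    Missing values stay missing and do not consume ranks.
    """
    x = np.asarray(values, dtype=float)
    ok = ~np.isnan(x)
    n = int(ok.sum())
    if n < 2:
        raise ValueError("need >= 2 non-missing values to rank-normalise")
    out = np.full(x.shape, np.nan)
    out[ok] = (stats.rankdata(x[ok]) - 1.0) / (n - 1.0)
    return out


@dataclass
class KMEstimate:
    """Product-limit survival estimate. ``survival[i]`` is S(t) just after
    ``event_times[i]``; censoring at an event time is counted after the
    events at that time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censor_times: np.ndarray

    def at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        i = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    def restricted_mean(self, horizon: float) -> float:
        """Restricted mean survival time: area under S(t) on [0, horizon]."""
        grid = np.concatenate([[0.0], self.event_times[self.event_times < horizon], [horizon]])
        heights = [self.at(t) for t in grid[:-1]]
        return float(np.sum(np.diff(grid) * heights))


def km_estimate(time, event) -> KMEstimate:
    """Kaplan–Meier estimate of the survival function."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise ValueError("empty input")
    if (time < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tab = kmf.event_table
    tab = tab[tab["observed"] > 0]
    times = tab.index.to_numpy(dtype=float)
    return KMEstimate(
        event_times=times,
        survival=kmf.survival_function_at_times(times).to_numpy(dtype=float),
        at_risk=tab["at_risk"].to_numpy(dtype=int),
        events=tab["observed"].to_numpy(dtype=int),
        censor_times=np.sort(time[event == 0]),
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Log-rank test across >= 2 groups; returns (chi2, p)."""
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(np.asarray(time, dtype=float), group, np.asarray(event, dtype=int))
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxModelResult:
    """Cox proportional-hazards fit: per-variable log-hazard coefficients,
    hazard ratios with 95% Wald intervals, Wald p-values, the maximised
    partial log-likelihood and the retained-variable set."""

    variables: list[str]
    beta: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    retained: list[str] = field(default_factory=list)
    n: int = 0
    n_events: int = 0

    def __getitem__(self, variable: str) -> dict:
        i = self.variables.index(variable)
        return {
            "beta": float(self.beta[i]), "hr": float(self.hr[i]),
            "ci_low": float(self.ci_low[i]), "ci_high": float(self.ci_high[i]),
            "p": float(self.p[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "hr": self.hr, "ci_low": self.ci_low,
             "ci_high": self.ci_high, "p": self.p},
            index=pd.Index(self.variables, name="variable"),
        )


def cox_fit(covariates: pd.DataFrame, time, event) -> CoxModelResult:
    """Fit a Cox model by partial-likelihood maximisation with Efron tie
    handling; rows with any missing covariate are dropped (logged)."""
    X = covariates.copy()
    X = X.apply(pd.to_numeric)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ok = ~X.isna().any(axis=1).to_numpy()
    if not ok.all():
        logger.info("cox_fit: dropped %d incomplete-covariate rows", int((~ok).sum()))
    X, time, event = X.loc[ok], time[ok], event[ok]
    if event.sum() < 1:
        raise ValueError("no events in the data")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")

    df = X.copy()
    df["_time"], df["_event"] = time, event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event",
                fit_options={"precision": 1e-9})
    except ConvergenceError as exc:
        raise RuntimeError(
            "Cox model failed to converge (possible complete separation; "
            f"consider penalisation): {exc}"
        ) from exc
    s = cph.summary
    return CoxModelResult(
        variables=list(X.columns),
        beta=s["coef"].to_numpy(),
        hr=s["exp(coef)"].to_numpy(),
        ci_low=s["exp(coef) lower 95%"].to_numpy(),
        ci_high=s["exp(coef) upper 95%"].to_numpy(),
        p=s["p"].to_numpy(),
        loglik=float(cph.log_likelihood_),
        retained=list(X.columns),
        n=len(df),
        n_events=int(event.sum()),
    )


def backward_select(
    covariates: pd.DataFrame,
    time,
    event,
    p_exit: float = 0.05,
    protected: tuple[str, ...] = (),
) -> CoxModelResult:
    """Stepwise backward likelihood-ratio selection.

    Repeatedly drops the unprotected variable whose removal has the largest
    LR p-value while that p-value is at least *p_exit*; ties break by column
    order. ``p_exit >= 1`` is the "select nothing" convention: every
    unprotected term is removed regardless of its p-value. Protected variables are never removed. A single remaining
    variable is kept even if non-significant (the model must stay fittable).
    """
    missing = [v for v in protected if v not in covariates.columns]
    if missing:
        raise ValueError(f"protected variable(s) not in covariates: {missing}")
    cols = list(covariates.columns)
    current = cox_fit(covariates[cols], time, event)
    while True:
        removable = [c for c in cols if c not in protected]
        if not removable or len(cols) == 1:
            break
        lr_p = []
        for c in removable:
            reduced_cols = [x for x in cols if x != c]
            if not reduced_cols:
                # LR test against the null (no-covariate) model
                ll0 = _null_loglik(covariates[cols], time, event)
                stat = 2.0 * (current.loglik - ll0)
            else:
                reduced = cox_fit(covariates[reduced_cols], time, event)
                stat = 2.0 * (current.loglik - reduced.loglik)
            lr_p.append(stats.chi2.sf(max(stat, 0.0), df=1))
        worst = int(np.argmax(lr_p))
        if lr_p[worst] < p_exit and p_exit < 1.0:
            break
        dropped = removable[worst]
        cols.remove(dropped)
        logger.info("backward_select: removed %r (LR p=%.4f)", dropped, lr_p[worst])
        if not cols:
            break
        current = cox_fit(covariates[cols], time, event)
    current.retained = cols
    return current


def _null_loglik(covariates: pd.DataFrame, time, event) -> float:
    """Efron partial log-likelihood at beta = 0 (risk-set counting only)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = len(t)
    ll = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())
        if d:
            at_risk = n - i
            # ties: Efron subtracts k/d of the tied deaths from the risk set
            ll -= float(np.sum(np.log(at_risk - (np.arange(d) / d) * d)))
        i = j
    return ll


@dataclass
class HelmertResult:
    """Four-group two-gene analysis: group sizes, the full contrast-coded
    Cox fit, and the final contrast (double-high vs mean of the others)."""

    model: CoxModelResult
    group_sizes: dict[str, int]
    contrast_hr: float
    contrast_ci: tuple[float, float]
    contrast_p: float


def two_gene_groups(gene_a_values, gene_b_values) -> np.ndarray:
    """Four-level factor from two median splits: -/-, +/-, -/+, +/+
    (gene A sign first; "+" = above the cohort median)."""
    a = median_dichotomize(gene_a_values)
    b = median_dichotomize(gene_b_values)
    lab = np.array([
        f"{'+' if x == 'high' else '-'}/{'+' if y == 'high' else '-'}"
        for x, y in zip(a, b)
    ], dtype=object)
    return lab


# Scaled Helmert coding over the level order (-/-, +/-, -/+, +/+): each
# classical Helmert column is divided by (k+1) so that the k-th coefficient
# equals mean(level k+1) − mean(levels 1..k) on the log-hazard scale; the
# model is saturated, so the identity holds for unbalanced groups too.
_HELMERT = np.array([
    [-1 / 2, -1 / 3, -1 / 4],
    [+1 / 2, -1 / 3, -1 / 4],
    [0.0, +2 / 3, -1 / 4],
    [0.0, 0.0, +3 / 4],
])
_HELMERT_NAMES = ["mid_vs_low", "third_vs_first_two", "double_high_vs_rest"]


def helmert_analysis(gene_a_values, gene_b_values, time, event) -> HelmertResult:
    """Cox model on the four two-gene groups with Helmert contrasts; the
    reported contrast compares the +/+ group against the average of the
    other three groups."""
    groups = two_gene_groups(gene_a_values, gene_b_values)
    sizes = {lvl: int((groups == lvl).sum()) for lvl in GROUP_LEVELS}
    if min(sizes.values()) == 0:
        raise ValueError(f"empty two-gene group; sizes: {sizes}")
    level_idx = np.array([GROUP_LEVELS.index(g) for g in groups])
    X = pd.DataFrame(_HELMERT[level_idx], columns=_HELMERT_NAMES)
    model = cox_fit(X, time, event)
    c = model["double_high_vs_rest"]
    return HelmertResult(
        model=model,
        group_sizes=sizes,
        contrast_hr=c["hr"],
        contrast_ci=(c["ci_low"], c["ci_high"]),
        contrast_p=c["p"],
    )


def signature_score(m: ExpressionMatrix, genes: list[str]) -> np.ndarray:
    """Per-sample score for a published gene signature.

    Each probe annotated to a signature gene is rank-normalised across
    samples; the per-sample mean over those probes is then itself
    rank-normalised to [0, 1]. Genes absent from the matrix are logged.
    """
    rows: list[int] = []
    missing: list[str] = []
    for g in genes:
        r = m.probes_for_gene(g)
        if not r and g in m.probe_ids:
            r = [m.probe_index(g)]
        if r:
            rows.extend(r)
        else:
            missing.append(g)
    if not rows:
        raise ValueError("no signature gene present in the matrix")
    if missing:
        logger.info("signature_score: %d/%d signature genes absent from matrix",
                    len(missing), len(genes))
    ranked = np.vstack([rank_normalize(m.values[i]) for i in rows])
    return rank_normalize(ranked.mean(axis=0))
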