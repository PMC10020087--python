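"""PSI-based prognostic risk signature.

A Lasso-penalized Cox proportional-hazards model is fitted on per-event PSI
covariates; each patient's risk score is the linear predictor

    score = sum_i beta_i * PSI_i

and patients are stratified at the 75th percentile of the training scores
(top quarter = high risk).  Kaplan–Meier estimation and the two-group
log-rank test compare the strata; auxiliary routines compare tumor vs
normal PSI distributions and correlate PSI with gene expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)


@dataclass
class SurvivalCohort:
    """Patients x PSI covariates with follow-up time and event indicator."""

    psi: pd.DataFrame  # patients x events, values in [0, 1] or NaN
    time: pd.Series  # positive follow-up times
    event: pd.Series  # 1 = death/event observed, 0 = censored
    expression: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not set(np.unique(self.event)).issubset({0, 1}):
            raise ValueError("event indicator must be 0/1")
        vals = self.psi.values
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("PSI values must lie in [0, 1] or be missing")

    @property
    def n_patients(self) -> int:
        return len(self.time)

    def complete_cases(self) -> "SurvivalCohort":
        keep = self.psi.notna().all(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d patients with missing PSI", n_drop)
        return SurvivalCohort(
            self.psi[keep],
            self.time[keep],
            self.event[keep],
            None if self.expression is None else self.expression[keep],
        )


@dataclass
class RiskModel:
    """Per-event Cox coefficients plus the trained percentile cutoff."""

    event_ids: list[str]
    betas: pd.Series
    penalty: float
    cutoff: float | None = None
    quantile: float = 0.75


def _breslow_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    order = np.argsort(time)
    lp, time, event = lp[order], time[order], event[order]
    # cumulative risk-set sums from the end (everyone with t_j >= t_i)
    rev_cumsum = np.cumsum(np.exp(lp)[::-1])[::-1]
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        # risk set: all with time >= time[i]
        j = np.searchsorted(time, time[i], side="left")
        ll += lp[i] - np.log(rev_cumsum[j])
    return ll


def _coxnet_betas(X, y, alphas):
    """Coordinate-descent Lasso-Cox path; returns (coefs, alphas actually fit).

    The solver may drop path points that fail to converge, so the fitted
    alphas are returned alongside the (n_features, n_alphas) coefficients.
    """
    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False,
        max_iter=100000, tol=1e-7,
    )
    model.fit(X, y)
    return model.coef_, np.asarray(model.alphas_, dtype=float)


def cox_lasso(
    cohort: SurvivalCohort,
    penalty: float | None = None,
    *,
    cv_folds: int = 5,
    seed: int = 0,
    quantile: float = 0.75,
    cv_rule: str = "1se",
) -> RiskModel:
    """Fit the L1-penalized Cox partial likelihood on PSI covariates.

    ``penalty=0`` gives the unpenalized Cox fit; ``penalty=None`` selects the
    penalty by seeded ``cv_folds``-fold cross-validated held-out partial
    likelihood over the coordinate-descent regularization path, using the
    one-standard-error rule (``cv_rule="1se"``, the sparser standard choice)
    or the CV maximum (``cv_rule="min"``).  Rows with missing PSI are dropped
    (complete-case).  The returned model carries the 75th-percentile cutoff
    of the training risk scores.
    """
    cc = cohort.complete_cases()
    if cc.n_patients == 0:
        raise ValueError("no complete cases")
    if int(cc.event.sum()) == 0:
        raise ValueError("cannot fit a Cox model on an all-censored cohort")
    X = cc.psi.values.astype(float)
    event_ids = list(cc.psi.columns)

    if penalty is not None and penalty == 0:
        df = cc.psi.copy()
        df["time"], df["event"] = cc.time.values, cc.event.values
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        betas = cph.params_.reindex(event_ids)
        chosen = 0.0
    else:
        y = Surv.from_arrays(event=cc.event.values.astype(bool),
                             time=cc.time.values.astype(float))
        if penalty is not None:
            coefs, _ = _coxnet_betas(X, y, [penalty])
            betas = pd.Series(coefs[:, 0], index=event_ids)
            chosen = float(penalty)
        else:
            path_model = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, n_alphas=30, alpha_min_ratio=0.01,
                fit_baseline_model=False, max_iter=100000,
            )
            path_model.fit(X, y)
            alphas = np.asarray(path_model.alphas_, dtype=float)
            rng = np.random.default_rng(seed)
            folds = np.empty(len(X), dtype=int)
            folds[rng.permutation(len(X))] = np.arange(len(X)) % cv_folds
            fold_scores = np.full((cv_folds, len(alphas)), np.nan)
            for f in range(cv_folds):
                tr, te = folds != f, folds == f
                if cc.event.values[te].sum() == 0 or cc.event.values[tr].sum() == 0:
                    continue
                coefs, fit_alphas = _coxnet_betas(X[tr], y[tr], alphas)
                for a, alpha in enumerate(alphas):
                    j = np.flatnonzero(np.isclose(fit_alphas, alpha))
                    if j.size == 0:
                        continue
                    lp = X[te] @ coefs[:, j[0]]
                    fold_scores[f, a] = _breslow_loglik(
                        lp, cc.time.values[te], cc.event.values[te]
                    )
            valid = ~np.isnan(fold_scores).any(axis=0)
            mean_score = np.where(valid, np.nanmean(fold_scores, axis=0), -np.inf)
            best_idx = int(np.argmax(mean_score))
            # one-standard-error rule with paired per-fold differences, so
            # fold-level likelihood scale cancels out of the SE
            diffs = fold_scores[:, best_idx][:, None] - fold_scores
            n_f = np.sum(~np.isnan(diffs), axis=0)
            with np.errstate(invalid="ignore"):
                se = np.nanstd(diffs, axis=0, ddof=1) / np.sqrt(np.maximum(n_f, 1))
                mean_diff = np.nanmean(diffs, axis=0)
            if cv_rule == "min":
                best = best_idx
            else:
                ok = np.flatnonzero(valid & (mean_diff <= se))
                best = int(ok[0]) if ok.size else best_idx  # alphas decrease
            coefs, fit_alphas = _coxnet_betas(X, y, alphas)
            j = np.flatnonzero(np.isclose(fit_alphas, alphas[best]))
            betas = pd.Series(coefs[:, j[0] if j.size else -1], index=event_ids)
            chosen = float(alphas[best])

    model = RiskModel(event_ids, betas, chosen, quantile=quantile)
    train_scores = risk_score(model, cc.psi)
    model.cutoff = float(np.quantile(train_scores.values, quantile))
    return model


def risk_score(model: RiskModel, psi: pd.DataFrame | pd.Series) -> pd.Series:
    """Linear risk score: dot product of coefficients and PSI values."""
    if isinstance(psi, pd.Series):
        psi = psi.to_frame().T
    missing = [e for e in model.event_ids if e not in psi.columns]
    if missing:
        raise KeyError(f"PSI table lacks model events: {missing}")
    scores = psi[model.event_ids].values @ model.betas.values
    return pd.Series(scores, index=psi.index, name="risk_score")


def percentile_split(scores: pd.Series, q: float = 0.75) -> pd.Series:
    """Label the top ceil((1-q)*n) patients by score as ``high``, rest ``low``.

    Patients are ranked by descending score; boundary ties are broken by
    stable input order (a warning is logged when a tie straddles the cut).
    For n = 1207 and q = 0.75 this yields groups of 302 and 905.
    """
    n = len(scores)
    if n == 0:
        raise ValueError("empty score vector")
    n_high = int(np.ceil((1.0 - q) * n))
    order = np.argsort(-scores.values, kind="stable")
    labels = np.full(n, "low", dtype=object)
    labels[order[:n_high]] = "high"
    if 0 < n_high < n and scores.values[order[n_high - 1]] == scores.values[order[n_high]]:
        logger.warning("percentile_split: tie at the %g-quantile boundary "
                       "broken by input order", q)
    return pd.Series(labels, index=scores.index, name="risk_group")


@dataclass
class KMCurve:
    """Product-limit survival estimate for one group."""

    event_times: np.ndarray  # distinct observed event times
    at_risk: np.ndarray
    survival: np.ndarray  # S(t) evaluated at the event times
    label: str = ""


def km_estimate(
    times: pd.Series, events: pd.Series, labels: pd.Series
) -> dict[str, KMCurve]:
    """Kaplan–Meier curves per group; censored subjects leave the risk set."""
    out = {}
    for g in pd.unique(labels):
        mask = (labels == g).values
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tbl = kmf.event_table
        ev = tbl[tbl["observed"] > 0]
        t = ev.index.values.astype(float)
        surv = kmf.survival_function_.loc[t].values.ravel()
        out[str(g)] = KMCurve(t, ev["at_risk"].values.astype(int), surv, str(g))
    return out


def logrank_test(
    times: pd.Series, events: pd.Series, labels: pd.Series
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(groups)}")
    m1 = (labels == groups[0]).values
    res = _ll_logrank(
        times[m1], times[~m1], event_observed_A=events[m1],
        event_observed_B=events[~m1],
    )
    return float(res.test_statistic), float(res.p_value)


def compare_psi_groups(
    psi_tumor: pd.DataFrame, psi_normal: pd.DataFrame, *, method: str = "ranksum"
) -> pd.Series:
    """Two-sided per-event comparison of PSI distributions (tumor vs normal).

    Default is the rank-sum (Mann–Whitney) test, exact when the pooled sample
    is small and untied; ``method="ttest"`` switches to Welch's t.
    """
    common = psi_tumor.columns.intersection(psi_normal.columns)
    pvals = {}
    for ev in common:
        x = psi_tumor[ev].dropna().values
        y = psi_normal[ev].dropna().values
        if len(x) == 0 or len(y) == 0:
            pvals[ev] = np.nan
            continue
        if np.array_equal(np.sort(x), np.sort(y)):
            pvals[ev] = 1.0
            continue
        if method == "ttest":
            pvals[ev] = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
        else:
            pooled = np.concatenate([x, y])
            exact = len(pooled) <= 60 and len(np.unique(pooled)) == len(pooled)
            res = stats.mannwhitneyu(
                x, y, alternative="two-sided",
                method="exact" if exact else "asymptotic",
                use_continuity=False,
            )
            pvals[ev] = float(res.pvalue)
    return pd.Series(pvals, name="pvalue")


def correlate_expression_psi(
    expression: pd.Series, psi: pd.Series
) -> tuple[float, float]:
    """Pearson R between expression and PSI with two-sided t-based p.

    Pairs with missing values are dropped; degenerate (constant) inputs
    return (nan, nan).
    """
    df = pd.concat([expression, psi], axis=1).dropna()
    if len(df) < 3:
        return (float("nan"), float("nan"))
    x, y = df.iloc[:, 0].values, df.iloc[:, 1].values
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    return (float(r), float(p))


class CoxLassoRisk:
    """Model object wrapping the Lasso–Cox risk signature workflow."""

    def __init__(self, cohort: SurvivalCohort, *, quantile: float = 0.75):
        self.cohort = cohort
        self.quantile = quantile

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, *, time_col="time", event_col="event",
        expression_col=None, quantile: float = 0.75,
    ) -> "CoxLassoRisk":
        psi_cols = [
            c for c in df.columns
            if c not in (time_col, event_col, expression_col)
        ]
        expr = df[expression_col] if expression_col else None
        return cls(
            SurvivalCohort(df[psi_cols], df[time_col], df[event_col], expr),
            quantile=quantile,
        )

    def fit(self, penalty: float | None = None, *, cv_folds: int = 5,
            seed: int = 0, cv_rule: str = "1se") -> "CoxLassoRiskResults":
        model = cox_lasso(self.cohort, penalty, cv_folds=cv_folds, seed=seed,
                          quantile=self.quantile, cv_rule=cv_rule)
        return CoxLassoRiskResults(self, model)


class CoxLassoRiskResults:
    """Fitted risk signature: coefficients, scores, stratification, tests."""

    def __init__(self, model_obj: CoxLassoRisk, model: RiskModel):
        self.model_obj = model_obj
        self.risk_model = model
        cc = model_obj.cohort.complete_cases()
        self.cohort = cc
        self.scores = risk_score(model, cc.psi)
        self.groups = percentile_split(self.scores, model.quantile)

    @property
    def betas(self) -> pd.Series:
        return self.risk_model.betas

    def km_curves(self) -> dict[str, KMCurve]:
        return km_estimate(self.cohort.time, self.cohort.event, self.groups)

    def logrank(self) -> tuple[float, float]:
        return logrank_test(self.cohort.time, self.cohort.event, self.groups)

    def summary(self) -> str:
        chi2, p = self.logrank()
        n_high = int((self.groups == "high").sum())
        n_low = int((self.groups == "low").sum())
        lines = [
            "Lasso-Cox PSI risk signature",
            f"  patients: {self.cohort.n_patients} "
            f"({int(self.cohort.event.sum())} events)",
            f"  penalty: {self.risk_model.penalty:.4g}",
            "  coefficients:",
        ]
        for ev, b in self.betas.items():
            lines.append(f"    {ev}: {b:+.4f}")
        lines += [
            f"  risk cutoff ({self.risk_model.quantile:.0%} percentile): "
            f"{self.risk_model.cutoff:.4f}",
            f"  groups: high={n_high}, low={n_low}",
            f"  log-rank: chi2={chi2:.3f}, p={p:.4g}",
        ]
        return "\n".join(lines)
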