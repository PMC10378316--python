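"""Kaplan-Meier estimation, log-rank testing, and univariate Cox screening.

KM curves and two-group log-rank tests are delegated to lifelines; the
univariate Cox proportional-hazards fit goes through statsmodels' PHReg
with Breslow tie handling (Newton iterations on the partial likelihood),
reporting the hazard ratio with its 95% Wald interval.

``survival_screen`` reproduces the per-feature screening used for marker
prognosis: expression is dichotomized at the cohort median (ties to the
low group), the hazard ratio compares high vs low expression, and the
p-value comes from the log-rank test on the two strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from statsmodels.duration.hazard_regression import PHReg

from .containers import SurvivalCohort, ValidationError

__all__ = [
    "KMCurve",
    "CoxResult",
    "km_curve",
    "logrank_test",
    "cox_univariate",
    "survival_screen",
]


@dataclass
class KMCurve:
    """Right-continuous product-limit estimate, S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out


@dataclass
class CoxResult:
    feature_id: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    logrank_p: float = float("nan")
    flagged: bool = False  # monotone likelihood / separation warning


def km_curve(times, events) -> KMCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValidationError("need >= 1 subject")
    if (times <= 0).any():
        raise ValidationError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMCurve(
        times=sf.index.to_numpy(float), survival=sf.iloc[:, 0].to_numpy(float)
    )


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank statistic (chi-square, 1 df) and p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValidationError("log-rank test needs exactly two non-empty groups")
    a = group == levels[0]
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def cox_univariate(
    covariate, times, events, feature_id: str = "", alpha: float = 0.05
) -> CoxResult:
    """Univariate Cox PH fit (Breslow ties, Newton iterations, Wald CI)."""
    x = np.asarray(covariate, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if np.ptp(x) == 0:
        raise ValidationError("constant covariate: beta unidentifiable")
    if events.sum() < 2:
        raise ValidationError("need >= 2 events")
    model = PHReg(times, x[:, None], status=events, ties="breslow")
    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(method="newton", maxiter=50, gtol=1e-8)
        beta = float(fit.params[0])
        se = float(fit.bse[0])
        wald_p = float(fit.pvalues[0])
    except np.linalg.LinAlgError:
        # monotone likelihood (separation): bounded maximization, flagged
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda b: -model.loglike(np.array([b])),
                              bounds=(-20.0, 20.0), method="bounded")
        beta, se, wald_p = float(res.x), float("inf"), 1.0
        flagged = True
    if not np.isfinite(se) or abs(beta) > 10 or se > 10:
        flagged = True
        warnings.warn(
            f"possible monotone likelihood for {feature_id or 'covariate'}"
        )
    z = 1.959963984540054  # Phi^-1(0.975)
    return CoxResult(
        feature_id=feature_id,
        beta=beta,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)) if np.isfinite(se) else 0.0,
        ci_high=float(np.exp(beta + z * se)) if np.isfinite(se) else float("inf"),
        wald_p=wald_p,
        flagged=flagged,
    )


def dichotomize(values: pd.Series, split: str = "median") -> pd.Series:
    """High/low expression indicator (1 = high); ties go to the low group."""
    if split != "median":
        raise ValidationError(f"unknown split {split!r}")
    cutoff = values.median()
    return (values > cutoff).astype(int)


def survival_screen(
    expression: pd.DataFrame,
    cohort: SurvivalCohort,
    split: str = "median",
    mode: str = "dichotomized",
) -> pd.DataFrame:
    """Per-feature prognostic screen over a survival cohort.

    ``expression`` is features x subjects (defaults to the cohort's own
    matrix when the frames match). In the default dichotomized mode each
    feature is median-split, the HR comes from a two-group Cox fit
    (high vs low) and the p-value from the log-rank test; continuous mode
    fits the standardized covariate directly.
    """
    extra = set(expression.columns) - set(cohort.clinical.index)
    if extra:
        raise ValidationError(
            f"expression subjects missing from cohort: {sorted(extra)[:5]}"
        )
    clin = cohort.clinical.loc[expression.columns]
    times = clin["time"].to_numpy(float)
    events = clin["event"].to_numpy(int)
    rows = []
    for feature, values in expression.iterrows():
        vals = values.astype(float)
        if mode == "dichotomized":
            ind = dichotomize(vals, split=split)
            n_high = int(ind.sum())
            if n_high < 2 or len(ind) - n_high < 2:
                warnings.warn(f"feature {feature!r} skipped: degenerate split")
                continue
            try:
                res = cox_univariate(ind.to_numpy(), times, events,
                                     feature_id=str(feature))
            except ValidationError:
                warnings.warn(f"feature {feature!r} skipped: Cox fit not possible")
                continue
            _, p = logrank_test(times, events, ind.to_numpy())
            res.logrank_p = p
        elif mode == "continuous":
            z = (vals - vals.mean()) / (vals.std(ddof=1) or 1.0)
            try:
                res = cox_univariate(z.to_numpy(), times, events,
                                     feature_id=str(feature))
            except ValidationError:
                warnings.warn(f"feature {feature!r} skipped: Cox fit not possible")
                continue
            res.logrank_p = res.wald_p
        else:
            raise ValidationError(f"unknown mode {mode!r}")
        rows.append(res)
    return pd.DataFrame(
        [
            {
                "feature_id": r.feature_id,
                "beta": r.beta,
                "hr": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "wald_p": r.wald_p,
                "logrank_p": r.logrank_p,
                "flagged": r.flagged,
            }
            for r in rows
        ]
    ).set_index("feature_id")
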