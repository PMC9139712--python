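"""Survival prognostication: Cox proportional-hazards and Kaplan–Meier/log-rank.

Residual overall survival (OS) and progression-free survival (PFS) are
measured from the MRI scan date with right censoring. Cox models are fit by
partial-likelihood maximization with Efron tie handling (via lifelines);
hazard ratios come with Wald 95% CIs and p-values. Continuous variables are
stratified for Kaplan–Meier/log-rank analysis by a median split (ties to
the low group).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "CoxResult",
    "KmLogrank",
    "cox_fit",
    "km_curve",
    "median_split",
    "survival_table",
]

log = logging.getLogger(__name__)


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs and p-values."""

    variables: list
    hazard_ratio: dict
    hr_ci95_lo: dict
    hr_ci95_hi: dict
    p_value: dict
    coef: dict
    coef_se: dict
    log_likelihood: float
    n: int
    n_events: int

    def __post_init__(self) -> None:
        for v in self.variables:
            if not self.hr_ci95_lo[v] <= self.hazard_ratio[v] <= self.hr_ci95_hi[v]:
                raise ValueError(f"CI does not bracket HR for {v!r}")
            if not 0.0 <= self.p_value[v] <= 1.0:
                raise ValueError(f"p-value out of range for {v!r}")


@dataclass
class KmLogrank:
    """Per-group Kaplan–Meier step functions plus the log-rank test."""

    groups: list
    survival: dict  # group -> DataFrame(time, survival)
    group_sizes: dict
    chi_square: float
    p_value: float
    df: int


def cox_fit(
    table: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariates: list,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Wald inference).

    Rows with missing covariate, time or event values are dropped (count
    logged). Constant covariates and perfect separation raise a diagnostic
    error naming the covariate.
    """
    cols = [time_col, event_col] + list(covariates)
    df = table[cols].copy()
    n_before = len(df)
    df = df.dropna()
    dropped = n_before - len(df)
    if dropped:
        log.info("cox_fit: dropped %d rows with missing values", dropped)
    if df[event_col].sum() < 1:
        raise ValueError("need at least one event")
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant after dropping missing rows")

    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox model failed to converge (possible separation) for covariates "
            f"{list(covariates)}: {err}"
        ) from err

    summ = cph.summary
    return CoxResult(
        variables=list(covariates),
        hazard_ratio={v: float(summ.loc[v, "exp(coef)"]) for v in covariates},
        hr_ci95_lo={v: float(summ.loc[v, "exp(coef) lower 95%"]) for v in covariates},
        hr_ci95_hi={v: float(summ.loc[v, "exp(coef) upper 95%"]) for v in covariates},
        p_value={v: float(summ.loc[v, "p"]) for v in covariates},
        coef={v: float(summ.loc[v, "coef"]) for v in covariates},
        coef_se={v: float(summ.loc[v, "se(coef)"]) for v in covariates},
        log_likelihood=float(cph.log_likelihood_),
        n=len(df),
        n_events=int(df[event_col].sum()),
    )


def km_curve(time, event, groups) -> KmLogrank:
    """Kaplan–Meier product-limit curves per group with a log-rank test.

    The chi-square statistic compares observed and expected event counts
    across groups; p is two-sided from chi-square with (groups − 1) degrees
    of freedom.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    names = [g for g in pd.unique(groups)]
    if any((groups == g).sum() < 1 for g in names):
        raise ValueError("every group needs at least one subject")

    survival = {}
    sizes = {}
    for g in names:
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        survival[g] = sf
        sizes[g] = int(sel.sum())

    if len(names) >= 2:
        res = multivariate_logrank_test(time, groups, event)
        chi2, p = float(res.test_statistic), float(res.p_value)
        dof = len(names) - 1
    else:
        chi2, p, dof = 0.0, 1.0, 0
    return KmLogrank(names, survival, sizes, chi2, p, dof)


def median_split(values) -> np.ndarray:
    """Binary stratification at the median: low = value <= median, high above.

    Ties go to the low group. Raises when either side would be empty
    (degenerate split), e.g. for constant input.
    """
    values = np.asarray(values, float)
    finite = values[np.isfinite(values)]
    if finite.size < 2:
        raise ValueError("need at least 2 finite values")
    med = np.median(finite)
    labels = np.where(values <= med, "low", "high")
    labels = np.where(np.isfinite(values), labels, "missing")
    n_low = int((labels == "low").sum())
    n_high = int((labels == "high").sum())
    if n_low == 0 or n_high == 0:
        raise ValueError("degenerate split: all values on one side of the median")
    return labels


_CLINICAL_COVARIATES = ["age_years", "on_treatment", "idh_mutant"]


def _stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def survival_table(
    features: pd.DataFrame,
    endpoints: tuple = ("os", "pfs"),
    variables: list | None = None,
    clinical_covariates: list | None = None,
) -> pd.DataFrame:
    """Univariate and covariate-adjusted Cox report, one row per variable.

    For each endpoint, clinical variables (age, treatment status, IDH) get
    univariate fits only; each imaging feature gets a univariate fit and a
    multivariate fit adjusted for the clinical covariates. Hazard ratios,
    Wald 95% CIs, p-values and significance stars are reported along with
    the per-row analysis n (patients missing a feature are excluded from
    that row only).
    """
    if variables is None:
        variables = [
            "median_mtr_asym_pct",
            "median_r2prime_s",
            "median_mtrxr2p",
            "median_rcbv_au",
            "tumor_volume_cm3",
            "acidic_volume_cm3",
            "acidic_fraction_pct",
        ]
        variables = [v for v in variables if v in features.columns]
    if clinical_covariates is None:
        clinical_covariates = [c for c in _CLINICAL_COVARIATES if c in features.columns]

    rows = []
    for ep in endpoints:
        tcol, ecol = f"{ep}_days", f"{ep}_event"
        for var in clinical_covariates + variables:
            uni = cox_fit(features, tcol, ecol, [var])
            row = {
                "endpoint": ep,
                "variable": var,
                "n": uni.n,
                "n_events": uni.n_events,
                "uni_hr": uni.hazard_ratio[var],
                "uni_ci_lo": uni.hr_ci95_lo[var],
                "uni_ci_hi": uni.hr_ci95_hi[var],
                "uni_p": uni.p_value[var],
                "uni_stars": _stars(uni.p_value[var]),
            }
            if var in variables and var not in clinical_covariates:
                covs = [var] + [c for c in clinical_covariates if c != var]
                multi = cox_fit(features, tcol, ecol, covs)
                row.update(
                    multi_hr=multi.hazard_ratio[var],
                    multi_ci_lo=multi.hr_ci95_lo[var],
                    multi_ci_hi=multi.hr_ci95_hi[var],
                    multi_p=multi.p_value[var],
                    multi_stars=_stars(multi.p_value[var]),
                    multi_n=multi.n,
                )
            rows.append(row)
    return pd.DataFrame(rows)
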