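"""Per-SD Cox proportional-hazards analysis with two-batch fixed-effect meta.

Metabolite exposures are processed per batch (natural log, winsorisation at
mean +- 5 SD, standardisation to mean 0 / SD 1), fitted in adjusted Cox
models (Efron ties) separately per batch, and pooled by inverse-variance
fixed-effect meta-analysis with Cochran's Q heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .microbiome_stats import bh_fdr  # noqa: F401 (re-export for results tables)

WINSOR_SD = 5.0
DEFAULT_COVARIATES = ("age", "sex", "bmi", "smoking", "crp")


@dataclass
class CoxResult:
    target_id: str
    log_hr: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int


def preprocess_exposure(values, already_log: bool = False) -> np.ndarray:
    """log -> winsorise to +-5 SD -> standardize, within one batch.

    Output has mean 0 and SD 1 exactly (standardisation happens after
    clamping).  Raw values must be positive unless ``already_log``.
    """
    x = np.asarray(values, dtype=float)
    if not already_log:
        if np.any(x <= 0):
            raise ValueError("raw exposure values must be positive for the log step")
        x = np.log(x)
    mu, sd = x.mean(), x.std(ddof=0)
    if sd == 0:
        raise ValueError("constant exposure")
    x = np.clip(x, mu - WINSOR_SD * sd, mu + WINSOR_SD * sd)
    return (x - x.mean()) / x.std(ddof=0)


def cox_per_sd(
    records: pd.DataFrame,
    exposure: str = "exposure",
    covariates=DEFAULT_COVARIATES,
    target_id: str | None = None,
) -> CoxResult:
    """Adjusted Cox model; the estimate is the hazard ratio per SD of exposure."""
    cols = [exposure, *covariates]
    df = records[["followup_time", "event", *cols]].dropna().copy()
    if df["event"].sum() < 1:
        raise ValueError("no events in the data")
    X = df[cols].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X - X.mean(axis=0)) < X.shape[1]:
        raise ValueError("singular design: collinear covariates")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="followup_time", event_col="event")
    log_hr = float(cph.params_[exposure])
    se = float(cph.standard_errors_[exposure])
    z = log_hr / se
    return CoxResult(
        target_id or exposure,
        log_hr,
        se,
        math.exp(log_hr),
        math.exp(log_hr - 1.96 * se),
        math.exp(log_hr + 1.96 * se),
        float(2.0 * stats.norm.sf(abs(z))),
        len(df),
        int(df["event"].sum()),
    )


def cox_per_batch(
    records: pd.DataFrame,
    exposure: str = "exposure_raw",
    covariates=DEFAULT_COVARIATES,
    batch_col: str = "batch",
    preprocess: bool = True,
) -> list[CoxResult]:
    """Batch-separate preprocessing and Cox fits for one metabolite."""
    out = []
    for batch, grp in records.groupby(batch_col, sort=True):
        grp = grp.copy()
        if preprocess:
            grp["exposure_std"] = preprocess_exposure(grp[exposure])
        else:
            grp["exposure_std"] = grp[exposure]
        out.append(
            cox_per_sd(grp, "exposure_std", covariates, target_id=f"batch{batch}")
        )
    return out


def fixed_effect_meta(batch_results: list[CoxResult]) -> dict:
    """Inverse-variance pooled log-HR with Cochran's Q heterogeneity."""
    if len(batch_results) < 1:
        raise ValueError("need at least one batch result")
    b = np.array([r.log_hr for r in batch_results])
    se = np.array([r.se for r in batch_results])
    if np.any(se <= 0):
        raise ValueError("non-positive SE in a batch result")
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(math.sqrt(1.0 / np.sum(w)))
    q = float(np.sum(w * (b - pooled) ** 2))
    df_q = len(batch_results) - 1
    p_het = float(stats.chi2.sf(q, df_q)) if df_q > 0 else math.nan
    z = pooled / pooled_se
    return {
        "log_hr": pooled,
        "se": pooled_se,
        "hr": math.exp(pooled),
        "ci_low": math.exp(pooled - 1.96 * pooled_se),
        "ci_high": math.exp(pooled + 1.96 * pooled_se),
        "p": float(2.0 * stats.norm.sf(abs(z))),
        "cochran_q": q,
        "q_df": df_q,
        "p_heterogeneity": p_het,
    }
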