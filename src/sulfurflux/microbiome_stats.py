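"""Statistics on community models and secretion screens.

Covers the model-side analyses: abundance-weighted reaction abundances,
fractional (logit-link quasi-likelihood) regressions with subject-resampling
bootstrap, group tests on log secretion potentials, fractional-polynomial
variance explanation, and the sulfur-enrichment Fisher exact test computed by
explicit hypergeometric enumeration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import special, stats

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 2000


@dataclass
class GroupTestResult:
    target_id: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    q: float = math.nan
    n_boot: int = 0


def bh_fdr(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with a declared family size.

    ``family_size`` may exceed ``len(p_values)`` when part of the declared
    family was skipped (the skipped tests are treated as non-discoveries,
    which is the conservative reading of a fixed family).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = int(family_size) if family_size is not None else p.size
    if m < p.size:
        raise ValueError("declared family smaller than the number of tests")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / (np.arange(p.size) + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# --------------------------------------------------------------------------
# reaction abundances
# --------------------------------------------------------------------------

def reaction_abundances(panel, profiles, reaction_ids) -> pd.DataFrame:
    """Abundance-weighted reaction presence per subject.

    abundance(subject, reaction) = sum of relative abundances of the
    subject's strains that carry the reaction; always in [0, 1].
    """
    carriage = {
        rid: {r.strain_id for r in panel if rid in set(r.reaction_ids)}
        for rid in reaction_ids
    }
    missing = [rid for rid, carriers in carriage.items() if not carriers]
    if missing:
        raise KeyError(f"reactions carried by no strain: {missing}")
    records = []
    for prof in profiles:
        for rid in reaction_ids:
            ab = sum(
                a for s, a in prof.abundances.items() if s in carriage[rid]
            )
            records.append((prof.subject_id, rid, ab))
    return pd.DataFrame(records, columns=["subject_id", "reaction_id", "abundance"])


# --------------------------------------------------------------------------
# fractional regression
# --------------------------------------------------------------------------

def _logit_fit(y: np.ndarray, group: np.ndarray) -> float:
    """Group log-odds-ratio from a quasi-likelihood logit fit on fractions."""
    X = sm.add_constant(group.astype(float))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return float(res.params[1])


def fractional_regression(
    y, group, n_boot: int = DEFAULT_N_BOOT, seed: int = 0
) -> GroupTestResult:
    """Fractional (logit-link) regression of a relative abundance on group.

    The estimate is the group log-odds-ratio; SE and percentile CI come from
    a nonparametric bootstrap resampling subjects with replacement; the
    p-value is a normal approximation on the bootstrap SE.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("fractional response must lie in [0, 1]")
    if len(np.unique(group)) < 2:
        raise ValueError("both groups must be non-empty")
    if group.dtype.kind in "OUS":
        g = (group == "PD").astype(float)
    else:
        g = (group == np.max(group)).astype(float)
    if np.allclose(y, y[0]):
        return GroupTestResult("group", 0.0, 0.0, 0.0, 0.0, 1.0, n_boot=0)
    est = _logit_fit(y, g)
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        while len(np.unique(g[idx])) < 2:
            idx = rng.integers(0, n, n)
        yb = y[idx]
        boots[b] = 0.0 if np.allclose(yb, yb[0]) else _logit_fit(yb, g[idx])
    se = float(np.std(boots, ddof=1))
    ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    p = 1.0 if se == 0 else 2.0 * stats.norm.sf(abs(est) / se)
    return GroupTestResult(
        "group", est, se, float(ci_low), float(ci_high), float(min(p, 1.0)),
        n_boot=n_boot,
    )


# --------------------------------------------------------------------------
# secretion-potential group tests
# --------------------------------------------------------------------------

def _zero_offset(values: np.ndarray) -> np.ndarray:
    """Log-transform with zeros offset by half the smallest positive value."""
    pos = values[values > 0]
    if pos.size == 0:
        raise ValueError("all potentials are zero")
    offset = pos.min() / 2.0
    out = values.copy()
    n_zero = int(np.sum(out <= 0))
    if n_zero:
        logger.info("offsetting %d zero potentials by %g", n_zero, offset)
        out[out <= 0] = offset
    return np.log(out)


def secretion_group_test(
    potentials: pd.DataFrame,
    group: pd.Series,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-metabolite linear regression of log potential on group.

    ``potentials``: subjects x metabolites.  Bootstrap (subject resampling)
    percentile CIs; BH q-values across the tested metabolite family.
    """
    rng = np.random.default_rng(seed)
    g = (group.loc[potentials.index] == "PD").to_numpy(dtype=float)
    rows = []
    for j, met in enumerate(potentials.columns):
        vals = potentials[met].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        if not ok.all():
            logger.info("%s: dropping %d infeasible subjects", met, (~ok).sum())
        v, gg = vals[ok], g[ok]
        if np.all(v == 0) or np.ptp(v) == 0:
            logger.info("%s: no variance in potentials, skipped", met)
            continue
        y = _zero_offset(v)
        est = float(np.mean(y[gg == 1]) - np.mean(y[gg == 0]))
        n = len(y)
        boots = np.empty(n_boot)
        child = np.random.default_rng(rng.integers(2**31))
        for b in range(n_boot):
            idx = child.integers(0, n, n)
            while len(np.unique(gg[idx])) < 2:
                idx = child.integers(0, n, n)
            boots[b] = np.mean(y[idx][gg[idx] == 1]) - np.mean(y[idx][gg[idx] == 0])
        se = float(np.std(boots, ddof=1))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        p = 1.0 if se == 0 else float(min(2.0 * stats.norm.sf(abs(est) / se), 1.0))
        rows.append((met, est, se, float(lo), float(hi), p, n_boot))
    out = pd.DataFrame(
        rows, columns=["metabolite", "estimate", "se", "ci_low", "ci_high", "p",
                       "n_boot"],
    )
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = []
    return out


# --------------------------------------------------------------------------
# variance explained via fractional polynomials
# --------------------------------------------------------------------------

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


def _fp_term(x: np.ndarray, power: float) -> np.ndarray:
    return np.log(x) if power == 0.0 else x ** power


def variance_explained(log_abundance, log_potential) -> dict:
    """Best degree<=2 fractional-polynomial fit of potential on abundance.

    Powers are drawn from the standard set {-2,-1,-0.5,0,0.5,1,2,3} (0 = log);
    a repeated power contributes x^p and x^p*log(x).  Inputs already on the
    log scale are shifted to positive support before the power transforms, as
    fractional-polynomial software does for non-positive regressors.  Returns
    {"r2", "powers", "p"}.
    """
    x = np.asarray(log_abundance, dtype=float)
    y = np.asarray(log_potential, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 subjects")
    if np.ptp(x) == 0:
        return {"r2": 0.0, "powers": (), "p": 1.0}
    if x.min() <= 0:
        x = x - x.min() + np.ptp(x) / len(x)

    candidates: list[tuple[tuple[float, ...], np.ndarray]] = []
    for (p1,) in ((p,) for p in FP_POWERS):
        candidates.append(((p1,), _fp_term(x, p1)[:, None]))
    for p1, p2 in combinations_with_replacement(FP_POWERS, 2):
        if p1 == p2:
            cols = np.column_stack([_fp_term(x, p1), _fp_term(x, p1) * np.log(x)])
        else:
            cols = np.column_stack([_fp_term(x, p1), _fp_term(x, p2)])
        candidates.append(((p1, p2), cols))

    best = None
    for powers, cols in candidates:
        X = sm.add_constant(cols)
        res = sm.OLS(y, X).fit()
        rss = float(res.ssr)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, powers, res)
    _, powers, res = best
    r2 = float(max(min(res.rsquared, 1.0), 0.0))
    p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
    return {"r2": r2, "powers": powers, "p": p}


# --------------------------------------------------------------------------
# sulfur enrichment (Fisher exact by enumeration)
# --------------------------------------------------------------------------

def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table by hypergeometric enumeration.

    Sums P(k) over all tables with the observed margins whose probability does
    not exceed the observed table's (with a small relative tolerance for
    floating-point ties, matching the conventional definition).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    row1, col1, n = a + b, a + c, a + b + c + d
    if n == 0:
        raise ValueError("empty table")

    def log_prob(k: int) -> float:
        return (
            special.gammaln(row1 + 1) - special.gammaln(k + 1)
            - special.gammaln(row1 - k + 1)
            + special.gammaln(n - row1 + 1) - special.gammaln(col1 - k + 1)
            - special.gammaln(n - row1 - col1 + k + 1)
            - (special.gammaln(n + 1) - special.gammaln(col1 + 1)
               - special.gammaln(n - col1 + 1))
        )

    k_min = max(0, col1 - (n - row1))
    k_max = min(row1, col1)
    lp_obs = log_prob(a)
    total = 0.0
    for k in range(k_min, k_max + 1):
        lp = log_prob(k)
        if lp <= lp_obs + 1e-7:
            total += math.exp(lp)
    return min(total, 1.0)


def sulfur_enrichment(
    p_values: dict[str, float],
    is_sulfur: dict[str, bool],
    alpha: float = 0.01,
) -> dict:
    """Overrepresentation of sulfur metabolites among significant screens.

    Builds the (sulfur x significant) 2x2 table at the p-value cutoff and
    reports its two-sided Fisher exact p.
    """
    if not p_values:
        raise ValueError("empty input")
    if set(p_values) != set(is_sulfur):
        raise ValueError("p_values and is_sulfur must share keys")
    a = sum(1 for m, p in p_values.items() if is_sulfur[m] and p < alpha)
    b = sum(1 for m, p in p_values.items() if is_sulfur[m] and p >= alpha)
    c = sum(1 for m, p in p_values.items() if not is_sulfur[m] and p < alpha)
    d = sum(1 for m, p in p_values.items() if not is_sulfur[m] and p >= alpha)
    table = [[a, b], [c, d]]
    return {"table": table, "p": fisher_exact_enumeration(table)}
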