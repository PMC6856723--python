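"""Longitudinal case/control metabolome analyses.

Implements the 3-wave analysis suite: outlier exclusion, random-intercept
trajectory models with a 3-degree-of-freedom global Wald test and trajectory
typing, the pairwise metabolite-by-group interaction screen, the two
medication paradigms (intra-individual change-on-change and global dosage /
drug tests), ordinal and linear associations with motor-scale scores,
lagged prediction models, ROC classification of levodopa intake by 3-OMD,
and BH FDR with declared family sizes.

Estimation: the random-intercept linear models are fitted as GEE with an
exchangeable working correlation — the feasible-GLS estimator of the
random-intercept model — and cluster-robust (sandwich) covariance, which is
what "generalized least-squares with heteroscedasticity-robust standard
errors" denotes in the econometric packages this analysis style comes from.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .microbiome_stats import GroupTestResult, bh_fdr  # noqa: F401 (re-export)

logger = logging.getLogger(__name__)

OUTLIER_SD = 4.0

#: declared multiple-testing family sizes for the full-cohort analyses
FAMILY_SIZES = {
    "trajectory": 272,
    "interaction_screen": 73712,
    "medication_change": 272,
    "medication_global": 524,
    "medication_single": 1632,
    "updrs_primary": 272,
    "updrs_prediction_primary": 15,
    "updrs_prediction_exploratory": 60,
}


class SingularDesignError(ValueError):
    pass


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def preprocess(table: pd.DataFrame, sd_limit: float = OUTLIER_SD) -> pd.DataFrame:
    """Remove per-metabolite outliers beyond ``sd_limit`` standard deviations.

    z-scores use each metabolite's full-sample mean/SD.  Records with missing
    dosage are kept here; dose-based analyses drop the observation (never the
    subject) themselves.
    """
    out = []
    n_removed = 0
    for met, grp in table.groupby("metabolite_id", sort=False):
        y = grp["log_concentration"]
        sd = y.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            out.append(grp)
            continue
        z = (y - y.mean()) / sd
        keep = z.abs() <= sd_limit
        n_removed += int((~keep).sum())
        out.append(grp[keep])
    if n_removed:
        logger.info("outlier exclusion removed %d observations", n_removed)
    return pd.concat(out, ignore_index=True)


def _metabolite_frame(table: pd.DataFrame, metabolite: str) -> pd.DataFrame:
    df = table[table["metabolite_id"] == metabolite].copy()
    if df.empty:
        raise KeyError(f"metabolite {metabolite!r} not in table")
    df["pd"] = (df["group"] == "PD").astype(float)
    df["wave"] = pd.Categorical(df["wave"], categories=["BL", "FU1", "FU2"])
    df["wave"] = df["wave"].cat.remove_unused_categories()
    return df


def _check_rank(res) -> None:
    X = res.model.exog
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(
            "singular design matrix (collinear or constant predictors)"
        )


def _gee(formula: str, data: pd.DataFrame, groups: str = "subject_id"):
    """Exchangeable-GEE fit: feasible GLS for the random-intercept model with
    cluster-robust covariance."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.gee(
            formula, groups=groups, data=data,
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        # bias-reduced (Mancl-DeRouen) sandwich: the plain robust covariance
        # is anti-conservative at the cohort's cluster count (~60 subjects)
        res = model.fit(cov_type="bias_reduced")
    _check_rank(res)
    return res


def _joint_wald(res, names: list[str]) -> tuple[float, float]:
    """Chi-square Wald statistic for H0: all named coefficients are zero,
    on the fit's (robust) covariance."""
    params = res.params
    cov = res.cov_params()
    idx = [list(params.index).index(n) for n in names]
    b = params.to_numpy()[idx]
    V = np.asarray(cov)[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(f"singular covariance for {names}") from exc
    p = float(stats.chi2.sf(chi2, len(idx)))
    return chi2, p


# --------------------------------------------------------------------------
# trajectory models
# --------------------------------------------------------------------------

@dataclass
class TrajectoryFit:
    metabolite_id: str
    beta_group: float
    beta_gw1: float
    beta_gw2: float
    se_group: float
    se_gw1: float
    se_gw2: float
    p_group: float
    p_gw1: float
    p_gw2: float
    global_wald_chi2: float
    global_p: float
    main_effect_beta: float
    main_effect_p: float
    q: float = math.nan
    type_label: str = "none"


_GW1 = "pd:wave[T.FU1]"
_GW2 = "pd:wave[T.FU2]"


def fit_trajectory_model(
    table: pd.DataFrame, metabolite: str, adjust_medication: bool = False
) -> TrajectoryFit:
    """Random-intercept model of one metabolite's log-concentration on group,
    wave, and group-wave interactions, adjusted for age and sex.

    The global test is a joint Wald test (robust covariance) of the group
    main effect and both interaction terms; the main-effect estimate comes
    from a refit without the interactions.
    """
    df = _metabolite_frame(table, metabolite)
    if df["wave"].nunique() < 2:
        raise SingularDesignError(f"{metabolite}: fewer than 2 waves present")
    if df["pd"].nunique() < 2:
        raise SingularDesignError(f"{metabolite}: one study group absent")
    extra = ""
    if adjust_medication:
        df = df[df["levodopa_dose"].notna()].copy()
        df["eq_dose"] = df["levodopa_dose"] + df["equivalent_dose_other"]
        df["fu2"] = (df["wave"] == "FU2").astype(float)
        extra = " + eq_dose + eq_dose:fu2"
    res = _gee(
        "log_concentration ~ pd * wave + age + sex" + extra, df
    )
    names = ["pd", _GW1, _GW2]
    names = [n for n in names if n in res.params.index]
    chi2, global_p = _joint_wald(res, names)
    res_main = _gee("log_concentration ~ pd + wave + age + sex" + extra, df)

    def grab(name):
        if name in res.params.index:
            b = float(res.params[name])
            se = float(res.bse[name])
            p = float(res.pvalues[name])
            return b, se, p
        return math.nan, math.nan, math.nan

    bg, seg, pg = grab("pd")
    b1, se1, p1 = grab(_GW1)
    b2, se2, p2 = grab(_GW2)
    return TrajectoryFit(
        metabolite, bg, b1, b2, seg, se1, se2, pg, p1, p2,
        chi2, global_p,
        float(res_main.params["pd"]), float(res_main.pvalues["pd"]),
    )


def classify_trajectory(
    fit: TrajectoryFit,
    alpha: float = 0.05,
    fdr_gate: bool = True,
) -> str:
    """Assign the disease-specific trajectory type.

    type1: constant elevation (main effect significant, interactions not);
    type2: equal baseline, rising in cases (baseline n.s., interactions
    significantly positive); type3: elevated baseline, declining in cases
    (baseline significantly positive, interactions significantly negative).
    The global FDR gate (q < 0.05) is applied first when a q-value is set.
    """
    if fdr_gate and np.isfinite(fit.q) and fit.q >= 0.05:
        return "none"
    int_sig_pos = fit.p_gw1 < alpha and fit.p_gw2 < alpha and \
        fit.beta_gw1 > 0 and fit.beta_gw2 > 0
    int_sig_neg = fit.p_gw1 < alpha and fit.p_gw2 < alpha and \
        fit.beta_gw1 < 0 and fit.beta_gw2 < 0
    int_null = fit.p_gw1 >= alpha and fit.p_gw2 >= alpha
    baseline_sig_pos = fit.p_group < alpha and fit.beta_group > 0
    if fit.main_effect_p < alpha and int_null:
        return "type1"
    if fit.p_group >= alpha and int_sig_pos:
        return "type2"
    if baseline_sig_pos and int_sig_neg:
        return "type3"
    return "none"


def trajectory_screen(
    table: pd.DataFrame,
    metabolites=None,
    adjust_medication: bool = False,
    family_size: int | None = None,
) -> list[TrajectoryFit]:
    """Global-test screen over metabolites with BH q-values and type labels."""
    metabolites = list(metabolites or table["metabolite_id"].unique())
    fits = [fit_trajectory_model(table, m, adjust_medication) for m in metabolites]
    qs = bh_fdr([f.global_p for f in fits], family_size or len(fits))
    for f, q in zip(fits, qs):
        f.q = float(q)
        f.type_label = classify_trajectory(f)
    return fits


# --------------------------------------------------------------------------
# pairwise interaction screen
# --------------------------------------------------------------------------

def interaction_effect(
    table: pd.DataFrame,
    response: str,
    predictor: str,
    adjust_medication: bool = True,
) -> GroupTestResult:
    """Metabolite-by-group interaction for one ordered pair.

    Random-intercept model of the response log-concentration on the predictor
    metabolite, its group interaction, age, sex, wave, group, and (optionally)
    equivalent dosage with a wave-dosage interaction.  The reported estimate
    is the predictor x group coefficient with robust SE.
    """
    resp = _metabolite_frame(table, response)
    pred = table[table["metabolite_id"] == predictor][
        ["subject_id", "wave", "log_concentration"]
    ].rename(columns={"log_concentration": "x_pred"})
    if pred.empty:
        raise KeyError(f"metabolite {predictor!r} not in table")
    df = resp.merge(pred, on=["subject_id", "wave"], how="inner")
    extra = ""
    if adjust_medication:
        df = df[df["levodopa_dose"].notna()].copy()
        df["eq_dose"] = df["levodopa_dose"] + df["equivalent_dose_other"]
        df["fu2"] = (df["wave"] == "FU2").astype(float)
        extra = " + eq_dose + eq_dose:fu2"
    df = df.dropna(subset=["log_concentration", "x_pred", "age", "sex"])
    if len(df) < 10:
        raise ValueError(
            f"pair ({response}, {predictor}): fewer than 10 complete cases"
        )
    res = _gee(
        "log_concentration ~ x_pred + x_pred:pd + pd + wave + age + sex" + extra,
        df,
    )
    name = "x_pred:pd"
    est = float(res.params[name])
    se = float(res.bse[name])
    p = float(res.pvalues[name])
    return GroupTestResult(
        f"{response}~{predictor}", est, se, est - 1.96 * se, est + 1.96 * se, p
    )


def interaction_screen(
    table: pd.DataFrame,
    metabolite_pairs=None,
    adjust_medication: bool = True,
    family_size: int | None = None,
) -> pd.DataFrame:
    """All-ordered-pairs metabolite-by-group interaction screen with BH FDR.

    Pairs with fewer than 10 complete cases are skipped (logged); the BH
    family defaults to the number of tests actually run but accepts the
    declared full-screen size.
    """
    mets = list(table["metabolite_id"].unique())
    if metabolite_pairs is None:
        if len(mets) < 2:
            raise ValueError("need at least 2 metabolites")
        metabolite_pairs = [
            (a, b) for a in mets for b in mets if a != b
        ]
    rows = []
    for a, b in metabolite_pairs:
        try:
            r = interaction_effect(table, a, b, adjust_medication)
        except (ValueError, SingularDesignError) as exc:
            logger.info("pair (%s, %s) skipped: %s", a, b, exc)
            continue
        rows.append((a, b, r.estimate, r.se, r.ci_low, r.ci_high, r.p))
    out = pd.DataFrame(
        rows,
        columns=["response", "predictor", "estimate", "se", "ci_low",
                 "ci_high", "p"],
    )
    out["q"] = bh_fdr(out["p"].to_numpy(), family_size) if len(out) else []
    return out


# --------------------------------------------------------------------------
# medication models
# --------------------------------------------------------------------------

def _change_frame(table: pd.DataFrame, metabolite: str, dose_variable: str):
    df = _metabolite_frame(table, metabolite)
    df = df[(df["pd"] == 1) & df[dose_variable].notna()]
    df = df.sort_values(["subject_id", "wave"])
    deltas = []
    for sid, grp in df.groupby("subject_id"):
        grp = grp.set_index("wave")
        for w0, w1, label in (("BL", "FU1", "BL-FU1"), ("FU1", "FU2", "FU1-FU2")):
            if w0 in grp.index and w1 in grp.index:
                deltas.append(
                    (
                        sid,
                        label,
                        grp.loc[w1, "log_concentration"] - grp.loc[w0, "log_concentration"],
                        grp.loc[w1, dose_variable] - grp.loc[w0, dose_variable],
                        grp.loc[w1, "age"],
                        grp.loc[w1, "sex"],
                        grp.loc[w1, "disease_length"],
                    )
                )
    return pd.DataFrame(
        deltas,
        columns=["subject_id", "interval", "d_conc", "d_dose", "age", "sex",
                 "disease_length"],
    )


def medication_change_model(
    table: pd.DataFrame,
    dose_variable: str = "levodopa_dose",
    metabolites=None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Intra-individual change-on-change: change in log-concentration between
    consecutive waves regressed on the change in equivalent dosage, adjusted
    for age, sex, disease length, and the interval."""
    metabolites = list(metabolites or table["metabolite_id"].unique())
    rows = []
    for met in metabolites:
        df = _change_frame(table, met, dose_variable)
        if len(df) < 4 or df["d_dose"].std(ddof=1) == 0:
            logger.info("%s: no dosage variation in changes, skipped", met)
            continue
        res = _gee(
            "d_conc ~ d_dose + age + sex + disease_length + C(interval)", df
        )
        est = float(res.params["d_dose"])
        se = float(res.bse["d_dose"])
        rows.append(
            (met, est, se, est - 1.96 * se, est + 1.96 * se,
             float(res.pvalues["d_dose"]))
        )
    out = pd.DataFrame(
        rows, columns=["metabolite", "estimate", "se", "ci_low", "ci_high", "p"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy(), family_size) if len(out) else []
    return out


def medication_global_test(
    table: pd.DataFrame,
    predictors: str = "doses",
    metabolites=None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Joint Wald test of all medication terms per metabolite (PD subjects).

    ``predictors='doses'`` uses the metric dosage columns; ``'drugs'`` uses
    binary intake indicators derived from them.
    """
    if predictors == "doses":
        terms = ["levodopa_dose", "equivalent_dose_other"]
    elif predictors == "drugs":
        terms = ["takes_levodopa", "takes_other"]
    else:
        raise ValueError("predictors must be 'doses' or 'drugs'")
    metabolites = list(metabolites or table["metabolite_id"].unique())
    rows = []
    for met in metabolites:
        df = _metabolite_frame(table, met)
        df = df[(df["pd"] == 1) & df["levodopa_dose"].notna()].copy()
        df["takes_levodopa"] = (df["levodopa_dose"] > 0).astype(float)
        df["takes_other"] = (df["equivalent_dose_other"] > 0).astype(float)
        if any(df[t].std(ddof=1) == 0 for t in terms):
            logger.info("%s: a medication term lacks variation, skipped", met)
            continue
        res = _gee(
            "log_concentration ~ "
            + " + ".join(terms)
            + " + age + sex + disease_length + wave",
            df,
        )
        chi2, p = _joint_wald(res, terms)
        rows.append((met, chi2, p))
    out = pd.DataFrame(rows, columns=["metabolite", "wald_chi2", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy(), family_size) if len(out) else []
    return out


# --------------------------------------------------------------------------
# motor-scale associations and prediction
# --------------------------------------------------------------------------

ORDINAL_SCALES = {"I": "updrs_i", "II": "updrs_ii", "IV": "updrs_iv"}
LINEAR_SCALES = {"III": "updrs_iii", "total": "updrs_total"}


def _updrs_frame(table, updrs_scores, metabolite):
    df = _metabolite_frame(table, metabolite)
    df = df[df["pd"] == 1]
    df = df.merge(updrs_scores, on=["subject_id", "wave"], how="inner")
    df = df[df["levodopa_dose"].notna()].copy()
    df["eq_dose"] = df["levodopa_dose"] + df["equivalent_dose_other"]
    df["fu2"] = (df["wave"] == "FU2").astype(float)
    df["wave_idx"] = df["wave"].map({"BL": 0.0, "FU1": 1.0, "FU2": 2.0})
    return df


def updrs_association(
    table: pd.DataFrame,
    updrs_scores: pd.DataFrame,
    scale: str = "total",
    metabolites=None,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Association of metabolite levels with a motor-scale score in cases.

    Scales I/II/IV: proportional-odds ordered logit (pooled observations,
    wave as covariate); III/total: random-intercept linear model.  Adjusted
    for age, sex, wave, disease length, and equivalent dosage.
    """
    if scale not in {**ORDINAL_SCALES, **LINEAR_SCALES}:
        raise ValueError(f"unknown scale {scale!r}")
    metabolites = list(metabolites or table["metabolite_id"].unique())
    rows = []
    for met in metabolites:
        df = _updrs_frame(table, updrs_scores, met)
        col = ORDINAL_SCALES.get(scale) or LINEAR_SCALES[scale]
        if df[col].nunique() < 2:
            raise ValueError(f"scale {scale}: no variation in scores")
        if scale in LINEAR_SCALES:
            res = _gee(
                f"{col} ~ log_concentration + age + sex + wave + "
                "disease_length + eq_dose + eq_dose:fu2",
                df,
            )
            est = float(res.params["log_concentration"])
            se = float(res.bse["log_concentration"])
            p = float(res.pvalues["log_concentration"])
        else:
            exog = df[["log_concentration", "age", "sex", "wave_idx",
                       "disease_length", "eq_dose"]].astype(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = OrderedModel(df[col].astype(int), exog, distr="logit")
                res = mod.fit(method="bfgs", disp=False)
            est = float(res.params["log_concentration"])
            se = float(res.bse["log_concentration"])
            p = float(res.pvalues["log_concentration"])
        rows.append((met, est, se, est - 1.96 * se, est + 1.96 * se, p))
    out = pd.DataFrame(
        rows, columns=["metabolite", "estimate", "se", "ci_low", "ci_high", "p"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy(), family_size) if len(out) else []
    return out


def updrs_prediction(
    table: pd.DataFrame,
    updrs_scores: pd.DataFrame,
    metabolites,
    scale: str = "III",
    lags=(("BL", "FU2"), ("FU1", "FU2"), ("BL", "FU1")),
    family_size: int | None = None,
) -> pd.DataFrame:
    """Lagged prediction of later motor scores from earlier metabolite levels,
    adjusting for the earlier score, age, sex, and disease length."""
    col = ORDINAL_SCALES.get(scale) or LINEAR_SCALES.get(scale)
    if col is None:
        raise ValueError(f"unknown scale {scale!r}")
    rows = []
    for met in metabolites:
        df = _updrs_frame(table, updrs_scores, met)
        wide = df.pivot_table(
            index="subject_id",
            columns="wave",
            values=["log_concentration", col, "age", "sex", "disease_length"],
            observed=True,
        )
        for w0, w1 in lags:
            try:
                sub = pd.DataFrame(
                    {
                        "y": wide[(col, w1)],
                        "x": wide[("log_concentration", w0)],
                        "y0": wide[(col, w0)],
                        "age": wide[("age", w0)],
                        "sex": wide[("sex", w0)],
                        "dl": wide[("disease_length", w0)],
                    }
                ).dropna()
            except KeyError:
                continue
            if len(sub) < 8:
                continue
            res = sm.OLS(
                sub["y"], sm.add_constant(sub[["x", "y0", "age", "sex", "dl"]])
            ).fit(cov_type="HC1")
            est = float(res.params["x"])
            se = float(res.bse["x"])
            rows.append(
                (met, f"{w0}->{w1}", est, se, float(res.pvalues["x"]))
            )
    out = pd.DataFrame(
        rows, columns=["metabolite", "lag", "estimate", "se", "p"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy(), family_size) if len(out) else []
    return out


# --------------------------------------------------------------------------
# levodopa classification
# --------------------------------------------------------------------------

def levodopa_auc(table: pd.DataFrame, metabolite: str = "3omd") -> float:
    """ROC AUC of 3-OMD log-concentration for levodopa intake in follow-ups.

    Intake labels come from the recorded dosage (> 0); ties are handled by
    midranks (Mann-Whitney AUC).
    """
    df = table[
        (table["metabolite_id"] == metabolite)
        & table["wave"].isin(["FU1", "FU2"])
        & (table["group"] == "PD")
        & table["levodopa_dose"].notna()
    ]
    labels = (df["levodopa_dose"] > 0).astype(int)
    if labels.nunique() < 2:
        raise ValueError("need both takers and non-takers in follow-up waves")
    return float(roc_auc_score(labels, df["log_concentration"]))
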