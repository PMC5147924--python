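"""Cross-validation of PAEE predictions against the criterion signal.

Agreement is summarised the way method-comparison studies in physical
activity epidemiology report it:

* between- and within-individual explained variance (squared Pearson
  correlation of participant means, and of pooled within-participant
  deviations, respectively — the repeated-measures partitioning);
* root mean squared error on the epoch level;
* mean bias with 95% limits of agreement (Bland–Altman, mean ± 1.96 SD
  of the differences), with error = predicted − criterion so positive
  values are overestimation;
* mean bias stratified by sex, age tertiles and BMI category
  (<25, [25, 30), ≥30 kg·m⁻²);
* linear bias trends per year of age and per kg·m⁻² of BMI, both
  mean-centred, adjusting for sex;
* conversion to METs via 1 MET = 71 J·min⁻¹·kg⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

JOULES_PER_MIN_PER_KG_PER_MET = 71.0

BMI_CATEGORY_LABELS = ("under/normal-weight", "overweight", "obese")


class UndefinedResultError(ValueError):
    """Raised when a statistic is undefined (degenerate variance)."""


def to_mets(value):
    """Convert J·min⁻¹·kg⁻¹ to METs (1 standard MET = 71 J·min⁻¹·kg⁻¹)."""
    return np.asarray(value, dtype=float) / JOULES_PER_MIN_PER_KG_PER_MET


def rmse(pred, crit) -> float:
    """Root mean squared error sqrt(mean((pred - crit)^2))."""
    pred = np.asarray(pred, dtype=float)
    crit = np.asarray(crit, dtype=float)
    if pred.shape != crit.shape:
        raise ValueError("pred and crit must have equal length")
    return float(np.sqrt(np.mean((pred - crit) ** 2)))


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a) <= 0 or np.var(b) <= 0:
        raise UndefinedResultError("degenerate variance in correlation input")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def variance_decomposition(pred, crit, participant_ids) -> tuple[float, float]:
    """Between- and within-individual explained variance (r²).

    Between: squared Pearson correlation of participant means of the
    prediction vs the criterion. Within: squared Pearson correlation of
    the within-participant deviations pooled across participants.
    """
    df = pd.DataFrame({"pred": np.asarray(pred, dtype=float),
                       "crit": np.asarray(crit, dtype=float),
                       "pid": np.asarray(participant_ids)}).dropna()
    counts = df.groupby("pid").size()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need at least 2 participants with at least 2 epochs each")
    means = df.groupby("pid")[["pred", "crit"]].mean()
    r2_between = _pearson_r2(means["pred"].to_numpy(), means["crit"].to_numpy())
    dev = df[["pred", "crit"]] - df.groupby("pid")[["pred", "crit"]].transform("mean")
    if float(np.var(dev["pred"])) <= 0 or float(np.var(dev["crit"])) <= 0:
        r2_within = 0.0  # no within-person signal in one of the series
    else:
        r2_within = _pearson_r2(dev["pred"].to_numpy(), dev["crit"].to_numpy())
    return r2_between, r2_within


def sum_of_squares_partition(values, participant_ids) -> tuple[float, float, float]:
    """(total, between, within) sums of squares of one series.

    Exact identity: total = between + within, with between computed from
    participant means weighted by epoch counts.
    """
    df = pd.DataFrame({"v": np.asarray(values, dtype=float),
                       "pid": np.asarray(participant_ids)}).dropna()
    grand = df["v"].mean()
    total = float(((df["v"] - grand) ** 2).sum())
    means = df.groupby("pid")["v"].transform("mean")
    between = float(((means - grand) ** 2).sum())
    within = float(((df["v"] - means) ** 2).sum())
    return total, between, within


def bias_loa(pred, crit, participant_ids=None,
             per_participant: bool = False) -> tuple[float, float, float]:
    """Mean bias and 95% limits of agreement (mean ± 1.96 SD of error).

    Error = predicted − criterion, so positive bias is overestimation.
    With ``per_participant`` the statistics are computed on
    participant-mean errors (requires ``participant_ids``).
    """
    err = np.asarray(pred, dtype=float) - np.asarray(crit, dtype=float)
    if per_participant:
        if participant_ids is None:
            raise ValueError("participant_ids required for per-participant limits")
        err = pd.Series(err).groupby(np.asarray(participant_ids)).mean().to_numpy()
    err = err[~np.isnan(err)]
    mean = float(err.mean())
    sd = float(err.std(ddof=1)) if len(err) > 1 else 0.0
    return mean, mean - 1.96 * sd, mean + 1.96 * sd


def bmi_category(bmi) -> pd.Categorical:
    """BMI classes <25, ≥25 & <30, ≥30 kg·m⁻²."""
    return pd.cut(np.asarray(bmi, dtype=float), [-np.inf, 25.0, 30.0, np.inf],
                  right=False, labels=list(BMI_CATEGORY_LABELS))


def age_tertiles(age, reference_age=None) -> pd.Categorical:
    """Tertile classes from the empirical distribution of ``reference_age``
    (default: ``age`` itself); boundary values fall in the lower tertile."""
    age = np.asarray(age, dtype=float)
    ref = age if reference_age is None else np.asarray(reference_age, dtype=float)
    cuts = np.quantile(ref, [1 / 3, 2 / 3])
    labels = ["youngest", "middle", "oldest"]
    idx = np.searchsorted(cuts, age, side="left")  # ties to the lower tertile
    return pd.Categorical([labels[i] for i in idx], categories=labels)


def stratified_bias(errors: pd.DataFrame) -> pd.DataFrame:
    """Participant-level mean bias by sex, age tertile and BMI category.

    ``errors`` needs columns participant_id, error, sex, age, bmi with
    one row per epoch (or per participant). Tertile cuts come from the
    supplied (test-set) participants' empirical age distribution.

    Returns a table with stratum, level, mean_bias, sd, n_participants.
    """
    per = errors.groupby("participant_id").agg(
        error=("error", "mean"), sex=("sex", "first"),
        age=("age", "first"), bmi=("bmi", "first")).reset_index()
    per["age_tertile"] = age_tertiles(per["age"])
    per["bmi_category"] = bmi_category(per["bmi"])
    rows = []
    for stratum, col in (("sex", "sex"), ("age_tertile", "age_tertile"),
                         ("bmi_category", "bmi_category")):
        for level, grp in per.groupby(col, observed=False):
            rows.append({"stratum": stratum, "level": str(level),
                         "mean_bias": grp["error"].mean(),
                         "sd": grp["error"].std(ddof=1),
                         "n_participants": len(grp)})
    return pd.DataFrame(rows)


def bias_trend(errors: pd.DataFrame) -> pd.DataFrame:
    """Linear regression of estimation error on sex + centred age + centred BMI.

    ``errors`` needs columns participant_id, error, sex, age, bmi; the
    regression runs on participant-mean errors. Age and BMI are centred
    on their means, so coefficients read as bias per year relative to
    mean age and per kg·m⁻² relative to mean BMI.
    """
    per = errors.groupby("participant_id").agg(
        error=("error", "mean"), sex=("sex", "first"),
        age=("age", "first"), bmi=("bmi", "first")).reset_index()
    X = pd.DataFrame({
        "intercept": 1.0,
        "female": (per["sex"] == "female").astype(float),
        "age_centred": per["age"] - per["age"].mean(),
        "bmi_centred": per["bmi"] - per["bmi"].mean(),
    })
    fit = sm.OLS(per["error"].to_numpy(), X).fit()
    ci = fit.conf_int()
    return pd.DataFrame({"coef": fit.params, "se": fit.bse,
                         "ci_lower": ci[0], "ci_upper": ci[1]})


@dataclass
class EvaluationReport:
    """Cross-validation summary of one prediction model."""

    r2_between: float
    r2_within: float
    rmse: float
    mean_bias: float
    loa_lower: float
    loa_upper: float
    n_test_participants: int
    n_epochs: int
    stratified: pd.DataFrame | None = None
    trends: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.loa_lower <= self.mean_bias <= self.loa_upper:
            raise ValueError("limits of agreement must bracket the mean bias")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "r2_between": self.r2_between, "r2_within": self.r2_within,
            "rmse": self.rmse, "rmse_mets": float(to_mets(self.rmse)),
            "mean_bias": self.mean_bias,
            "loa_lower": self.loa_lower, "loa_upper": self.loa_upper,
            "n_test_participants": self.n_test_participants,
            "n_epochs": self.n_epochs}])


def evaluate_predictions(test_epochs: pd.DataFrame, pred: np.ndarray,
                         cohort: pd.DataFrame | None = None,
                         crit_col: str = "paee_jminkg") -> EvaluationReport:
    """Full evaluation of epoch-level predictions in the held-out set.

    ``test_epochs`` must carry participant_id and the criterion column;
    stratified biases and covariate trends are added when ``cohort``
    (with sex, age, bmi) is supplied.
    """
    df = test_epochs[["participant_id", crit_col]].copy()
    df["pred"] = np.asarray(pred, dtype=float)
    df = df.dropna()
    r2b, r2w = variance_decomposition(df["pred"], df[crit_col], df["participant_id"])
    err_rmse = rmse(df["pred"], df[crit_col])
    bias, lo, hi = bias_loa(df["pred"], df[crit_col])
    strat = trends = None
    if cohort is not None:
        errors = df.assign(error=df["pred"] - df[crit_col]).merge(
            cohort[["participant_id", "sex", "age", "bmi"]], on="participant_id")
        strat = stratified_bias(errors)
        trends = bias_trend(errors)
    return EvaluationReport(
        r2_between=r2b, r2_within=r2w, rmse=err_rmse, mean_bias=bias,
        loa_lower=lo, loa_upper=hi,
        n_test_participants=df["participant_id"].nunique(), n_epochs=len(df),
        stratified=strat, trends=trends)
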