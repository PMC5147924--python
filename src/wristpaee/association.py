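"""PAEE–BMI dose-response association, per PAEE source.

The epidemiological pay-off of a calibration model is whether the
exposure–outcome association it supports matches the one obtained with
the criterion measure. Here the association of interest is the linear
dose-response of BMI on habitual PAEE (participant mean over wear time),
adjusted for age and sex, estimated separately with criterion PAEE and
with each wrist-model prediction, then compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass(frozen=True)
class AssociationResult:
    """BMI-on-PAEE regression slope with its 95% confidence interval."""

    paee_source: str
    beta: float  # kg·m⁻² per J·min⁻¹·kg⁻¹
    ci_lower: float
    ci_upper: float
    n: int

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.beta <= self.ci_upper:
            raise ValueError("confidence interval must bracket the point estimate")


def participant_paee(epochs: pd.DataFrame, source_col: str = "paee_jminkg"
                     ) -> pd.Series:
    """Arithmetic mean of valid-epoch PAEE per participant (wear time only).

    Participants with no valid epoch for the source are excluded.
    """
    import logging
    vals = epochs[["participant_id", source_col]].dropna()
    n_before = epochs["participant_id"].nunique()
    means = vals.groupby("participant_id")[source_col].mean()
    if len(means) < n_before:
        logging.getLogger(__name__).warning(
            "%d participant(s) had no valid epoch and were excluded",
            n_before - len(means))
    return means


def fit_bmi_association(cohort: pd.DataFrame, paee: pd.Series,
                        source: str = "criterion") -> AssociationResult:
    """OLS of BMI on participant-mean PAEE, adjusting for age and sex.

    BMI = γ0 + γ1·PAEE + γ2·age + γ3·female; returns γ1 with its
    normal-theory 95% confidence interval.
    """
    df = cohort.merge(paee.rename("paee"), left_on="participant_id",
                      right_index=True)
    if len(df) < 10:
        raise ValueError("need at least 10 participants for the association model")
    X = pd.DataFrame({
        "intercept": 1.0,
        "paee": df["paee"].to_numpy(dtype=float),
        "age": df["age"].to_numpy(dtype=float),
        "female": (df["sex"] == "female").astype(float).to_numpy(),
    })
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            "collinear design: PAEE/age/sex columns are linearly dependent")
    fit = sm.OLS(df["bmi"].to_numpy(dtype=float), X).fit()
    ci = fit.conf_int()
    return AssociationResult(paee_source=source, beta=float(fit.params["paee"]),
                             ci_lower=float(ci.loc["paee", 0]),
                             ci_upper=float(ci.loc["paee", 1]), n=len(df))


def compare_sources(results: dict[str, AssociationResult],
                    criterion_key: str = "criterion") -> pd.DataFrame:
    """Forest-plot table flagging agreement of each source with the criterion.

    For each model source: whether its point estimate lies inside the
    criterion's 95% CI, and whether its own CI covers the criterion's
    point estimate.
    """
    if criterion_key not in results:
        raise ValueError("criterion result must be present")
    crit = results[criterion_key]
    rows = []
    for key, r in results.items():
        rows.append({
            "paee_source": key, "beta": r.beta,
            "ci_lower": r.ci_lower, "ci_upper": r.ci_upper, "n": r.n,
            "point_in_criterion_ci": bool(crit.ci_lower <= r.beta <= crit.ci_upper),
            "ci_covers_criterion_point": bool(r.ci_lower <= crit.beta <= r.ci_upper),
        })
    return pd.DataFrame(rows)
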