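"""Derivation of wrist-acceleration → PAEE / trunk-acceleration models.

Four model forms are fitted, enumerated as in the analysis:

1. linear ENMO, 2. quadratic ENMO, 3. linear HPFVM, 4. quadratic HPFVM,

each as a multi-level (random-intercept) linear regression with the
participant as the clustering unit, estimated by REML. The wrist metric
is mean-centred before squaring for numerical conditioning and the
coefficients are reported back on the raw-mg scale. Models are derived
on a person-level random 60% split and evaluated on the remaining 40%.

Predictions use fixed effects only (held-out participants have no
estimated random intercept). Concave quadratic equations peak at the
vertex −β₁/(2β₂); beyond it predictions are truncated flat at the
vertex value, and all predictions are floored at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

METRIC_COLUMNS = {"enmo": "enmo_mg", "hpfvm": "hpfvm_mg"}
OUTCOME_COLUMNS = {"paee": "paee_jminkg", "trunk_acc": "trunk_acc_ms2"}


@dataclass(frozen=True)
class ModelSpec:
    """One of the four (metric, form) model combinations for an outcome."""

    metric: str  # "enmo" or "hpfvm"
    form: str  # "linear" or "quadratic"
    outcome: str = "paee"  # "paee" or "trunk_acc"

    def __post_init__(self) -> None:
        if self.metric not in METRIC_COLUMNS:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.form not in ("linear", "quadratic"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {self.outcome!r}")


#: canonical numbering of the four prediction models
MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec("enmo", "linear"),
    2: ModelSpec("enmo", "quadratic"),
    3: ModelSpec("hpfvm", "linear"),
    4: ModelSpec("hpfvm", "quadratic"),
}


@dataclass
class FittedModel:
    """Fixed-effect coefficients and variance components of a fitted model.

    Coefficients are on the raw metric scale (outcome units per mg):
    prediction = alpha + beta_linear*m + beta_quadratic*m**2.
    """

    spec: ModelSpec
    alpha: float
    beta_linear: float
    beta_quadratic: float = 0.0
    se_alpha: float = np.nan
    se_beta_linear: float = np.nan
    se_beta_quadratic: float = np.nan
    random_intercept_sd: float = 0.0
    residual_sd: float = 0.0
    n_train_participants: int = 0
    n_epochs: int = 0
    pooled_fallback: bool = False

    @property
    def vertex(self) -> float | None:
        """Metric value (mg) of the quadratic's global extremum; None if linear."""
        if self.spec.form != "quadratic" or self.beta_quadratic == 0.0:
            return None
        return -self.beta_linear / (2.0 * self.beta_quadratic)

    def confint(self, level: float = 0.95) -> pd.DataFrame:
        from scipy import stats
        z = stats.norm.ppf(0.5 + level / 2.0)
        rows = {}
        for name, est, se in (("alpha", self.alpha, self.se_alpha),
                              ("beta_linear", self.beta_linear, self.se_beta_linear),
                              ("beta_quadratic", self.beta_quadratic,
                               self.se_beta_quadratic)):
            rows[name] = (est, est - z * se, est + z * se)
        return pd.DataFrame(rows, index=["estimate", "lower", "upper"]).T


@dataclass(frozen=True)
class SplitAssignment:
    """Person-level train/test partition."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_fraction: float
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "participant_id": list(self.train_ids) + list(self.test_ids),
            "split": ["train"] * len(self.train_ids) + ["test"] * len(self.test_ids)})


def split_participants(cohort: pd.DataFrame | Iterable[str],
                       train_fraction: float = 0.60,
                       seed: int = 0) -> SplitAssignment:
    """Randomly assign whole participants to train/test.

    Train size is ``round(train_fraction * n)`` on a seeded uniform
    shuffle; all of a person's epochs share the assignment.
    """
    if isinstance(cohort, pd.DataFrame):
        ids = cohort["participant_id"].tolist()
    else:
        ids = list(cohort)
    if len(ids) < 5:
        raise ValueError("cohort too small to split (need at least 5 participants)")
    if not 0.0 < train_fraction <= 1.0:
        raise ValueError("train_fraction must lie in (0, 1]")
    order = np.random.default_rng(seed).permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    test = tuple(ids[i] for i in sorted(order[n_train:]))
    return SplitAssignment(train, test, train_fraction, seed)


def _cluster_robust_cov(X: np.ndarray, y: np.ndarray, codes: np.ndarray,
                        beta: np.ndarray, sigma2: float, tau2: float) -> np.ndarray:
    """Cluster-robust (sandwich) covariance of the random-intercept GLS
    fixed effects.

    With V_g = sigma2*I + tau2*11', the bread is A = sum_g X_g'V_g^{-1}X_g and
    the meat stacks per-cluster scores X_g'V_g^{-1}r_g, so the covariance is
    valid under heteroscedastic or otherwise misspecified error structure.
    """
    r = y - X @ beta
    order = np.argsort(codes, kind="stable")
    Xo, ro, co = X[order], r[order], codes[order]
    bounds = np.r_[0, np.flatnonzero(np.diff(co)) + 1, len(co)]
    p = X.shape[1]
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        Xg, rg = Xo[i0:i1], ro[i0:i1]
        n_g = i1 - i0
        gamma = n_g * tau2 / (sigma2 + n_g * tau2) if tau2 > 0 else 0.0
        xbar = Xg.mean(axis=0)
        A += (Xg.T @ Xg - gamma * n_g * np.outer(xbar, xbar)) / sigma2
        score = (Xg.T @ rg - gamma * n_g * xbar * rg.mean()) / sigma2
        B += np.outer(score, score)
    n_clusters = len(bounds) - 1
    # CR1 small-sample correction
    B *= n_clusters / max(n_clusters - 1, 1)
    A_inv = np.linalg.inv(A)
    return A_inv @ B @ A_inv


def _design(m_centred: np.ndarray, form: str) -> np.ndarray:
    cols = [np.ones_like(m_centred), m_centred]
    if form == "quadratic":
        cols.append(m_centred**2)
    return np.column_stack(cols)


def _to_raw_scale(params: np.ndarray, cov: np.ndarray, centre: float, form: str):
    """Back-transform centred-metric coefficients to the raw-mg scale."""
    if form == "quadratic":
        a, b1, b2 = params
        T = np.array([[1.0, -centre, centre**2],
                      [0.0, 1.0, -2.0 * centre],
                      [0.0, 0.0, 1.0]])
    else:
        a, b1 = params
        b2 = 0.0
        T = np.array([[1.0, -centre], [0.0, 1.0]])
    raw = T @ np.asarray(params)
    raw_cov = T @ np.asarray(cov) @ T.T
    ses = np.sqrt(np.diag(raw_cov))
    if form == "linear":
        raw = np.r_[raw, 0.0]
        ses = np.r_[ses, np.nan]
    return raw, ses


def fit_mixed_model(epochs: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Fit one model on training epochs with a participant random intercept.

    Falls back to pooled OLS with cluster-robust standard errors when the
    mixed fit is singular (e.g. zero wrist variance), with a logged warning.
    On noise-free data the exact least-squares solution is returned directly.
    """
    ycol, mcol = OUTCOME_COLUMNS[spec.outcome], METRIC_COLUMNS[spec.metric]
    data = epochs[["participant_id", mcol, ycol]].dropna()
    groups, codes = np.unique(data["participant_id"].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 participants to fit a multi-level model")
    if len(data) / len(groups) < 10:
        raise ValueError("need on average at least 10 epochs per participant")

    m = data[mcol].to_numpy(dtype=float)
    y = data[ycol].to_numpy(dtype=float)
    centre = float(m.mean())
    X = _design(m - centre, spec.form)

    def build(params, cov, re_sd, resid_sd, pooled=False):
        raw, ses = _to_raw_scale(np.asarray(params), np.asarray(cov), centre, spec.form)
        return FittedModel(spec=spec, alpha=float(raw[0]), beta_linear=float(raw[1]),
                           beta_quadratic=float(raw[2]), se_alpha=float(ses[0]),
                           se_beta_linear=float(ses[1]), se_beta_quadratic=float(ses[2]),
                           random_intercept_sd=float(re_sd), residual_sd=float(resid_sd),
                           n_train_participants=len(groups), n_epochs=len(data),
                           pooled_fallback=pooled)

    singular = np.var(m) < 1e-12
    if not singular:
        # exact-fit shortcut: noise-free data admits a perfect solution
        ols = sm.OLS(y, X).fit()
        scale = max(np.std(y), 1.0)
        if np.sqrt(ols.ssr / len(y)) < 1e-9 * scale:
            return build(ols.params, np.zeros((X.shape[1],) * 2), 0.0, 0.0)
        try:
            res = sm.MixedLM(y, X, groups=codes).fit(reml=True)
            if not np.all(np.isfinite(res.fe_params)):
                raise ValueError("non-finite fixed effects")
            tau2 = float(np.asarray(res.cov_re)[0, 0])
            # sandwich covariance: model-based SEs understate the sampling
            # variance when the error is heteroscedastic (e.g. criterion
            # error scaling with intensity), which real criterion signals are
            cov_fe = _cluster_robust_cov(X, y, codes, res.fe_params,
                                         float(res.scale), tau2)
            return build(res.fe_params, cov_fe, np.sqrt(tau2), np.sqrt(res.scale))
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("mixed fit failed (%s); pooled fallback", err)

    logger.warning("falling back to pooled regression with cluster-robust errors")
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": codes})
    return build(res.params, res.cov_params(), 0.0, np.sqrt(res.scale), pooled=True)


def predict(model: FittedModel, epochs: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Population-level (fixed effects only) prediction with truncation.

    Metric values beyond a concave quadratic's vertex yield the vertex
    value (flat extrapolation); predictions are floored at zero.
    """
    if isinstance(epochs, pd.DataFrame):
        mcol = METRIC_COLUMNS[model.spec.metric]
        if mcol not in epochs.columns:
            raise ValueError(f"epochs lack the model's metric column {mcol!r}")
        m = epochs[mcol].to_numpy(dtype=float)
    else:
        m = np.asarray(epochs, dtype=float)
    if model.spec.form == "quadratic" and model.beta_quadratic < 0:
        v = model.vertex
        if v is not None and v > 0:
            m = np.minimum(m, v)
    pred = model.alpha + model.beta_linear * m + model.beta_quadratic * m**2
    return np.maximum(pred, 0.0)


def vertex_of(model: FittedModel) -> float | None:
    """Closed-form location (mg) of the quadratic's global extremum."""
    return model.vertex


def fit_all_models(epochs: pd.DataFrame, outcome: str = "paee"
                   ) -> dict[int, FittedModel]:
    """Fit models 1–4 for one outcome; returns {model_number: FittedModel}."""
    return {k: fit_mixed_model(epochs, ModelSpec(s.metric, s.form, outcome))
            for k, s in MODEL_SPECS.items()}


def select_best(models: Sequence[FittedModel],
                rmse_paee: Sequence[float],
                rmse_trunk: Sequence[float] | None = None) -> FittedModel:
    """Pick the model minimising RMSE on both outcomes.

    If no single model minimises both, the PAEE RMSE decides; exact ties
    on PAEE RMSE are broken by the trunk-acceleration RMSE.
    """
    models = list(models)
    if not models:
        raise ValueError("no models supplied")
    if len(models) == 1:
        return models[0]
    rmse_paee = np.asarray(rmse_paee, dtype=float)
    i_paee = int(np.argmin(rmse_paee))
    if rmse_trunk is None:
        return models[i_paee]
    rmse_trunk = np.asarray(rmse_trunk, dtype=float)
    i_trunk = int(np.argmin(rmse_trunk))
    if i_paee == i_trunk:
        return models[i_paee]
    ties = np.flatnonzero(rmse_paee == rmse_paee[i_paee])
    if len(ties) > 1:
        return models[int(ties[np.argmin(rmse_trunk[ties])])]
    logger.info("no model minimises both RMSEs; choosing by PAEE RMSE")
    return models[i_paee]


def models_to_frame(models: dict[int, FittedModel]) -> pd.DataFrame:
    """Coefficient table (one row per model) for the plain-text export."""
    rows = []
    for k, mdl in sorted(models.items()):
        rows.append({
            "model": k, "outcome": mdl.spec.outcome, "metric": mdl.spec.metric,
            "form": mdl.spec.form, "alpha": mdl.alpha,
            "beta_linear": mdl.beta_linear, "beta_quadratic": mdl.beta_quadratic,
            "se_alpha": mdl.se_alpha, "se_beta_linear": mdl.se_beta_linear,
            "se_beta_quadratic": mdl.se_beta_quadratic,
            "vertex_mg": mdl.vertex if mdl.vertex is not None else np.nan,
            "random_intercept_sd": mdl.random_intercept_sd,
            "residual_sd": mdl.residual_sd,
            "n_train_participants": mdl.n_train_participants,
            "n_epochs": mdl.n_epochs, "pooled_fallback": mdl.pooled_fallback,
        })
    return pd.DataFrame(rows)


def save_models(models: dict[int, FittedModel], path: str | Path) -> None:
    models_to_frame(models).to_csv(path, index=False)


def load_models(path: str | Path) -> dict[int, FittedModel]:
    frame = pd.read_csv(path)
    out: dict[int, FittedModel] = {}
    for _, r in frame.iterrows():
        spec = ModelSpec(r["metric"], r["form"], r["outcome"])
        out[int(r["model"])] = FittedModel(
            spec=spec, alpha=r["alpha"], beta_linear=r["beta_linear"],
            beta_quadratic=0.0 if np.isnan(r["beta_quadratic"]) else r["beta_quadratic"],
            se_alpha=r["se_alpha"], se_beta_linear=r["se_beta_linear"],
            se_beta_quadratic=r["se_beta_quadratic"],
            random_intercept_sd=r["random_intercept_sd"],
            residual_sd=r["residual_sd"],
            n_train_participants=int(r["n_train_participants"]),
            n_epochs=int(r["n_epochs"]), pooled_fallback=bool(r["pooled_fallback"]))
    return out
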