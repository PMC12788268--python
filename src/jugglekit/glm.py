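"""Gamma-Log and Normal-Identity generalized linear models with inference.

The performance model is a Gamma GLM with log link,

    Perf ~ Gamma(mu, phi),   log(mu) = b0 + b_P Z_P + b_A Z_A + b_S Z_S,

fitted by iteratively reweighted least squares (IRLS).  A Normal-Identity
GLM (ordinary least squares) serves as the comparator.  Inference follows
the usual Wald machinery: for the Gamma family the coefficient covariance
is ``phi * (X'WX)^-1`` with the Pearson dispersion estimate
``phi = sum(((y - mu)/mu)^2) / (n - k)``, and the log-likelihood is
profiled over the shape parameter at the fitted means.  AIC counts the
``k`` regression coefficients only (dispersion treated as profiled out),
the convention under which AIC = -2*loglik + 2k reproduces standard GLM
software output for this model family.

Evaluation utilities cover pooled and day-wise R^2/RMSE/MAE on the
response scale, Cox-Snell pseudo-R^2, leave-one-subject-out
cross-validation, a MAD-based residual summary over the non-outlier
performance range, and the sensitivity-model suite (interactions, Group
and Day fixed effects, participant fixed intercepts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .transforms import MAD_CONSISTENCY

__all__ = [
    "DesignSpec",
    "GLMFit",
    "EvalReport",
    "RankDeficientError",
    "ConvergenceError",
    "build_design",
    "fit_glm",
    "fit_glm_arrays",
    "wald_inference",
    "model_metrics",
    "loso_cv",
    "daywise_metrics",
    "residual_outlier_summary",
    "sensitivity_suite",
]

GAMMA_LOG = "gamma_log"
NORMAL_IDENTITY = "normal_identity"


class RankDeficientError(np.linalg.LinAlgError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """Model design: response, predictors, interactions and fixed factors.

    Factors use treatment (dummy) coding with reference levels Normal-g
    (Group), the smallest day (Day) and the smallest id (Participant).
    """

    response: str = "Perf"
    predictors: tuple = ("Z_P", "Z_A", "Z_S")
    interactions: tuple = ()  # pairs of predictor names
    fixed_factors: tuple = ()  # subset of {"Group", "Day", "Participant"}

    def label(self) -> str:
        parts = list(self.predictors)
        parts += [f"{a}:{b}" for a, b in self.interactions]
        parts += list(self.fixed_factors)
        return " + ".join(parts)


_FACTOR_COLUMN = {"Group": "group", "Day": "day", "Participant": "participant"}
_FACTOR_REFERENCE = {"Group": "Normal-g"}


def build_design(
    data: pd.DataFrame, spec: DesignSpec, check_rank: bool = True
) -> tuple[np.ndarray, np.ndarray, list]:
    """Build (X, y, names) from a day-level table; raises on rank deficiency
    unless ``check_rank`` is off (prediction-only designs)."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names = ["Intercept"]
    for pred in spec.predictors:
        cols.append(data[pred].to_numpy(dtype=float))
        names.append(pred)
    for a, b in spec.interactions:
        cols.append(data[a].to_numpy(dtype=float) * data[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    for factor in spec.fixed_factors:
        col = _FACTOR_COLUMN[factor]
        levels = sorted(data[col].unique(), key=str)
        ref = _FACTOR_REFERENCE.get(factor, levels[0])
        for lev in levels:
            if lev == ref:
                continue
            cols.append((data[col] == lev).to_numpy(dtype=float))
            names.append(f"{factor}[{lev}]")
    X = np.column_stack(cols)
    y = data[spec.response].to_numpy(dtype=float)
    if check_rank and np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficientError(f"design matrix is rank deficient ({spec.label()})")
    return X, y, names


@dataclass
class GLMFit:
    """Fitted GLM with Wald inference and likelihood quantities."""

    family: str
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    dispersion: float  # Pearson phi (Gamma) or sigma^2 = SSE/(n-k) (Normal)
    dispersion_ml: float  # profile-ML phi (Gamma) or SSE/n (Normal)
    loglik: float
    n: int
    k: int  # regression coefficients counted by AIC
    names: list
    converged: bool
    n_iter: int

    @property
    def z(self) -> np.ndarray:
        return self.beta / self.se

    @property
    def p(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def ci95(self) -> np.ndarray:
        half = 1.96 * self.se
        return np.column_stack([self.beta - half, self.beta + half])

    @property
    def exp_beta(self) -> np.ndarray | None:
        return np.exp(self.beta) if self.family == GAMMA_LOG else None

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = np.asarray(X, dtype=float) @ self.beta
        return np.exp(eta) if self.family == GAMMA_LOG else eta


@dataclass
class EvalReport:
    r2: float
    rmse: float
    mae: float
    aic: float
    loglik: float
    pseudo_r2_cs: float
    by_day: pd.DataFrame | None = None
    loso: dict | None = None
    residual_summary: dict | None = None


def _gamma_profile_loglik(y: np.ndarray, mu: np.ndarray) -> tuple[float, float]:
    """Gamma log-likelihood maximized over the shape alpha at fixed means.

    Parameterization: shape alpha = 1/phi, scale mu*phi.  Returns
    (loglik, phi_ml).
    """
    ratio = y / mu

    def nll(log_alpha: float) -> float:
        alpha = np.exp(log_alpha)
        ll = np.sum(
            alpha * np.log(alpha)
            - special.gammaln(alpha)
            - alpha * np.log(mu)
            + (alpha - 1.0) * np.log(y)
            - alpha * ratio
        )
        return -ll

    res = optimize.minimize_scalar(nll, bounds=(-10.0, 12.0), method="bounded")
    alpha = float(np.exp(res.x))
    return -float(res.fun), 1.0 / alpha


def fit_glm_arrays(
    X: np.ndarray,
    y: np.ndarray,
    family: str = GAMMA_LOG,
    names: list | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GLMFit:
    """Fit a GLM by IRLS on prepared arrays.

    Gamma-Log: with the log link the IRLS weights are identically one and
    each step regresses the working response ``eta + (y - mu)/mu`` on X;
    convergence is declared when the relative deviance change drops below
    ``tol``.  Normal-Identity reduces to a single least-squares solve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    if np.linalg.matrix_rank(X) < k:
        raise RankDeficientError("design matrix is rank deficient")

    if family == NORMAL_IDENTITY:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        mu = X @ beta
        sse = float(np.sum((y - mu) ** 2))
        sigma2 = sse / (n - k) if n > k else np.nan
        sigma2_ml = sse / n
        cov = sigma2 * np.linalg.inv(X.T @ X)
        loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2_ml) + 1.0)
        return GLMFit(
            family, beta, np.sqrt(np.diag(cov)), cov, sigma2, sigma2_ml,
            float(loglik), n, k, names, True, 1,
        )

    if family != GAMMA_LOG:
        raise ValueError(f"unknown family {family!r}")
    if np.any(y <= 0):
        raise ValueError("Gamma response must be strictly positive")

    def _deviance(mu_: np.ndarray) -> float:
        return 2.0 * float(np.sum(-np.log(y / mu_) + (y - mu_) / mu_))

    eta = np.clip(np.log(np.clip(y, np.finfo(float).tiny, None)), -300.0, 300.0)
    mu = np.exp(eta)
    converged = False
    it = 0
    beta = np.full(k, np.inf)
    dev = _deviance(mu)
    for it in range(1, max_iter + 1):
        z = eta + (y - mu) / mu
        new_beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        # step-halve when a full IRLS step increases the deviance
        if np.isfinite(beta).all():
            for _ in range(30):
                eta_try = np.clip(X @ new_beta, -300.0, 300.0)
                new_dev = _deviance(np.exp(eta_try))
                if np.isfinite(new_dev) and new_dev <= dev * (1.0 + 1e-12) + 1e-12:
                    break
                new_beta = 0.5 * (new_beta + beta)
        step = np.abs(new_beta - beta).max() if np.isfinite(beta).all() else np.inf
        beta = new_beta
        eta = np.clip(X @ beta, -300.0, 300.0)
        mu = np.exp(eta)
        dev = _deviance(mu)
        if step <= tol * (1.0 + np.abs(beta).max()):
            converged = True
            break
    if not converged:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    pearson = float(np.sum(((y - mu) / mu) ** 2))
    phi = pearson / (n - k) if n > k else np.nan
    cov = phi * np.linalg.inv(X.T @ X)  # W = I under the log link
    loglik, phi_ml = _gamma_profile_loglik(y, mu)
    return GLMFit(
        family, beta, np.sqrt(np.diag(cov)), cov, phi, phi_ml,
        loglik, n, k, names, converged, it,
    )


def fit_glm(spec: DesignSpec, data: pd.DataFrame, family: str = GAMMA_LOG) -> GLMFit:
    """Fit a design on a day-level table (rows with missing values dropped)."""
    needed = [spec.response, *spec.predictors]
    needed += [c for pair in spec.interactions for c in pair]
    needed += [_FACTOR_COLUMN[f] for f in spec.fixed_factors]
    clean = data.dropna(subset=list(dict.fromkeys(needed)))
    X, y, names = build_design(clean, spec)
    return fit_glm_arrays(X, y, family=family, names=names)


def wald_inference(fit: GLMFit) -> pd.DataFrame:
    """Coefficient table: beta, SE, Wald z, p, 95% CI and exp(beta)."""
    if not fit.converged:
        raise ConvergenceError("inference requires a converged fit")
    ci = fit.ci95
    table = pd.DataFrame(
        {
            "beta": fit.beta,
            "se": fit.se,
            "z": fit.z,
            "p": fit.p,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        },
        index=fit.names,
    )
    if fit.family == GAMMA_LOG:
        table["exp_beta"] = fit.exp_beta
    return table


def _response_metrics(y: np.ndarray, mu: np.ndarray) -> tuple[float, float, float]:
    resid = y - mu
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else np.nan
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    return r2, rmse, mae


def model_metrics(fit: GLMFit, spec: DesignSpec, data: pd.DataFrame) -> EvalReport:
    """Pooled fit metrics: likelihood-based and response-scale."""
    clean = data.dropna(subset=[spec.response, *spec.predictors])
    X, y, _ = build_design(clean, spec)
    mu = fit.predict(X)
    r2, rmse, mae = _response_metrics(y, mu)
    null_fit = fit_glm_arrays(np.ones((len(y), 1)), y, family=fit.family)
    pseudo = 1.0 - float(np.exp((2.0 / len(y)) * (null_fit.loglik - fit.loglik)))
    return EvalReport(r2, rmse, mae, fit.aic, fit.loglik, pseudo)


def loso_cv(spec: DesignSpec, data: pd.DataFrame, family: str = GAMMA_LOG) -> dict:
    """Leave-one-subject-out cross-validation on the response scale.

    Each participant's rows are predicted from a model fitted on all other
    participants; held-out predictions are pooled and scored with SST about
    the pooled observed mean.  Folds that fail to converge are dropped with
    a record.
    """
    clean = data.dropna(subset=[spec.response, *spec.predictors]).reset_index(drop=True)
    participants = clean["participant"].unique()
    if len(participants) < 3:
        raise ValueError("LOSO-CV needs at least three participants")
    y_all, mu_all, failed = [], [], []
    for p in participants:
        train = clean[clean["participant"] != p]
        test = clean[clean["participant"] == p]
        try:
            fit = fit_glm(spec, train, family=family)
        except (ConvergenceError, RankDeficientError):
            failed.append(p)
            continue
        X_test, y_test, _ = build_design(test, spec, check_rank=False)
        y_all.append(y_test)
        mu_all.append(fit.predict(X_test))
    y = np.concatenate(y_all)
    mu = np.concatenate(mu_all)
    r2, rmse, mae = _response_metrics(y, mu)
    return {"r2": r2, "rmse": rmse, "mae": mae, "failed_folds": failed}


def daywise_metrics(fit: GLMFit, spec: DesignSpec, data: pd.DataFrame) -> pd.DataFrame:
    """Within-day R^2 and RMSE using the pooled fit's predictions.

    Negative within-day R^2 is reported as 0.000 with a flag, the common
    truncation convention for subsets the pooled model cannot explain.
    """
    clean = data.dropna(subset=[spec.response, *spec.predictors])
    rows = []
    if spec.fixed_factors:
        raise ValueError("day-wise metrics are defined for factor-free designs")
    for day, grp in clean.groupby("day"):
        Xd = np.column_stack(
            [np.ones(len(grp))]
            + [grp[p].to_numpy(dtype=float) for p in spec.predictors]
            + [
                grp[a].to_numpy(dtype=float) * grp[b].to_numpy(dtype=float)
                for a, b in spec.interactions
            ]
        )
        yv = grp[spec.response].to_numpy(dtype=float)
        mu = fit.predict(Xd)
        r2, rmse, _ = _response_metrics(yv, mu)
        floored = bool(np.isnan(r2) or r2 < 0)
        rows.append(
            {"day": day, "r2": 0.0 if floored else r2, "rmse": rmse, "r2_floored": floored}
        )
    return pd.DataFrame(rows)


def residual_outlier_summary(fit: GLMFit, spec: DesignSpec, data: pd.DataFrame) -> dict:
    """Median residual and median |residual| excluding upper-tail outliers.

    The non-outlier range keeps rows with observed Perf at or below
    ``median(Perf) + 3 * 1.4826 * MAD(Perf)``.
    """
    clean = data.dropna(subset=[spec.response, *spec.predictors])
    X, y, _ = build_design(clean, spec)
    mu = fit.predict(X)
    med = float(np.median(y))
    mad = float(np.median(np.abs(y - med)))
    cutoff = med + 3.0 * MAD_CONSISTENCY * mad
    keep = y <= cutoff
    resid = (y - mu)[keep]
    return {
        "cutoff": cutoff,
        "n_excluded": int(np.sum(~keep)),
        "median_residual": float(np.median(resid)),
        "median_abs_residual": float(np.median(np.abs(resid))),
    }


_SENSITIVITY_DESIGNS = [
    ("base", DesignSpec()),
    (
        "base + skill interactions",
        DesignSpec(interactions=(("Z_P", "Z_A"), ("Z_P", "Z_S"), ("Z_A", "Z_S"))),
    ),
    (
        "base + interactions + Group + Day",
        DesignSpec(
            interactions=(("Z_P", "Z_A"), ("Z_P", "Z_S"), ("Z_A", "Z_S")),
            fixed_factors=("Group", "Day"),
        ),
    ),
    (
        # participant intercepts absorb the (between-subject) Group factor
        "base + interactions + Day + subject",
        DesignSpec(
            interactions=(("Z_P", "Z_A"), ("Z_P", "Z_S"), ("Z_A", "Z_S")),
            fixed_factors=("Day", "Participant"),
        ),
    ),
]


def sensitivity_suite(data: pd.DataFrame, full_data: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fit the sensitivity-model ladder and report AIC / R^2 / RMSE per model.

    ``data`` is the complete-case table; when ``full_data`` (the table
    before low-window-day exclusion) is supplied, an extra row refits the
    base model on it with missing Z_S imputed at the standardized median
    (Z_S = 0).  Rank-deficient extended designs are reported as failed
    rows, not fatal errors.
    """
    rows = []

    def _run(name: str, spec: DesignSpec, table: pd.DataFrame) -> None:
        try:
            fit = fit_glm(spec, table, family=GAMMA_LOG)
            report = model_metrics(fit, spec, table)
        except (RankDeficientError, ConvergenceError) as exc:
            rows.append({"model": name, "error": str(exc)})
            return
        coef = dict(zip(fit.names, fit.beta))
        rows.append(
            {
                "model": name,
                "aic": fit.aic,
                "r2": report.r2,
                "rmse": report.rmse,
                "beta_Z_P": coef.get("Z_P", np.nan),
                "beta_Z_A": coef.get("Z_A", np.nan),
                "beta_Z_S": coef.get("Z_S", np.nan),
                "beta_Z_P:Z_S": coef.get("Z_P:Z_S", np.nan),
                "error": "",
            }
        )

    _run(*_SENSITIVITY_DESIGNS[0], data)
    if full_data is not None:
        imputed = full_data.copy()
        imputed["Z_S"] = imputed["Z_S"].fillna(0.0)
        _run("base + full dataset (Z_S imputed)", DesignSpec(), imputed)
    for name, spec in _SENSITIVITY_DESIGNS[1:]:
        _run(name, spec, data)
    return pd.DataFrame(rows)
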