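"""Coefficient estimation from visit-level data.

Every model variant is exactly linear in its coefficients: each term of
the energy balance is coefficient times a known quantity (a radiative
flux, a convection regressor, or the constant evaporative loss). The
module therefore provides two routes to the same optimum:

``fit_linear``
    ordinary least squares through a QR/SVD decomposition -- the exact,
    closed-form reference;
``fit_iterative``
    a Levenberg-Marquardt iteration on the same residuals, stopping when
    the change in reduced chi-square (RSS/df) falls below a tolerance
    (default 1e-9). Because the problem is convex with a unique optimum,
    it must agree with ``fit_linear`` to numerical precision; the pair
    acts as a built-in cross-check.

Fit quality is summarised the way the published tables report it:
SD of residuals (df denominator), SEM of residuals, adjusted R-squared,
per-coefficient SE / t / two-sided P>|t|. The F statistic follows the
uncentered no-intercept ANOVA convention F = ((sum(y^2) - RSS)/k) /
(RSS/df); other software may report other conventions for models
without an intercept.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .budget import (
    VARIANT_COEFFICIENTS,
    CoefficientSet,
    as_visit_frame,
    body_mean_temperature,
    convection_basis,
)
from .constants import DEFAULT_CONSTANTS, ThermalConstants
from .exceptions import CollinearityError, ValidationError
from .geometry import DEFAULT_SURFACE, BodySurface
from .radiation import radiation_budget

logger = logging.getLogger(__name__)

W_TO_MW = 1000.0

#: Relative singular-value cutoff below which the design is treated as
#: rank deficient.
_RANK_RTOL = 1e-10


@dataclass(frozen=True)
class DesignMatrix:
    """Linearized regression problem for one variant.

    Column order is the variant's coefficient schema: the radiative-loss
    flux (for r_l), the negated radiative gain (for r_g), the constant
    evaporative loss (for e_lev), then the convection regressors.
    Response ``y`` is measured energy turnover in W.
    """

    X: np.ndarray
    y: np.ndarray
    columns: tuple[str, ...]
    variant: str
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def df(self) -> int:
        return self.n - self.k


def build_design_matrix(
    data,
    variant: str,
    surface: BodySurface = DEFAULT_SURFACE,
    constants: ThermalConstants = DEFAULT_CONSTANTS,
    T_surround=None,
    include_reflected: bool = False,
) -> DesignMatrix:
    """Assemble the design matrix and response for ``variant``.

    Rows with missing measured M are excluded (count logged and
    recorded). Raises if no usable rows remain.
    """
    frame = as_visit_frame(data)
    if "M_mW" not in frame.columns:
        raise ValidationError("visit data has no M_mW column; cannot fit")
    usable = frame["M_mW"].notna().to_numpy()
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("excluding %d visits with missing M_mW", n_excluded)
    frame = frame.loc[usable]
    if len(frame) == 0:
        raise ValidationError("no visits with measured M_mW")

    T_b = body_mean_temperature(frame)
    if T_surround is None:
        T_surround = frame["T_a_C"].to_numpy(float)
    budget = radiation_budget(
        T_b,
        frame["G_Wm2"].to_numpy(float),
        surface.A_b,
        constants,
        T_surround=T_surround,
        include_reflected=include_reflected,
    )
    conv = convection_basis(frame, variant, surface)
    n = len(frame)
    X = np.column_stack(
        [
            np.asarray(budget.R_loss),
            -np.asarray(budget.R_gain),
            np.full(n, constants.E_ev),
            conv,
        ]
    )
    y = frame["M_mW"].to_numpy(float) / W_TO_MW
    return DesignMatrix(
        X=X,
        y=y,
        columns=VARIANT_COEFFICIENTS[variant],
        variant=variant,
        n_excluded=n_excluded,
    )


class FitStatistics(NamedTuple):
    """Residual summary: SD_res, SEM_res (same units as the residuals),
    adjusted R-squared, F value, residual df."""

    sd_res: float
    sem_res: float
    adj_r2: float
    f_value: float
    df: int


def fit_statistics(residuals, n_coefficients: int, response) -> FitStatistics:
    """Summary statistics from residuals and the observed response.

    SD_res = sqrt(RSS/df) with df = N - k; SEM_res = SD_res/sqrt(N);
    adj R^2 = 1 - (RSS/df)/(TSS/(N-1)) with TSS about the response mean;
    F = ((sum(y^2) - RSS)/k)/(RSS/df) (uncentered, no-intercept ANOVA).
    """
    residuals = np.asarray(residuals, dtype=float)
    response = np.asarray(response, dtype=float)
    n = residuals.size
    df = n - n_coefficients
    if df <= 0:
        raise ValidationError(f"non-positive residual df: N={n}, k={n_coefficients}")
    rss = float(residuals @ residuals)
    sd_res = np.sqrt(rss / df)
    sem_res = sd_res / np.sqrt(n)
    tss = float(np.sum((response - response.mean()) ** 2))
    adj_r2 = 1.0 - (rss / df) / (tss / (n - 1)) if tss > 0 else np.nan
    ess = float(response @ response) - rss
    f_value = (ess / n_coefficients) / (rss / df) if rss > 0 else np.inf
    return FitStatistics(sd_res, sem_res, adj_r2, f_value, df)


@dataclass(frozen=True)
class FitResult:
    """A fitted coefficient set plus the published-style fit summary.

    Residual quantities are stored in W; the ``*_mW`` properties give
    the user-facing milliwatt scale.
    """

    coefficients: CoefficientSet
    se: dict
    t_value: dict
    p_gt_t: dict
    sd_res_W: float
    sem_res_W: float
    adj_r2: float
    f_value: float
    df: int
    n: int
    converged: bool
    n_iterations: int
    reduced_chi2: float
    residuals: np.ndarray
    fitted: np.ndarray
    n_excluded: int = 0

    @property
    def sd_res_mW(self) -> float:
        return self.sd_res_W * W_TO_MW

    @property
    def sem_res_mW(self) -> float:
        return self.sem_res_W * W_TO_MW

    def to_report(self) -> dict:
        """JSON-ready report mirroring the published table layout."""
        names = self.coefficients.names
        return {
            "variant": self.coefficients.variant,
            "coefficients": [
                {
                    "coefficient": k,
                    "value": self.coefficients[k],
                    "se": self.se[k],
                    "t_value": self.t_value[k],
                    "p_gt_t": self.p_gt_t[k],
                }
                for k in names
            ],
            "sd_res_mW": self.sd_res_mW,
            "sem_res_mW": self.sem_res_mW,
            "adj_r2": self.adj_r2,
            "f_value": self.f_value,
            "df": self.df,
            "n": self.n,
            "n_excluded": self.n_excluded,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "reduced_chi2": self.reduced_chi2,
        }


def _check_rank(design: DesignMatrix) -> None:
    """Raise CollinearityError naming the dependent columns if X is
    numerically rank deficient."""
    X = design.X
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    u, s, vt = np.linalg.svd(X / scale, full_matrices=False)
    if s[-1] > _RANK_RTOL * s[0]:
        return
    null = vt[-1]
    involved = [
        name for name, w in zip(design.columns, null) if abs(w) > 1e-3 * np.abs(null).max()
    ]
    raise CollinearityError(involved)


def _finalize(
    design: DesignMatrix,
    beta: np.ndarray,
    converged: bool,
    n_iterations: int,
) -> FitResult:
    X, y = design.X, design.y
    fitted = X @ beta
    residuals = y - fitted
    st = fit_statistics(residuals, design.k, y)
    rss = float(residuals @ residuals)
    xtx_inv = np.linalg.pinv(X.T @ X)
    sigma2 = rss / st.df
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), st.df)
    names = design.columns
    return FitResult(
        coefficients=CoefficientSet.from_array(design.variant, beta),
        se=dict(zip(names, se)),
        t_value=dict(zip(names, t)),
        p_gt_t=dict(zip(names, p)),
        sd_res_W=st.sd_res,
        sem_res_W=st.sem_res,
        adj_r2=st.adj_r2,
        f_value=st.f_value,
        df=st.df,
        n=design.n,
        converged=converged,
        n_iterations=n_iterations,
        reduced_chi2=rss / st.df,
        residuals=residuals,
        fitted=fitted,
        n_excluded=design.n_excluded,
    )


def fit_linear(design: DesignMatrix) -> FitResult:
    """Closed-form ordinary least squares (the exact reference fit)."""
    _check_rank(design)
    beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
    return _finalize(design, beta, converged=True, n_iterations=0)


def fit_iterative(
    design: DesignMatrix,
    init: Sequence[float] | None = None,
    tol: float = 1e-9,
    max_iterations: int = 1000,
) -> FitResult:
    """Levenberg-Marquardt minimisation of the residual sum of squares.

    Damped normal equations with adaptive damping; convergence is
    declared when an accepted step changes reduced chi-square (RSS/df)
    by less than ``tol``. Because the model is linear the Jacobian is
    the design matrix itself and the iteration reaches the unique
    optimum almost immediately; the route exists as an independent
    cross-check of :func:`fit_linear`.
    """
    if tol <= 0:
        raise ValidationError(f"tolerance must be positive, got {tol}")
    _check_rank(design)
    X, y = design.X, design.y
    df = design.df
    beta = np.ones(design.k) if init is None else np.asarray(init, dtype=float)
    if beta.shape != (design.k,):
        raise ValidationError(f"init must have {design.k} entries, got {beta.shape}")

    jtj = X.T @ X
    diag = np.diag(np.diag(jtj))
    lam = 1e-3
    r = y - X @ beta
    red_chi2 = float(r @ r) / df
    converged = False
    n_iter = 0
    while n_iter < max_iterations:
        n_iter += 1
        step = np.linalg.solve(jtj + lam * diag, X.T @ r)
        trial = beta + step
        r_trial = y - X @ trial
        red_trial = float(r_trial @ r_trial) / df
        if red_trial <= red_chi2:
            delta = red_chi2 - red_trial
            beta, r, red_chi2 = trial, r_trial, red_trial
            lam = max(lam / 10.0, 1e-12)
            if delta < tol:
                converged = True
                break
        else:
            lam *= 10.0
    if converged:
        # near the optimum the damping goes to zero; one undamped
        # Gauss-Newton polish step removes the residual damping bias
        polish = beta + np.linalg.solve(jtj, X.T @ r)
        r_polish = y - X @ polish
        if float(r_polish @ r_polish) / df <= red_chi2:
            beta, r = polish, r_polish
    if not converged:
        logger.warning("L-M did not converge within %d iterations", max_iterations)
    return _finalize(design, beta, converged=converged, n_iterations=n_iter)


def compare_variants(
    data,
    variants: Sequence[str],
    surface: BodySurface = DEFAULT_SURFACE,
    constants: ThermalConstants = DEFAULT_CONSTANTS,
    method: str = "linear",
) -> pd.DataFrame:
    """Fit several variants on identical data; side-by-side summary.

    Returns one row per variant with SD_res (mW), adjusted R-squared,
    df, N and convergence info.
    """
    if len(variants) < 2:
        raise ValidationError("compare_variants needs at least two variants")
    fit = {"linear": fit_linear, "iterative": fit_iterative}[method]
    rows = []
    for variant in variants:
        result = fit(build_design_matrix(data, variant, surface, constants))
        rows.append(
            {
                "variant": variant,
                "sd_res_mW": result.sd_res_mW,
                "adj_r2": result.adj_r2,
                "df": result.df,
                "n": result.n,
                "converged": result.converged,
            }
        )
    return pd.DataFrame(rows).set_index("variant")
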