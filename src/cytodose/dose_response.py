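"""Poisson-weighted dose-response curve fitting for cytogenetic yields.

The yield of aberrations per cell is modelled as A = c + alpha*D (linear)
or A = c + alpha*D + beta*D^2 (linear-quadratic), with D the absorbed dose
in Gy.  Aberration counts at each dose point are treated as Poisson with
mean cells * A(D); coefficients are obtained by maximum likelihood via
iteratively reweighted least squares (IRLS) on the yields with weights
cells / fitted_yield — the identity-link Poisson GLM with cell-number
exposure that the standard cytogenetic-dosimetry software implements.
Standard errors come from the inverse Fisher information at the optimum.

The module also provides curve evaluation and inversion (the enabling step
for dose-specific RBE), the chi-squared goodness-of-fit test, and the
two-sample z-test used to compare coefficients between radiation qualities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import ConvergenceError, DomainError

__all__ = [
    "DoseResponsePoint",
    "DoseResponseCurve",
    "FitDiagnostics",
    "fit_dose_response",
    "evaluate_curve",
    "invert_curve",
    "z_compare",
    "chi2_goodness_of_fit",
    "poisson_deviance",
]

_MODELS = ("linear", "linear_quadratic")
#: floor applied to fitted mean yields so IRLS weights stay finite
_MEAN_FLOOR = 1e-9
_MAX_ITER = 100
_REL_TOL = 1e-8


@dataclass
class DoseResponsePoint:
    """One dose point: scored cells, aberration total and dose in Gy."""

    dose_Gy: float
    cells: int
    aberrations: int

    def __post_init__(self):
        if self.dose_Gy < 0:
            raise ValueError("dose must be non-negative")
        if self.cells <= 0:
            raise ValueError("cells must be positive")
        if self.aberrations < 0:
            raise ValueError("aberration count must be non-negative")

    @property
    def yield_per_cell(self) -> float:
        return self.aberrations / self.cells


@dataclass
class DoseResponseCurve:
    """Fitted (or published) yield curve A = c + alpha*D (+ beta*D^2)."""

    model: str
    c: float
    alpha: float
    beta: Optional[float] = None
    se_c: float = 0.0
    se_alpha: float = 0.0
    se_beta: Optional[float] = None
    cov: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self):
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.model == "linear_quadratic" and self.beta is None:
            raise ValueError("linear_quadratic model requires beta")
        if self.model == "linear" and self.beta is not None:
            raise ValueError("linear model must not carry beta")
        for se in (self.se_c, self.se_alpha, self.se_beta):
            if se is not None and se < 0:
                raise ValueError("standard errors must be non-negative")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            p = self.n_params
            if self.cov.shape != (p, p):
                raise ValueError(f"covariance must be {p}x{p}")
            if not np.allclose(self.cov, self.cov.T, atol=1e-10):
                raise ValueError("covariance must be symmetric")

    @property
    def n_params(self) -> int:
        return 2 if self.model == "linear" else 3

    @property
    def coefficients(self) -> np.ndarray:
        if self.model == "linear":
            return np.array([self.c, self.alpha])
        return np.array([self.c, self.alpha, self.beta])

    def covariance(self) -> np.ndarray:
        """Coefficient covariance; built from SEs (independence) if absent."""
        if self.cov is not None:
            return self.cov
        ses = [self.se_c, self.se_alpha] + (
            [self.se_beta or 0.0] if self.model == "linear_quadratic" else []
        )
        return np.diag(np.square(ses))


@dataclass
class FitDiagnostics:
    """Goodness-of-fit and coefficient-significance summary."""

    chi2: float
    dof: int
    p_value: float
    r_squared: float
    alpha_p: float
    beta_p: Optional[float] = None
    computable: bool = field(default=True)


def _design_matrix(doses: np.ndarray, model: str) -> np.ndarray:
    cols = [np.ones_like(doses), doses]
    if model == "linear_quadratic":
        cols.append(doses ** 2)
    return np.column_stack(cols)


def poisson_deviance(points: Sequence[DoseResponsePoint], coefs: np.ndarray,
                     model: str) -> float:
    """Poisson deviance of aberration counts against mean cells*A(D)."""
    doses = np.array([p.dose_Gy for p in points])
    cells = np.array([p.cells for p in points], dtype=float)
    counts = np.array([p.aberrations for p in points], dtype=float)
    mu = cells * np.maximum(_design_matrix(doses, model) @ coefs, _MEAN_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(counts > 0, counts * np.log(counts / mu), 0.0)
    return 2.0 * float(np.sum(term - (counts - mu)))


def fit_dose_response(points: Sequence[DoseResponsePoint], model: str = "linear",
                      label: str = "") -> tuple[DoseResponseCurve, FitDiagnostics]:
    """Maximum-likelihood fit of the yield curve by IRLS.

    Starts from ordinary least squares on the yields, then iterates
    weighted least squares with weights cells / max(fitted_yield, floor)
    until the maximum relative coefficient change drops below 1e-8
    (cap 100 iterations).  Steps that drive any fitted data-point mean
    negative are halved (up to 30 halvings) before failing.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}")
    p = 2 if model == "linear" else 3
    if len(points) < p:
        raise ValueError(f"{model} fit needs at least {p} dose points")

    doses = np.array([pt.dose_Gy for pt in points], dtype=float)
    cells = np.array([pt.cells for pt in points], dtype=float)
    yields = np.array([pt.yield_per_cell for pt in points], dtype=float)
    X = _design_matrix(doses, model)

    beta_hat, *_ = np.linalg.lstsq(X, yields, rcond=None)
    if np.any(X @ beta_hat <= 0.0):
        # OLS start infeasible (negative fitted yield, typically at the
        # background point): fall back to a non-negative LS start with a
        # small positive intercept so every fitted mean is positive
        beta_hat, _res = optimize.nnls(X, yields)
        beta_hat[0] = max(beta_hat[0], _MEAN_FLOOR * 10)
    for _iter in range(_MAX_ITER):
        mu = np.maximum(X @ beta_hat, _MEAN_FLOOR)
        w = cells / mu
        XtW = X.T * w
        try:
            beta_new = np.linalg.solve(XtW @ X, XtW @ yields)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular weighted normal equations: {exc}", beta_hat
            ) from exc
        # damp steps that push fitted means negative at the data points
        step = beta_new - beta_hat
        halvings = 0
        while np.any(X @ (beta_hat + step) <= 0.0) and halvings < 30:
            step *= 0.5
            halvings += 1
        if halvings == 30:
            raise ConvergenceError(
                "persistent negative fitted means during IRLS", beta_hat
            )
        beta_new = beta_hat + step
        # mixed criterion: relative per coefficient, with an absolute floor
        # so a coefficient converging to the zero boundary (e.g. c for a
        # background-free dataset) still terminates
        converged = np.all(
            np.abs(step) <= np.maximum(_REL_TOL * np.abs(beta_new), 1e-12)
        )
        beta_hat = beta_new
        if converged:
            break
    else:
        raise ConvergenceError(
            f"IRLS did not converge in {_MAX_ITER} iterations", beta_hat
        )

    mu = np.maximum(X @ beta_hat, _MEAN_FLOOR)
    info = (X.T * (cells / mu)) @ X
    cov = np.linalg.inv(info)
    ses = np.sqrt(np.diag(cov))

    curve = DoseResponseCurve(
        model=model,
        c=float(beta_hat[0]),
        alpha=float(beta_hat[1]),
        beta=float(beta_hat[2]) if p == 3 else None,
        se_c=float(ses[0]),
        se_alpha=float(ses[1]),
        se_beta=float(ses[2]) if p == 3 else None,
        cov=cov,
        label=label,
    )
    diagnostics = _diagnostics(points, curve)
    return curve, diagnostics


def _diagnostics(points: Sequence[DoseResponsePoint],
                 curve: DoseResponseCurve) -> FitDiagnostics:
    chi2, dof, p_value = chi2_goodness_of_fit(points, curve)
    yields = np.array([pt.yield_per_cell for pt in points])
    fitted = np.array([evaluate_curve(curve, pt.dose_Gy) for pt in points])
    if np.ptp(yields) > 0 and np.ptp(fitted) > 0:
        r = float(np.corrcoef(yields, fitted)[0, 1])
        r2 = r * r
    else:
        r2 = float("nan")
    alpha_p = _coef_p(curve.alpha, curve.se_alpha)
    beta_p = (
        _coef_p(curve.beta, curve.se_beta)
        if curve.model == "linear_quadratic" else None
    )
    return FitDiagnostics(
        chi2=chi2, dof=dof, p_value=p_value, r_squared=r2,
        alpha_p=alpha_p, beta_p=beta_p, computable=dof > 0,
    )


def _coef_p(value: float, se: float) -> float:
    if se <= 0:
        return float("nan")
    return 2.0 * stats.norm.sf(abs(value) / se)


def evaluate_curve(curve: DoseResponseCurve, dose_Gy: float):
    """Yield per cell at a dose: c + alpha*D (+ beta*D^2)."""
    d = np.asarray(dose_Gy, dtype=float)
    out = curve.c + curve.alpha * d
    if curve.model == "linear_quadratic":
        out = out + curve.beta * d * d
    return out if out.ndim else float(out)


def invert_curve(curve: DoseResponseCurve, yield_per_cell: float) -> float:
    """Dose (Gy) producing a given yield: the inverse of evaluate_curve.

    Linear: D = (A - c)/alpha.  Linear-quadratic: the positive root
    D = (-alpha + sqrt(alpha^2 + 4 beta (A - c))) / (2 beta).
    """
    excess = yield_per_cell - curve.c
    if excess < 0:
        raise DomainError(
            f"yield {yield_per_cell} below curve background c={curve.c}"
        )
    if excess == 0:
        return 0.0
    if curve.model == "linear":
        if curve.alpha <= 0:
            raise DomainError("no solution: alpha <= 0 for linear curve")
        return excess / curve.alpha
    beta = curve.beta
    if beta == 0.0:
        if curve.alpha <= 0:
            raise DomainError("no solution: alpha <= 0 with beta = 0")
        return excess / curve.alpha
    disc = curve.alpha ** 2 + 4.0 * beta * excess
    if disc < 0 or (curve.alpha <= 0 and beta <= 0):
        raise DomainError("no positive-dose solution for the requested yield")
    return (-curve.alpha + math.sqrt(disc)) / (2.0 * beta)


def z_compare(a1: float, se1: float, a2: float, se2: float) -> tuple[float, float]:
    """Two-sample z-test for equality of two independent estimates.

    Returns (|z|, two-sided p) with z = |a1 - a2| / sqrt(se1^2 + se2^2).
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("z-test requires positive standard errors")
    z = abs(a1 - a2) / math.hypot(se1, se2)
    return z, 2.0 * stats.norm.sf(z)


def chi2_goodness_of_fit(points: Sequence[DoseResponsePoint],
                         curve: DoseResponseCurve) -> tuple[float, int, float]:
    """Pearson chi-squared against the fitted curve.

    chi2 = sum cells_i * (yield_i - fitted_i)^2 / fitted_i with
    dof = points - parameters; p is the upper tail.  With dof <= 0 the
    p-value is NaN (flagged not-computable by the caller).
    """
    fitted = np.array([evaluate_curve(curve, pt.dose_Gy) for pt in points])
    if np.any(fitted <= 0):
        raise DomainError("chi-squared requires positive fitted means")
    cells = np.array([pt.cells for pt in points], dtype=float)
    yields = np.array([pt.yield_per_cell for pt in points])
    chi2 = float(np.sum(cells * (yields - fitted) ** 2 / fitted))
    dof = len(points) - curve.n_params
    p = float(stats.chi2.sf(chi2, dof)) if dof > 0 else float("nan")
    return chi2, dof, p


def points_from_distributions(dists: Iterable) -> list[DoseResponsePoint]:
    """Convert aberration distributions (doses in mGy) to fit points in Gy."""
    pts = []
    for d in dists:
        k = np.arange(d.counts.size)
        pts.append(DoseResponsePoint(
            dose_Gy=d.dose_total_mGy / 1000.0,
            cells=d.cells,
            aberrations=int(np.dot(k, d.counts)),
        ))
    return pts
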