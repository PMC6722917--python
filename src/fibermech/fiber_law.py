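"""Single-fiber logarithmic constitutive law.

Electrospun nanofibers tested in uniaxial tension are well described by the
empirical law

    sigma(eps) = a - b * ln(eps + c)        [sigma in MPa, eps dimensionless]

with fitted parameters ``a`` (stress scale, MPa), ``b`` (stress slope, MPa,
negative for strain-hardening fibers) and ``c`` (strain offset, > 0, keeps
the logarithm defined at zero strain). Because the raw law is negative at
very small strain for typical fits, evaluation clamps negative values to
zero by default: a fiber carries no tensile force until the law turns
positive. The raw (unclamped) law remains available via ``clamp=False`` and
is what the coefficient of determination is computed against.

The "harmonic stress" variant rescales the law by (1 + d/D)/2, where ``d``
is an individual fiber's diameter and ``D`` the harmonic mean diameter of
the mat, correcting single-fiber test data for diameter dispersion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FiberLawParams",
    "StressStrainCurve",
    "FitError",
    "evaluate_fiber_stress",
    "harmonic_stress",
    "fit_fiber_law",
    "r_squared",
    "FiberLawRegressor",
]


class FitError(RuntimeError):
    """Raised when the constitutive fit is impossible or does not converge."""


@dataclass(frozen=True)
class FiberLawParams:
    """Fitted parameters of sigma = a - b*ln(eps + c).

    ``b`` is stored exactly as fitted/printed (negative for hardening
    fibers); it is never re-signed.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            val = getattr(self, name)
            if not (isinstance(val, (int, float)) and math.isfinite(val)):
                raise ValueError(f"parameter {name!r} must be a finite number, got {val!r}")
        if self.c <= 0:
            raise ValueError(f"strain offset c must be > 0 (got {self.c}); "
                             "the logarithm must stay defined at zero strain")


@dataclass(frozen=True)
class StressStrainCurve:
    """A sampled stress-strain curve (strain dimensionless, stress MPa).

    Strain must be non-negative, finite and non-decreasing; stress finite
    and the same length. Fitting and file input additionally require a
    strictly increasing strain grid (see :func:`require_strict_strain`).
    """

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        strain = np.atleast_1d(np.asarray(self.strain, dtype=float))
        stress = np.atleast_1d(np.asarray(self.stress, dtype=float))
        if strain.ndim != 1 or stress.ndim != 1:
            raise ValueError("strain and stress must be one-dimensional")
        if strain.shape != stress.shape:
            raise ValueError(
                f"strain and stress lengths differ: {strain.size} vs {stress.size}")
        if strain.size == 0:
            raise ValueError("curve must contain at least one point")
        if not (np.all(np.isfinite(strain)) and np.all(np.isfinite(stress))):
            raise ValueError("curve contains non-finite entries")
        if np.any(strain < 0):
            raise ValueError("strain values must be non-negative")
        if np.any(np.diff(strain) < 0):
            raise ValueError("strain grid must be non-decreasing")
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)

    def __len__(self) -> int:
        return int(self.strain.size)


def require_strict_strain(curve: StressStrainCurve) -> StressStrainCurve:
    """Reject curves with duplicated strain values."""
    if np.any(np.diff(curve.strain) <= 0):
        raise ValueError("strain grid must be strictly increasing (duplicate values found)")
    return curve


def _validate_strain(params: FiberLawParams, strain) -> np.ndarray:
    eps = np.asarray(strain, dtype=float)
    if not np.all(np.isfinite(eps)):
        raise ValueError("strain must be finite")
    if np.any(eps < 0):
        raise ValueError("strain must be non-negative")
    if np.any(eps + params.c <= 0):
        raise ValueError("strain + c must be positive for the logarithm to be defined")
    return eps


def evaluate_fiber_stress(params: FiberLawParams, strain, *, clamp: bool = True):
    """Evaluate the fiber law sigma = a - b*ln(eps + c) in MPa.

    With ``clamp=True`` (default) negative law values are set to zero:
    fibers carry no negative tensile stress. Accepts scalars or arrays.
    """
    eps = _validate_strain(params, strain)
    raw = params.a - params.b * np.log(eps + params.c)
    out = np.maximum(raw, 0.0) if clamp else raw
    return float(out) if np.isscalar(strain) or np.ndim(strain) == 0 else out


def harmonic_stress(params: FiberLawParams, strain, d: float, D: float, *,
                    clamp: bool = True):
    """Diameter-corrected fiber stress: (1 + d/D)/2 * sigma(eps).

    ``d`` is the diameter of the fiber being evaluated and ``D`` the
    harmonic mean diameter of the mat (both nm, both > 0). The clamp is
    applied to the bracketed law before scaling, so the correction factor
    never resurrects a negative stress.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        raise ValueError(f"fiber diameter d must be positive and finite")
    if not (isinstance(D, (int, float)) and math.isfinite(D) and D > 0):
        raise ValueError(f"harmonic mean diameter D must be positive and finite, got {D!r}")
    factor = 0.5 * (1.0 + d / D)
    return factor * evaluate_fiber_stress(params, strain, clamp=clamp)


def r_squared(curve: StressStrainCurve, params: FiberLawParams) -> float:
    """Coefficient of determination of the *unclamped* law on the curve.

    R^2 = 1 - SS_res / SS_tot, in (-inf, 1]. Raises on a zero-variance
    stress column, where R^2 is undefined.
    """
    predicted = evaluate_fiber_stress(params, curve.strain, clamp=False)
    ss_res = float(np.sum((curve.stress - predicted) ** 2))
    ss_tot = float(np.sum((curve.stress - np.mean(curve.stress)) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: stress column has zero variance")
    return 1.0 - ss_res / ss_tot


_DEFAULT_C0 = 1e-3
_C_LOWER_BOUND = 1e-8


def _default_initial_guess(curve: StressStrainCurve) -> tuple[float, float, float]:
    # a ~ max stress; b from the stress span over the log-strain span at the
    # default offset c0 (well-defined for any strictly increasing grid).
    c0 = _DEFAULT_C0
    smin, smax = float(curve.strain[0]), float(curve.strain[-1])
    span = float(np.max(curve.stress) - np.min(curve.stress))
    log_span = math.log((smax + c0) / (smin + c0))
    b0 = -span / log_span if log_span > 0 else -1.0
    return float(np.max(curve.stress)), b0, c0


def fit_fiber_law(
    curve: StressStrainCurve,
    initial_guess: FiberLawParams | None = None,
) -> tuple[FiberLawParams, float]:
    """Least-squares fit of (a, b, c) in sigma = a - b*ln(eps + c).

    Uses a trust-region-reflective solver with analytic Jacobian and the
    offset bounded below (c >= 1e-8) to keep the logarithm defined and the
    Jacobian conditioned. Deterministic for a given curve and initial guess.

    Returns the fitted parameters and R^2 on the input points. Raises
    :class:`FitError` for degenerate curves (fewer than 4 distinct strain
    points, constant stress) or non-convergence.
    """
    require_strict_strain(curve)
    if len(np.unique(curve.strain)) < 4:
        raise FitError("need at least 4 distinct strain points to fit 3 parameters")
    if float(np.ptp(curve.stress)) == 0.0:
        raise FitError("cannot fit a constant-stress curve (zero stress variance)")

    eps, sigma = curve.strain, curve.stress
    if initial_guess is not None:
        x0 = (initial_guess.a, initial_guess.b, max(initial_guess.c, _C_LOWER_BOUND))
    else:
        x0 = _default_initial_guess(curve)

    def residual(x):
        a, b, c = x
        return a - b * np.log(eps + c) - sigma

    def jacobian(x):
        a, b, c = x
        return np.column_stack([
            np.ones_like(eps),
            -np.log(eps + c),
            -b / (eps + c),
        ])

    result = least_squares(
        residual,
        x0=x0,
        jac=jacobian,
        bounds=([-np.inf, -np.inf, _C_LOWER_BOUND], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=10_000,
    )
    if not result.success:
        raise FitError(f"constitutive fit did not converge: {result.message}")
    params = FiberLawParams(*map(float, result.x))
    return params, r_squared(curve, params)


class FiberLawRegressor(RegressorMixin, BaseEstimator):
    """Scikit-learn style regressor for the logarithmic fiber law.

    ``fit(X, y)`` takes strain as a single-column feature matrix (or 1-d
    array) and stress in MPa as the target; ``predict`` evaluates the fitted
    law (clamped by default).

    Parameters
    ----------
    clamp : bool, default True
        Clamp negative predicted stresses to zero.
    initial_guess : FiberLawParams or None
        Starting point for the solver; a data-driven default otherwise.

    Attributes
    ----------
    a_, b_, c_ : float
        Fitted law parameters.
    params_ : FiberLawParams
    r_squared_ : float
        Coefficient of determination of the unclamped law on the training
        points.
    """

    def __init__(self, clamp: bool = True,
                 initial_guess: FiberLawParams | None = None):
        self.clamp = clamp
        self.initial_guess = initial_guess

    @staticmethod
    def _as_strain(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError(f"expected a single strain feature, got shape {X.shape}")
            X = X[:, 0]
        elif X.ndim != 1:
            raise ValueError("X must be 1-d strain values or an (n, 1) matrix")
        return X

    def fit(self, X, y):
        strain = self._as_strain(X)
        stress = np.asarray(y, dtype=float)
        order = np.argsort(strain, kind="stable")
        curve = StressStrainCurve(strain[order], stress[order])
        self.params_, self.r_squared_ = fit_fiber_law(curve, self.initial_guess)
        self.a_, self.b_, self.c_ = self.params_.a, self.params_.b, self.params_.c
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise AttributeError("this FiberLawRegressor instance is not fitted yet")
        strain = self._as_strain(X)
        return evaluate_fiber_stress(self.params_, strain, clamp=self.clamp)
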