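"""Discrete-fiber Monte-Carlo simulator and synthetic-data generators.

The simulator realizes the membrane as an explicit sample of fibers —
orientation uniform on [0, pi/2], diameters lognormal — and evaluates the
axial force of every fiber at every membrane strain (reorientation, fiber
strain, clamped diameter-corrected law, sin-projection), summing literally
instead of integrating. Scaled to the unit-cell fiber count, its expectation
is the analytic orientation integral, so it serves as an independent oracle
for the membrane model: agreement within Monte-Carlo error validates the
quadrature and the kinematics chain without sharing any code path with the
integral.

Unlike the analytic model (which evaluates the force at d = D), the
simulator applies each fiber's own diameter both in the d^2 force term and
in the (1 + d/D)/2 correction; for dispersed diameters the two therefore
differ systematically, and the comparison isolates that modeling choice.
With all diameters equal to D they agree in expectation exactly.

The generators also make noisy single-fiber test curves and diameter
samples at the scale of electrospun SF/PCL mats, so every pipeline stage is
testable without laboratory data. All randomness flows through explicit
integer seeds; regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fibermech.fiber_law import FiberLawParams, StressStrainCurve, evaluate_fiber_stress
from fibermech.geometry import DiameterSample, MembraneSpec, fiber_count
from fibermech.kinematics import DeformationState, fiber_axial_strain, reorient_angle
from fibermech.membrane import _clamped_law

__all__ = [
    "DiscreteFiberNetwork",
    "build_network",
    "simulate_tension",
    "generate_synthetic_fiber_curve",
    "generate_diameter_sample",
]

_HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class DiscreteFiberNetwork:
    """An explicit sample of fibers: orientations (rad) and diameters (nm)."""

    theta: np.ndarray
    diameters: np.ndarray
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        th = np.atleast_1d(np.asarray(self.theta, dtype=float))
        d = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        if th.shape != d.shape or th.ndim != 1:
            raise ValueError("theta and diameters must be 1-d arrays of equal length")
        if th.size == 0:
            raise ValueError("network must contain at least one fiber")
        if np.any(th < 0) or np.any(th > _HALF_PI) or not np.all(np.isfinite(th)):
            raise ValueError("all orientations must lie in [0, pi/2]")
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise ValueError("all diameters must be positive and finite")
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "diameters", d)

    def __len__(self) -> int:
        return int(self.theta.size)


def build_network(n_fibers: int, mu_ln: float, sigma_ln: float,
                  seed: int) -> DiscreteFiberNetwork:
    """Sample a random network: theta ~ U[0, pi/2], d ~ lognormal(mu, sigma).

    ``mu_ln`` and ``sigma_ln`` parameterize ln(d/nm); ``sigma_ln = 0``
    degenerates to all diameters equal to exp(mu_ln). Bit-reproducible for a
    given seed.
    """
    if n_fibers < 1:
        raise ValueError("n_fibers must be >= 1")
    if not (math.isfinite(mu_ln) and math.isfinite(sigma_ln)) or sigma_ln < 0:
        raise ValueError("invalid lognormal parameters: need finite mu_ln and sigma_ln >= 0")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, _HALF_PI, size=n_fibers)
    diameters = np.exp(rng.normal(mu_ln, sigma_ln, size=n_fibers)) if sigma_ln > 0 \
        else np.full(n_fibers, math.exp(mu_ln))
    return DiscreteFiberNetwork(
        theta=theta, diameters=diameters, seed=seed,
        provenance={"n_fibers": int(n_fibers), "mu_ln": float(mu_ln),
                    "sigma_ln": float(sigma_ln), "orientation": "uniform[0, pi/2]"})


def simulate_tension(network: DiscreteFiberNetwork, spec: MembraneSpec,
                     params: FiberLawParams, strain_grid, *,
                     convention: str = "literal-eq2", clamp: bool = True,
                     return_se: bool = False):
    """Membrane stress-strain of a discrete network under uniaxial tension.

    For each grid strain the per-fiber chain theta -> theta' -> eps_f ->
    clamped law -> (1 + d_i/D)/2 correction -> (pi/4) d_i^2 sigma sin(theta')
    is evaluated with each fiber's own diameter, and the sum is rescaled to
    the unit-cell fiber count n from the porosity relation:

        stress(eps) = (n / N) * sum_i f_y,i(eps) / A.

    With ``return_se=True`` also returns the per-point standard error of the
    Monte-Carlo mean (same stress units), zero only where no fiber is loaded.
    """
    grid = np.atleast_1d(np.asarray(strain_grid, dtype=float))
    if grid.size == 0 or np.any(grid < 0) or np.any(np.diff(grid) < 0):
        raise ValueError("strain grid must be non-empty, non-negative and non-decreasing")
    D = spec.harmonic_d_nm
    n_model = fiber_count(spec)
    N = len(network)
    d = network.diameters
    corr = 0.5 * (1.0 + d / D)
    area_term = (math.pi / 4.0) * d ** 2

    stress = np.empty(grid.size)
    se = np.empty(grid.size)
    for i, eps in enumerate(grid):
        state = DeformationState(strain=float(eps), shrinkage_v=spec.shrinkage_v,
                                 convention=convention)
        tp = reorient_angle(network.theta, state)
        ef = fiber_axial_strain(network.theta, state)
        sigma_bar = corr * _clamped_law(params, ef, clamp=clamp)
        fy = area_term * sigma_bar * np.sin(tp)
        stress[i] = n_model * np.mean(fy) / spec.area_nm2
        sd = np.std(fy, ddof=1) if N > 1 else 0.0
        se[i] = n_model * sd / math.sqrt(N) / spec.area_nm2

    curve = StressStrainCurve(grid, stress)
    return (curve, se) if return_se else curve


def generate_synthetic_fiber_curve(params: FiberLawParams, noise_sd: float,
                                   n_points: int, strain_range: tuple[float, float],
                                   seed: int) -> StressStrainCurve:
    """Noisy single-fiber test curve: clamped law + i.i.d. Gaussian noise.

    Emulates a nano-tensile measurement of one fiber on a uniform strain
    grid over ``strain_range``. ``noise_sd`` is in MPa; zero gives the exact
    law values.
    """
    if n_points < 4:
        raise ValueError("n_points must be >= 4")
    lo, hi = strain_range
    if not (math.isfinite(lo) and math.isfinite(hi)) or lo < 0 or hi <= lo:
        raise ValueError(f"invalid strain range {strain_range!r}")
    if lo + params.c <= 0:
        raise ValueError("strain range outside the law's domain (strain + c <= 0)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    strain = np.linspace(lo, hi, n_points)
    stress = evaluate_fiber_stress(params, strain, clamp=True)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, size=n_points)
    return StressStrainCurve(strain, stress)


def generate_diameter_sample(mu_ln: float, sigma_ln: float, n: int,
                             seed: int) -> DiameterSample:
    """Lognormal fiber-diameter sample (nm), emulating SEM measurements.

    Lognormal is the natural choice for electrospun mats: positive support
    and right skew. ``sigma_ln = 0`` gives a degenerate sample where the
    arithmetic, RMS and harmonic means coincide.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (math.isfinite(mu_ln) and math.isfinite(sigma_ln)) or sigma_ln < 0:
        raise ValueError("invalid lognormal parameters")
    rng = np.random.default_rng(seed)
    d = np.exp(rng.normal(mu_ln, sigma_ln, size=n)) if sigma_ln > 0 \
        else np.full(n, math.exp(mu_ln))
    return DiameterSample(d)
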