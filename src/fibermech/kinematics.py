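"""Affine reorientation kinematics of the fiber network.

A unit circle of fibers through a common intersection deforms affinely into
an ellipse under uniaxial stretch along y: the in-plane map is the diagonal
stretch diag(lambda_x, lambda_y) with lambda_y = 1 + eps. A fiber initially
inclined at theta (measured from the transverse x axis, in [0, pi/2] by the
layup symmetry) rotates to

    theta' = arctan( lambda_y * sin(theta) / (lambda_x * cos(theta)) )

and its half-length scales as r' = r0 * sqrt(lambda_x^2 cos^2 theta +
lambda_y^2 sin^2 theta), giving the fiber axial strain eps_f = r'/r0 - 1.

The transverse factor lambda_x is set by the shrinkage coefficient v of the
membrane under one of two conventions:

* ``literal-eq2``: lambda_x = v — v acts directly as a constant transverse
  scale factor (the form the reorientation formula is usually printed in);
* ``strain-ratio``: lambda_x = 1 + v * eps — v read as a ratio of transverse
  to axial strain.

``literal-eq2`` is the default; both are kept because the choice changes the
numbers and the literature is ambiguous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CONVENTIONS",
    "DeformationState",
    "FiberState",
    "reorient_angle",
    "deformed_half_length",
    "fiber_axial_strain",
    "projection_strain",
]

CONVENTIONS = ("literal-eq2", "strain-ratio")
_HALF_PI = math.pi / 2.0


@dataclass(frozen=True)
class DeformationState:
    """Membrane strain, shrinkage coefficient and the lambda_x convention."""

    strain: float
    shrinkage_v: float
    convention: str = "literal-eq2"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.strain) and self.strain >= 0):
            raise ValueError(f"membrane strain must be finite and >= 0, got {self.strain!r}")
        if not (math.isfinite(self.shrinkage_v) and self.shrinkage_v > 0):
            raise ValueError(f"shrinkage coefficient must be > 0, got {self.shrinkage_v!r}")
        if self.convention not in CONVENTIONS:
            raise ValueError(
                f"unknown convention {self.convention!r}; expected one of {CONVENTIONS}")
        if self.lambda_x <= 0:
            raise ValueError("transverse scale factor lambda_x must be positive")

    @property
    def lambda_y(self) -> float:
        """Axial stretch 1 + eps."""
        return 1.0 + self.strain

    @property
    def lambda_x(self) -> float:
        """Transverse scale factor under the configured convention."""
        if self.convention == "literal-eq2":
            return self.shrinkage_v
        return 1.0 + self.shrinkage_v * self.strain


@dataclass(frozen=True)
class FiberState:
    """Full kinematic/force record of one fiber at one membrane strain."""

    theta: float            # initial inclination (rad)
    theta_prime: float      # deformed inclination (rad)
    r_prime: float          # deformed half-length
    fiber_strain: float     # axial strain eps_f (may be negative: compression)
    axial_stress: float     # sigma_f (MPa), clamped law
    harmonic_stress: float  # diameter-corrected sigma_f-bar (MPa)
    force_y: float          # axial force contribution (MPa * nm^2)


def _validate_theta(theta) -> np.ndarray:
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("theta must be finite")
    if np.any(th < 0) or np.any(th > _HALF_PI):
        raise ValueError("theta must lie in [0, pi/2]")
    return th


def _maybe_scalar(value, template):
    return float(value) if np.ndim(template) == 0 else value


def reorient_angle(theta, state: DeformationState):
    """Deformed inclination theta' in [0, pi/2].

    arctan2 handles the transverse limit theta = pi/2 exactly (cos -> 0
    gives theta' = pi/2). Strictly increasing in theta, and >= theta whenever
    lambda_y >= lambda_x (fibers rotate toward the stretch axis).
    """
    th = _validate_theta(theta)
    tp = np.arctan2(state.lambda_y * np.sin(th), state.lambda_x * np.cos(th))
    return _maybe_scalar(tp, theta)


def deformed_half_length(theta, r0: float, state: DeformationState):
    """Deformed fiber half-length r' = r0*sqrt(lx^2 cos^2 + ly^2 sin^2)."""
    th = _validate_theta(theta)
    if not (math.isfinite(r0) and r0 > 0):
        raise ValueError(f"r0 must be positive, got {r0!r}")
    rp = r0 * np.sqrt((state.lambda_x * np.cos(th)) ** 2
                      + (state.lambda_y * np.sin(th)) ** 2)
    return _maybe_scalar(rp, theta)


def fiber_axial_strain(theta, state: DeformationState):
    """Fiber axial strain eps_f = r'/r0 - 1.

    Negative for fibers near the transverse axis when the membrane shrinks
    sideways (lambda_x < 1): those fibers are in compression.
    """
    th = _validate_theta(theta)
    ef = np.sqrt((state.lambda_x * np.cos(th)) ** 2
                 + (state.lambda_y * np.sin(th)) ** 2) - 1.0
    return _maybe_scalar(ef, theta)


def projection_strain(theta, r0: float, state: DeformationState, *,
                      denominator: str = "reference"):
    """Axial-projection strain of a fiber: change of its y-projection.

    With ``denominator="reference"`` (default) the strain is measured
    against the undeformed projection r0*sin(theta); under the affine map
    this equals the membrane strain eps identically (r' sin(theta') =
    r0 * lambda_y * sin(theta)). ``denominator="deformed"`` divides by the
    deformed projection r' sin(theta') instead, yielding eps/(1+eps); it is
    retained because the membrane-strain relation is sometimes printed in
    that form. Undefined at theta = 0 (zero projection).
    """
    th = _validate_theta(theta)
    if np.any(th == 0):
        raise ValueError("projection strain undefined at theta = 0 (zero projection)")
    if denominator not in ("reference", "deformed"):
        raise ValueError(f"denominator must be 'reference' or 'deformed', got {denominator!r}")
    rp = deformed_half_length(th, r0, state)
    tp = reorient_angle(th, state)
    ref = r0 * np.sin(th)
    deformed = rp * np.sin(tp)
    denom = ref if denominator == "reference" else deformed
    out = (deformed - ref) / denom
    return _maybe_scalar(out, theta)
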