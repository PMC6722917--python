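"""Diameter statistics and unit-cell bookkeeping for the fiber network.

The membrane unit cell is a slab of cross-section area ``A`` and thickness
equal to one fiber length ``2*r0``, so its volume is V = A * 2*r0. Under
this convention every fiber assigned to the cell crosses the mid-plane, the
all-fiber force sum equals a cross-section force without an
orientation-dependent crossing correction, and the membrane stress is simply
F_y / A.

The fiber count in the cell follows from porosity ``p``: the solid volume
V*(1 - p) divided by the volume of one fiber (pi/4)*D^2*2*r0 gives

    n = 2 * V * (1 - p) / (r0 * pi * D^2)

where ``D`` is the harmonic mean fiber diameter, the same average used in
the diameter correction of the fiber law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiameterSample",
    "MembraneSpec",
    "diameter_statistics",
    "fiber_count",
    "solid_volume_fraction",
]


@dataclass(frozen=True)
class DiameterSample:
    """A sample of fiber diameters in nm (all positive)."""

    diameters: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        if d.size == 0:
            raise ValueError("diameter sample must be non-empty")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("all diameters must be positive and finite")
        object.__setattr__(self, "diameters", d)

    @property
    def arithmetic_mean(self) -> float:
        return float(np.mean(self.diameters))

    @property
    def rms(self) -> float:
        """Root-mean-square diameter, sqrt(mean of d^2)."""
        return float(np.sqrt(np.mean(self.diameters ** 2)))

    @property
    def harmonic_mean(self) -> float:
        return float(self.diameters.size / np.sum(1.0 / self.diameters))

    def __len__(self) -> int:
        return int(self.diameters.size)


def diameter_statistics(sample: DiameterSample) -> tuple[float, float, float]:
    """Return (arithmetic mean, RMS, harmonic mean) in nm.

    The power-mean inequality guarantees harmonic <= arithmetic <= RMS, with
    equality iff all diameters coincide.
    """
    return sample.arithmetic_mean, sample.rms, sample.harmonic_mean


def _check_positive(name: str, value: float) -> float:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class MembraneSpec:
    """Geometry and porosity of the membrane unit cell.

    Parameters
    ----------
    porosity : float in [0, 1)
        Void volume fraction.
    r0_nm : float
        Fiber half-length (nm); the unit cell is 2*r0 thick.
    area_nm2 : float
        Unit-cell cross-section area (nm^2) used to convert force to stress.
    harmonic_d_nm : float
        Harmonic mean fiber diameter D (nm).
    shrinkage_v : float
        Transverse shrinkage coefficient of the membrane (> 0); consumed by
        the deformation kinematics.
    arithmetic_d_nm : float, optional
        Arithmetic mean diameter; only needed for the expected diameter
        correction (1 + dbar/D)/2.
    """

    porosity: float
    r0_nm: float
    area_nm2: float
    harmonic_d_nm: float
    shrinkage_v: float
    arithmetic_d_nm: float | None = None

    def __post_init__(self) -> None:
        p = self.porosity
        if not (isinstance(p, (int, float)) and math.isfinite(p) and 0 <= p < 1):
            raise ValueError(f"porosity must lie in [0, 1), got {p!r}")
        _check_positive("r0_nm", self.r0_nm)
        _check_positive("area_nm2", self.area_nm2)
        _check_positive("harmonic_d_nm", self.harmonic_d_nm)
        _check_positive("shrinkage_v", self.shrinkage_v)
        if self.arithmetic_d_nm is not None:
            _check_positive("arithmetic_d_nm", self.arithmetic_d_nm)

    @property
    def volume_nm3(self) -> float:
        """Unit-cell volume under the slab convention V = A * 2*r0."""
        return self.area_nm2 * 2.0 * self.r0_nm

    @classmethod
    def from_sample(cls, sample: DiameterSample, *, porosity: float, r0_nm: float,
                    area_nm2: float, shrinkage_v: float) -> "MembraneSpec":
        return cls(
            porosity=porosity,
            r0_nm=r0_nm,
            area_nm2=area_nm2,
            harmonic_d_nm=sample.harmonic_mean,
            shrinkage_v=shrinkage_v,
            arithmetic_d_nm=sample.arithmetic_mean,
        )


def fiber_count(spec: MembraneSpec) -> float:
    """Number of fibers in the unit cell: n = 2 V (1-p) / (r0 pi D^2).

    Satisfies the solid-volume conservation identity
    n * (pi/4) * D^2 * 2*r0 = V * (1 - p) to machine precision.
    """
    return (2.0 * spec.volume_nm3 * (1.0 - spec.porosity)
            / (spec.r0_nm * math.pi * spec.harmonic_d_nm ** 2))


def solid_volume_fraction(spec: MembraneSpec) -> float:
    """Fiber solid fraction 1 - p; round-trips with :func:`fiber_count`."""
    return 1.0 - spec.porosity
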