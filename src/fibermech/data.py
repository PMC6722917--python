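"""Published reference values for electrospun SF/PCL blend nanofibers.

Single-fiber constitutive fits (sigma = a - b*ln(eps + c), stress in MPa)
and SEM-based diameter summaries (nm) for silk-fibroin/poly(e-caprolactone)
blend membranes at five SF:PCL weight ratios. These are the model's measured
inputs: the fits come from nano-tensile tests of individual fibers, the
diameter summaries from 100 SEM measurements per membrane.
"""

from __future__ import annotations

from fibermech.fiber_law import FiberLawParams

__all__ = ["SFPCL_FIBER_FITS", "SFPCL_FIT_R2", "SFPCL_DIAMETERS", "BLEND_LABELS"]

BLEND_LABELS = ("100/0", "75/25", "50/50", "25/75", "0/100")

#: Fitted single-fiber law parameters per SF/PCL weight ratio.
SFPCL_FIBER_FITS: dict[str, FiberLawParams] = {
    "100/0": FiberLawParams(a=27.207, b=-3.297, c=1.006e-4),
    "75/25": FiberLawParams(a=22.669, b=-2.810, c=2.663e-4),
    "50/50": FiberLawParams(a=26.576, b=-4.313, c=1.290e-3),
    "25/75": FiberLawParams(a=12.569, b=-1.802, c=5.822e-4),
    "0/100": FiberLawParams(a=17.130, b=-3.219, c=8.120e-3),
}

#: Coefficient of determination of each published fit.
SFPCL_FIT_R2: dict[str, float] = {
    "100/0": 0.984,
    "75/25": 0.976,
    "50/50": 0.975,
    "25/75": 0.949,
    "0/100": 0.975,
}

#: (arithmetic mean, RMS, harmonic mean) fiber diameter in nm per blend.
SFPCL_DIAMETERS: dict[str, tuple[float, float, float]] = {
    "100/0": (85.87, 91.29, 79.49),
    "75/25": (70.52, 76.12, 62.96),
    "50/50": (63.76, 71.91, 57.11),
    "25/75": (76.56, 80.41, 70.54),
    "0/100": (99.37, 110.18, 88.62),
}
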