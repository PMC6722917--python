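"""File I/O and run configuration.

Curves and diameter samples travel as headered CSV (UTF-8, comma separator,
decimal point); fitted parameters as a plain key-value record; run
configuration as a YAML mapping with typo-safe key validation. Every parse
error names the offending file and, for tabular data, the 1-based line
number. Defaults filled into a configuration are logged, as are the two
conventions (transverse-shrinkage handling and the stress clamp) that change
predicted numbers.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from fibermech.fiber_law import FiberLawParams, StressStrainCurve, require_strict_strain
from fibermech.geometry import DiameterSample, MembraneSpec
from fibermech.kinematics import CONVENTIONS

__all__ = [
    "CURVE_HEADER",
    "DIAMETER_HEADER",
    "RunConfig",
    "read_curve_csv",
    "write_curve_csv",
    "read_diameter_csv",
    "write_diameter_csv",
    "read_params_record",
    "write_params_record",
    "load_config",
    "save_config",
    "build_spec",
]

logger = logging.getLogger("fibermech")

CURVE_HEADER = ("strain", "stress_mpa")
DIAMETER_HEADER = ("diameter_nm",)


class ParseError(ValueError):
    """A malformed input file; message carries file name and line number."""


def _read_table(path: str | Path, expected_header: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{path}: no such file")
    try:
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"{path}: cannot parse CSV ({exc})") from exc
    if tuple(frame.columns) != expected_header:
        raise ParseError(
            f"{path}, line 1: expected header {','.join(expected_header)!r}, "
            f"got {','.join(map(str, frame.columns))!r}")
    numeric = pd.DataFrame()
    for col in expected_header:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() | ~np.isfinite(converted)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}, line {row + 2}: non-numeric or non-finite value "
                f"{frame[col].iloc[row]!r} in column {col!r}")
        numeric[col] = converted.astype(float)
    return numeric


def read_curve_csv(path: str | Path) -> StressStrainCurve:
    """Read a `strain,stress_mpa` CSV; rejects unsorted or duplicated strain."""
    frame = _read_table(path, CURVE_HEADER)
    strain = frame["strain"].to_numpy()
    diffs = np.diff(strain)
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0])
        kind = "duplicated" if diffs[row] == 0 else "unsorted"
        raise ParseError(f"{path}, line {row + 3}: {kind} strain value {strain[row + 1]!r}")
    try:
        return require_strict_strain(StressStrainCurve(strain, frame["stress_mpa"].to_numpy()))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_curve_csv(path: str | Path, curve: StressStrainCurve) -> None:
    pd.DataFrame({"strain": curve.strain, "stress_mpa": curve.stress}).to_csv(
        path, index=False, float_format="%.12g")


def read_diameter_csv(path: str | Path) -> DiameterSample:
    """Read a one-column `diameter_nm` CSV."""
    frame = _read_table(path, DIAMETER_HEADER)
    d = frame["diameter_nm"].to_numpy()
    nonpos = d <= 0
    if nonpos.any():
        row = int(np.flatnonzero(nonpos)[0])
        raise ParseError(f"{path}, line {row + 2}: diameter must be positive, got {d[row]!r}")
    return DiameterSample(d)


def write_diameter_csv(path: str | Path, sample: DiameterSample) -> None:
    pd.DataFrame({"diameter_nm": sample.diameters}).to_csv(
        path, index=False, float_format="%.12g")


# -- fitted-parameter record --------------------------------------------------

def write_params_record(path: str | Path, params: FiberLawParams, *,
                        r_squared: float | None = None,
                        blend_label: str = "") -> None:
    """Plain key-value record of a fitted single-fiber law."""
    lines = [f"a = {params.a:.12g}", f"b = {params.b:.12g}", f"c = {params.c:.12g}"]
    if r_squared is not None:
        lines.append(f"r_squared = {r_squared:.12g}")
    if blend_label:
        lines.append(f"blend_label = {blend_label}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_params_record(path: str | Path) -> tuple[FiberLawParams, dict]:
    """Read a key-value parameter record; returns params and extras."""
    path = Path(path)
    entries: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}, line {lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        entries[key.strip()] = value.strip()
    try:
        params = FiberLawParams(a=float(entries.pop("a")), b=float(entries.pop("b")),
                                c=float(entries.pop("c")))
    except KeyError as exc:
        raise ParseError(f"{path}: missing parameter key {exc}") from exc
    extras: dict = {}
    if "r_squared" in entries:
        extras["r_squared"] = float(entries.pop("r_squared"))
    if "blend_label" in entries:
        extras["blend_label"] = entries.pop("blend_label")
    if entries:
        raise ParseError(f"{path}: unknown keys {sorted(entries)}")
    return params, extras


# -- run configuration --------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration for the prediction pipeline.

    Either ``diameter_file`` (a diameter CSV, from which the harmonic and
    arithmetic means are computed) or ``harmonic_d_nm`` must be given.
    """

    porosity: float
    r0_nm: float
    area_nm2: float
    shrinkage_v: float
    blend_label: str = ""
    v_convention: str = "literal-eq2"
    quadrature_order: int = 64
    clamp: bool = True
    seed: int = 0
    diameter_file: str | None = None
    harmonic_d_nm: float | None = None
    arithmetic_d_nm: float | None = None
    curve_file: str | None = None
    params_file: str | None = None
    strain_max: float = 0.5
    strain_points: int = 101

    def __post_init__(self) -> None:
        def fail(key: str, why: str):
            raise ValueError(f"config key {key!r} invalid: {why}")

        if not (0 <= self.porosity < 1):
            fail("porosity", f"must lie in [0, 1), got {self.porosity}")
        for key in ("r0_nm", "area_nm2", "shrinkage_v", "strain_max"):
            val = getattr(self, key)
            if not (isinstance(val, (int, float)) and math.isfinite(val) and val > 0):
                fail(key, f"must be positive, got {val!r}")
        if self.v_convention not in CONVENTIONS:
            fail("v_convention", f"must be one of {CONVENTIONS}")
        if self.quadrature_order < 2:
            fail("quadrature_order", "must be >= 2")
        if self.strain_points < 2:
            fail("strain_points", "must be >= 2")
        if self.diameter_file is None and self.harmonic_d_nm is None:
            raise ValueError("config must provide 'diameter_file' or 'harmonic_d_nm'")


_DEFAULTED_KEYS = ("blend_label", "v_convention", "quadrature_order", "clamp",
                   "seed", "strain_max", "strain_points")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys rejected."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ParseError(f"{path}: unknown config keys {sorted(unknown)}; known keys: "
                         f"{sorted(known)}")
    try:
        config = RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for key in _DEFAULTED_KEYS:
        if key not in raw:
            logger.info("config %s: key %r defaulted to %r", path, key, getattr(config, key))
    logger.info("config %s: v_convention=%s clamp=%s seed=%d", path,
                config.v_convention, config.clamp, config.seed)
    return config


def save_config(path: str | Path, config: RunConfig) -> None:
    data = {k: v for k, v in dataclasses.asdict(config).items() if v is not None}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def build_spec(config: RunConfig, *, base_dir: str | Path | None = None) -> MembraneSpec:
    """Materialize the MembraneSpec from a config, reading the diameter file
    (resolved relative to ``base_dir``, typically the config's directory) if
    one is referenced."""
    harmonic, arithmetic = config.harmonic_d_nm, config.arithmetic_d_nm
    if config.diameter_file is not None:
        file_path = Path(config.diameter_file)
        if base_dir is not None and not file_path.is_absolute():
            file_path = Path(base_dir) / file_path
        sample = read_diameter_csv(file_path)
        harmonic, arithmetic = sample.harmonic_mean, sample.arithmetic_mean
    return MembraneSpec(porosity=config.porosity, r0_nm=config.r0_nm,
                        area_nm2=config.area_nm2, harmonic_d_nm=harmonic,
                        shrinkage_v=config.shrinkage_v, arithmetic_d_nm=arithmetic)
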