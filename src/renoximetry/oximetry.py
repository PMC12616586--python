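"""Blood-water T2 <-> venous oxygen saturation calibration.

The transverse relaxation rate of blood water increases with deoxyhemoglobin
content.  Over the physiological range this is well described by a
Luz--Meiboom-type exchange model, quadratic in the deoxygenated fraction
``1 - Y`` with hematocrit-dependent coefficients::

    R2(Y, Hct) = A(Hct) + B(Hct) * (1 - Y) + C(Hct) * (1 - Y)**2   [s^-1]

where ``Y`` is the hemoglobin oxygen saturation (fraction) and each of
``A``, ``B``, ``C`` is a quadratic polynomial in Hct.  The forward map
(oxygenation to T2) drives the simulator; the inverse (measured T2 to SvO2)
is the analysis step.  Coefficient sets are shipped as named, swappable
configurations; see :data:`DEFAULT_CALIBRATION`.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, replace

import numpy as np
import yaml

__all__ = [
    "CalibrationModel",
    "CalibrationDomainError",
    "OxygenationResult",
    "DEFAULT_CALIBRATION",
    "forward_t2",
    "t2_to_svo2",
    "conversion_table",
    "load_calibration",
    "save_calibration",
]


class CalibrationDomainError(ValueError):
    """Measured T2 is inconsistent with the calibration at the given Hct."""

    def __init__(self, message: str, admissible_t2_ms: tuple[float, float] | None = None):
        super().__init__(message)
        self.admissible_t2_ms = admissible_t2_ms


def _poly(coeffs: tuple[float, float, float], hct: float) -> float:
    c0, c1, c2 = coeffs
    return c0 + c1 * hct + c2 * hct * hct


@dataclass(frozen=True)
class CalibrationModel:
    """Named, versioned T2-oxygenation calibration.

    ``coeff_a``, ``coeff_b`` and ``coeff_c`` are ``(c0, c1, c2)`` triples
    giving A(Hct) = c0 + c1*Hct + c2*Hct^2 (s^-1), and likewise for B and C.
    ``tau_cpmg_ms`` records the refocusing interval the coefficients refer to.
    """

    name: str
    coeff_a: tuple[float, float, float]
    coeff_b: tuple[float, float, float]
    coeff_c: tuple[float, float, float]
    tau_cpmg_ms: float
    valid_hct: tuple[float, float] = (0.30, 0.55)
    valid_svo2: tuple[float, float] = (0.30, 1.00)

    def __post_init__(self) -> None:
        h_lo, h_hi = self.valid_hct
        y_lo, y_hi = self.valid_svo2
        if not (0.0 < h_lo < h_hi < 1.0):
            raise ValueError("valid_hct must be an interval inside (0, 1)")
        if not (0.0 <= y_lo < y_hi <= 1.0):
            raise ValueError("valid_svo2 must be an interval inside [0, 1]")
        # Monotonicity (T2 strictly increasing in Y) and R2 > 0 across the
        # whole valid domain; checked on a grid once at construction.
        for hct in np.linspace(h_lo, h_hi, 11):
            a, b, c = self.a(hct), self.b(hct), self.c(hct)
            x = np.linspace(0.0, 1.0 - y_lo, 25)
            r2 = a + b * x + c * x * x
            if np.any(r2 <= 0.0):
                raise ValueError(f"{self.name}: non-positive R2 at Hct {hct:.2f}")
            if np.any(b + 2.0 * c * x <= 0.0):
                raise ValueError(
                    f"{self.name}: R2 not strictly increasing in (1-Y) at Hct {hct:.2f}"
                )

    def a(self, hct: float) -> float:
        return _poly(self.coeff_a, hct)

    def b(self, hct: float) -> float:
        return _poly(self.coeff_b, hct)

    def c(self, hct: float) -> float:
        return _poly(self.coeff_c, hct)

    def r2_rate(self, svo2: float, hct: float) -> float:
        """Relaxation rate R2 (s^-1) at saturation ``svo2`` and hematocrit ``hct``."""
        x = 1.0 - svo2
        return self.a(hct) + self.b(hct) * x + self.c(hct) * x * x

    def admissible_t2_ms(self, hct: float) -> tuple[float, float]:
        """Closed T2 interval (ms) invertible at ``hct`` given ``valid_svo2``."""
        x_max = 1.0 - self.valid_svo2[0]
        r2_hi = self.a(hct) + self.b(hct) * x_max + self.c(hct) * x_max * x_max
        r2_lo = self.r2_rate(self.valid_svo2[1], hct)
        return 1000.0 / r2_hi, 1000.0 / r2_lo

    def check_hct(self, hct: float) -> None:
        lo, hi = self.valid_hct
        if not (lo <= hct <= hi):
            raise ValueError(f"hct {hct} outside calibration validity [{lo}, {hi}]")


@dataclass(frozen=True)
class OxygenationResult:
    """Inverted oxygen saturation together with its inputs and branch note."""

    svo2: float
    t2: float
    hct: float
    branch_note: str = ""


# Default venous-blood calibration at 3 T.  C uses the literature exchange form
# C = 247.4 * Hct * (1 - Hct); A (linear in Hct, plasma intercept ~1 s^-1) and
# B (proportional to Hct) are anchored to venous reference T2-Y pairs at
# Hct 0.42 (159 ms <-> Y 0.92, 100 ms <-> Y 0.76).
DEFAULT_CALIBRATION = CalibrationModel(
    name="venous-3t-anchored-v1",
    coeff_a=(1.0, 10.93, 0.0),
    coeff_b=(0.0, 9.31, 0.0),
    coeff_c=(0.0, 247.4, -247.4),
    tau_cpmg_ms=10.0,
)


def forward_t2(svo2: float, hct: float, calib: CalibrationModel = DEFAULT_CALIBRATION) -> float:
    """Blood-water T2 (ms) at oxygen saturation ``svo2`` and hematocrit ``hct``."""
    calib.check_hct(hct)
    y_lo, y_hi = calib.valid_svo2
    if not (y_lo <= svo2 <= y_hi):
        raise ValueError(f"svo2 {svo2} outside calibration validity [{y_lo}, {y_hi}]")
    return 1000.0 / calib.r2_rate(svo2, hct)


def t2_to_svo2(
    t2: float, hct: float, calib: CalibrationModel = DEFAULT_CALIBRATION
) -> OxygenationResult:
    """Invert the calibration: measured T2 (ms) to venous oxygen saturation.

    Solves the quadratic in ``x = 1 - Y`` in closed form and returns the root
    on the physiological (monotone-increasing R2) branch.  Raises
    :class:`CalibrationDomainError` when no root lies inside ``valid_svo2``,
    reporting the admissible T2 interval at this hematocrit.
    """
    if t2 <= 0.0:
        raise ValueError("t2 must be positive")
    calib.check_hct(hct)
    a, b, c = calib.a(hct), calib.b(hct), calib.c(hct)
    r2 = 1000.0 / t2
    tol = 1e-12
    lo, hi = calib.valid_svo2
    bounds = calib.admissible_t2_ms(hct)

    def _fail() -> CalibrationDomainError:
        return CalibrationDomainError(
            f"t2 = {t2:.3f} ms has no oxygen saturation in [{lo}, {hi}] at hct "
            f"{hct:.3f}; admissible T2 range is [{bounds[0]:.1f}, {bounds[1]:.1f}] ms",
            admissible_t2_ms=bounds,
        )

    if abs(c) < 1e-12:
        # Degenerate linear calibration: Y = 1 - (R2 - A)/B.
        x = (r2 - a) / b
        y = 1.0 - x
        if not (lo - tol <= y <= hi + tol):
            raise _fail()
        return OxygenationResult(min(max(y, lo), hi), t2, hct, "linear (C = 0) branch")

    disc = b * b + 4.0 * c * (r2 - a)
    if disc < 0.0:
        raise _fail()
    sq = math.sqrt(disc)
    x_mono = (-b + sq) / (2.0 * c)  # monotone (physiological) branch
    x_other = (-b - sq) / (2.0 * c)
    y_mono, y_other = 1.0 - x_mono, 1.0 - x_other
    mono_ok = lo - tol <= y_mono <= hi + tol
    other_ok = lo - tol <= y_other <= hi + tol
    if mono_ok and other_ok:
        note = "both roots in valid interval; monotone branch chosen"
        y = y_mono
    elif mono_ok:
        note = "monotone branch"
        y = y_mono
    elif other_ok:
        note = "non-monotone root only; returned with caution"
        y = y_other
    else:
        raise _fail()
    return OxygenationResult(min(max(y, lo), hi), t2, hct, note)


def conversion_table(
    calib: CalibrationModel, hct: float, svo2_grid: np.ndarray | None = None
):
    """T2-vs-SvO2 lookup table (pandas DataFrame) at a fixed hematocrit."""
    import pandas as pd

    if svo2_grid is None:
        svo2_grid = np.linspace(calib.valid_svo2[0], calib.valid_svo2[1], 71)
    rows = [
        {"svo2": float(y), "t2_ms": forward_t2(float(y), hct, calib), "hct": hct}
        for y in svo2_grid
    ]
    return pd.DataFrame(rows)


def save_calibration(calib: CalibrationModel, path) -> None:
    payload = asdict(calib)
    payload = {
        k: list(v) if isinstance(v, tuple) else v for k, v in payload.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_calibration(path) -> CalibrationModel:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    for key in ("coeff_a", "coeff_b", "coeff_c", "valid_hct", "valid_svo2"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return CalibrationModel(**payload)
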