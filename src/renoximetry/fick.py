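"""Whole-organ renal metabolic rate of oxygen via Fick's Principle.

The unilateral rate for one kidney is

    rMRO2 = CRBC * Hct * BFR * (SaO2 - SvO2) / kidney_mass * 100

in (umol O2/min)/100 g, with CRBC the oxygen-carrying capacity of red blood
cells (19.93 umol O2/mL RBC), BFR the renal venous flow in mL/min and the
saturations as fractions.  The bilateral rate replaces the single-vessel
flow and saturation with the suprarenal/infrarenal IVC difference, whose
venous-saturation term is the flow-weighted average over both renal veins.
First-order and Monte-Carlo error propagation quantify how measurement
uncertainty in the inputs (SvO2 above all) magnifies in the rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PhysiologicalConstants",
    "DEFAULT_CONSTANTS",
    "MetabolicRecord",
    "UncertaintyBudget",
    "hb_to_hct",
    "kidney_mass_from_volume",
    "unilateral_rmro2",
    "bilateral_svo2",
    "bilateral_rmro2",
    "propagate_uncertainty",
    "round_for_report",
]


@dataclass(frozen=True)
class PhysiologicalConstants:
    """Fixed physical constants of the metabolic-rate computation."""

    crbc: float = 19.93  # umol O2 per mL RBC
    tissue_density: float = 1.06  # g/mL
    hb_to_hct_divisor: float = 0.34  # Hct(%) = Hb (g/dL) / 0.34

    def __post_init__(self) -> None:
        if min(self.crbc, self.tissue_density, self.hb_to_hct_divisor) <= 0:
            raise ValueError("constants must be positive")


DEFAULT_CONSTANTS = PhysiologicalConstants()


@dataclass(frozen=True)
class MetabolicRecord:
    """One derived measurement row (subject x condition x site/scope)."""

    subject_id: str
    condition: str
    site_or_scope: str  # left_kidney, suprarenal_ivc, infrarenal_ivc, bilateral
    sao2: float
    svo2: float
    avdo2: float
    bfr: float
    rmro2: float | None = None  # only for left_kidney / bilateral scopes
    t2: float | None = None  # ms

    def __post_init__(self) -> None:
        if abs(self.avdo2 - (self.sao2 - self.svo2)) > 1e-12:
            raise ValueError("avdo2 must equal sao2 - svo2")
        if self.site_or_scope in ("suprarenal_ivc", "infrarenal_ivc") and self.rmro2 is not None:
            raise ValueError("rmro2 is defined only for left_kidney and bilateral scopes")


@dataclass(frozen=True)
class UncertaintyBudget:
    """Propagated rMRO2 uncertainty and per-input sensitivities."""

    input_sds: Mapping[str, float]
    rmro2_sd_linear: float | None
    rmro2_sd_mc: float | None
    sensitivity: Mapping[str, float]  # d(rMRO2)/d(input)


def hb_to_hct(hb: float, constants: PhysiologicalConstants = DEFAULT_CONSTANTS) -> float:
    """Hematocrit fraction from hemoglobin in g/dL."""
    if hb <= 0:
        raise ValueError("hb must be positive")
    return hb / constants.hb_to_hct_divisor / 100.0


def kidney_mass_from_volume(
    volume: float, constants: PhysiologicalConstants = DEFAULT_CONSTANTS
) -> float:
    """Kidney mass (g) from segmented volume (mL) at the renal tissue density."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return volume * constants.tissue_density


def _check_fractions(**kwargs) -> None:
    for name, value in kwargs.items():
        if not (0.0 < value <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {value}")


def unilateral_rmro2(
    bfr: float,
    sao2: float,
    svo2: float,
    hct: float,
    kidney_mass: float,
    constants: PhysiologicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Single-kidney metabolic rate in (umol O2/min)/100 g.

    A negative result (possible on noisy inputs with SvO2 > SaO2) is returned
    with a warning, never clipped.
    """
    if kidney_mass <= 0:
        raise ValueError("kidney_mass must be positive")
    if bfr <= 0:
        raise ValueError("bfr must be positive")
    _check_fractions(sao2=sao2, svo2=svo2, hct=hct)
    value = constants.crbc * hct * bfr * (sao2 - svo2) / kidney_mass * 100.0
    if value < 0:
        warnings.warn("negative rMRO2 (SvO2 exceeds SaO2)", RuntimeWarning, stacklevel=2)
    return value


def bilateral_svo2(qvs: float, svo2s: float, qvi: float, svo2i: float) -> float:
    """Flow-weighted venous saturation of the combined renal outflow.

    ``qvs``/``qvi`` are suprarenal/infrarenal IVC flows (mL/min) and
    ``svo2s``/``svo2i`` the matching saturations.  A value outside [0, 1]
    signals a physically inconsistent measurement and is returned with a
    warning, not clipped.
    """
    if qvs == qvi:
        raise ZeroDivisionError("equal IVC flows: flow-weighted saturation undefined")
    if qvi <= 0 or qvs <= 0:
        raise ValueError("IVC flows must be positive")
    if qvs < qvi:
        warnings.warn(
            "suprarenal flow below infrarenal flow (inconsistent measurement)",
            RuntimeWarning,
            stacklevel=2,
        )
    value = (qvs * svo2s - qvi * svo2i) / (qvs - qvi)
    if not (0.0 <= value <= 1.0):
        warnings.warn(
            f"flow-weighted venous saturation {value:.3f} outside [0, 1] "
            "(physically inconsistent measurement)",
            RuntimeWarning,
            stacklevel=2,
        )
    return value


def bilateral_rmro2(
    qvs: float,
    svo2s: float,
    qvi: float,
    svo2i: float,
    sao2: float,
    hct: float,
    total_mass: float,
    constants: PhysiologicalConstants = DEFAULT_CONSTANTS,
    form: str = "difference",
) -> float:
    """Combined metabolic rate of both kidneys in (umol O2/min)/100 g.

    ``form='difference'`` evaluates
    ``CRBC*Hct/total_mass * [QVs(SaO2-SvO2s) - QVi(SaO2-SvO2i)] * 100``;
    ``form='mixed'`` evaluates the algebraically identical flow-weighted
    mixing form through :func:`bilateral_svo2`.  Both paths are provided so
    their equivalence can be asserted.
    """
    if total_mass <= 0:
        raise ValueError("total_mass must be positive")
    _check_fractions(sao2=sao2, hct=hct)
    scale = constants.crbc * hct / total_mass * 100.0
    if form == "difference":
        extraction = qvs * (sao2 - svo2s) - qvi * (sao2 - svo2i)
    elif form == "mixed":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mixed = bilateral_svo2(qvs, svo2s, qvi, svo2i)
        extraction = (qvs - qvi) * (sao2 - mixed)
    else:
        raise ValueError(f"unknown form {form!r}")
    value = scale * extraction
    if value < 0:
        warnings.warn(
            "negative bilateral rMRO2 (inconsistent IVC measurements)",
            RuntimeWarning,
            stacklevel=2,
        )
    return value


def propagate_uncertainty(
    bfr: float,
    sao2: float,
    svo2: float,
    hct: float,
    kidney_mass: float,
    input_sds: Mapping[str, float],
    method: str = "linear",
    n_draws: int = 10_000,
    seed=None,
    constants: PhysiologicalConstants = DEFAULT_CONSTANTS,
) -> UncertaintyBudget:
    """Propagate input uncertainty through the unilateral Fick equation.

    ``input_sds`` maps any of ``bfr, sao2, svo2, hct, kidney_mass`` to its
    standard deviation (same units as the input).  ``method`` is ``linear``
    (first-order with analytic partials), ``monte_carlo`` (empirical SD over
    independent Gaussian draws; requires ``n_draws >= 1000``) or ``both``.
    """
    valid = {"bfr", "sao2", "svo2", "hct", "kidney_mass"}
    unknown = set(input_sds) - valid
    if unknown:
        raise ValueError(f"unknown parameters in input_sds: {sorted(unknown)}")
    if any(sd < 0 for sd in input_sds.values()):
        raise ValueError("SDs must be non-negative")
    if method not in ("linear", "monte_carlo", "both"):
        raise ValueError(f"unknown method {method!r}")

    point = {"bfr": bfr, "sao2": sao2, "svo2": svo2, "hct": hct, "kidney_mass": kidney_mass}
    r = constants.crbc * hct * bfr * (sao2 - svo2) / kidney_mass * 100.0
    scale = constants.crbc * hct * bfr / kidney_mass * 100.0
    sensitivity = {
        "bfr": r / bfr,
        "sao2": scale,
        "svo2": -scale,
        "hct": r / hct,
        "kidney_mass": -r / kidney_mass,
    }

    sd_linear = None
    if method in ("linear", "both"):
        sd_linear = math.sqrt(
            sum((sensitivity[p] * sd) ** 2 for p, sd in input_sds.items())
        )

    sd_mc = None
    if method in ("monte_carlo", "both"):
        if n_draws < 1000:
            raise ValueError("n_draws must be >= 1000 for Monte-Carlo propagation")
        rng = np.random.default_rng(seed)
        draws = {
            p: point[p] + rng.normal(0.0, input_sds.get(p, 0.0), n_draws)
            for p in valid
        }
        values = (
            constants.crbc
            * draws["hct"]
            * draws["bfr"]
            * (draws["sao2"] - draws["svo2"])
            / draws["kidney_mass"]
            * 100.0
        )
        sd_mc = float(np.std(values, ddof=1))

    return UncertaintyBudget(
        input_sds=dict(input_sds),
        rmro2_sd_linear=sd_linear,
        rmro2_sd_mc=sd_mc,
        sensitivity=sensitivity,
    )


_ROUND_STEP = {
    "bfr": 10.0,
    "delta_bfr": 10.0,
    "rmro2": 10.0,
    "sao2": 1.0,  # percent
    "svo2": 1.0,  # percent
    "avdo2": 1.0,  # percent
    "t2": 1.0,  # ms
}


def round_for_report(value: float, parameter_kind: str) -> float:
    """Reporting-layer rounding: flows and rates to the nearest ten (half away
    from zero), saturations (in percent) to whole percent, T2 to whole ms."""
    if not math.isfinite(value):
        raise ValueError("value must be finite")
    try:
        step = _ROUND_STEP[parameter_kind]
    except KeyError:
        raise ValueError(f"unknown parameter kind {parameter_kind!r}") from None
    return math.copysign(math.floor(abs(value) / step + 0.5) * step, value) if value else 0.0
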