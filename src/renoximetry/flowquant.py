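"""Blood flow rate from phase-contrast velocity maps and ROI geometry.

Per velocity map, the ROI-mean signed velocity (cm/s) is multiplied by the
ROI area (mask pixel count x pixel area, cm^2) and by 60 to yield mL/min; the
final flow is the mean over the maps of one acquisition.  Velocity averaging
precedes flow computation within a map; across maps, flows are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FlowResult", "compute_bfr", "delta_bfr"]

_SUPRA = "suprarenal_ivc"
_INFRA = "infrarenal_ivc"


@dataclass(frozen=True)
class FlowResult:
    """Flow for one acquisition: final BFR plus per-interleave values."""

    bfr: float  # mL/min
    per_interleave_bfr: tuple[float, ...]
    roi_area: float  # cm^2
    mean_velocity: float  # cm/s, after the expected-direction flag
    site: str = ""


def compute_bfr(series, site: str = "", expected_direction: float = 1.0) -> FlowResult:
    """Blood flow rate from one velocity-map series.

    ``expected_direction`` is +1/-1 for the site's through-plane flow sign
    convention (flow toward the heart positive); the returned BFR is positive
    for flow in the expected direction.
    """
    mask = np.asarray(series.roi_mask, dtype=bool)
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("ROI mask is empty")
    area = n_px * float(series.pixel_area)
    per_map = []
    mean_vs = []
    for vmap in series.velocity_maps:
        vmap = np.asarray(vmap, dtype=float)
        if vmap.shape != mask.shape:
            raise ValueError("velocity map shape does not match mask")
        if getattr(series, "venc", None) and np.any(np.abs(vmap) > series.venc):
            warnings.warn(
                "velocities exceed VENC; phase aliasing likely (no unwrapping applied)",
                RuntimeWarning,
                stacklevel=2,
            )
        v = float(vmap[mask].mean()) * expected_direction
        mean_vs.append(v)
        per_map.append(v * area * 60.0)
    return FlowResult(
        bfr=float(np.mean(per_map)),
        per_interleave_bfr=tuple(per_map),
        roi_area=area,
        mean_velocity=float(np.mean(mean_vs)),
        site=site or getattr(series, "site", ""),
    )


def delta_bfr(supra, infra) -> float:
    """Suprarenal minus infrarenal IVC flow = total renal venous outflow (mL/min).

    Accepts :class:`FlowResult` objects (site labels are validated) or bare
    flow values in mL/min.  A negative difference on noisy input is returned
    with a warning, never clipped.
    """
    if isinstance(supra, FlowResult) or isinstance(infra, FlowResult):
        if not (isinstance(supra, FlowResult) and isinstance(infra, FlowResult)):
            raise TypeError("supply two FlowResults or two plain flow values")
        if supra.site and supra.site != _SUPRA:
            raise ValueError(f"first argument must be the {_SUPRA} result, got {supra.site!r}")
        if infra.site and infra.site != _INFRA:
            raise ValueError(f"second argument must be the {_INFRA} result, got {infra.site!r}")
        supra, infra = supra.bfr, infra.bfr
    diff = float(supra) - float(infra)
    if diff < 0:
        warnings.warn(
            "negative suprarenal-infrarenal flow difference (noisy measurement?)",
            RuntimeWarning,
            stacklevel=2,
        )
    return diff
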