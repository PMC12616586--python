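"""Mono-exponential T2 decay fitting of ROI-mean blood signal.

The acquisition produces a short series of magnitude images at increasing
effective echo times; the mean signal over the vessel ROI decays as
``S(TE) = S0 * exp(-TE / T2)``.  Fitting is performed per acquisition on the
ROI means (not per pixel).  Two fitters are provided: a log-linear solution
(closed form, requires positive signals) and nonlinear least squares
initialized from it (the default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["T2Fit", "FitError", "roi_mean_signal", "fit_t2", "fit_series", "fit_signal_table"]


class FitError(ValueError):
    """The decay model cannot be fit to the given points."""


@dataclass(frozen=True)
class T2Fit:
    """Fitted decay parameters and diagnostics for one acquisition."""

    t2: float  # ms
    s0: float  # signal units
    residual_rms: float
    n_points: int
    r_squared: float
    method: str = "nls"

    def __post_init__(self) -> None:
        if self.t2 <= 0:
            raise FitError("fitted T2 must be positive")


def roi_mean_signal(series) -> list[tuple[float, float]]:
    """One ``(effective TE, ROI-mean signal)`` pair per image, in TE order."""
    mask = np.asarray(series.roi_mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("ROI mask is empty")
    out = []
    for te, image in zip(series.effective_tes, series.images):
        image = np.asarray(image, dtype=float)
        if image.shape != mask.shape:
            raise ValueError(
                f"image shape {image.shape} does not match mask shape {mask.shape}"
            )
        out.append((float(te), float(image[mask].mean())))
    return out


def _log_linear(tes: np.ndarray, signals: np.ndarray) -> tuple[float, float]:
    if np.any(signals <= 0):
        raise FitError(
            "log-linear fit requires strictly positive signals; use method='nls'"
        )
    slope, intercept = np.polyfit(tes, np.log(signals), 1)
    if slope >= 0:
        raise FitError("series does not decay: fitted T2 would be negative or unbounded")
    return float(np.exp(intercept)), float(-1.0 / slope)


def _model(te, s0, t2):
    return s0 * np.exp(-te / t2)


def _jac(te, s0, t2):
    e = np.exp(-te / t2)
    return np.stack([e, s0 * te / (t2 * t2) * e], axis=-1)


def fit_t2(
    points: Iterable[tuple[float, float]],
    method: str = "nls",
    fix_s0: bool = False,
) -> T2Fit:
    """Fit ``S(TE) = S0 exp(-TE/T2)`` to ``(te_ms, signal)`` points.

    ``method`` is ``"log_linear"`` (closed form on log signals) or ``"nls"``
    (sum-of-squared-residuals minimum, initialized from the log-linear
    solution).  With ``fix_s0`` the amplitude is pinned to the signal at the
    earliest TE and only T2 is fit.  A non-decaying series raises
    :class:`FitError` rather than silently clamping.
    """
    pts = sorted((float(t), float(s)) for t, s in points)
    if len(pts) < 3:
        raise FitError("at least 3 points are required for a reported fit")
    tes = np.array([p[0] for p in pts])
    signals = np.array([p[1] for p in pts])

    if method == "log_linear":
        if fix_s0:
            # Line through the earliest point: slope from the remaining points.
            if np.any(signals <= 0):
                raise FitError(
                    "log-linear fit requires strictly positive signals; use method='nls'"
                )
            dt = tes[1:] - tes[0]
            dlog = np.log(signals[1:] / signals[0])
            slope = float(np.sum(dt * dlog) / np.sum(dt * dt))
            if slope >= 0:
                raise FitError(
                    "series does not decay: fitted T2 would be negative or unbounded"
                )
            t2 = -1.0 / slope
            s0 = float(signals[0] * np.exp(tes[0] / t2))
        else:
            s0, t2 = _log_linear(tes, signals)
    elif method == "nls":
        pos = signals > 0
        if pos.sum() < 2:
            raise FitError("too few positive signals for initialization")
        s0_init, t2_init = _log_linear(tes[pos], signals[pos])
        if fix_s0:
            s0 = signals[0] * 1.0 if tes[0] == 0 else s0_init
            (t2,), _ = curve_fit(
                lambda te, t2: _model(te, s0, t2),
                tes,
                signals,
                p0=[t2_init],
                bounds=([1e-9], [np.inf]),
            )
            t2 = float(t2)
        else:
            (s0, t2), _ = curve_fit(
                _model,
                tes,
                signals,
                p0=[s0_init, t2_init],
                jac=_jac,
                bounds=([0.0, 1e-9], [np.inf, np.inf]),
                maxfev=10000,
            )
            s0, t2 = float(s0), float(t2)
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = signals - _model(tes, s0, t2)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((signals - signals.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return T2Fit(
        t2=t2,
        s0=s0,
        residual_rms=float(np.sqrt(ss_res / len(pts))),
        n_points=len(pts),
        r_squared=float(min(max(r_squared, 0.0), 1.0)),
        method=method,
    )


def fit_series(series, method: str = "nls", fix_s0: bool = False) -> T2Fit:
    """ROI-mean extraction followed by decay fitting, in one call."""
    return fit_t2(roi_mean_signal(series), method=method, fix_s0=fix_s0)


def fit_signal_table(table: pd.DataFrame, method: str = "nls") -> pd.DataFrame:
    """Fit every acquisition in a long table of ``(acquisition_id, te_ms, signal)``.

    Returns one row per acquisition with fit parameters and diagnostics;
    acquisitions that cannot be fit are reported with NaN parameters and the
    error message in an ``error`` column.
    """
    required = {"acquisition_id", "te_ms", "signal"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    rows = []
    for acq_id, group in table.groupby("acquisition_id", sort=True):
        row = {"acquisition_id": acq_id, "error": ""}
        try:
            fit = fit_t2(zip(group["te_ms"], group["signal"]), method=method)
            row.update(
                t2_ms=fit.t2,
                s0=fit.s0,
                residual_rms=fit.residual_rms,
                n_points=fit.n_points,
                r_squared=fit.r_squared,
            )
        except (FitError, RuntimeError) as exc:
            row.update(
                t2_ms=np.nan, s0=np.nan, residual_rms=np.nan,
                n_points=len(group), r_squared=np.nan, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
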