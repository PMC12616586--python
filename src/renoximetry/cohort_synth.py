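"""Synthetic cohorts and forward-simulated renal MR oximetry acquisitions.

This module generates everything the downstream analysis consumes, with the
statistical structure of a graded isocapnic-hypoxia study in healthy adults:

* a cohort of subjects with demographics, hemoglobin-derived hematocrit and
  kidney masses drawn from truncated normal distributions;
* per subject x breathing-condition physiological truth (arterial saturation,
  site-wise venous saturation and blood flow rate) for the four stages
  baseline, mild hypoxia (target end-tidal O2 62 mmHg), moderate hypoxia
  (52 mmHg) and recovery;
* image-level acquisitions: background-suppressed T2-prepared magnitude
  images at increasing effective TEs (Rician noise) and phase-contrast
  velocity maps (Gaussian noise) with elliptical vessel ROI masks as ground
  truth.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .oximetry import CalibrationModel, DEFAULT_CALIBRATION, forward_t2

__all__ = [
    "CONDITIONS",
    "SITES",
    "LEFT_RENAL_VEIN",
    "SUPRARENAL_IVC",
    "INFRARENAL_IVC",
    "TruncatedNormal",
    "SubjectProfile",
    "ConditionState",
    "ConditionSpec",
    "AcquisitionGeometry",
    "T2PrepSeries",
    "VelocitySeries",
    "DEFAULT_DEMOGRAPHY",
    "DEFAULT_PHYSIOLOGY",
    "generate_cohort",
    "generate_condition_truth",
    "generate_subject_schedule",
    "render_t2prep_series",
    "render_velocity_series",
    "default_geometry",
    "scale_demography",
    "scale_physiology",
]

LEFT_RENAL_VEIN = "left_renal_vein"
SUPRARENAL_IVC = "suprarenal_ivc"
INFRARENAL_IVC = "infrarenal_ivc"
SITES: tuple[str, ...] = (LEFT_RENAL_VEIN, SUPRARENAL_IVC, INFRARENAL_IVC)
CONDITIONS: tuple[str, ...] = ("baseline", "mild_hypoxia", "moderate_hypoxia", "recovery")

HB_TO_HCT_DIVISOR = 0.34  # Hct(%) = Hb (g/dL) / 0.34


from functools import lru_cache


@lru_cache(maxsize=1024)
def _matched_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Center of the underlying normal such that the truncated mean equals ``mean``.

    Reported ranges are often asymmetric about the reported mean (age above
    all); recentering keeps the generator's marginal mean at the reported
    value despite truncation.
    """
    from scipy.optimize import brentq

    def truncated_mean(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    if abs(truncated_mean(mean) - mean) < 1e-12:
        return mean
    return float(brentq(lambda loc: truncated_mean(loc) - mean, mean - 12 * sd, mean + 12 * sd))


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal distribution truncated to ``[lo, hi]``; ``sd = 0`` degenerates to the mean.

    The underlying normal is recentered so that the *truncated* distribution
    has exactly the specified mean.
    """

    mean: float
    sd: float
    lo: float = -math.inf
    hi: float = math.inf

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(
                f"truncation bounds [{self.lo}, {self.hi}] exclude the mean {self.mean}"
            )

    def _loc(self) -> float:
        return _matched_loc(self.mean, self.sd, self.lo, self.hi)

    def sample(self, rng: np.random.Generator, size=None):
        if self.sd == 0:
            return self.mean if size is None else np.full(size, self.mean)
        loc = self._loc()
        a = (self.lo - loc) / self.sd
        b = (self.hi - loc) / self.sd
        return stats.truncnorm.rvs(a, b, loc=loc, scale=self.sd, size=size, random_state=rng)


def _sample_with_latent(
    spec: TruncatedNormal, rng: np.random.Generator, z_latent: float, frac: float
) -> float:
    """Draw with a shared subject-level effect: value = c + sd*(f*z_s + sqrt(1-f^2)*z).

    ``c`` is the mean-matched center of the truncated distribution; bounds are
    enforced by redrawing the condition-level innovation only, so the subject
    effect is preserved and the marginal mean stays at the specified value.
    """
    if spec.sd == 0:
        return spec.mean
    center = spec._loc()
    g = math.sqrt(max(0.0, 1.0 - frac * frac))
    for _ in range(10_000):
        z = rng.standard_normal()
        v = center + spec.sd * (frac * z_latent + g * z)
        if spec.lo <= v <= spec.hi:
            return float(v)
    raise RuntimeError("rejection sampling failed; truncation bounds too tight")


@dataclass(frozen=True)
class SubjectProfile:
    """One participant's fixed attributes entering the Fick computation."""

    subject_id: str
    sex: str
    age: float  # years
    height: float  # m
    weight: float  # kg
    hb: float  # g/dL
    hct: float  # fraction
    left_kidney_mass: float  # g
    right_kidney_mass: float  # g

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if abs(self.hct - self.hb / HB_TO_HCT_DIVISOR / 100.0) > 1e-9:
            raise ValueError("hct inconsistent with hb / 0.34 rule")
        if not (0.15 < self.hct < 0.60):
            raise ValueError(f"hct {self.hct} outside plausible range (0.15, 0.60)")
        if self.left_kidney_mass <= 0 or self.right_kidney_mass <= 0:
            raise ValueError("kidney masses must be positive")

    @property
    def total_kidney_mass(self) -> float:
        return self.left_kidney_mass + self.right_kidney_mass


@dataclass(frozen=True)
class ConditionState:
    """Ground-truth physiology for one subject x breathing condition."""

    condition: str
    target_peto2: float  # mmHg
    sao2: float  # fraction
    svo2_by_site: Mapping[str, float]
    bfr_by_site: Mapping[str, float]  # mL/min

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not (0.0 < self.sao2 <= 1.0):
            raise ValueError("sao2 must be in (0, 1]")
        for site, y in self.svo2_by_site.items():
            if not (0.0 < y <= self.sao2):
                raise ValueError(f"svo2 at {site} must be in (0, sao2]")
        for site, q in self.bfr_by_site.items():
            if q <= 0:
                raise ValueError(f"BFR at {site} must be positive")
        if SUPRARENAL_IVC in self.bfr_by_site and INFRARENAL_IVC in self.bfr_by_site:
            if self.bfr_by_site[SUPRARENAL_IVC] <= self.bfr_by_site[INFRARENAL_IVC]:
                raise ValueError("suprarenal BFR must exceed infrarenal BFR")


@dataclass(frozen=True)
class ConditionSpec:
    """Marginal distributions for one breathing condition.

    Suprarenal IVC flow is constructed as infrarenal flow plus the renal
    venous outflow difference ``delta_bfr``, which guarantees a positive
    suprarenal-infrarenal difference and reproduces the reported outflow
    distribution directly.
    """

    target_peto2: float
    sao2: TruncatedNormal
    svo2: Mapping[str, TruncatedNormal]
    bfr: Mapping[str, TruncatedNormal]  # left_renal_vein and infrarenal_ivc
    delta_bfr: TruncatedNormal

    def implied_bfr_mean(self, site: str) -> float:
        if site == SUPRARENAL_IVC:
            return self.bfr[INFRARENAL_IVC].mean + self.delta_bfr.mean
        return self.bfr[site].mean


def _tn(mean, sd, lo=-math.inf, hi=math.inf) -> TruncatedNormal:
    return TruncatedNormal(mean, sd, lo, hi)


DEFAULT_DEMOGRAPHY: dict[str, TruncatedNormal] = {
    "age": _tn(30.0, 9.0, 23.0, 53.0),  # years
    "height": _tn(1.71, 0.12, 1.50, 1.91),  # m
    "weight": _tn(71.0, 14.0, 55.0, 100.0),  # kg
    # Hemoglobin in g/dL; hematocrit follows from Hct(%) = Hb/0.34, so the
    # Hct summary 42 +/- 4 (range 34-46) maps to Hb 14.28 +/- 1.36 (11.56-15.64).
    "hb": _tn(14.28, 1.36, 11.56, 15.64),
    "left_kidney_mass": _tn(172.0, 29.0, 124.0, 226.0),  # g
    "right_kidney_mass": _tn(159.0, 26.0, 117.0, 221.0),  # g
}

_SVO2_LO, _SVO2_HI = 0.35, 0.995  # kept inside the calibration validity interval

DEFAULT_PHYSIOLOGY: dict[str, ConditionSpec] = {
    "baseline": ConditionSpec(
        target_peto2=100.0,
        sao2=_tn(0.99, 0.01, 0.90, 1.0),
        svo2={
            LEFT_RENAL_VEIN: _tn(0.92, 0.03, _SVO2_LO, _SVO2_HI),
            SUPRARENAL_IVC: _tn(0.83, 0.04, _SVO2_LO, _SVO2_HI),
            INFRARENAL_IVC: _tn(0.71, 0.10, _SVO2_LO, _SVO2_HI),
        },
        bfr={LEFT_RENAL_VEIN: _tn(410.0, 65.0, 50.0), INFRARENAL_IVC: _tn(1390.0, 530.0, 200.0)},
        delta_bfr=_tn(1030.0, 180.0, 50.0),
    ),
    "mild_hypoxia": ConditionSpec(
        target_peto2=62.0,
        sao2=_tn(0.90, 0.01, 0.80, 1.0),
        svo2={
            LEFT_RENAL_VEIN: _tn(0.83, 0.04, _SVO2_LO, _SVO2_HI),
            SUPRARENAL_IVC: _tn(0.71, 0.05, _SVO2_LO, _SVO2_HI),
            INFRARENAL_IVC: _tn(0.67, 0.04, _SVO2_LO, _SVO2_HI),
        },
        bfr={LEFT_RENAL_VEIN: _tn(430.0, 56.0, 50.0), INFRARENAL_IVC: _tn(1580.0, 420.0, 200.0)},
        delta_bfr=_tn(1160.0, 250.0, 50.0),
    ),
    "moderate_hypoxia": ConditionSpec(
        target_peto2=52.0,
        sao2=_tn(0.84, 0.02, 0.74, 1.0),
        svo2={
            LEFT_RENAL_VEIN: _tn(0.76, 0.05, _SVO2_LO, _SVO2_HI),
            SUPRARENAL_IVC: _tn(0.68, 0.06, _SVO2_LO, _SVO2_HI),
            INFRARENAL_IVC: _tn(0.62, 0.10, _SVO2_LO, _SVO2_HI),
        },
        bfr={LEFT_RENAL_VEIN: _tn(440.0, 48.0, 50.0), INFRARENAL_IVC: _tn(1760.0, 380.0, 200.0)},
        delta_bfr=_tn(1230.0, 470.0, 50.0),
    ),
    "recovery": ConditionSpec(
        target_peto2=100.0,
        sao2=_tn(0.98, 0.01, 0.88, 1.0),
        svo2={
            LEFT_RENAL_VEIN: _tn(0.92, 0.03, _SVO2_LO, _SVO2_HI),
            SUPRARENAL_IVC: _tn(0.80, 0.03, _SVO2_LO, _SVO2_HI),
            INFRARENAL_IVC: _tn(0.75, 0.05, _SVO2_LO, _SVO2_HI),
        },
        bfr={LEFT_RENAL_VEIN: _tn(410.0, 56.0, 50.0), INFRARENAL_IVC: _tn(1510.0, 240.0, 200.0)},
        delta_bfr=_tn(1010.0, 210.0, 50.0),
    ),
}


def scale_demography(demography: Mapping[str, TruncatedNormal], sd_scale: float):
    """Return a copy with every SD multiplied by ``sd_scale`` (0 gives exact means)."""
    return {k: replace(v, sd=v.sd * sd_scale) for k, v in demography.items()}


def scale_physiology(physiology: Mapping[str, ConditionSpec], sd_scale: float):
    def _s(tn: TruncatedNormal) -> TruncatedNormal:
        return replace(tn, sd=tn.sd * sd_scale)

    return {
        cond: ConditionSpec(
            target_peto2=spec.target_peto2,
            sao2=_s(spec.sao2),
            svo2={k: _s(v) for k, v in spec.svo2.items()},
            bfr={k: _s(v) for k, v in spec.bfr.items()},
            delta_bfr=_s(spec.delta_bfr),
        )
        for cond, spec in physiology.items()
    }


def generate_cohort(
    n_subjects: int,
    seed,
    demography: Mapping[str, TruncatedNormal] | None = None,
) -> list[SubjectProfile]:
    """Draw a reproducible cohort; hematocrit derives from hemoglobin by the 0.34 rule."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    demography = dict(DEFAULT_DEMOGRAPHY if demography is None else demography)
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        attrs = {name: float(spec.sample(rng)) for name, spec in sorted(demography.items())}
        hct = attrs["hb"] / HB_TO_HCT_DIVISOR / 100.0
        cohort.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                sex="MF"[i % 2],
                age=attrs["age"],
                height=attrs["height"],
                weight=attrs["weight"],
                hb=attrs["hb"],
                hct=hct,
                left_kidney_mass=attrs["left_kidney_mass"],
                right_kidney_mass=attrs["right_kidney_mass"],
            )
        )
    return cohort


def _draw_condition(
    rng: np.random.Generator,
    condition: str,
    spec: ConditionSpec,
    latents: Mapping | None,
    frac: float,
) -> ConditionState:
    latents = latents or {}

    def lat(key) -> float:
        return float(latents.get(key, 0.0))

    sao2 = _sample_with_latent(spec.sao2, rng, lat("sao2"), frac)
    svo2 = {}
    for site in SITES:
        for _ in range(1000):
            v = _sample_with_latent(spec.svo2[site], rng, lat(("svo2", site)), frac)
            if v < sao2:
                break
        else:
            raise RuntimeError(f"could not draw svo2 < sao2 at {site}")
        svo2[site] = v
    bfr = {
        LEFT_RENAL_VEIN: _sample_with_latent(
            spec.bfr[LEFT_RENAL_VEIN], rng, lat(("bfr", LEFT_RENAL_VEIN)), frac
        ),
        INFRARENAL_IVC: _sample_with_latent(
            spec.bfr[INFRARENAL_IVC], rng, lat(("bfr", INFRARENAL_IVC)), frac
        ),
    }
    delta = _sample_with_latent(spec.delta_bfr, rng, lat("delta_bfr"), frac)
    bfr[SUPRARENAL_IVC] = bfr[INFRARENAL_IVC] + delta
    return ConditionState(
        condition=condition,
        target_peto2=spec.target_peto2,
        sao2=sao2,
        svo2_by_site=svo2,
        bfr_by_site=bfr,
    )


def generate_condition_truth(
    subject: SubjectProfile,
    condition: str,
    seed,
    physiology: Mapping[str, ConditionSpec] | None = None,
) -> ConditionState:
    """Ground-truth physiology for one condition, independent of other conditions."""
    physiology = DEFAULT_PHYSIOLOGY if physiology is None else physiology
    if condition not in physiology:
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    return _draw_condition(rng, condition, physiology[condition], None, 0.0)


_LATENT_KEYS = (
    "sao2",
    ("svo2", LEFT_RENAL_VEIN),
    ("svo2", SUPRARENAL_IVC),
    ("svo2", INFRARENAL_IVC),
    ("bfr", LEFT_RENAL_VEIN),
    ("bfr", INFRARENAL_IVC),
    "delta_bfr",
)


def generate_subject_schedule(
    subject: SubjectProfile,
    seed,
    physiology: Mapping[str, ConditionSpec] | None = None,
    subject_effect_frac: float = 0.5,
) -> dict[str, ConditionState]:
    """All four condition states for one subject with a shared subject-level effect.

    A per-channel latent z-score is drawn once and contributes a fraction
    ``subject_effect_frac`` of each parameter's SD to every condition, so that
    within-subject repeated measures are positively correlated while marginal
    means and SDs stay at their specified values.
    """
    if not (0.0 <= subject_effect_frac <= 1.0):
        raise ValueError("subject_effect_frac must be in [0, 1]")
    physiology = DEFAULT_PHYSIOLOGY if physiology is None else physiology
    rng = np.random.default_rng(seed)
    latents = {key: float(rng.standard_normal()) for key in _LATENT_KEYS}
    return {
        cond: _draw_condition(rng, cond, physiology[cond], latents, subject_effect_frac)
        for cond in CONDITIONS
        if cond in physiology
    }


# --------------------------------------------------------------------------
# Image-level forward model


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Pixel grid, vessel ellipse and acquisition settings for one imaging site."""

    matrix: tuple[int, int] = (48, 48)
    pixel_area: float = 0.0144  # cm^2/pixel (1.2 mm isotropic)
    vessel_center: tuple[float, float] = (23.5, 23.5)  # (row, col) pixels
    vessel_radii: tuple[float, float] = (4.5, 5.5)  # ellipse semi-axes, pixels
    venc: float = 60.0  # cm/s
    effective_tes: tuple[float, ...] = (0.0, 40.0, 80.0, 160.0, 240.0)  # ms
    noise_sigma: float = 20.0  # magnitude-image noise scale, signal units
    velocity_noise_sigma: float = 0.5  # cm/s

    def __post_init__(self) -> None:
        tes = np.asarray(self.effective_tes)
        if len(tes) < 2 or np.any(np.diff(tes) <= 0) or tes[0] < 0:
            raise ValueError("effective_tes must be strictly increasing with first entry >= 0")
        if self.venc <= 0 or self.pixel_area <= 0:
            raise ValueError("venc and pixel_area must be positive")
        (cy, cx), (ry, rx) = self.vessel_center, self.vessel_radii
        if ry <= 0 or rx <= 0:
            raise ValueError("vessel radii must be positive")
        if cy - ry < 0 or cy + ry > self.matrix[0] - 1 or cx - rx < 0 or cx + rx > self.matrix[1] - 1:
            raise ValueError("vessel ellipse must lie fully inside the matrix")
        if self.noise_sigma < 0 or self.velocity_noise_sigma < 0:
            raise ValueError("noise scales must be non-negative")

    def ellipse_mask(self) -> np.ndarray:
        yy, xx = np.mgrid[0 : self.matrix[0], 0 : self.matrix[1]]
        (cy, cx), (ry, rx) = self.vessel_center, self.vessel_radii
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    def normalized_radius_sq(self) -> np.ndarray:
        yy, xx = np.mgrid[0 : self.matrix[0], 0 : self.matrix[1]]
        (cy, cx), (ry, rx) = self.vessel_center, self.vessel_radii
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2

    def roi_area_cm2(self) -> float:
        return float(self.ellipse_mask().sum() * self.pixel_area)


_SITE_RADII = {
    LEFT_RENAL_VEIN: (4.5, 5.5),
    SUPRARENAL_IVC: (7.5, 7.5),
    INFRARENAL_IVC: (6.5, 6.5),
}
_SITE_VENC = {LEFT_RENAL_VEIN: 60.0, SUPRARENAL_IVC: 100.0, INFRARENAL_IVC: 100.0}


def default_geometry(
    site: str,
    matrix: tuple[int, int] = (48, 48),
    noise_sigma: float = 20.0,
    velocity_noise_sigma: float = 0.5,
    effective_tes: Sequence[float] = (0.0, 40.0, 80.0, 160.0, 240.0),
) -> AcquisitionGeometry:
    """Site-appropriate default geometry (vessel caliber and VENC per site)."""
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    center = ((matrix[0] - 1) / 2.0, (matrix[1] - 1) / 2.0)
    return AcquisitionGeometry(
        matrix=tuple(matrix),
        vessel_center=center,
        vessel_radii=_SITE_RADII[site],
        venc=_SITE_VENC[site],
        effective_tes=tuple(float(t) for t in effective_tes),
        noise_sigma=noise_sigma,
        velocity_noise_sigma=velocity_noise_sigma,
    )


@dataclass(frozen=True, eq=False)
class T2PrepSeries:
    """One acquisition's T2-prepared magnitude stack with its ROI mask."""

    images: np.ndarray  # (n_te, rows, cols), signal units
    effective_tes: tuple[float, ...]  # ms
    roi_mask: np.ndarray  # bool
    acquisition_id: str = ""

    def __post_init__(self) -> None:
        if len(self.images) != len(self.effective_tes):
            raise ValueError("one image per effective TE required")
        if np.any(np.asarray(self.images) < 0):
            raise ValueError("magnitude images must be non-negative")
        if not np.any(self.roi_mask):
            raise ValueError("ROI mask must be non-empty")


@dataclass(frozen=True, eq=False)
class VelocitySeries:
    """One acquisition's signed through-plane velocity maps with ROI mask."""

    velocity_maps: np.ndarray  # (n_maps, rows, cols), cm/s
    pixel_area: float  # cm^2
    roi_mask: np.ndarray
    acquisition_id: str = ""
    venc: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if not np.any(self.roi_mask):
            raise ValueError("ROI mask must be non-empty")


def _rician(rng: np.random.Generator, clean: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0:
        return clean.copy()
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    return np.hypot(clean + n1, n2)


def render_t2prep_series(
    state: ConditionState,
    geom: AcquisitionGeometry,
    calib: CalibrationModel,
    hct: float,
    site: str,
    seed,
    s0: float = 1000.0,
    background_frac: float = 0.02,
    acquisition_id: str = "",
) -> T2PrepSeries:
    """Forward-model the T2-prepared stack for one site under a condition state.

    Vessel pixels decay as ``s0 * exp(-TE / T2_blood)`` with ``T2_blood`` from
    the calibration at the site's true SvO2; background pixels carry a small
    suppressed signal; Rician noise of scale ``geom.noise_sigma`` is applied
    to every pixel.
    """
    if site not in state.svo2_by_site:
        raise ValueError(f"site {site!r} missing from condition state")
    t2_blood = forward_t2(state.svo2_by_site[site], hct, calib)
    if t2_blood <= 0:
        raise ValueError("non-positive blood T2")
    rng = np.random.default_rng(seed)
    mask = geom.ellipse_mask()
    tes = np.asarray(geom.effective_tes, dtype=float)
    vessel = s0 * np.exp(-tes / t2_blood)
    clean = np.where(mask[None, :, :], vessel[:, None, None], background_frac * s0)
    return T2PrepSeries(
        images=_rician(rng, clean, geom.noise_sigma),
        effective_tes=tuple(tes.tolist()),
        roi_mask=mask,
        acquisition_id=acquisition_id,
    )


def render_velocity_series(
    state: ConditionState,
    geom: AcquisitionGeometry,
    site: str,
    seed,
    profile: str = "parabolic",
    n_maps: int = 5,
    acquisition_id: str = "",
) -> VelocitySeries:
    """Forward-model the phase-contrast velocity maps for one site.

    The vessel carries a laminar (parabolic, Poiseuille) profile scaled so the
    discrete ROI-mean velocity times ROI area times 60 equals the site's true
    flow exactly; ``profile='uniform'`` substitutes plug flow.  Zero-mean
    Gaussian noise of scale ``geom.velocity_noise_sigma`` is added everywhere;
    the ``n_maps`` interleaves share the truth with independent noise.
    """
    if site not in state.bfr_by_site:
        raise ValueError(f"site {site!r} missing from condition state")
    rng = np.random.default_rng(seed)
    mask = geom.ellipse_mask()
    area = float(mask.sum()) * geom.pixel_area
    target_mean_v = state.bfr_by_site[site] / (60.0 * area)  # cm/s
    if profile == "parabolic":
        shape = np.clip(1.0 - geom.normalized_radius_sq(), 0.0, None)
    elif profile == "uniform":
        shape = np.ones(geom.matrix)
    else:
        raise ValueError(f"unknown profile {profile!r}")
    shape = np.where(mask, shape, 0.0)
    scale = target_mean_v / shape[mask].mean()
    clean = scale * shape
    v_max = float(clean.max())
    if v_max > geom.venc:
        raise ValueError(
            f"peak velocity {v_max:.1f} cm/s exceeds VENC {geom.venc:.1f} cm/s (would alias)"
        )
    maps = clean[None, :, :] + (
        rng.normal(0.0, geom.velocity_noise_sigma, (n_maps, *geom.matrix))
        if geom.velocity_noise_sigma > 0
        else np.zeros((n_maps, *geom.matrix))
    )
    return VelocitySeries(
        velocity_maps=maps,
        pixel_area=geom.pixel_area,
        roi_mask=mask,
        acquisition_id=acquisition_id,
        venc=geom.venc,
    )
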