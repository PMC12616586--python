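"""File-format helpers: NIfTI image stacks, CSV tables, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .cohort_synth import T2PrepSeries, VelocitySeries

__all__ = [
    "save_stack_nifti",
    "save_mask_nifti",
    "load_stack_nifti",
    "load_mask_nifti",
    "save_t2prep_series",
    "load_t2prep_series",
    "save_velocity_series",
    "load_velocity_series",
]


def _affine(pixel_area_cm2: float) -> np.ndarray:
    spacing_mm = float(np.sqrt(pixel_area_cm2) * 10.0)
    return np.diag([spacing_mm, spacing_mm, 1.0, 1.0])


def save_stack_nifti(stack: np.ndarray, path, pixel_area_cm2: float = 0.0144) -> None:
    """Write a (frames, rows, cols) stack as one 3-D volume (rows, cols, frames)."""
    data = np.asarray(stack, dtype=np.float32).transpose(1, 2, 0)
    nib.save(nib.Nifti1Image(data, _affine(pixel_area_cm2)), str(path))


def save_mask_nifti(mask: np.ndarray, path, pixel_area_cm2: float = 0.0144) -> None:
    data = np.asarray(mask, dtype=np.uint8)
    nib.save(nib.Nifti1Image(data, _affine(pixel_area_cm2)), str(path))


def load_stack_nifti(path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return data.transpose(2, 0, 1)


def load_mask_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_t2prep_series(series: T2PrepSeries, image_path, mask_path, meta_path=None,
                       pixel_area_cm2: float = 0.0144) -> None:
    save_stack_nifti(series.images, image_path, pixel_area_cm2)
    save_mask_nifti(series.roi_mask, mask_path, pixel_area_cm2)
    if meta_path is not None:
        Path(meta_path).write_text(
            json.dumps(
                {
                    "acquisition_id": series.acquisition_id,
                    "effective_tes_ms": list(series.effective_tes),
                },
                sort_keys=True,
            )
        )


def load_t2prep_series(image_path, mask_path, effective_tes=None, meta_path=None,
                       acquisition_id: str = "") -> T2PrepSeries:
    if effective_tes is None:
        if meta_path is None:
            raise ValueError("provide effective_tes or a meta_path sidecar")
        meta = json.loads(Path(meta_path).read_text())
        effective_tes = meta["effective_tes_ms"]
        acquisition_id = acquisition_id or meta.get("acquisition_id", "")
    return T2PrepSeries(
        images=load_stack_nifti(image_path),
        effective_tes=tuple(float(t) for t in effective_tes),
        roi_mask=load_mask_nifti(mask_path),
        acquisition_id=acquisition_id,
    )


def save_velocity_series(series: VelocitySeries, image_path, mask_path) -> None:
    save_stack_nifti(series.velocity_maps, image_path, series.pixel_area)
    save_mask_nifti(series.roi_mask, mask_path, series.pixel_area)


def load_velocity_series(image_path, mask_path, pixel_area_cm2: float,
                         venc: float | None = None,
                         acquisition_id: str = "") -> VelocitySeries:
    return VelocitySeries(
        velocity_maps=load_stack_nifti(image_path),
        pixel_area=pixel_area_cm2,
        roi_mask=load_mask_nifti(mask_path),
        acquisition_id=acquisition_id,
        venc=venc,
    )
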