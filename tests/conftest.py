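import numpy as np
import pytest

from renoximetry.cohort_synth import (
    INFRARENAL_IVC,
    LEFT_RENAL_VEIN,
    SUPRARENAL_IVC,
    ConditionState,
    T2PrepSeries,
)


@pytest.fixture
def baseline_state() -> ConditionState:
    """Cohort-mean baseline physiology (room air)."""
    return ConditionState(
        condition="baseline",
        target_peto2=100.0,
        sao2=0.99,
        svo2_by_site={
            LEFT_RENAL_VEIN: 0.92,
            SUPRARENAL_IVC: 0.83,
            INFRARENAL_IVC: 0.71,
        },
        bfr_by_site={
            LEFT_RENAL_VEIN: 410.0,
            SUPRARENAL_IVC: 2420.0,
            INFRARENAL_IVC: 1390.0,
        },
    )


def make_t2prep(images, tes, mask=None, acquisition_id="test"):
    """Build a T2PrepSeries from plain arrays (full mask by default)."""
    images = np.asarray(images, dtype=float)
    if mask is None:
        mask = np.ones(images.shape[1:], dtype=bool)
    return T2PrepSeries(
        images=images,
        effective_tes=tuple(float(t) for t in tes),
        roi_mask=np.asarray(mask, dtype=bool),
        acquisition_id=acquisition_id,
    )


@pytest.fixture
def t2prep_factory():
    return make_t2prep
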