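import numpy as np
import pytest

from habitat_rfa.imaging import ImageVolume, MaskVolume, window_scale
from habitat_rfa.synthcohort import (
    ClinicalRecord,
    LesionCase,
    LesionParams,
    generate_lesion,
)


@pytest.fixture(scope="session")
def lesion_case():
    """One deterministic non-CR phantom lesion on a 1 mm isotropic grid."""
    rng = np.random.default_rng(7)
    return generate_lesion(
        LesionParams(diameter_cm=1.2, label="nonCR", spacing_mm=(1.0, 1.0, 1.0)),
        rng,
    )


@pytest.fixture(scope="session")
def preprocessed_pre(lesion_case):
    """Windowed/scaled pre-ablation image with its tumour mask."""
    return window_scale(lesion_case.pre_image), lesion_case.tumor_mask


def _tiny_volume():
    img = ImageVolume(np.zeros((4, 4, 4)))
    msk = MaskVolume(np.pad(np.ones((2, 2, 2), bool), 1))
    return img, msk


def make_dummy_record() -> ClinicalRecord:
    return ClinicalRecord(
        age=60.0, sex="M", cea=5.0, ca199=20.0, lymphadenopathy=False,
        systemic_treatment=True, primary_site="rectum", nodule_size=1.2,
        lobe="RUL", near_vessels=False, near_pleura=True,
        electrode="expandable", pneumothorax=False, iah=False,
    )


def make_dummy_cases(labels) -> list:
    """Lightweight lesion cases sharing one tiny volume (for split tests)."""
    img, msk = _tiny_volume()
    rec = make_dummy_record()
    cases = []
    for i, lab in enumerate(labels):
        cases.append(LesionCase(
            lesion_id=f"L{i:04d}", patient_id=f"P{i:04d}",
            pre_image=img, post_image=img, tumor_mask=msk,
            ablation_mask=msk, lung_mask=msk, clinical=rec, label=lab,
        ))
    return cases
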