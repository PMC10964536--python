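"""Seeded synthetic cohorts of ablated lung metastases.

Real ablation CT cohorts are not publicly deposited, so this module is the
test substrate for the whole pipeline. Each lesion is a small paired CT-like
phantom:

* **pre-ablation** — an ellipsoidal nodule (diameter ~1.2 +/- 0.7 cm,
  capped at 3 cm per the usual ablation inclusion criterion) embedded in
  aerated-lung background, with three concentric latent texture zones
  (necrotic core / effusion band / congested rim) realised as smoothed
  Gaussian intensity fields with distinct means and variances;
* **post-ablation** — an ablation zone that encloses the tumour with a
  random 3-8 mm margin, a ground-glass halo around it, and — in non-CR
  lesions only — a wedge of residual tumour-like texture occupying 5-30%
  of the ablation-zone periphery;
* **clinical covariates** — moment-matched to the marginal distributions a
  typical colorectal-lung-metastasis RFA cohort reports (CA19-9 and CEA
  stochastically higher, lower-lobe location and straight electrodes more
  frequent in non-CR lesions).

Effect sizes are scalable: ``effect_sizes={"texture": 0, "clinical": 0}``
yields a label-free null cohort for calibration tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ImageVolume, MaskVolume, read_nifti, write_nifti

__all__ = [
    "ClinicalRecord",
    "LesionCase",
    "CohortConfig",
    "LesionParams",
    "generate_cohort",
    "generate_lesion",
    "split_cohort",
    "write_cohort",
    "read_cohort",
]

PRIMARY_SITES = ("rectum", "sigmoid_left", "transverse_right", "caecum")
LOBES = ("RUL", "RML", "RLL", "LUL", "LLL")
ELECTRODES = ("expandable", "straight")


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-lesion clinical and radiological covariates."""

    age: float
    sex: str
    cea: float
    ca199: float
    lymphadenopathy: bool
    systemic_treatment: bool
    primary_site: str
    nodule_size: float  # cm, maximum diameter
    lobe: str
    near_vessels: bool   # lesion within 1 cm of great vessels / mediastinum
    near_pleura: bool    # lesion within 1 cm of pleura / diaphragm
    electrode: str
    pneumothorax: bool
    iah: bool            # intra-alveolar haemorrhage

    def __post_init__(self):
        if not (0 < self.nodule_size <= 3.0):
            raise ValueError(
                f"nodule size must be in (0, 3] cm, got {self.nodule_size}"
            )
        for name in ("age", "cea", "ca199"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.primary_site not in PRIMARY_SITES:
            raise ValueError(f"unknown primary site {self.primary_site!r}")
        if self.lobe not in LOBES:
            raise ValueError(f"unknown lobe {self.lobe!r}")
        if self.electrode not in ELECTRODES:
            raise ValueError(f"unknown electrode type {self.electrode!r}")


@dataclass
class LesionCase:
    """One treated metastasis: paired volumes, masks, covariates, outcome."""

    lesion_id: str
    patient_id: str
    pre_image: ImageVolume
    post_image: ImageVolume
    tumor_mask: MaskVolume
    ablation_mask: MaskVolume
    lung_mask: MaskVolume
    clinical: ClinicalRecord
    label: str  # "CR" | "nonCR"

    def __post_init__(self):
        if self.label not in ("CR", "nonCR"):
            raise ValueError(f"label must be 'CR' or 'nonCR', got {self.label!r}")


def _default_effects() -> dict[str, float]:
    return {"texture": 1.0, "clinical": 1.0}


@dataclass
class CohortConfig:
    """Generator configuration; defaults match the emulated study conditions."""

    n_lesions: int = 515
    noncr_prevalence: float = 0.2
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.25)
    latent_subregions: int = 3
    effect_sizes: dict[str, float] = field(default_factory=_default_effects)
    max_ring_mm: float = 10.0  # largest peritumoral shell the FOV must hold
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.noncr_prevalence < 1.0):
            raise ValueError(
                f"non-CR prevalence must be in (0,1), got {self.noncr_prevalence}"
            )
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.latent_subregions < 1:
            raise ValueError("latent_subregions must be >= 1")

    @property
    def texture_effect(self) -> float:
        return float(self.effect_sizes.get("texture", 1.0))

    @property
    def clinical_effect(self) -> float:
        return float(self.effect_sizes.get("clinical", 1.0))


# ---------------------------------------------------------------------------
# clinical covariate calibration (moment-matched marginals, CR vs non-CR)

_CLINICAL_MARGINALS = {
    # continuous: (mean, sd) per class
    "age": {"CR": (57.7, 10.4), "nonCR": (58.4, 10.7)},
    "cea": {"CR": (12.48, 37.91), "nonCR": (27.13, 65.92)},
    "ca199": {"CR": (25.41, 48.32), "nonCR": (51.75, 88.38)},
    "nodule_size": {"CR": (1.12, 0.38), "nonCR": (1.35, 0.42)},
    # binary: P(flag) per class
    "male": {"CR": 184 / 330, "nonCR": 50 / 82},
    "lymphadenopathy": {"CR": 218 / 330, "nonCR": 64 / 82},
    "systemic_treatment": {"CR": 231 / 330, "nonCR": 45 / 82},
    "near_vessels": {"CR": 53 / 330, "nonCR": 19 / 82},
    "near_pleura": {"CR": 199 / 330, "nonCR": 52 / 82},
    "straight_electrode": {"CR": 20 / 330, "nonCR": 12 / 82},
    "pneumothorax": {"CR": 93 / 330, "nonCR": 22 / 82},
    "iah": {"CR": 93 / 330, "nonCR": 15 / 82},
    # categorical frequencies per class
    "primary_site": {
        "CR": (216 / 330, 50 / 330, 60 / 330, 4 / 330),
        "nonCR": (58 / 82, 8 / 82, 15 / 82, 1 / 82),
    },
    "lobe": {
        "CR": (87 / 330, 32 / 330, 57 / 330, 79 / 330, 75 / 330),
        "nonCR": (11 / 82, 7 / 82, 21 / 82, 15 / 82, 28 / 82),
    },
}


def _interp(cr_val, noncr_val, label: str, effect: float):
    """Class-conditional parameter, with the non-CR shift scaled by effect."""
    if label == "CR":
        return cr_val
    a = np.asarray(cr_val, dtype=np.float64)
    b = np.asarray(noncr_val, dtype=np.float64)
    out = a + effect * (b - a)
    return out if out.ndim else float(out)


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Draw from a log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _sample_clinical(
    label: str, effect: float, rng: np.random.Generator, nodule_size_cm: float,
    lobe: str,
) -> ClinicalRecord:
    M = _CLINICAL_MARGINALS

    def cont(name):
        m, s = _interp(M[name]["CR"], M[name]["nonCR"], label, effect)
        return _lognormal(rng, float(m), float(s))

    def flag(name):
        p = _interp(M[name]["CR"], M[name]["nonCR"], label, effect)
        return bool(rng.random() < p)

    age_m, age_s = _interp(M["age"]["CR"], M["age"]["nonCR"], label, effect)
    site_p = _interp(M["primary_site"]["CR"], M["primary_site"]["nonCR"], label, effect)
    site_p = np.asarray(site_p) / np.sum(site_p)
    return ClinicalRecord(
        age=float(np.clip(rng.normal(age_m, age_s), 18.0, 95.0)),
        sex="M" if flag("male") else "F",
        cea=cont("cea"),
        ca199=cont("ca199"),
        lymphadenopathy=flag("lymphadenopathy"),
        systemic_treatment=flag("systemic_treatment"),
        primary_site=PRIMARY_SITES[int(rng.choice(4, p=site_p))],
        nodule_size=nodule_size_cm,
        lobe=lobe,
        near_vessels=flag("near_vessels"),
        near_pleura=flag("near_pleura"),
        electrode="straight" if flag("straight_electrode") else "expandable",
        pneumothorax=flag("pneumothorax"),
        iah=flag("iah"),
    )


def _sample_diameter_cm(label: str, effect: float, rng: np.random.Generator) -> float:
    m, s = _interp(
        _CLINICAL_MARGINALS["nodule_size"]["CR"],
        _CLINICAL_MARGINALS["nodule_size"]["nonCR"],
        label, effect,
    )
    for _ in range(100):
        d = _lognormal(rng, float(m), float(s))
        if 0.4 <= d <= 3.0:
            return d
    return float(np.clip(d, 0.4, 3.0))


def _sample_lobe(label: str, effect: float, rng: np.random.Generator) -> str:
    p = _interp(_CLINICAL_MARGINALS["lobe"]["CR"], _CLINICAL_MARGINALS["lobe"]["nonCR"],
                label, effect)
    p = np.asarray(p) / np.sum(p)
    return LOBES[int(rng.choice(5, p=p))]


# ---------------------------------------------------------------------------
# image synthesis

# HU means/SDs of the latent texture zones, inner -> outer
# (necrotic core, effusion band, congested rim). Means rise inner->outer;
# the effusion band is fluid and therefore nearly homogeneous while the
# necrotic debris and congested rim are heterogeneous, so the SD profile is
# V-shaped rather than monotone.
_ZONE_MEAN_HU = (10.0, 45.0, 80.0)
_ZONE_SD_HU = (16.0, 4.0, 16.0)
# spatial scale (voxels) of the noisy radial potential shaping zone borders
_ZONE_BORDER_SMOOTH = 3.0
_ZONE_BORDER_AMP = 0.3
_LUNG_HU = (-850.0, 40.0)
_ABLATED_HU = (-120.0, 25.0)
_HALO_HU = (-500.0, 60.0)
_CHEST_WALL_HU = 40.0
_HALO_MM = 4.0


def _zone_params(n_zones: int) -> tuple[np.ndarray, np.ndarray]:
    if n_zones == 1:
        return np.array([_ZONE_MEAN_HU[1]]), np.array([_ZONE_SD_HU[1]])
    t = np.linspace(0.0, 1.0, n_zones)
    means = _ZONE_MEAN_HU[0] + t * (_ZONE_MEAN_HU[-1] - _ZONE_MEAN_HU[0])
    # V-shaped heterogeneity: homogeneous middle, rough inner/outer
    sds = _ZONE_SD_HU[1] + (_ZONE_SD_HU[0] - _ZONE_SD_HU[1]) * np.abs(2 * t - 1)
    return means, sds


def _smooth_field(rng: np.random.Generator, shape, sigma_vox: float = 0.8) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    return f / f.std()


@dataclass
class LesionParams:
    """Inputs for one phantom lesion."""

    diameter_cm: float
    label: str
    lobe: str = "RUL"
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.25)
    latent_subregions: int = 3
    texture_effect: float = 1.0
    clinical_effect: float = 1.0
    fov_mm: float | None = None  # override field of view (error if too small)
    margin_mm: float | None = None  # ablation margin; random 3-8 if None
    max_ring_mm: float = 10.0  # largest peritumoral shell the FOV must hold


def generate_lesion(params: LesionParams, rng: np.random.Generator) -> LesionCase:
    """Synthesise one paired pre/post lesion phantom."""
    d_mm = params.diameter_cm * 10.0
    margin = params.margin_mm if params.margin_mm is not None else float(rng.uniform(3.0, 8.0))
    pad_mm = margin + params.max_ring_mm + 4.0  # margin + widest ring + slack
    fov = params.fov_mm if params.fov_mm is not None else d_mm + 2 * pad_mm
    if fov < d_mm + 2.0:
        raise ValueError(
            f"field of view {fov:.1f} mm cannot contain a {d_mm:.1f} mm lesion"
        )
    spacing = tuple(float(s) for s in params.spacing_mm)
    shape = tuple(int(np.ceil(fov / s)) for s in spacing)
    center = np.array([(n - 1) * s / 2 for n, s in zip(shape, spacing)])

    # ellipsoid: longest semi-axis = d/2 on a random axis, others shrunk
    semi = np.full(3, d_mm / 2.0)
    shrink = rng.uniform(0.75, 1.0, size=2)
    long_axis = int(rng.integers(0, 3))
    others = [a for a in range(3) if a != long_axis]
    semi[others[0]] *= shrink[0]
    semi[others[1]] *= shrink[1]

    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    rho = np.sqrt(sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)))
    tumor = rho <= 1.0
    if not tumor.any():
        raise ValueError("lesion diameter below voxel resolution")

    n_zones = params.latent_subregions
    means, sds = _zone_params(n_zones)
    # concentric zones with irregular borders: quantiles of a noisy radial
    # potential, so each zone keeps its inner->outer order but has a blobby,
    # partial-volume-realistic boundary and near-equal volume
    if n_zones > 1:
        border = _smooth_field(rng, shape, _ZONE_BORDER_SMOOTH)
        phi = rho + _ZONE_BORDER_AMP * border
        qs = np.quantile(phi[tumor], np.linspace(0, 1, n_zones + 1)[1:-1])
        zone = np.clip(np.digitize(phi, qs), 0, n_zones - 1)
    else:
        zone = np.zeros(shape, dtype=np.int64)

    noise = rng.standard_normal(shape)  # white: CT noise at ~1 mm scale
    lung_noise = _smooth_field(rng, shape, 1.2)
    pre = _LUNG_HU[0] + _LUNG_HU[1] * lung_noise
    tumor_tex = means[zone] + sds[zone] * noise
    pre[tumor] = tumor_tex[tumor]

    # chest wall slab so lung clipping is exercised
    lung = np.ones(shape, dtype=bool)
    lung[:2, :, :] = False
    pre[~lung] = _CHEST_WALL_HU

    # post-ablation: margin-dilated ablation zone, halo, optional residual wedge
    dist_to_tumor = ndimage.distance_transform_edt(~tumor, sampling=spacing)
    ablation = dist_to_tumor <= margin
    post_noise = _smooth_field(rng, shape)
    post = _LUNG_HU[0] + _LUNG_HU[1] * _smooth_field(rng, shape, 1.2)
    halo = (~ablation) & (ndimage.distance_transform_edt(~ablation, sampling=spacing) <= _HALO_MM)
    post[halo] = _HALO_HU[0] + _HALO_HU[1] * post_noise[halo]
    post[ablation] = _ABLATED_HU[0] + _ABLATED_HU[1] * post_noise[ablation]

    e_tex = params.texture_effect
    if params.label == "nonCR" and e_tex > 0:
        # residual disease presents as an eccentric wedge of tumour-like
        # texture at the ablation-zone periphery that spills a few mm beyond
        # the zone boundary (the incomplete-margin pattern radiologists read
        # as peripheral enhancement around the ablated area)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        frac = float(rng.uniform(0.05, 0.30))
        spill_mm = float(rng.uniform(2.0, 5.0))
        cos_cut = 1.0 - 2.0 * frac
        offs = np.stack([g - c for g, c in zip(grids, center)])
        norms = np.sqrt((offs**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.where(norms > 0, np.tensordot(u, offs, axes=1) / np.where(norms > 0, norms, 1.0), 1.0)
        rho_abl = np.where(ablation, dist_to_tumor / max(margin, 1e-6), 0.0)
        dist_to_abl = ndimage.distance_transform_edt(~ablation, sampling=spacing)
        inner_part = ablation & ((rho <= 1.2) | (rho_abl >= 0.3))
        spill_part = (~ablation) & (dist_to_abl <= spill_mm)
        wedge = (cosang >= cos_cut) & (inner_part | spill_part)
        residual = means[-1] + sds[-1] * post_noise
        post[wedge] = (1 - e_tex) * post[wedge] + e_tex * residual[wedge]
    post[~lung] = _CHEST_WALL_HU

    diameter_cm = params.diameter_cm
    clinical = _sample_clinical(
        params.label, params.clinical_effect, rng, diameter_cm, params.lobe
    )
    mk = lambda v: MaskVolume(v, spacing=spacing)
    return LesionCase(
        lesion_id="",
        patient_id="",
        pre_image=ImageVolume(pre, spacing=spacing),
        post_image=ImageVolume(post, spacing=spacing),
        tumor_mask=mk(tumor),
        ablation_mask=mk(ablation),
        lung_mask=mk(lung),
        clinical=clinical,
        label=params.label,
    )


def sample_outcomes(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    """Per-lesion Bernoulli outcome draw ('CR'/'nonCR')."""
    if not (0.0 < prevalence < 1.0):
        raise ValueError(f"non-CR prevalence must be in (0,1), got {prevalence}")
    return np.where(rng.random(n) < prevalence, "nonCR", "CR")


def generate_cohort(config: CohortConfig) -> list[LesionCase]:
    """Generate a full seeded cohort; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    labels = sample_outcomes(config.n_lesions, config.noncr_prevalence, rng)
    lesion_seeds = rng.integers(0, 2**31 - 1, size=config.n_lesions)
    cases: list[LesionCase] = []
    patient_idx = 0
    for i in range(config.n_lesions):
        lrng = np.random.default_rng(int(lesion_seeds[i]))
        # ~2.2 lesions per patient, as multi-nodule patients contribute each
        # nodule individually
        if i == 0 or lrng.random() < 0.45:
            patient_idx += 1
        label = str(labels[i])
        diameter = _sample_diameter_cm(label, config.clinical_effect, lrng)
        lobe = _sample_lobe(label, config.clinical_effect, lrng)
        case = generate_lesion(
            LesionParams(
                diameter_cm=diameter,
                label=label,
                lobe=lobe,
                spacing_mm=config.spacing_mm,
                latent_subregions=config.latent_subregions,
                texture_effect=config.texture_effect,
                clinical_effect=config.clinical_effect,
                max_ring_mm=config.max_ring_mm,
            ),
            lrng,
        )
        case.lesion_id = f"L{i:04d}"
        case.patient_id = f"P{patient_idx:04d}"
        cases.append(case)
    return cases


def split_cohort(
    cases: list[LesionCase], ratio_train: float, seed: int = 0
) -> tuple[list[LesionCase], list[LesionCase]]:
    """Random lesion-level train/test split, stratified by outcome.

    The training size is round(ratio * n) (ties toward train); class counts
    are allocated by largest remainder so both partitions contain both
    labels whenever n and prevalence permit.
    """
    n = len(cases)
    if n < 2:
        raise ValueError("need at least 2 lesions to split")
    if not (0.0 < ratio_train < 1.0):
        raise ValueError(f"ratio must be in (0,1), got {ratio_train}")
    n_train = int(np.floor(ratio_train * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)

    rng = np.random.default_rng(seed)
    by_label: dict[str, list[int]] = {}
    for i, c in enumerate(cases):
        by_label.setdefault(c.label, []).append(i)
    # largest-remainder allocation of the train quota across classes
    labels = sorted(by_label, key=lambda l: -len(by_label[l]))
    targets = {l: ratio_train * len(by_label[l]) for l in labels}
    alloc = {l: int(np.floor(targets[l])) for l in labels}
    multi_class = len(labels) > 1

    def _cap(l):
        # keep >= 1 lesion of each class on both sides when the class allows
        n_l = len(by_label[l])
        return n_l - 1 if (multi_class and n_l >= 2) else n_l

    for l in labels:
        if multi_class and len(by_label[l]) >= 2:
            alloc[l] = min(max(alloc[l], 1), _cap(l))
    remaining = n_train - sum(alloc.values())
    order = sorted(labels, key=lambda l: (-(targets[l] - alloc[l]),
                                          -len(by_label[l])))
    i = 0
    while remaining > 0 and any(alloc[l] < _cap(l) for l in labels):
        l = order[i % len(order)]
        if alloc[l] < _cap(l):
            alloc[l] += 1
            remaining -= 1
        i += 1
    while remaining < 0 and any(alloc[l] > (1 if multi_class else 0)
                                for l in labels):
        l = order[i % len(order)]
        if alloc[l] > (1 if multi_class else 0):
            alloc[l] -= 1
            remaining += 1
        i += 1
    train_idx: list[int] = []
    for l in labels:
        idx = np.array(by_label[l])
        perm = rng.permutation(len(idx))
        k = min(alloc[l], max(len(idx) - 1, 0)) if len(by_label) == 1 else alloc[l]
        train_idx.extend(idx[perm[:k]].tolist())
    train_set = set(train_idx)
    train = [cases[i] for i in range(n) if i in train_set]
    test = [cases[i] for i in range(n) if i not in train_set]
    return train, test


# ---------------------------------------------------------------------------
# on-disk cohort layout: NIfTI volumes + clinical CSV + JSON manifest

_CLINICAL_COLUMNS = [
    "lesion_id", "patient_id", "label", "age", "sex", "cea", "ca199",
    "lymphadenopathy", "systemic_treatment", "primary_site", "nodule_size",
    "lobe", "near_vessels", "near_pleura", "electrode", "pneumothorax", "iah",
]


def write_cohort(cases: list[LesionCase], directory) -> dict:
    """Write per-case NIfTI volumes, a clinical CSV and a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    entries = []
    for case in cases:
        stem = case.lesion_id
        files = {
            "pre_image": f"{stem}_pre.nii.gz",
            "post_image": f"{stem}_post.nii.gz",
            "tumor_mask": f"{stem}_tumor.nii.gz",
            "ablation_mask": f"{stem}_ablation.nii.gz",
            "lung_mask": f"{stem}_lung.nii.gz",
        }
        for attr, fname in files.items():
            write_nifti(getattr(case, attr), directory / fname)
        entries.append({"lesion_id": stem, "patient_id": case.patient_id,
                        "label": case.label, "files": files})
        rec = dataclasses.asdict(case.clinical)
        rec.update(lesion_id=stem, patient_id=case.patient_id, label=case.label)
        rows.append(rec)
    pd.DataFrame(rows)[_CLINICAL_COLUMNS].to_csv(directory / "clinical.csv", index=False)
    manifest = {"n_lesions": len(cases), "cases": entries}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory) -> list[LesionCase]:
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    clin = pd.read_csv(directory / "clinical.csv").set_index("lesion_id")
    cases = []
    for entry in manifest["cases"]:
        f = entry["files"]
        row = clin.loc[entry["lesion_id"]]
        record = ClinicalRecord(
            age=float(row["age"]), sex=str(row["sex"]), cea=float(row["cea"]),
            ca199=float(row["ca199"]),
            lymphadenopathy=bool(row["lymphadenopathy"]),
            systemic_treatment=bool(row["systemic_treatment"]),
            primary_site=str(row["primary_site"]),
            nodule_size=float(row["nodule_size"]), lobe=str(row["lobe"]),
            near_vessels=bool(row["near_vessels"]),
            near_pleura=bool(row["near_pleura"]),
            electrode=str(row["electrode"]),
            pneumothorax=bool(row["pneumothorax"]), iah=bool(row["iah"]),
        )
        cases.append(LesionCase(
            lesion_id=entry["lesion_id"],
            patient_id=entry["patient_id"],
            pre_image=read_nifti(directory / f["pre_image"]),
            post_image=read_nifti(directory / f["post_image"]),
            tumor_mask=read_nifti(directory / f["tumor_mask"], as_mask=True),
            ablation_mask=read_nifti(directory / f["ablation_mask"], as_mask=True),
            lung_mask=read_nifti(directory / f["lung_mask"], as_mask=True),
            clinical=record,
            label=entry["label"],
        ))
    return cases
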