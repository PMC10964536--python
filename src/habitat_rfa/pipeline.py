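"""End-to-end orchestration: simulate -> preprocess -> rings -> habitats ->
features -> selection -> signatures -> evaluation.

``run_all`` executes the whole workflow from a single :class:`RunConfig`;
``run_analysis`` does the same from an existing cohort (so stages can be
replayed or fed real data). Every random stage derives its seed from the
config seed, so identical configs reproduce identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import habitat as hb
from .evaluation import EvaluationReport
from .imaging import MaskVolume, RingSpec, dilate_ring, resample_isotropic, window_scale
from .modeling import (
    DEFAULT_FAMILIES,
    SignatureModel,
    encode_clinical,
    fit_signature,
    multivariate_screen,
    predict,
)
from .radiomics import extract_features, fuse_phases
from .selection import (
    SelectionTrace,
    ZScorer,
    corr_prune,
    icc_filter,
    lasso_select,
    mrmr_select,
    ttest_filter,
)
from .synthcohort import CohortConfig, LesionCase, generate_cohort, split_cohort

logger = logging.getLogger("habitat_rfa")

__all__ = ["RunConfig", "PipelineResult", "run_all", "run_analysis"]

ALL_SIGNATURES = ("Clinical", "Intra", "Peri5", "Peri10", "Habitat", "HabitatPeri5")


@dataclass
class RunConfig:
    """Single configuration object for a reproducible pipeline run."""

    # cohort
    n_lesions: int = 60
    noncr_prevalence: float = 0.2
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.25)
    latent_subregions: int = 3
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"texture": 1.0, "clinical": 1.0}
    )
    ratio_train: float = 0.8
    # preprocessing
    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    window: tuple[float, float, float] = (-1200.0, 600.0, 255.0)
    ring_mm: tuple[float, float] = (5.0, 10.0)
    bin_width: float = 25.0
    # habitats
    k: int | str = "auto"  # "auto" -> Calinski-Harabasz selection
    k_range: tuple[int, int] = (2, 6)
    k_vote_lesions: int = 10
    # selection
    icc_enabled: bool = True
    icc_threshold: float = 0.85
    ttest_alpha: float = 0.05
    corr_threshold: float = 0.9
    mrmr_m: int = 8
    lasso_folds: int = 10
    # modeling
    cv_folds: int = 5
    grid_search: bool = True  # False -> single default hyperparameter setting
    families: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_FAMILIES))
    signatures: tuple[str, ...] = ALL_SIGNATURES
    # bookkeeping
    seed: int = 17
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = yaml.safe_dump(_config_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_to_dict(cfg: RunConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("spacing_mm", "target_spacing", "window", "ring_mm", "k_range",
                "signatures"):
        d[key] = list(d[key])
    return d


def config_from_dict(d: dict) -> RunConfig:
    kwargs = dict(d)
    for key in ("spacing_mm", "target_spacing", "window", "ring_mm", "k_range",
                "signatures"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


@dataclass
class PipelineResult:
    """Everything a run produces, for reporting and replay checks."""

    config: RunConfig
    n_clusters: int
    selected_features: dict[str, list[str]]
    traces: dict[str, SelectionTrace]
    models: dict[str, SignatureModel]
    report_train: EvaluationReport
    report_test: EvaluationReport
    test_probs: dict[str, np.ndarray]
    train_probs: dict[str, np.ndarray]
    feature_table_train: pd.DataFrame
    feature_table_test: pd.DataFrame
    train_labels: np.ndarray
    test_labels: np.ndarray
    screening: object | None = None
    timings: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# per-lesion stages


def _preprocess_phase(image, mask, lung, cfg: RunConfig):
    img = resample_isotropic(image, cfg.target_spacing, mode="bspline")
    img = window_scale(img, *cfg.window)
    m = resample_isotropic(mask, cfg.target_spacing, mode="nearest")
    lg = resample_isotropic(lung, cfg.target_spacing, mode="nearest")
    return img, m, lg


def _perturb_mask(mask: MaskVolume, rng: np.random.Generator) -> MaskVolume:
    """One-voxel morphological jitter emulating a second rater's contour."""
    op = rng.integers(0, 2)
    if op == 0:
        new = ndimage.binary_dilation(mask.values)
    else:
        new = ndimage.binary_erosion(mask.values)
        if new.sum() < 8:
            new = mask.values
    return mask.with_values(new)


def _needed_regions(cfg: RunConfig) -> tuple[bool, list[tuple[float, str]], bool]:
    sigs = set(cfg.signatures)
    need_intra = "Intra" in sigs
    rings = []
    if "Peri5" in sigs or "HabitatPeri5" in sigs:
        rings.append((cfg.ring_mm[0], "peri5"))
    if "Peri10" in sigs:
        rings.append((cfg.ring_mm[1], "peri10"))
    need_habitat = "Habitat" in sigs or "HabitatPeri5" in sigs
    return need_intra, rings, need_habitat


def _lesion_features(case: LesionCase, cfg: RunConfig, n_clusters: int,
                     lesion_seed: int, with_perturbed: bool):
    """Fused pre+post feature row (and optionally the perturbed re-test row)."""
    rng = np.random.default_rng(lesion_seed)
    need_intra, rings, need_habitat = _needed_regions(cfg)
    phases = {}
    perturbed_phases = {}

    def _region_feats(img, roi, lung):
        feats: dict[str, float] = {}
        if need_intra:
            feats.update({f"intra.{k}": v for k, v in
                          extract_features(img, roi, cfg.bin_width).items()})
        for thick, tag in rings:
            ring = dilate_ring(roi, RingSpec(thickness_mm=thick), lung=lung)
            peri = roi.with_values(roi.values | ring.values)
            feats.update({f"{tag}.{k}": v for k, v in
                          extract_features(img, peri, cfg.bin_width).items()})
        return feats

    for phase, image, roi_mask in (
        ("pre", case.pre_image, case.tumor_mask),
        ("post", case.post_image, case.ablation_mask),
    ):
        img, roi, lung = _preprocess_phase(image, roi_mask, case.lung_mask, cfg)
        feats = _region_feats(img, roi, lung)
        if need_habitat:
            try:
                blocks = hb.block_features(img, roi)
                k_eff = min(n_clusters, blocks.n_blocks)
                hmap = hb.cluster_habitats(blocks, k_eff, seed=lesion_seed,
                                           roi=roi)
            except ValueError:
                hmap = hb.HabitatMap(labels=roi.values.astype(np.int64),
                                     n_clusters=1)
            hfeats = hb.habitat_features(img, hmap, bin_width=cfg.bin_width)
            for lab in range(hmap.n_clusters + 1, n_clusters + 1):
                for name in list(hfeats):
                    if name.startswith("habitat1."):
                        hfeats[f"habitat{lab}.{name[len('habitat1.'):]}"] = np.nan
            feats.update(hfeats)
        phases[phase] = feats

        if with_perturbed and (need_intra or rings):
            roi_p = _perturb_mask(roi, rng)
            perturbed_phases[phase] = _region_feats(img, roi_p, lung)

    row = fuse_phases(phases["pre"], phases["post"])
    prow = (fuse_phases(perturbed_phases["pre"], perturbed_phases["post"])
            if perturbed_phases else None)
    return row, prow


def _choose_k(cases: list[LesionCase], cfg: RunConfig) -> int:
    """Cluster count: fixed, or Calinski-Harabasz majority vote over lesions."""
    if cfg.k != "auto":
        return int(cfg.k)
    votes = []
    rng = np.random.default_rng(cfg.seed + 1)
    sample = list(rng.permutation(len(cases))[: cfg.k_vote_lesions])
    for i in sample:
        case = cases[i]
        for phase, image, roi_mask in (
            ("pre", case.pre_image, case.tumor_mask),
            ("post", case.post_image, case.ablation_mask),
        ):
            img, roi, _ = _preprocess_phase(image, roi_mask, case.lung_mask, cfg)
            try:
                blocks = hb.block_features(img, roi)
            except ValueError:
                continue
            lo, hi = cfg.k_range
            hi = min(hi, blocks.n_blocks - 1)
            if hi < lo:
                continue
            votes.append(hb.select_k(blocks.vectors, range(lo, hi + 1),
                                     seed=cfg.seed))
    if not votes:
        return cfg.latent_subregions
    vals, counts = np.unique(votes, return_counts=True)
    return int(vals[np.argmax(counts)])


# ---------------------------------------------------------------------------
# cohort-level selection + modeling


def _clean_table(train: pd.DataFrame, *others: pd.DataFrame):
    """Drop mostly-missing columns; median-impute the rest (train-fitted)."""
    frac = train.isna().mean()
    keep = frac[frac < 0.3].index
    train = train[keep]
    med = train.median()
    train = train.fillna(med)
    out = [train]
    for o in others:
        out.append(o[keep].fillna(med))
    return out


_POOL_PREFIXES = {
    "Intra": (".intra.",),
    "Peri5": (".peri5.",),
    "Peri10": (".peri10.",),
    "Habitat": (".habitat",),
}


def _pool_columns(table: pd.DataFrame, signature: str) -> list[str]:
    prefixes = _POOL_PREFIXES[signature]
    return [c for c in table.columns if any(p in c for p in prefixes)]


def _select_pool(
    name: str,
    train_z: pd.DataFrame,
    y_train: np.ndarray,
    cfg: RunConfig,
    icc_values: dict[str, float] | None,
) -> tuple[list[str], SelectionTrace]:
    """ICC -> t-test -> correlation pruning -> mRMR -> LASSO for one pool."""
    trace = SelectionTrace()
    cols = list(train_z.columns)

    if icc_values is not None and name != "Habitat":
        kept = [c for c in cols if icc_values.get(c, 0.0) >= cfg.icc_threshold]
        trace.add("icc", cols, kept)
        cols = kept
    if not cols:
        return [], trace

    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        kept, pvals = ttest_filter(train_z[cols], y_train, alpha=cfg.ttest_alpha)
    trace.add("ttest", cols, kept, {"p": pvals})
    cols = kept
    if not cols:
        return [], trace

    kept = corr_prune(train_z[cols], threshold=cfg.corr_threshold)
    trace.add("corr_prune", cols, kept)
    cols = kept
    if not cols:
        return [], trace

    kept = mrmr_select(train_z[cols], y_train, m=cfg.mrmr_m)
    trace.add("mrmr", cols, kept)
    cols = kept

    folds = min(cfg.lasso_folds, len(y_train) - 1, int(y_train.sum()),
                int((1 - y_train).sum()))
    folds = max(folds, 2)
    kept, coef, lam = lasso_select(train_z[cols], y_train, folds=folds,
                                   seed=cfg.seed)
    trace.add("lasso", cols, kept,
              {"lambda": lam, "coef": coef.to_dict()})
    return kept, trace


def run_analysis(
    cases: list[LesionCase],
    cfg: RunConfig,
    presplit: tuple[list[LesionCase], list[LesionCase]] | None = None,
) -> PipelineResult:
    """Run preprocessing, habitats, features, selection, modeling and
    evaluation on an existing cohort.

    ``presplit`` bypasses the internal train/test split (useful for audits
    and for feeding an externally defined partition).
    """
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    if presplit is not None:
        train_cases, test_cases = presplit
    else:
        train_cases, test_cases = split_cohort(cases, cfg.ratio_train,
                                               seed=cfg.seed)
    y_train = np.array([1 if c.label == "nonCR" else 0 for c in train_cases])
    y_test = np.array([1 if c.label == "nonCR" else 0 for c in test_cases])
    if y_train.sum() < 2 or (1 - y_train).sum() < 2:
        raise ValueError(
            "training set needs at least 2 lesions of each outcome class; "
            "increase the cohort size or prevalence"
        )
    timings["split"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    n_clusters = _choose_k(train_cases, cfg)
    timings["select_k"] = time.perf_counter() - t0
    logger.info("habitat cluster count K=%d", n_clusters)

    t0 = time.perf_counter()
    rows_train, rows_pert, ids_train = [], [], []
    for i, case in enumerate(train_cases):
        lesion_seed = (cfg.seed * 1000003 + i * 7919 + 13) % (2**31 - 1)
        try:
            row, prow = _lesion_features(case, cfg, n_clusters, lesion_seed,
                                         with_perturbed=cfg.icc_enabled)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for lesion {case.lesion_id}"
            ) from exc
        rows_train.append(row)
        rows_pert.append(prow)
        ids_train.append(case.lesion_id or f"train{i}")
    rows_test, ids_test = [], []
    for i, case in enumerate(test_cases):
        lesion_seed = (cfg.seed * 1000003 + (10000 + i) * 7919 + 13) % (2**31 - 1)
        try:
            row, _ = _lesion_features(case, cfg, n_clusters, lesion_seed,
                                      with_perturbed=False)
        except Exception as exc:
            raise RuntimeError(
                f"feature extraction failed for lesion {case.lesion_id}"
            ) from exc
        rows_test.append(row)
        ids_test.append(case.lesion_id or f"test{i}")
    F_train = pd.DataFrame(rows_train, index=ids_train)
    F_test = pd.DataFrame(rows_test, index=ids_test)
    F_train, F_test = _clean_table(F_train, F_test)
    timings["features"] = time.perf_counter() - t0

    # ICC on training lesions only (perturbed re-extraction as second rater)
    icc_values: dict[str, float] | None = None
    if cfg.icc_enabled and rows_pert[0] is not None:
        t0 = time.perf_counter()
        F_pert = pd.DataFrame(rows_pert, index=ids_train)
        common = [c for c in F_train.columns if c in F_pert.columns]
        _, icc_values = icc_filter(F_train[common], F_pert[common],
                                   threshold=cfg.icc_threshold)
        timings["icc"] = time.perf_counter() - t0

    # train-fitted z-scoring, applied unchanged to the test table
    scaler = ZScorer().fit(F_train)
    Z_train = scaler.transform(F_train)
    Z_test = scaler.transform(F_test)

    t0 = time.perf_counter()
    selected: dict[str, list[str]] = {}
    traces: dict[str, SelectionTrace] = {}
    for name in ("Intra", "Peri5", "Peri10", "Habitat"):
        if name not in cfg.signatures and not (
            name in ("Peri5", "Habitat") and "HabitatPeri5" in cfg.signatures
        ):
            continue
        pool = _pool_columns(Z_train, name)
        feats, trace = _select_pool(name, Z_train[pool], y_train, cfg, icc_values)
        selected[name] = feats
        traces[name] = trace
    if "HabitatPeri5" in cfg.signatures:
        union = list(dict.fromkeys(selected.get("Habitat", []) +
                                   selected.get("Peri5", [])))
        selected["HabitatPeri5"] = union
    timings["selection"] = time.perf_counter() - t0

    # clinical screen
    screening = None
    if "Clinical" in cfg.signatures:
        t0 = time.perf_counter()
        clin_train = encode_clinical([c.clinical for c in train_cases])
        clin_test = encode_clinical([c.clinical for c in test_cases])
        clin_train.index = ids_train
        clin_test.index = ids_test
        screening = multivariate_screen(clin_train, y_train)
        clin_feats = screening.retained or screening.candidates
        selected["Clinical"] = clin_feats
        cscaler = ZScorer().fit(clin_train)
        C_train = cscaler.transform(clin_train)
        C_test = cscaler.transform(clin_test)
        timings["screening"] = time.perf_counter() - t0

    # signatures
    t0 = time.perf_counter()
    models: dict[str, SignatureModel] = {}
    train_probs: dict[str, np.ndarray] = {}
    test_probs: dict[str, np.ndarray] = {}
    for name in cfg.signatures:
        feats = selected.get(name, [])
        if name == "Clinical":
            tab_train, tab_test = C_train[feats], C_test[feats]
        else:
            tab_train, tab_test = Z_train[feats], Z_test[feats]
        family = cfg.families.get(name, "lr")
        grid = None if cfg.grid_search else "first"
        model = fit_signature(tab_train, y_train, family=family, grid=grid,
                              folds=cfg.cv_folds, seed=cfg.seed, name=name)
        models[name] = model
        train_probs[name] = model.train_probs
        test_probs[name] = predict(model, tab_test)
    timings["modeling"] = time.perf_counter() - t0

    # evaluation
    t0 = time.perf_counter()
    report_train, report_test = EvaluationReport(), EvaluationReport()
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", UserWarning)
        for name in cfg.signatures:
            thr = models[name].threshold
            if len(np.unique(y_train)) == 2:
                report_train.add_signature(name, train_probs[name], y_train,
                                           threshold=thr)
            if len(np.unique(y_test)) == 2:
                report_test.add_signature(name, test_probs[name], y_test,
                                          threshold=thr)
    if len(np.unique(y_test)) == 2:
        names = list(cfg.signatures)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                report_test.add_delong(names[i], names[j],
                                       test_probs[names[i]],
                                       test_probs[names[j]], y_test)
    timings["evaluation"] = time.perf_counter() - t0

    return PipelineResult(
        config=cfg, n_clusters=n_clusters, selected_features=selected,
        traces=traces, models=models, report_train=report_train,
        report_test=report_test, test_probs=test_probs,
        train_probs=train_probs, feature_table_train=F_train,
        feature_table_test=F_test, train_labels=y_train, test_labels=y_test,
        screening=screening, timings=timings,
    )


def run_all(cfg: RunConfig) -> PipelineResult:
    """Generate a synthetic cohort from the config and analyse it."""
    t0 = time.perf_counter()
    _, rings, _ = _needed_regions(cfg)
    max_ring = max((t for t, _ in rings), default=cfg.ring_mm[0])
    cohort = generate_cohort(CohortConfig(
        n_lesions=cfg.n_lesions,
        noncr_prevalence=cfg.noncr_prevalence,
        spacing_mm=cfg.spacing_mm,
        latent_subregions=cfg.latent_subregions,
        effect_sizes=cfg.effect_sizes,
        max_ring_mm=max_ring,
        seed=cfg.seed,
    ))
    result = run_analysis(cohort, cfg)
    result.timings["total"] = time.perf_counter() - t0
    if cfg.outdir:
        _write_artifacts(result, Path(cfg.outdir))
    return result


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=True)
    result.report_train.to_json(outdir / "report_train.json")
    result.report_test.to_json(outdir / "report_test.json")
    result.report_test.summary_table().to_csv(outdir / "summary_test.csv",
                                              index=False)
    result.report_train.summary_table().to_csv(outdir / "summary_train.csv",
                                               index=False)
    with open(outdir / "selected_features.txt", "w") as fh:
        for name, feats in result.selected_features.items():
            fh.write(f"[{name}]\n")
            for f in feats:
                fh.write(f"{f}\n")
            fh.write("\n")
    with open(outdir / "selection_trace.json", "w") as fh:
        json.dump({k: v.to_dict() for k, v in result.traces.items()},
                  fh, indent=2, default=float)
    provenance = {
        "config_hash": cfg.config_hash(),
        "n_clusters": result.n_clusters,
        "timings_s": result.timings,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2)
    result.feature_table_train.to_csv(outdir / "features_train.csv")
    result.feature_table_test.to_csv(outdir / "features_test.csv")
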