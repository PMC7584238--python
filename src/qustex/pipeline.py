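"""End-to-end orchestration: simulate -> extract -> classify -> report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from qustex import __version__
from qustex.config import PipelineConfig
from qustex.glcm_texture import (
    FeatureVector,
    GLCMConfig,
    QUS_BASES,
    TEXTURE_FEATURES,
    assemble_feature_vector,
    texture_derivatives,
    texture_map,
    texture_scalar,
)
from qustex.parametric_maps import (
    MAP_NAMES,
    build_parametric_maps,
    plan_subrois,
    volume_mean,
)
from qustex.phantom_sim import (
    ClassParams,
    ReferencePhantom,
    RFVolume,
    SimulatedTumor,
    generate_cohort,
    generate_reference,
)
from qustex.response_model import (
    CohortTable,
    aggregate_subsets,
    balanced_subsets,
    classifier_factory,
    loocv_evaluate,
)

log = logging.getLogger("qustex")

FEATURE_SETS = ("tex1", "tex2")  # QUS+Tex1 (25) vs QUS+Tex1+Tex1-Tex2 (105)
CLASSIFIERS = ("fld", "knn", "svm")


class StageError(RuntimeError):
    """Pipeline failure tagged with the failing stage (and patient, if any)."""

    def __init__(self, stage: str, message: str, patient: str | None = None):
        self.stage = stage
        self.patient = patient
        tag = f"[{stage}]" + (f" patient={patient}" if patient else "")
        super().__init__(f"{tag} {message}")


@dataclass
class ExtractionResult:
    features: FeatureVector
    frame_maps: list  # per frame: dict[name, ParametricMap] | None
    texture_maps: list = field(default_factory=list)  # per frame: dict[name, TextureMap]


def _mean_over_frames(per_frame: list[dict[str, float]]) -> dict[str, float]:
    """Equal-weight average of per-frame scalars, ignoring NaN frames."""
    out: dict[str, float] = {}
    if not per_frame:
        return out
    keys = per_frame[0].keys()
    for key in keys:
        vals = np.array([d[key] for d in per_frame], dtype=float)
        ok = np.isfinite(vals)
        out[key] = float(vals[ok].mean()) if ok.any() else float("nan")
    return out


def extract_features(
    rf: RFVolume,
    masks: list[np.ndarray],
    reference: ReferencePhantom,
    config: PipelineConfig,
    patient: str | None = None,
) -> ExtractionResult:
    """Per-patient extraction: parametric maps, first-pass texture scalars and
    maps, second-pass texture derivatives, assembled into the 105-entry
    feature vector."""
    config.validate()
    pulse = config.acquisition.pulse()
    glcm_cfg = GLCMConfig(
        levels=config.glcm.levels,
        distances=tuple(config.glcm.distances),
        angles=tuple(config.glcm.angles),
        symmetric=config.glcm.symmetric,
    )
    try:
        grid = plan_subrois(
            masks, pulse, rf,
            overlap=config.subroi.overlap, inclusion=config.subroi.inclusion,
        )
        if grid.is_empty:
            raise ValueError("ROI smaller than one analysis window")
        frame_maps = build_parametric_maps(
            rf, masks, grid, reference,
            band=tuple(config.acquisition.band),
            center=config.acquisition.center_frequency,
        )
    except ValueError as exc:
        raise StageError("parametric_maps", str(exc), patient) from exc

    qus_means = {name: volume_mean(frame_maps, name) for name in MAP_NAMES}

    tex1_frames: list[dict[str, float]] = []
    tex2_frames: list[dict[str, float]] = []
    texmaps_per_frame = []
    for maps in frame_maps:
        if maps is None:
            continue
        tex1 = {}
        frame_texmaps = {}
        for base in QUS_BASES:
            scalars = texture_scalar(maps[base].values, glcm_cfg)
            for feat in TEXTURE_FEATURES:
                tex1[f"{base}-{feat}"] = scalars[feat]
            tmaps = texture_map(
                maps[base].values, glcm_cfg,
                neighborhood=config.glcm.neighborhood, step=config.glcm.step,
                parent=base,
            )
            for tm in tmaps.values():
                frame_texmaps[tm.name] = tm
        if len(frame_texmaps) != 20:
            raise StageError(
                "glcm_texture", f"expected 20 texture maps, got {len(frame_texmaps)}",
                patient,
            )
        tex1_frames.append(tex1)
        tex2_frames.append(texture_derivatives(frame_texmaps, glcm_cfg))
        texmaps_per_frame.append(frame_texmaps)
    if not tex1_frames:
        raise StageError("glcm_texture", "no frames with usable maps", patient)

    tex1 = _mean_over_frames(tex1_frames)
    tex2 = _mean_over_frames(tex2_frames)
    try:
        fv = assemble_feature_vector(qus_means, tex1, tex2)
    except ValueError as exc:
        raise StageError("feature_vector", str(exc), patient) from exc
    return ExtractionResult(features=fv, frame_maps=frame_maps,
                            texture_maps=texmaps_per_frame)


def run_extract(
    rf: RFVolume,
    masks: list[np.ndarray],
    reference: ReferencePhantom,
    config: PipelineConfig,
    patient: str = "patient",
) -> FeatureVector:
    return extract_features(rf, masks, reference, config, patient).features


def simulate_cohort(config: PipelineConfig, seed: int | None = None
                    ) -> tuple[list[SimulatedTumor], ReferencePhantom]:
    """Synthetic two-class cohort plus a matched reference phantom."""
    config.validate()
    if seed is None:
        seed = config.seed
    sim = config.sim
    pulse = config.acquisition.pulse()
    class_params = {
        "R": ClassParams(sim.responder_radius_um, sim.responder_density_mm2,
                         sim.responder_amplitude_cv),
        "NR": ClassParams(sim.nonresponder_radius_um, sim.nonresponder_density_mm2,
                          sim.nonresponder_amplitude_cv),
    }
    cohort = generate_cohort(
        sim.n_per_class, class_params, noise=sim.noise, seed=seed,
        pulse=pulse, n_lines=sim.n_lines,
        line_spacing=config.acquisition.line_spacing,
        extent_axial=sim.extent_axial, n_frames=sim.n_frames,
    )
    reference = generate_reference(
        pulse, n_lines=max(64, sim.n_lines),
        line_spacing=config.acquisition.line_spacing,
        seed=seed + 99991, extent_axial=sim.extent_axial + 0.004,
    )
    return cohort, reference


def extract_cohort(
    cohort: list[SimulatedTumor],
    reference: ReferencePhantom,
    config: PipelineConfig,
) -> CohortTable:
    """Extraction for every patient; failures are skipped and logged."""
    import pandas as pd

    from qustex.glcm_texture import feature_names

    records = []
    for i, tumor in enumerate(cohort):
        pid = f"p{i:03d}"
        try:
            fv = run_extract(tumor.rf, tumor.masks, reference, config, patient=pid)
        except StageError as exc:
            log.error("extraction failed: %s", exc)
            continue
        rec = {"id": pid, "label": tumor.label}
        rec.update(fv.values)
        records.append(rec)
    if not records:
        raise StageError("extract", "no patients extracted")
    df = pd.DataFrame(records, columns=["id", "label"] + feature_names())
    return CohortTable(df)


def feature_set_columns(table: CohortTable, which: str) -> list[str]:
    """'tex1' -> QUS + first-pass (25 cols); 'tex2' -> all 105."""
    if which == "tex1":
        return [c for c in table.feature_columns if len(c.split("-")) <= 2]
    if which == "tex2":
        return list(table.feature_columns)
    raise ValueError(f"unknown feature set {which!r}")


def classify_cohort(
    table: CohortTable,
    config: PipelineConfig,
    classifier: str,
    feature_set: str = "tex2",
    seed: int | None = None,
) -> dict:
    """Balanced subsets -> LOOCV per subset -> aggregated evaluation panel."""
    config.validate()
    if seed is None:
        seed = config.seed
    n0, n1 = table.class_counts()
    if n0 == 0 or n1 == 0:
        raise StageError("classify", "classification needs both labels present")
    params: dict = {}
    if classifier == "knn":
        params = {"k": config.classifier.knn_k}
    elif classifier == "svm":
        params = {"C": config.classifier.svm_C, "gamma": config.classifier.svm_gamma}
    factory = classifier_factory(classifier, **params)
    candidates = feature_set_columns(table, feature_set)
    subsets = balanced_subsets(table, config.classifier.n_subsets, seed=seed)
    results = []
    for subset in subsets:
        results.append(
            loocv_evaluate(
                subset, factory, candidate_features=candidates,
                selection_policy=config.classifier.selection_mode,
                max_features=config.classifier.max_features,
            )
        )
    agg = aggregate_subsets(results, rule="mean")
    return {
        "classifier": classifier,
        "feature_set": feature_set,
        "selection_mode": config.classifier.selection_mode,
        "seed": seed,
        "config_hash": config.hash(),
        "version": __version__,
        "panel": agg.panel(),
        "selected_features": agg.selected_features,
        "per_subset": [
            {**r.panel(), "selected_features": r.selected_features} for r in results
        ],
    }


def run_cohort(
    cohort: list[SimulatedTumor],
    reference: ReferencePhantom,
    config: PipelineConfig,
) -> tuple[CohortTable, dict]:
    """Full pipeline on an in-memory cohort: extraction plus all six panels
    (3 classifiers x 2 feature sets)."""
    if len(cohort) < 4:
        raise StageError("cohort", "need >= 4 patients")
    table = extract_cohort(cohort, reference, config)
    n0, n1 = table.class_counts()
    reports: dict = {"config_hash": config.hash(), "seed": config.seed, "panels": []}
    if n0 == 0 or n1 == 0:
        log.error("single-class cohort: classification refused, features emitted")
        return table, reports
    for clf in CLASSIFIERS:
        for fset in FEATURE_SETS:
            reports["panels"].append(classify_cohort(table, config, clf, fset))
    return table, reports


def provenance(config: PipelineConfig, seed: int) -> dict:
    return {"config_hash": config.hash(), "seed": seed, "version": __version__,
            "config": config.to_dict()}


def write_provenance(path: str | Path, config: PipelineConfig, seed: int) -> None:
    from qustex.io import write_json

    write_json(path, provenance(config, seed))
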