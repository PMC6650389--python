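"""End-to-end orchestration of the screening pipeline.

``run_screen`` executes simulate -> (segment -> features -> classify) ->
profile -> screen -> cluster/enrich from a single validated
:class:`RunConfig`, writing every intermediate artifact as flat CSV/JSON
(and TIFF when frames are rendered) plus a machine-readable run manifest
with config hash, seeds, per-stage output checksums and timing.  Rerunning
the same config reproduces the outputs bit-for-bit.

Two imaging modes exist: ``render=True`` draws pixels and pushes them through
segmentation + feature extraction + classification (the full image pipeline,
intended for demonstration-sized screens), while ``render=False`` uses the
generator's per-cell labels directly (for large calibration screens).  Well
and time indices are 0-based internally and 1-based in human-facing reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import label_cells, train_classifiers
from .clustering import select_k_by_silhouette
from .enrichment import fisher_enrichment
from .features import features_table
from .io import plsda_to_json, reference_to_json, simca_to_json, write_frame, write_ground_truth
from .outliers import empirical_limits, fit_reference, flag, score_many
from .profiling import (
    PROFILE_COLUMNS,
    batch_correct,
    build_profiles,
    qc_wells,
    summaries_from_counts,
    summarize_well,
)
from .segmentation import SegmentationConfig, label_image, segment_frame
from .simca import DEFAULT_COMPONENTS
from .synth import simulate_screen
from .training import labeled_cell_features

__all__ = ["RunConfig", "ScreenConfig", "validate_config", "run_screen"]


@dataclass(frozen=True)
class ScreenConfig:
    n_strains: int = 12
    n_wt_replicates: int = 36
    plates: int = 3
    timepoints: int = 3
    effect_spec: dict = field(default_factory=lambda: {"slow_lysis": 2, "stable_bulge": 2})
    mean_density: float = 40.0
    render: bool = False
    image_height: int = 512
    image_width: int = 512


@dataclass(frozen=True)
class ClassifierConfig:
    n_components: int = 3
    alpha: float = 0.05
    k_by_class: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    training_counts: dict = field(
        default_factory=lambda: {
            "normal": 120,
            "elongated": 80,
            "round": 80,
            "small": 80,
            "deformed": 80,
            "lysed": 240,
        }
    )


@dataclass(frozen=True)
class OutlierConfig:
    k_rule: float = 0.90
    flag_percentile: float = 99.0


@dataclass(frozen=True)
class ClusterConfig:
    k_min: int = 2
    k_max: int = 8
    n_restarts: int = 50


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    out_dir: str = "screen_run"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    outliers: OutlierConfig = field(default_factory=OutlierConfig)
    clustering: ClusterConfig = field(default_factory=ClusterConfig)


_SECTIONS = {
    "screen": ScreenConfig,
    "segmentation": SegmentationConfig,
    "classifier": ClassifierConfig,
    "outliers": OutlierConfig,
    "clustering": ClusterConfig,
}


def config_from_dict(d: dict) -> RunConfig:
    """Build a RunConfig from a (YAML-loaded) mapping; unknown keys raise."""
    d = dict(d or {})
    kwargs: dict = {}
    for key in ("seed", "out_dir"):
        if key in d:
            kwargs[key] = d.pop(key)
    for name, cls in _SECTIONS.items():
        if name in d:
            sub = dict(d.pop(name))
            known = {f.name for f in dataclasses.fields(cls)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown key(s) in section {name!r}: {sorted(unknown)}")
            kwargs[name] = cls(**sub)
    if d:
        raise ValueError(f"unknown top-level config key(s): {sorted(d)}")
    return RunConfig(**kwargs)


def config_from_yaml(path: str | Path) -> RunConfig:
    import yaml

    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def validate_config(config: RunConfig) -> list[str]:
    """Cross-field checks; returns a list of human-readable problems."""
    errors: list[str] = []
    sc = config.screen
    if sc.n_strains < 1:
        errors.append("screen.n_strains must be >= 1")
    if sum(sc.effect_spec.values()) > sc.n_strains:
        errors.append("screen.effect_spec assigns more strains than n_strains")
    if sc.timepoints != 3:
        errors.append(
            f"screen.timepoints={sc.timepoints}: profiles require exactly 3 time-points"
        )
    if config.segmentation.tophat_radius <= 0:
        errors.append("segmentation.tophat_radius must be positive")
    for cls, k in config.classifier.k_by_class.items():
        if k < 1:
            errors.append(f"classifier.k_by_class[{cls!r}] must be a positive component count")
    if config.classifier.n_components < 1:
        errors.append("classifier.n_components must be >= 1")
    if not 0 < config.outliers.k_rule:
        errors.append("outliers.k_rule must be positive")
    if not 2 <= config.clustering.k_min <= config.clustering.k_max:
        errors.append("clustering needs 2 <= k_min <= k_max")
    return errors


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_screen(config: RunConfig, write_frames: bool = False) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    Returns a summary dict (also serialized as ``manifest.json``).  Raises on
    invalid configuration or missing stage inputs before any compute starts.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    artifacts: dict[str, Path] = {}

    def _stage_done(name: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][name] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }

    sc = config.screen
    rng_seed = config.seed

    # --- stage: simulate -------------------------------------------------
    t0 = time.time()
    frames, truth = simulate_screen(
        sc.n_strains,
        n_wt_replicates=sc.n_wt_replicates,
        plates=sc.plates,
        timepoints=sc.timepoints,
        effect_spec=dict(sc.effect_spec),
        rng=rng_seed,
        mean_density=sc.mean_density,
        render=sc.render,
        image_shape=(sc.image_height, sc.image_width),
    )
    truth.wells.to_csv(out / "ground_truth_wells.csv", index=False)
    truth.strains.to_csv(out / "strains.csv", index=False)
    truth.cog.to_csv(out / "cog_labels.csv", index=False)
    files = [out / "ground_truth_wells.csv", out / "strains.csv", out / "cog_labels.csv"]
    if sc.render:
        gt = write_ground_truth(frames, out / "ground_truth_cells.csv")
        files.append(out / "ground_truth_cells.csv")
        if write_frames:
            for frame in frames:
                write_frame(frame, out / "frames")
    _stage_done("simulate", t0, files)

    # --- stages: segment + features + classify (rendered mode only) ------
    if sc.render:
        t0 = time.time()
        clf_rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]))
        Xtr, ytr = labeled_cell_features(dict(config.classifier.training_counts), rng=clf_rng)
        clf = train_classifiers(
            Xtr,
            ytr,
            n_components=config.classifier.n_components,
            k_by_class=dict(config.classifier.k_by_class),
            alpha=config.classifier.alpha,
        )
        plsda_to_json(clf.plsda, out / "plsda_model.json")
        simca_to_json(clf.simca, out / "simca_model.json")
        _stage_done("train_classifiers", t0, [out / "plsda_model.json", out / "simca_model.json"])

        t0 = time.time()
        from .features import FEATURE_NAMES

        tables = []
        for frame in frames:
            records = segment_frame(frame.image, config.segmentation, frame_ref=frame.meta)
            li = label_image(records, frame.image.shape)
            tables.append(features_table(records, frame.image, li, frame_meta=frame.meta))
        feat = pd.concat([t for t in tables if len(t)], ignore_index=True)
        feat.to_csv(out / "cell_features.csv", index=False)
        _stage_done("segment_features", t0, [out / "cell_features.csv"])

        t0 = time.time()
        feat["label"] = label_cells(clf, feat[list(FEATURE_NAMES)].to_numpy())
        feat.to_csv(out / "cell_labels.csv", index=False)
        summaries = pd.DataFrame(
            [
                summarize_well(
                    grp["label"].to_numpy(),
                    strain_id=strain,
                    plate_id=plate,
                    timepoint=tp,
                )
                for (strain, plate, tp), grp in feat.groupby(
                    ["strain_id", "plate_id", "timepoint"]
                )
            ]
        )
        _stage_done("classify", t0, [out / "cell_labels.csv"])
    else:
        summaries = summaries_from_counts(truth.wells)

    # --- stage: profile (QC -> 18-dim profiles -> batch correction) ------
    t0 = time.time()
    if sc.timepoints != 3:
        raise ValueError(f"expected 3 time-points for profiles, got {sc.timepoints}")
    qc = qc_wells(truth.wells)
    qc.to_csv(out / "qc_report.csv", index=False)
    passing = set(qc.loc[qc["pass"], "strain_id"])
    summaries = summaries[summaries["strain_id"].isin(passing)]
    profiles = build_profiles(summaries)
    profiles.to_csv(out / "profiles_raw.csv", index=False)
    corrected = batch_correct(profiles)
    corrected.to_csv(out / "profiles_corrected.csv", index=False)
    _stage_done(
        "profile",
        t0,
        [out / "qc_report.csv", out / "profiles_raw.csv", out / "profiles_corrected.csv"],
    )

    # --- stage: screen (reference model, T2/SPE, flags) -------------------
    t0 = time.time()
    merged = corrected.merge(truth.strains[["strain_id", "archetype"]], on="strain_id")
    wt = merged[merged["archetype"] == "wt"]
    mut = merged[merged["archetype"] != "wt"]
    ref = fit_reference(wt, k_rule=config.outliers.k_rule, min_profiles=min(30, len(wt)))
    reference_to_json(ref, out / "reference_model.json")
    limits = empirical_limits(*score_many(ref, wt))
    t2, spe = score_many(ref, mut)
    results = flag(
        t2,
        spe,
        limits,
        percentile=config.outliers.flag_percentile,
        strain_ids=mut["strain_id"].to_numpy(),
    )
    results.to_csv(out / "screen_results.csv", index=False)
    _stage_done("screen", t0, [out / "reference_model.json", out / "screen_results.csv"])

    # --- stage: cluster + enrichment --------------------------------------
    t0 = time.time()
    hits = results[results["hit"]]
    cluster_files = []
    summary_extra: dict = {}
    if len(hits) >= config.clustering.k_min + 1:
        hp = (
            corrected.set_index("strain_id")
            .loc[hits["strain_id"], list(PROFILE_COLUMNS)]
            .to_numpy()
        )
        cres = select_k_by_silhouette(
            hp,
            k_range=range(config.clustering.k_min, min(config.clustering.k_max, len(hits) - 1) + 1),
            n_restarts=config.clustering.n_restarts,
            rng=config.seed,
        )
        summary_extra["selected_k"] = cres.k
        if cres.k is not None:
            cl = pd.DataFrame(
                {
                    "strain_id": hits["strain_id"].to_numpy(),
                    "cluster": cres.assignment,
                    "silhouette": cres.silhouette,
                    "pc1": cres.embedding[:, 0],
                    "pc2": cres.embedding[:, 1],
                }
            )
            cl.to_csv(out / "clusters.csv", index=False)
            cluster_files.append(out / "clusters.csv")
            cog = truth.cog.set_index("strain_id")["categories"]
            common = [s for s in cl["strain_id"] if s in cog.index]
            if common:
                enrich = fisher_enrichment(
                    cl.set_index("strain_id")["cluster"].loc[common],
                    cog.loc[common],
                )
                enrich.to_csv(out / "enrichment.csv", index=False)
                cluster_files.append(out / "enrichment.csv")
    sil_curve = pd.DataFrame(
        {"k": list(summary_extra and cres.mean_silhouette_by_k or {}),
         "mean_silhouette": list((summary_extra and cres.mean_silhouette_by_k or {}).values())}
    )
    sil_curve.to_csv(out / "silhouette_curve.csv", index=False)
    cluster_files.append(out / "silhouette_curve.csv")
    _stage_done("cluster", t0, cluster_files)

    manifest["n_hits"] = int(results["hit"].sum())
    manifest["flag_breakdown"] = results["flag"].value_counts().to_dict()
    manifest["reference_k"] = ref.k
    manifest.update(summary_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
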