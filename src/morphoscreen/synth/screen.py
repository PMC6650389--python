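"""Whole-screen simulation with ground truth.

A screen is a set of strains laid out on plates, imaged at three time-points
after antibiotic addition.  Each strain follows a :class:`StrainTrajectory`:
the expected proportion of the six population categories (intact, normal,
round, elongated, small, deformed; lysed = 1 - intact) at every time-point.
The wild type lyses quickly — its intact fraction decays across the three
time-points while round/deformed cells transiently accumulate.  Mutant
archetypes perturb this curve in logit space:

``fast_lysis``
    lyses even faster than the wild type; extreme but preserves the
    wild-type correlation structure (a Hotelling-T2-type deviation).
``slow_lysis``
    intact fraction stays high at the late time-points; breaks the
    time-correlation of the profile (an SPE-type deviation).
``stable_bulge``
    round + deformed cells accumulate and persist (delayed lysis through
    stable mid-cell bulges).
``filament``
    elongated cells accumulate (division inhibited, cells filament).

Per-plate batch effects are injected as additive logit offsets, and every
well receives biological + technical logit noise shared by wild-type
replicates and mutants alike, so "null" mutants are statistically exchangeable
with wild-type control wells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CellGeometry, default_shape_params
from .render import Frame, NoiseParams, render_frame, scatter_cells

__all__ = [
    "CATEGORIES",
    "PARTITION",
    "StrainTrajectory",
    "ScreenTruth",
    "acquisition_policy",
    "wildtype_trajectory",
    "archetype_trajectory",
    "simulate_screen",
    "ARCHETYPES",
]

#: profile category order, frozen for golden files (intact first)
CATEGORIES = ("intact", "normal", "round", "elongated", "small", "deformed")
#: the exclusive per-cell partition used when drawing labels
PARTITION = ("lysed", "normal", "round", "elongated", "small", "deformed")

# wild-type category proportions at the three time-points (rows sum rule:
# intact = normal+round+elongated+small+deformed; lysed = 1 - intact)
_WT_CURVE = np.array(
    [
        # intact, normal, round, elong, small, deformed
        [0.88, 0.60, 0.02, 0.06, 0.08, 0.12],
        [0.45, 0.18, 0.05, 0.03, 0.04, 0.15],
        [0.15, 0.04, 0.035, 0.01, 0.015, 0.05],
    ]
)

# archetype logit offsets on the PARTITION axes, shape (T, 6)
_Z = [0.0, 0.0, 0.0]
ARCHETYPES: dict[str, dict[str, list[float]]] = {
    "fast_lysis": {"lysed": [1.2, 1.0, 0.8]},
    "slow_lysis": {"lysed": [-0.3, -2.0, -2.2]},
    "stable_bulge": {
        "round": [0.8, 1.8, 2.4],
        "deformed": [0.6, 1.2, 1.2],
        "lysed": [-0.2, -1.2, -1.6],
    },
    "filament": {"elongated": [1.8, 2.4, 2.4], "lysed": [-0.2, -1.0, -1.2]},
}

# time course of the per-well response-speed factor on the lysed logit:
# a fast well is further along the lysis curve at every time-point
_SPEED_PROFILE = np.array([0.6, 1.0, 0.8])

# planted functional-category enrichment used by the enrichment stage tests
_COG_POOL = tuple("JKLMNOFGPQU")
_ARCHETYPE_COG = {"slow_lysis": "L", "stable_bulge": "M", "filament": "O", "fast_lysis": "F"}


def acquisition_policy(pilot_cell_count: int) -> int:
    """Number of images to record in a well given the pilot-frame cell count.

    Sparse wells (fewer than 15 cells seen in the pilot image) get nine
    images so enough cells are collected for population statistics; denser
    wells get four.
    """
    if pilot_cell_count < 0:
        raise ValueError(f"pilot cell count must be >= 0, got {pilot_cell_count}")
    return 9 if pilot_cell_count < 15 else 4


@dataclass(frozen=True)
class StrainTrajectory:
    """Expected category proportions of one strain at each time-point."""

    strain_id: str
    plate_id: str
    curve: np.ndarray  # shape (T, 6) over CATEGORIES

    def __post_init__(self) -> None:
        c = np.asarray(self.curve, float)
        if c.ndim != 2 or c.shape[1] != len(CATEGORIES):
            raise ValueError(f"curve must be (T, {len(CATEGORIES)}), got {c.shape}")
        morph_sum = c[:, 1:].sum(axis=1)
        if not np.allclose(morph_sum, c[:, 0], atol=1e-8):
            raise ValueError("morphology proportions must sum to the intact proportion")
        if (c < -1e-12).any() or (c[:, 0] > 1 + 1e-12).any():
            raise ValueError("proportions must lie in [0, 1]")

    @property
    def n_timepoints(self) -> int:
        return self.curve.shape[0]

    def partition_probs(self) -> np.ndarray:
        """(T, 6) probabilities over the exclusive PARTITION (lysed first)."""
        c = self.curve
        return np.column_stack([1.0 - c[:, 0], c[:, 1:]])


def _to_logits(partition_probs: np.ndarray) -> np.ndarray:
    return np.log(np.clip(partition_probs, 1e-6, None))


def _from_logits(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _curve_from_partition(p: np.ndarray) -> np.ndarray:
    return np.column_stack([1.0 - p[:, 0], p[:, 1:]])


def wildtype_trajectory(strain_id: str = "WT", plate_id: str = "P1") -> StrainTrajectory:
    return StrainTrajectory(strain_id, plate_id, _WT_CURVE.copy())


def archetype_trajectory(
    archetype: str, strain_id: str | None = None, plate_id: str = "P1"
) -> StrainTrajectory:
    """Wild-type trajectory perturbed by one named archetype."""
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; expected one of {sorted(ARCHETYPES)}")
    logits = _to_logits(wildtype_trajectory().partition_probs())
    for cat, offs in ARCHETYPES[archetype].items():
        logits[:, PARTITION.index(cat)] += np.asarray(offs)
    curve = _curve_from_partition(_from_logits(logits))
    return StrainTrajectory(strain_id or archetype, plate_id, curve)


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen.

    ``wells`` holds one row per (strain, time-point) with the true per-class
    cell counts; ``strains`` maps strain_id to its archetype ("wt"/"null"/
    archetype name); ``trajectories`` are the noise-free expected curves;
    ``cog`` assigns synthetic functional-category letters per mutant strain.
    """

    wells: pd.DataFrame
    strains: pd.DataFrame  # strain_id, plate_id, archetype
    trajectories: dict[str, StrainTrajectory]
    plate_offsets: dict[str, np.ndarray]
    cog: pd.DataFrame  # strain_id, categories (string of letters)
    seed: int | None
    timepoints: int = 3


def _well_counts(
    probs_t: np.ndarray,
    rng: np.random.Generator,
    density: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-frame cell counts and per-class totals for one well/time-point."""
    pilot = int(rng.poisson(density))
    n_images = acquisition_policy(pilot)
    frame_counts = rng.poisson(density, size=n_images)
    n_cells = int(frame_counts.sum())
    counts = rng.multinomial(n_cells, probs_t) if n_cells > 0 else np.zeros(6, int)
    return frame_counts, counts


def simulate_screen(
    n_strains: int,
    n_wt_replicates: int = 276,
    plates: int = 3,
    timepoints: int = 3,
    effect_spec: dict[str, int] | None = None,
    rng: np.random.Generator | int | None = None,
    mean_density: float = 40.0,
    sigma_density: float = 0.45,
    sigma_well: float = 0.08,
    sigma_speed: float = 0.5,
    sigma_strain: float = 0.08,
    sigma_plate: float = 0.25,
    plate_offsets: dict[str, np.ndarray] | None = None,
    render: bool = False,
    image_shape: tuple[int, int] = (512, 512),
    noise_params: NoiseParams | None = None,
) -> tuple[list[Frame], ScreenTruth]:
    """Simulate a full multi-plate screen.

    ``n_strains`` mutant strains (one well each) plus ``n_wt_replicates``
    wild-type control wells are distributed round-robin over ``plates``
    plates.  ``effect_spec`` maps archetype names to the number of strains
    carrying that deviation; remaining strains are "null" (wild-type-like).

    Returns ``(frames, truth)``.  ``frames`` is empty unless ``render=True``
    (rendering is intended for small screens; the label-level ground truth in
    ``truth.wells`` is always complete).
    """
    if effect_spec is None:
        effect_spec = {}
    n_effect = sum(effect_spec.values())
    if n_effect > n_strains:
        raise ValueError("effect_spec assigns more strains than n_strains")
    if timepoints != 3:
        warnings.warn(
            f"timepoints={timepoints} != 3: phenotypic profiles will not have "
            "the standard 18 entries",
            stacklevel=2,
        )
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = int(rng) if rng is not None else None
        rng = np.random.default_rng(np.random.SeedSequence(seed))
    else:
        seed = None

    plate_ids = [f"P{i + 1}" for i in range(int(plates))]
    if plate_offsets is None:
        plate_offsets = {
            p: rng.normal(0.0, sigma_plate, size=len(PARTITION)) for p in plate_ids
        }

    base_logits = _to_logits(wildtype_trajectory().partition_probs())
    if timepoints != base_logits.shape[0]:
        # stretch/trim the 3-point curve to the requested grid
        idx = np.linspace(0, base_logits.shape[0] - 1, timepoints)
        base_logits = np.array(
            [
                [np.interp(i, np.arange(base_logits.shape[0]), base_logits[:, j])
                 for j in range(base_logits.shape[1])]
                for i in idx
            ]
        )

    # strain roster: archetypes first, then nulls, then WT replicates
    roster: list[tuple[str, str]] = []
    k = 0
    for arch, count in effect_spec.items():
        if arch not in ARCHETYPES:
            raise ValueError(f"unknown archetype {arch!r} in effect_spec")
        for _ in range(count):
            roster.append((f"mut{k:05d}", arch))
            k += 1
    for _ in range(n_strains - n_effect):
        roster.append((f"mut{k:05d}", "null"))
        k += 1
    for j in range(n_wt_replicates):
        roster.append((f"WT{j + 1:04d}", "wt"))

    arch_logit_offsets = {
        arch: np.array(
            [
                [spec.get(cat, _Z)[min(t, 2)] for cat in PARTITION]
                for t in range(timepoints)
            ]
        )
        for arch, spec in ((a, ARCHETYPES[a]) for a in ARCHETYPES)
    }

    rows = []
    frames: list[Frame] = []
    trajectories: dict[str, StrainTrajectory] = {}
    cog_rows = []
    shape_params = default_shape_params()
    for i, (strain_id, arch) in enumerate(roster):
        plate_id = plate_ids[i % len(plate_ids)]
        logits = base_logits.copy()
        if arch in arch_logit_offsets:
            logits = logits + arch_logit_offsets[arch]
        trajectories[strain_id] = StrainTrajectory(
            strain_id, plate_id, _curve_from_partition(_from_logits(logits))
        )
        # nuisance terms: plate batch offset, per-strain noise, a shared
        # per-well response-speed factor (wells run slightly ahead of or
        # behind the mean lysis kinetics), and residual iid logit noise
        logits = logits + plate_offsets[plate_id][None, :]
        logits = logits + rng.normal(0.0, sigma_strain, size=len(PARTITION))[None, :]
        speed = rng.normal(0.0, sigma_speed)
        speed_profile = np.interp(
            np.linspace(0.0, 2.0, timepoints), [0.0, 1.0, 2.0], _SPEED_PROFILE
        )
        logits[:, PARTITION.index("lysed")] += speed * speed_profile
        logits = logits + rng.normal(0.0, sigma_well, size=logits.shape)
        probs = _from_logits(logits)
        # wells differ substantially in cell density (dilution and growth
        # variability); the acquisition policy partially compensates by
        # taking more images of sparse wells
        density = mean_density * float(np.exp(rng.normal(0.0, sigma_density)))
        density = min(max(density, 4.0), 150.0)

        if arch != "wt":
            planted = _ARCHETYPE_COG.get(arch)
            cats = {rng.choice(_COG_POOL)}
            if planted is not None and rng.uniform() < 0.6:
                cats.add(planted)
            cog_rows.append({"strain_id": strain_id, "categories": "".join(sorted(cats))})

        for t in range(timepoints):
            frame_counts, counts = _well_counts(probs[t], rng, density)
            row = {
                "strain_id": strain_id,
                "plate_id": plate_id,
                "timepoint": t,
                "n_cells": int(counts.sum()),
                "n_frames": len(frame_counts),
                "max_frame_count": int(frame_counts.max()) if len(frame_counts) else 0,
            }
            for cat, n in zip(PARTITION, counts):
                row[f"n_{cat}"] = int(n)
            rows.append(row)
            if render:
                labels_pool = np.repeat(np.arange(6), counts)
                rng.shuffle(labels_pool)
                splits = np.array_split(labels_pool, len(frame_counts))
                for f_idx, frame_labels in enumerate(splits):
                    names = [PARTITION[j] for j in frame_labels]
                    cells = scatter_cells(names, image_shape, rng, params=shape_params)
                    frames.append(
                        render_frame(
                            cells,
                            image_shape,
                            noise_params=noise_params,
                            rng=rng,
                            meta={
                                "strain_id": strain_id,
                                "plate_id": plate_id,
                                "timepoint": t,
                                "frame": f_idx,
                            },
                        )
                    )

    truth = ScreenTruth(
        wells=pd.DataFrame(rows),
        strains=pd.DataFrame(
            [
                {"strain_id": s, "plate_id": plate_ids[i % len(plate_ids)], "archetype": a}
                for i, (s, a) in enumerate(roster)
            ]
        ),
        trajectories=trajectories,
        plate_offsets=plate_offsets,
        cog=pd.DataFrame(cog_rows, columns=["strain_id", "categories"]),
        seed=seed,
        timepoints=timepoints,
    )
    return frames, truth
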