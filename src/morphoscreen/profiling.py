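"""Phenotypic profiles: per-well summaries, 18-dimensional profiles,
per-plate batch correction and screen QC.

A well summary gives the proportion of every category over the *whole*
population including lysed cells: the denominator is always the total cell
count, so ``normal + round + elongated + small + deformed = intact`` and
``intact + lysed = 1``.  A phenotypic profile stacks the six category
proportions (order: intact, normal, round, elongated, small, deformed) for
the three time-points, ascending — 18 values per strain/well.

Batch (plate) effects are removed by centering and scaling each of the 18
variables to unit standard deviation within each plate separately, using all
wells on the plate.  QC fails a well with fewer than 50 cells in total or
more than 150 cells in any single frame; failed wells are listed "to repeat".
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synth.screen import CATEGORIES

__all__ = [
    "PROFILE_COLUMNS",
    "summarize_well",
    "summaries_from_counts",
    "build_profile",
    "build_profiles",
    "batch_correct",
    "qc_wells",
    "QC_MIN_TOTAL",
    "QC_MAX_PER_FRAME",
]

QC_MIN_TOTAL = 50
QC_MAX_PER_FRAME = 150

N_TIMEPOINTS = 3
#: frozen 18-column profile layout: categories within time-point, time ascending
PROFILE_COLUMNS = tuple(f"{cat}_t{t}" for t in range(N_TIMEPOINTS) for cat in CATEGORIES)


def summarize_well(labels, strain_id: str = "", plate_id: str = "", timepoint: int = 0) -> dict:
    """Category proportions of one well/time-point from per-cell labels.

    The denominator is the total population (intact + lysed).  Zero cells is
    a QC failure and yields undefined proportions (error).
    """
    labels = np.asarray(labels, dtype=object)
    total = len(labels)
    if total == 0:
        raise ValueError("zero cells in well: proportions undefined (QC fail)")
    row = {
        "strain_id": strain_id,
        "plate_id": plate_id,
        "timepoint": int(timepoint),
        "n_cells": total,
    }
    n_lysed = int(np.sum(labels == "lysed"))
    row["intact"] = (total - n_lysed) / total
    for cat in CATEGORIES[1:]:
        row[cat] = int(np.sum(labels == cat)) / total
    return row


def summaries_from_counts(wells: pd.DataFrame) -> pd.DataFrame:
    """Vectorized well summaries from a per-well count table (the generator's
    ground-truth layout: columns ``n_lysed``, ``n_normal``, ...)."""
    out = wells[["strain_id", "plate_id", "timepoint", "n_cells"]].copy()
    total = wells["n_cells"].to_numpy(float)
    if (total == 0).any():
        raise ValueError("zero-cell wells present: run QC first")
    out["intact"] = (total - wells["n_lysed"]) / total
    for cat in CATEGORIES[1:]:
        out[cat] = wells[f"n_{cat}"] / total
    return out


def build_profile(summaries: pd.DataFrame | list[dict]) -> np.ndarray:
    """Assemble one 18-value phenotypic profile from three well summaries.

    The three rows must share strain/plate and cover three distinct
    time-points; input order is irrelevant (sorted by time internally).
    Missing time-points raise — there is no imputation.
    """
    df = pd.DataFrame(summaries)
    if len(df) != N_TIMEPOINTS or df["timepoint"].nunique() != N_TIMEPOINTS:
        raise ValueError(
            f"expected {N_TIMEPOINTS} time-points per profile, got "
            f"{sorted(df['timepoint'].tolist())}"
        )
    df = df.sort_values("timepoint")
    return df[list(CATEGORIES)].to_numpy(float).ravel()


def build_profiles(summaries: pd.DataFrame) -> pd.DataFrame:
    """Profiles for every strain in a summary table (rows: strain/plate;
    columns: metadata + the 18 frozen profile columns)."""
    rows = []
    for (strain, plate), grp in summaries.groupby(["strain_id", "plate_id"], sort=True):
        vec = build_profile(grp)
        row = {"strain_id": strain, "plate_id": plate}
        row.update(zip(PROFILE_COLUMNS, vec))
        rows.append(row)
    return pd.DataFrame(rows, columns=["strain_id", "plate_id", *PROFILE_COLUMNS])


def batch_correct(profiles: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Center and scale each profile variable to unit SD within each plate.

    Uses all wells on the plate.  A zero-variance variable on a plate is
    left centered with scale 1 (warning).  Requires >= 2 wells per plate.
    """
    out = profiles.copy()
    cols = [c for c in PROFILE_COLUMNS if c in out.columns]
    for plate, grp in out.groupby("plate_id"):
        if len(grp) < 2:
            raise ValueError(f"plate {plate!r} has fewer than 2 wells; cannot batch-correct")
        vals = grp[cols].to_numpy(float)
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=ddof)
        bad = sd == 0
        if bad.any():
            warnings.warn(
                f"plate {plate!r}: {int(bad.sum())} zero-variance variable(s) left unscaled",
                stacklevel=2,
            )
            sd[bad] = 1.0
        out.loc[grp.index, cols] = (vals - mean) / sd
    return out


def qc_wells(wells: pd.DataFrame) -> pd.DataFrame:
    """Per-well QC report.

    A well fails iff its total cell count over the three time-points is
    below ``QC_MIN_TOTAL`` or any single frame holds more than
    ``QC_MAX_PER_FRAME`` cells; both bounds are inclusive pass thresholds.
    ``wells`` needs columns strain_id/plate_id plus n_cells and
    max_frame_count per time-point row.
    """
    rows = []
    for (strain, plate), grp in wells.groupby(["strain_id", "plate_id"], sort=True):
        total = int(grp["n_cells"].sum())
        max_frame = int(grp["max_frame_count"].max()) if "max_frame_count" in grp else 0
        reasons = []
        if total < QC_MIN_TOTAL:
            reasons.append(f"total cells {total} < {QC_MIN_TOTAL}")
        if max_frame > QC_MAX_PER_FRAME:
            reasons.append(f"frame with {max_frame} > {QC_MAX_PER_FRAME} cells")
        rows.append(
            {
                "strain_id": strain,
                "plate_id": plate,
                "total_cells": total,
                "max_frame_count": max_frame,
                "pass": not reasons,
                "reason": "; ".join(reasons),
            }
        )
    return pd.DataFrame(rows)
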