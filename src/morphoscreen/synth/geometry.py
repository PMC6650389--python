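"""Single-cell geometry archetypes for the synthetic phase-contrast generator.

Six morphological categories are modelled, mirroring the response of rod-shaped
bacteria to a lysis-inducing beta-lactam: ``normal`` rods, ``small`` rods,
``elongated`` (filamented) rods, ``round`` cells (enlarged stable bulges),
``deformed`` cells (rods carrying a mid-cell bulge), and ``lysed`` cells
(low-contrast ghosts left behind after the cell bursts).

Sizes are in pixels; at a typical 40x air-objective sampling (~0.16 um/px) a
2-4 um rod spans roughly 15-25 px, which the defaults reflect.  The per-class
size distributions are free parameters of the generator (declared here, not
measured values) and are shared by every downstream test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

MORPH_CLASSES = ("normal", "small", "elongated", "round", "deformed")
#: The six generator categories: five renderable intact morphologies + lysed.
CELL_CLASSES = MORPH_CLASSES + ("lysed",)


@dataclass(frozen=True)
class ClassShapeParams:
    """Sampling distribution for one morphological class.

    ``length``/``width`` are (mean, sd) of truncated normals in px;
    ``contrast`` is (mean, sd) of the dimensionless cell depth relative to
    background, ``(background - cell) / background`` in [0, 1].
    """

    length: tuple[float, float]
    width: tuple[float, float]
    contrast: tuple[float, float]
    aspect_max: float | None = None  # only used by "round"
    bulge_factor: tuple[float, float] | None = None  # only used by "deformed"


def default_shape_params() -> dict[str, ClassShapeParams]:
    return {
        "normal": ClassShapeParams(length=(24.0, 3.0), width=(9.0, 0.7), contrast=(0.45, 0.05)),
        "small": ClassShapeParams(length=(14.0, 1.8), width=(8.0, 0.6), contrast=(0.45, 0.05)),
        "elongated": ClassShapeParams(length=(55.0, 9.0), width=(9.0, 0.7), contrast=(0.45, 0.05)),
        "round": ClassShapeParams(
            length=(17.0, 2.0), width=(16.0, 2.0), contrast=(0.40, 0.05), aspect_max=1.25
        ),
        "deformed": ClassShapeParams(
            length=(32.0, 5.0), width=(9.0, 0.7), contrast=(0.42, 0.05), bulge_factor=(1.7, 0.25)
        ),
        "lysed": ClassShapeParams(length=(26.0, 4.0), width=(10.0, 1.0), contrast=(0.12, 0.025)),
    }


@dataclass(frozen=True)
class CellGeometry:
    """A single cell to be painted into a frame."""

    morph_class: str
    centroid: tuple[float, float]  # (row, col), px
    orientation: float  # radians, angle of the long axis w.r.t. the column axis
    length: float  # px, tip-to-tip
    width: float  # px
    bulge_diameter: float  # px; 0 unless deformed/round
    contrast: float  # (background - cell)/background, dimensionless

    def __post_init__(self) -> None:
        if self.length < self.width or self.width <= 0:
            raise ValueError(
                f"invalid geometry: need length >= width > 0, got "
                f"length={self.length:.2f}, width={self.width:.2f}"
            )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    # simple rejection; lo is far enough in the bulk that this terminates fast
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    return float(max(lo * 1.01, mean))


def sample_cell(
    morph_class: str,
    params: Mapping[str, ClassShapeParams] | None = None,
    rng: np.random.Generator | None = None,
    centroid: tuple[float, float] = (0.0, 0.0),
) -> CellGeometry:
    """Draw one cell geometry from its class distribution.

    Raises ``ValueError`` for an unknown class name.
    """
    if params is None:
        params = default_shape_params()
    if morph_class not in params:
        raise ValueError(
            f"unknown morphology class {morph_class!r}; expected one of {sorted(params)}"
        )
    if rng is None:
        rng = np.random.default_rng()
    p = params[morph_class]

    width = _trunc_normal(rng, *p.width, lo=3.0)
    if p.aspect_max is not None:
        # round cells: near-isotropic ellipse, aspect ratio capped
        aspect = rng.uniform(1.0, p.aspect_max)
        length = width * aspect
    else:
        length = _trunc_normal(rng, *p.length, lo=width)
    length = max(length, width)

    bulge = 0.0
    if p.bulge_factor is not None:
        bulge = width * max(1.2, rng.normal(*p.bulge_factor))
    elif morph_class == "round":
        bulge = width  # a round cell is, in effect, all bulge

    contrast = float(np.clip(rng.normal(*p.contrast), 0.03, 0.8))
    orientation = float(rng.uniform(0.0, np.pi))
    return CellGeometry(
        morph_class=morph_class,
        centroid=centroid,
        orientation=orientation,
        length=length,
        width=width,
        bulge_diameter=bulge,
        contrast=contrast,
    )


def with_centroid(cell: CellGeometry, centroid: tuple[float, float]) -> CellGeometry:
    return replace(cell, centroid=centroid)
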