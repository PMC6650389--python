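"""Painting of phase-contrast-like frames.

The optical appearance is an idealisation, not an optical model: cells are
dark bodies on a bright background surrounded by a thin bright halo rim --
the familiar phase-contrast convention -- on top of a smooth shading gradient
and additive Gaussian sensor noise.  Lysed cells are painted as low-contrast
ghosts with an irregular, gently modulated outline.

Every rendered frame carries its own ground truth (a label image plus the
cell list), so segmentation and classification can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CellGeometry, sample_cell

__all__ = ["NoiseParams", "Frame", "render_frame", "scatter_cells"]


@dataclass(frozen=True)
class NoiseParams:
    """Background / noise model of a rendered frame (intensities as fractions
    of full scale)."""

    background: float = 0.55
    shading: float = 0.04  # peak-to-centre amplitude of the linear gradient
    noise_sd: float = 0.015
    halo_width: int = 2  # px
    halo_strength: float = 0.35  # halo height = strength * contrast * background
    bit_depth: int = 16

    @property
    def full_scale(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class Frame:
    """One synthetic frame with pixel data and exact ground truth."""

    image: np.ndarray  # uint16 (or uint8), shape (H, W)
    labels: np.ndarray  # int32, 0 = background, i+1 = cells[i]
    cells: list[CellGeometry]
    clipped: list[bool]  # True if the ideal mask extends beyond the frame
    overlap_warnings: list[tuple[int, int, int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _cell_mask(cell: CellGeometry, shape: tuple[int, int], rng: np.random.Generator):
    """Boolean mask of one cell on the full frame, plus a clipped flag.

    Rods are spherocylinders, round cells ellipses, deformed cells a rod with a
    circular mid-cell bulge, lysed cells a rod whose radius is smoothly
    modulated to a ragged ghost outline.
    """
    r0, c0 = cell.centroid
    half = max(cell.length, cell.bulge_diameter) / 2.0 + 3.0
    lo_r, hi_r = int(np.floor(r0 - half)), int(np.ceil(r0 + half)) + 1
    lo_c, hi_c = int(np.floor(c0 - half)), int(np.ceil(c0 + half)) + 1
    clipped = lo_r < 0 or lo_c < 0 or hi_r > shape[0] or hi_c > shape[1]

    rr = np.arange(max(lo_r, 0), min(hi_r, shape[0]))
    cc = np.arange(max(lo_c, 0), min(hi_c, shape[1]))
    if rr.size == 0 or cc.size == 0:
        return np.zeros((0, 0), bool), (0, 0), True
    R, C = np.meshgrid(rr - r0, cc - c0, indexing="ij")
    ct, st = np.cos(cell.orientation), np.sin(cell.orientation)
    u = C * ct + R * st  # along the long axis
    v = -C * st + R * ct

    w2 = cell.width / 2.0
    if cell.morph_class == "round":
        a, b = cell.length / 2.0, cell.width / 2.0
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    else:
        a = max(cell.length / 2.0 - w2, 0.0)
        d = np.hypot(np.maximum(np.abs(u) - a, 0.0), v)
        if cell.morph_class == "lysed":
            # smooth random radius modulation -> ragged ghost outline
            amp = 0.15
            ph = rng.uniform(0, 2 * np.pi, size=3)
            span = max(a + w2, 1.0)
            mod = 1.0 + amp * (
                np.sin(np.pi * u / span + ph[0]) * 0.6
                + np.sin(2 * np.pi * u / span + ph[1]) * 0.3
                + np.sin(3 * np.pi * u / span + ph[2]) * 0.1
            )
            mask = d <= w2 * mod
        else:
            mask = d <= w2
        if cell.morph_class == "deformed" and cell.bulge_diameter > 0:
            mask |= np.hypot(u, v) <= cell.bulge_diameter / 2.0
    # a clipped cell really loses pixels only if its mask touches the cut edge
    if clipped and mask.any():
        touches = (
            (lo_r < 0 and mask[0].any())
            or (hi_r > shape[0] and mask[-1].any())
            or (lo_c < 0 and mask[:, 0].any())
            or (hi_c > shape[1] and mask[:, -1].any())
        )
        clipped = bool(touches)
    return mask, (int(rr[0]), int(cc[0])), clipped


def render_frame(
    cells: Sequence[CellGeometry],
    image_shape: tuple[int, int] = (512, 512),
    noise_params: NoiseParams | None = None,
    rng: np.random.Generator | None = None,
    overlap_tolerance: int = 0,
    meta: dict | None = None,
) -> Frame:
    """Render a list of cells into one frame.

    Cells extending beyond the frame are clipped (and flagged).  Overlapping
    cell pairs whose shared pixel count exceeds ``overlap_tolerance`` are
    recorded in ``overlap_warnings`` as ``(i, j, n_shared_px)``; overlaps are
    painted (later cell wins) but never silently ignored in the ground truth.
    """
    if noise_params is None:
        noise_params = NoiseParams()
    if rng is None:
        rng = np.random.default_rng()
    if not (len(image_shape) == 2 and all(s > 0 for s in image_shape)):
        raise ValueError(f"image_shape must be 2-D positive, got {image_shape!r}")

    H, W = image_shape
    np_ = noise_params
    # background with a random-direction linear shading gradient
    gy, gx = rng.uniform(-1, 1, size=2)
    rr = (np.arange(H) / max(H - 1, 1) - 0.5)[:, None]
    cc = (np.arange(W) / max(W - 1, 1) - 0.5)[None, :]
    img = np_.background * (1.0 + 2.0 * np_.shading * (gy * rr + gx * cc))

    labels = np.zeros((H, W), np.int32)
    clipped_flags: list[bool] = []
    masks: list[tuple[np.ndarray, tuple[int, int]]] = []
    from scipy.ndimage import binary_dilation

    for i, cell in enumerate(cells):
        mask, (orow, ocol), clipped = _cell_mask(cell, (H, W), rng)
        clipped_flags.append(clipped)
        masks.append((mask, (orow, ocol)))
        if mask.size == 0:
            continue
        sl = np.s_[orow : orow + mask.shape[0], ocol : ocol + mask.shape[1]]
        labels[sl][mask] = i + 1

    # overlap bookkeeping: any pixel claimed twice
    overlap_warnings: list[tuple[int, int, int]] = []
    for i in range(len(cells)):
        mi, (ri, ci) = masks[i]
        if mi.size == 0:
            continue
        sl = np.s_[ri : ri + mi.shape[0], ci : ci + mi.shape[1]]
        owners = labels[sl][mi]
        for j in np.unique(owners):
            if j not in (0, i + 1):
                n_shared = int(np.sum(owners == j))
                if n_shared > overlap_tolerance:
                    overlap_warnings.append((min(i, j - 1), max(i, j - 1), n_shared))

    # halo rim: a thin bright ring around every body, painted under bodies
    if np_.halo_width > 0 and cells:
        body_any = labels > 0
        halo = binary_dilation(body_any, iterations=np_.halo_width) & ~body_any
        img[halo] *= 1.0 + np_.halo_strength * float(np.mean([c.contrast for c in cells]))
    for i, cell in enumerate(cells):
        mi, (ri, ci) = masks[i]
        if mi.size == 0:
            continue
        sl = np.s_[ri : ri + mi.shape[0], ci : ci + mi.shape[1]]
        body = mi & (labels[sl] == i + 1)
        img[sl][body] *= 1.0 - cell.contrast

    img = img + rng.normal(0.0, np_.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    dtype = np.uint16 if np_.bit_depth > 8 else np.uint8
    image = np.round(img * np_.full_scale).astype(dtype)
    return Frame(
        image=image,
        labels=labels,
        cells=list(cells),
        clipped=clipped_flags,
        overlap_warnings=overlap_warnings,
        meta=dict(meta or {}),
    )


def scatter_cells(
    class_names: Sequence[str],
    image_shape: tuple[int, int],
    rng: np.random.Generator,
    params=None,
    gap: float = 6.0,
    max_tries: int = 200,
) -> list[CellGeometry]:
    """Sample geometries for ``class_names`` and place them without overlap.

    Placement is rejection sampling on bounding circles separated by ``gap``
    px; cells that cannot be placed after ``max_tries`` attempts are dropped
    (the returned list may therefore be shorter than the request — callers
    that need exact counts should check ``len``).
    """
    H, W = image_shape
    placed: list[CellGeometry] = []
    radii: list[float] = []
    for name in class_names:
        cell = sample_cell(name, params=params, rng=rng)
        r = max(cell.length, cell.bulge_diameter) / 2.0
        for _ in range(max_tries):
            cy = rng.uniform(r + 2, H - r - 2) if H > 2 * r + 4 else rng.uniform(0, H)
            cx = rng.uniform(r + 2, W - r - 2) if W > 2 * r + 4 else rng.uniform(0, W)
            ok = all(
                np.hypot(cy - p.centroid[0], cx - p.centroid[1]) >= r + pr + gap
                for p, pr in zip(placed, radii)
            )
            if ok:
                placed.append(
                    CellGeometry(
                        morph_class=cell.morph_class,
                        centroid=(cy, cx),
                        orientation=cell.orientation,
                        length=cell.length,
                        width=cell.width,
                        bulge_diameter=cell.bulge_diameter,
                        contrast=cell.contrast,
                    )
                )
                radii.append(r)
                break
    return placed
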