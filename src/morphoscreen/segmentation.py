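"""Single-cell segmentation of phase-contrast frames.

Three stages, composed by :func:`segment_frame`:

1. :func:`enhance` — contrast-limited adaptive histogram equalization (CLAHE)
   followed by black top-hat filtering.  The top-hat removes the slowly
   varying background (shading, halos) and returns an image in which cell
   bodies are *bright* on a near-zero background, regardless of the input
   polarity (auto-detected).
2. :func:`binarize` — a deliberately permissive threshold a fixed number of
   robust standard deviations above the background mode, so that both
   high-contrast intact cells and faint lysed ghosts survive.  A bimodal
   method (Otsu etc.) is unsuitable here because ghosts break bimodality.
3. :func:`prune` — connected components failing minimal cell-shape criteria
   (area, solidity, aspect ratio, border contact) are discarded; survivors
   become :class:`CellRecord` objects with sub-pixel closed contours.

Touching cells are not split: in liquid suspension cells stay separated, and
merged blobs are removed by the aspect/area criteria instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure, measure, morphology

__all__ = ["SegmentationConfig", "CellRecord", "enhance", "binarize", "prune", "segment_frame"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of the segmentation stages (units: px, px^2)."""

    clahe_clip: float = 0.01
    clahe_tile: int = 64
    tophat_radius: int = 15
    threshold_k: float = 4.0  # robust SDs above background mode
    min_area: int = 40
    max_area: int = 6000
    min_solidity: float = 0.5
    max_aspect: float = 12.0
    border_policy: str = "discard"  # or "keep"

    def __post_init__(self) -> None:
        if not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")
        if not (0 < self.min_solidity <= 1):
            raise ValueError("min_solidity must be in (0, 1]")
        if self.border_policy not in ("discard", "keep"):
            raise ValueError(f"border_policy must be keep/discard, got {self.border_policy!r}")


@dataclass
class CellRecord:
    """One segmented cell: crop mask + sub-pixel contour in frame coordinates.

    ``mask`` is the boolean crop at ``bbox = (min_row, min_col, max_row,
    max_col)``; ``contour`` is a closed (first point repeated last),
    counter-clockwise ``(N, 2)`` array of (row, col) points; coordinates are
    0-based with origin at the top-left pixel centre.
    """

    label_id: int
    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    contour: np.ndarray
    centroid: tuple[float, float]
    frame_ref: dict = field(default_factory=dict)

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def mask_slices(self) -> tuple[slice, slice]:
        r0, c0, r1, c1 = self.bbox
        return slice(r0, r1), slice(c0, c1)


def _as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a single-channel 2-D image, got shape {img.shape}")
    img = img.astype(float)
    if np.issubdtype(np.asarray(image).dtype, np.integer):
        img /= np.iinfo(np.asarray(image).dtype).max
    return img


def _objects_are_dark(img: np.ndarray) -> bool:
    """Guess polarity from tail asymmetry around the median."""
    med = np.median(img)
    lo, hi = np.percentile(img, [1, 99])
    return (med - lo) >= (hi - med)


def enhance(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Contrast enhancement: CLAHE + black top-hat.

    Deterministic; output is float with cells bright on a ~zero background.
    """
    if config is None:
        config = SegmentationConfig()
    img = _as_float(image)
    if np.ptp(img) == 0:
        return np.zeros_like(img)
    if not _objects_are_dark(img):
        img = img.max() + img.min() - img  # flip polarity so objects are dark
    if config.clahe_clip > 0:
        span = np.ptp(img)
        norm = (img - img.min()) / span
        eq = exposure.equalize_adapthist(
            norm, kernel_size=config.clahe_tile, clip_limit=config.clahe_clip
        )
        # blend keeps the ghost/background ordering while flattening shading
        img = 0.5 * norm + 0.5 * eq
    footprint = morphology.disk(config.tophat_radius, decomposition="sequence")
    closed = morphology.closing(img, footprint)
    return closed - img  # black top-hat: dark objects become bright


def binarize(image: np.ndarray, config: SegmentationConfig | None = None) -> np.ndarray:
    """Permissive foreground mask from an enhanced image.

    Threshold = background mode + ``threshold_k`` robust SDs, where the mode
    and SD are estimated from the median and the median absolute deviation
    (cells occupy a small area fraction, so the median is background).
    """
    if config is None:
        config = SegmentationConfig()
    img = np.asarray(image, float)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    med = np.median(img)
    sigma = 1.4826 * np.median(np.abs(img - med))
    if sigma == 0:
        sigma = img.std() or 1.0
    mask = img > med + config.threshold_k * sigma
    frac = mask.mean()
    if frac in (0.0, 1.0):
        warnings.warn(
            f"binarization produced an all-{'foreground' if frac else 'background'} mask",
            stacklevel=2,
        )
    # fill pinholes inside cell bodies; close 1-px gaps in faint ghosts
    mask = morphology.closing(mask, morphology.disk(1))
    mask = ndimage.binary_fill_holes(mask)
    return mask


def _contour_of(mask: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2))
    contour = max(contours, key=len) + np.asarray(origin) - 1.0
    if not np.array_equal(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    # counter-clockwise in (x=col, y=row) axes: positive shoelace area
    x, y = contour[:, 1], contour[:, 0]
    area2 = np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    if area2 < 0:
        contour = contour[::-1]
    return contour


def prune(
    mask: np.ndarray,
    config: SegmentationConfig | None = None,
    frame_ref: dict | None = None,
) -> list[CellRecord]:
    """Keep connected components that satisfy the minimal cell-shape criteria.

    Survivors are returned ordered by centroid (row-major).  Rejections are
    silent except merged high-aspect blobs, which are reported via a warning.
    """
    if config is None:
        config = SegmentationConfig()
    labeled = measure.label(mask, connectivity=2)
    records: list[CellRecord] = []
    H, W = mask.shape
    for rp in measure.regionprops(labeled):
        if rp.area < config.min_area or rp.area > config.max_area:
            continue
        if rp.solidity < config.min_solidity:
            continue
        minor = rp.axis_minor_length or 1.0
        aspect = rp.axis_major_length / minor
        if aspect > config.max_aspect:
            warnings.warn(
                f"component {rp.label} rejected: aspect {aspect:.1f} > "
                f"{config.max_aspect} (possible merged cells)",
                stacklevel=2,
            )
            continue
        r0, c0, r1, c1 = rp.bbox
        if config.border_policy == "discard" and (r0 == 0 or c0 == 0 or r1 == H or c1 == W):
            continue
        crop = labeled[r0:r1, c0:c1] == rp.label
        contour = _contour_of(crop, (r0, c0))
        if len(contour) <= 3:
            continue
        records.append(
            CellRecord(
                label_id=rp.label,
                mask=crop,
                bbox=(r0, c0, r1, c1),
                contour=contour,
                centroid=tuple(map(float, rp.centroid)),
                frame_ref=dict(frame_ref or {}),
            )
        )
    records.sort(key=lambda r: r.centroid)
    for new_id, rec in enumerate(records, start=1):
        rec.label_id = new_id
    return records


def segment_frame(
    image: np.ndarray,
    config: SegmentationConfig | None = None,
    frame_ref: dict | None = None,
) -> list[CellRecord]:
    """enhance -> binarize -> prune; deterministic end-to-end."""
    if config is None:
        config = SegmentationConfig()
    enhanced = enhance(image, config)
    mask = binarize(enhanced, config)
    return prune(mask, config, frame_ref=frame_ref)


def records_from_label_image(
    labels: np.ndarray, frame_ref: dict | None = None
) -> list[CellRecord]:
    """Build CellRecords directly from a (ground-truth) label image.

    Used to train classifiers on generator cells with known identities,
    bypassing the segmentation stages.  Ordering follows label ids.
    """
    records: list[CellRecord] = []
    for rp in measure.regionprops(np.asarray(labels)):
        r0, c0, r1, c1 = rp.bbox
        crop = labels[r0:r1, c0:c1] == rp.label
        contour = _contour_of(crop, (r0, c0))
        if len(contour) <= 3:
            continue
        records.append(
            CellRecord(
                label_id=int(rp.label),
                mask=crop,
                bbox=(r0, c0, r1, c1),
                contour=contour,
                centroid=tuple(map(float, rp.centroid)),
                frame_ref=dict(frame_ref or {}),
            )
        )
    return records


def label_image(records: list[CellRecord], shape: tuple[int, int]) -> np.ndarray:
    """Rebuild a full-frame label image from records (for inspection/IO)."""
    out = np.zeros(shape, np.int32)
    for rec in records:
        sl = rec.mask_slices()
        out[sl][rec.mask] = rec.label_id
    return out
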