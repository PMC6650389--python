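"""The 54-descriptor feature vector of a segmented cell.

Four blocks, in this frozen order (see :data:`FEATURE_NAMES`):

* **shape** (22): size and form of the mask/contour — cell length, width,
  aspect ratio, area, perimeter, circularity, solidity, eccentricity, radial
  profile and curvature summaries.  Length/width come from the minimum-area
  bounding rectangle of the contour, with a medial-axis fallback for bent
  cells (low solidity), where length = area / (2 x median medial radius).
* **fourier** (10): magnitudes of complex contour harmonics ``|F_k|/|F_1|``
  for k = 2..11, computed on the arc-length-resampled contour.  Dropping
  ``F_0`` removes translation, dividing by ``|F_1|`` removes scale, and
  taking magnitudes removes rotation and the contour starting point.
* **intensity** (12): statistics of the pixel values inside the mask.  The
  moment/quantile ratios (skewness, kurtosis, ``(mean-median)/sd``,
  ``IQR/sd``) are invariant to affine intensity rescaling; the raw
  statistics are covariant.
* **microenvironment** (10): contrasts between the cell interior and an
  immediately surrounding annulus (default 3 px wide), with pixels belonging
  to neighbouring cells excluded from the annulus.

Every valid cell yields exactly :data:`N_FEATURES` finite values.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.stats import kurtosis, skew
from skimage.morphology import medial_axis

from .segmentation import CellRecord

__all__ = [
    "N_FEATURES",
    "FEATURE_NAMES",
    "FEATURE_BLOCKS",
    "shape_features",
    "fourier_descriptors",
    "intensity_features",
    "microenvironment_features",
    "extract_features",
    "features_table",
    "resample_contour",
]

SHAPE_NAMES = (
    "area",
    "perimeter",
    "length",
    "width",
    "aspect_ratio",
    "circularity",
    "solidity",
    "eccentricity",
    "extent",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
    "convexity",
    "rectangularity",
    "radius_mean",
    "radius_std_norm",
    "radius_max_norm",
    "radius_min_norm",
    "curvature_mean_abs",
    "curvature_std",
    "curvature_max_abs",
    "bending_energy",
)
FOURIER_NAMES = tuple(f"fourier_mag_{k}" for k in range(2, 12))
INTENSITY_NAMES = (
    "int_mean",
    "int_std",
    "int_min",
    "int_max",
    "int_median",
    "int_q25",
    "int_q75",
    "int_iqr",
    "int_skewness",
    "int_kurtosis",
    "int_med_offset_norm",
    "int_iqr_over_std",
)
MICROENV_NAMES = (
    "env_mean",
    "env_std",
    "env_median",
    "env_contrast_mean",
    "env_contrast_median",
    "env_weber_contrast",
    "env_michelson_contrast",
    "env_std_contrast",
    "env_halo_contrast",
    "env_range",
)

FEATURE_BLOCKS = {
    "shape": SHAPE_NAMES,
    "fourier": FOURIER_NAMES,
    "intensity": INTENSITY_NAMES,
    "microenvironment": MICROENV_NAMES,
}
FEATURE_NAMES: tuple[str, ...] = SHAPE_NAMES + FOURIER_NAMES + INTENSITY_NAMES + MICROENV_NAMES
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 54

_RESAMPLE_N = 128


def resample_contour(contour: np.ndarray, n: int = _RESAMPLE_N) -> np.ndarray:
    """Resample a closed contour to ``n`` points equally spaced in arc length.

    Input is ``(M, 2)`` (row, col) with the first point repeated last (it is
    appended if missing).  The output does not repeat the first point.
    """
    c = np.asarray(contour, float)
    if c.ndim != 2 or c.shape[1] != 2 or len(c) < 4:
        raise ValueError(f"contour must be (M>=4, 2), got shape {c.shape}")
    if not np.array_equal(c[0], c[-1]):
        c = np.vstack([c, c[:1]])
    seg = np.hypot(*np.diff(c, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate contour with zero length")
    t = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(t, s, c[:, 0]), np.interp(t, s, c[:, 1])])


def _min_area_rect(points: np.ndarray) -> tuple[float, float]:
    """(length, width) of the minimum-area bounding rectangle (rotating
    calipers over convex-hull edge directions)."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise ValueError("need >= 3 points")
    hull = pts[ConvexHull(pts).vertices]
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 0], edges[:, 1]), np.pi))
    best = (np.inf, 0.0, 0.0)
    for a in angles:
        ca, sa = np.cos(a), np.sin(a)
        u = hull[:, 1] * ca + hull[:, 0] * sa
        v = -hull[:, 1] * sa + hull[:, 0] * ca
        du, dv = np.ptp(u), np.ptp(v)
        if du * dv < best[0]:
            best = (du * dv, du, dv)
    _, du, dv = best
    return (max(du, dv), min(du, dv))


def _curvature(closed: np.ndarray) -> np.ndarray:
    """Signed curvature at each point of an evenly resampled closed contour,
    normalized so a circle has curvature 1 everywhere."""
    y, x = closed[:, 0], closed[:, 1]
    dx, dy = np.gradient(x), np.gradient(y)
    # periodic end handling
    dx[0] = (x[1] - x[-1]) / 2.0
    dx[-1] = (x[0] - x[-2]) / 2.0
    dy[0] = (y[1] - y[-1]) / 2.0
    dy[-1] = (y[0] - y[-2]) / 2.0
    ddx, ddy = np.gradient(dx), np.gradient(dy)
    ddx[0] = (dx[1] - dx[-1]) / 2.0
    ddx[-1] = (dx[0] - dx[-2]) / 2.0
    ddy[0] = (dy[1] - dy[-1]) / 2.0
    ddy[-1] = (dy[0] - dy[-2]) / 2.0
    denom = (dx**2 + dy**2) ** 1.5
    denom[denom == 0] = np.finfo(float).eps
    kappa = (dx * ddy - dy * ddx) / denom
    seg = np.hypot(np.diff(np.vstack([closed, closed[:1]])[:, 0]),
                   np.diff(np.vstack([closed, closed[:1]])[:, 1]))
    perimeter = seg.sum()
    return kappa * perimeter / (2.0 * np.pi)


def shape_features(cell: CellRecord) -> np.ndarray:
    """The 22-value shape block; raises for degenerate (<=3-point) contours."""
    if cell.contour is None or len(cell.contour) <= 3:
        raise ValueError("degenerate contour: need more than 3 points")
    mask = cell.mask
    area = float(mask.sum())
    if area == 0:
        raise ValueError("empty mask")

    res = resample_contour(cell.contour)
    seg = np.hypot(*np.diff(np.vstack([res, res[:1]]), axis=0).T)
    perimeter = float(seg.sum())

    solidity, ecc, extent, major, minor = _regionprops_block(mask)
    # light circular smoothing suppresses rasterization jaggies that bias
    # the min-area rectangle's width estimate
    from scipy.ndimage import uniform_filter1d

    smooth = np.column_stack(
        [uniform_filter1d(res[:, 0], 5, mode="wrap"), uniform_filter1d(res[:, 1], 5, mode="wrap")]
    )
    length, width = _min_area_rect(smooth)
    if solidity < 0.8:
        # bent cell: medial-axis estimate (length = area / mean cross width)
        skel, dist = medial_axis(mask, return_distance=True)
        if skel.any():
            w_med = 2.0 * float(np.median(dist[skel]))
            if w_med > 1.0:
                width = w_med
                length = max(area / w_med, width)
    width = max(width, 1.0)
    length = max(length, width)

    centroid = res.mean(axis=0)
    radii = np.hypot(res[:, 0] - centroid[0], res[:, 1] - centroid[1])
    r_mean = float(radii.mean()) or 1.0

    kappa = _curvature(res)
    circularity = float(4.0 * np.pi * area / perimeter**2) if perimeter > 0 else 0.0
    hull_perimeter = _hull_perimeter(cell.contour)
    return np.array(
        [
            area,
            perimeter,
            length,
            width,
            length / width,
            min(circularity, 1.0),
            solidity,
            ecc,
            extent,
            float(np.sqrt(4.0 * area / np.pi)),
            major,
            minor,
            min(hull_perimeter / perimeter, 1.0) if perimeter > 0 else 1.0,
            min(area / (length * width), 1.0),
            r_mean,
            float(radii.std()) / r_mean,
            float(radii.max()) / r_mean,
            float(radii.min()) / r_mean,
            float(np.mean(np.abs(kappa))),
            float(np.std(kappa)),
            float(np.max(np.abs(kappa))),
            float(np.mean(kappa**2)),
        ]
    )


def _regionprops_block(mask: np.ndarray) -> tuple[float, float, float, float, float]:
    from skimage.measure import regionprops

    rp = regionprops(mask.astype(np.uint8))[0]
    return (
        float(rp.solidity),
        float(rp.eccentricity),
        float(rp.extent),
        float(rp.axis_major_length),
        float(rp.axis_minor_length or 1.0),
    )


def _hull_perimeter(contour: np.ndarray) -> float:
    hull = contour[ConvexHull(contour).vertices]
    closed = np.vstack([hull, hull[:1]])
    return float(np.hypot(*np.diff(closed, axis=0).T).sum())


def fourier_descriptors(contour: np.ndarray, n_harmonics: int = 10) -> np.ndarray:
    """Contour harmonic magnitudes, invariant to translation, rotation,
    scale and the starting point of the contour parameterization."""
    if n_harmonics + 2 > _RESAMPLE_N:
        raise ValueError(f"n_harmonics={n_harmonics} exceeds resample count {_RESAMPLE_N}")
    res = resample_contour(contour)
    z = res[:, 1] + 1j * res[:, 0]
    F = np.fft.fft(z) / len(z)
    scale = np.abs(F[1])
    if scale == 0:
        scale = np.finfo(float).eps
    return np.abs(F[2 : 2 + n_harmonics]) / scale


def _image_as_float(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    out = img.astype(float)
    if np.issubdtype(img.dtype, np.integer):
        out /= np.iinfo(img.dtype).max
    return out


def intensity_features(cell: CellRecord, image: np.ndarray) -> np.ndarray:
    """The 12-value intensity block from in-mask pixels."""
    img = _image_as_float(image)
    vals = img[cell.mask_slices()][cell.mask]
    if vals.size == 0:
        raise ValueError("empty mask: no in-cell pixels")
    q25, med, q75 = np.percentile(vals, [25, 50, 75])
    sd = float(vals.std())
    if sd > 0 and vals.size > 2:
        sk = float(skew(vals))
        ku = float(kurtosis(vals))
        med_off = float((vals.mean() - med) / sd)
        iqr_std = float((q75 - q25) / sd)
    else:
        sk = ku = med_off = iqr_std = 0.0
    return np.array(
        [
            float(vals.mean()),
            sd,
            float(vals.min()),
            float(vals.max()),
            float(med),
            float(q25),
            float(q75),
            float(q75 - q25),
            sk,
            ku,
            med_off,
            iqr_std,
        ]
    )


def microenvironment_features(
    cell: CellRecord,
    image: np.ndarray,
    annulus_width: int = 3,
    label_image: np.ndarray | None = None,
) -> np.ndarray:
    """The 10-value microenvironment block.

    The annulus is the morphological dilation of the cell mask minus the
    mask, with pixels belonging to other cells (per ``label_image``)
    excluded.  If the annulus ends up empty the block is a zero sentinel and
    a warning is issued.
    """
    img = _image_as_float(image)
    H, W = img.shape
    r0, c0, r1, c1 = cell.bbox
    er0, ec0 = max(r0 - annulus_width, 0), max(c0 - annulus_width, 0)
    er1, ec1 = min(r1 + annulus_width, H), min(c1 + annulus_width, W)
    big = np.zeros((er1 - er0, ec1 - ec0), bool)
    big[r0 - er0 : r1 - er0, c0 - ec0 : c1 - ec0] = cell.mask
    ann = ndimage.binary_dilation(big, iterations=annulus_width) & ~big
    if label_image is not None:
        other = label_image[er0:er1, ec0:ec1]
        ann &= (other == 0) | (other == cell.label_id)
    env = img[er0:er1, ec0:ec1][ann]
    cell_vals = img[cell.mask_slices()][cell.mask]
    if env.size == 0:
        warnings.warn("empty annulus: microenvironment block set to 0", stacklevel=2)
        return np.zeros(len(MICROENV_NAMES))
    q10, a_med, q90 = np.percentile(env, [10, 50, 90])
    a_mean, a_std = float(env.mean()), float(env.std())
    c_mean, c_med, c_std = float(cell_vals.mean()), float(np.median(cell_vals)), float(cell_vals.std())
    eps = np.finfo(float).eps
    return np.array(
        [
            a_mean,
            a_std,
            float(a_med),
            c_mean - a_mean,
            c_med - a_med,
            (c_mean - a_mean) / (abs(a_mean) + eps),
            (c_mean - a_mean) / (abs(c_mean) + abs(a_mean) + eps),
            (c_std - a_std) / (c_std + a_std + eps),
            float(q90 - a_med),
            float(q90 - q10),
        ]
    )


def extract_features(
    cell: CellRecord,
    image: np.ndarray,
    label_image: np.ndarray | None = None,
    annulus_width: int = 3,
    n_harmonics: int = 10,
) -> np.ndarray:
    """Concatenate the four blocks into the 54-value descriptor vector."""
    vec = np.concatenate(
        [
            shape_features(cell),
            fourier_descriptors(cell.contour, n_harmonics),
            intensity_features(cell, image),
            microenvironment_features(cell, image, annulus_width, label_image),
        ]
    )
    assert vec.shape == (N_FEATURES,)
    return vec


def features_table(records, image, label_image=None, frame_meta: dict | None = None):
    """Feature matrix for a list of records as a pandas DataFrame
    (metadata columns first, then the 54 named feature columns)."""
    import pandas as pd

    rows = []
    for rec in records:
        row = dict(frame_meta or {})
        row.update(rec.frame_ref)
        row["label_id"] = rec.label_id
        row["centroid_row"], row["centroid_col"] = rec.centroid
        vec = extract_features(rec, image, label_image=label_image)
        row.update(zip(FEATURE_NAMES, vec))
        rows.append(row)
    cols = list(rows[0].keys()) if rows else ["label_id", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=cols)
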