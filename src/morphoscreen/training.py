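"""Labelled training-cell generation for the supervised classifiers.

Renders frames of cells with known class identities and extracts the
54-descriptor vectors from the ground-truth masks (so training labels are
exact).  The screening defaults mirror the reference training design:
1728 lysed + 2017 intact cells for the intact/lysed discriminant stage and
332 round / 258 small / 595 normal / 376 elongated cells for the morphology
class models.
"""

from __future__ import annotations

import numpy as np

from .features import extract_features
from .segmentation import records_from_label_image
from .synth import NoiseParams, render_frame, scatter_cells

__all__ = ["labeled_cell_features", "DEFAULT_TRAINING_COUNTS"]

DEFAULT_TRAINING_COUNTS = {
    "normal": 595,
    "elongated": 376,
    "round": 332,
    "small": 258,
    "deformed": 300,
    "lysed": 1728,
}


def labeled_cell_features(
    counts: dict[str, int] | None = None,
    rng: np.random.Generator | int | None = None,
    cells_per_frame: int = 40,
    image_shape: tuple[int, int] = (512, 512),
    noise_params: NoiseParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix + class labels for a labelled synthetic cell bank.

    Cells of the requested classes are rendered in mixed frames and their
    descriptors computed from the ground-truth masks.  Returns ``(X, labels)``
    with ``X`` of shape (n_cells, 54).  Placement failures in crowded frames
    make the realised counts occasionally fall slightly short of the request.
    """
    if counts is None:
        counts = dict(DEFAULT_TRAINING_COUNTS)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    pool = [name for name, n in counts.items() for _ in range(n)]
    rng.shuffle(pool)
    X, labels = [], []
    for start in range(0, len(pool), cells_per_frame):
        batch = pool[start : start + cells_per_frame]
        cells = scatter_cells(batch, image_shape, rng)
        frame = render_frame(cells, image_shape, noise_params=noise_params, rng=rng)
        records = records_from_label_image(frame.labels)
        for rec in records:
            X.append(extract_features(rec, frame.image, frame.labels))
            labels.append(frame.cells[rec.label_id - 1].morph_class)
    return np.asarray(X), np.asarray(labels, dtype=object)
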