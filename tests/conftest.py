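import numpy as np
import pytest

from morphoscreen.segmentation import records_from_label_image
from morphoscreen.synth import render_frame, scatter_cells


@pytest.fixture(scope="session")
def mixed_frame():
    """One 512x512 frame with a known mix of all six cell classes."""
    rng = np.random.default_rng(1234)
    names = (
        ["normal"] * 4
        + ["small"] * 2
        + ["elongated"] * 2
        + ["round"] * 2
        + ["deformed"] * 2
        + ["lysed"] * 3
    )
    cells = scatter_cells(names, (512, 512), rng)
    frame = render_frame(cells, (512, 512), rng=rng)
    return frame


@pytest.fixture(scope="session")
def gt_records(mixed_frame):
    """Ground-truth CellRecords of the mixed frame (segmentation bypassed)."""
    return records_from_label_image(mixed_frame.labels)


@pytest.fixture(scope="session")
def cell_bank():
    """Labelled feature bank: ~80 cells per class, ~160 lysed."""
    from morphoscreen.training import labeled_cell_features

    counts = {
        "normal": 80,
        "small": 80,
        "elongated": 80,
        "round": 80,
        "deformed": 80,
        "lysed": 160,
    }
    X, labels = labeled_cell_features(counts, rng=99)
    return X, labels
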