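"""Flat-file interfaces: TIFF frames, CSV tables, JSON model files.

All intermediate artifacts of the pipeline are plain TIFF/CSV/JSON so that
every stage can be audited and rerun in isolation.  Frames are written as
16-bit grayscale TIFFs named ``<plate>_<well>_t<timepoint>_f<frame>.tif``;
classifier and reference models serialize to JSON (means, scales, loadings,
limits) for auditability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .outliers import ReferenceModel
from .plsda import PLSDAModel
from .simca import ClassSubModel, SIMCAModel
from .synth import Frame

__all__ = [
    "frame_filename",
    "write_frame",
    "read_frame",
    "write_ground_truth",
    "plsda_to_json",
    "plsda_from_json",
    "simca_to_json",
    "simca_from_json",
    "reference_to_json",
    "reference_from_json",
]


def frame_filename(meta: dict) -> str:
    return (
        f"{meta.get('plate_id', 'P0')}_{meta.get('strain_id', 'S0')}"
        f"_t{meta.get('timepoint', 0)}_f{meta.get('frame', 0)}.tif"
    )


def write_frame(frame: Frame, out_dir: str | Path, with_labels: bool = True) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / frame_filename(frame.meta)
    tifffile.imwrite(path, frame.image)
    if with_labels:
        tifffile.imwrite(path.with_suffix(".labels.tif"), frame.labels.astype(np.uint16))
    return path


def read_frame(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_ground_truth(frames: list[Frame], out_path: str | Path) -> pd.DataFrame:
    """One row per rendered cell: provenance, true class, geometry."""
    rows = []
    for frame in frames:
        for i, cell in enumerate(frame.cells):
            rows.append(
                {
                    **{k: frame.meta.get(k) for k in ("plate_id", "strain_id", "timepoint", "frame")},
                    "cell_index": i + 1,
                    "morph_class": cell.morph_class,
                    "centroid_row": cell.centroid[0],
                    "centroid_col": cell.centroid[1],
                    "length": cell.length,
                    "width": cell.width,
                    "contrast": cell.contrast,
                    "clipped": frame.clipped[i],
                }
            )
    df = pd.DataFrame(rows)
    df.to_csv(out_path, index=False)
    return df


def _json_default(o):
    if hasattr(o, "item"):
        return o.item()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _arr(x) -> list:
    return np.asarray(x).tolist()


def plsda_to_json(model: PLSDAModel, path: str | Path) -> None:
    payload = {
        "kind": "plsda",
        "n_components": model.n_components,
        "x_mean": _arr(model.x_mean),
        "x_scale": _arr(model.x_scale),
        "y_mean": model.y_mean,
        "weights": _arr(model.weights),
        "x_loadings": _arr(model.x_loadings),
        "y_loadings": _arr(model.y_loadings),
        "coef": _arr(model.coef),
        "kept": _arr(model.kept),
        "threshold": model.threshold,
        "classes": list(model.classes),
    }
    Path(path).write_text(json.dumps(payload, default=_json_default))


def plsda_from_json(path: str | Path) -> PLSDAModel:
    d = json.loads(Path(path).read_text())
    return PLSDAModel(
        n_components=d["n_components"],
        x_mean=np.array(d["x_mean"]),
        x_scale=np.array(d["x_scale"]),
        y_mean=d["y_mean"],
        weights=np.array(d["weights"]),
        x_loadings=np.array(d["x_loadings"]),
        y_loadings=np.array(d["y_loadings"]),
        coef=np.array(d["coef"]),
        kept=np.array(d["kept"], bool),
        threshold=d["threshold"],
        classes=tuple(d["classes"]),
    )


def simca_to_json(model: SIMCAModel, path: str | Path) -> None:
    payload = {
        "kind": "simca",
        "alpha": model.alpha,
        "classes": {
            name: {
                "k": sub.k,
                "mean": _arr(sub.mean),
                "scale": _arr(sub.scale),
                "loadings": _arr(sub.loadings),
                "eigenvalues": _arr(sub.eigenvalues),
                "sd2_norm": sub.sd2_norm,
                "od2_norm": sub.od2_norm,
                "limit": sub.limit,
                "n_train": sub.n_train,
            }
            for name, sub in model.classes.items()
        },
    }
    Path(path).write_text(json.dumps(payload, default=_json_default))


def simca_from_json(path: str | Path) -> SIMCAModel:
    d = json.loads(Path(path).read_text())
    classes = {
        name: ClassSubModel(
            name=name,
            k=s["k"],
            mean=np.array(s["mean"]),
            scale=np.array(s["scale"]),
            loadings=np.array(s["loadings"]),
            eigenvalues=np.array(s["eigenvalues"]),
            sd2_norm=s["sd2_norm"],
            od2_norm=s["od2_norm"],
            limit=s["limit"],
            n_train=s["n_train"],
        )
        for name, s in d["classes"].items()
    }
    return SIMCAModel(classes=classes, alpha=d["alpha"])


def reference_to_json(model: ReferenceModel, path: str | Path) -> None:
    payload = {
        "kind": "pca_reference",
        "mean": _arr(model.mean),
        "scale": _arr(model.scale),
        "loadings": _arr(model.loadings),
        "eigenvalues": _arr(model.eigenvalues),
        "k": model.k,
        "n": model.n,
        "explained": model.explained,
    }
    Path(path).write_text(json.dumps(payload, default=_json_default))


def reference_from_json(path: str | Path) -> ReferenceModel:
    d = json.loads(Path(path).read_text())
    return ReferenceModel(
        mean=np.array(d["mean"]),
        scale=np.array(d["scale"]),
        loadings=np.array(d["loadings"]),
        eigenvalues=np.array(d["eigenvalues"]),
        k=d["k"],
        n=d["n"],
        explained=d["explained"],
    )
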