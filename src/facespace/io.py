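"""Readers and writers for datasets, models, results tables and configs.

Dataset layout on disk: a directory of 8-bit grayscale PNG (or PGM)
images, one per sample with zero-padded ``sample_id`` filenames, plus a
``labels.csv`` with header ``sample_id,identity,sex,race,expression,viewpoint``.
Intensities are stored as v/255, so generation -> write -> load is
lossless (the generator quantizes to 8-bit levels).

All CSV round-trips are lossless at full float precision; parsers reject
malformed input rather than coercing it.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .faces import IMAGE_SHAPE, LABEL_COLUMNS, LabeledFaceSet
from .subspace import EigenModel, FisherModel

__all__ = [
    "DatasetManifest",
    "write_faceset",
    "load_faceset",
    "write_results",
    "read_results",
    "save_eigen_model",
    "load_eigen_model",
    "save_fisher_model",
    "load_fisher_model",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class DatasetManifest:
    """Location and layout of an on-disk image + label-table dataset."""

    root: Path
    image_format: str = "png"  # "png" | "pgm"
    labels_file: str = "labels.csv"
    checksums: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "root", Path(self.root))
        if self.image_format not in ("png", "pgm"):
            raise ValueError("image_format must be 'png' or 'pgm'")

    def image_path(self, sample_id: str) -> Path:
        return self.root / f"{sample_id}.{self.image_format}"


def write_faceset(
    faceset: LabeledFaceSet,
    root: str | Path,
    image_format: str = "png",
    checksum: bool = False,
) -> DatasetManifest:
    """Write images (8-bit grayscale, one file per sample) + labels.csv."""
    manifest = DatasetManifest(root=Path(root), image_format=image_format)
    manifest.root.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for i in range(faceset.n_samples):
        sid = str(faceset.labels["sample_id"].iloc[i])
        arr = np.round(faceset.images[i] * 255.0).astype(np.uint8)
        path = manifest.image_path(sid)
        pil_format = {"png": "PNG", "pgm": "PPM"}[image_format]
        Image.fromarray(arr, mode="L").save(path, format=pil_format)
        if checksum:
            checksums[sid] = hashlib.sha256(path.read_bytes()).hexdigest()
    faceset.labels.to_csv(manifest.root / manifest.labels_file, index=False)
    return DatasetManifest(
        root=manifest.root, image_format=image_format, checksums=checksums
    )


def load_faceset(
    manifest: DatasetManifest | str | Path,
    expected_shape: tuple[int, int] = IMAGE_SHAPE,
) -> LabeledFaceSet:
    """Load a dataset directory back into memory ([0,1] intensities),
    in labels.csv row order.

    Raises
    ------
    ValueError
        naming the offending sample or column for a missing image, wrong
        resolution, non-grayscale image or missing label column.
    """
    if not isinstance(manifest, DatasetManifest):
        manifest = DatasetManifest(root=Path(manifest))
    labels_path = manifest.root / manifest.labels_file
    if not labels_path.exists():
        raise FileNotFoundError(f"no label table at {labels_path}")
    labels = pd.read_csv(labels_path, dtype={"sample_id": str})
    missing_cols = [c for c in LABEL_COLUMNS if c not in labels.columns]
    if missing_cols:
        raise ValueError(f"labels.csv missing column(s): {missing_cols}")
    images = np.empty((len(labels), *expected_shape))
    for i, sid in enumerate(labels["sample_id"]):
        path = manifest.image_path(sid)
        if not path.exists():
            raise ValueError(f"missing image file for sample_id {sid!r}: {path}")
        with Image.open(path) as im:
            if im.mode != "L":
                raise ValueError(
                    f"sample_id {sid!r}: image mode {im.mode!r} is not "
                    "8-bit grayscale ('L')"
                )
            arr = np.asarray(im)
        if arr.shape != expected_shape:
            raise ValueError(
                f"sample_id {sid!r}: resolution {arr.shape} != "
                f"expected {expected_shape}"
            )
        images[i] = arr / 255.0
    return LabeledFaceSet(images=images, labels=labels)


# -- results tables ---------------------------------------------------------

RESULTS_FLOAT_FORMAT = "%.17g"  # round-trips float64 exactly


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Results CSV with full-precision numeric fields."""
    table.to_csv(path, index=False, float_format=RESULTS_FLOAT_FORMAT)


def read_results(path: str | Path) -> pd.DataFrame:
    try:
        return pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed results CSV {path}: {exc}") from exc


# -- model containers -------------------------------------------------------


def save_eigen_model(model: EigenModel, path: str | Path) -> None:
    """Single-file container: arrays + JSON metadata."""
    meta = {"kind": "eigen", "image_shape": list(model.image_shape)}
    np.savez(
        path,
        mean_face=model.mean_face,
        components=model.components,
        eigenvalues=model.eigenvalues,
        metadata=np.array(json.dumps(meta)),
    )


def load_eigen_model(path: str | Path) -> EigenModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["metadata"]))
        if meta.get("kind") != "eigen":
            raise ValueError(f"{path} is not an Eigenface model container")
        return EigenModel(
            mean_face=z["mean_face"],
            components=z["components"],
            eigenvalues=z["eigenvalues"],
            image_shape=tuple(meta["image_shape"]),
        )


def save_fisher_model(model: FisherModel, path: str | Path) -> None:
    meta = {
        "kind": "fisher",
        "trained_property": model.trained_property,
        "class_labels": [str(c) for c in model.class_labels],
        "ridge": model.ridge,
        "n_discriminants": model.n_discriminants,
        "n_padded": model.n_padded,
    }
    np.savez(
        path,
        directions=model.directions,
        eigenvalues=model.eigenvalues,
        padding=model.padding,
        s_w=model.s_w,
        metadata=np.array(json.dumps(meta)),
    )


def load_fisher_model(path: str | Path) -> FisherModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["metadata"]))
        if meta.get("kind") != "fisher":
            raise ValueError(f"{path} is not a Fisherface model container")
        return FisherModel(
            directions=z["directions"],
            eigenvalues=z["eigenvalues"],
            trained_property=meta["trained_property"],
            class_labels=tuple(meta["class_labels"]),
            ridge=float(meta["ridge"]),
            s_w=z["s_w"],
            padding=z["padding"],
        )


# -- configuration ----------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
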