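"""File formats, manifests and run directories.

Label maps travel as 8-bit indexed PNG (with a fixed inspection palette
per class scheme) or as single-slice NIfTI volumes; images as 8-bit
grayscale PNG or float NIfTI. A *manifest* is a tab-separated table
listing sample_id, image path, label path and provenance, with paths
resolved relative to the manifest file.

Coordinate convention: label maps are row-major, origin at the top-left,
0-based class indices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .core import CANONICAL_SCHEME, ClassScheme, SliceSample

__all__ = [
    "PALETTE",
    "save_sample",
    "read_sample",
    "write_manifest",
    "read_manifest",
    "load_samples",
    "write_run_dir",
]

# Inspection palette (RGB), one entry per canonical class: background black,
# muscle pink, subcutaneous fat yellow, visceral fat blue.
PALETTE: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),
    (255, 105, 180),
    (255, 215, 0),
    (65, 105, 225),
)

_MANIFEST_COLUMNS = ["sample_id", "image_path", "label_path", "provenance"]
_MANIFEST_HEADER = (
    "# labelrefine manifest: tab-separated; paths relative to this file.\n"
    "# label maps are row-major, origin top-left, 0-based class indices.\n"
)


# ---------------------------------------------------------------------------
# single-slice readers / writers

def _save_labels_png(labels: np.ndarray, path: Path) -> None:
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = list(np.asarray(PALETTE, dtype=np.uint8).ravel())
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)


def _save_nifti(data: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(data[..., None], affine=np.eye(4)), str(path))


def save_sample(sample: SliceSample, directory, fmt: str = "png") -> tuple[Path, Path]:
    """Write a sample's image and label map; returns the two paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "png":
        image_path = directory / f"{sample.sample_id}_image.png"
        label_path = directory / f"{sample.sample_id}_labels.png"
        Image.fromarray(
            np.round(sample.image * 255).astype(np.uint8), mode="L"
        ).save(image_path)
        _save_labels_png(sample.labels, label_path)
    elif fmt == "nifti":
        image_path = directory / f"{sample.sample_id}_image.nii.gz"
        label_path = directory / f"{sample.sample_id}_labels.nii.gz"
        _save_nifti(sample.image.astype(np.float32), image_path)
        _save_nifti(sample.labels.astype(np.uint8), label_path)
    else:
        raise ValueError(f"unsupported format {fmt!r}; use 'png' or 'nifti'")
    return image_path, label_path


def _read_array(path: Path) -> np.ndarray:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(str(path)).dataobj)
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-slice volume, got shape {data.shape}")
        return data
    if name.endswith(".png"):
        return np.asarray(Image.open(path))
    raise ValueError(f"{path}: unsupported format (PNG or NIfTI expected)")


def read_sample(image_path, label_path, scheme: ClassScheme = CANONICAL_SCHEME,
                provenance: str = "weak", sample_id: str | None = None) -> SliceSample:
    """Read one image + label pair; normalizes the image to [0, 1] and
    validates the labels against the scheme."""
    image_path, label_path = Path(image_path), Path(label_path)
    raw = _read_array(image_path)
    image = raw.astype(np.float64)
    if np.issubdtype(raw.dtype, np.integer):
        image /= np.iinfo(raw.dtype).max
    image = np.clip(image, 0.0, 1.0)

    labels = _read_array(label_path)
    if labels.ndim == 3:  # RGB-encoded label PNG is not supported
        raise ValueError(f"{label_path}: label map must be single-channel")
    labels = labels.astype(np.int64)
    bad = labels[(labels < 0) | (labels >= scheme.count)]
    if bad.size:
        raise ValueError(
            f"{label_path}: unknown class value {int(bad.flat[0])} "
            f"(scheme has {scheme.count} classes)"
        )
    if image.shape != labels.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} ({image_path}) vs "
            f"labels {labels.shape} ({label_path})"
        )
    if sample_id is None:
        sample_id = image_path.name
        for suffix in (".nii.gz", ".nii", ".png"):
            if sample_id.lower().endswith(suffix):
                sample_id = sample_id[: -len(suffix)]
                break
        sample_id = sample_id.replace("_image", "")
    return SliceSample(
        image=image, labels=labels, provenance=provenance,
        sample_id=sample_id, scheme=scheme,
    )


# ---------------------------------------------------------------------------
# manifests

def write_manifest(samples: Sequence[SliceSample], directory, fmt: str = "png",
                   provenance: str | None = None,
                   manifest_name: str = "manifest.tsv") -> Path:
    """Write all samples plus a manifest listing them; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        image_path, label_path = save_sample(s, directory, fmt=fmt)
        rows.append(dict(sample_id=s.sample_id,
                         image_path=image_path.name,
                         label_path=label_path.name,
                         provenance=provenance or s.provenance))
    path = directory / manifest_name
    with open(path, "w") as fh:
        fh.write(_MANIFEST_HEADER)
        pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(fh, sep="\t", index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    """Read and validate a manifest; paths are resolved against its directory."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_ids {dup}")
    bad_prov = set(frame["provenance"]) - {"strong", "weak", "truth"}
    if bad_prov:
        raise ValueError(f"{path}: invalid provenance values {sorted(bad_prov)}")
    base = path.parent
    for col in ("image_path", "label_path"):
        frame[col] = [str(base / p) for p in frame[col]]
        for p in frame[col]:
            if not Path(p).exists():
                raise FileNotFoundError(f"{path}: referenced file missing: {p}")
    return frame


def load_samples(path, scheme: ClassScheme = CANONICAL_SCHEME) -> list[SliceSample]:
    """Load every sample listed in a manifest."""
    frame = read_manifest(path)
    return [
        read_sample(r.image_path, r.label_path, scheme=scheme,
                    provenance=r.provenance, sample_id=r.sample_id)
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# run directories

def write_run_dir(run, cfg, out_dir, package_version: str | None = None) -> Path:
    """Persist a refinement run: config echo, history log, final weak
    revisions, metrics report and a model checkpoint."""
    from dataclasses import asdict

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if package_version is None:
        from . import __version__ as package_version
    echo = dict(train=asdict(cfg), model=run.model.config,
                package_version=package_version)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=False)
    run.history.to_csv(out_dir / "history.csv", index=False)
    write_manifest(run.weak_set, out_dir / "label_revisions",
                   manifest_name="manifest.tsv")
    (out_dir / "checkpoints").mkdir(exist_ok=True)
    run.model.save(out_dir / "checkpoints" / "model.npz")
    if run.metrics is not None:
        with open(out_dir / "metrics.json", "w") as fh:
            json.dump(run.metrics.to_dict(), fh, indent=2)
    return out_dir
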