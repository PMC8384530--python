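"""Reading and writing images, manifests and model checkpoints.

Grayscale PNG/TIFF rasters are read through imageio; DICOM slices through
pydicom when it is installed (the rescale slope/intercept are applied).
Manifests are plain CSV files with ``path,label`` columns, paths relative to
the manifest's directory.  Checkpoints are NumPy ``.npz`` archives holding the
architecture as JSON plus the flat parameter vector.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .cnn import ArchitectureSpec, NetworkParams


def load_image(path: str | Path) -> np.ndarray:
    """Load one grayscale slice as a 2-D float array.

    PNG/TIFF: 8/16-bit rasters are converted to float (original integer range
    preserved); RGB inputs are averaged to one channel.  ``.dcm`` files are
    read with pydicom and mapped through RescaleSlope/RescaleIntercept.
    """
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError("reading DICOM requires the 'pydicom' extra") from exc
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept
    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D grayscale image, got shape {arr.shape}")
    return arr


def save_png(path: str | Path, image: np.ndarray) -> None:
    """Write a float image as 8-bit PNG, min-max scaled to [0, 255]."""
    arr = np.asarray(image, dtype=float)
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    iio.imwrite(Path(path), (scaled * 255).round().astype(np.uint8))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """CSV with ``path,label`` columns; label coerced to int."""
    df = pd.read_csv(path)
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    df = df.copy()
    df["label"] = df["label"].astype(int)
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df[["path", "label"]].to_csv(path, index=False)


def load_manifest_images(manifest: pd.DataFrame, root: str | Path) -> np.ndarray:
    """Load every image listed in a manifest (paths relative to ``root``)."""
    root = Path(root)
    return np.stack([load_image(root / p) for p in manifest["path"]])


def save_checkpoint(path: str | Path, arch: ArchitectureSpec, params: NetworkParams) -> None:
    """Portable archive: architecture JSON + flat parameter vector (.npz)."""
    from .mpa_cnn import flatten_params

    arch_json = json.dumps({
        "input_shape": arch.input_shape,
        "conv_filters": arch.conv_filters,
        "conv_kernel": arch.conv_kernel,
        "pool_window": arch.pool_window,
        "dense_units": arch.dense_units,
        "num_classes": arch.num_classes,
        "dropout_rate": arch.dropout_rate,
    })
    np.savez(Path(path), arch=np.array(arch_json), flat=flatten_params(params))


def load_checkpoint(path: str | Path) -> tuple[ArchitectureSpec, NetworkParams]:
    from .mpa_cnn import unflatten_params

    with np.load(Path(path), allow_pickle=False) as data:
        spec = json.loads(str(data["arch"]))
        flat = data["flat"]
    arch = ArchitectureSpec(
        input_shape=tuple(spec["input_shape"]),
        conv_filters=tuple(spec["conv_filters"]),
        conv_kernel=tuple(spec["conv_kernel"]),
        pool_window=tuple(spec["pool_window"]),
        dense_units=tuple(spec["dense_units"]),
        num_classes=spec["num_classes"],
        dropout_rate=spec["dropout_rate"],
    )
    return arch, unflatten_params(flat, arch)
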