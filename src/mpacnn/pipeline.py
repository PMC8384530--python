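"""End-to-end workflow: preprocess -> split -> train -> evaluate.

A :class:`RunConfig` describes one experiment: where the images come from (a
manifest directory or the synthetic generator), the preprocessing settings,
the network architecture, the optimizer (RMSprop or MPA) and its budget, and
the global seed.  :func:`run_pipeline` executes the stages in order and returns
a JSON-serializable report containing the resolved configuration, the
confusion-matrix metrics on the held-out split and the training history, so a
run can be reproduced from its own report.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import metrics as metrics_mod
from .cnn import ArchitectureSpec, one_hot, predict_labels, train_rmsprop
from .mpa_cnn import EncodingSpec, train_with_mpa
from .preprocess import preprocess_stack
from .synthetic import SyntheticSpec, generate_dataset


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    Defaults mirror the full-scale protocol: 80/20 random split, batch 32,
    200 optimizer iterations, population 100, 227x227 network input.  The
    desk-scale presets shrink the image and network so the whole MPA loop runs
    in seconds on one CPU.
    """

    seed: int = 0
    split_fraction: float = 0.8
    stratify: bool = True
    # data source: exactly one of input_dir (manifest directory) or synthetic
    input_dir: str | None = None
    synthetic: SyntheticSpec | None = None
    # preprocessing
    kernel: tuple[int, int] = (5, 5)
    network_input: tuple[int, int] = (227, 227)
    # architecture
    conv_filters: tuple[int, ...] = (32, 64, 128)
    conv_kernel: tuple[int, int] = (3, 3)
    pool_window: tuple[int, int] = (2, 2)
    dense_units: tuple[int, ...] = (64,)
    dropout_rate: float = 0.5
    # training
    optimizer: str = "mpa"  # mpa | rmsprop
    mode: str = "weights-only"
    cost: str = "mse"
    population: int = 100
    iterations: int = 200
    batch_size: int = 32
    eta: float = 1e-4
    weight_bound: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie strictly between 0 and 1")
        if self.optimizer not in ("mpa", "rmsprop"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    def architecture(self) -> ArchitectureSpec:
        return ArchitectureSpec(
            input_shape=(*self.network_input, 1),
            conv_filters=self.conv_filters,
            conv_kernel=self.conv_kernel,
            pool_window=self.pool_window,
            dense_units=self.dense_units,
            num_classes=2,
            dropout_rate=self.dropout_rate,
        )

    @classmethod
    def easy_synthetic(cls, seed: int = 0, iterations: int = 100,
                       population: int = 20) -> "RunConfig":
        """Desk-scale preset: easy synthetic data, tiny network, MPA weights.

        64x64 images with a high-contrast nodule and 5% impulse noise.  The
        network input is downsampled to 6x6 and the conv stage uses two 1x1
        filters (a learned pixelwise intensity transfer), leaving the spatial
        reasoning to the dense readout: per-image min-max normalization maps
        the nodule peak to 1 in every positive, so the discriminative signal
        is the compressed mid-tone distribution, which a coarse weighted sum
        captures better than a blob detector.  The whole weight vector stays
        near 40 dimensions so the optimizer budget is small.
        """
        return cls(
            seed=seed,
            synthetic=SyntheticSpec(n_images=60, image_size=(64, 64),
                                    nodule_contrast=0.5, noise_fraction=0.05,
                                    seed=seed),
            kernel=(3, 3),
            network_input=(6, 6),
            conv_filters=(2,),
            conv_kernel=(1, 1),
            dense_units=(),
            dropout_rate=0.0,
            optimizer="mpa",
            population=population,
            iterations=iterations,
        )

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        if data.get("synthetic") is not None:
            syn = dict(data["synthetic"])
            for key in ("image_size", "nodule_radius_range"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            data["synthetic"] = SyntheticSpec(**syn)
        for key in ("kernel", "network_input", "conv_filters", "conv_kernel",
                    "pool_window", "dense_units"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def default_arch_for(size: tuple[int, int], num_classes: int = 2) -> ArchitectureSpec:
    """Full-scale architecture trimmed to what the input size supports.

    Keeps the longest prefix of the default 32/64/128 conv stack whose feature
    maps stay at least as large as the pool window; small inputs may end up
    with one stage and a narrower dense head.
    """
    filters = (32, 64, 128)
    for keep in (3, 2, 1):
        try:
            return ArchitectureSpec(input_shape=(*size, 1),
                                    conv_filters=filters[:keep],
                                    dense_units=(64,) if min(size) >= 32 else (8,),
                                    num_classes=num_classes)
        except ValueError:
            continue
    raise ValueError(f"input size {size} too small for any conv stage")


def split_dataset(
    manifest: pd.DataFrame,
    split_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split into disjoint, exhaustive train/test manifests.

    With ``stratify`` (default) the split is performed within each class, so
    both sides match the overall class balance to within one sample per class.
    Raises if either side would be empty.
    """
    if len(manifest) == 0:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(seed)
    if stratify:
        train_parts, test_parts = [], []
        for _, group in manifest.groupby("label", sort=True):
            order = rng.permutation(len(group))
            n_train = int(round(len(group) * split_fraction))
            train_parts.append(group.iloc[order[:n_train]])
            test_parts.append(group.iloc[order[n_train:]])
        train = pd.concat(train_parts)
        test = pd.concat(test_parts)
    else:
        order = rng.permutation(len(manifest))
        n_train = int(round(len(manifest) * split_fraction))
        train = manifest.iloc[order[:n_train]]
        test = manifest.iloc[order[n_train:]]
    if len(train) == 0 or len(test) == 0:
        raise ValueError(f"split {split_fraction} leaves one side empty for n={len(manifest)}")
    return train.reset_index(drop=True), test.reset_index(drop=True)


def _load_data(cfg: RunConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    if (cfg.synthetic is None) == (cfg.input_dir is None):
        raise ValueError("config must set exactly one of synthetic / input_dir")
    if cfg.synthetic is not None:
        return generate_dataset(cfg.synthetic)
    from .io import load_manifest_images, read_manifest

    root = Path(cfg.input_dir)
    manifest = read_manifest(root / "manifest.csv")
    images = load_manifest_images(manifest, root)
    return images, manifest["label"].to_numpy(), manifest


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute preprocess -> split -> train -> evaluate; return the run report."""
    timings: dict[str, float] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        images, labels, manifest = _load_data(cfg)
        timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        processed = preprocess_stack(images, kernel=cfg.kernel, size=cfg.network_input)
        timings[stage] = time.perf_counter() - t0

        stage = "split"
        t0 = time.perf_counter()
        manifest = manifest.reset_index(drop=True)
        manifest["_row"] = np.arange(len(manifest))
        train_m, test_m = split_dataset(manifest, cfg.split_fraction, cfg.seed, cfg.stratify)
        tr = train_m["_row"].to_numpy()
        te = test_m["_row"].to_numpy()
        timings[stage] = time.perf_counter() - t0

        stage = "train"
        t0 = time.perf_counter()
        arch = cfg.architecture()
        targets = one_hot(labels[tr], 2)
        if cfg.optimizer == "mpa":
            result = train_with_mpa(
                arch, processed[tr], targets,
                encoding=EncodingSpec(mode=cfg.mode, weight_bound=cfg.weight_bound),
                cost_kind=cfg.cost, n=cfg.population, max_iter=cfg.iterations,
                seed=cfg.seed,
            )
            params, arch = result.params, result.arch
            history = result.history
        else:
            trained = train_rmsprop(arch, processed[tr], targets,
                                    iterations=cfg.iterations, eta=cfg.eta,
                                    batch_size=cfg.batch_size, seed=cfg.seed)
            params = trained.params
            history = trained.history
        timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        pred = predict_labels(params, processed[te], arch)
        counts = metrics_mod.confusion(labels[te], pred)
        report = metrics_mod.report(counts)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "n_train": int(len(tr)),
        "n_test": int(len(te)),
        "metrics": report,
        "history": [float(h) for h in history],
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "_params": params,
        "_arch": arch,
    }
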