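"""End-to-end orchestration: clean -> integrate -> discretize -> scatter ->
select -> post-process -> classify -> evaluate, with an 80/20 stratified
split and train-only fitting of every stateful stage.

The pipeline is configured by a :class:`PipelineConfig` (YAML-friendly
nested dicts); ``run_pipeline`` returns a :class:`~harpipe.metrics.MetricReport`
and optionally writes feature matrices, fitted models and the report to an
output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import cleaning, io_formats, postprocess, scattering, selection, transform
from .classifier import TrainConfig, init_network, predict, train
from .metrics import MetricReport, evaluate_predictions
from .records import RawRecordSet, WindowSet
from .synthetic import DefectSpec, default_activity_models, generate_dataset

__all__ = ["PipelineConfig", "split_80_20", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, grouped per stage."""

    data: dict = field(default_factory=lambda: {
        "source": "synthetic",            # or a CSV path
        "n_windows_per_class": 200,
        "window_len": 128,
        "n_channels": 3,
        "missing_rate": 0.01,
        "duplicate_rate": 0.02,           # inserted copies; removed before segmentation
        "corrupt_rate": 0.01,
        "corrupt_magnitude": 50.0,
        "permute_labels": False,
    })
    cleaning: dict = field(default_factory=lambda: {
        "n_bins": 16, "strategy": "equal-frequency", "smoothing": "means",
    })
    transform: dict = field(default_factory=lambda: {
        "enabled": True, "candidate_ks": [4, 6, 8, 12, 16], "n_init": 5,
        "n_hist_bins": 32, "C_boltz": 1.0,
    })
    scattering: dict = field(default_factory=lambda: {"J": 4, "normalize": True})
    selection: dict = field(default_factory=lambda: {
        "enabled": True, "pop_size": 20, "iter_max": 60,
        "omega": 0.1, "threshold": 0.5,
    })
    classifier: dict = field(default_factory=lambda: {
        "n_lego": 4, "fragment_dim": 4, "kernel_len": 3, "n_layers": 2,
        "learning_rate": 0.05, "epochs": 300, "batch_size": 32, "patience": 50,
        "val_fraction": 0.1,
    })
    eval: dict = field(default_factory=lambda: {"train_fraction": 0.8})

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            overrides = yaml.safe_load(fh) or {}
        cfg = cls()
        for section, values in overrides.items():
            if not hasattr(cfg, section):
                raise ValueError(f"unknown config section {section!r}")
            getattr(cfg, section).update(values or {})
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def split_80_20(
    windows: WindowSet, seed: int, train_fraction: float = 0.8
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split (default 80/20), deterministic.

    Per class, ``round(train_fraction * n_class)`` windows go to train.
    Returns (train_idx, test_idx), disjoint and exhaustive.
    """
    rng = np.random.default_rng(seed)
    labels = windows.labels
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ValueError(f"class {cls} has fewer than 2 windows; cannot stratify")
        idx = rng.permutation(idx)
        n_tr = int(round(train_fraction * len(idx)))
        n_tr = min(max(n_tr, 1), len(idx) - 1)
        train_idx.append(idx[:n_tr])
        test_idx.append(idx[n_tr:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _load_windows(cfg: PipelineConfig, seed: int) -> WindowSet:
    d = cfg.data
    if d["source"] == "synthetic":
        defects = DefectSpec(
            missing_rate=d["missing_rate"],
            duplicate_rate=d["duplicate_rate"],
            corrupt_rate=d["corrupt_rate"],
            corrupt_magnitude=d["corrupt_magnitude"],
        )
        records, _ = generate_dataset(
            default_activity_models(d["n_channels"]),
            n_windows_per_class=d["n_windows_per_class"],
            window_len=d["window_len"],
            n_channels=d["n_channels"],
            defects=defects,
            seed=seed,
        )
    else:
        records = io_formats.read_raw_csv(d["source"])
    records, n_dup = cleaning.drop_consecutive_duplicates(records)
    if n_dup:
        logger.info("removed %d exact consecutive duplicates", n_dup)
    records = transform.integrate([records])
    windows = io_formats.segment_stream(
        records, window_len=d["window_len"], allow_missing=True
    )
    if d.get("permute_labels"):
        rng = np.random.default_rng(seed + 1)
        windows.labels = rng.permutation(windows.labels)
    return windows


def _flat_stream(values_3d: np.ndarray, channel_names: list[str]) -> RawRecordSet:
    """View a window stack as a flat record stream for stream-level fitters."""
    n, c, L = values_3d.shape
    flat = values_3d.transpose(0, 2, 1).reshape(n * L, c)
    return RawRecordSet(
        timestamps=np.arange(n * L),
        values=flat,
        labels=np.zeros(n * L, dtype=np.int64),
        source_ids=np.full(n * L, "train"),
        stage="cleaned",
        channel_names=channel_names,
    )


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir: str | os.PathLike | None = None,
) -> MetricReport:
    """Run every stage on one dataset and evaluate on the held-out 20%.

    All stateful transforms (binning model, discretizer, selection mask,
    scatter summary, classifier) are fitted on the training windows only.
    """
    cfg = config or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    windows = _load_windows(cfg, seed)
    timings["load"] = time.perf_counter() - t0
    logger.info("windows: %s", windows.windows.shape)

    train_idx, test_idx = split_80_20(
        windows, seed=seed, train_fraction=cfg.eval["train_fraction"]
    )

    # cleaning: fit bins on train values only, smooth+impute both splits
    t = time.perf_counter()
    n, c, L = windows.windows.shape
    train_vals = windows.windows[train_idx].transpose(0, 2, 1).reshape(-1, c)
    clean_model = cleaning.fit_cleaning_model(
        train_vals,
        n_bins=cfg.cleaning["n_bins"],
        strategy=cfg.cleaning["strategy"],
        smoothing=cfg.cleaning["smoothing"],
        channel_names=windows.channel_names,
    )
    flat_all = windows.windows.transpose(0, 2, 1).reshape(-1, c)
    cleaned = cleaning.apply_to_array(clean_model, flat_all)
    cleaned_windows = WindowSet(
        windows=cleaned.reshape(n, L, c).transpose(0, 2, 1),
        labels=windows.labels,
        channel_names=windows.channel_names,
        provenance=windows.provenance,
        stage="cleaned",
    )
    timings["cleaning"] = time.perf_counter() - t

    # E-C-D discretization, train-fitted
    t = time.perf_counter()
    if cfg.transform["enabled"]:
        disc = transform.fit_discretizer(
            _flat_stream(cleaned_windows.windows[train_idx], windows.channel_names),
            candidate_ks=cfg.transform["candidate_ks"],
            n_init=cfg.transform["n_init"],
            seed=seed,
            n_hist_bins=cfg.transform["n_hist_bins"],
            C_boltz=cfg.transform["C_boltz"],
        )
        digital = np.empty_like(cleaned_windows.windows)
        for j in range(c):
            digital[:, j, :] = transform.quantize_channel(
                cleaned_windows.windows[:, j, :], disc.centroids[j]
            )
        work_windows = WindowSet(
            windows=digital, labels=windows.labels,
            channel_names=windows.channel_names, stage="digital",
        )
    else:
        disc = None
        work_windows = cleaned_windows
    timings["transform"] = time.perf_counter() - t

    # wavelet scattering features
    t = time.perf_counter()
    bank = scattering.build_filter_bank(
        cfg.scattering["J"], L, normalize=cfg.scattering["normalize"]
    )
    feats = scattering.extract_features(work_windows, bank)
    timings["scattering"] = time.perf_counter() - t

    # standardize with train statistics, then GEO selection on train
    t = time.perf_counter()
    pre_summary = postprocess.scatter_matrix(feats.features[train_idx])
    z_all = postprocess.normalize(feats.features, pre_summary)
    if cfg.selection["enabled"]:
        sel = selection.select_features(
            z_all[train_idx],
            windows.labels[train_idx],
            fitness=selection.FitnessSpec(
                omega=cfg.selection["omega"],
                threshold=cfg.selection["threshold"],
                cv_seed=seed,
            ),
            pop_size=cfg.selection["pop_size"],
            iter_max=cfg.selection["iter_max"],
            seed=seed,
            feature_names=feats.feature_names,
        )
        mask = sel.mask
    else:
        sel = None
        mask = np.ones(z_all.shape[1], dtype=bool)
    timings["selection"] = time.perf_counter() - t

    # scatter-matrix post-processing on the selected training features
    t = time.perf_counter()
    summary = postprocess.scatter_matrix(feats.features[train_idx][:, mask])
    X_all = postprocess.normalize(feats.features[:, mask], summary)
    timings["postprocess"] = time.perf_counter() - t

    # classifier with a small validation split carved from train
    t = time.perf_counter()
    y = windows.labels
    tr_sub, val_sub = split_80_20(
        WindowSet(
            windows=np.zeros((len(train_idx), 1, 1)), labels=y[train_idx]
        ),
        seed=seed + 2,
        train_fraction=1.0 - cfg.classifier["val_fraction"],
    )
    ccfg = cfg.classifier
    model = init_network(
        input_dim=int(mask.sum()),
        n_classes=len(np.unique(y)),
        n_lego=ccfg["n_lego"],
        fragment_dim=min(ccfg["fragment_dim"], int(mask.sum())),
        kernel_len=ccfg["kernel_len"],
        n_layers=ccfg["n_layers"],
        seed=seed,
    )
    tconf = TrainConfig(
        learning_rate=ccfg["learning_rate"],
        epochs=ccfg["epochs"],
        batch_size=ccfg["batch_size"],
        seed=seed,
        patience=ccfg["patience"],
    )
    Xtr = X_all[train_idx]
    train(
        model,
        Xtr[tr_sub],
        y[train_idx][tr_sub],
        tconf,
        X_val=Xtr[val_sub],
        y_val=y[train_idx][val_sub],
    )
    timings["train"] = time.perf_counter() - t

    preds = predict(model, X_all[test_idx])
    report = evaluate_predictions(y[test_idx], preds.labels)
    report.seed = seed
    report.config_hash = cfg.hash()
    report.split_sizes = {"train": len(train_idx), "test": len(test_idx)}

    if out_dir is not None:
        _write_artifacts(
            out_dir, cfg, feats, mask, sel, disc, report, timings
        )
    return report


def _write_artifacts(out_dir, cfg, feats, mask, sel, disc, report, timings):
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    pd.DataFrame(feats.features, columns=feats.feature_names).to_csv(
        os.path.join(out_dir, "features.csv"), index=False
    )
    if disc is not None:
        disc.to_json(os.path.join(out_dir, "discretizer.json"))
    with open(os.path.join(out_dir, "selection.json"), "w") as fh:
        json.dump(
            {
                "mask": mask.astype(int).tolist(),
                "selected_names": sel.selected_names if sel else feats.feature_names,
                "best_fitness": None if sel is None else sel.best_fitness,
                "trace": None if sel is None else sel.trace.tolist(),
            },
            fh,
            indent=1,
        )
    payload = report.to_dict()
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    with open(os.path.join(out_dir, "timings.json"), "w") as fh:
        json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=1)
    with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
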