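"""End-to-end orchestration: simulate/load -> bin -> train -> predict -> evaluate.

A run is driven by a single :class:`RunConfig` and is fully reproducible
from it: the global seed fans out to per-stage seeds through a fixed
counter scheme (simulation = seed, augmentation = seed + 1, split =
seed + 2, training = seed + 3, threshold selection = seed + 4).
Artifacts written per run: the model archive, a prediction table, a
metrics table and a machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .augmentation import AugmentConfig, augment_dataset
from .binning import BinGrid, DensityPrior, bin_sample, build_adaptive_grid, build_uniform_grid, scale_minmax
from .decision import REJECTED, classify_with_reject, select_threshold
from .evaluation import MacroReport, MetricsReport, macro_metrics, stratified_split
from .io import Sample, read_mzml
from .model import EnsembleModel, MemberConfig, predict_proba, save_ensemble, train_ensemble
from .synthetic import SimConfig, make_signatures, simulate_dataset, BatchProfile

logger = logging.getLogger("lcmsnet")

__all__ = ["RunConfig", "RunResult", "run_end_to_end", "run_cross_batch"]

_REQUIRED_KEYS = ("seed", "grid", "member")


@dataclass
class RunConfig:
    """Everything needed to reproduce one end-to-end run.

    Either ``sim`` (synthetic study design) or ``input_paths`` +
    ``labels`` (mzML files on disk) provides the data.  ``grid``
    describes the binning lattice; ``reject_threshold`` is a margin in
    [0, 1], ``"auto"`` (specificity-optimised on 10% of the training
    data) or ``None`` for plain argmax.
    """

    seed: int = 0
    sim: SimConfig | None = None
    n_markers: int = 10
    batches: tuple[BatchProfile, ...] = (BatchProfile(batch_id="batch0"),)
    input_paths: tuple[str, ...] = ()
    labels: dict[str, str] = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    scaling_mode: str = "per_column"
    augment: AugmentConfig | None = AugmentConfig()
    oversample: bool = True
    member: MemberConfig = MemberConfig()
    n_members: int = 5
    reject_threshold: float | str | None = None
    test_fraction: float = 0.25
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        """Build from a plain (e.g. YAML-loaded) dict, validating required keys."""
        missing = [k for k in _REQUIRED_KEYS if k not in d]
        if missing:
            raise ValueError(f"config missing required key(s): {', '.join(missing)}")
        d = dict(d)
        if "sim" in d and d["sim"] is not None and not isinstance(d["sim"], SimConfig):
            sim = dict(d["sim"])
            for key in ("samples_per_class", "shared_peaks", "mz_span"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["sim"] = SimConfig(**sim)
        if "batches" in d:
            d["batches"] = tuple(
                b if isinstance(b, BatchProfile) else BatchProfile(**b) for b in d["batches"]
            )
        if "augment" in d and d["augment"] is not None and not isinstance(d["augment"], AugmentConfig):
            d["augment"] = AugmentConfig(**d["augment"])
        if "member" in d and not isinstance(d["member"], MemberConfig):
            d["member"] = MemberConfig(**d["member"])
        return cls(**d)

    def build_grid(self, acquisition_span: tuple[float, float]) -> BinGrid:
        g = dict(self.grid)
        mode = g.get("mode", "adaptive")
        rt_span = tuple(g.get("rt_span", acquisition_span))
        if mode == "uniform":
            return build_uniform_grid(
                rt_span, g["rt_width"], tuple(g["mz_span"]), g["mz_width"]
            )
        if mode == "adaptive":
            prior = DensityPrior(regions=tuple(tuple(r) for r in g["prior"]))
            return build_adaptive_grid(rt_span, g["acquisition_interval"], prior)
        raise ValueError(f"unknown grid mode: {mode!r}")


@dataclass
class RunResult:
    """Outcome of one end-to-end run."""

    report: MacroReport
    predictions: pd.DataFrame
    threshold: float
    n_rejected: int
    model: EnsembleModel
    manifest: dict


def _load_data(config: RunConfig) -> list[Sample]:
    if config.sim is not None:
        signatures = make_signatures(config.sim.n_classes, config.n_markers, config.sim)
        samples = simulate_dataset(config.sim, signatures, config.batches)
        logger.info("pipeline: simulated %d samples", len(samples))
        return samples
    if not config.input_paths:
        raise ValueError("config provides neither a simulation nor input mzML paths")
    samples = []
    for path in config.input_paths:
        s = read_mzml(path)
        s.label = config.labels.get(s.sample_id)
        samples.append(s)
    logger.info("pipeline: loaded %d mzML files", len(samples))
    return samples


def _bin_all(samples: Sequence[Sample], grid: BinGrid, mode: str) -> np.ndarray:
    images = np.empty((len(samples), grid.n_rt, grid.n_mz), dtype=np.float32)
    dropped = 0
    for i, s in enumerate(samples):
        image = scale_minmax(bin_sample(s, grid), mode=mode)
        dropped += image.n_dropped
        images[i] = image.values
    logger.info("binning: %d samples, %d out-of-grid points dropped", len(samples), dropped)
    return images


def _predict_table(model, images, samples, threshold) -> pd.DataFrame:
    probs = predict_proba(model, images)
    rows = []
    for sample, p in zip(samples, probs):
        result = classify_with_reject(p, model.class_order, threshold, sample_id=sample.sample_id)
        row = {"sample_id": sample.sample_id, "true_label": sample.label,
               "predicted": result.predicted, "margin": result.margin}
        row.update({f"p_{c}": float(v) for c, v in zip(model.class_order, p)})
        rows.append(row)
    return pd.DataFrame(rows)


def run_end_to_end(config: RunConfig) -> RunResult:
    """Execute the full pipeline and (optionally) write its artifacts.

    Stages: data (simulate or read mzML) -> stratified train/test split
    -> RT-shift augmentation of the raw training samples -> binning +
    per-sample min-max scaling -> ensemble training (with per-member
    oversampling) -> threshold selection -> prediction -> metrics.
    """
    samples = _load_data(config)
    labels = [s.label for s in samples]
    if any(l is None for l in labels):
        raise ValueError("pipeline: every sample needs a label for training")

    assignment = stratified_split(labels, test_fraction=config.test_fraction,
                                  seed=config.seed + 2)
    train = [s for s, a in zip(samples, assignment) if a == 0]
    test = [s for s, a in zip(samples, assignment) if a == 1]

    threshold_val: list[Sample] = []
    if config.reject_threshold == "auto":
        # hold out 10% of the training data (at least one sample per
        # class) for threshold selection
        rng = np.random.default_rng(config.seed + 4)
        train_labels = np.asarray([s.label for s in train])
        val_mask = np.zeros(len(train), dtype=bool)
        for cls in np.unique(train_labels):
            idx = rng.permutation(np.flatnonzero(train_labels == cls))
            n_val = max(1, int(round(0.1 * idx.size)))
            val_mask[idx[:min(n_val, idx.size - 1)]] = True
        threshold_val = [s for s, v in zip(train, val_mask) if v]
        train = [s for s, v in zip(train, val_mask) if not v]

    if config.augment is not None and config.augment.copies_per_sample > 0:
        aug = AugmentConfig(max_shift=config.augment.max_shift,
                            copies_per_sample=config.augment.copies_per_sample,
                            seed=config.seed + 1)
        train = augment_dataset(train, aug)
        logger.info("augmentation: training set expanded to %d samples", len(train))

    span = samples[0].acquisition_span
    grid = config.build_grid(span)
    x_train = _bin_all(train, grid, config.scaling_mode)
    x_test = _bin_all(test, grid, config.scaling_mode)

    member = MemberConfig(**{**asdict(config.member), "seed": config.seed + 3})
    model = train_ensemble(
        x_train, [s.label for s in train], n_members=config.n_members,
        config=member, oversample_classes=config.oversample,
    )

    if config.reject_threshold == "auto":
        x_val = _bin_all(threshold_val, grid, config.scaling_mode)
        val_probs = predict_proba(model, x_val)
        threshold = select_threshold(val_probs, [s.label for s in threshold_val],
                                     model.class_order)
        logger.info("decision: selected margin threshold %.2f", threshold)
    elif config.reject_threshold is None:
        threshold = 0.0
    else:
        threshold = float(config.reject_threshold)

    predictions = _predict_table(model, x_test, test, threshold)
    accepted = predictions[predictions["predicted"] != REJECTED]
    if len(accepted):
        report = macro_metrics(accepted["true_label"], accepted["predicted"],
                               classes=model.class_order)
    else:  # every test sample rejected: no confusion counts exist
        nan = float("nan")
        undefined = MetricsReport(nan, nan, nan, nan, scope="macro",
                                  undefined=("accuracy", "sensitivity", "specificity", "f1"))
        report = MacroReport(per_class={}, macro=undefined, overall_accuracy=nan,
                             n_undefined_excluded=4 * len(model.class_order))
    manifest = {
        "lcmsnet_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": {"simulation": config.seed, "augmentation": config.seed + 1,
                        "split": config.seed + 2, "training": config.seed + 3,
                        "threshold": config.seed + 4},
        "config": _manifest_config(config),
        "threshold": threshold,
        "n_train": len(train), "n_test": len(test),
        "grid_shape": list(grid.shape),
    }
    result = RunResult(report=report, predictions=predictions, threshold=threshold,
                       n_rejected=int((predictions["predicted"] == REJECTED).sum()),
                       model=model, manifest=manifest)
    if config.out_dir is not None:
        _write_artifacts(config, result)
    return result


def _manifest_config(config: RunConfig) -> dict:
    d = asdict(config)
    d["sim"] = asdict(config.sim) if config.sim is not None else None
    return json.loads(json.dumps(d, default=str))


def _metrics_frame(report: MacroReport) -> pd.DataFrame:
    rows = [{"scope": "macro", **report.macro.as_dict(),
             "overall_accuracy": report.overall_accuracy}]
    for cls, r in report.per_class.items():
        rows.append({"scope": cls, **r.as_dict(), "overall_accuracy": np.nan})
    return pd.DataFrame(rows)


def _write_artifacts(config: RunConfig, result: RunResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_ensemble(result.model, out / "model.npz")
    result.predictions.to_csv(out / "predictions.csv", index=False)
    _metrics_frame(result.report).to_csv(out / "metrics.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    logger.info("pipeline: artifacts written to %s", out)


def run_cross_batch(config: RunConfig, batch_a: str, batch_b: str) -> dict[str, MacroReport]:
    """Train/test across two acquisition batches, both directions.

    Returns four condition reports: within-batch baselines
    ``A->A``/``B->B`` (75/25 within the batch) and the transfer
    conditions ``A->B``/``B->A`` (train on the full source batch, test
    on the full target batch).
    """
    samples = _load_data(config)
    by_batch = {batch_a: [], batch_b: []}
    for s in samples:
        if s.batch_id in by_batch:
            by_batch[s.batch_id].append(s)
    for name, group in by_batch.items():
        if not group:
            raise ValueError(f"batch {name!r} has no samples")

    span = samples[0].acquisition_span
    grid = config.build_grid(span)

    def fit(train: list[Sample]) -> EnsembleModel:
        if config.augment is not None and config.augment.copies_per_sample > 0:
            aug = AugmentConfig(max_shift=config.augment.max_shift,
                                copies_per_sample=config.augment.copies_per_sample,
                                seed=config.seed + 1)
            train = augment_dataset(train, aug)
        x = _bin_all(train, grid, config.scaling_mode)
        member = MemberConfig(**{**asdict(config.member), "seed": config.seed + 3})
        return train_ensemble(x, [s.label for s in train], n_members=config.n_members,
                              config=member, oversample_classes=config.oversample)

    def score(model: EnsembleModel, test: list[Sample]) -> MacroReport:
        x = _bin_all(test, grid, config.scaling_mode)
        table = _predict_table(model, x, test, threshold=0.0)
        classes = model.class_order
        missing = set(s.label for s in test) - set(classes)
        if missing:
            raise ValueError(f"test batch contains unseen class(es): {sorted(missing)}")
        return macro_metrics(table["true_label"], table["predicted"], classes=classes)

    # one model per source batch, trained on its 75% portion and scored
    # both within batch (its own 25%) and on the full other batch, so
    # the within/cross comparison is paired on the same model
    reports: dict[str, MacroReport] = {}
    models: dict[str, EnsembleModel] = {}
    held_out: dict[str, list[Sample]] = {}
    for name in (batch_a, batch_b):
        group = by_batch[name]
        assignment = stratified_split([s.label for s in group],
                                      test_fraction=config.test_fraction,
                                      seed=config.seed + 2)
        models[name] = fit([s for s, a in zip(group, assignment) if a == 0])
        held_out[name] = [s for s, a in zip(group, assignment) if a == 1]
        reports[f"{name}->{name}"] = score(models[name], held_out[name])
    reports[f"{batch_a}->{batch_b}"] = score(models[batch_a], by_batch[batch_b])
    reports[f"{batch_b}->{batch_a}"] = score(models[batch_b], by_batch[batch_a])
    return reports
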