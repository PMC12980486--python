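"""Synthetic centroided LC-HRMS runs with class markers and batch effects.

The generator emulates a Q-TOF-style untargeted metabolomics acquisition:
a gradient of fixed length sampled at a regular scan interval, Gaussian
chromatographic elution profiles, one centroid per scan per compound
(delta-like in m/z), lognormal intensity variation, per-sample retention
time drift, uniform background noise, and instrument/batch-level RT,
m/z and intensity offsets.  Classes are distinguished by disjoint sets
of marker compounds on top of peaks shared by all classes.

Everything is a pure function of the seeds: the same
:class:`SimConfig` always produces bit-identical point clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import Sample

__all__ = [
    "Marker",
    "ClassSignature",
    "BatchProfile",
    "SimConfig",
    "make_signatures",
    "simulate_sample",
    "simulate_dataset",
    "benchmark_config",
]

# fraction of a marker's mean height below which sampled points are not emitted
DETECTION_THRESHOLD_FRACTION = 0.01


@dataclass(frozen=True)
class Marker:
    """One marker compound: elution center (s), m/z (Th), mean apex height, RT width (s)."""

    rt_center: float
    mz_center: float
    mean_height: float
    rt_sigma: float


@dataclass(frozen=True)
class ClassSignature:
    """A class and the marker compounds that characterise it."""

    class_id: str
    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("a class signature needs at least one marker")


@dataclass(frozen=True)
class BatchProfile:
    """Systematic instrument/batch-level offsets applied to every sample of a batch."""

    batch_id: str
    rt_offset: float = 0.0
    intensity_scale: float = 1.0
    mz_offset: float = 0.0
    noise_floor: float = 50.0

    def __post_init__(self) -> None:
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Study design of a simulated experiment.

    Defaults emulate a 12-min Q-TOF gradient sampled once per second.
    ``samples_per_class`` may be a single count or one count per class to
    allow imbalance.  ``height_cv`` is the coefficient of variation of
    the lognormal peak-height noise; ``rt_drift_sd`` the standard
    deviation of the per-sample retention time drift.  ``seed`` fixes
    the full output.
    """

    n_classes: int = 5
    samples_per_class: int | tuple[int, ...] = 20
    shared_peaks: tuple[Marker, ...] = ()
    scan_interval: float = 1.0
    acquisition_span: float = 720.0
    mz_span: tuple[float, float] = (100.0, 1000.0)
    rt_drift_sd: float = 2.0
    height_cv: float = 0.3
    background_points_per_scan: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be > 0")
        if self.acquisition_span <= 0:
            raise ValueError("acquisition_span must be > 0")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    def per_class_counts(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_class, int):
            return (self.samples_per_class,) * self.n_classes
        if len(self.samples_per_class) != self.n_classes:
            raise ValueError("samples_per_class length must equal n_classes")
        return tuple(self.samples_per_class)

    def scan_times(self) -> np.ndarray:
        return np.arange(0.0, self.acquisition_span + 1e-9, self.scan_interval)


def make_signatures(n_classes: int, n_markers: int, config: SimConfig) -> list[ClassSignature]:
    """Draw class signatures with disjoint marker sets, deterministic in the seed.

    Marker elution centers are uniform over the central 90% of the
    gradient (so full peaks fit inside the acquisition), m/z uniform
    over the configured span, apex heights log-uniform over one decade.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if n_markers < 1:
        raise ValueError("need at least 1 marker per class")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    span = config.acquisition_span
    lo_mz, hi_mz = config.mz_span
    signatures = []
    for c in range(n_classes):
        rt_centers = rng.uniform(0.05 * span, 0.95 * span, n_markers)
        mz_centers = rng.uniform(lo_mz, hi_mz, n_markers)
        heights = 10 ** rng.uniform(3.0, 4.0, n_markers)
        sigmas = rng.uniform(2.0, 5.0, n_markers)
        markers = tuple(
            Marker(float(rt), float(mz), float(h), float(s))
            for rt, mz, h, s in zip(rt_centers, mz_centers, heights, sigmas)
        )
        signatures.append(ClassSignature(class_id=f"class_{c}", markers=markers))
    return signatures


def _emit_peak(
    marker: Marker,
    scan_times: np.ndarray,
    rt_shift: float,
    mz_shift: float,
    scale: float,
    height_cv: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one Gaussian elution profile at the scan times."""
    center = marker.rt_center + rt_shift
    gauss = np.exp(-0.5 * ((scan_times - center) / marker.rt_sigma) ** 2)
    if height_cv > 0:
        sigma_log = np.sqrt(np.log(1.0 + height_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma_log**2, sigma=sigma_log, size=scan_times.size)
    else:
        noise = np.ones(scan_times.size)
    base = marker.mean_height * gauss * noise
    # detection threshold applies to the un-scaled signal so batch
    # intensity scaling acts as an exact multiplicative factor
    keep = base >= DETECTION_THRESHOLD_FRACTION * marker.mean_height
    rt = scan_times[keep]
    return rt, np.full(rt.size, marker.mz_center + mz_shift), base[keep] * scale


def simulate_sample(
    signature: ClassSignature,
    batch: BatchProfile,
    config: SimConfig,
    sample_seed: int,
    sample_id: str | None = None,
) -> Sample:
    """Simulate one labeled run.

    Every marker of the signature and every shared peak elutes as a
    Gaussian profile centered at ``rt_center + drift + batch.rt_offset``
    and is sampled at each scan time; emitted intensities are
    ``mean_height * gaussian * lognormal(height_cv) * intensity_scale``,
    truncated below 1% of the marker's mean height.  Uniform background
    points with exponentially distributed intensities around the batch
    noise floor are added.
    """
    rng = np.random.default_rng(np.random.SeedSequence(sample_seed))
    scan_times = config.scan_times()
    drift = rng.normal(0.0, config.rt_drift_sd) if config.rt_drift_sd > 0 else 0.0
    rt_shift = drift + batch.rt_offset

    rts, mzs, intens = [], [], []
    for marker in tuple(signature.markers) + tuple(config.shared_peaks):
        rt, mz, inten = _emit_peak(
            marker, scan_times, rt_shift, batch.mz_offset,
            batch.intensity_scale, config.height_cv, rng,
        )
        rts.append(rt)
        mzs.append(mz)
        intens.append(inten)

    n_background = rng.poisson(config.background_points_per_scan * scan_times.size)
    if n_background > 0:
        bg_rt = scan_times[rng.integers(0, scan_times.size, n_background)]
        bg_mz = rng.uniform(config.mz_span[0], config.mz_span[1], n_background)
        bg_int = rng.exponential(batch.noise_floor, n_background) * batch.intensity_scale
        keep = bg_int > 0
        rts.append(bg_rt[keep])
        mzs.append(bg_mz[keep])
        intens.append(bg_int[keep])

    rt = np.concatenate(rts)
    keep = (rt >= 0) & (rt <= config.acquisition_span)
    if sample_id is None:
        sample_id = f"{signature.class_id}_{batch.batch_id}_{sample_seed}"
    return Sample(
        sample_id=sample_id,
        rt=rt[keep],
        mz=np.concatenate(mzs)[keep],
        intensity=np.concatenate(intens)[keep],
        label=signature.class_id,
        batch_id=batch.batch_id,
        acquisition_span=(0.0, config.acquisition_span),
    )


def simulate_dataset(
    config: SimConfig,
    signatures: Sequence[ClassSignature],
    batches: Sequence[BatchProfile],
) -> list[Sample]:
    """Simulate ``samples_per_class`` runs per class per batch.

    Per-sample seeds are spawned deterministically from ``config.seed``,
    so the full dataset is a pure function of the configuration.
    """
    if not batches:
        raise ValueError("need at least one batch profile")
    if len(signatures) != config.n_classes:
        raise ValueError("number of signatures must equal config.n_classes")
    counts = config.per_class_counts()
    samples = []
    counter = 0
    for batch in batches:
        for signature, n in zip(signatures, counts):
            for replicate in range(n):
                seed = np.random.SeedSequence(config.seed, spawn_key=(1, counter))
                counter += 1
                sample_seed_rng = np.random.default_rng(seed)
                sample_seed = int(sample_seed_rng.integers(0, 2**31 - 1))
                samples.append(
                    simulate_sample(
                        signature, batch, config, sample_seed,
                        sample_id=f"{signature.class_id}_{batch.batch_id}_r{replicate}",
                    )
                )
    return samples


def benchmark_config(
    n_classes: int = 5,
    samples_per_class: int | tuple[int, ...] = 100,
    seed: int = 0,
) -> SimConfig:
    """The desk-scale synthetic benchmark design.

    A shortened 10-min gradient sampled every 2 s keeps pseudoimages
    small enough to train the full ensemble on one CPU while preserving
    the structure of a real acquisition (tens of resolvable marker
    peaks, RT drift comparable to peak widths, realistic dynamic range).
    """
    return SimConfig(
        n_classes=n_classes,
        samples_per_class=samples_per_class,
        scan_interval=2.0,
        acquisition_span=600.0,
        mz_span=(100.0, 1000.0),
        rt_drift_sd=2.0,
        height_cv=0.3,
        background_points_per_scan=3.0,
        seed=seed,
    )
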