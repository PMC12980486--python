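"""Pseudoimage construction: RT x m/z binning and min-max scaling.

A raw run is a point cloud of (RT, m/z, intensity) triples; binning maps
every point onto a predefined grid and aggregates by taking the maximum
intensity within each bin, producing a fixed-shape "pseudoimage" with RT
bins as rows and m/z bins as columns.  The grid may be uniform, or
adaptive: RT bin width matching the instrument's scan interval and m/z
bin widths that are finer in regions where more metabolites are
expected.  Per-sample min-max scaling along each m/z column then maps
intensities into [0, 1].

Bins are half-open ``[edge_i, edge_{i+1})`` except the last bin of each
axis, which is closed so the upper span bound belongs to the grid.
Points outside the grid span are dropped; the drop count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io import Sample

__all__ = [
    "BinGrid",
    "DensityPrior",
    "Pseudoimage",
    "build_uniform_grid",
    "build_adaptive_grid",
    "estimate_density_prior",
    "bin_sample",
    "scale_minmax",
    "DEFAULT_COD_PRIOR",
    "default_cod_grid",
]


@dataclass(frozen=True)
class BinGrid:
    """Bin edges of the pseudoimage lattice.

    ``rt_edges`` has length n_rt + 1 (seconds), ``mz_edges`` length
    n_mz + 1 (Thomson); both strictly increasing.
    """

    rt_edges: np.ndarray
    mz_edges: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rt_edges", np.asarray(self.rt_edges, dtype=np.float64))
        object.__setattr__(self, "mz_edges", np.asarray(self.mz_edges, dtype=np.float64))
        for name, edges in (("rt_edges", self.rt_edges), ("mz_edges", self.mz_edges)):
            if edges.size < 2:
                raise ValueError(f"{name} needs at least two edges")
            if not np.all(np.diff(edges) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def n_rt(self) -> int:
        return self.rt_edges.size - 1

    @property
    def n_mz(self) -> int:
        return self.mz_edges.size - 1

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rt, self.n_mz)


@dataclass(frozen=True)
class DensityPrior:
    """Piecewise m/z bin widths: (mz_lo, mz_hi, bin_width) regions.

    Regions must be sorted, abutting (each region's upper bound equals
    the next region's lower bound) and have positive widths; together
    they cover the full m/z span of the grid.
    """

    regions: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        regions = tuple((float(a), float(b), float(w)) for a, b, w in self.regions)
        object.__setattr__(self, "regions", regions)
        if not regions:
            raise ValueError("prior needs at least one region")
        for lo, hi, width in regions:
            if hi <= lo:
                raise ValueError(f"degenerate region ({lo}, {hi})")
            if width <= 0:
                raise ValueError("region bin_width must be > 0")
        for (_, hi_prev, _), (lo_next, _, _) in zip(regions, regions[1:]):
            if not np.isclose(hi_prev, lo_next):
                raise ValueError("prior regions must abut (no gaps or overlaps)")

    @property
    def mz_span(self) -> tuple[float, float]:
        return (self.regions[0][0], self.regions[-1][1])


@dataclass
class Pseudoimage:
    """Binned intensity matrix of shape (n_rt, n_mz) plus its grid.

    ``n_dropped`` counts points that fell outside the grid span during
    binning.
    """

    values: np.ndarray
    grid: BinGrid
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"values shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.values.size and self.values.min() < 0:
            raise ValueError("pseudoimage intensities must be non-negative")


def _edges_from_width(lo: float, hi: float, width: float) -> np.ndarray:
    """Equally spaced edges of the given width; last bin may be narrower."""
    if width <= 0:
        raise ValueError("bin width must be > 0")
    if hi <= lo:
        raise ValueError(f"degenerate span ({lo}, {hi})")
    n_full = int(np.floor((hi - lo) / width + 1e-9))
    edges = lo + width * np.arange(n_full + 1)
    if edges[-1] < hi - 1e-9 * max(1.0, abs(hi)):
        edges = np.append(edges, hi)
    else:
        edges[-1] = hi
    return edges


def build_uniform_grid(
    rt_span: tuple[float, float],
    rt_width: float,
    mz_span: tuple[float, float],
    mz_width: float,
) -> BinGrid:
    """Uniform grid with fixed bin widths on both axes.

    The final bin on each axis is narrower when the width does not
    divide the span evenly, so the grid ends exactly at the upper bound.
    """
    return BinGrid(
        rt_edges=_edges_from_width(rt_span[0], rt_span[1], rt_width),
        mz_edges=_edges_from_width(mz_span[0], mz_span[1], mz_width),
    )


def build_adaptive_grid(
    rt_span: tuple[float, float],
    acquisition_interval: float,
    prior: DensityPrior,
) -> BinGrid:
    """Adaptive grid: RT bins at the instrument's scan interval, m/z bins per prior.

    RT bin width equals ``acquisition_interval`` so each row corresponds
    to one sampling step of the instrument.  The m/z axis is built
    region by region with each region's own bin width (last bin of a
    region narrower if needed).
    """
    if acquisition_interval <= 0:
        raise ValueError("acquisition_interval must be > 0")
    rt_edges = _edges_from_width(rt_span[0], rt_span[1], acquisition_interval)
    mz_parts = []
    for index, (lo, hi, width) in enumerate(prior.regions):
        edges = _edges_from_width(lo, hi, width)
        mz_parts.append(edges if index == 0 else edges[1:])
    return BinGrid(rt_edges=rt_edges, mz_edges=np.concatenate(mz_parts))


def estimate_density_prior(
    samples: Sequence[Sample],
    n_regions: int,
    fine_width: float,
    broad_width: float,
) -> DensityPrior:
    """Estimate a piecewise m/z bin-width prior from pooled point density.

    The pooled m/z span is split into ``n_regions`` contiguous regions at
    empirical quantile change-points; regions whose point density exceeds
    the median density get ``fine_width``, the rest ``broad_width``.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    all_mz = np.concatenate([s.mz for s in samples]) if samples else np.zeros(0)
    if all_mz.size == 0:
        raise ValueError("no points available to estimate a density prior")
    lo, hi = float(all_mz.min()), float(all_mz.max())
    if np.isclose(lo, hi):
        hi = lo + max(broad_width, fine_width)
    # contiguous regions at equally spaced quantiles of the pooled m/z values
    quantiles = np.quantile(all_mz, np.linspace(0, 1, n_regions + 1))
    boundaries = np.concatenate([[lo], quantiles[1:-1], [hi]])
    # collapse duplicate boundaries arising from ties
    boundaries = np.unique(boundaries)
    counts, _ = np.histogram(all_mz, bins=boundaries)
    widths = np.diff(boundaries)
    density = counts / widths
    median_density = np.median(density)
    regions = tuple(
        (float(boundaries[i]), float(boundaries[i + 1]),
         fine_width if density[i] > median_density else broad_width)
        for i in range(boundaries.size - 1)
    )
    return DensityPrior(regions=regions)


def _digitize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per value; -1 for out of span.  Last bin closed."""
    idx = np.searchsorted(edges, values, side="right") - 1
    # the exact upper bound belongs to the last bin
    idx[values == edges[-1]] = edges.size - 2
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


def bin_sample(sample: Sample, grid: BinGrid) -> Pseudoimage:
    """Bin a point cloud onto a grid with per-bin maximum aggregation.

    Empty bins are 0.  Points outside the grid span are dropped and
    tallied in the returned image's ``n_dropped``.
    """
    rt_idx = _digitize(sample.rt, grid.rt_edges)
    mz_idx = _digitize(sample.mz, grid.mz_edges)
    inside = (rt_idx >= 0) & (mz_idx >= 0)
    values = np.zeros(grid.shape, dtype=np.float64)
    flat = rt_idx[inside] * grid.n_mz + mz_idx[inside]
    np.maximum.at(values.ravel(), flat, sample.intensity[inside])
    return Pseudoimage(values=values, grid=grid, n_dropped=int((~inside).sum()))


def scale_minmax(
    image: Pseudoimage,
    mode: Literal["per_column", "global"] = "per_column",
) -> Pseudoimage:
    """Min-max scale a pseudoimage into [0, 1].

    ``per_column`` (default) rescales each m/z column independently over
    the RT dimension, giving every channel of the downstream depthwise
    convolution the same dynamic range; ``global`` rescales the whole
    image with a single min/max.  Constant columns (or a constant image)
    map to all zeros.
    """
    v = image.values
    if mode == "per_column":
        lo = v.min(axis=0, keepdims=True)
        hi = v.max(axis=0, keepdims=True)
    elif mode == "global":
        lo = v.min()
        hi = v.max()
    else:
        raise ValueError(f"unknown scaling mode: {mode!r}")
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.0)
    return Pseudoimage(values=out, grid=image.grid, n_dropped=image.n_dropped)


# Default CoD-scale grid: a 12-min gradient sampled every second, with a
# finer m/z resolution below 400 Th where small-molecule density is
# highest.  900 m/z bins x 720 RT bins.
DEFAULT_COD_PRIOR = DensityPrior(regions=((100.0, 400.0, 0.5), (400.0, 1000.0, 2.0)))


def default_cod_grid() -> BinGrid:
    """The default adaptive grid for a 12-min, 1 Hz Q-TOF acquisition."""
    return build_adaptive_grid((0.0, 720.0), 1.0, DEFAULT_COD_PRIOR)
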