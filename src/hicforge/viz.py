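"""Heatmaps, histograms, DI tracks and triangular TAD plots (PDF output).

Pixel intensity is proportional to the contact count; the color scale can
be capped at a percentile of the matrix entries (computed over the full
upper triangle, zeros included) or at a fixed count, with values above
the cap drawn in a dedicated over-cutoff color. O/E maps use a symmetric
diverging scale centered at zero, with black marking bins without
expected signal and gray bins without observed contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .matrix import SENT_NO_EXPECTED, SENT_NO_OBSERVED, ContactMatrix
from .tad import DITrack, StateTrack

DEFAULT_COUNT_COLORS = ["white", "#ffe5d9", "#fcae91", "#fb6a4a", "#cb181d"]
DEFAULT_OVER_COLOR = "#67000d"  # dark brown-red for above-cutoff values


@dataclass
class PlotSpec:
    cutoff_percentile: float | None = None  # in (0, 100)
    cutoff_max: float | None = None
    colormap: str | list[str] = "counts"
    over_color: str = DEFAULT_OVER_COLOR
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.cutoff_percentile is not None and not 0 < self.cutoff_percentile < 100:
            raise ValueError("percentile cutoff must be in (0, 100)")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")

    def resolve_cmap(self):
        if isinstance(self.colormap, list):
            return LinearSegmentedColormap.from_list("custom", self.colormap)
        if self.colormap == "counts":
            return LinearSegmentedColormap.from_list("counts", DEFAULT_COUNT_COLORS)
        return plt.get_cmap(self.colormap)


def color_scale_max(matrix: ContactMatrix, spec: PlotSpec) -> float:
    """Upper color limit: exact percentile over all upper-triangle entries
    (zeros included), a fixed maximum, or the matrix maximum."""
    if spec.cutoff_max is not None:
        return float(spec.cutoff_max)
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.values[iu]
    if spec.cutoff_percentile is not None:
        return float(np.percentile(vals, spec.cutoff_percentile))
    return float(vals.max())


def _region_slice(matrix: ContactMatrix, region) -> slice:
    if region is None:
        return slice(0, matrix.n_bins)
    start, end = region
    lo = start // matrix.bin_size
    hi = -(-end // matrix.bin_size)
    if lo >= matrix.n_bins or hi <= lo or start < 0:
        raise ValueError(f"region {region} outside chromosome")
    return slice(lo, min(hi, matrix.n_bins))


def _mb_axis(ax, sl: slice, bin_size: int):
    ticks = ax.get_xticks()
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("position (Mb)")
    fmt = lambda v, _: f"{(sl.start + v) * bin_size / 1e6:g}"
    ax.xaxis.set_major_formatter(plt.FuncFormatter(fmt))
    ax.yaxis.set_major_formatter(plt.FuncFormatter(fmt))
    return ticks


def plot_heatmap(matrix: ContactMatrix, spec: PlotSpec, path, region=None) -> float:
    """Contact heatmap; returns the color-scale maximum actually used."""
    if matrix.role not in ("observed", "normalized", "correction"):
        raise ValueError(f"plot_heatmap does not accept role {matrix.role!r}")
    sl = _region_slice(matrix, region)
    sub = matrix.values[sl, sl]
    vmax = color_scale_max(matrix, spec)
    cmap = spec.resolve_cmap()
    cmap.set_over(spec.over_color)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(sub, cmap=cmap, vmin=0, vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, extend="max", label=f"{matrix.role} contacts")
    _mb_axis(ax, sl, matrix.bin_size)
    ax.set_title(f"{matrix.chrom} ({matrix.role})")
    fig.savefig(path, dpi=spec.dpi, format="pdf")
    plt.close(fig)
    return vmax


def plot_oe_heatmap(matrix: ContactMatrix, spec: PlotSpec, path, region=None) -> float:
    """log2 O/E heatmap with sentinel coloring; returns the color limit."""
    if matrix.role != "oe_log2":
        raise ValueError("plot_oe_heatmap requires an oe_log2 matrix")
    sl = _region_slice(matrix, region)
    sub = matrix.values[sl, sl].copy()
    sent = (
        matrix.sentinels[sl, sl]
        if matrix.sentinels is not None
        else np.zeros_like(sub, dtype=np.int8)
    )
    finite = sent == 0
    lim = float(np.abs(sub[finite]).max()) if finite.any() else 1.0
    lim = lim or 1.0
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(
        np.ma.masked_array(sub, ~finite),
        cmap="RdBu_r", vmin=-lim, vmax=lim, interpolation="nearest",
    )
    # overlay sentinels: black = no expected, gray = no observed
    overlay = np.zeros((*sub.shape, 4))
    overlay[sent == SENT_NO_EXPECTED] = (0, 0, 0, 1)
    overlay[sent == SENT_NO_OBSERVED] = (0.6, 0.6, 0.6, 1)
    ax.imshow(overlay, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="log2(O/E)")
    _mb_axis(ax, sl, matrix.bin_size)
    ax.set_title(f"{matrix.chrom} (O/E)")
    fig.savefig(path, dpi=spec.dpi, format="pdf")
    plt.close(fig)
    return lim


def plot_histogram(matrix: ContactMatrix, path, bins: int = 50, dpi: int = 150) -> np.ndarray:
    """Distribution of upper-triangle contact values; returns the counts."""
    iu = np.triu_indices(matrix.n_bins)
    vals = matrix.values[iu]
    label = "contact count"
    if matrix.role == "oe_log2":
        label = "log2(O/E)"
        if matrix.sentinels is not None:
            vals = vals[matrix.sentinels[iu] == 0]
    fig, ax = plt.subplots(figsize=(5, 4))
    counts, _, _ = ax.hist(vals, bins=bins, color="#cb181d")
    ax.set_xlabel(label)
    ax.set_ylabel("bin frequency")
    fig.savefig(path, dpi=dpi, format="pdf")
    plt.close(fig)
    return counts


def plot_di(di: DITrack, states: StateTrack | None, path, region=None, dpi: int = 150) -> None:
    """Observed DI bars with the decoded +-1/0 state step track."""
    n = len(di.di)
    sl = slice(0, n)
    if region is not None:
        sl = slice(region[0] // di.bin_size, -(-region[1] // di.bin_size))
    x = np.arange(n)[sl]
    fig, ax = plt.subplots(figsize=(8, 3))
    vals = np.nan_to_num(di.di[sl])
    ax.bar(x, vals, width=1.0, color=np.where(vals >= 0, "#cb181d", "#2171b5"))
    if states is not None:
        scale = max(np.abs(vals).max(), 1.0)
        ax.step(x, np.nan_to_num(states.states[sl]) * scale * 0.5, where="mid",
                color="black", linewidth=1.0)
    ax.set_xlabel("bin")
    ax.set_ylabel("DI")
    fig.savefig(path, dpi=dpi, format="pdf")
    plt.close(fig)


def plot_tads_triangle(
    matrix: ContactMatrix, tads, path, region=None, spec: PlotSpec | None = None
) -> None:
    """45-degree rotated upper triangle with TAD extents along the diagonal."""
    spec = spec or PlotSpec(cutoff_percentile=95.0)
    sl = _region_slice(matrix, region)
    sub = matrix.values[sl, sl]
    vmax = color_scale_max(matrix, spec)
    n = sub.shape[0]
    # rotate: pixel (i, j) in the upper triangle -> ((i+j)/2, (j-i)/2)
    fig, ax = plt.subplots(figsize=(8, 4))
    cmap = spec.resolve_cmap()
    cmap.set_over(spec.over_color)
    tri = np.full((n // 2 + 1, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            h = (j - i) // 2
            if h < tri.shape[0]:
                tri[h, (i + j) // 2] = sub[i, j]
    ax.imshow(tri, origin="lower", cmap=cmap, vmin=0, vmax=vmax,
              interpolation="nearest", aspect="auto")
    lo_bp = sl.start * matrix.bin_size
    for start, end in tads:
        s = (start - lo_bp) / matrix.bin_size
        e = (end - lo_bp) / matrix.bin_size
        if e <= 0 or s >= n:
            continue
        mid = (s + e) / 2
        ax.plot([s, mid, e], [0, (e - s) / 2, 0], color="#2171b5", linewidth=1.5)
    ax.set_xlabel("bin")
    ax.set_yticks([])
    fig.savefig(path, dpi=spec.dpi, format="pdf")
    plt.close(fig)
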