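"""Construction of temporal multilayer functional-connectivity networks.

A subject's region x time signal matrix is segmented into consecutive,
non-overlapping windows; each window yields one connectivity layer (Pearson
correlation with the diagonal and negative values set to zero); the ordered
layers are coupled node-to-self between adjacent layers with weight ``omega``
(ordinal coupling), forming a temporal multilayer network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionTimeSeries:
    """One subject's region x time signal matrix.

    Parameters
    ----------
    values : ndarray, shape (n_regions, n_timepoints)
        Signal matrix, one row per region.
    tr_s : float
        Sampling interval (repetition time) in seconds.
    region_ids : list of str, optional
        Ordered region labels; defaults to ``r000, r001, ...``.
    """

    values: np.ndarray
    tr_s: float
    region_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region x time matrix")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 timepoints per region")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(self.values.shape[0])]
        elif len(self.region_ids) != self.values.shape[0]:
            raise ValueError("region_ids length does not match region count")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class LayerMatrix:
    """A single windowed connectivity layer: symmetric, non-negative, zero diagonal."""

    weights: np.ndarray
    window_index: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("layer weights must be square")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("layer weights must be symmetric")
        if np.any(w < 0):
            raise ValueError("layer weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("layer diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class TemporalMultilayerNetwork:
    """Ordered connectivity layers with ordinal (adjacent-layer) coupling ``omega``."""

    layers: list[LayerMatrix]
    omega: float

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("need at least one layer")
        n = self.layers[0].n_nodes
        if any(l.n_nodes != n for l in self.layers):
            raise ValueError("all layers must have the same node count")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].n_nodes

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer_stack(self) -> np.ndarray:
        """Return layers as a (n_layers, n_nodes, n_nodes) array."""
        return np.stack([l.weights for l in self.layers])

    def n_interlayer_couplings(self) -> int:
        """Number of undirected node-to-self couplings in the ordinal chain."""
        return self.n_nodes * (self.n_layers - 1)


class EmptySegmentationError(ValueError):
    """Raised when fewer timepoints remain than fit in a single window."""


def segment_windows(
    ts: RegionTimeSeries,
    window_len_s: float = 30.0,
    drop_initial: int = 2,
    window_timepoints: int | None = None,
) -> list[np.ndarray]:
    """Segment a time series into consecutive non-overlapping windows.

    The first ``drop_initial`` timepoints are discarded (steady-state
    volumes), then the remainder is cut into equal windows of
    ``round(window_len_s / tr_s)`` timepoints; trailing timepoints that do
    not fill a window are dropped.  ``window_timepoints`` overrides the
    seconds-based arithmetic when a window length is not an integer number
    of samples.
    """
    if window_timepoints is None:
        per_window = window_len_s / ts.tr_s
        window_timepoints = int(round(per_window))
        if window_timepoints < 1 or abs(per_window - window_timepoints) > 1e-9:
            raise ValueError(
                f"window_len_s={window_len_s} is not an integer number of "
                f"samples at tr_s={ts.tr_s}; pass window_timepoints explicitly"
            )
    if window_timepoints < 1:
        raise ValueError("window_timepoints must be >= 1")
    data = ts.values[:, drop_initial:]
    n_windows = data.shape[1] // window_timepoints
    if n_windows == 0:
        raise EmptySegmentationError(
            f"{data.shape[1]} timepoints remain after dropping {drop_initial}; "
            f"fewer than one window of {window_timepoints}"
        )
    return [
        data[:, w * window_timepoints : (w + 1) * window_timepoints]
        for w in range(n_windows)
    ]


def window_connectivity(window: np.ndarray, window_index: int = 0) -> LayerMatrix:
    """Pearson-correlation connectivity of one window.

    Entry (i, j) is ``max(0, r_ij)``; the diagonal is forced to zero.  A
    region with zero variance inside the window has undefined correlations;
    its row and column are set to zero with a warning.
    """
    window = np.asarray(window, dtype=float)
    if window.shape[1] < 3:
        raise ValueError("need at least 3 timepoints per window")
    sd = window.std(axis=1)
    flat = sd == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} region(s) with zero variance in window "
            f"{window_index}; their connectivity is set to zero",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(window)
    r = np.nan_to_num(r, nan=0.0)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    np.clip(r, 0.0, None, out=r)
    np.fill_diagonal(r, 0.0)
    r = (r + r.T) / 2.0
    return LayerMatrix(weights=r, window_index=window_index)


def build_multilayer(
    layers: list[LayerMatrix], omega: float = 0.5
) -> TemporalMultilayerNetwork:
    """Couple ordered layers into a temporal multilayer network.

    Interlayer edges exist only between the same node in adjacent layers,
    each with weight ``omega``; non-adjacent layers are never coupled.
    """
    if len(layers) < 2:
        raise ValueError("a temporal multilayer network needs at least 2 layers")
    return TemporalMultilayerNetwork(layers=list(layers), omega=omega)


def subject_multilayer(
    ts: RegionTimeSeries,
    window_len_s: float = 30.0,
    drop_initial: int = 2,
    omega: float = 0.5,
    window_timepoints: int | None = None,
) -> TemporalMultilayerNetwork:
    """Convenience: segment, correlate, and couple in one call."""
    windows = segment_windows(
        ts, window_len_s=window_len_s, drop_initial=drop_initial,
        window_timepoints=window_timepoints,
    )
    layers = [window_connectivity(w, i) for i, w in enumerate(windows)]
    return build_multilayer(layers, omega=omega)
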