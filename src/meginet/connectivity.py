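"""Normalized mutual information connectivity between wavelet band series.

Functional connectivity between sensors is measured as the mutual
information (MI) between their band-limited wavelet series within a single
trial, estimated with a plug-in equal-width histogram (default 8 bins for
216-sample epochs, roughly the sqrt(n)/2 rule; quantile binning is
available as an option). MI is normalized following Strehl & Ghosh by the
geometric mean of the marginal entropies,

    NMI(x, y) = I(x; y) / sqrt(H(x) H(y)),

so that every weight lies in [0, 1] with NMI(x, x) = 1.

Per trial this yields 4 intra-frequency matrices (one per band) and 6
inter-frequency matrices (one per unordered band pair): with 66 trials,
660 weighted networks per subject. Inter-frequency MI is asymmetric in
the sensor roles (sensor i at band f1 vs sensor j at band f2); stored
weights are symmetrized by the arithmetic mean, with the raw asymmetric
matrix retained for inspection. Diagonals are zero throughout (no
self-loops). No small-sample bias correction is applied; trial ensembles
are the mitigation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import BANDS, BandDecomposition

__all__ = [
    "NETWORK_KINDS",
    "histogram_mi",
    "normalized_mi",
    "pairwise_nmi",
    "ConnectivityMatrix",
    "StrengthProfile",
    "build_intra_matrix",
    "build_inter_matrix",
    "trial_matrices",
    "strength",
]

#: The 10 network kinds in canonical order: 4 intra then 6 inter.
NETWORK_KINDS = tuple(f"intra:{b}" for b in BANDS) + tuple(
    f"inter:{a}-{b}" for a, b in itertools.combinations(BANDS, 2)
)


def _bin_labels(x: np.ndarray, n_bins: int, binning: str = "width") -> np.ndarray:
    """Integer bin labels in 0..n_bins-1 along the last axis.

    'width': equal-width bins over each series' observed range (constant
    series collapse into bin 0). 'quantile': equal-count bins, invariant
    to strictly monotone transforms.
    """
    x = np.asarray(x, dtype=float)
    if binning == "width":
        lo = x.min(axis=-1, keepdims=True)
        hi = x.max(axis=-1, keepdims=True)
        span = hi - lo
        span = np.where(span == 0, 1.0, span)
        lab = np.floor((x - lo) / span * n_bins).astype(np.intp)
        return np.clip(lab, 0, n_bins - 1)
    if binning == "quantile":
        order = np.argsort(x, axis=-1, kind="stable")
        ranks = np.empty_like(order)
        n = x.shape[-1]
        np.put_along_axis(ranks, order, np.arange(n).reshape((1,) * (x.ndim - 1) + (n,)) * np.ones(x.shape[:-1] + (1,), dtype=np.intp), axis=-1)
        return (ranks * n_bins // n).astype(np.intp)
    raise ValueError(f"unknown binning {binning!r}")


def _entropy_from_counts(counts: np.ndarray, axis) -> np.ndarray:
    p = counts / counts.sum(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=axis)


def histogram_mi(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 8,
    binning: str = "width",
) -> tuple[float, float, float]:
    """Plug-in histogram MI: returns (I, H(x), H(y)) in bits.

    I = H(x) + H(y) - H(x, y), clipped at 0. A constant series has zero
    marginal entropy; MI is then 0 and a warning is emitted.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if x.size < 32:
        raise ValueError("need at least 32 samples for the MI estimate")
    lx = _bin_labels(x, n_bins, binning)
    ly = _bin_labels(y, n_bins, binning)
    joint = np.zeros((n_bins, n_bins))
    np.add.at(joint, (lx, ly), 1.0)
    hx = float(_entropy_from_counts(joint.sum(axis=1), axis=-1))
    hy = float(_entropy_from_counts(joint.sum(axis=0), axis=-1))
    hxy = float(_entropy_from_counts(joint.ravel(), axis=-1))
    if hx == 0.0 or hy == 0.0:
        warnings.warn("constant series: zero marginal entropy, MI set to 0")
        return 0.0, hx, hy
    return max(hx + hy - hxy, 0.0), hx, hy


def normalized_mi(
    x: np.ndarray, y: np.ndarray, n_bins: int = 8, binning: str = "width"
) -> float:
    """Strehl-Ghosh NMI = I / sqrt(H(x) H(y)), clipped into [0, 1]."""
    i, hx, hy = histogram_mi(x, y, n_bins=n_bins, binning=binning)
    if hx == 0.0 or hy == 0.0:
        return 0.0
    return float(np.clip(i / np.sqrt(hx * hy), 0.0, 1.0))


def _one_hot(labels: np.ndarray, n_bins: int) -> np.ndarray:
    """(n_series, T) int labels -> (n_series * n_bins, T) float one-hot."""
    n, t = labels.shape
    out = np.zeros((n, n_bins, t))
    rows = np.repeat(np.arange(n), t)
    out[rows, labels.ravel(), np.tile(np.arange(t), n)] = 1.0
    return out.reshape(n * n_bins, t)


def pairwise_nmi(
    x: np.ndarray,
    y: np.ndarray | None = None,
    n_bins: int = 8,
    binning: str = "width",
) -> np.ndarray:
    """All-pairs NMI between the rows of ``x`` (and ``y`` if given).

    Returns an (n_x, n_y) matrix; with ``y=None`` it is the symmetric
    intra-set matrix with unit diagonal. Joint histograms for all pairs
    are accumulated in a single matrix product over one-hot bin
    indicators, which makes whole-trial connectivity matrices cheap.
    Numerically identical to looping :func:`normalized_mi`.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be (n_series, n_samples)")
    t = x.shape[1]
    if t < 32:
        raise ValueError("need at least 32 samples for the MI estimate")
    lx = _bin_labels(x, n_bins, binning)
    ox = _one_hot(lx, n_bins)
    if y is None:
        ly, oy = lx, ox
    else:
        y = np.asarray(y, dtype=float)
        if y.shape[1] != t:
            raise ValueError("x and y sample counts differ")
        ly = _bin_labels(y, n_bins, binning)
        oy = _one_hot(ly, n_bins)
    nx, ny = lx.shape[0], ly.shape[0]
    joint = (ox @ oy.T).reshape(nx, n_bins, ny, n_bins)
    joint = joint.transpose(0, 2, 1, 3)  # (nx, ny, bins, bins)
    hx = _entropy_from_counts(
        np.apply_along_axis(np.bincount, 1, lx, minlength=n_bins), axis=-1
    )
    hy = (
        hx
        if y is None
        else _entropy_from_counts(
            np.apply_along_axis(np.bincount, 1, ly, minlength=n_bins), axis=-1
        )
    )
    hxy = _entropy_from_counts(
        joint.reshape(nx, ny, n_bins * n_bins), axis=-1
    )
    mi = np.clip(hx[:, None] + hy[None, :] - hxy, 0.0, None)
    denom = np.sqrt(hx[:, None] * hy[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        nmi = np.where(denom > 0, mi / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(nmi, 0.0, 1.0)


@dataclass
class ConnectivityMatrix:
    """One trial's N x N NMI weight matrix for one network kind.

    ``kind`` is ``"intra:<band>"`` or ``"inter:<band1>-<band2>"``. Stored
    ``weights`` are symmetric with zero diagonal; for inter-frequency
    matrices the unsymmetrized matrix is kept in ``raw``.
    """

    kind: str
    trial: int
    weights: np.ndarray
    raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")
        self.weights = w

    @property
    def n_sensors(self) -> int:
        return self.weights.shape[0]


@dataclass
class StrengthProfile:
    """Per-sensor and network-average connection strength."""

    sensor_strength: np.ndarray
    network_strength: float


def build_intra_matrix(
    bands: BandDecomposition,
    band: str,
    trial: int,
    n_bins: int = 8,
    binning: str = "width",
) -> ConnectivityMatrix:
    """Intra-frequency NMI matrix for one band and trial."""
    series = bands.band(band)[:, trial, :]
    if series.shape[0] < 8:
        raise ValueError("need at least 8 sensors")
    w = pairwise_nmi(series, n_bins=n_bins, binning=binning)
    w = (w + w.T) / 2.0  # exact symmetry despite float reduction order
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(kind=f"intra:{band}", trial=trial, weights=w)


def build_inter_matrix(
    bands: BandDecomposition,
    band1: str,
    band2: str,
    trial: int,
    n_bins: int = 8,
    binning: str = "width",
) -> ConnectivityMatrix:
    """Inter-frequency NMI matrix (mean-symmetrized) for one band pair."""
    if band1 == band2:
        raise ValueError("band pair must differ; use build_intra_matrix")
    x = bands.band(band1)[:, trial, :]
    y = bands.band(band2)[:, trial, :]
    raw = pairwise_nmi(x, y, n_bins=n_bins, binning=binning)
    w = (raw + raw.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(
        kind=f"inter:{band1}-{band2}", trial=trial, weights=w, raw=raw
    )


def trial_matrices(
    bands: BandDecomposition,
    trial: int,
    n_bins: int = 8,
    binning: str = "width",
) -> dict[str, ConnectivityMatrix]:
    """All 10 connectivity matrices (4 intra + 6 inter) for one trial."""
    out: dict[str, ConnectivityMatrix] = {}
    for band in BANDS:
        m = build_intra_matrix(bands, band, trial, n_bins, binning)
        out[m.kind] = m
    for b1, b2 in itertools.combinations(BANDS, 2):
        m = build_inter_matrix(bands, b1, b2, trial, n_bins, binning)
        out[m.kind] = m
    return out


def strength(w: ConnectivityMatrix | np.ndarray) -> StrengthProfile:
    """Mean off-diagonal weight per sensor, and its network average."""
    mat = w.weights if isinstance(w, ConnectivityMatrix) else np.asarray(w, float)
    n = mat.shape[0]
    if n < 2:
        raise ValueError("strength needs at least 2 sensors")
    sensor = (mat.sum(axis=1) - np.diag(mat)) / (n - 1)
    return StrengthProfile(sensor, float(sensor.mean()))
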