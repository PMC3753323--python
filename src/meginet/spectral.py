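"""Resampling, epoching, and maximal-overlap wavelet decomposition.

Sensor time series are resampled from the native acquisition rate (600 Hz)
to the 120 Hz analysis rate so that the dyadic wavelet scales line up with
the classical electrophysiological bands: at 120 Hz, detail scale 1 covers
roughly 30-60 Hz (low gamma), scale 2 covers 15-30 Hz (beta), scale 3
covers 8-15 Hz (alpha), and scale 4 covers 4-8 Hz (theta). Frequencies
below 4 Hz are not examined (epochs are only 1.8 s long).

The decomposition is the maximal overlap discrete wavelet transform
(MODWT): an undecimated, energy-preserving transform whose per-scale
detail series keep the length of the input, so 216-sample epochs yield
216-sample band series. Boundary handling is periodic (circular), which
makes the energy identity exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pywt
from scipy.signal import resample_poly

__all__ = [
    "BANDS",
    "BAND_SCALES",
    "EpochedRecording",
    "BandDecomposition",
    "resample_to_analysis_rate",
    "epoch",
    "modwt",
    "modwt_decompose",
    "decompose_recording",
]

#: Band names in ascending-frequency order of the wavelet scales.
#: Scale 1 is the highest frequency band ("low gamma" at 120 Hz).
BAND_SCALES = {"gamma_low": 1, "beta": 2, "alpha": 3, "theta": 4}

#: Canonical band order used for matrices and reports (low to high frequency).
BANDS = ("theta", "alpha", "beta", "gamma_low")

# MODWT wavelet filters. "d4" is the 4-tap Daubechies filter with two
# vanishing moments (PyWavelets name 'db2'); "db4" is the 8-tap filter.
_WAVELET_ALIASES = {"d4": "db2", "db2": "db2", "db4": "db4"}


@dataclass
class EpochedRecording:
    """One subject's epoched sensor data: sensors x trials x samples."""

    subject_id: str
    group: str
    data: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be sensors x trials x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("epoched data contains non-finite values")

    @property
    def n_sensors(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class BandDecomposition:
    """Per-band MODWT detail coefficients for one recording.

    ``coefficients`` maps band name -> array (sensors x trials x samples),
    same sample count as the input epochs. ``smooth`` is the final scaling
    (approximation) series at the deepest scale, kept so the energy
    identity can be verified.
    """

    subject_id: str
    group: str
    sampling_rate: float
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    smooth: np.ndarray | None = None

    def band(self, name: str) -> np.ndarray:
        if name not in self.coefficients:
            raise KeyError(f"band {name!r} missing from decomposition")
        return self.coefficients[name]


def resample_to_analysis_rate(
    recording: EpochedRecording, target_rate: float
) -> EpochedRecording:
    """Resample each epoch to ``target_rate`` with polyphase anti-aliasing.

    The epoch duration must map to an integer number of samples at the
    target rate (1800 ms at 120 Hz -> 216 samples).
    """
    native = recording.sampling_rate
    if target_rate == native:
        return recording
    from fractions import Fraction

    frac = Fraction(target_rate / native).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    n_out = recording.n_samples * up / down
    if abs(n_out - round(n_out)) > 1e-9:
        raise ValueError(
            f"resampling {recording.n_samples} samples by {up}/{down} "
            "does not give an integer epoch length"
        )
    data = resample_poly(recording.data, up, down, axis=-1)
    return replace(recording, data=data, sampling_rate=float(target_rate))


def epoch(
    continuous: np.ndarray,
    onsets: Sequence[int],
    duration: float,
    rate: float,
    subject_id: str = "",
    group: str = "",
) -> EpochedRecording:
    """Cut a continuous sensors x time array into fixed-length trials.

    Each trial is the half-open window ``[onset, onset + duration*rate)``;
    trials are ordered by the supplied onset sequence. Overlapping and
    duplicate onsets are allowed.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous data must be sensors x time")
    n_samp = duration * rate
    if abs(n_samp - round(n_samp)) > 1e-9:
        raise ValueError("duration x rate must be an integer sample count")
    n_samp = int(round(n_samp))
    n_time = continuous.shape[1]
    trials = []
    for onset in onsets:
        onset = int(onset)
        if onset < 0 or onset + n_samp > n_time:
            raise IndexError(f"onset {onset} outside the record")
        trials.append(continuous[:, onset : onset + n_samp])
    data = np.stack(trials, axis=1)
    return EpochedRecording(subject_id, group, data, float(rate))


def _modwt_filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        name = _WAVELET_ALIASES[wavelet]
    except KeyError:
        raise ValueError(f"unknown wavelet {wavelet!r}; use 'd4' or 'db4'")
    w = pywt.Wavelet(name)
    # MODWT filters are the orthonormal DWT filters rescaled by 1/sqrt(2).
    g = np.asarray(w.dec_lo, dtype=float)[::-1] / np.sqrt(2.0)
    h = np.asarray(w.dec_hi, dtype=float)[::-1] / np.sqrt(2.0)
    return g, h


def modwt(
    x: np.ndarray, wavelet: str = "d4", level: int = 4
) -> tuple[list[np.ndarray], np.ndarray]:
    """MODWT pyramid with periodic boundaries along the last axis.

    Returns ``(details, smooth)`` where ``details[j-1]`` is the scale-j
    detail series, each the same length as the input, and ``smooth`` is
    the level-``level`` scaling series. Satisfies the exact energy
    identity ``||x||^2 = sum_j ||W_j||^2 + ||V_level||^2``.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    g, h = _modwt_filters(wavelet)
    if n < len(g) * 2 ** (level - 1):
        raise ValueError(
            f"series of length {n} too short for level {level} "
            f"with a {len(g)}-tap filter"
        )
    idx = np.arange(n)
    v = x
    details: list[np.ndarray] = []
    for j in range(1, level + 1):
        step = 2 ** (j - 1)
        w_j = np.zeros_like(v)
        v_j = np.zeros_like(v)
        for tap in range(len(g)):
            shifted = np.take(v, (idx - tap * step) % n, axis=-1)
            w_j += h[tap] * shifted
            v_j += g[tap] * shifted
        details.append(w_j)
        v = v_j
    return details, v


def modwt_decompose(
    trial_series: np.ndarray, n_scales: int = 4, wavelet: str = "d4"
) -> dict[str, np.ndarray]:
    """Detail series for scales 1..n_scales keyed by band name."""
    details, _ = modwt(trial_series, wavelet=wavelet, level=n_scales)
    out: dict[str, np.ndarray] = {}
    for band, scale in BAND_SCALES.items():
        if scale <= n_scales:
            out[band] = details[scale - 1]
    return out


def decompose_recording(
    recording: EpochedRecording, wavelet: str = "d4"
) -> BandDecomposition:
    """Four-band MODWT decomposition of every sensor and trial."""
    details, smooth = modwt(recording.data, wavelet=wavelet, level=4)
    coeffs = {band: details[scale - 1] for band, scale in BAND_SCALES.items()}
    return BandDecomposition(
        subject_id=recording.subject_id,
        group=recording.group,
        sampling_rate=recording.sampling_rate,
        coefficients=coeffs,
        smooth=smooth,
    )


def cache_decomposition(decomp: BandDecomposition, path) -> None:
    """Cache band detail series under /subjects/<id>/bands/<band> in HDF5."""
    import h5py

    with h5py.File(path, "a") as f:
        base = f.require_group(f"subjects/{decomp.subject_id}/bands")
        for band, coeffs in decomp.coefficients.items():
            if band in base:
                del base[band]
            base.create_dataset(band, data=coeffs)
        base.attrs["group"] = decomp.group
        base.attrs["sampling_rate"] = decomp.sampling_rate


def load_cached_decomposition(path, subject_id: str) -> BandDecomposition:
    """Read a cached band decomposition back from HDF5."""
    import h5py

    with h5py.File(path, "r") as f:
        base = f[f"subjects/{subject_id}/bands"]
        coeffs = {band: base[band][...] for band in base}
        return BandDecomposition(
            subject_id=subject_id,
            group=str(base.attrs.get("group", "")),
            sampling_rate=float(base.attrs.get("sampling_rate", 0.0)),
            coefficients=coeffs,
        )
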