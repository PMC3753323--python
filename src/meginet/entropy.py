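"""Shannon wavelet entropy of band-limited sensor series.

For a single trial's band series ``w`` the squared coefficients are
normalized into a distribution over time points,

    p_k = w_k^2 / sum_m w_m^2,

and the entropy is ``H = -sum_k p_k log2 p_k`` (bits, with 0 log 0 = 0).
A regular, constant-envelope oscillation spreads its energy evenly over
the trial and has entropy near the log2(N) maximum; bursty, irregular
activity concentrates energy in few time points and has lower entropy.
H is invariant to rescaling the series.

An amplitude-histogram variant (entropy of the distribution of coefficient
values over equal-width bins) is provided behind the ``method`` switch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import BANDS, BandDecomposition

__all__ = [
    "UndefinedEntropyError",
    "wavelet_entropy",
    "entropy_array",
    "EntropyProfile",
    "entropy_profile",
]


class UndefinedEntropyError(ValueError):
    """Raised when entropy is requested for an all-zero series."""


def _energy_entropy(w: np.ndarray) -> np.ndarray:
    peak = np.abs(w).max(axis=-1, keepdims=True)
    if np.any(peak == 0):
        raise UndefinedEntropyError("entropy undefined for an all-zero series")
    e = (w / peak) ** 2  # rescaling avoids underflow; H is scale-invariant
    tot = e.sum(axis=-1, keepdims=True)
    p = e / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def _histogram_entropy(w: np.ndarray, n_bins: int) -> np.ndarray:
    w2 = w.reshape(-1, w.shape[-1])
    out = np.empty(w2.shape[0])
    for i, row in enumerate(w2):
        lo, hi = row.min(), row.max()
        if hi == lo:
            raise UndefinedEntropyError("entropy undefined for a constant series")
        counts, _ = np.histogram(row, bins=n_bins, range=(lo, hi))
        p = counts / counts.sum()
        p = p[p > 0]
        out[i] = -(p * np.log2(p)).sum()
    return out.reshape(w.shape[:-1])


def wavelet_entropy(
    band_series: np.ndarray,
    method: str = "energy",
    n_bins: int = 8,
    normalized: bool = False,
) -> float | np.ndarray:
    """Shannon wavelet entropy (bits) along the last axis.

    ``method='energy'`` (default) uses the relative wavelet-energy
    distribution over time points; ``method='histogram'`` uses an
    equal-width amplitude histogram. With ``normalized=True`` the result
    is divided by its maximum (log2 of the number of samples or bins).
    """
    w = np.asarray(band_series, dtype=float)
    if method == "energy":
        h = _energy_entropy(w)
        h_max = np.log2(w.shape[-1])
    elif method == "histogram":
        h = _histogram_entropy(w, n_bins)
        h_max = np.log2(n_bins)
    else:
        raise ValueError(f"unknown entropy method {method!r}")
    if normalized:
        h = h / h_max
    if np.ndim(h) == 0:
        return float(h)
    return h


def entropy_array(decomp: BandDecomposition, **kwargs) -> np.ndarray:
    """Entropy for every sensor, band, trial: array (sensors, bands, trials).

    Band axis follows :data:`meginet.spectral.BANDS` order.
    """
    per_band = [wavelet_entropy(decomp.band(b), **kwargs) for b in BANDS]
    return np.stack(per_band, axis=1)


@dataclass
class EntropyProfile:
    """Cohort entropy values plus subject-level summaries.

    values
        Array (subjects, sensors, bands, trials), bits.
    summaries
        DataFrame with one row per (subject, band): the mean over sensors
        and trials, as displayed in group-level entropy comparisons.
    """

    subject_ids: list[str]
    groups: list[str]
    values: np.ndarray
    summaries: pd.DataFrame

    def table(self) -> pd.DataFrame:
        """Long-form table: subject, group, band, sensor, trial, H."""
        n_subj, n_sens, n_band, n_trial = self.values.shape
        idx = pd.MultiIndex.from_product(
            [range(n_subj), range(n_sens), range(n_band), range(n_trial)],
            names=["si", "sensor", "bi", "trial"],
        )
        df = pd.DataFrame({"H": self.values.ravel()}, index=idx).reset_index()
        df["subject"] = [self.subject_ids[i] for i in df["si"]]
        df["group"] = [self.groups[i] for i in df["si"]]
        df["band"] = [BANDS[i] for i in df["bi"]]
        return df[["subject", "group", "band", "sensor", "trial", "H"]]


def entropy_profile(
    decompositions: list[BandDecomposition], **kwargs
) -> EntropyProfile:
    """Per-element wavelet entropy for a cohort of band decompositions."""
    if not decompositions:
        raise ValueError("no decompositions supplied")
    for d in decompositions:
        missing = [b for b in BANDS if b not in d.coefficients]
        if missing:
            raise ValueError(f"{d.subject_id}: missing bands {missing}")
    values = np.stack([entropy_array(d, **kwargs) for d in decompositions])
    subject_ids = [d.subject_id for d in decompositions]
    groups = [d.group for d in decompositions]
    rows = []
    for i, sid in enumerate(subject_ids):
        for bi, band in enumerate(BANDS):
            rows.append(
                {
                    "subject": sid,
                    "group": groups[i],
                    "band": band,
                    "mean_H": float(values[i, :, bi, :].mean()),
                }
            )
    return EntropyProfile(subject_ids, groups, values, pd.DataFrame(rows))
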