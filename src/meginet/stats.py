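"""Group-difference and network-dynamics statistics.

* Non-parametric permutation tests on subject-level scalars (statistic:
  absolute group-mean difference; 10000 label permutations by default,
  p = (1 + #{permuted >= observed}) / (n_perm + 1)), Holm-Bonferroni
  corrected across bands.
* Functional-data-analysis (FDA) permutation tests that compare whole
  diagnostic-versus-cost curves between groups (integrated absolute mean
  difference by default, supremum statistic optional; 20000 permutations
  by default), with Benjamini-Hochberg FDR control across the
  (network kind x diagnostic) grid of p-values.
* Coefficient of variation (sample SD over mean) of diagnostics across
  trials, summarizing trial-to-trial network variability; compared across
  groups with a classical repeated-measures ANOVA (group between
  subjects; network kind and diagnostic within subjects).
* Ordinary least-squares fits of the entropy-strength relationship per
  group and band, at subject or sensor level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "permutation_test",
    "holm_bonferroni",
    "benjamini_hochberg",
    "fda_permutation_test",
    "coefficient_of_variation",
    "GroupComparisonGrid",
    "AnovaResult",
    "rm_anova_cv",
    "RegressionFit",
    "entropy_strength_fit",
]


def permutation_test(
    a: np.ndarray, b: np.ndarray, n_perm: int = 10000, seed: int = 0
) -> float:
    """Two-sample permutation p-value for |mean(a) - mean(b)|.

    Uses the add-one convention p = (1 + #{perm >= obs}) / (n_perm + 1),
    so the smallest attainable p is 1/(n_perm + 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    observed = abs(a.mean() - b.mean())
    # canonical form (sorted pool, smaller group selected) makes the
    # p-value exactly invariant under exchanging the two samples
    pooled = np.sort(pooled)
    n_sel = min(a.size, b.size)
    n_tot = pooled.size
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, n_tot))
    idx = np.argpartition(keys, n_sel - 1, axis=1)[:, :n_sel]
    perm_a = pooled[idx].mean(axis=1)
    tot_sum = pooled.sum()
    perm_b = (tot_sum - perm_a * n_sel) / (n_tot - n_sel)
    count = int(np.sum(np.abs(perm_a - perm_b) >= observed - 1e-12))
    return (1 + count) / (n_perm + 1)


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, original order preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg discovery flags at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def fda_permutation_test(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    n_perm: int = 20000,
    seed: int = 0,
    statistic: str = "integral",
) -> float:
    """Functional permutation test comparing two sets of curves.

    ``curves_a``/``curves_b`` are (n_subjects, n_grid) arrays on a common
    cost grid; each subject's whole curve is the unit of analysis. The
    statistic is the integrated (summed) absolute difference of group
    mean curves ('integral', default) or its supremum ('sup'). Grid
    points where either group is entirely missing are dropped pairwise.
    NaN is returned when no grid point is usable.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if a.shape[1] != b.shape[1]:
        raise ValueError("curves must share the cost grid")
    usable = ~(
        np.all(np.isnan(a), axis=0) | np.all(np.isnan(b), axis=0)
    )
    if not usable.any():
        return np.nan
    a, b = a[:, usable], b[:, usable]
    pooled = np.vstack([a, b])
    # canonical subject order + smaller-group selection: the p-value is
    # then exactly invariant under exchanging the two groups
    key = np.where(np.isnan(pooled), np.inf, pooled)
    pooled = pooled[np.lexsort(key.T[::-1])]
    n_a = min(a.shape[0], b.shape[0])
    n_tot = a.shape[0] + b.shape[0]

    def stat(mean_a, mean_b):
        diff = np.abs(mean_a - mean_b)
        if statistic == "integral":
            return np.nansum(diff, axis=-1)
        if statistic == "sup":
            return np.nanmax(diff, axis=-1)
        raise ValueError(f"unknown FDA statistic {statistic!r}")

    observed = float(stat(np.nanmean(a, axis=0), np.nanmean(b, axis=0)))
    rng = np.random.default_rng(seed)
    count = 0
    block = 2000  # permutations processed per vectorized chunk
    done = 0
    while done < n_perm:
        k = min(block, n_perm - done)
        keys = rng.random((k, n_tot))
        order = np.argsort(keys, axis=1)
        idx_a = order[:, :n_a]
        idx_b = order[:, n_a:]
        mean_a = np.nanmean(pooled[idx_a], axis=1)
        mean_b = np.nanmean(pooled[idx_b], axis=1)
        count += int(np.sum(stat(mean_a, mean_b) >= observed - 1e-12))
        done += k
    return (1 + count) / (n_perm + 1)


def coefficient_of_variation(values) -> float:
    """Sample CV = SD (n-1 denominator) / mean; NaN when the mean is 0."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size < 2:
        return np.nan
    mu = v.mean()
    if mu == 0:
        return np.nan
    return float(v.std(ddof=1) / mu)


@dataclass
class GroupComparisonGrid:
    """FDA p-values over (network kind x diagnostic), with FDR flags.

    ``direction`` is +1 where the patient-group mean curve integrates
    higher than the control group's, -1 otherwise.
    """

    kinds: list[str]
    diagnostics: list[str]
    p_values: np.ndarray
    direction: np.ndarray
    q: float = 0.05
    alpha: float = 0.05
    fdr_flags: np.ndarray = field(init=False)
    uncorrected_flags: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        p = np.asarray(self.p_values, dtype=float)
        if p.shape != (len(self.kinds), len(self.diagnostics)):
            raise ValueError("p-value grid shape mismatch")
        flat = p.ravel()
        ok = ~np.isnan(flat)
        fdr = np.zeros(flat.size, dtype=bool)
        if ok.any():
            fdr[ok] = benjamini_hochberg(flat[ok], q=self.q)
        self.fdr_flags = fdr.reshape(p.shape)
        self.uncorrected_flags = (p <= self.alpha) & ~np.isnan(p)

    def table(self) -> pd.DataFrame:
        rows = []
        for i, kind in enumerate(self.kinds):
            for j, diag in enumerate(self.diagnostics):
                rows.append(
                    {
                        "network_kind": kind,
                        "diagnostic": diag,
                        "p": self.p_values[i, j],
                        "fdr_flag": bool(self.fdr_flags[i, j]),
                        "uncorrected_flag": bool(self.uncorrected_flags[i, j]),
                        "direction": int(self.direction[i, j]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA table (one row per effect)."""

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


def rm_anova_cv(
    data: np.ndarray, groups, kinds=None, diagnostics=None
) -> AnovaResult:
    """Repeated-measures ANOVA of CV values.

    ``data`` is a balanced (n_subjects, n_kinds, n_diagnostics) array with
    no missing cells; ``groups`` assigns each subject to a group. Group is
    a between-subject factor; network kind ("frequency band") and
    diagnostic are within-subject factors. Classical unadjusted univariate
    sums-of-squares decomposition; each within effect is tested against
    its own effect-by-subject(group) error stratum.
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError("data must be (subjects, kinds, diagnostics)")
    if np.any(np.isnan(y)):
        raise ValueError("missing cells are not supported (no imputation)")
    groups = np.asarray(groups)
    n_s, n_b, n_d = y.shape
    if groups.size != n_s:
        raise ValueError("one group label per subject required")
    glabels, gidx = np.unique(groups, return_inverse=True)
    n_g = glabels.size

    grand = y.mean()
    m_g = np.array([y[gidx == g].mean() for g in range(n_g)])
    n_per = np.array([(gidx == g).sum() for g in range(n_g)])
    m_s = y.mean(axis=(1, 2))
    m_b = y.mean(axis=(0, 2))
    m_d = y.mean(axis=(0, 1))
    m_gb = np.array([y[gidx == g].mean(axis=(0, 2)) for g in range(n_g)])
    m_gd = np.array([y[gidx == g].mean(axis=(0, 1)) for g in range(n_g)])
    m_bd = y.mean(axis=0)
    m_sb = y.mean(axis=2)
    m_sd = y.mean(axis=1)
    m_gbd = np.array([y[gidx == g].mean(axis=0) for g in range(n_g)])

    ss_group = n_b * n_d * float(np.sum(n_per * (m_g - grand) ** 2))
    ss_subj = n_b * n_d * float(np.sum((m_s - m_g[gidx]) ** 2))
    ss_band = n_s * n_d * float(np.sum((m_b - grand) ** 2))
    ss_bg = n_d * float(
        np.sum(
            n_per[:, None]
            * (m_gb - m_g[:, None] - m_b[None, :] + grand) ** 2
        )
    )
    ss_bs = n_d * float(
        np.sum((m_sb - m_s[:, None] - m_gb[gidx] + m_g[gidx][:, None]) ** 2)
    )
    ss_diag = n_s * n_b * float(np.sum((m_d - grand) ** 2))
    ss_dg = n_b * float(
        np.sum(
            n_per[:, None]
            * (m_gd - m_g[:, None] - m_d[None, :] + grand) ** 2
        )
    )
    ss_ds = n_b * float(
        np.sum((m_sd - m_s[:, None] - m_gd[gidx] + m_g[gidx][:, None]) ** 2)
    )
    ss_bd = n_s * float(
        np.sum((m_bd - m_b[:, None] - m_d[None, :] + grand) ** 2)
    )
    ss_bdg = float(
        np.sum(
            n_per[:, None, None]
            * (
                m_gbd
                - m_gb[:, :, None]
                - m_gd[:, None, :]
                - m_bd[None, :, :]
                + m_g[:, None, None]
                + m_b[None, :, None]
                + m_d[None, None, :]
                - grand
            )
            ** 2
        )
    )
    ss_total = float(np.sum((y - grand) ** 2))
    ss_bds = ss_total - (
        ss_group + ss_subj + ss_band + ss_bg + ss_bs
        + ss_diag + ss_dg + ss_ds + ss_bd + ss_bdg
    )

    df_group = n_g - 1
    df_subj = n_s - n_g
    df_band = n_b - 1
    df_diag = n_d - 1
    df_bg = df_group * df_band
    df_dg = df_group * df_diag
    df_bd = df_band * df_diag
    df_bdg = df_group * df_band * df_diag
    df_bs = df_subj * df_band
    df_ds = df_subj * df_diag
    df_bds = df_subj * df_band * df_diag

    def row(effect, ss, df, ss_err, df_err):
        ms = ss / df
        ms_err = ss_err / df_err
        f = ms / ms_err if ms_err > 0 else np.nan
        p = float(sps.f.sf(f, df, df_err)) if np.isfinite(f) else np.nan
        return {
            "effect": effect, "SSE": ss, "DF": df, "MSE": ms, "F": f, "p": p,
        }

    table = pd.DataFrame(
        [
            row("group", ss_group, df_group, ss_subj, df_subj),
            row("band", ss_band, df_band, ss_bs, df_bs),
            row("diagnostic", ss_diag, df_diag, ss_ds, df_ds),
            row("band*diagnostic", ss_bd, df_bd, ss_bds, df_bds),
            row("band*group", ss_bg, df_bg, ss_bs, df_bs),
            row("diagnostic*group", ss_dg, df_dg, ss_ds, df_ds),
            row("band*diagnostic*group", ss_bdg, df_bdg, ss_bds, df_bds),
        ]
    )
    return AnovaResult(table)


@dataclass
class RegressionFit:
    """OLS fit of strength on entropy for one group and band."""

    group: str
    band: str
    level: str
    slope: float
    intercept: float
    r_squared: float
    n: int


def entropy_strength_fit(
    entropy: np.ndarray,
    strength: np.ndarray,
    group: str = "",
    band: str = "",
    level: str = "subject",
) -> RegressionFit:
    """Least-squares line strength ~ entropy with R^2.

    Slope is NaN when the entropy values have zero variance.
    """
    x = np.asarray(entropy, dtype=float).ravel()
    y = np.asarray(strength, dtype=float).ravel()
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        return RegressionFit(group, band, level, np.nan, np.nan, np.nan, x.size)
    res = sps.linregress(x, y)
    return RegressionFit(
        group, band, level,
        float(res.slope), float(res.intercept), float(res.rvalue**2), x.size,
    )
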