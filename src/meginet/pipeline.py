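"""End-to-end orchestration: simulate -> decompose -> connectivity ->
networks -> diagnostics -> statistics.

A single :class:`RunConfig` document reaches every stage parameter.
Randomness is derived from one seed with fixed offsets per (subject,
stage), so re-running an identical configuration reproduces every output
exactly, regardless of worker count or evaluation order.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .connectivity import NETWORK_KINDS, strength, trial_matrices
from .diagnostics import (
    CV_DIAGNOSTICS,
    DIAGNOSTICS,
    DiagnosticsConfig,
    cost_efficiency,
    evaluate_ensembles,
)
from .entropy import entropy_array
from .networks import default_cost_grid, er_random_graphs, threshold_sweep
from .spectral import BANDS, decompose_recording, resample_to_analysis_rate
from .stats import (
    GroupComparisonGrid,
    coefficient_of_variation,
    entropy_strength_fit,
    fda_permutation_test,
    holm_bonferroni,
    permutation_test,
    rm_anova_cv,
)
from .synthetic import Cohort, CohortConfig, GroupParams, generate_cohort, load_cohort

logger = logging.getLogger("meginet")

__all__ = ["RunConfig", "ResultBundle", "run_pipeline", "write_report"]


@dataclass
class RunConfig:
    """Every downstream parameter of one analysis run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    input_path: str | None = None  # analyze an existing HDF5 cohort instead
    n_bins: int = 8
    binning: str = "width"
    entropy_method: str = "energy"
    wavelet: str = "d4"
    cost_grid: list[float] | None = None
    diagnostics: tuple[str, ...] = DIAGNOSTICS
    modularity_restarts: int = 10
    n_attack_orders: int = 20
    rent_boxes: int = 5000
    synchronizability: str = "ratio"
    n_perm_scalar: int = 10000
    n_perm_fda: int = 20000
    fda_statistic: str = "integral"
    q: float = 0.05
    alpha: float = 0.05
    er_null: bool = True
    seed: int = 0
    jobs: int = 1

    _KNOWN = None  # populated below

    def grid(self) -> np.ndarray:
        if self.cost_grid is None:
            return default_cost_grid()
        return np.asarray(self.cost_grid, dtype=float)

    def diag_config(self) -> DiagnosticsConfig:
        return DiagnosticsConfig(
            modularity_restarts=self.modularity_restarts,
            n_attack_orders=self.n_attack_orders,
            rent_boxes=self.rent_boxes,
            synchronizability=self.synchronizability,
            wavelet=self.wavelet,
        )

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_jsonable()
        d["diagnostics"] = list(self.diagnostics)
        d.pop("_KNOWN", None)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_jsonable(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        known = {f for f in cls.__dataclass_fields__ if f != "_KNOWN"}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "cohort" in doc:
            cdoc = dict(doc["cohort"])
            for key in ("control_params", "patient_params"):
                if key in cdoc:
                    pdoc = dict(cdoc[key])
                    if "xfreq_coupling" in pdoc and isinstance(
                        pdoc["xfreq_coupling"], dict
                    ):
                        pdoc["xfreq_coupling"] = {
                            tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                            for k, v in pdoc["xfreq_coupling"].items()
                        }
                    cdoc[key] = GroupParams(**pdoc)
            ck = set(cdoc) - set(CohortConfig.__dataclass_fields__)
            if ck:
                raise ValueError(f"unknown cohort config keys: {sorted(ck)}")
            doc["cohort"] = CohortConfig(**cdoc)
        if "diagnostics" in doc:
            doc["diagnostics"] = tuple(doc["diagnostics"])
        return cls(**doc)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(json.load(f))


@dataclass
class SubjectResult:
    """Per-subject intermediate results (cached between stages)."""

    subject_id: str
    group: str
    entropy: np.ndarray  # (sensors, bands, trials)
    network_strength: np.ndarray  # (kinds, trials)
    sensor_strength: np.ndarray  # (kinds, trials, sensors)
    diag_values: np.ndarray  # (kinds, diagnostics, trials, costs)


@dataclass
class ResultBundle:
    """All tables produced by one pipeline run."""

    config: RunConfig
    subjects: list[SubjectResult]
    entropy_table: pd.DataFrame
    strength_table: pd.DataFrame
    curves: pd.DataFrame
    cost_efficiency_table: pd.DataFrame
    comparison_grid: GroupComparisonGrid
    cv_table: pd.DataFrame
    anova: object | None
    regression_table: pd.DataFrame
    scalar_tests: pd.DataFrame
    er_null_curves: pd.DataFrame | None
    manifest: dict


def _analyze_subject(args) -> SubjectResult:
    recording, config = args
    t0 = time.perf_counter()
    rec = resample_to_analysis_rate(recording, config.cohort.analysis_rate)
    decomp = decompose_recording(rec, wavelet=config.wavelet)
    ent = entropy_array(decomp, method=config.entropy_method)
    n_trials = rec.n_trials
    n_sens = rec.n_sensors
    grid = config.grid()
    kinds = NETWORK_KINDS
    names = config.diagnostics
    net_strength = np.zeros((len(kinds), n_trials))
    sens_strength = np.zeros((len(kinds), n_trials, n_sens))
    ensembles: dict[str, list] = {k: [] for k in kinds}
    for t in range(n_trials):
        mats = trial_matrices(decomp, t, n_bins=config.n_bins, binning=config.binning)
        for ki, kind in enumerate(kinds):
            sp = strength(mats[kind])
            net_strength[ki, t] = sp.network_strength
            sens_strength[ki, t] = sp.sensor_strength
            ensembles[kind].append(threshold_sweep(mats[kind].weights, grid))
    subj_seed = int(
        hashlib.sha256(recording.subject_id.encode()).hexdigest()[:8], 16
    ) ^ (config.seed & 0x7FFFFFFF)
    diag = np.full((len(kinds), len(names), n_trials, len(grid)), np.nan)
    cfg = config.diag_config()
    layout = _analyze_subject.layout  # set by caller (picklable via global)
    for ki, kind in enumerate(kinds):
        diag[ki] = evaluate_ensembles(
            ensembles[kind], layout, seed=subj_seed + ki, config=cfg, names=names
        )
    logger.info(
        "subject %s analyzed in %.1fs", recording.subject_id,
        time.perf_counter() - t0,
    )
    return SubjectResult(
        recording.subject_id, recording.group, ent, net_strength, sens_strength, diag
    )


_analyze_subject.layout = None


def _init_worker(layout):
    _analyze_subject.layout = layout


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> ResultBundle:
    """Execute every stage and assemble the result bundle."""
    t_start = time.perf_counter()
    if cohort is None:
        if config.input_path is not None:
            recs, layout, manifest = load_cohort(config.input_path)
            cohort = Cohort(recs, layout, config.cohort, manifest)
        else:
            cohort = generate_cohort(config.cohort)
            logger.info("cohort simulated: %d subjects", len(cohort.recordings))
    layout = cohort.layout
    grid = config.grid()
    kinds = list(NETWORK_KINDS)
    names = list(config.diagnostics)

    tasks = [(rec, config) for rec in cohort.recordings]
    if config.jobs > 1:
        with ProcessPoolExecutor(
            max_workers=config.jobs, initializer=_init_worker, initargs=(layout,)
        ) as pool:
            subjects = list(pool.map(_analyze_subject, tasks))
    else:
        _init_worker(layout)
        subjects = [_analyze_subject(t) for t in tasks]

    groups = sorted({s.group for s in subjects})
    if len(groups) != 2:
        raise ValueError("pipeline statistics require exactly two groups")
    g_a, g_b = groups  # alphabetical: control, patient

    # ---- entropy and strength tables (subject-level summaries) ----
    ent_rows, str_rows = [], []
    for s in subjects:
        for bi, band in enumerate(BANDS):
            ent_rows.append(
                {
                    "subject": s.subject_id, "group": s.group, "band": band,
                    "mean_H": float(s.entropy[:, bi, :].mean()),
                }
            )
        for ki, kind in enumerate(kinds):
            str_rows.append(
                {
                    "subject": s.subject_id, "group": s.group, "kind": kind,
                    "mean_strength": float(s.network_strength[ki].mean()),
                }
            )
    entropy_table = pd.DataFrame(ent_rows)
    strength_table = pd.DataFrame(str_rows)

    # ---- scalar group tests (per band), Holm-corrected ----
    rng_off = config.seed
    scalar_rows = []
    for measure, table, key in (
        ("entropy", entropy_table, "mean_H"),
        ("strength", strength_table[strength_table["kind"].str.startswith("intra")], "mean_strength"),
    ):
        sub_ps = []
        labels = []
        for band in BANDS:
            if measure == "entropy":
                t = table[table["band"] == band]
            else:
                t = table[table["kind"] == f"intra:{band}"]
            a = t[t["group"] == g_a][key].to_numpy()
            b = t[t["group"] == g_b][key].to_numpy()
            p = permutation_test(
                a, b, n_perm=config.n_perm_scalar,
                seed=rng_off + 1000 * BANDS.index(band)
                + (0 if measure == "entropy" else 7),
            )
            sub_ps.append(p)
            labels.append(band)
        adj = holm_bonferroni(sub_ps)
        for band, p, pa in zip(labels, sub_ps, adj):
            scalar_rows.append(
                {"measure": measure, "band": band, "p": p, "p_holm": float(pa)}
            )
    scalar_tests = pd.DataFrame(scalar_rows)

    # ---- diagnostic curves (subject means over trials) ----
    curve_rows = []
    curves_by = {}  # (kind, diag) -> dict group -> (n_subj, n_costs)
    for ki, kind in enumerate(kinds):
        for di, diag in enumerate(names):
            per_group = {g: [] for g in groups}
            for s in subjects:
                with np.errstate(invalid="ignore"):
                    mean_curve = np.nanmean(s.diag_values[ki, di], axis=0)
                per_group[s.group].append(mean_curve)
                for ci, cost in enumerate(grid):
                    curve_rows.append(
                        {
                            "subject": s.subject_id, "group": s.group,
                            "network_kind": kind, "diagnostic": diag,
                            "cost": float(cost), "value": mean_curve[ci],
                            "missing_flag": bool(np.isnan(mean_curve[ci])),
                        }
                    )
            curves_by[(kind, diag)] = {
                g: np.asarray(v) for g, v in per_group.items()
            }
    curves = pd.DataFrame(curve_rows)

    # ---- FDA grid over (kind x diagnostic) ----
    p_grid = np.full((len(kinds), len(names)), np.nan)
    direction = np.zeros((len(kinds), len(names)))
    for ki, kind in enumerate(kinds):
        for di, diag in enumerate(names):
            byg = curves_by[(kind, diag)]
            a, b = byg[g_a], byg[g_b]
            if np.all(np.isnan(a)) or np.all(np.isnan(b)):
                continue
            p_grid[ki, di] = fda_permutation_test(
                a, b, n_perm=config.n_perm_fda,
                seed=config.seed + ki * 131 + di,
                statistic=config.fda_statistic,
            )
            with np.errstate(invalid="ignore"):
                diff = np.nansum(np.nanmean(b, axis=0) - np.nanmean(a, axis=0))
            direction[ki, di] = 1.0 if diff >= 0 else -1.0
    comparison_grid = GroupComparisonGrid(
        kinds, names, p_grid, direction, q=config.q, alpha=config.alpha
    )

    # ---- cost-efficiency per subject/kind ----
    ce_rows = []
    if "global_efficiency" in names:
        di_eg = names.index("global_efficiency")
        for s in subjects:
            for ki, kind in enumerate(kinds):
                with np.errstate(invalid="ignore"):
                    curve = np.nanmean(s.diag_values[ki, di_eg], axis=0)
                ce = cost_efficiency(curve, grid)
                ce_rows.append(
                    {
                        "subject": s.subject_id, "group": s.group, "kind": kind,
                        "cost_efficiency": ce.cost_efficiency,
                        "optimal_cost": ce.optimal_cost,
                    }
                )
    cost_efficiency_table = pd.DataFrame(ce_rows)

    # ---- temporal variability: CV over trials, averaged over costs ----
    cv_diags = [d for d in names if d in CV_DIAGNOSTICS]
    cv_rows = []
    cv_array = np.full((len(subjects), len(kinds), len(cv_diags)), np.nan)
    for si, s in enumerate(subjects):
        for ki, kind in enumerate(kinds):
            for dj, diag in enumerate(cv_diags):
                di = names.index(diag)
                vals = s.diag_values[ki, di]  # (trials, costs)
                cvs = []
                for ci in range(vals.shape[1]):
                    cv = coefficient_of_variation(vals[:, ci])
                    if not np.isnan(cv):
                        cvs.append(cv)
                cv_val = float(np.mean(cvs)) if cvs else np.nan
                cv_array[si, ki, dj] = cv_val
                cv_rows.append(
                    {
                        "subject": s.subject_id, "group": s.group,
                        "network_kind": kind, "diagnostic": diag, "cv": cv_val,
                    }
                )
    cv_table = pd.DataFrame(cv_rows)

    anova = None
    if not np.any(np.isnan(cv_array)) and all(
        sum(1 for s in subjects if s.group == g) >= 2 for g in groups
    ):
        anova = rm_anova_cv(
            cv_array, [s.group for s in subjects], kinds, cv_diags
        )

    # ---- entropy-strength regressions ----
    reg_rows = []
    for bi, band in enumerate(BANDS):
        ki = kinds.index(f"intra:{band}")
        for g in groups:
            gs = [s for s in subjects if s.group == g]
            ent = np.array([s.entropy[:, bi, :].mean() for s in gs])
            stg = np.array([s.network_strength[ki].mean() for s in gs])
            if ent.size >= 3:
                try:
                    fit = entropy_strength_fit(ent, stg, g, band, "subject")
                    reg_rows.append(asdict(fit))
                except ValueError:
                    pass
            # sensor level: per-sensor means over trials and subjects
            ent_sens = np.mean([s.entropy[:, bi, :].mean(axis=1) for s in gs], axis=0)
            stg_sens = np.mean([s.sensor_strength[ki].mean(axis=0) for s in gs], axis=0)
            if ent_sens.size >= 3:
                try:
                    fit = entropy_strength_fit(ent_sens, stg_sens, g, band, "sensor")
                    reg_rows.append(asdict(fit))
                except ValueError:
                    pass
    regression_table = pd.DataFrame(reg_rows)

    # ---- ER null curves ----
    er_null_curves = None
    if config.er_null:
        n_nodes = layout.n_sensors
        n_graphs = cohort.config.n_trials if cohort.config else 66
        null_rows = []
        cfg_d = config.diag_config()
        for ci, cost in enumerate(grid):
            ens = er_random_graphs(
                n_nodes, float(cost), n_graphs=n_graphs,
                seed=config.seed + 77_000 + ci,
            )
            vals = evaluate_ensembles(
                [ens], layout, seed=config.seed + 88_000 + ci,
                config=cfg_d, names=tuple(names),
            )  # (n_diag, 1, n_graphs) -- one ensemble treated as trials
            for di, diag in enumerate(names):
                with np.errstate(invalid="ignore"):
                    null_rows.append(
                        {
                            "diagnostic": diag, "cost": float(cost),
                            "mean": float(np.nanmean(vals[di])),
                            "sd": float(np.nanstd(vals[di])),
                        }
                    )
        er_null_curves = pd.DataFrame(null_rows)

    manifest = {
        "config": config.to_jsonable(),
        "config_hash": config.config_hash(),
        "software_version": __version__,
        "n_subjects": len(subjects),
        "network_kinds": kinds,
        "diagnostics": names,
        "cost_grid": [float(c) for c in grid],
        "wall_time_s": round(time.perf_counter() - t_start, 2),
    }
    logger.info("pipeline finished in %.1fs", time.perf_counter() - t_start)
    return ResultBundle(
        config=config,
        subjects=subjects,
        entropy_table=entropy_table,
        strength_table=strength_table,
        curves=curves,
        cost_efficiency_table=cost_efficiency_table,
        comparison_grid=comparison_grid,
        cv_table=cv_table,
        anova=anova,
        regression_table=regression_table,
        scalar_tests=scalar_tests,
        er_null_curves=er_null_curves,
        manifest=manifest,
    )


def write_report(bundle: ResultBundle, outdir) -> list[str]:
    """Write CSV tables, the JSON manifest, and summary figures.

    Returns the list of files written (relative names).
    """
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def save_csv(df, name):
        if df is None or (hasattr(df, "empty") and df.empty):
            return
        df.to_csv(out / name, index=False)
        written.append(name)

    save_csv(bundle.entropy_table, "entropy.csv")
    save_csv(bundle.strength_table, "strength.csv")
    save_csv(bundle.curves, "diagnostic_curves.csv")
    save_csv(bundle.cost_efficiency_table, "cost_efficiency.csv")
    save_csv(bundle.comparison_grid.table(), "comparison_grid.csv")
    save_csv(bundle.cv_table, "cv.csv")
    save_csv(bundle.scalar_tests, "scalar_tests.csv")
    save_csv(bundle.regression_table, "regression_fits.csv")
    if bundle.er_null_curves is not None:
        save_csv(bundle.er_null_curves, "er_null_curves.csv")
    if bundle.anova is not None:
        save_csv(bundle.anova.table, "anova.csv")
    with open(out / "manifest.json", "w") as f:
        json.dump(bundle.manifest, f, indent=2, sort_keys=True)
    written.append("manifest.json")

    # --- figures ---
    groups = sorted(bundle.entropy_table["group"].unique())
    colors = {groups[0]: "tab:blue", groups[-1]: "tab:red"}

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    for ax, (table, key, title) in zip(
        axes,
        [
            (bundle.entropy_table, "mean_H", "wavelet entropy"),
            (
                bundle.strength_table[
                    bundle.strength_table["kind"].str.startswith("intra")
                ].assign(band=lambda d: d["kind"].str.split(":").str[1]),
                "mean_strength",
                "network strength",
            ),
        ],
    ):
        for gi, g in enumerate(groups):
            t = table[table["group"] == g]
            means = t.groupby("band", sort=False)[key].mean().reindex(list(BANDS))
            sems = t.groupby("band", sort=False)[key].sem().reindex(list(BANDS))
            x = np.arange(len(BANDS)) + 0.35 * gi
            ax.bar(x, means, 0.35, yerr=sems, label=g, color=colors[g])
        ax.set_xticks(np.arange(len(BANDS)) + 0.17)
        ax.set_xticklabels(BANDS, rotation=30)
        ax.set_title(title)
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "group_entropy_strength.png", dpi=110)
    plt.close(fig)
    written.append("group_entropy_strength.png")

    grid_df = bundle.comparison_grid
    fig, ax = plt.subplots(figsize=(7, 4))
    signed = np.where(
        np.isnan(grid_df.p_values), 0.0,
        grid_df.direction * (
            2.0 * grid_df.fdr_flags + 1.0 * (
                grid_df.uncorrected_flags & ~grid_df.fdr_flags
            )
        ),
    )
    im = ax.imshow(signed.T, cmap="coolwarm", vmin=-2, vmax=2, aspect="auto")
    ax.set_xticks(range(len(grid_df.kinds)))
    ax.set_xticklabels(grid_df.kinds, rotation=90, fontsize=6)
    ax.set_yticks(range(len(grid_df.diagnostics)))
    ax.set_yticklabels(grid_df.diagnostics, fontsize=6)
    fig.colorbar(im, label="signed significance")
    fig.tight_layout()
    fig.savefig(out / "comparison_grid.png", dpi=110)
    plt.close(fig)
    written.append("comparison_grid.png")

    if not bundle.cost_efficiency_table.empty:
        fig, ax = plt.subplots(figsize=(8, 3.5))
        ce = bundle.cost_efficiency_table
        kinds = list(dict.fromkeys(ce["kind"]))
        for gi, g in enumerate(groups):
            t = ce[ce["group"] == g]
            means = t.groupby("kind", sort=False)["cost_efficiency"].mean().reindex(kinds)
            x = np.arange(len(kinds)) + 0.35 * gi
            ax.bar(x, means, 0.35, label=g, color=colors[g])
        if bundle.er_null_curves is not None:
            null_eg = bundle.er_null_curves[
                bundle.er_null_curves["diagnostic"] == "global_efficiency"
            ]
            if not null_eg.empty:
                ce_null = float(
                    (null_eg["mean"] - null_eg["cost"]).max()
                )
                ax.axhline(ce_null, color="gray", lw=2, alpha=0.6, label="ER null")
        ax.set_xticks(np.arange(len(kinds)) + 0.17)
        ax.set_xticklabels(kinds, rotation=90, fontsize=6)
        ax.set_ylabel("cost-efficiency")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "cost_efficiency.png", dpi=110)
        plt.close(fig)
        written.append("cost_efficiency.png")

    return written
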