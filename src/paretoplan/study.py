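"""Evaluative-study machinery: cohorts, paired statistics and reports.

Implements the paired nonparametric comparison used to contrast two planning
arms metric-by-metric: a two-sided Wilcoxon signed-rank test in which exactly
tied pairs (zero differences) are omitted and no test is performed when fewer
than 10 informative pairs remain.  The exact null law is used for n ≤ 15
(rank-sum distribution over all 2^n sign assignments, tied ranks handled by
averaging) and a tie-corrected normal approximation with continuity
correction beyond that.

Also provides the calibration-propagation experiment — navigate a
four-dimension Pareto dataset on one patient, commit a rectum-sparing (Cal1)
and a balanced (Cal2) calibration, replan a whole cohort under both and
report how rectum Dmean, HI(PTV60) and CI(PTV48) shift — and a synthetic
end-to-end study runner in which a deliberately mis-prioritised comparator
protocol stands in for the manual clinical arm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics
from .dose_engine import BeamConfig, build_influence_matrix
from .metrics import MetricSpec, evaluate_goal_table, evaluate_metric
from .pareto import (NavigationDimension, commit_calibration, generate_dataset)
from .pbaio import PBAIOConfig, autoplan
from .phantom import build_ptvs, generate_patient
from .protocol import AutoPlanProtocol, load_builtin_goal_table, load_builtin_protocol

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "CohortResult",
    "ComparisonRow",
    "compare_cohorts",
    "default_metric_panel",
    "UtilityExperimentConfig",
    "run_utility_experiment",
    "StudyConfig",
    "run_study",
]

MIN_TESTED_N = 10
EXACT_MAX_N = 15


@dataclasses.dataclass(frozen=True)
class WilcoxonResult:
    """Outcome of one paired test; ``p_value`` is None when not tested."""

    p_value: Optional[float]
    statistic: Optional[float]
    n_effective: int
    tested: bool

    @property
    def significant(self) -> bool:
        return self.tested and self.p_value is not None and self.p_value <= 0.05


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for the signed-rank statistic.

    Builds the null distribution of W+ over all 2^n equally likely sign
    assignments of the (possibly tied, averaged) ranks by dynamic
    programming on doubled ranks, then doubles the smaller tail.
    """
    r2 = np.rint(ranks * 2).astype(int)  # halves -> integers
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(w_plus * 2))
    lo = pmf[: w2 + 1].sum()
    hi = pmf[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_signed_rank(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test with tie omission and n<10 skip.

    Zero differences are dropped; if fewer than 10 informative pairs remain
    the comparison is reported as "not tested".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n < MIN_TESTED_N:
        return WilcoxonResult(None, None, n, False)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_MAX_N:
        p = _exact_two_sided_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(ranks, return_counts=True)
        var -= (counts**3 - counts).sum() / 48.0
        diff = w_plus - mu
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)  # continuity correction
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(p, w_plus, n, True)


# --- cohort comparison -------------------------------------------------------

@dataclasses.dataclass
class CohortResult:
    """Per-patient, per-arm metric values (long-format DataFrame)."""

    table: pd.DataFrame  # columns: patient, arm, metric, value
    arms: Tuple[str, str]
    seeds: List[int]

    def arm_values(self, metric: str, arm: str) -> np.ndarray:
        t = self.table
        sel = t[(t["metric"] == metric) & (t["arm"] == arm)].sort_values("patient")
        return sel["value"].to_numpy()


@dataclasses.dataclass
class ComparisonRow:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    p_value: Optional[float]
    tested: bool
    significant: bool


def compare_cohorts(result: CohortResult,
                    metric_names: Optional[Sequence[str]] = None) -> List[ComparisonRow]:
    """One comparison row per metric: means ± SD per arm plus the paired test."""
    arm_a, arm_b = result.arms
    if metric_names is None:
        metric_names = list(dict.fromkeys(result.table["metric"]))
    rows = []
    for m in metric_names:
        a = result.arm_values(m, arm_a)
        b = result.arm_values(m, arm_b)
        if a.size != b.size:
            raise ValueError(f"arms cover different patients for metric {m!r}")
        w = wilcoxon_signed_rank(a, b)
        rows.append(ComparisonRow(
            metric=m,
            mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
            mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
            p_value=w.p_value, tested=w.tested, significant=w.significant))
    return rows


def comparison_to_frame(rows: Sequence[ComparisonRow], arms: Tuple[str, str]) -> pd.DataFrame:
    a, b = arms
    return pd.DataFrame([{
        "metric": r.metric,
        f"{a}_mean": r.mean_a, f"{a}_sd": r.sd_a,
        f"{b}_mean": r.mean_b, f"{b}_sd": r.sd_b,
        "p_value": "n < 10" if not r.tested else f"{r.p_value:.4f}",
        "significant": r.significant,
    } for r in rows])


def format_comparison(rows: Sequence[ComparisonRow], arms: Tuple[str, str]) -> str:
    """Plain-text table: metric, mean ± SD per arm, p value."""
    a, b = arms
    lines = [f"{'Metric':34s} {a:>18s} {b:>18s} {'p':>8s}"]
    for r in rows:
        p = "n<10" if not r.tested else f"{r.p_value:.3f}"
        mark = "*" if r.significant else " "
        lines.append(f"{r.metric:34s} {r.mean_a:9.2f}±{r.sd_a:<7.2f} "
                     f"{r.mean_b:9.2f}±{r.sd_b:<7.2f} {p:>8s}{mark}")
    return "\n".join(lines)


def default_metric_panel(profile: str = "instA") -> List[MetricSpec]:
    """PTV D98/D2/HI (subtraction convention) + CI, OAR means, key V-levels."""
    specs: List[MetricSpec] = []
    for ptv, presc in (("PTV60", 60.0), ("PTV57.5", 57.5), ("PTV48", 48.0)):
        sub = ptv != "PTV60"
        specs += [
            MetricSpec("D_percent", ptv, 98.0, subtract=sub),
            MetricSpec("D_percent", ptv, 2.0, subtract=sub),
            MetricSpec("HI", ptv, subtract=sub),
            MetricSpec("CI", ptv, reference_dose=0.95 * presc),
        ]
    for level in (24.3, 32.4, 40.5, 48.6, 52.7, 56.8, 60.0):
        specs.append(MetricSpec("V_dose_percent", "rectum", level))
    specs.append(MetricSpec("Dmean", "rectum"))
    for level in (40.5, 48.6, 60.0):
        specs.append(MetricSpec("V_dose_percent", "bladder", level))
    specs.append(MetricSpec("Dmean", "bladder"))
    specs.append(MetricSpec("D_abs_volume", "external", 1.8))
    if profile == "instB":
        specs.append(MetricSpec("V_dose_abs", "bowel", 40.5))
        specs.append(MetricSpec("V_dose_percent", "femoral_head_left", 40.5))
        specs.append(MetricSpec("V_dose_percent", "femoral_head_right", 40.5))
    return specs


# --- calibration-propagation (utility) experiment ----------------------------

@dataclasses.dataclass
class UtilityExperimentConfig:
    """Four-dimension navigation on patient 1, propagated to a cohort.

    Dimension samples bracket a rectum-sparing vertex (Cal1: relaxed PTV60
    min/max targets, high rectum-Dmean WF, low external fall-off WF) and a
    balanced vertex matching the calibrated protocol (Cal2).
    """

    n_patients: int = 10
    seed: int = 1
    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)
    profile: str = "instA"
    beam_config: BeamConfig = dataclasses.field(
        default_factory=lambda: BeamConfig(n_beams=12))
    pbaio_config: PBAIOConfig = dataclasses.field(
        default_factory=lambda: PBAIOConfig(inner_iterations=20, outer_loops=3))
    ptv60_dmin_samples: Tuple[float, float] = (96.0, 98.7)     # %Presc,PTV
    ptv60_dmax_samples: Tuple[float, float] = (101.7, 104.0)   # %Presc,PTV
    rectum_wf_samples: Tuple[float, float] = (5.84, 58.4)
    falloff_wf_samples: Tuple[float, float] = (20.4, 204.0)


def _cohort_geometries(n, seed, grid_shape, spacing, profile):
    geos = []
    for i in range(n):
        g = generate_patient(seed + i, grid_shape=grid_shape, spacing=spacing,
                             profile=profile)
        geos.append(build_ptvs(g))
    return geos


def _utility_metrics(dose, geometry) -> Dict[str, float]:
    return {
        "rectum Dmean": evaluate_metric(MetricSpec("Dmean", "rectum"), dose, geometry),
        "HI PTV60": evaluate_metric(MetricSpec("HI", "PTV60"), dose, geometry),
        "CI PTV48": evaluate_metric(
            MetricSpec("CI", "PTV48", reference_dose=0.95 * 48.0), dose, geometry),
    }


def run_utility_experiment(config: UtilityExperimentConfig):
    """Generate the 4-D navigation dataset on patient 1, commit Cal1/Cal2 and
    replan the whole cohort under both calibrations.

    Returns a dict with the per-patient metric table (DataFrame), the
    Cal1−Cal2 deltas and cohort means.
    """
    base = load_builtin_protocol(config.profile)
    geos = _cohort_geometries(config.n_patients, config.seed, config.grid_shape,
                              config.spacing, config.profile)
    dims = [
        NavigationDimension("PTV60", "min_dose", "target", config.ptv60_dmin_samples),
        NavigationDimension("PTV60", "max_dose", "target", config.ptv60_dmax_samples),
        NavigationDimension("rectum", "mean_dose", "weighting_factor",
                            config.rectum_wf_samples),
        NavigationDimension("external", "dose_falloff_external", "weighting_factor",
                            config.falloff_wf_samples),
    ]
    dataset = generate_dataset(geos[0], base, dims, config.beam_config,
                               config.pbaio_config)
    labels = dataset.labels
    cal1_pos = dict(zip(labels, (config.ptv60_dmin_samples[0],
                                 config.ptv60_dmax_samples[1],
                                 config.rectum_wf_samples[1],
                                 config.falloff_wf_samples[0])))
    cal2_pos = dict(zip(labels, (config.ptv60_dmin_samples[1],
                                 config.ptv60_dmax_samples[0],
                                 config.rectum_wf_samples[0],
                                 config.falloff_wf_samples[1])))
    cal1 = commit_calibration(dataset, cal1_pos, base)
    cal2 = commit_calibration(dataset, cal2_pos, base)

    records = []
    for i, geo in enumerate(geos):
        influence = build_influence_matrix(geo, config.beam_config)
        for cal_name, proto in (("Cal1", cal1), ("Cal2", cal2)):
            plan = autoplan(geo, proto, config.beam_config, config.pbaio_config,
                            influence=influence)
            for m, v in _utility_metrics(plan.dose.values, geo).items():
                records.append({"patient": i + 1, "calibration": cal_name,
                                "metric": m, "value": v})
    table = pd.DataFrame(records)
    wide = table.pivot_table(index=["patient", "metric"], columns="calibration",
                             values="value").reset_index()
    wide["delta"] = wide["Cal1"] - wide["Cal2"]
    means = wide.groupby("metric")[["Cal1", "Cal2", "delta"]].mean()
    return {"table": table, "per_patient": wide, "cohort_means": means,
            "cal1": cal1, "cal2": cal2, "dataset": dataset,
            "positions": {"Cal1": cal1_pos, "Cal2": cal2_pos}}


# --- end-to-end synthetic study ----------------------------------------------

@dataclasses.dataclass
class StudyConfig:
    """Synthetic evaluative study: calibrate, then compare against a
    deliberately mis-prioritised comparator protocol on a validation cohort."""

    n_calibration: int = 10
    n_validation: int = 20
    seed: int = 100
    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    spacing: Tuple[float, float, float] = (4.0, 4.0, 4.0)
    profile: str = "instA"
    beam_config: BeamConfig = dataclasses.field(
        default_factory=lambda: BeamConfig(n_beams=12))
    pbaio_config: PBAIOConfig = dataclasses.field(
        default_factory=lambda: PBAIOConfig(inner_iterations=20, outer_loops=3))
    rectum_wf_samples: Tuple[float, ...] = (2.92, 5.84, 11.68)
    navigated_rectum_wf: float = 8.76     # scripted stand-in for the operator
    comparator_rectum_wf_factor: float = 0.05
    comparator_falloff_wf_factor: float = 0.1
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        beam = BeamConfig(**raw.pop("beam_config", {}))
        pbaio = PBAIOConfig(**raw.pop("pbaio_config", {}))
        for key in ("grid_shape", "spacing", "rectum_wf_samples"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(beam_config=beam, pbaio_config=pbaio, **raw)


def _perturbed_comparator(protocol: AutoPlanProtocol, cfg: StudyConfig) -> AutoPlanProtocol:
    """Comparator arm: rectum trade-offs down-weighted, fall-off de-prioritised."""
    comp = protocol.clone()
    for g in comp.goals:
        if g.priority != "P3":
            continue
        if g.roi == "rectum":
            g.weighting_factor *= cfg.comparator_rectum_wf_factor
        if g.goal_type == "dose_falloff_external":
            g.weighting_factor *= cfg.comparator_falloff_wf_factor
    return comp


def run_study(config: StudyConfig, outdir: Union[str, Path, None] = None):
    """Full synthetic study: calibration via scripted navigation, validation
    under calibrated vs comparator protocols, Wilcoxon comparison table, goal
    pass rates and a reproducibility manifest.  Deterministic given config."""
    base = load_builtin_protocol(config.profile)

    # Calibration: 1-D rectum-Dmean-WF navigation on calibration patient 1.
    cal_geos = _cohort_geometries(config.n_calibration, config.seed,
                                  config.grid_shape, config.spacing, config.profile)
    dim = NavigationDimension("rectum", "mean_dose", "weighting_factor",
                              config.rectum_wf_samples)
    dataset = generate_dataset(cal_geos[0], base, [dim], config.beam_config,
                               config.pbaio_config)
    position = {dataset.labels[0]: config.navigated_rectum_wf}
    calibrated = commit_calibration(dataset, position, base)
    comparator = _perturbed_comparator(calibrated, config)

    # Validation cohort under both arms.
    val_seeds = [config.seed + 1000 + i for i in range(config.n_validation)]
    panel = default_metric_panel(config.profile)
    goal_table = load_builtin_goal_table(config.profile)
    records, pass_rates = [], {"calibrated": 0, "comparator": 0}
    n_goal_rows = 0
    for pi, seed in enumerate(val_seeds):
        geo = build_ptvs(generate_patient(seed, grid_shape=config.grid_shape,
                                          spacing=config.spacing,
                                          profile=config.profile))
        influence = build_influence_matrix(geo, config.beam_config)
        for arm, proto in (("calibrated", calibrated), ("comparator", comparator)):
            plan = autoplan(geo, proto, config.beam_config, config.pbaio_config,
                            influence=influence)
            for spec in panel:
                records.append({"patient": pi + 1, "arm": arm, "metric": spec.label,
                                "value": evaluate_metric(spec, plan.dose.values, geo)})
            rows = evaluate_goal_table(plan.dose.values, geo, goal_table)
            pass_rates[arm] += sum(r.passed for r in rows)
            if arm == "calibrated":
                n_goal_rows += len(rows)
    cohort = CohortResult(pd.DataFrame(records), ("calibrated", "comparator"),
                          val_seeds)
    rows = compare_cohorts(cohort)
    frame = comparison_to_frame(rows, cohort.arms)
    pass_frac = {arm: cnt / max(n_goal_rows, 1) for arm, cnt in pass_rates.items()}
    manifest = {
        "seed": config.seed,
        "validation_seeds": val_seeds,
        "grid_shape": list(config.grid_shape),
        "spacing": list(config.spacing),
        "profile": config.profile,
        "beam_config": dataclasses.asdict(config.beam_config),
        "pbaio_config": dataclasses.asdict(config.pbaio_config),
        "navigated_rectum_wf": config.navigated_rectum_wf,
        "goal_pass_fraction": pass_frac,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.table.to_csv(outdir / "cohort_metrics.csv", index=False)
        frame.to_csv(outdir / "comparison_table.csv", index=False)
        (outdir / "comparison_table.txt").write_text(
            format_comparison(rows, cohort.arms) + "\n")
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
        if config.make_plots:
            _one_to_one_plots(cohort, outdir)

    return {"cohort": cohort, "comparison": rows, "comparison_frame": frame,
            "goal_pass_fraction": pass_frac, "manifest": manifest,
            "calibrated": calibrated, "comparator": comparator}


def _one_to_one_plots(cohort: CohortResult, outdir: Path,
                      metrics_to_plot: Sequence[str] = ("rectum Dmean",
                                                        "PTV60 HI", "PTV48 CI@45.6Gy")):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    present = [m for m in metrics_to_plot
               if (cohort.table["metric"] == m).any()]
    if not present:
        return
    fig, axes = plt.subplots(1, len(present), figsize=(4 * len(present), 4))
    axes = np.atleast_1d(axes)
    a, b = cohort.arms
    for ax, m in zip(axes, present):
        va, vb = cohort.arm_values(m, a), cohort.arm_values(m, b)
        ax.scatter(vb, va, s=18)
        lims = [min(va.min(), vb.min()), max(va.max(), vb.max())]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel(f"{m} ({b})")
        ax.set_ylabel(f"{m} ({a})")
    fig.tight_layout()
    fig.savefig(outdir / "one_to_one.png", dpi=110)
    plt.close(fig)
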