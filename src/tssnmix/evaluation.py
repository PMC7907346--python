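"""Estimator evaluation over a factorial grid of simulation scenarios.

This layer reproduces a simulation-study design for TSS N-mixture models:
a Cartesian grid over population trend, initial abundance, study duration,
survey effort and detection probability (the canonical value sets give
3 x 3 x 2 x 2 x 4 = 144 scenarios); per-dataset relative errors of the
abundance and trend estimates; CI coverage accounting; the coefficient of
variation of the true yearly abundances ("abundance heterogeneity"); and
cross-scenario summaries (covered/uncovered Mann-Whitney split, Spearman
correlation of heterogeneity with absolute abundance error).

Error conventions: N-error = (N_hat - N) / N with N the scenario's initial
abundance; T-error = (T_hat - T) / T, except for constant-population
scenarios (T = 0) where the raw distance T_hat - T is used. A positive
error means overestimation; N-error = 0.2 reads "abundance overestimated
by 20%".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.stats import mannwhitneyu, spearmanr

from .gof import bootstrap_gof
from .nmix import TSSNMixture, TssFit
from .simulator import CountDataset, ScenarioSpec, simulate_dataset

__all__ = [
    "PAPER_GRID_VALUES",
    "build_grid",
    "canonical_grid",
    "compute_errors",
    "compute_heterogeneity",
    "run_evaluation",
    "summarize_records",
    "summarize_coverage_split",
    "heterogeneity_error_correlation",
    "headline_report",
]

# canonical factorial design value sets
PAPER_GRID_VALUES = {
    "trend": (-0.1, 0.0, 0.1),
    "initial_abundance": (5, 20, 100),
    "n_years": (10, 20),
    "n_surveys": (3, 5),
    "detection_prob": (0.1, 0.3, 0.5, 0.7),
}

RECORD_COLUMNS = [
    "scenario_id", "rep_index", "trend_coeff", "initial_abundance", "n_years",
    "n_surveys", "detection_prob", "seed", "converged", "reason",
    "n_hat", "t_hat", "p_hat", "n_error", "t_error",
    "n_covered", "t_covered", "n_heterogeneity", "gof_p", "c_hat",
]


def build_grid(trend=PAPER_GRID_VALUES["trend"],
               initial_abundance=PAPER_GRID_VALUES["initial_abundance"],
               n_years=PAPER_GRID_VALUES["n_years"],
               n_surveys=PAPER_GRID_VALUES["n_surveys"],
               detection_prob=PAPER_GRID_VALUES["detection_prob"],
               n_reps: int = 100, base_seed: int = 0) -> list[ScenarioSpec]:
    """Cartesian scenario grid in a fixed documented order.

    The product iterates trend outermost, then initial abundance, years,
    surveys, and detection probability innermost; ``scenario_id`` is the
    position in that order, so a given configuration always maps to the
    same id.
    """
    for name, vals in [("trend", trend), ("initial_abundance", initial_abundance),
                       ("n_years", n_years), ("n_surveys", n_surveys),
                       ("detection_prob", detection_prob)]:
        if len(tuple(vals)) == 0:
            raise ValueError(f"value set '{name}' is empty")
    grid = []
    combos = itertools.product(trend, initial_abundance, n_years, n_surveys,
                               detection_prob)
    for sid, (t, n0, ny, ns, p) in enumerate(combos):
        grid.append(ScenarioSpec(
            trend_coeff=float(t), initial_abundance=int(n0), n_years=int(ny),
            n_surveys=int(ns), detection_prob=float(p), n_reps=int(n_reps),
            base_seed=int(base_seed), scenario_id=sid))
    return grid


def canonical_grid(n_reps: int = 100, base_seed: int = 0) -> list[ScenarioSpec]:
    """The full 144-scenario design."""
    return build_grid(n_reps=n_reps, base_seed=base_seed)


def compute_heterogeneity(true_N) -> float:
    """Coefficient of variation of the true yearly abundances (sample sd, n-1)."""
    arr = np.asarray(true_N, dtype=float)
    m = arr.mean()
    if m <= 0:
        raise ValueError("heterogeneity undefined for all-zero abundances")
    return float(arr.std(ddof=1) / m)


def compute_errors(fit: TssFit, truth: CountDataset) -> dict:
    """Per-dataset error and coverage record for one fitted dataset."""
    sc = truth.scenario
    rec = {
        "scenario_id": sc.scenario_id,
        "rep_index": truth.rep_index,
        "trend_coeff": sc.trend_coeff,
        "initial_abundance": sc.initial_abundance,
        "n_years": sc.n_years,
        "n_surveys": sc.n_surveys,
        "detection_prob": sc.detection_prob,
        "seed": truth.seed,
        "converged": bool(fit.converged),
        "reason": fit.reason,
        "n_hat": math.nan, "t_hat": math.nan, "p_hat": math.nan,
        "n_error": math.nan, "t_error": math.nan,
        "n_covered": math.nan, "t_covered": math.nan,
        "n_heterogeneity": compute_heterogeneity(truth.true_N)
        if truth.true_N.mean() > 0 else math.nan,
        "gof_p": math.nan, "c_hat": math.nan,
    }
    if not fit.converged:
        return rec
    N, T = sc.initial_abundance, sc.trend_coeff
    rec["n_hat"], rec["t_hat"], rec["p_hat"] = fit.n_hat, fit.t_hat, fit.p_hat
    rec["n_error"] = (fit.n_hat - N) / N
    rec["t_error"] = (fit.t_hat - T) / T if T != 0 else fit.t_hat - T
    rec["n_covered"] = float(fit.n_hat_ci[0] <= N <= fit.n_hat_ci[1])
    rec["t_covered"] = float(fit.t_hat_ci[0] <= T <= fit.t_hat_ci[1])
    return rec


def _run_scenario(scenario: ScenarioSpec, with_gof: bool, n_boot: int) -> list[dict]:
    est = TSSNMixture()
    out = []
    for r in range(scenario.n_reps):
        ds = simulate_dataset(scenario, r)
        fit = est.fit(ds.counts).result_
        rec = compute_errors(fit, ds)
        if with_gof and fit.converged:
            gof = bootstrap_gof(ds.counts, fit, n_boot=n_boot,
                                seed=(ds.seed + 1) % (2 ** 32))
            rec["gof_p"], rec["c_hat"] = gof.p_value, gof.c_hat
        out.append(rec)
    return out


def run_evaluation(grid: list[ScenarioSpec], with_gof: bool = False,
                   n_boot: int = 200, n_jobs: int = 1,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate, fit and score every scenario x replicate of a grid.

    Returns the per-dataset record table and the per-scenario summary table.
    Per-dataset seeds are fixed by the grid itself, so the result is
    independent of ``n_jobs`` and identical across runs.
    """
    if n_jobs == 1:
        chunks = [_run_scenario(sc, with_gof, n_boot) for sc in grid]
    else:
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_run_scenario)(sc, with_gof, n_boot) for sc in grid)
    records = pd.DataFrame([rec for ch in chunks for rec in ch],
                           columns=RECORD_COLUMNS)
    return records, summarize_records(records)


def summarize_records(records: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario aggregates over converged fits, with exclusion counts."""
    rows = []
    for sid, g in records.groupby("scenario_id", sort=True):
        ok = g[g["converged"]]
        rows.append({
            "scenario_id": sid,
            "trend_coeff": g["trend_coeff"].iloc[0],
            "initial_abundance": g["initial_abundance"].iloc[0],
            "n_years": g["n_years"].iloc[0],
            "n_surveys": g["n_surveys"].iloc[0],
            "detection_prob": g["detection_prob"].iloc[0],
            "n_error_mean": ok["n_error"].mean(),
            "n_error_sd": ok["n_error"].std(ddof=1),
            "t_error_mean": ok["t_error"].mean(),
            "t_error_sd": ok["t_error"].std(ddof=1),
            "n_coverage_rate": ok["n_covered"].mean(),
            "t_coverage_rate": ok["t_covered"].mean(),
            "n_reps_used": len(ok),
            "n_failed": len(g) - len(ok),
        })
    return pd.DataFrame(rows)


@dataclass
class CoverageSplit:
    """Datasets pooled by whether their scenario's abundance CI coverage
    reaches the threshold, with a two-sided Mann-Whitney comparison."""

    threshold: float
    n_scenarios_covered: int
    n_scenarios_uncovered: int
    covered_n_error_mean: float
    covered_n_error_sd: float
    uncovered_n_error_mean: float
    uncovered_n_error_sd: float
    covered_t_error_mean: float
    covered_t_error_sd: float
    uncovered_t_error_mean: float
    uncovered_t_error_sd: float
    mannwhitney_u: float | None
    p_value: float | None
    degenerate: bool


def summarize_coverage_split(records: pd.DataFrame,
                             threshold: float = 0.95) -> CoverageSplit:
    """Split datasets by scenario-level abundance-CI coverage and compare errors.

    A scenario is "covered" when the proportion of its converged datasets
    whose 95% CI contains the true initial abundance is at least the
    threshold. Per-dataset N-errors are pooled within each group and the
    groups compared with a two-sided Mann-Whitney test (normal
    approximation with tie correction). If one group is empty the result is
    flagged ``degenerate`` and the test is not performed.
    """
    if records["scenario_id"].nunique() < 2:
        raise ValueError("need records from at least 2 scenarios")
    ok = records[records["converged"]]
    cov = ok.groupby("scenario_id")["n_covered"].mean()
    covered_ids = set(cov[cov >= threshold].index)
    uncovered_ids = set(cov[cov < threshold].index)
    cg = ok[ok["scenario_id"].isin(covered_ids)]
    ug = ok[ok["scenario_id"].isin(uncovered_ids)]

    def _stats(g):
        return (g["n_error"].mean(), g["n_error"].std(ddof=1),
                g["t_error"].mean(), g["t_error"].std(ddof=1))

    degenerate = len(cg) == 0 or len(ug) == 0
    if degenerate:
        u = p = None
    else:
        u, p = mannwhitneyu(cg["n_error"], ug["n_error"],
                            alternative="two-sided", method="asymptotic")
        u, p = float(u), float(p)
    c_stats = _stats(cg) if len(cg) else (math.nan,) * 4
    u_stats = _stats(ug) if len(ug) else (math.nan,) * 4
    return CoverageSplit(
        threshold=threshold,
        n_scenarios_covered=len(covered_ids),
        n_scenarios_uncovered=len(uncovered_ids),
        covered_n_error_mean=c_stats[0], covered_n_error_sd=c_stats[1],
        covered_t_error_mean=c_stats[2], covered_t_error_sd=c_stats[3],
        uncovered_n_error_mean=u_stats[0], uncovered_n_error_sd=u_stats[1],
        uncovered_t_error_mean=u_stats[2], uncovered_t_error_sd=u_stats[3],
        mannwhitney_u=u, p_value=p, degenerate=degenerate)


def heterogeneity_error_correlation(records: pd.DataFrame
                                    ) -> tuple[float, float]:
    """Spearman correlation of abundance heterogeneity with |N-error|.

    Computed over converged datasets from constant-trend scenarios. Returns
    ``(nan, nan)`` when the ranks are degenerate (all heterogeneity values
    identical).
    """
    sub = records[(records["trend_coeff"] == 0.0) & records["converged"]]
    if len(sub) < 3:
        raise ValueError("need at least 3 converged constant-trend records")
    x = sub["n_heterogeneity"].to_numpy()
    y = np.abs(sub["n_error"].to_numpy())
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (math.nan, math.nan)
    rho, p = spearmanr(x, y)
    return float(rho), float(p)


def headline_report(records: pd.DataFrame, summaries: pd.DataFrame) -> dict:
    """Bundle the study's headline statistics into one JSON-serialisable dict."""
    ok = records[records["converged"]]
    const = records[records["trend_coeff"] == 0.0]
    report = {
        "n_datasets": int(len(records)),
        "n_converged": int(len(ok)),
        "pooled_n_error_mean": float(ok["n_error"].mean()),
        "pooled_n_error_sd": float(ok["n_error"].std(ddof=1)),
        "pooled_abs_t_error_mean": float(ok["t_error"].abs().mean()),
        "constant_trend_mean_heterogeneity":
            float(const["n_heterogeneity"].mean()) if len(const) else None,
        "constant_trend_sd_heterogeneity":
            float(const["n_heterogeneity"].std(ddof=1)) if len(const) else None,
    }
    if records["scenario_id"].nunique() >= 2:
        split = summarize_coverage_split(records)
        report["coverage_split"] = {
            "covered_n_error_mean": split.covered_n_error_mean,
            "covered_n_error_sd": split.covered_n_error_sd,
            "uncovered_n_error_mean": split.uncovered_n_error_mean,
            "uncovered_n_error_sd": split.uncovered_n_error_sd,
            "n_scenarios_covered": split.n_scenarios_covered,
            "n_scenarios_uncovered": split.n_scenarios_uncovered,
            "mannwhitney_p": split.p_value,
        }
    n_const_ok = int(const["converged"].sum()) if len(const) else 0
    if n_const_ok >= 3:
        rho, p = heterogeneity_error_correlation(records)
        report["heterogeneity_error_spearman"] = {"rho": rho, "p": p}
    return report
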