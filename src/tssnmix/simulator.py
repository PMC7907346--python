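"""Synthetic repeated-count data for a single population surveyed within years.

The generator follows the standard time-for-space-substitution (TSS) design:
years stand in for the "sites" of a classical N-mixture sampling design, and
the J surveys within a year are the closed-population temporal replicates.

Latent yearly abundance is Poisson with a log-linear trend,

    N_i ~ Poisson(lambda_i),   log(lambda_i) = beta0 + beta1 * t_i,

with the year covariate coded t_i = i - 1 so that ``exp(beta0)`` is the
abundance expected in the first year (the scenario's "initial abundance").
Counts are binomial thinnings of the latent state with a constant
per-individual detection probability p = logistic(alpha0):

    C_ij | N_i ~ Binomial(N_i, p).

Every dataset is reproducible in isolation: its seed is derived from
``(base_seed, scenario_id, rep_index)`` through a splittable
:class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioSpec",
    "CountDataset",
    "simulate_dataset",
    "simulate_from_fit",
    "dataset_seed",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of a simulation design.

    Parameters
    ----------
    trend_coeff : float
        Log-linear slope of abundance over years (true T).
    initial_abundance : int
        Expected abundance in year 1 (true N); ``beta0 = log(initial_abundance)``.
    n_years : int
        Number of years (replicate units under TSS).
    n_surveys : int
        Surveys per year (within-year replicates).
    detection_prob : float
        Per-individual detection probability p, strictly in (0, 1).
    n_reps : int
        Number of datasets to simulate for this scenario.
    base_seed : int
        Root seed of the study; combined with ``scenario_id`` and the
        replicate index to seed each dataset.
    scenario_id : int
        Position of this cell in its grid (0 for a standalone scenario).
    """

    trend_coeff: float
    initial_abundance: int
    n_years: int
    n_surveys: int
    detection_prob: float
    n_reps: int = 1
    base_seed: int = 0
    scenario_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_prob < 1.0:
            raise ValueError(
                f"detection_prob must be in (0, 1), got {self.detection_prob}"
            )
        if self.initial_abundance < 1:
            raise ValueError(
                f"initial_abundance must be >= 1, got {self.initial_abundance}"
            )
        if self.n_years < 2:
            raise ValueError(f"n_years must be >= 2, got {self.n_years}")
        if self.n_surveys < 2:
            raise ValueError(f"n_surveys must be >= 2, got {self.n_surveys}")
        if self.n_reps < 1:
            raise ValueError(f"n_reps must be >= 1, got {self.n_reps}")

    @property
    def beta0(self) -> float:
        return math.log(self.initial_abundance)

    @property
    def alpha0(self) -> float:
        p = self.detection_prob
        return math.log(p / (1.0 - p))

    def lambdas(self) -> np.ndarray:
        """Expected abundance per year, lambda_i = exp(beta0 + beta1*(i-1))."""
        t = np.arange(self.n_years, dtype=float)
        return np.exp(self.beta0 + self.trend_coeff * t)


@dataclass
class CountDataset:
    """A simulated dataset: observed counts plus the latent truth."""

    counts: np.ndarray  # (n_years, n_surveys) non-negative ints
    true_N: np.ndarray  # (n_years,) latent abundances
    scenario: ScenarioSpec | None
    rep_index: int
    seed: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.true_N = np.asarray(self.true_N, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-d matrix (years x surveys)")
        if self.true_N.shape != (self.counts.shape[0],):
            raise ValueError("true_N length must equal the number of years")
        if (self.counts < 0).any() or (self.true_N < 0).any():
            raise ValueError("counts and true_N must be non-negative")
        if (self.counts > self.true_N[:, None]).any():
            raise ValueError("a count exceeds its year's latent abundance")

    @property
    def n_years(self) -> int:
        return self.counts.shape[0]

    @property
    def n_surveys(self) -> int:
        return self.counts.shape[1]

    # ---- persistence -----------------------------------------------------
    def counts_frame(self) -> pd.DataFrame:
        cols = [f"survey_{j + 1}" for j in range(self.n_surveys)]
        return pd.DataFrame(self.counts, columns=cols)

    def write_csv(self, path: str | Path) -> None:
        self.counts_frame().to_csv(path, index=False)

    def write_truth_json(self, path: str | Path) -> None:
        truth = {
            "true_N": self.true_N.tolist(),
            "rep_index": self.rep_index,
            "seed": self.seed,
        }
        if self.scenario is not None:
            truth["scenario"] = asdict(self.scenario)
        Path(path).write_text(json.dumps(truth, indent=1))


def read_counts_csv(path: str | Path) -> np.ndarray:
    """Read a years x surveys count matrix written by :meth:`CountDataset.write_csv`."""
    df = pd.read_csv(path)
    arr = df.to_numpy()
    if arr.size == 0:
        raise ValueError(f"{path}: empty count matrix")
    if not np.issubdtype(arr.dtype, np.integer):
        flo = arr.astype(float)
        if not np.all(np.isfinite(flo)) or not np.all(flo == np.round(flo)):
            raise ValueError(f"{path}: count matrix must contain integers only")
        arr = flo.astype(np.int64)
    if (arr < 0).any():
        raise ValueError(f"{path}: negative counts present")
    return arr.astype(np.int64)


def dataset_seed(base_seed: int, scenario_id: int, rep_index: int) -> int:
    """Deterministic 32-bit seed for a single dataset.

    Built from a SeedSequence keyed on the triplet, so any dataset can be
    regenerated in isolation without replaying the rest of the study.
    """
    ss = np.random.SeedSequence([int(base_seed), int(scenario_id), int(rep_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def simulate_dataset(scenario: ScenarioSpec, rep_index: int) -> CountDataset:
    """Draw one dataset under a scenario's true dynamics.

    Deterministic given ``(scenario.base_seed, scenario.scenario_id, rep_index)``.
    """
    if not 0 <= rep_index < scenario.n_reps:
        raise ValueError(
            f"rep_index {rep_index} outside [0, n_reps={scenario.n_reps})"
        )
    seed = dataset_seed(scenario.base_seed, scenario.scenario_id, rep_index)
    rng = np.random.default_rng(seed)
    lam = scenario.lambdas()
    true_N = rng.poisson(lam)
    counts = rng.binomial(
        true_N[:, None], scenario.detection_prob,
        size=(scenario.n_years, scenario.n_surveys),
    )
    return CountDataset(counts=counts, true_N=true_N, scenario=scenario,
                        rep_index=rep_index, seed=seed)


def simulate_from_fit(fit, n_years: int, n_surveys: int, seed: int) -> CountDataset:
    """Parametric-bootstrap draw from a fitted model.

    Generates a dataset under the fitted (beta0, beta1, alpha0) with the same
    ``t_i = i - 1`` year coding used in fitting; ``true_N`` carries the
    bootstrap latent abundances.
    """
    if not getattr(fit, "converged", False):
        raise ValueError("cannot simulate from a non-converged fit")
    rng = np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)
    lam = np.exp(fit.beta0_hat + fit.beta1_hat * t)
    p = 1.0 / (1.0 + math.exp(-fit.alpha0_hat))
    true_N = rng.poisson(lam)
    counts = rng.binomial(true_N[:, None], p, size=(n_years, n_surveys))
    return CountDataset(counts=counts, true_N=true_N, scenario=None,
                        rep_index=-1, seed=int(seed))
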