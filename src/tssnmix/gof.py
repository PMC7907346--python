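"""Parametric-bootstrap goodness-of-fit testing for fitted TSS N-mixture models.

The observed fit statistic is the Pearson chi-square over all year x survey
cells, with fitted cell expectation E_ij = lambda_hat_i * p_hat (the marginal
mean of a count under the model). Its null distribution is built by the
standard parametric bootstrap: simulate datasets from the fitted model, refit
each, and evaluate the statistic under the replicate's own refit. The
overdispersion ratio c-hat is the observed statistic divided by the mean of
the bootstrap distribution; values near 1 indicate an adequate model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nmix import TSSNMixture, TssFit, _validate_counts
from .simulator import simulate_from_fit

__all__ = ["GofResult", "pearson_chi2", "bootstrap_gof", "classify_fit"]


@dataclass
class GofResult:
    """Outcome of a parametric-bootstrap Pearson chi-square test."""

    chi2_obs: float
    chi2_boot: np.ndarray
    p_value: float
    c_hat: float
    n_boot: int
    n_boot_failed: int

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["chi2_boot"] = list(np.asarray(self.chi2_boot, dtype=float))
        s = json.dumps(d, indent=1, default=float)
        if path is not None:
            Path(path).write_text(s)
        return s


def _expected_cells(fit: TssFit, n_years: int, n_surveys: int) -> np.ndarray:
    t = np.arange(n_years, dtype=float)
    lam = np.exp(fit.beta0_hat + fit.beta1_hat * t)
    return np.repeat((lam * fit.p_hat)[:, None], n_surveys, axis=1)


def pearson_chi2(counts, fit: TssFit) -> float:
    """Pearson chi-square of a count matrix against its fitted expectations."""
    if not fit.converged:
        raise ValueError(f"fit did not converge (reason: {fit.reason})")
    arr = _validate_counts(counts)
    E = _expected_cells(fit, arr.shape[0], arr.shape[1])
    if np.any(E == 0):
        raise ValueError("zero fitted expectation; chi-square undefined")
    return float(((arr - E) ** 2 / E).sum())


def bootstrap_gof(counts, fit: TssFit, n_boot: int = 200,
                  seed: int = 0) -> GofResult:
    """Parametric-bootstrap GOF test.

    For each replicate: simulate from the fitted model, refit, and evaluate
    the Pearson statistic under the replicate's own refit. Replicates whose
    refit does not converge are dropped and counted in ``n_boot_failed``.
    The p-value is the proportion of retained bootstrap statistics at least
    as large as the observed one.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    arr = _validate_counts(counts)
    chi2_obs = pearson_chi2(arr, fit)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_boot,
                                                              dtype=np.uint32)
    boot = []
    n_failed = 0
    est = TSSNMixture()
    for b in range(n_boot):
        ds = simulate_from_fit(fit, fit.n_years, fit.n_surveys,
                               int(child_seeds[b]))
        if ds.counts.max() == 0:
            n_failed += 1
            continue
        bfit = est.fit(ds.counts).result_
        if not bfit.converged:
            n_failed += 1
            continue
        boot.append(pearson_chi2(ds.counts, bfit))
    if not boot:
        raise RuntimeError("every bootstrap refit failed to converge")
    boot_arr = np.asarray(boot)
    p_value = float((boot_arr >= chi2_obs).sum() / boot_arr.size)
    c_hat = float(chi2_obs / boot_arr.mean())
    return GofResult(chi2_obs=chi2_obs, chi2_boot=boot_arr, p_value=p_value,
                     c_hat=c_hat, n_boot=n_boot, n_boot_failed=n_failed)


def classify_fit(gof: GofResult) -> str:
    """'good' when the bootstrap p-value exceeds 0.1 (strictly), else 'poor'."""
    return "good" if gof.p_value > 0.1 else "poor"
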