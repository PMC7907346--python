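"""Maximum-likelihood fitting of the TSS binomial N-mixture model.

The model for a years x surveys count matrix C is

    N_i ~ Poisson(lambda_i),        log(lambda_i) = beta0 + beta1 * t_i
    C_ij | N_i ~ Binomial(N_i, p),  logit(p) = alpha0

with t_i = i - 1. The latent abundances are marginalised by a finite sum
over N = 0..K (the truncation bound K), giving the marginal log-likelihood

    l(beta0, beta1, alpha0) =
        sum_i log sum_{N >= max_j C_ij}^{K} Pois(N; lambda_i)
                                            prod_j Bin(C_ij; N, p).

Estimation is by quasi-Newton optimisation of l; standard errors come from
the inverse of a finite-difference Hessian at the optimum, and 95% intervals
are Wald intervals on the link scales, back-transformed (exp for abundance,
logistic for detection).

The public surface is the sklearn-style :class:`TSSNMixture` estimator plus
thin functional wrappers (:func:`fit_tss`, :func:`marginal_loglik`,
:func:`choose_K`, :func:`predict_abundance`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.special import gammaln, logsumexp, expit
from scipy.stats import norm

try:  # sklearn is optional at runtime; the estimator degrades gracefully
    from sklearn.base import BaseEstimator
except ImportError:  # pragma: no cover
    class BaseEstimator:  # type: ignore[no-redef]
        pass

__all__ = [
    "TssFit",
    "TSSNMixture",
    "marginal_loglik",
    "choose_K",
    "fit_tss",
    "predict_abundance",
]

# box bounds for (beta0, beta1, alpha0); estimates at a bound are flagged
# non-converged (the likelihood ridge of near-zero detection pushes there)
_BOUNDS = [(-10.0, 20.0), (-3.0, 3.0), (-15.0, 15.0)]
_BOUND_TOL = 1e-4


@dataclass
class TssFit:
    """A fitted TSS N-mixture model."""

    beta0_hat: float
    beta1_hat: float
    alpha0_hat: float
    vcov: np.ndarray | None
    loglik: float
    K: int
    converged: bool
    reason: str | None
    n_hat: float
    p_hat: float
    t_hat: float
    n_hat_ci: tuple[float, float]
    t_hat_ci: tuple[float, float]
    p_hat_ci: tuple[float, float]
    n_years: int
    n_surveys: int

    def to_json(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        d["vcov"] = None if self.vcov is None else list(np.ravel(self.vcov))
        for k in ("n_hat_ci", "t_hat_ci", "p_hat_ci"):
            d[k] = list(d[k])
        s = json.dumps(d, indent=1, default=float)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "TssFit":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        if d.get("vcov") is not None:
            d["vcov"] = np.asarray(d["vcov"], dtype=float).reshape(3, 3)
        for k in ("n_hat_ci", "t_hat_ci", "p_hat_ci"):
            d[k] = tuple(d[k])
        return cls(**d)


def choose_K(counts) -> int:
    """Automatic truncation bound for the latent-abundance sum: max(counts) + 100.

    This is the field's conventional automatic rule and the default
    (``K="auto"``). Note that a bound tied to the observed maximum alone can
    clip the latent distribution when detection is low or abundance large
    (the fitted lambda may exceed it), which bounds how far abundance
    estimates can run but also biases them; ``K="adaptive"`` instead
    enlarges the bound until the fitted Poisson tail above it is negligible.
    """
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("counts must be non-empty")
    return int(arr.max()) + 100


def _validate_counts(counts) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise ValueError("counts must be a 2-d years x surveys matrix")
    flo = arr.astype(float)
    if not np.all(np.isfinite(flo)) or not np.all(flo == np.round(flo)):
        raise ValueError("counts must be integers")
    arr = flo.astype(np.int64)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return arr


class _Likelihood:
    """Precomputed workspace for repeated likelihood evaluations on one matrix.

    Everything that depends only on (counts, K) — factorial tables, the
    per-year lower bound of the latent sum, the binomial coefficient pieces —
    is computed once; each evaluation is then O(n_years * K) table lookups.
    """

    def __init__(self, counts: np.ndarray, K: int):
        if K < counts.max():
            raise ValueError(
                f"K={K} is below the largest observed count {counts.max()}"
            )
        self.counts = counts
        self.K = int(K)
        self.I, self.J = counts.shape
        self.n = np.arange(self.K + 1, dtype=np.int64)
        fact = gammaln(np.arange(self.K + 2, dtype=float) + 1.0)  # fact[m]=log m!
        self.t = np.arange(self.I, dtype=float)
        self.row_sum = counts.sum(axis=1).astype(float)  # sum_j C_ij
        self.row_max = counts.max(axis=1)
        # sum_j log C(n, C_ij) = J*fact[n] - sum_j fact[C_ij] - sum_j fact[n-C_ij]
        diff = self.n[None, None, :] - counts[:, :, None]  # (I, J, K+1)
        np.clip(diff, 0, None, out=diff)
        self.log_choose = (
            self.J * fact[self.n][None, :]
            - fact[counts].sum(axis=1)[:, None]
            - fact[diff].sum(axis=1)
        )  # (I, K+1)
        self.log_fact_n = fact[self.n]
        self.invalid = self.n[None, :] < self.row_max[:, None]

    def loglik(self, beta0: float, beta1: float, alpha0: float) -> float:
        eta = np.clip(beta0 + beta1 * self.t, -50.0, 50.0)
        lam = np.exp(eta)
        log_p = -np.logaddexp(0.0, -alpha0)    # log p
        log_q = -np.logaddexp(0.0, alpha0)     # log (1-p)
        # Poisson(N; lam_i) + sum_j Binomial(C_ij; N, p), on the log scale
        ll = (
            self.n[None, :] * eta[:, None]
            - lam[:, None]
            - self.log_fact_n[None, :]
            + self.log_choose
            + self.row_sum[:, None] * log_p
            + (self.J * self.n[None, :] - self.row_sum[:, None]) * log_q
        )
        ll[self.invalid] = -np.inf
        return float(logsumexp(ll, axis=1).sum())

    def loglik_grad(self, beta0: float, beta1: float, alpha0: float):
        """Log-likelihood and its gradient in (beta0, beta1, alpha0).

        The gradient uses the posterior expectation of the latent abundance:
        with w_iN the normalised within-year weights of the latent grid,
        d l / d beta0 = sum_i (E_w[N_i] - lambda_i), the beta1 component
        carries the extra factor t_i, and d l / d alpha0
        = sum_i (sum_j C_ij - J p E_w[N_i]).
        """
        eta = np.clip(beta0 + beta1 * self.t, -50.0, 50.0)
        lam = np.exp(eta)
        log_p = -np.logaddexp(0.0, -alpha0)
        log_q = -np.logaddexp(0.0, alpha0)
        p = np.exp(log_p)
        ll = (
            self.n[None, :] * eta[:, None]
            - lam[:, None]
            - self.log_fact_n[None, :]
            + self.log_choose
            + self.row_sum[:, None] * log_p
            + (self.J * self.n[None, :] - self.row_sum[:, None]) * log_q
        )
        ll[self.invalid] = -np.inf
        row_lse = logsumexp(ll, axis=1)
        if not np.all(np.isfinite(row_lse)):
            return float(row_lse.sum()), np.zeros(3)
        w = np.exp(ll - row_lse[:, None])
        e_n = (w * self.n[None, :]).sum(axis=1)  # E[N_i | C_i]
        g0 = float((e_n - lam).sum())
        g1 = float(((e_n - lam) * self.t).sum())
        ga = float((self.row_sum - self.J * p * e_n).sum())
        return float(row_lse.sum()), np.array([g0, g1, ga])


def marginal_loglik(counts, beta0: float, beta1: float, alpha0: float,
                    K: int) -> float:
    """Marginal log-likelihood of the TSS N-mixture model at given parameters.

    Raises if ``K`` is below the largest observed count (the likelihood is
    undefined when the truncation excludes the data).
    """
    arr = _validate_counts(counts)
    return _Likelihood(arr, K).loglik(beta0, beta1, alpha0)


def _numerical_hessian(grad, x: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Hessian from central differences of a gradient function at x."""
    k = x.size
    h = rel_step * (1.0 + np.abs(x))
    H = np.empty((k, k))
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        H[i] = (grad(x + ei) - grad(x - ei)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


def _start_values(counts: np.ndarray) -> np.ndarray:
    """Heuristic initial values on the link scales."""
    cmax = counts.max()
    p0 = float(np.clip(counts.mean() / max(cmax, 1), 0.05, 0.95))
    n0 = max(counts.max(axis=1).mean() / p0, 0.5)
    return np.array([math.log(n0), 0.0, math.log(p0 / (1.0 - p0))])


_Z95 = float(norm.ppf(0.975))


class TSSNMixture(BaseEstimator):
    """Binomial N-mixture model for a single population, years as replicates.

    Parameters
    ----------
    K : int, "auto" or "adaptive"
        Truncation bound of the latent-abundance sum. "auto" (default) uses
        the conventional automatic rule ``max(counts) + 100``; "adaptive"
        starts there and enlarges the bound until the fitted Poisson tail
        above it is negligible (use this when the estimates themselves, not
        the behaviour of the standard fixed rule, are of interest).
    n_restarts : int
        Jittered restarts attempted when the first optimisation fails.
    random_state : int
        Seed for the restart jitter (the fit itself is deterministic).

    Attributes (after ``fit``)
    --------------------------
    beta0_, beta1_, alpha0_ : link-scale ML estimates
    n_hat_, t_hat_, p_hat_ : derived initial abundance, trend and detection
    n_hat_ci_, t_hat_ci_, p_hat_ci_ : Wald 95% intervals
    vcov_ : 3x3 covariance of the link-scale estimates (None if unavailable)
    loglik_, K_, converged_, reason_ : fit metadata
    result_ : the full :class:`TssFit` record
    """

    def __init__(self, K: int | str = "auto", n_restarts: int = 5,
                 random_state: int = 0):
        self.K = K
        self.n_restarts = n_restarts
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        counts = _validate_counts(X)
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need at least 2 years and 2 surveys")
        if self.K == "auto":
            self.result_ = self._fit_mle(counts, choose_K(counts))
        elif self.K == "adaptive":
            self.result_ = self._fit_adaptive_K(counts)
        else:
            self.result_ = self._fit_mle(counts, int(self.K))
        r = self.result_
        self.beta0_, self.beta1_, self.alpha0_ = r.beta0_hat, r.beta1_hat, r.alpha0_hat
        self.n_hat_, self.t_hat_, self.p_hat_ = r.n_hat, r.t_hat, r.p_hat
        self.n_hat_ci_, self.t_hat_ci_, self.p_hat_ci_ = (
            r.n_hat_ci, r.t_hat_ci, r.p_hat_ci)
        self.vcov_, self.loglik_ = r.vcov, r.loglik
        self.K_, self.converged_, self.reason_ = r.K, r.converged, r.reason
        self.n_years_, self.n_surveys_ = r.n_years, r.n_surveys
        return self

    # the latent sum is truncated adequately when the fitted Poisson mass
    # above K is below this per-year tail bound (keeps the log-likelihood
    # truncation error under ~1e-8 and the estimates stable under doubling K)
    _TAIL_EPS = 1e-10
    # a converged fit demanding a bound beyond this is on the detection->0
    # ridge (lambda-hat far above any plausible abundance); flag it rather
    # than chase the ridge with ever larger latent grids
    _K_CAP = 5_000

    def _fit_adaptive_K(self, counts: np.ndarray) -> TssFit:
        """Fit with automatic truncation: start at max(counts)+100 and
        enlarge K until the fitted latent distribution has negligible mass
        above it."""
        from scipy.stats import poisson

        K = choose_K(counts)
        for _ in range(10):
            # refit from scratch at each K: warm-starting at the previous
            # optimum can stall the quasi-Newton line search on the flat
            # abundance/detection ridge before it reacts to the new bound
            fit = self._fit_mle(counts, K)
            if not fit.converged:
                return fit
            t_last = counts.shape[0] - 1
            eta_max = max(fit.beta0_hat, fit.beta0_hat + fit.beta1_hat * t_last)
            lam_max = math.exp(min(eta_max, 50.0))
            if poisson.sf(K, lam_max) < self._TAIL_EPS:
                return fit
            K = max(2 * K, int(lam_max + 12.0 * math.sqrt(lam_max) + 10))
            if K > self._K_CAP:
                fit.converged = False
                fit.reason = "K_overflow"
                return fit
        fit.converged = False
        fit.reason = "K_unstable"
        return fit

    def _fit_mle(self, counts: np.ndarray, K: int) -> TssFit:
        I, J = counts.shape
        nan_ci = (math.nan, math.nan)

        def failed(reason: str, x=None, ll=math.nan) -> TssFit:
            b0, b1, a0 = (x if x is not None else (math.nan,) * 3)
            return TssFit(
                beta0_hat=float(b0), beta1_hat=float(b1), alpha0_hat=float(a0),
                vcov=None, loglik=float(ll), K=K, converged=False,
                reason=reason, n_hat=math.nan, p_hat=math.nan, t_hat=float(b1),
                n_hat_ci=nan_ci, t_hat_ci=nan_ci, p_hat_ci=nan_ci,
                n_years=I, n_surveys=J)

        if counts.max() == 0:
            # p and lambda are jointly unidentifiable from all-zero data
            return failed("all_zero_counts")

        lik = _Likelihood(counts, K)

        def nll(x: np.ndarray):
            v, g = lik.loglik_grad(*x)
            if not np.isfinite(v):
                return 1e10, np.zeros(3)
            return -v, -g

        rng = np.random.default_rng(self.random_state)
        x0 = _start_values(counts)
        starts = [x0] + [
            x0 + rng.normal(0.0, [1.0, 0.2, 1.0]) for _ in range(self.n_restarts)
        ]
        starts = [np.clip(s, [b[0] for b in _BOUNDS], [b[1] for b in _BOUNDS])
                  for s in starts]

        def grad_only(x: np.ndarray) -> np.ndarray:
            return nll(x)[1]

        last_reason = "optimizer_failed"
        best = None
        for s in starts:
            res = optimize.minimize(nll, s, jac=True, method="L-BFGS-B",
                                    bounds=_BOUNDS)
            if not res.success or not np.isfinite(res.fun):
                last_reason = "optimizer_failed"
                continue
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            x = res.x
            at_bound = any(
                x[i] - lo < _BOUND_TOL or hi - x[i] < _BOUND_TOL
                for i, (lo, hi) in enumerate(_BOUNDS)
            )
            if at_bound:
                last_reason = "estimate_at_bound"
                continue
            H = _numerical_hessian(grad_only, x)
            if not np.all(np.isfinite(H)):
                last_reason = "hessian_not_finite"
                continue
            try:
                eig = np.linalg.eigvalsh(H)
            except np.linalg.LinAlgError:
                last_reason = "hessian_not_pd"
                continue
            if eig.min() <= 0:
                last_reason = "hessian_not_pd"
                continue
            vcov = np.linalg.inv(H)
            return self._build_fit(x, vcov, -res.fun, K, I, J)

        if best is not None:
            return failed(last_reason, x=best.x, ll=-best.fun)
        return failed(last_reason)

    @staticmethod
    def _build_fit(x: np.ndarray, vcov: np.ndarray, loglik: float,
                   K: int, I: int, J: int) -> TssFit:
        b0, b1, a0 = (float(v) for v in x)
        se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
        n_ci = (math.exp(b0 - _Z95 * se[0]), math.exp(b0 + _Z95 * se[0]))
        t_ci = (b1 - _Z95 * se[1], b1 + _Z95 * se[1])
        p_ci = (float(expit(a0 - _Z95 * se[2])), float(expit(a0 + _Z95 * se[2])))
        return TssFit(
            beta0_hat=b0, beta1_hat=b1, alpha0_hat=a0, vcov=vcov,
            loglik=float(loglik), K=K, converged=True, reason=None,
            n_hat=math.exp(b0), p_hat=float(expit(a0)), t_hat=b1,
            n_hat_ci=n_ci, t_hat_ci=t_ci, p_hat_ci=p_ci,
            n_years=I, n_surveys=J)

    # ------------------------------------------------------------------
    def predict(self, years=None):
        """Estimated abundance trajectory for the given years (1-based).

        Defaults to all years seen in ``fit``.
        """
        self._check_fitted()
        if years is None:
            years = np.arange(1, self.n_years_ + 1)
        years = np.atleast_1d(years)
        return np.exp(self.beta0_ + self.beta1_ * (years - 1.0))

    def predict_abundance(self, year: int):
        """Abundance estimate and Wald 95% CI for one year (1-based)."""
        self._check_fitted()
        if not 1 <= year <= self.n_years_:
            raise ValueError(f"year must be in [1, {self.n_years_}]")
        g = np.array([1.0, year - 1.0, 0.0])
        eta = self.beta0_ + self.beta1_ * (year - 1.0)
        var = float(g @ self.vcov_ @ g)
        half = _Z95 * math.sqrt(max(var, 0.0))
        return math.exp(eta), (math.exp(eta - half), math.exp(eta + half))

    def score(self, X, y=None) -> float:
        """Marginal log-likelihood of a count matrix under the fitted parameters."""
        self._check_fitted()
        return marginal_loglik(X, self.beta0_, self.beta1_, self.alpha0_,
                               max(self.K_, int(np.asarray(X).max()) + 100))

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise AttributeError("estimator is not fitted; call fit first")
        if not self.converged_:
            raise ValueError(f"fit did not converge (reason: {self.reason_})")


# ---------------------------------------------------------------------------
# functional wrappers


def fit_tss(counts, K: int | str = "auto", n_restarts: int = 5,
            random_state: int = 0) -> TssFit:
    """Fit the TSS N-mixture model to a count matrix; returns a :class:`TssFit`."""
    est = TSSNMixture(K=K, n_restarts=n_restarts, random_state=random_state)
    return est.fit(counts).result_


def predict_abundance(fit: TssFit, year: int):
    """Abundance estimate and Wald 95% CI at a given year for a fitted model."""
    if not fit.converged:
        raise ValueError(f"fit did not converge (reason: {fit.reason})")
    if not 1 <= year <= fit.n_years:
        raise ValueError(f"year must be in [1, {fit.n_years}]")
    eta = fit.beta0_hat + fit.beta1_hat * (year - 1.0)
    g = np.array([1.0, year - 1.0, 0.0])
    var = float(g @ fit.vcov @ g)
    half = _Z95 * math.sqrt(max(var, 0.0))
    return math.exp(eta), (math.exp(eta - half), math.exp(eta + half))
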