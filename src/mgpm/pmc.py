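"""Posterior simulation by Laplace-initialized Population Monte Carlo.

The sampler is a fixed two-stage adaptive importance-sampling pipeline:

1. find the posterior mode in the unbounded parameter space and build a
   Gaussian proposal from Laplace's approximation (inverse negative Hessian
   at the mode);
2. draw S particles from that proposal and weight them by
   posterior / proposal;
3. multinomially resample S particles by those weights;
4. rejuvenate: move each resampled particle by one draw from a local
   Gaussian kernel with shared diagonal covariance (1/S) * diag of the
   empirical coordinate variances of the resampled set, and reweight each
   new particle against its own kernel density.

The output is a weighted sample {theta_i, w_i} in the unbounded space
(back-transformable through the model's transform), with effective sample
size and a log-normalizing-constant estimate as by-products.  Exactly 2S
posterior evaluations are spent after the Laplace stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .likelihood import loglik_function
from .models import ModelSpec
from .priors import PriorSpec
from .treeio import TraitData

__all__ = [
    "LaplaceApprox",
    "WeightedSample",
    "laplace_approximation",
    "importance_stage",
    "multinomial_resample",
    "rejuvenate_and_reweight",
    "run_pmc",
    "pmc_sample",
]


@dataclass(frozen=True)
class LaplaceApprox:
    """Gaussian approximation to the posterior in unbounded coordinates."""

    mode: np.ndarray
    cov: np.ndarray
    spd_repaired: bool = False

    def __post_init__(self):
        object.__setattr__(self, "mode", np.asarray(self.mode, dtype=float))
        object.__setattr__(self, "cov", np.asarray(self.cov, dtype=float))

    @property
    def dim(self) -> int:
        return self.mode.size

    def _chol(self) -> np.ndarray:
        return np.linalg.cholesky(self.cov)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.mode + rng.standard_normal((size, self.dim)) @ self._chol().T

    def logpdf(self, z: np.ndarray) -> np.ndarray:
        L = self._chol()
        diff = np.atleast_2d(z) - self.mode
        y = np.linalg.solve(L, diff.T)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out = -0.5 * (self.dim * math.log(2 * math.pi) + logdet + (y * y).sum(axis=0))
        return out if np.ndim(z) > 1 else float(out[0])


@dataclass(frozen=True)
class WeightedSample:
    """S posterior draws with normalized importance weights.

    ``z`` holds the draws in unbounded coordinates; ``theta`` back-transforms
    them when the producing model spec is attached.
    """

    z: np.ndarray
    weights: np.ndarray
    log_norm: float
    spec: ModelSpec | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        z = np.atleast_2d(np.asarray(self.z, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "weights", w)
        if z.shape[0] != w.size:
            raise ValueError("one weight per draw required")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")

    @property
    def size(self) -> int:
        return self.weights.size

    @property
    def ess(self) -> float:
        """Effective sample size 1 / sum(w_i^2), in [1, S]."""
        return float(1.0 / np.sum(self.weights ** 2))

    @property
    def theta(self) -> np.ndarray:
        """Draws in the original parameter space (requires an attached spec)."""
        if self.spec is None:
            return self.z
        return self.spec.transform.from_unbounded(self.z)

    @property
    def param_names(self) -> tuple:
        if self.spec is None:
            return tuple(f"z{j}" for j in range(self.z.shape[1]))
        return self.spec.param_names


def _finite_difference_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of ``f`` at ``x``."""
    d = x.size
    h = rel_step * (1.0 + np.abs(x))
    hess = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / (h[i] ** 2)
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return hess


def laplace_approximation(
    log_posterior,
    starts: np.ndarray,
    rel_step: float = 1e-4,
    eig_floor: float = 1e-8,
) -> LaplaceApprox:
    """Gaussian posterior approximation at the mode.

    ``starts`` is an array of initial points (rows) for the quasi-Newton
    maximization; the best converged optimum is the mode.  The Hessian is
    computed by central finite differences with relative step ``rel_step``;
    if the negative Hessian is not positive definite, its eigenvalues are
    floored at ``eig_floor`` times the largest one and the repair is flagged.
    """
    starts = np.atleast_2d(np.asarray(starts, dtype=float))

    def neg(z):
        v = log_posterior(z)
        return -v if np.isfinite(v) else 1e12

    best = None
    for z0 in starts:
        res = optimize.minimize(
            neg, z0, method="L-BFGS-B",
            options={"ftol": 1e-14, "gtol": 1e-9, "maxiter": 500},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("no Laplace start converged")
    mode = best.x
    neg_hess = -_finite_difference_hessian(log_posterior, mode, rel_step)
    evals, evecs = np.linalg.eigh(neg_hess)
    repaired = bool(np.any(evals <= 0))
    floor = eig_floor * max(evals.max(), eig_floor)
    evals = np.maximum(evals, floor)
    cov = (evecs / evals) @ evecs.T
    cov = 0.5 * (cov + cov.T)
    return LaplaceApprox(mode, cov, spd_repaired=repaired)


def _normalize_log_weights(logw: np.ndarray):
    finite = np.isfinite(logw)
    if not finite.any():
        raise RuntimeError(
            "all importance weights are zero: the proposal misses the posterior; "
            "consider inflating the proposal covariance or revisiting the prior"
        )
    mx = logw[finite].max()
    w = np.where(finite, np.exp(logw - mx), 0.0)
    total = w.sum()
    log_norm = mx + math.log(total) - math.log(logw.size)
    return w / total, log_norm


def _batch_eval(f, z: np.ndarray, n_jobs: int = 1) -> np.ndarray:
    """Evaluate f at each row of z.  Evaluations are independent, so with
    ``n_jobs > 1`` they run on a joblib thread pool; the result is identical
    to the serial loop because every random draw precedes the evaluations."""
    if n_jobs == 1:
        return np.array([f(zi) for zi in z])
    from joblib import Parallel, delayed

    return np.array(Parallel(n_jobs=n_jobs, backend="threading")(delayed(f)(zi) for zi in z))


def importance_stage(
    log_posterior, proposal: LaplaceApprox, S: int, rng: np.random.Generator, n_jobs: int = 1
) -> WeightedSample:
    """One importance-sampling pass: S iid draws from the Gaussian proposal,
    weighted by posterior / proposal with log-sum-exp normalization.

    The evaluated log-posterior values are stashed in
    ``diagnostics["log_target"]`` so downstream stages can reuse them.
    """
    if S < 2:
        raise ValueError("S must be >= 2")
    z = proposal.sample(rng, S)
    logq = proposal.logpdf(z)
    logp = _batch_eval(log_posterior, z, n_jobs)
    w, log_norm = _normalize_log_weights(logp - logq)
    return WeightedSample(z, w, log_norm, diagnostics={"log_target": logp})


def multinomial_resample(weights: np.ndarray, S: int, rng: np.random.Generator) -> np.ndarray:
    """S iid categorical draws of particle indices by the given weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-8):
        raise ValueError("weights must lie on the simplex")
    return rng.choice(w.size, size=S, replace=True, p=w / w.sum())


def _mixture_log_density(z: np.ndarray, centers: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Log-density of each row of ``z`` under the equal-weight Gaussian-kernel
    mixture centred at ``centers`` with shared diagonal scale ``sd``."""
    uniq, counts = np.unique(centers, axis=0, return_counts=True)
    zs = z / sd
    cs = uniq / sd
    log_counts = np.log(counts / centers.shape[0])
    const = -0.5 * z.shape[1] * math.log(2 * math.pi) - np.log(sd).sum()
    out = np.empty(z.shape[0])
    cs_sq = (cs * cs).sum(axis=1)
    chunk = max(1, 2**22 // max(uniq.shape[0], 1))
    from scipy.special import logsumexp

    for lo in range(0, z.shape[0], chunk):
        zb = zs[lo:lo + chunk]
        sq = (zb * zb).sum(axis=1)[:, None] + cs_sq[None, :] - 2.0 * zb @ cs.T
        out[lo:lo + chunk] = logsumexp(log_counts[None, :] - 0.5 * sq, axis=1) + const
    return out


def rejuvenate_and_reweight(
    log_posterior,
    resampled: np.ndarray,
    rng: np.random.Generator,
    min_var: float = 1e-12,
    n_jobs: int = 1,
    method: str = "move",
    log_target_resampled: np.ndarray | None = None,
) -> WeightedSample:
    """Local-kernel rejuvenation of a multinomially resampled particle set.

    Every variant perturbs each particle with one draw from a Gaussian
    kernel centred on it with shared diagonal covariance (1/S) * diag of the
    empirical coordinate variances of the resampled set (floored at
    ``min_var`` against degenerate coordinates).  They differ in how the
    perturbed particles are weighted:

    ``"move"`` (default)
        Metropolis-corrected move: the perturbed particle is accepted with
        probability min(1, posterior ratio), otherwise the particle stays
        put; the output carries equal weights.  The kernel is symmetric, so
        this leaves the posterior invariant and only improves the resampled
        approximation (a resample-move step).  ``log_target_resampled`` can
        supply the already-known posterior values of the resampled set so
        the stage spends exactly S new posterior evaluations.
    ``"mixture"``
        Importance reweighting against the equal-weight mixture of all S
        kernels (the balance heuristic of adaptive importance sampling).
    ``"own"``
        Importance reweighting against the particle's own generating kernel
        only.  This variant's log-weights carry an additive +|Z|^2/2 term
        from the particle's own standardized jump, independent of the
        target, so its weight distribution has unbounded variance under the
        1/S-scaled kernel and its ESS plateaus at a small constant as S
        grows.  Kept for reference; see the methods note for the analysis.
    """
    if method not in ("move", "mixture", "own"):
        raise ValueError("method must be 'move', 'mixture' or 'own'")
    resampled = np.atleast_2d(np.asarray(resampled, dtype=float))
    S, d = resampled.shape
    var = resampled.var(axis=0, ddof=1) if S > 1 else np.zeros(d)
    sigma2 = np.maximum(var / S, min_var)
    sd = np.sqrt(sigma2)
    z = resampled + rng.standard_normal((S, d)) * sd
    if method == "move":
        logp_new = _batch_eval(log_posterior, z, n_jobs)
        if log_target_resampled is None:
            logp_old = _batch_eval(log_posterior, resampled, n_jobs)
        else:
            logp_old = np.asarray(log_target_resampled, dtype=float)
        accept = np.log(rng.uniform(size=S)) < logp_new - logp_old
        moved = np.where(accept[:, None], z, resampled)
        return WeightedSample(
            moved, np.full(S, 1.0 / S), 0.0,
            diagnostics={"acceptance_rate": float(accept.mean())},
        )
    if method == "mixture":
        logq = _mixture_log_density(z, resampled, sd)
    else:
        # diagonal Gaussian log-density of each particle under its own kernel
        logq = (
            -0.5 * d * math.log(2 * math.pi)
            - 0.5 * np.log(sigma2).sum()
            - 0.5 * (((z - resampled) / sd) ** 2).sum(axis=1)
        )
    logp = _batch_eval(log_posterior, z, n_jobs)
    w, log_norm = _normalize_log_weights(logp - logq)
    return WeightedSample(z, w, log_norm)


def run_pmc(
    log_posterior,
    starts: np.ndarray,
    S: int,
    seed: int,
    inflate: float = 1.0,
    n_jobs: int = 1,
    rejuvenation: str = "move",
) -> WeightedSample:
    """The full PMC pipeline on an arbitrary log-posterior over R^d.

    ``starts`` seeds the Laplace stage; ``inflate`` optionally scales the
    Laplace covariance (default 1, i.e. off); ``rejuvenation`` selects the
    final-stage variant (see :func:`rejuvenate_and_reweight`).  One pass
    spends exactly 2S posterior evaluations beyond the Laplace stage.
    Deterministic given ``seed``; per-stage RNG streams keep the draw
    sequence independent of how the posterior evaluations are executed, so
    ``n_jobs`` does not change the result.
    """
    rng_is, rng_rs, rng_rj = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(3)
    ]
    counter = _CountingTarget(log_posterior)
    lap = laplace_approximation(counter, starts)
    n_laplace = counter.count
    proposal = (
        lap if inflate == 1.0 else LaplaceApprox(lap.mode, inflate * lap.cov, lap.spd_repaired)
    )
    first = importance_stage(counter, proposal, S, rng_is, n_jobs=n_jobs)
    idx = multinomial_resample(first.weights, S, rng_rs)
    final = rejuvenate_and_reweight(
        counter, first.z[idx], rng_rj, n_jobs=n_jobs, method=rejuvenation,
        log_target_resampled=first.diagnostics["log_target"][idx],
    )
    log_norm = first.log_norm if rejuvenation == "move" else final.log_norm
    diagnostics = {
        "laplace_mode": lap.mode,
        "laplace_spd_repaired": lap.spd_repaired,
        "ess_stage1": first.ess,
        "ess": final.ess,
        "n_loglik_evals": counter.count,
        "n_laplace_evals": n_laplace,
        **final.diagnostics,
    }
    return WeightedSample(final.z, final.weights, log_norm, diagnostics=diagnostics)


class _CountingTarget:
    def __init__(self, f):
        self._f = f
        self.count = 0

    def __call__(self, z):
        self.count += 1
        return self._f(z)


def pmc_sample(
    spec: ModelSpec,
    prior: PriorSpec,
    x: TraitData | np.ndarray,
    S: int,
    seed: int,
    n_starts: int = 5,
    inflate: float = 1.0,
    n_jobs: int = 1,
    rejuvenation: str = "move",
) -> WeightedSample:
    """Simulate the posterior of a mixed Gaussian phylogenetic model.

    Composes the likelihood, the transformed prior, and the PMC pipeline;
    Laplace starts are drawn from the prior.  ``n_jobs > 1`` scores the two
    batched importance stages on a joblib thread pool; the result is
    identical to the serial run for a fixed seed.
    """
    ll = loglik_function(spec, x)
    tf = spec.transform

    def log_posterior(z):
        return ll(tf.from_unbounded(z)) + prior.log_prior(z)

    start_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]).generate_state(1)[0])
    starts = prior.sample_unbounded(start_rng, n_starts)
    sample = run_pmc(
        log_posterior, starts, S, seed,
        inflate=inflate, n_jobs=n_jobs, rejuvenation=rejuvenation,
    )
    return WeightedSample(
        sample.z, sample.weights, sample.log_norm, spec=spec, diagnostics=sample.diagnostics
    )
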