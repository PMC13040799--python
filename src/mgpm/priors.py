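"""Per-parameter priors, the joint transformed prior, and calibration recipes.

Parameters are a priori pairwise independent, so the joint prior is a
product of one-dimensional densities in the layout order of the model.
Evaluation happens in the unbounded space reached through the parameter
transform (log for alpha and sigma), with the change-of-variables Jacobian
included, so the transformed prior has full support on R^d.

The calibration helpers encode a biologically motivated recipe for OU
priors on an ultrametric tree of height t_H:

* a Normal prior on X0 and theta pinned down by two stated quantiles of the
  plausible trait range;
* a Half-Normal prior on alpha whose upper quantile corresponds to the
  fastest plausible adaptation, expressed through the phylogenetic
  half-life t_1/2 = ln(2) / alpha;
* a Half-Normal prior on sigma whose upper quantile matches the diffusion
  rate a BM process would need to reach a stated trait variance at the tips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import ModelSpec, Transform

__all__ = [
    "Normal",
    "HalfNormal",
    "PriorSpec",
    "normal_from_quantiles",
    "halfnormal_from_quantile",
    "alpha_prior_from_halflife",
    "sigma_prior_from_tip_variance",
    "diffuse_prior",
    "moderate_prior",
    "antler_prior",
    "preset_prior",
    "prior_from_table",
]


@dataclass(frozen=True)
class Normal:
    """Normal(mu, sd) prior on an unconstrained parameter."""

    mu: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    positive_only = False

    def logpdf(self, x):
        return stats.norm.logpdf(x, self.mu, self.sd)

    def rvs(self, rng, size=None):
        return rng.normal(self.mu, self.sd, size=size)

    @property
    def var(self) -> float:
        return self.sd ** 2


@dataclass(frozen=True)
class HalfNormal:
    """Half-Normal(scale) prior on a positive parameter."""

    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    positive_only = True

    def logpdf(self, x):
        return stats.halfnorm.logpdf(x, scale=self.scale)

    def rvs(self, rng, size=None):
        return np.abs(rng.normal(0.0, self.scale, size=size))

    def quantile(self, p: float) -> float:
        return float(stats.halfnorm.ppf(p, scale=self.scale))


@dataclass(frozen=True)
class PriorSpec:
    """Independent per-parameter priors aligned with a model's flat layout."""

    dists: tuple
    transform: Transform

    def __post_init__(self):
        if len(self.dists) != self.transform.dim:
            raise ValueError("one prior per parameter required")
        for dist, pos in zip(self.dists, self.transform.positive):
            if dist.positive_only and not pos:
                raise ValueError(
                    "Half-Normal prior only allowed on positive-constrained parameters"
                )
        object.__setattr__(self, "dists", tuple(self.dists))

    @property
    def dim(self) -> int:
        return self.transform.dim

    def log_prior_original(self, theta: np.ndarray) -> float:
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return float(sum(d.logpdf(t) for d, t in zip(self.dists, theta)))

    def log_prior(self, z: np.ndarray) -> float:
        """Joint log-density of the transformed prior at unbounded z."""
        theta = self.transform.from_unbounded(np.atleast_1d(np.asarray(z, dtype=float)))
        return self.log_prior_original(theta) + float(self.transform.log_jacobian(z))

    def sample_unbounded(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` vectors from the prior, returned in unbounded coordinates."""
        theta = np.column_stack([d.rvs(rng, size=size) for d in self.dists])
        return self.transform.to_unbounded(theta)


# ----- quantile-matching calibration -----

def normal_from_quantiles(q_lo: float, p_lo: float, q_hi: float, p_hi: float) -> Normal:
    """The unique Normal with value ``q_lo`` at probability ``p_lo`` and
    ``q_hi`` at ``p_hi``."""
    if not (0 < p_lo < p_hi < 1) or not q_lo < q_hi:
        raise ValueError("require p_lo < p_hi in (0,1) and q_lo < q_hi")
    z_lo, z_hi = stats.norm.ppf([p_lo, p_hi])
    sd = (q_hi - q_lo) / (z_hi - z_lo)
    mu = (q_lo * z_hi - q_hi * z_lo) / (z_hi - z_lo)
    return Normal(float(mu), float(sd))


def halfnormal_from_quantile(q: float, p: float) -> HalfNormal:
    """The Half-Normal whose ``p`` quantile equals ``q``.

    The Half-Normal CDF is 2*Phi(x/scale) - 1, so scale = q / Phi^{-1}((1+p)/2).
    """
    if not 0 < p < 1 or q <= 0:
        raise ValueError("require 0 < p < 1 and q > 0")
    return HalfNormal(float(q / stats.norm.ppf((1 + p) / 2)))


def alpha_prior_from_halflife(
    t_h: float, halflife_fraction: float = 0.01, p: float = 0.95
):
    """Half-Normal prior for the OU rate alpha from the shortest plausible half-life.

    The half-life t_1/2 = ln(2)/alpha is assumed to be no shorter than
    ``halflife_fraction * t_h``; the corresponding rate
    ``alpha* = ln(2) / (halflife_fraction * t_h)`` becomes the ``p`` quantile
    of the prior.  Returns ``(prior, alpha_star)``.
    """
    if t_h <= 0 or halflife_fraction <= 0:
        raise ValueError("t_h and halflife_fraction must be positive")
    alpha_star = math.log(2.0) / (halflife_fraction * t_h)
    return halfnormal_from_quantile(alpha_star, p), alpha_star


def sigma_prior_from_tip_variance(tip_var: float, t_h: float, p: float = 0.95):
    """Half-Normal prior for the diffusion sigma from a plausible tip variance.

    A BM process reaches variance sigma^2 t_H at the tips, so the diffusion
    consistent with ``tip_var`` is ``sigma* = sqrt(tip_var / t_h)``; that value
    becomes the ``p`` quantile of the prior.  Returns ``(prior, sigma_star)``.
    """
    if tip_var <= 0 or t_h <= 0:
        raise ValueError("tip_var and t_h must be positive")
    sigma_star = math.sqrt(tip_var / t_h)
    return halfnormal_from_quantile(sigma_star, p), sigma_star


# ----- presets -----

def _by_role(spec: ModelSpec, positive_dist, real_dist) -> PriorSpec:
    dists = [positive_dist if pos else real_dist for pos in spec.positive]
    return PriorSpec(tuple(dists), spec.transform)


def diffuse_prior(spec: ModelSpec) -> PriorSpec:
    """Half-N(10) on positive parameters, N(0, var 100) on unconstrained ones."""
    return _by_role(spec, HalfNormal(10.0), Normal(0.0, 10.0))


def moderate_prior(spec: ModelSpec) -> PriorSpec:
    """Half-N(5) on positive parameters, N(0, sd 5) on unconstrained ones."""
    return _by_role(spec, HalfNormal(5.0), Normal(0.0, 5.0))


def antler_prior(spec: ModelSpec) -> PriorSpec:
    """The log-posterior-skull-length calibration: every alpha ~ Half-N(2.5210),
    sigma ~ Half-N(0.2940), X0 and theta ~ N(1.9560, var 2.3295)."""
    normal = Normal(1.9560, math.sqrt(2.3295))
    dists = []
    for name in spec.param_names:
        if name.endswith(".alpha"):
            dists.append(HalfNormal(2.5210))
        elif name.endswith(".sigma"):
            dists.append(HalfNormal(0.2940))
        else:
            dists.append(normal)
    return PriorSpec(tuple(dists), spec.transform)


_PRESETS = {
    "diffuse": diffuse_prior,
    "moderate": moderate_prior,
    "antler": antler_prior,
}


def preset_prior(name: str, spec: ModelSpec) -> PriorSpec:
    """Named prior presets: ``diffuse``, ``moderate``, ``antler``."""
    try:
        return _PRESETS[name](spec)
    except KeyError:
        raise KeyError(f"unknown prior preset {name!r}; have {sorted(_PRESETS)}") from None


def prior_from_table(spec: ModelSpec, table) -> PriorSpec:
    """Priors from ``{parameter name: distribution}`` in any order."""
    missing = set(spec.param_names) - set(table)
    if missing:
        raise ValueError(f"missing priors for {sorted(missing)}")
    return PriorSpec(tuple(table[n] for n in spec.param_names), spec.transform)
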