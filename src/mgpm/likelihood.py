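"""Likelihood of tip data under a mixed Gaussian phylogenetic model.

`pruning_loglik` evaluates the log-density of the observed tip vector in
O(n) by passing log-quadratic Gaussian messages from the tips to the root
(Felsenstein-style pruning generalized to per-edge affine-Gaussian
transitions).  `dense_loglik_oracle` builds the full n-variate normal tip
distribution by a pre-order covariance recursion and evaluates it directly;
it is O(n^3) and exists to cross-check the pruning code.  `ml_fit` is a
multi-start bounded maximum-likelihood baseline in the unbounded
(log-transformed) parameter space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .models import ModelSpec, edge_coefficients
from .treeio import TraitData

__all__ = [
    "pruning_loglik",
    "loglik_function",
    "dense_loglik_oracle",
    "tip_moments",
    "MLFit",
    "ml_fit",
]

_LOG2PI = math.log(2.0 * math.pi)


def loglik_function(spec: ModelSpec, x: TraitData | np.ndarray):
    """Return a fast closure ``theta -> log p(x | theta)`` for repeated evaluation.

    The tree bookkeeping (post-order, children, tip values) is resolved once;
    each call only recomputes the per-edge transition coefficients and runs
    the message-passing loop.  Returns ``-inf`` for parameter vectors whose
    likelihood underflows or is otherwise non-finite.
    """
    tree = spec.tree
    xv = x.as_array(tree) if isinstance(x, TraitData) else np.asarray(x, dtype=float)
    if xv.shape != (tree.n_tips,):
        raise ValueError("one trait value per tip expected")
    tip_value = np.full(tree.n_nodes, np.nan)
    tip_value[list(tree.tips)] = xv
    tip_value = tip_value.tolist()
    is_tip = [False] * tree.n_nodes
    for t in tree.tips:
        is_tip[t] = True
    order = [int(v) for v in tree.postorder if v != tree.root]
    parent = tree.parent.tolist()
    n_nodes = tree.n_nodes
    for t in tree.tips:
        if tree.lengths[t] == 0.0:
            raise ValueError(
                "zero-length terminal edge: the tip datum would be deterministic "
                "and the likelihood atomic"
            )

    def loglik(theta: np.ndarray) -> float:
        av_, bv_, vv_ = edge_coefficients(spec, theta)
        a, b, v = av_.tolist(), bv_.tolist(), vv_.tolist()
        # per-node accumulated message coefficients in that node's own state
        p = [0.0] * n_nodes
        m = [0.0] * n_nodes
        c = [0.0] * n_nodes
        for node in order:
            av, bv, vv = a[node], b[node], v[node]
            if is_tip[node]:
                if vv <= 0.0:
                    # variance underflow at extreme parameters: signal an
                    # invalid parameter region rather than a structural error
                    return -math.inf
                xi = tip_value[node] - bv
                pn = -av * av / vv
                mn = av * xi / vv
                cn = -0.5 * (_LOG2PI + math.log(vv)) - 0.5 * xi * xi / vv
            else:
                pu, mu, cu = p[node], m[node], c[node]
                denom = 1.0 - pu * vv  # >= 1 since p <= 0, V >= 0
                p1 = pu / denom
                m1 = mu / denom
                c1 = cu + 0.5 * mu * mu * vv / denom - 0.5 * math.log(denom)
                pn = p1 * av * av
                mn = (p1 * bv + m1) * av
                cn = c1 + 0.5 * p1 * bv * bv + m1 * bv
            par = parent[node]
            p[par] += pn
            m[par] += mn
            c[par] += cn
        x0 = float(theta[0])
        out = 0.5 * p[0] * x0 * x0 + m[0] * x0 + c[0]
        return out if math.isfinite(out) else -math.inf

    return loglik


def pruning_loglik(spec: ModelSpec, theta: np.ndarray, x: TraitData | np.ndarray) -> float:
    """Log-likelihood of the tip data by O(n) pruning; conditions on X0 = theta[0]."""
    return loglik_function(spec, x)(spec.validate(theta))


def tip_moments(spec: ModelSpec, theta: np.ndarray):
    """Analytic mean vector and covariance matrix of the tips given theta.

    Pre-order recursion: for a child v of u over an edge with coefficients
    (a, b, V): mean_v = a mean_u + b, Var_v = a^2 Var_u + V, and covariances
    with every other node scale by a.  The root has mean X0 and variance 0.
    """
    tree = spec.tree
    theta = spec.validate(theta)
    a, b, v = edge_coefficients(spec, theta)
    n = tree.n_nodes
    mean = np.zeros(n)
    cov = np.zeros((n, n))
    mean[0] = theta[0]
    for node in range(1, n):
        par = tree.parent[node]
        mean[node] = a[node] * mean[par] + b[node]
        row = a[node] * cov[par, :node]
        cov[node, :node] = row
        cov[:node, node] = row
        cov[node, node] = a[node] ** 2 * cov[par, par] + v[node]
    tips = list(tree.tips)
    return mean[tips], cov[np.ix_(tips, tips)]


def dense_loglik_oracle(spec: ModelSpec, theta: np.ndarray, x: TraitData | np.ndarray) -> float:
    """O(n^3) multivariate-normal evaluation of the same likelihood.

    Independent of the pruning code path; intended for verification on small
    trees (n <= a few dozen).
    """
    tree = spec.tree
    xv = x.as_array(tree) if isinstance(x, TraitData) else np.asarray(x, dtype=float)
    mean, cov = tip_moments(spec, theta)
    return float(stats.multivariate_normal.logpdf(xv, mean=mean, cov=cov))


@dataclass(frozen=True)
class MLFit:
    """Result of a multi-start maximum-likelihood fit."""

    theta: np.ndarray
    loglik: float
    n_converged: int
    n_starts: int

    @property
    def converged(self) -> bool:
        return self.n_converged > 0


def ml_fit(
    spec: ModelSpec,
    x: TraitData | np.ndarray,
    n_starts: int = 10,
    seed: int = 0,
    positive_box: tuple = (1e-8, 100.0),
    real_box: tuple = (-200.0, 200.0),
) -> MLFit:
    """Multi-start bounded maximization of the pruning log-likelihood.

    The search runs in the unbounded space (log scale for alpha and sigma);
    box constraints are stated in the original space and mapped through the
    transform.  Starts are drawn uniformly over the original-space box
    (random initialization within the restricted search space), so repeated
    runs explore distinct basins of the often multimodal surface.
    Deterministic given ``seed``; the best converged run is returned.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    ll = loglik_function(spec, x)
    tf = spec.transform
    pos = spec.positive
    d = spec.n_params
    lo = np.where(pos, math.log(positive_box[0]), real_box[0])
    hi = np.where(pos, math.log(positive_box[1]), real_box[1])
    bounds = list(zip(lo, hi))

    def neg(z):
        val = ll(tf.from_unbounded(z))
        return -val if np.isfinite(val) else 1e12

    rng = np.random.default_rng(seed)
    start_lo = np.where(pos, positive_box[0] + 1e-6, real_box[0])
    start_hi = np.where(pos, positive_box[1], real_box[1])
    best = None
    n_conv = 0
    for _ in range(n_starts):
        z0 = tf.to_unbounded(rng.uniform(start_lo, start_hi))
        res = optimize.minimize(neg, z0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        if res.success:
            n_conv += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or n_conv == 0:
        raise RuntimeError(f"no ML start converged out of {n_starts}")
    return MLFit(tf.from_unbounded(best.x), -float(best.fun), n_conv, n_starts)
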