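"""Forward simulation, posterior predictive sampling, and predictive loss.

A fitted model is judged by how closely data replicated under it resembles
the observed tips.  Replicates are drawn in two steps: resample parameter
vectors from the weighted posterior sample, then simulate the trait down
the tree once per vector.  The posterior predictive loss is

    PPL(lambda) = sum_i (x_i - m_i)^2 + lambda * sum_i s_i^2,

where m_i and s_i^2 are the per-tip sample mean and variance of the
replicates; lambda = 1 is the plain score and lambda in {ln p, p} (p = the
model's parameter count, including X0) penalizes complexity explicitly.
Per-tip predictive density curves are computed exactly as mixtures of the
normal tip marginals implied by each resampled parameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ModelSpec, edge_coefficients
from .pmc import WeightedSample, multinomial_resample
from .treeio import TraitData

__all__ = [
    "simulate_tips",
    "PredictiveDraws",
    "posterior_predictive_draws",
    "PplScore",
    "ppl",
    "predictive_density_at_tips",
    "model_comparison",
]


def _simulate_node_values(spec: ModelSpec, thetas: np.ndarray, rng) -> np.ndarray:
    """Simulate one trait realization per parameter vector (rows of thetas).

    Pre-order traversal from X0; each node's value is drawn from
    N(a * parent + b, V) with its edge's regime coefficients.  Returns an
    array of shape (n_draws, n_tips) in tree tip order.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    tree = spec.tree
    R, n_nodes = thetas.shape[0], tree.n_nodes
    a = np.ones((n_nodes, R))
    b = np.zeros((n_nodes, R))
    v = np.zeros((n_nodes, R))
    for r in range(R):
        ar, br, vr = edge_coefficients(spec, thetas[r])
        a[:, r], b[:, r], v[:, r] = ar, br, vr
    values = np.empty((n_nodes, R))
    values[0] = thetas[:, 0]
    noise = rng.standard_normal((n_nodes, R))
    for node in range(1, n_nodes):
        par = tree.parent[node]
        values[node] = a[node] * values[par] + b[node] + np.sqrt(v[node]) * noise[node]
    return values[list(tree.tips)].T


def simulate_tips(spec: ModelSpec, theta: np.ndarray, seed: int | np.random.Generator) -> TraitData:
    """Simulate one set of tip observations from the model at ``theta``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = _simulate_node_values(spec, spec.validate(theta), rng)[0]
    return TraitData(dict(zip(spec.tree.tip_labels, vals)))


@dataclass(frozen=True)
class PredictiveDraws:
    """Posterior predictive tip replicates and their per-tip moments."""

    replicates: np.ndarray  # (S_p, n_tips), tree tip order
    tip_labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "replicates", np.atleast_2d(np.asarray(self.replicates, float)))

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]

    @property
    def tip_means(self) -> np.ndarray:
        return self.replicates.mean(axis=0)

    @property
    def tip_variances(self) -> np.ndarray:
        return self.replicates.var(axis=0, ddof=1)


def posterior_predictive_draws(
    sample: WeightedSample, S_p: int, seed: int | np.random.Generator
) -> PredictiveDraws:
    """Two-step posterior predictive sampling.

    Multinomially resample ``S_p`` parameter vectors by the final weights,
    then simulate the tips once per vector.  The producing model spec must
    be attached to the sample.
    """
    if S_p < 2:
        raise ValueError("S_p must be >= 2")
    if sample.spec is None:
        raise ValueError("sample carries no model spec")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = multinomial_resample(sample.weights, S_p, rng)
    thetas = sample.theta[idx]
    reps = _simulate_node_values(sample.spec, thetas, rng)
    return PredictiveDraws(reps, sample.spec.tree.tip_labels)


@dataclass(frozen=True)
class PplScore:
    """Posterior predictive loss decomposition: total = SSE + lambda * variance term."""

    sse: float
    variance_term: float
    lam: float

    @property
    def total(self) -> float:
        return self.sse + self.lam * self.variance_term


def ppl(x: TraitData | np.ndarray, draws: PredictiveDraws, lam: float = 1.0) -> PplScore:
    """Estimated posterior predictive loss of observed tips against replicates."""
    if lam < 1.0:
        raise ValueError("lambda must be >= 1")
    if isinstance(x, TraitData):
        if set(x) != set(draws.tip_labels):
            raise ValueError("tip labels do not match the predictive draws")
        xv = np.array([x[lbl] for lbl in draws.tip_labels])
    else:
        xv = np.asarray(x, dtype=float)
        if xv.shape != (len(draws.tip_labels),):
            raise ValueError("one observation per tip expected")
    sse = float(np.sum((xv - draws.tip_means) ** 2))
    var_term = float(np.sum(draws.tip_variances))
    return PplScore(sse, var_term, float(lam))


def predictive_density_at_tips(
    sample: WeightedSample, grid: np.ndarray, S: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Per-tip posterior predictive density curves on ``grid``.

    For each of S equal-weight resampled posterior draws the tip marginal is
    an exact normal obtained by composing the (a, b, V) coefficients along
    the root-to-tip path; the returned curve is the mixture average over
    draws, shape (n_tips, len(grid)).
    """
    if sample.spec is None:
        raise ValueError("sample carries no model spec")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = multinomial_resample(sample.weights, S, rng)
    thetas = sample.theta[idx]
    spec = sample.spec
    tree = spec.tree
    tips = list(tree.tips)
    curves = np.zeros((len(tips), grid.size))
    for theta in thetas:
        a, b, v = edge_coefficients(spec, theta)
        mean = np.empty(tree.n_nodes)
        var = np.empty(tree.n_nodes)
        mean[0], var[0] = theta[0], 0.0
        for node in range(1, tree.n_nodes):
            par = tree.parent[node]
            mean[node] = a[node] * mean[par] + b[node]
            var[node] = a[node] ** 2 * var[par] + v[node]
        curves += stats.norm.pdf(grid[None, :], mean[tips, None], np.sqrt(var[tips, None]))
    return curves / len(thetas)


def model_comparison(
    x: TraitData,
    fitted: list,
    S_p: int,
    seed: int,
    lambda_rule: str = "1",
) -> pd.DataFrame:
    """Rank fitted models of the same data by posterior predictive loss.

    ``fitted`` is a list of ``(name, WeightedSample)`` pairs whose specs all
    share one tree.  The table reports SSE, the variance term, and PPL at
    lambda in {1, ln p, p} per model, ranked by ``lambda_rule``
    ("1", "ln_p", or "p").
    """
    col = {"1": "ppl", "ln_p": "ppl_ln_p", "p": "ppl_p"}[lambda_rule]
    trees = {id(s.spec.tree) for _, s in fitted}
    if len(trees) > 1:
        raise ValueError("all fitted models must share one tree")
    rows = []
    ss = np.random.SeedSequence(seed)
    for (name, sample), child in zip(fitted, ss.spawn(len(fitted))):
        draws = posterior_predictive_draws(sample, S_p, np.random.default_rng(child))
        p = sample.spec.n_params
        base = ppl(x, draws, 1.0)
        rows.append({
            "model": name,
            "p": p,
            "sse": base.sse,
            "variance_term": base.variance_term,
            "ppl": base.total,
            "ppl_ln_p": base.sse + np.log(p) * base.variance_term,
            "ppl_p": base.sse + p * base.variance_term,
        })
    return pd.DataFrame(rows).sort_values(col, ignore_index=True)
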