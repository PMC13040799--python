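"""Seeded verification fixtures: random model instances and analytic targets.

These generators back the test suite and the acceptance script.  They are
deliberately part of the package: cross-validating the pruning likelihood
against the dense oracle, and the sampler against closed-form posteriors,
are operations users may want to repeat on their own installations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .likelihood import loglik_function, tip_moments
from .models import ModelSpec
from .predictive import simulate_tips
from .treeio import random_clade_painting, random_ultrametric_tree

__all__ = ["random_mixed_instance", "conjugate_root_state_problem"]


def random_mixed_instance(seed: int, n_min: int = 2, n_max: int = 20, k_max: int = 3):
    """A random tree + painting + mixed BM/OU model + parameters + tip data.

    The data are simulated from the instance's own model so log-densities
    stay O(n) and independent likelihood implementations can be compared at
    tight absolute tolerance.  Returns ``(spec, theta, x)`` with ``x`` an
    array in tree tip order.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    tree = random_ultrametric_tree(n, seed)
    k = int(rng.integers(1, min(k_max, max(1, n // 2)) + 1))
    for trial in range(20):
        try:
            painting = random_clade_painting(
                tree, k, seed + 1000 + trial, min_frac=0.0, max_frac=1.0
            )
            break
        except Exception:
            continue
    else:
        painting = random_clade_painting(tree, 1, 0)
    kinds = tuple(rng.choice(["BM", "OU"]) for _ in range(painting.n_regimes))
    spec = ModelSpec(tree, painting, kinds)
    params = []
    for kind in kinds:
        if kind == "BM":
            params.append((rng.uniform(0.2, 2.0),))
        else:
            params.append((rng.uniform(0.1, 4.0), rng.normal(0, 2), rng.uniform(0.2, 2.0)))
    theta = spec.pack(rng.normal(0, 2), params)
    x = simulate_tips(spec, theta, seed + 5).as_array(tree)
    return spec, theta, x


def conjugate_root_state_problem(seed: int = 0, prior_mean: float = 0.0,
                                 prior_sd: float = 3.0, sigma: float = 1.1):
    """A 4-tip BM model with known sigma and only the root state X0 free.

    The posterior of X0 is normal with closed-form moments (conjugate
    normal algebra on the shared-path covariance matrix).  Returns
    ``(log_posterior over R^1, posterior mean, posterior sd)``.
    """
    from .treeio import paint_regimes, read_newick

    tree = read_newick("(((A:1,B:1):1,C:2):0.5,D:2.5);")
    spec = ModelSpec(tree, paint_regimes(tree, default="G"), ("BM",))
    rng = np.random.default_rng(seed)
    x = rng.normal(0.5, 1.0, size=4)
    _, cov = tip_moments(spec, spec.pack(0.0, [(sigma,)]))
    ll = loglik_function(spec, x)

    def log_posterior(z):
        x0 = float(np.atleast_1d(z)[0])
        return ll(np.array([x0, sigma])) + stats.norm.logpdf(x0, prior_mean, prior_sd)

    ones = np.ones(4)
    ci = np.linalg.solve(cov, ones)
    prec = 1 / prior_sd**2 + ones @ ci
    mean = (prior_mean / prior_sd**2 + x @ ci) / prec
    return log_posterior, float(mean), float(1 / np.sqrt(prec))
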