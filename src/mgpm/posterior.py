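"""Summaries and expectations under a weighted posterior sample.

All summaries are computed on original-space draws (alpha and sigma
back-transformed from the log scale), since that is the scale on which the
parameters are interpreted.  Weighted quantiles invert the step-function
weighted ECDF without interpolation (left-continuous convention: atoms
carry their full mass), and the Monte Carlo standard error of the mean uses
the self-normalized importance-sampling delta-method formula
sqrt(sum_i w_i^2 (h_i - mean)^2).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .pmc import WeightedSample

__all__ = [
    "weighted_expectation",
    "weighted_quantile",
    "summarize",
    "credible_interval",
]


def weighted_expectation(h, sample: WeightedSample) -> np.ndarray | float:
    """Posterior expectation of ``h(theta)``: sum_i h(theta_i) w_i.

    ``h`` receives one original-space draw at a time and may return a scalar
    or an array.
    """
    vals = np.array([np.asarray(h(t), dtype=float) for t in sample.theta])
    if not np.all(np.isfinite(vals[sample.weights > 0])):
        raise ValueError("h is non-finite at a positively weighted draw")
    return np.tensordot(sample.weights, vals, axes=(0, 0))


def weighted_quantile(values: np.ndarray, weights: np.ndarray, p) -> np.ndarray | float:
    """Inverse of the weighted ECDF at probabilities ``p`` (left-continuous)."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    idx = np.searchsorted(cw, np.asarray(p, dtype=float), side="left")
    out = v[np.minimum(idx, v.size - 1)]
    return out if np.ndim(p) else float(out)


def _moments(values, weights, ess_ref=None):
    mean = float(np.sum(weights * values))
    var = float(np.sum(weights * (values - mean) ** 2))
    sd = float(np.sqrt(var))
    # self-normalized IS delta-method standard error of the mean
    mcse = float(np.sqrt(np.sum(weights ** 2 * (values - mean) ** 2)))
    if ess_ref is not None and ess_ref > 0:
        # after resampling + rejuvenation the binding sample size is the
        # first-stage ESS, and one multinomial resampling step doubles the
        # asymptotic variance; take the more conservative of the two
        mcse = max(mcse, sd * math.sqrt(2.0 / ess_ref))
    return mean, sd, mcse


def summarize(sample: WeightedSample, ess_warn: float = 50.0) -> pd.DataFrame:
    """Per-parameter posterior summary table.

    One row per parameter (layout order) with mean, standard deviation, MC
    standard error of the mean, and the 2.5/50/97.5 percent quantiles; the
    sample's ESS and log-normalizer are stored in ``DataFrame.attrs``.
    """
    if sample.size == 0:
        raise ValueError("empty sample")
    ess_ref = sample.diagnostics.get("ess_stage1")
    ess_eff = min(sample.ess, ess_ref) if ess_ref is not None else sample.ess
    if ess_eff < ess_warn:
        warnings.warn(
            f"effective sample size {ess_eff:.1f} below {ess_warn}; "
            "summaries may be unreliable",
            stacklevel=2,
        )
    theta = sample.theta
    rows = []
    for j, name in enumerate(sample.param_names):
        mean, sd, mcse = _moments(theta[:, j], sample.weights, ess_ref)
        q025, q50, q975 = weighted_quantile(theta[:, j], sample.weights, [0.025, 0.5, 0.975])
        rows.append({
            "parameter": name, "mean": mean, "sd": sd, "mcse": mcse,
            "q2.5": q025, "q50": q50, "q97.5": q975,
        })
    df = pd.DataFrame(rows)
    df.attrs["ess"] = ess_eff
    df.attrs["log_norm"] = sample.log_norm
    return df


def credible_interval(sample: WeightedSample, level: float, parameter) -> tuple:
    """Equal-tailed credible interval for one parameter (name or index)."""
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    j = parameter if isinstance(parameter, int) else sample.param_names.index(parameter)
    lo = (1 - level) / 2
    vals = sample.theta[:, j]
    return (
        weighted_quantile(vals, sample.weights, lo),
        weighted_quantile(vals, sample.weights, 1 - lo),
    )
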