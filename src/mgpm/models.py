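"""Gaussian transition algebra for BM/OU regimes and the flat parameter vector.

Both Brownian motion and the Ornstein-Uhlenbeck process have Gaussian
transition densities whose conditional mean is linear in the ancestral value
and whose variance does not depend on it: over an elapsed time ``l``,

    x(t) | x(s)  ~  N( a * x(s) + b ,  V ),

with (a, b, V) = (1, 0, sigma^2 l) for BM and
(e^{-alpha l}, (1 - e^{-alpha l}) theta, sigma^2 (1 - e^{-2 alpha l}) / (2 alpha))
for OU.  A mixed model pairs each regime of a painted tree with one such
process; all regimes share the root state X0.  The flat parameter vector is
ordered (X0, theta_1, ..., theta_K) with (sigma,) per BM regime and
(alpha, theta, sigma) per OU regime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .treeio import PhyloTree, RegimePainting

__all__ = [
    "GaussianTransition",
    "bm_coefficients",
    "ou_coefficients",
    "ModelSpec",
    "Transform",
    "edge_coefficients",
]

# Below this value of alpha*l the exact OU variance formula hits 0/0 noise;
# a first-order series in alpha*l is exact to O((alpha l)^2).
_SMALL_ALPHA_L = 1e-8


class GaussianTransition(NamedTuple):
    """Coefficients (a, b, V) of one Gaussian transition over an edge."""

    a: float
    b: float
    V: float


def bm_coefficients(sigma: float, l: float) -> GaussianTransition:
    """Transition coefficients of Brownian motion over elapsed time ``l``."""
    if l < 0:
        raise ValueError("elapsed time must be non-negative")
    return GaussianTransition(1.0, 0.0, sigma * sigma * l)


def ou_coefficients(alpha: float, theta: float, sigma: float, l: float) -> GaussianTransition:
    """Transition coefficients of an OU process over elapsed time ``l``.

    Continuous in alpha at 0 with the BM limit (1, 0, sigma^2 l); for
    alpha*l below a small threshold a stable series expansion is used.
    """
    if l < 0:
        raise ValueError("elapsed time must be non-negative")
    al = alpha * l
    if al < _SMALL_ALPHA_L:
        a = 1.0 - al
        b = al * theta
        v = sigma * sigma * l * (1.0 - al)
        return GaussianTransition(a, b, v)
    e = math.exp(-al)
    a = e
    b = (1.0 - e) * theta
    v = sigma * sigma / (2.0 * alpha) * (1.0 - e * e)
    return GaussianTransition(a, b, v)


@dataclass(frozen=True)
class ModelSpec:
    """A mixed Gaussian phylogenetic model: painted tree + per-regime process kind.

    ``kinds[k]`` is ``"BM"`` or ``"OU"`` for regime ``k`` of the painting.
    The spec owns the parameter layout; parameter values travel as flat
    numpy vectors in layout order.
    """

    tree: PhyloTree
    painting: RegimePainting
    kinds: tuple

    def __post_init__(self):
        if len(self.kinds) != self.painting.n_regimes:
            raise ValueError("one process kind per regime required")
        for k in self.kinds:
            if k not in ("BM", "OU"):
                raise ValueError(f"unknown process kind {k!r}")
        object.__setattr__(self, "kinds", tuple(self.kinds))

    @property
    def param_names(self) -> tuple:
        names = ["X0"]
        for k, kind in enumerate(self.kinds):
            reg = self.painting.names[k]
            if kind == "BM":
                names.append(f"{reg}.sigma")
            else:
                names += [f"{reg}.alpha", f"{reg}.theta", f"{reg}.sigma"]
        return tuple(names)

    @property
    def n_params(self) -> int:
        return 1 + sum(1 if k == "BM" else 3 for k in self.kinds)

    @property
    def positive(self) -> np.ndarray:
        """Boolean mask of positive-constrained parameters (alpha's, sigma's)."""
        return np.array([n.endswith((".alpha", ".sigma")) for n in self.param_names])

    @property
    def transform(self) -> "Transform":
        return Transform(self.positive)

    def regime_slices(self) -> list:
        """Index array into the flat vector for each regime's own parameters."""
        out, i = [], 1
        for kind in self.kinds:
            w = 1 if kind == "BM" else 3
            out.append(np.arange(i, i + w))
            i += w
        return out

    def validate(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"parameter vector of length {self.n_params} expected, got {theta.shape}"
            )
        if np.any(theta[self.positive] <= 0):
            raise ValueError("positive-constrained parameter is not > 0")
        return theta

    def pack(self, x0: float, regime_params) -> np.ndarray:
        """Flatten X0 and per-regime parameter tuples into the layout order."""
        vec = [float(x0)]
        if len(regime_params) != len(self.kinds):
            raise ValueError("one parameter tuple per regime required")
        for kind, pars in zip(self.kinds, regime_params):
            pars = tuple(np.atleast_1d(pars).astype(float))
            if len(pars) != (1 if kind == "BM" else 3):
                raise ValueError(f"{kind} regime takes {1 if kind == 'BM' else 3} parameters")
            vec.extend(pars)
        return self.validate(np.array(vec))

    def unpack(self, theta: np.ndarray):
        """Inverse of :meth:`pack`: returns (X0, [per-regime tuples])."""
        theta = self.validate(theta)
        return float(theta[0]), [tuple(theta[idx]) for idx in self.regime_slices()]


@dataclass(frozen=True)
class Transform:
    """Coordinate-wise bijection g from the parameter space onto R^d.

    Positive parameters (alpha, sigma) map through log; unconstrained ones
    (X0, theta) through the identity.  ``log_jacobian`` is the log of
    |d g^{-1} / dz|, i.e. the sum of z over log-transformed coordinates.
    """

    positive: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "positive", np.asarray(self.positive, dtype=bool))

    @property
    def dim(self) -> int:
        return self.positive.size

    def to_unbounded(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if np.any(theta[..., self.positive] <= 0):
            raise ValueError("non-positive value in a log-transformed slot")
        z = theta.copy()
        z[..., self.positive] = np.log(theta[..., self.positive])
        return z

    def from_unbounded(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        theta = z.copy()
        theta[..., self.positive] = np.exp(z[..., self.positive])
        return theta

    def log_jacobian(self, z: np.ndarray) -> float | np.ndarray:
        z = np.asarray(z, dtype=float)
        return z[..., self.positive].sum(axis=-1)


def edge_coefficients(spec: ModelSpec, theta: np.ndarray):
    """Per-edge transition coefficients (a, b, V), indexed by child node.

    Root entries are the identity transition (1, 0, 0).  Vectorized per
    regime; this is the workhorse behind the likelihood and the simulator.
    """
    theta = spec.validate(theta)
    tree, painting = spec.tree, spec.painting
    a = np.ones(tree.n_nodes)
    b = np.zeros(tree.n_nodes)
    v = np.zeros(tree.n_nodes)
    _, regimes = spec.unpack(theta)
    for k, (kind, pars) in enumerate(zip(spec.kinds, regimes)):
        edges = painting.edges_in(k)
        l = tree.lengths[edges]
        if kind == "BM":
            (sigma,) = pars
            v[edges] = sigma * sigma * l
        else:
            alpha, th, sigma = pars
            al = alpha * l
            small = al < _SMALL_ALPHA_L
            e = np.exp(-al)
            a[edges] = np.where(small, 1.0 - al, e)
            b[edges] = np.where(small, al * th, (1.0 - e) * th)
            v[edges] = np.where(
                small,
                sigma * sigma * l * (1.0 - al),
                sigma * sigma / (2.0 * alpha) * (1.0 - e * e),
            )
    return a, b, v
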