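"""Phylogenetic trees, regime paintings, and trait tables.

A :class:`PhyloTree` is a rooted tree with branch lengths in time units,
stored as flat arrays (parent pointers and edge lengths indexed by node id).
Each non-root node owns the edge to its parent, so edges are identified by
their child node throughout the package.  Trees are expected to be
ultrametric: every root-to-tip path has the same length ``t_H`` (the tree
height), because the prior-calibration recipes assume a single height.

A :class:`RegimePainting` assigns every edge to exactly one of K evolutionary
regimes.  Regimes may be disconnected: two unrelated clades can share a
regime and hence a parameter set.
"""

from __future__ import annotations

import io
from collections.abc import Mapping
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "RegimePainting",
    "TraitData",
    "read_newick",
    "write_newick",
    "validate_ultrametric",
    "paint_regimes",
    "painting_from_table",
    "random_ultrametric_tree",
    "random_clade_painting",
    "read_traits_csv",
    "write_traits_csv",
]


class TreeError(ValueError):
    """Raised for malformed trees, paintings, or trait tables."""


@dataclass(frozen=True)
class PhyloTree:
    """Rooted phylogenetic tree with branch lengths.

    Nodes are integers ``0 .. n_nodes-1`` in preorder (root first).  ``parent[v]``
    is the parent of ``v`` (``-1`` for the root) and ``lengths[v]`` is the length
    of the edge from ``v`` up to its parent (``0.0`` for the root).  ``labels[v]``
    is the tip label for tips, an optional label (or ``None``) for internal
    nodes.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: tuple

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=np.intp)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "lengths", lengths)
        if parent.shape != lengths.shape or parent.ndim != 1:
            raise TreeError("parent and lengths must be matching 1-d arrays")
        if (parent == -1).sum() != 1 or parent[0] != -1:
            raise TreeError("exactly one root expected, at node 0")
        if np.any(lengths < 0):
            raise TreeError("negative branch length")
        if np.any(parent[1:] >= np.arange(1, parent.size)):
            raise TreeError("nodes must be in preorder (parent before child)")
        children = [[] for _ in range(parent.size)]
        for v in range(1, parent.size):
            children[parent[v]].append(v)
        object.__setattr__(self, "_children", tuple(tuple(c) for c in children))
        tips = tuple(v for v in range(parent.size) if not children[v])
        object.__setattr__(self, "_tips", tips)
        tip_labels = tuple(self.labels[v] for v in tips)
        if any(lbl is None for lbl in tip_labels):
            raise TreeError("every tip must carry a label")
        if len(set(tip_labels)) != len(tip_labels):
            raise TreeError("duplicate tip label")

    # ----- basic structure -----
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return 0

    @property
    def children(self) -> tuple:
        return self._children

    @property
    def tips(self) -> tuple:
        """Node ids of the tips, in preorder."""
        return self._tips

    @property
    def n_tips(self) -> int:
        return len(self._tips)

    @property
    def tip_labels(self) -> tuple:
        return tuple(self.labels[v] for v in self._tips)

    @property
    def preorder(self) -> np.ndarray:
        return np.arange(self.n_nodes)

    @property
    def postorder(self) -> np.ndarray:
        return np.arange(self.n_nodes - 1, -1, -1)

    def depths(self) -> np.ndarray:
        """Distance of every node from the root."""
        d = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    @property
    def height(self) -> float:
        """Tree height t_H: the maximum root-to-tip distance."""
        d = self.depths()
        return float(d[list(self._tips)].max())

    def node_by_label(self, label: str) -> int:
        for v, lbl in enumerate(self.labels):
            if lbl == label:
                return v
        raise TreeError(f"no node labelled {label!r}")

    def mrca(self, labels) -> int:
        """Most recent common ancestor of a set of tip/internal labels."""
        nodes = [self.node_by_label(l) for l in labels]
        if not nodes:
            raise TreeError("mrca of an empty label set")
        ancestors = set()
        v = nodes[0]
        while v != -1:
            ancestors.add(v)
            v = self.parent[v]
        for u in nodes[1:]:
            while u not in ancestors:
                u = self.parent[u]
            # restrict to ancestors of u as well
            keep = set()
            w = u
            while w != -1:
                if w in ancestors:
                    keep.add(w)
                w = self.parent[w]
            ancestors = keep
        return max(ancestors)  # deepest shared ancestor (preorder ids grow downward on paths)

    def clade(self, node: int) -> list:
        """All nodes of the subtree rooted at ``node`` (including it)."""
        out = [node]
        stack = [node]
        while stack:
            u = stack.pop()
            for c in self._children[u]:
                out.append(c)
                stack.append(c)
        return out


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are required on every edge except the root edge; quoted
    labels are supported and tip labels are preserved verbatim.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"Newick parse failure: {exc}") from exc
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent, lengths, labels = [], [], []
    for i, nd in enumerate(nodes):
        if nd.parent_node is None:
            parent.append(-1)
            lengths.append(0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            if nd.edge.length is None:
                raise TreeError("missing branch length on a non-root edge")
            lengths.append(float(nd.edge.length))
        if nd.taxon is not None:
            labels.append(nd.taxon.label)
        else:
            labels.append(nd.label)
    return PhyloTree(np.array(parent), np.array(lengths), tuple(labels))


def write_newick(tree: PhyloTree) -> str:
    """Serialize a :class:`PhyloTree` to Newick (lengths with full precision)."""

    def fmt(v: int) -> str:
        kids = tree.children[v]
        if kids:
            inner = ",".join(fmt(c) for c in kids)
            lbl = tree.labels[v] or ""
            s = f"({inner}){_quote(lbl)}"
        else:
            s = _quote(tree.labels[v])
        if v != tree.root:
            s += f":{float(tree.lengths[v])!r}"
        return s

    return fmt(tree.root) + ";"


def _quote(label) -> str:
    if label is None:
        return ""
    if any(ch in label for ch in " ():,;[]'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def validate_ultrametric(tree: PhyloTree, rel_tol: float = 1e-6) -> None:
    """Check that all root-to-tip depths equal t_H within ``rel_tol`` relative.

    Raises :class:`TreeError` naming the worst-offending tip otherwise.
    """
    d = tree.depths()
    tip_ids = list(tree.tips)
    depths = d[tip_ids]
    t_h = depths.max()
    if t_h == 0.0:
        return
    if t_h - depths.min() > rel_tol * t_h:
        # name the tip deviating most from the typical depth; ties go to the
        # deeper tip, which is usually the anomalous one in dated trees
        dev = np.abs(depths - np.median(depths))
        worst = int(np.lexsort((-depths, -dev))[0])
        raise TreeError(
            f"tree is not ultrametric: tip {tree.labels[tip_ids[worst]]!r} has "
            f"depth {depths[worst]:.9g} vs height {t_h:.9g}"
        )


@dataclass(frozen=True)
class RegimePainting:
    """Total assignment of edges (identified by child node) to K regimes.

    ``regime_of[v]`` is the regime index of the edge above node ``v``; the
    root entry is ``-1`` since the root owns no edge.
    """

    regime_of: np.ndarray
    names: tuple

    def __post_init__(self):
        r = np.asarray(self.regime_of, dtype=np.intp)
        object.__setattr__(self, "regime_of", r)
        k = len(self.names)
        if len(set(self.names)) != k:
            raise TreeError("regime name collision")
        if r[0] != -1:
            raise TreeError("root carries no regime")
        if np.any(r[1:] < 0) or np.any(r[1:] >= k):
            raise TreeError("uncovered edge or regime index out of range")
        used = np.unique(r[1:])
        if used.size != k:
            missing = sorted(set(range(k)) - set(used.tolist()))
            raise TreeError(f"regimes never used on any edge: {missing}")

    @property
    def n_regimes(self) -> int:
        return len(self.names)

    def edges_in(self, regime: int) -> np.ndarray:
        """Child-node ids of the edges painted with ``regime``."""
        return np.flatnonzero(self.regime_of == regime)


def paint_regimes(tree: PhyloTree, clades=(), default: str | None = None) -> RegimePainting:
    """Build a painting from clade declarations over a default regime.

    ``clades`` is a sequence of ``(anchor, regime_name)`` pairs where the
    anchor is a node label or an iterable of tip labels (their MRCA is used).
    The declared regime covers the crown node's stem edge and every edge of
    the clade below it.  Later declarations override earlier ones on
    overlapping edges.  With no declarations, all edges fall in the single
    ``default`` regime.
    """
    if default is None and not clades:
        raise TreeError("no clade declarations and no default regime")
    names: list[str] = []
    if default is not None:
        names.append(default)
    regime_of = np.full(tree.n_nodes, -2, dtype=np.intp)
    regime_of[1:] = 0 if default is not None else -2
    for anchor, name in clades:
        if name in names:
            idx = names.index(name)
        else:
            names.append(name)
            idx = len(names) - 1
        if isinstance(anchor, str):
            crown = tree.node_by_label(anchor)
        else:
            crown = tree.mrca(list(anchor))
        for v in tree.clade(crown):
            if v != tree.root:
                regime_of[v] = idx
    if np.any(regime_of[1:] == -2):
        raise TreeError("uncovered edge when no default regime is given")
    regime_of[0] = -1
    return RegimePainting(regime_of, tuple(names))


def painting_from_table(tree: PhyloTree, mapping: Mapping[str, str]) -> RegimePainting:
    """Painting from an explicit edge table: child node/tip label -> regime name."""
    names: list[str] = []
    regime_of = np.full(tree.n_nodes, -2, dtype=np.intp)
    for label, name in mapping.items():
        v = tree.node_by_label(label)
        if v == tree.root:
            raise TreeError("the root owns no edge and cannot be painted")
        if name not in names:
            names.append(name)
        regime_of[v] = names.index(name)
    if np.any(regime_of[1:] == -2):
        missing = [v for v in range(1, tree.n_nodes) if regime_of[v] == -2]
        raise TreeError(f"edges without a regime: nodes {missing}")
    regime_of[0] = -1
    return RegimePainting(regime_of, tuple(names))


def random_ultrametric_tree(n_tips: int, seed: int) -> PhyloTree:
    """Pure-birth (Yule) tree with ``n_tips`` tips, rescaled to unit height.

    Deterministic for a fixed seed; ultrametric by construction.  Tips are
    labelled ``t1 .. tN``.
    """
    if n_tips < 1:
        raise TreeError("n_tips must be >= 1")
    rng = np.random.default_rng(seed)
    if n_tips == 1:
        return PhyloTree(np.array([-1, 0]), np.array([0.0, 1.0]), (None, "t1"))
    # Event times of a Yule process with per-lineage rate 1; root splits at 0.
    birth = {0: 0.0}  # provisional node id -> time the lineage began
    parent_of = {}
    active = []
    next_id = 1
    t = 0.0
    # root split
    for _ in range(2):
        birth[next_id] = 0.0
        parent_of[next_id] = 0
        active.append(next_id)
        next_id += 1
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        split = active.pop(rng.integers(len(active)))
        for _ in range(2):
            birth[next_id] = t
            parent_of[next_id] = split
            active.append(next_id)
            next_id += 1
    t_present = t + rng.exponential(1.0 / len(active))
    # Assemble arrays in preorder of the provisional ids (parents precede
    # children by construction), with edge length = child's lifespan.
    ids = sorted(birth)  # 0..next_id-1, already topologically ordered
    end_time = {v: t_present for v in active}
    # an internal node ends when it splits: recover from its children's births
    for child, par in parent_of.items():
        end_time[par] = birth[child]
    parent = np.full(len(ids), -1, dtype=np.intp)
    lengths = np.zeros(len(ids))
    labels: list = [None] * len(ids)
    tip_counter = 0
    for v in ids[1:]:
        parent[v] = parent_of[v]
        lengths[v] = end_time[v] - birth[v]
    for v in ids:
        if v in active:
            tip_counter += 1
            labels[v] = f"t{tip_counter}"
    lengths /= t_present
    return PhyloTree(parent, lengths, tuple(labels))


def random_clade_painting(
    tree: PhyloTree,
    n_regimes: int,
    seed: int,
    ancestral: str = "Ancestral",
    min_frac: float = 0.1,
    max_frac: float = 0.6,
) -> RegimePainting:
    """Seeded painting with ``n_regimes - 1`` random clade regimes over a default.

    Clades are drawn among internal nodes whose tip share lies in
    ``[min_frac, max_frac]``; later picks override earlier ones so every run
    yields a total painting with exactly ``n_regimes`` regimes.
    """
    if n_regimes == 1:
        return paint_regimes(tree, default=ancestral)
    rng = np.random.default_rng(seed)
    n = tree.n_tips
    tipcount = np.zeros(tree.n_nodes, dtype=int)
    for v in tree.postorder:
        kids = tree.children[v]
        tipcount[v] = 1 if not kids else sum(tipcount[c] for c in kids)
    candidates = [
        v for v in range(1, tree.n_nodes)
        if tree.children[v] and min_frac * n <= tipcount[v] <= max_frac * n
    ]
    for _ in range(200):
        picks = rng.choice(candidates, size=n_regimes - 1, replace=False) \
            if len(candidates) >= n_regimes - 1 else None
        if picks is None:
            raise TreeError("tree too small for the requested number of regimes")
        try:
            painting = _paint_by_nodes(tree, sorted(picks), ancestral)
        except TreeError:
            continue
        if painting.n_regimes == n_regimes:
            return painting
    raise TreeError("could not draw a painting with all regimes represented")


def _paint_by_nodes(tree: PhyloTree, crowns, ancestral: str) -> RegimePainting:
    regime_of = np.full(tree.n_nodes, 0, dtype=np.intp)
    names = [ancestral] + [f"R{i+1}" for i in range(len(crowns))]
    for i, crown in enumerate(crowns):
        for v in tree.clade(crown):
            if v != tree.root:
                regime_of[v] = i + 1
    regime_of[0] = -1
    return RegimePainting(regime_of, tuple(names))


class TraitData(Mapping):
    """Univariate continuous trait values at the tips: label -> real value.

    Values are assumed already transformed to the real line (e.g. log scale).
    """

    def __init__(self, values: Mapping[str, float]):
        vals = {str(k): float(v) for k, v in values.items()}
        if not all(np.isfinite(list(vals.values()))):
            raise TreeError("non-finite trait value")
        self._values = vals

    def __getitem__(self, key):
        return self._values[key]

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)

    def as_array(self, tree: PhyloTree) -> np.ndarray:
        """Values ordered by the tree's tip order; label sets must match exactly."""
        if set(self._values) != set(tree.tip_labels):
            raise TreeError("trait labels do not match the tree's tips")
        return np.array([self._values[lbl] for lbl in tree.tip_labels])


def read_traits_csv(path_or_buffer) -> TraitData:
    """Read a 2-column CSV (tip label, value) into :class:`TraitData`."""
    df = pd.read_csv(path_or_buffer, header=None, names=["tip", "value"], dtype={0: str})
    if df["tip"].duplicated().any():
        raise TreeError("duplicate tip label in trait table")
    return TraitData(dict(zip(df["tip"], df["value"])))


def write_traits_csv(traits: TraitData, path_or_buffer) -> None:
    pd.DataFrame({"tip": list(traits), "value": [traits[k] for k in traits]}).to_csv(
        path_or_buffer, header=False, index=False
    )
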