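"""Phylogenetic trees with branch-type labels, NJ and bootstrap support.

Branch types drive the branch-site and clade codon models: every branch
carries a type name (default ``"background"``); foreground clades are
labeled via :func:`label_branches` or a ``#TYPE`` suffix in newick input,
e.g. ``((a,b)#TR,c);`` labels the stem branch of (a,b) with type ``TR``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

BACKGROUND = "background"
DEFAULT_BRANCH_LENGTH = 0.1


class Node:
    __slots__ = ("name", "length", "label", "children", "parent", "support")

    def __init__(self, name=None, length=0.0, label=BACKGROUND):
        self.name = name
        self.length = float(length)
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.support: float | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class LabeledTree:
    """A (rooted representation of a) phylogeny with typed branches."""

    def __init__(self, root: Node):
        self.root = root
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf names in tree")

    # -- traversal ----------------------------------------------------
    def postorder(self) -> list[Node]:
        out, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                out.append(node)
            else:
                stack.append((node, True))
                for ch in reversed(node.children):
                    stack.append((ch, False))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def branches(self) -> list[Node]:
        """All non-root nodes; each represents the branch above it."""
        return [n for n in self.postorder() if n is not self.root]

    def branch_labels(self) -> dict:
        return {id(n): n.label for n in self.branches()}

    def label_set(self) -> set:
        return {n.label for n in self.branches()}

    def copy(self) -> "LabeledTree":
        def rec(node):
            c = Node(node.name, node.length, node.label)
            c.support = node.support
            for ch in node.children:
                c.add(rec(ch))
            return c
        return LabeledTree(rec(self.root))

    def scale(self, factor: float) -> "LabeledTree":
        t = self.copy()
        for n in t.branches():
            n.length *= factor
        return t

    def total_length(self) -> float:
        return sum(n.length for n in self.branches())

    def leafset_below(self, node: Node) -> frozenset:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def bipartitions(self) -> set[frozenset]:
        """Canonical nontrivial splits (smaller side, ties by sorted tuple)."""
        all_leaves = frozenset(self.leaf_names())
        splits = set()
        for node in self.branches():
            side = self.leafset_below(node)
            if 1 < len(side) < len(all_leaves) - 1:
                splits.add(_canonical_split(side, all_leaves))
        return splits

    # -- newick -------------------------------------------------------
    def to_newick(self, with_support: bool = False) -> str:
        def fmt(node):
            if node.is_leaf:
                core = _escape(node.name)
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if with_support and node.support is not None:
                    core += "%g" % node.support
                elif node.name:
                    core += _escape(node.name)
            if node.label != BACKGROUND:
                core += f"#{node.label}"
            if node is not self.root:
                core += ":%.10g" % node.length
            return core
        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "LabeledTree":
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True)
        except Exception as exc:  # dendropy raises several parse errors
            raise ValueError(f"malformed newick: {exc}") from exc
        missing = [False]

        def rec(dnode):
            raw = (dnode.taxon.label if dnode.taxon is not None
                   else dnode.label) or ""
            name, label = _split_label(raw)
            if dnode.edge.length is None:
                missing[0] = True
                length = DEFAULT_BRANCH_LENGTH
            else:
                length = float(dnode.edge.length)
            node = Node(name or None, length, label)
            if not dnode.is_leaf() and name and re.fullmatch(
                    r"\d+(\.\d+)?", name):
                node.support = float(name)
                node.name = None
            for ch in dnode.child_nodes():
                node.add(rec(ch))
            return node

        root = rec(dtree.seed_node)
        root.length = 0.0
        if missing[0]:
            logger.info("newick lacked some branch lengths; "
                        "defaulting them to %.2f", DEFAULT_BRANCH_LENGTH)
        return cls(root)


def _escape(name: str) -> str:
    return name if re.fullmatch(r"[\w.\-|]+", name or "") else f"'{name}'"


def _split_label(raw: str) -> tuple[str, str]:
    if "#" in raw:
        name, label = raw.split("#", 1)
        if not re.fullmatch(r"\w+", label):
            raise ValueError(f"malformed branch-type label {raw!r}")
        return name, label
    return raw, BACKGROUND


def _canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    other = all_leaves - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return side if tuple(sorted(side)) < tuple(sorted(other)) else other


def read_newick(path) -> LabeledTree:
    return LabeledTree.from_newick(Path(path).read_text())


def write_newick(tree: LabeledTree, path, with_support: bool = False) -> None:
    Path(path).write_text(tree.to_newick(with_support=with_support) + "\n")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    taxa: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("distances must be finite and nonnegative")

    def get(self, a: str, b: str) -> float:
        return self.values[self.taxa.index(a), self.taxa.index(b)]


_SATURATION = {"p": 1.0, "poisson": 1.0, "jc": 0.75}


def distance(alignment, model: str = "p") -> DistanceMatrix:
    """Pairwise distances from an aligned set of records.

    ``p``: mismatch fraction over shared ungapped columns; ``poisson``:
    -ln(1-p) (proteins); ``jc``: Jukes-Cantor -3/4 ln(1 - 4p/3) (DNA).
    """
    records = _as_records(alignment)
    if model not in _SATURATION:
        raise ValueError(f"unknown distance model {model!r}")
    taxa = [r.id for r in records]
    rows = [r.seq.upper() for r in records]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows have unequal lengths")
    arr = np.array([list(r) for r in rows])
    gap = arr == "-"
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            if not shared.any():
                raise ValueError(f"no shared columns for pair "
                                 f"({taxa[i]}, {taxa[j]})")
            p = float(np.mean(arr[i, shared] != arr[j, shared]))
            if p >= _SATURATION[model]:
                raise ValueError(
                    f"pair ({taxa[i]}, {taxa[j]}) saturated under "
                    f"{model!r} (p={p:.3f})")
            if model == "p":
                dij = p
            elif model == "poisson":
                dij = -np.log(1.0 - p)
            else:
                dij = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(taxa, d)


def _as_records(alignment):
    if hasattr(alignment, "to_dna_records"):
        return alignment.to_dna_records()
    return list(alignment)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj(dist: DistanceMatrix) -> LabeledTree:
    """Classical neighbor joining (Saitou-Nei with Studier-Keppler Q).

    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch; ties in the Q criterion are broken by the
    lexicographically smallest pair of cluster keys, so output is
    deterministic. Additive matrices are inverted exactly.
    """
    n = len(dist.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = [Node(t) for t in dist.taxa]
    keys = list(dist.taxa)  # smallest descendant leaf name per cluster
    d = dist.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                q = (m - 2) * sub[a, b] - r[a] - r[b]
                key = tuple(sorted((keys[active[a]], keys[active[b]])))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, a, b)
        _q, _key, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = Node()
        parent.add(_with_length(nodes[i], li))
        parent.add(_with_length(nodes[j], lj))
        new = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        drow = np.zeros(new + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new, k] = d[k, new] = 0.5 * (d[i, k] + d[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [new]
        del drow

    root = Node()
    if len(active) == 1:
        root = nodes[active[0]]
    elif len(active) == 2:
        i, j = active
        dij = d[i, j]
        root.add(_with_length(nodes[i], dij / 2.0))
        root.add(_with_length(nodes[j], dij / 2.0))
    else:
        i, j, k = active
        li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
        lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
        lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        for idx, ln in ((i, li), (j, lj), (k, lk)):
            root.add(_with_length(nodes[idx], max(ln, 0.0)))
    return LabeledTree(root)


def _with_length(node: Node, length: float) -> Node:
    node.length = float(length)
    return node


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def default_builder(alignment, model: str = "p") -> LabeledTree:
    return nj(distance(alignment, model=model))


def bootstrap_support(alignment, builder: Callable = default_builder,
                      replicates: int = 1000, seed: int = 0) -> LabeledTree:
    """Nonparametric bootstrap support on the point-estimate NJ tree.

    Columns are resampled with replacement; support for each internal
    bipartition of the point tree is the percent of replicate trees
    containing it.
    """
    records = _as_records(alignment)
    point = builder(records)
    ncols = len(records[0].seq)
    rng = np.random.default_rng(seed)
    counts = {split: 0 for split in point.bipartitions()}
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        resampled = [type(r)(r.id, "".join(r.seq[c] for c in cols), r.moltype)
                     for r in records]
        for split in builder(resampled).bipartitions():
            if split in counts:
                counts[split] += 1
    all_leaves = frozenset(point.leaf_names())
    for node in point.branches():
        side = point.leafset_below(node)
        if 1 < len(side) < len(all_leaves) - 1:
            split = _canonical_split(side, all_leaves)
            node.support = 100.0 * counts[split] / replicates
    return point


# ---------------------------------------------------------------------------
# branch labeling
# ---------------------------------------------------------------------------

def label_branches(tree: LabeledTree, clade_spec: dict,
                   include_stem: bool = True) -> LabeledTree:
    """Label the stem branch of each named (monophyletic) clade.

    ``clade_spec`` maps type name -> set of leaf names. Nested clades are
    fine (they have distinct stem branches); two names resolving to the
    same branch are an error, as is a non-monophyletic leaf set.
    """
    out = tree.copy()
    taken: dict[int, str] = {}
    for name, leafset in clade_spec.items():
        leafset = frozenset(leafset)
        target = None
        for node in out.branches():
            if out.leafset_below(node) == leafset:
                target = node
                break
        if target is None:
            raise ValueError(f"leaf set for type {name!r} is not "
                             f"monophyletic in the tree")
        if id(target) in taken:
            raise ValueError(
                f"types {taken[id(target)]!r} and {name!r} label the "
                f"same branch")
        taken[id(target)] = name
        if include_stem:
            target.label = name
    return out


# ---------------------------------------------------------------------------
# random trees (testing / simulation defaults)
# ---------------------------------------------------------------------------

def random_tree(names: Sequence[str], seed: int = 0,
                min_len: float = 0.05, max_len: float = 0.5) -> LabeledTree:
    """Random binary topology with uniform branch lengths (seeded)."""
    rng = np.random.default_rng(seed)
    nodes = [Node(n, float(rng.uniform(min_len, max_len))) for n in names]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(None, float(rng.uniform(min_len, max_len)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return LabeledTree(root)
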