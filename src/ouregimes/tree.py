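"""Rooted phylogenies: Newick/Nexus I/O, ultrametricity checks, pruning,
and painting of selective regimes onto branches.

The central object is :class:`Phylogeny`, a light array-backed rooted tree
with branch lengths in relative time.  Trees are read with dendropy and
converted; the rest of the package operates on the arrays directly.

Regime painting follows the child-node convention: each branch carries the
state of the node at its tipward end, so a state change reconstructed at a
node recolours the branch subtending it.
"""

from __future__ import annotations

import dataclasses
import re
import warnings

import numpy as np
import dendropy

DEFAULT_REGIMES: tuple[str, ...] = ("LS", "CC", "CS")

__all__ = [
    "Phylogeny",
    "RegimePainting",
    "TreeError",
    "DEFAULT_REGIMES",
    "normalize_name",
    "read_newick",
    "read_tree",
    "write_newick",
    "check_ultrametric",
    "prune_to",
    "paint_regimes",
]


class TreeError(ValueError):
    """Raised for malformed trees or invalid tree operations."""


def normalize_name(name: str) -> str:
    """Canonical species label: trimmed, whitespace/underscore runs unified."""
    return re.sub(r"[\s_]+", "_", str(name).strip())


@dataclasses.dataclass
class Phylogeny:
    """Rooted tree with branch lengths.

    Nodes are integers ``0 .. n_nodes-1``.  ``parent[i]`` is the parent of
    node ``i`` (``-1`` for the root); ``lengths[i]`` is the length of the
    branch above node ``i`` (0.0 for the root); ``labels[i]`` is the tip
    label for leaves and ``None`` (or an internal label) otherwise.
    """

    parent: np.ndarray
    lengths: np.ndarray
    labels: list
    root: int

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=int)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.parent.size
        if not (0 <= self.root < n) or self.parent[self.root] != -1:
            raise TreeError("root must be the unique node with parent -1")
        if int(np.sum(self.parent == -1)) != 1:
            raise TreeError("tree must have exactly one root")
        if np.any(self.lengths[np.arange(n) != self.root] < 0):
            raise TreeError("negative branch length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        order = self.preorder()
        if order.size != n:
            raise TreeError("tree contains nodes unreachable from the root")
        tips = self.tips
        names = [self.labels[t] for t in tips]
        if any(not nm for nm in names):
            raise TreeError("every tip needs a non-empty label")
        seen: set[str] = set()
        for nm in names:
            if nm in seen:
                raise TreeError(f"duplicate tip label: {nm!r}")
            seen.add(nm)
        zero_internal = [
            i for i in range(n)
            if i != self.root and self.children[i] and self.lengths[i] == 0.0
        ]
        if zero_internal:
            warnings.warn(
                f"{len(zero_internal)} internal branch(es) of length 0 "
                "(soft polytomies); covariances remain well defined",
                stacklevel=2,
            )
        self._cache: dict = {}

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def tips(self) -> np.ndarray:
        return np.array(
            [i for i in range(self.n_nodes) if not self.children[i]], dtype=int
        )

    @property
    def n_tips(self) -> int:
        return self.tips.size

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tips]

    def preorder(self) -> np.ndarray:
        """Node ids root-first; parents before children."""
        out, stack = [], [self.root]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(reversed(self.children[v]))
        return np.array(out, dtype=int)

    def postorder(self) -> np.ndarray:
        return self.preorder()[::-1].copy()

    def depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        d = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                d[v] = d[self.parent[v]] + self.lengths[v]
        return d

    @property
    def height(self) -> float:
        return float(self.depths()[self.tips].max())

    def tip_index(self) -> dict[str, int]:
        return {self.labels[i]: i for i in self.tips}

    def mrca_matrix(self) -> np.ndarray:
        """n_tips x n_tips matrix of MRCA node ids (tip order = self.tips)."""
        if "mrca" in self._cache:
            return self._cache["mrca"]
        tips = self.tips
        pos = {t: k for k, t in enumerate(tips)}
        n = tips.size
        M = np.zeros((n, n), dtype=int)
        below: dict[int, list[int]] = {}
        for v in self.postorder():
            if not self.children[v]:
                below[v] = [v]
                M[pos[v], pos[v]] = v
            else:
                kids = [below[c] for c in self.children[v]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for x in kids[a]:
                            for y in kids[b]:
                                M[pos[x], pos[y]] = v
                                M[pos[y], pos[x]] = v
                below[v] = [x for lst in kids for x in lst]
        self._cache["mrca"] = M
        return M

    def copy(self) -> "Phylogeny":
        return Phylogeny(
            self.parent.copy(), self.lengths.copy(), list(self.labels), self.root
        )


# -- I/O -------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    labels: list = [None] * len(nodes)
    for nd in nodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            lengths[i] = float(nd.edge.length or 0.0)
        raw = nd.taxon.label if nd.taxon is not None else nd.label
        if raw is not None:
            labels[i] = normalize_name(raw)
    return Phylogeny(parent, lengths, labels, index[id(dtree.seed_node)])


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths, quoted labels supported)."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports row/column in its message
        raise TreeError(f"Newick parse failure: {exc}") from exc
    tree = _from_dendropy(dtree)
    if tree.n_tips == 1:
        warnings.warn("degenerate single-tip tree", stacklevel=2)
    return tree


def read_tree(source: str) -> Phylogeny:
    """Read a tree from a path or a literal string; Newick or Nexus.

    Nexus input is recognised by its ``#NEXUS`` header and the first tree of
    the TREES block is used.
    """
    import os

    text = source
    if os.path.exists(source):
        with open(source) as fh:
            text = fh.read()
    if text.lstrip().upper().startswith("#NEXUS"):
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="nexus", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:
            raise TreeError(f"Nexus parse failure: {exc}") from exc
        return _from_dendropy(dtree)
    return read_newick(text)


def _quote(label: str) -> str:
    if re.search(r"[\s()\[\]{}:;,'\"]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny, node_labels: dict[int, str] | None = None,
                 precision: int = 12) -> str:
    """Serialize to Newick; optional internal-node annotation labels."""
    node_labels = node_labels or {}

    def rec(v: int) -> str:
        if tree.children[v]:
            inner = ",".join(rec(c) for c in tree.children[v])
            lab = node_labels.get(v, "")
            s = f"({inner}){_quote(lab) if lab else ''}"
        else:
            s = _quote(node_labels.get(v, tree.labels[v]))
        if v != tree.root:
            s += f":{tree.lengths[v]:.{precision}g}"
        return s

    return rec(tree.root) + ";"


# -- checks and surgery ----------------------------------------------------


def check_ultrametric(tree: Phylogeny, rel_tol: float = 1e-4):
    """Test equal root-to-tip depths.

    Returns ``(ok, max_relative_deviation, offending_tip_label)`` where the
    deviation is ``max |depth - mean depth| / mean depth``.
    """
    d = tree.depths()[tree.tips]
    mean = float(d.mean())
    if mean <= 0:
        raise TreeError("zero-height tree")
    dev = np.abs(d - mean) / mean
    k = int(np.argmax(dev))
    worst = float(dev[k])
    ok = worst <= rel_tol
    return ok, worst, (None if ok else tree.tip_labels[k])


def prune_to(tree: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on a tip set; unary nodes suppressed, depths preserved."""
    keep = {normalize_name(k) for k in keep}
    have = set(tree.tip_labels)
    unknown = sorted(keep - have)
    if unknown:
        raise TreeError(f"species not in tree: {', '.join(unknown)}")
    if len(keep) < 2:
        raise TreeError("need at least 2 tips to prune to")

    retain = np.zeros(tree.n_nodes, dtype=bool)
    for t in tree.tips:
        if tree.labels[t] in keep:
            retain[t] = True
    for v in tree.postorder():
        if tree.children[v]:
            retain[v] = any(retain[c] for c in tree.children[v])

    # new node records: (parent_new, length, label)
    parent_new: list[int] = []
    lengths_new: list[float] = []
    labels_new: list = []

    def build(v: int, pending: float, parent_id: int) -> None:
        kept_kids = [c for c in tree.children[v] if retain[c]]
        length = pending + (tree.lengths[v] if parent_id != -2 else 0.0)
        if tree.children[v] and len(kept_kids) == 1 and parent_id != -2:
            # unary: merge this branch into the child's
            build(kept_kids[0], length, parent_id)
            return
        my_id = len(parent_new)
        parent_new.append(parent_id)
        lengths_new.append(length if parent_id >= 0 else 0.0)
        labels_new.append(tree.labels[v] if not tree.children[v] else None)
        for c in kept_kids:
            build(c, 0.0, my_id)

    # root of the pruned tree: deepest retained node that has >=2 kept children
    r = tree.root
    while True:
        kept_kids = [c for c in tree.children[r] if retain[c]]
        if len(kept_kids) == 1 and tree.children[r]:
            r = kept_kids[0]
        else:
            break
    build(r, 0.0, -2)
    parent_arr = np.array([p if p >= 0 else -1 for p in parent_new], dtype=int)
    return Phylogeny(parent_arr, np.array(lengths_new), labels_new, 0)


# -- regime painting -------------------------------------------------------


@dataclasses.dataclass
class RegimePainting:
    """One regime label per branch, by the child-node convention.

    ``regime[i]`` is the regime index of the branch above node ``i``; the
    root's slot holds the root regime.
    """

    regime: np.ndarray
    alphabet: tuple[str, ...]
    root_regime: int

    def __post_init__(self):
        self.regime = np.asarray(self.regime, dtype=int)
        if np.any((self.regime < 0) | (self.regime >= len(self.alphabet))):
            raise ValueError("regime index outside the alphabet")

    @property
    def n_regimes(self) -> int:
        return len(self.alphabet)

    def label_of(self, node: int) -> str:
        return self.alphabet[self.regime[node]]

    def branch_counts(self, tree: Phylogeny) -> dict[str, int]:
        counts = {a: 0 for a in self.alphabet}
        for v in range(tree.n_nodes):
            if v != tree.root:
                counts[self.alphabet[self.regime[v]]] += 1
        return counts


def paint_regimes(tree: Phylogeny, node_states: dict,
                  alphabet: tuple[str, ...] = DEFAULT_REGIMES,
                  tip_states: dict | None = None) -> RegimePainting:
    """Paint branches from per-node states (tips observed, internals from ASR).

    ``node_states`` maps every node id to a label in ``alphabet``.  When
    ``tip_states`` (species -> label) is given, tip assignments are checked
    against it.
    """
    idx = {a: i for i, a in enumerate(alphabet)}
    regime = np.zeros(tree.n_nodes, dtype=int)
    for v in range(tree.n_nodes):
        if v not in node_states:
            raise ValueError(f"missing regime state for node {v}")
        st = node_states[v]
        if st not in idx:
            raise ValueError(f"state {st!r} of node {v} not in alphabet {alphabet}")
        regime[v] = idx[st]
    if tip_states is not None:
        obs = {normalize_name(k): v for k, v in tip_states.items()}
        for t in tree.tips:
            lab = tree.labels[t]
            if lab in obs and obs[lab] != node_states[t]:
                raise ValueError(
                    f"tip {lab}: painted {node_states[t]} but observed {obs[lab]}"
                )
    warn_small = [a for a in alphabet
                  if sum(1 for v in range(tree.n_nodes)
                         if v != tree.root and regime[v] == idx[a]) in (1,)]
    if warn_small:
        warnings.warn(
            f"regime(s) on a single branch: {', '.join(warn_small)}", stacklevel=2
        )
    return RegimePainting(regime, tuple(alphabet), regime[tree.root])
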