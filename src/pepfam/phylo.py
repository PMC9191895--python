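"""Distances, neighbor joining, rooting, clade extraction and logos.

Trees over candidate sets are built with canonical Saitou–Nei neighbor
joining on p- or Poisson-corrected distances.  NJ recovers additive
(tree-metric) distances exactly, which is the module's primary oracle: a
random tree's path-length matrix inverts back to the same topology and
branch lengths.

Clades are cut from a rooted tree with an *age cutoff*: the age of a node
is its maximum branch-length path to any descendant leaf, and clades are
the maximal nodes whose age does not exceed the cutoff — every leaf ends
up in exactly one clade.  Bootstrap support comes from column resampling
of the fixed alignment (no realignment).  Occupancy-trimmed sequence-logo
matrices report per-column residue frequencies and information content
IC = log2(20) − H in bits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import Msa, PhyloTree, TreeNode, is_rooted

#: distances are capped here when p-distance saturates (p -> 1)
MAX_DISTANCE = 10.0

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {c: i for i, c in enumerate(_AA20)}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a model tag ('p' or 'poisson')."""

    ids: list[str]
    matrix: np.ndarray
    model: str = "p"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self.ids.index(a), self.ids.index(b)])


@dataclass
class CladeSet:
    """Disjoint monophyletic clades extracted at an age cutoff."""

    clades: list[tuple[str, list[str], float]]
    cutoff: float

    def leaf_to_clade(self) -> dict[str, str]:
        return {leaf: cid for cid, leaves, _ in self.clades for leaf in leaves}

    def __len__(self) -> int:
        return len(self.clades)


@dataclass
class LogoMatrix:
    """Occupancy-trimmed per-column frequencies and information content."""

    frequencies: np.ndarray  # (n_kept, 20), rows sum to 1
    information: np.ndarray  # bits, in [0, log2 20]
    columns: list[int]       # retained source-alignment column indices
    occupancy_min: float

    @property
    def n_columns(self) -> int:
        return len(self.columns)


def msa_distance(msa: Msa, model: str = "p") -> DistanceMatrix:
    """Pairwise p-distances with pairwise gap deletion.

    ``p = mismatches / shared ungapped columns``; under the poisson model
    ``d = -ln(1 - p)``, capped at :data:`MAX_DISTANCE` when p saturates.
    A pair sharing zero ungapped columns is an error naming the pair.
    """
    if msa.n_rows < 2:
        raise ValueError("need >= 2 rows")
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    ids = msa.ids()
    rows = [row for _, row in msa.records]
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = mism = 0
            for a, b in zip(rows[i], rows[j]):
                if a != "-" and b != "-":
                    shared += 1
                    if a != b:
                        mism += 1
            if shared == 0:
                raise ValueError(
                    f"no shared ungapped columns between {ids[i]!r} and {ids[j]!r}"
                )
            p = mism / shared
            if model == "poisson":
                d = MAX_DISTANCE if p >= 1.0 - 1e-9 else min(-math.log(1.0 - p),
                                                             MAX_DISTANCE)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids=ids, matrix=D, model=model)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou–Nei neighbor joining (unrooted).

    Pair choice minimises ``Q(i,j) = (n-2) d(i,j) - r_i - r_j``; ties
    break on the lexicographically smallest id pair (ids of internal
    nodes are the smallest leaf label beneath them).  Negative branch
    lengths are clamped to zero with the subtraction shifted to the
    sister branch.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    D = {i: {j: float(dm.matrix[a, b]) for b, j in enumerate(dm.ids)}
         for a, i in enumerate(dm.ids)}
    nodes: dict[str, TreeNode] = {i: TreeNode(name=i) for i in dm.ids}
    active = sorted(dm.ids)

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i][k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i][j] - r[i] - r[j]
                key = (q, min(i, j), max(i, j))
                if best is None or key < best:
                    best = key
        _, i, j = best
        li = D[i][j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i][j] - li
        li, lj = clamp(li, lj)
        new_id = min(i, j)
        child_i, child_j = nodes.pop(i), nodes.pop(j)
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j] if i < j else [child_j, child_i])
        dij = D[i][j]
        newrow = {k: (D[i][k] + D[j][k] - dij) / 2.0
                  for k in active if k not in (i, j)}
        for k in newrow:
            D[k][new_id] = newrow[k]
        D[new_id] = newrow
        active = sorted(set(active) - {i, j} | {new_id})
        nodes[new_id] = parent

    a, b, c = active
    la = (D[a][b] + D[a][c] - D[b][c]) / 2.0
    lb = (D[a][b] + D[b][c] - D[a][c]) / 2.0
    lc = (D[a][c] + D[b][c] - D[a][b]) / 2.0
    for node, ln in zip((a, b, c), (la, lb, lc)):
        nodes[node].length = max(ln, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    root.length = 0.0
    return root


def root_tree(tree: PhyloTree, outgroup: str | None = None,
              midpoint: bool = False) -> PhyloTree:
    """Root on the outgroup's pendant edge (its midpoint), or at midpoint.

    Total path lengths between any pair of leaves are unchanged.
    """
    if midpoint:
        rooted = _root_at_midpoint(tree)
    else:
        if outgroup is None:
            raise ValueError("need an outgroup leaf or midpoint=True")
        try:
            tip = tree.find(outgroup)
        except Exception as exc:
            raise ValueError(f"outgroup {outgroup!r} not in tree") from exc
        if not tip.is_tip():
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")
        rooted = tree.root_at(tip, above=tip.length / 2.0, reset=True)
    for node in rooted.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return rooted


def _root_at_midpoint(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest tip-to-tip path.

    Handles degenerate trees (zero diameter) by rooting on an arbitrary
    pendant edge, which any midpoint convention permits there.
    """
    tips = list(tree.tips())
    tt = tree.tip_tip_distances()
    best, pair = -1.0, None
    names = [t.name for t in tips]
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if tt[a, b] > best:
                best, pair = tt[a, b], (a, b)
    if best <= 0:
        return tree.root_at(tree.find(names[0]), above=0.0, reset=True)
    a, b = (tree.find(n) for n in pair)
    anc_a = [a] + list(a.ancestors())
    anc_b = set([b] + list(b.ancestors()))
    lca = next(n for n in anc_a if n in anc_b)
    half = best / 2.0
    # walk a -> lca, then lca -> b, hunting the edge holding the midpoint
    path: list = []
    node = a
    while node is not lca:
        path.append(node)
        node = node.parent
    down = []
    node = b
    while node is not lca:
        down.append(node)
        node = node.parent
    path.extend(reversed(down))
    down_set = set(down)
    cum = 0.0
    for node in path:
        length = node.length or 0.0
        if cum + length >= half - 1e-12:
            # 'above' is measured rootward from the node on its own branch;
            # down-phase edges are entered from their rootward end
            above = (length - (half - cum)) if node in down_set else (half - cum)
            above = min(max(above, 0.0), length)
            return tree.root_at(node, above=above, reset=True)
        cum += length
    return tree.root_at(path[-1], above=(path[-1].length or 0.0), reset=True)


def node_ages(tree: PhyloTree) -> dict[int, float]:
    """Max branch-length path from each node to its descendant leaves."""
    ages: dict[int, float] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            ages[id(node)] = 0.0
        else:
            ages[id(node)] = max(
                ages[id(c)] + (c.length or 0.0) for c in node.children
            )
    return ages


def clades_by_age(tree: PhyloTree, cutoff: float) -> CladeSet:
    """Maximal clades whose age (max root-ward depth) is <= cutoff.

    The tree must be rooted; every leaf falls in exactly one clade (a
    singleton leaf qualifies at age 0).
    """
    if not is_rooted(tree):
        raise ValueError("clade extraction requires a rooted tree")
    ages = node_ages(tree)
    clades: list[tuple[str, list[str], float]] = []

    def walk(node) -> None:
        if ages[id(node)] <= cutoff:
            leaves = sorted(t.name for t in node.tips()) if not node.is_tip() \
                else [node.name]
            clades.append((f"clade{len(clades) + 1}", leaves, ages[id(node)]))
            return
        for child in node.children:
            walk(child)

    walk(tree)
    return CladeSet(clades=clades, cutoff=cutoff)


# ---------------------------------------------------------------------------
# Bootstrap


def _bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions as frozensets of leaf-name sides."""
    all_leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(frozenset((side, all_leaves - side)))
    return out


def bootstrap_support(msa: Msa, n_replicates: int = 100, rng_seed: int = 0,
                      model: str = "p") -> tuple[PhyloTree, dict[frozenset, float]]:
    """Column-resampling bootstrap of the NJ tree.

    Returns the reference tree plus support (fraction of replicates
    containing each internal bipartition of the reference).
    """
    if n_replicates < 1:
        raise ValueError("need >= 1 replicate")
    if msa.n_rows < 4:
        raise ValueError("bootstrap needs >= 4 sequences (no internal edges)")
    ref = nj_tree(msa_distance(msa, model))
    ref_bip = _bipartitions(ref)
    counts = {b: 0 for b in ref_bip}
    rng = np.random.default_rng(rng_seed)
    n_cols = msa.n_cols
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = Msa([
            (rid, "".join(row[c] for c in cols)) for rid, row in msa.records
        ])
        rep_bip = _bipartitions(nj_tree(msa_distance(rep, model)))
        for b in ref_bip & rep_bip:
            counts[b] += 1
    return ref, {b: c / n_replicates for b, c in counts.items()}


# ---------------------------------------------------------------------------
# Sequence logo


def sequence_logo(msa: Msa, occupancy_min: float = 0.05) -> LogoMatrix:
    """Occupancy-trimmed residue frequencies and information content.

    Columns whose non-gap occupancy is strictly below ``occupancy_min``
    are removed; frequencies are over non-gap standard residues and
    ``IC = log2(20) - H`` per retained column.
    """
    if msa.n_rows == 0:
        raise ValueError("empty alignment")
    kept, freqs, ics = [], [], []
    n = msa.n_rows
    for j in range(msa.n_cols):
        col = msa.column(j)
        nongap = [c for c in col if c != "-"]
        if len(nongap) / n < occupancy_min:
            continue
        counts = np.zeros(20)
        for c in nongap:
            k = _AA_INDEX.get(c)
            if k is not None:
                counts[k] += 1
        if counts.sum() == 0:
            continue
        p = counts / counts.sum()
        nz = p[p > 0]
        h = -(nz * np.log2(nz)).sum()
        kept.append(j)
        freqs.append(p)
        ics.append(math.log2(20) - h)
    if not kept:
        raise ValueError("all columns trimmed from the logo")
    return LogoMatrix(
        frequencies=np.vstack(freqs), information=np.array(ics),
        columns=kept, occupancy_min=occupancy_min,
    )
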