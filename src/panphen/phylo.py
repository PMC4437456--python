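"""Strain phylogeny and the Brownian-motion trait covariance.

The association stage needs a rooted tree with branch lengths for the
strain panel.  The faithful path is a user-supplied newick (for example a
maximum-likelihood tree computed with an external tool); the self-contained
fallback builds a distance tree: mean per-site p-distances over
single-copy representatives of the core clusters, neighbor joining, then
midpoint rooting.

Under Brownian motion on a rooted tree, the expected covariance of a
continuous character between two strains is proportional to the shared
branch length from the root down to their most recent common ancestor;
``bm_covariance`` assembles that matrix.  It is used unnormalized — the
Brownian rate is absorbed into the residual variance of the generalized
least-squares fit, whose p-values are invariant to rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "BMCovariance", "core_distance_matrix",
           "neighbor_joining", "midpoint_root", "bm_covariance",
           "read_tree", "write_tree"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    strains: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.strains)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match strains")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains,
                            columns=self.strains)


@dataclass
class BMCovariance:
    """Expected Brownian-motion covariance of a trait over the panel.

    ``V[i, j]`` is the root-to-MRCA path length of leaves i and j; the
    diagonal holds root-to-leaf depths.
    """

    strains: list[str]
    values: np.ndarray

    def restrict(self, strains: Sequence[str]) -> "BMCovariance":
        idx = [self.strains.index(s) for s in strains]
        return BMCovariance(list(strains), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains,
                            columns=self.strains)


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _p_distance(a: str, b: str, aligner: Align.PairwiseAligner) -> float:
    """Mismatches over aligned (non-gap) columns of a global alignment."""
    if a == b:
        return 0.0
    counts = aligner.align(a, b)[0].counts()
    aligned = counts.identities + counts.mismatches
    return counts.mismatches / aligned if aligned else 1.0


def core_distance_matrix(core_sequences: Mapping[str, Mapping[str, str | Sequence[str]]],
                         strains: Sequence[str] | None = None,
                         ) -> DistanceMatrix:
    """Average per-cluster pairwise p-distances over the core genome.

    ``core_sequences`` maps cluster id -> strain -> protein sequence (or a
    list of paralogous sequences, of which the longest represents the
    strain).  Clusters missing any panel strain are skipped with a
    warning; each remaining cluster contributes with equal weight.
    """
    if strains is None:
        panel: list[str] = sorted({s for seqs in core_sequences.values()
                                   for s in seqs})
    else:
        panel = list(strains)
    n = len(panel)
    aligner = _global_aligner()
    total = np.zeros((n, n))
    used = 0
    for cid, by_strain in core_sequences.items():
        if not set(panel) <= set(by_strain):
            logger.warning("core cluster %s missing strains %s; skipped",
                           cid, sorted(set(panel) - set(by_strain)))
            continue
        reps = []
        for s in panel:
            seq = by_strain[s]
            if not isinstance(seq, str):
                seq = max(seq, key=len)
            reps.append(seq)
        for i in range(n):
            for j in range(i + 1, n):
                d = _p_distance(reps[i], reps[j], aligner)
                total[i, j] += d
                total[j, i] += d
        used += 1
    if used == 0:
        raise ValueError("no core cluster covers the full strain panel")
    return DistanceMatrix(panel, total / used)


def _newick_escape(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining, returned as an unrooted dendropy tree.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling branch (the pair's total is preserved).  Joins are
    tie-broken on leaf labels, so taxon order does not affect the result.
    """
    n = len(dm.strains)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    # active nodes: newick fragment + smallest leaf label as sort key
    nodes = [( _newick_escape(s), s) for s in dm.strains]
    d = {}
    for i in range(n):
        for j in range(i + 1, n):
            d[frozenset((i, j))] = dm.values[i, j]
    active = list(range(n))
    next_id = n
    frags = {i: nodes[i][0] for i in active}
    keys = {i: nodes[i][1] for i in active}

    def dist(a: int, b: int) -> float:
        return d[frozenset((a, b))]

    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1:]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                tie = tuple(sorted((keys[a], keys[b])))
                cand = (q, tie, a, b)
                if best is None or cand < best:
                    best = cand
        _, _, a, b = best
        if keys[b] < keys[a]:
            a, b = b, a
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        u = next_id
        next_id += 1
        frags[u] = f"({frags[a]}:{la:.12g},{frags[b]}:{lb:.12g})"
        keys[u] = min(keys[a], keys[b])
        for k in active:
            if k in (a, b):
                continue
            d[frozenset((u, k))] = 0.5 * (dist(a, k) + dist(b, k) - dab)
        active = [k for k in active if k not in (a, b)] + [u]

    a, b = sorted(active, key=lambda i: keys[i])
    dab = dist(a, b) if len(active) == 2 else 0.0
    if a >= n or b >= n:
        # attach the remaining subtree under the internal node with the
        # full joining branch (standard trifurcating unrooted output)
        internal, other = (a, b) if a >= n else (b, a)
        newick = frags[internal][:-1] + f",{frags[other]}:{dab:.12g});"
    else:  # two taxa only: split the single branch evenly
        newick = f"({frags[a]}:{dab / 2:.12g},{frags[b]}:{dab / 2:.12g});"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path."""
    import itertools

    rooted = tree.clone(depth=1)
    pdm = rooted.phylogenetic_distance_matrix()
    max_d = max((pdm.distance(t1, t2) for t1, t2 in
                 itertools.combinations(rooted.taxon_namespace, 2)),
                default=0.0)
    if max_d <= 0:
        logger.warning("all branch lengths are zero; rooting at the current "
                       "seed node")
        rooted.is_rooted = True
        return rooted
    # already midpoint-rooted? (max seed-to-leaf depth equals half the
    # longest path) -- rerooting again would be a no-op
    depth = {id(rooted.seed_node): 0.0}
    max_depth = 0.0
    for node in rooted.preorder_node_iter():
        if node is rooted.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (
            node.edge.length or 0.0)
        if node.is_leaf():
            max_depth = max(max_depth, depth[id(node)])
    if abs(max_depth - max_d / 2) < 1e-12:
        rooted.is_rooted = True
        return rooted
    rooted.reroot_at_midpoint(update_bipartitions=True)
    rooted.is_rooted = True
    return rooted


def bm_covariance(tree: dendropy.Tree,
                  strains: Sequence[str] | None = None) -> BMCovariance:
    """Shared root-to-MRCA path lengths for all leaf pairs.

    Requires a rooted tree (run :func:`midpoint_root` first for trees read
    from unrooted newick).
    """
    if not tree.is_rooted:
        raise ValueError("bm_covariance needs a rooted tree; apply "
                         "midpoint_root (or supply a rooted newick) first")
    # node depths from the root (the root's own edge, if any, is ignored)
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (
            node.edge.length or 0.0)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    if strains is not None:
        order = {s: i for i, s in enumerate(strains)}
        missing = set(strains) - set(labels)
        if missing:
            raise ValueError(f"strains absent from the tree: {sorted(missing)}")
        pairs = sorted((lf for lf in leaves if lf.taxon.label in order),
                       key=lambda lf: order[lf.taxon.label])
        leaves = pairs
        labels = [lf.taxon.label for lf in leaves]
    # ancestor chains
    chains = []
    for lf in leaves:
        chain = []
        node = lf
        while node is not None:
            chain.append(id(node))
            node = node.parent_node
        chains.append(set(chain))
    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        V[i, i] = depth[id(leaves[i])]
        node_sets = chains[i]
        for j in range(i + 1, n):
            # deepest common ancestor
            common = node_sets & chains[j]
            V[i, j] = V[j, i] = max(depth[x] for x in common)
    return BMCovariance(labels, V)


def read_tree(path: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    if rooted is not None:
        tree.is_rooted = rooted
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               unquoted_underscores=True, suppress_rooting=False)
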