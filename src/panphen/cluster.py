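"""Orthologue clustering by filtered single-linkage over all-vs-all hits.

Proteins are grouped into clusters of putative orthologues by taking the
connected components of the graph whose edges are protein pairs with a
similarity hit passing three filters: e-value <= ``evalue_max``, percent
identity >= ``identity_min`` and alignment coverage >= ``coverage_min`` on
*both* sequences (the minimum of query and subject coverage is compared to
the threshold — the strictest symmetric reading, which keeps the graph
undirected).  The identity and coverage thresholds are chosen by an
exhaustive grid search (by default 70..100 in steps of 2) maximizing the
number of *core* clusters, i.e. clusters with at least one member in every
strain of the panel.

For small panels the all-vs-all comparison can be computed internally with
a Smith-Waterman aligner (BLOSUM62, gap open -11 / extend -1); for anything
beyond a few thousand proteins, ingest external tabular hits through
:func:`panphen.io.read_similarity_hits` instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ProteinRecord", "SimilarityHit", "ThresholdGrid", "Cluster",
    "ClusterSet", "GridSearchResult", "align_pair", "compute_pairwise_hits",
    "filter_hits", "single_linkage_cluster", "count_core_clusters",
    "grid_search_thresholds",
]

# Karlin-Altschul parameters used for the internal aligner's e-values
# (gapped BLOSUM62 defaults; external hits carry their own e-values).
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass(frozen=True)
class ProteinRecord:
    """One predicted protein of one strain."""

    protein_id: str
    strain_id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: length must be >= 1")


@dataclass(frozen=True)
class SimilarityHit:
    """A pairwise local-alignment hit between two proteins.

    Coverages are derived, not stored: alignment columns over the
    respective sequence length, as a percentage.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_length: int
    evalue: float
    query_length: int
    subject_length: int
    bitscore: float = 0.0

    @property
    def query_coverage(self) -> float:
        return 100.0 * self.aln_length / self.query_length

    @property
    def subject_coverage(self) -> float:
        return 100.0 * self.aln_length / self.subject_length

    @property
    def min_coverage(self) -> float:
        return min(self.query_coverage, self.subject_coverage)

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id


@dataclass(frozen=True)
class ThresholdGrid:
    """The identity x coverage grid scanned by the threshold search."""

    identity: tuple[float, ...] = tuple(range(70, 101, 2))
    coverage: tuple[float, ...] = tuple(range(70, 101, 2))

    def __post_init__(self) -> None:
        for name, vals in (("identity", self.identity),
                           ("coverage", self.coverage)):
            if not vals:
                raise ValueError(f"{name} grid is empty")
            if any(not 0 <= v <= 100 for v in vals):
                raise ValueError(f"{name} grid values must lie in [0, 100]")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} grid must be strictly increasing")

    @classmethod
    def from_range(cls, lo: float, hi: float, step: float) -> "ThresholdGrid":
        if not (0 < lo <= hi <= 100 and step > 0):
            raise ValueError("need 0 < lo <= hi <= 100 and step > 0")
        vals = []
        v = lo
        while v <= hi + 1e-9:
            vals.append(round(v, 6))
            v += step
        return cls(tuple(vals), tuple(vals))


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: tuple[str, ...]          # protein ids, sorted
    strain_counts: Mapping[str, int]  # strain -> copy count

    @property
    def strains(self) -> frozenset[str]:
        return frozenset(self.strain_counts)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ClusterSet:
    """A partition of all input proteins into orthologue clusters."""

    clusters: list[Cluster]
    protein_strain: Mapping[str, str]
    identity_min: float | None = None
    coverage_min: float | None = None
    evalue_max: float | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.clusters:
            if not c.members:
                raise ValueError(f"cluster {c.cluster_id} is empty")
            overlap = seen.intersection(c.members)
            if overlap:
                raise ValueError(f"proteins in several clusters: {overlap}")
            seen.update(c.members)
        missing = set(self.protein_strain) - seen
        if missing:
            raise ValueError(f"proteins not covered by any cluster: {missing}")

    def __len__(self) -> int:
        return len(self.clusters)

    def partition(self) -> list[frozenset[str]]:
        return [frozenset(c.members) for c in self.clusters]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "local"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_pair(a: ProteinRecord, b: ProteinRecord,
               aligner: Align.PairwiseAligner | None = None) -> SimilarityHit:
    """Smith-Waterman alignment of two proteins, reported as a hit.

    Identity is matches over alignment columns (gap columns included);
    the e-value follows the Karlin-Altschul formula
    ``E = K * m * n * exp(-lambda * S)`` with the module constants.
    """
    if a.sequence is None or b.sequence is None:
        raise ValueError("align_pair needs sequences on both records")
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a.sequence, b.sequence)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    evalue = KA_K * a.length * b.length * math.exp(-KA_LAMBDA * aln.score)
    bitscore = (KA_LAMBDA * aln.score - math.log(KA_K)) / math.log(2)
    return SimilarityHit(
        query_id=a.protein_id, subject_id=b.protein_id,
        identity=identity, aln_length=columns, evalue=evalue,
        query_length=a.length, subject_length=b.length, bitscore=bitscore,
    )


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def compute_pairwise_hits(proteins: Sequence[ProteinRecord],
                          kmer: int = 4,
                          include_self: bool = True,
                          ) -> list[SimilarityHit]:
    """All-vs-all local alignments after a shared k-mer prefilter.

    Pairs sharing no exact ``kmer``-mer are skipped; unrelated sequences
    would not survive the identity/coverage filters anyway.  Intended for
    desk-scale panels (<= ~5000 proteins); larger panels should ingest
    external search output.
    """
    aligner = _make_aligner()
    hits: list[SimilarityHit] = []
    kmer_sets = [_kmers(p.sequence or "", kmer) for p in proteins]
    for i, a in enumerate(proteins):
        if include_self:
            hits.append(align_pair(a, a, aligner))
        for j in range(i + 1, len(proteins)):
            if kmer_sets[i].isdisjoint(kmer_sets[j]):
                continue
            hits.append(align_pair(a, proteins[j], aligner))
    return hits


def filter_hits(hits: Iterable[SimilarityHit],
                identity_min: float,
                coverage_min: float,
                evalue_max: float,
                require_both_directions: bool = False,
                ) -> set[tuple[str, str]]:
    """Reduce hits to the undirected edges passing all three filters.

    An edge (a, b) is kept when *some* hit in either direction satisfies
    e-value <= ``evalue_max``, identity >= ``identity_min`` and
    min(query, subject coverage) >= ``coverage_min``.  With
    ``require_both_directions`` a passing hit must exist in each
    direction.  Self-hits never produce edges.
    """
    passing: dict[tuple[str, str], set[str]] = {}
    for h in hits:
        if h.is_self:
            continue
        if (h.evalue <= evalue_max and h.identity >= identity_min
                and h.min_coverage >= coverage_min):
            key = (min(h.query_id, h.subject_id),
                   max(h.query_id, h.subject_id))
            passing.setdefault(key, set()).add(h.query_id)
    if require_both_directions:
        return {k for k, dirs in passing.items() if len(dirs) == 2}
    return set(passing)


def single_linkage_cluster(edges: Iterable[tuple[str, str]],
                           proteins: Sequence[ProteinRecord],
                           ) -> ClusterSet:
    """Connected components of the edge graph; edge-less proteins become
    singleton clusters.  Output is deterministic: members sorted within a
    cluster, clusters ordered by decreasing size then first member."""
    strain_of = {p.protein_id: p.strain_id for p in proteins}
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(strain_of)
    for a, b in edges:
        if a not in strain_of or b not in strain_of:
            raise ValueError(f"edge endpoint not a known protein: {(a, b)}")
        graph.add_edge(a, b)
    components = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    width = max(5, len(str(len(components))))
    clusters = []
    for i, members in enumerate(components, 1):
        counts: dict[str, int] = {}
        for m in members:
            counts[strain_of[m]] = counts.get(strain_of[m], 0) + 1
        clusters.append(Cluster(f"OC{i:0{width}d}", members, counts))
    return ClusterSet(clusters, strain_of)


def count_core_clusters(clusters: ClusterSet,
                        strains: Sequence[str]) -> int:
    """Number of clusters with at least one member in every panel strain."""
    panel = set(strains)
    unknown = set(clusters.protein_strain.values()) - panel
    if unknown:
        raise ValueError(f"proteins from strains outside the panel: {unknown}")
    return sum(1 for c in clusters.clusters if c.strains == panel)


@dataclass
class GridSearchResult:
    identity: float
    coverage: float
    clusters: ClusterSet
    core_counts: "pd.DataFrame"  # identity (rows) x coverage (cols)


def grid_search_thresholds(hits: Sequence[SimilarityHit],
                           proteins: Sequence[ProteinRecord],
                           strains: Sequence[str],
                           grid: ThresholdGrid | None = None,
                           evalue_max: float = 1e-3,
                           require_both_directions: bool = False,
                           ) -> GridSearchResult:
    """Cluster at every grid point and keep the core-maximizing thresholds.

    Ties are broken towards the larger identity, then larger coverage
    (the most stringent of the tied optima).
    """
    import pandas as pd

    if grid is None:
        grid = ThresholdGrid()
    # pre-reduce: per unordered pair, the (identity, min_coverage) pairs of
    # hits passing the e-value filter, per direction
    table = pd.DataFrame(0, index=list(grid.identity),
                         columns=list(grid.coverage), dtype=int)
    best: tuple[int, float, float] | None = None
    best_clusters: ClusterSet | None = None
    for ident in grid.identity:
        for cov in grid.coverage:
            edges = filter_hits(hits, ident, cov, evalue_max,
                                require_both_directions)
            cs = single_linkage_cluster(edges, proteins)
            cs.identity_min, cs.coverage_min, cs.evalue_max = (
                ident, cov, evalue_max)
            n_core = count_core_clusters(cs, strains)
            table.loc[ident, cov] = n_core
            key = (n_core, ident, cov)
            if best is None or key > best:
                best, best_clusters = key, cs
    assert best is not None and best_clusters is not None
    return GridSearchResult(best[1], best[2], best_clusters, table)
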