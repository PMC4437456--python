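"""Synthetic strain panels with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes for a dairy-bacterium strain panel: a pure-birth (Yule) strain
phylogeny; a core genome shared by every strain; accessory genes gained at
Poisson events on branches and lost at a constant rate thereafter; a
multi-gene *causal island* inherited as a block by one clade, which
determines a binary trait; optional nonsense mutations that pseudogenize
causal genes and degrade a quantitative trait scored on the API 50CH-style
0..1 grid in steps of 0.25; and per-strain protein/CDS/genome FASTA whose
orthologues sit at a controlled protein identity and whose island genes
carry a shifted GC content (synonymous-codon reweighting, so the protein
sequences are unaffected and island detection must work from DNA alone).

Everything is deterministic given the seed.  The generated truth
(:class:`SimTruth`) lets recovery tests score the pipeline end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import PhenotypeTable
from .pangenome import PresenceAbsenceMatrix

__all__ = ["SimConfig", "SimTruth", "SimPanel", "simulate_tree",
           "simulate_gene_content", "plant_causal_island",
           "plant_premature_stop", "simulate_phenotypes", "emit_sequences",
           "simulate_panel"]

SCORE_GRID_STEP = 0.25


@dataclass(frozen=True)
class SimConfig:
    """Generative knobs for a synthetic strain panel.

    Defaults describe the study conditions the pipeline targets: a
    22-strain panel, a causal island of 3 genes against 200 decoy
    accessory clusters, orthologues near 85% protein identity, a 67%-GC
    background genome with the island 10 points lower.
    """

    n_strains: int = 22
    birth_rate: float = 1.0
    n_core: int = 100
    gain_rate: float = 20.0
    loss_rate: float = 1.0
    n_decoy_accessory: int | None = 200
    island_size: int = 3
    island_gc_offset: float = -10.0
    background_gc: float = 67.0
    ortholog_identity_target: float = 85.0
    nonsense_fraction: float = 0.0
    cds_codons: tuple[int, int] = (300, 1500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")
        if min(self.birth_rate, self.gain_rate, self.loss_rate) < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.ortholog_identity_target <= 100:
            raise ValueError("ortholog_identity_target must be in [0, 100]")
        if not 0 <= self.nonsense_fraction <= 1:
            raise ValueError("nonsense_fraction must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulated panel."""

    tree: dendropy.Tree
    causal_cluster_ids: set[str] = field(default_factory=set)
    strains_with_island: set[str] = field(default_factory=set)
    planted_stops: list[tuple[str, str, int]] = field(default_factory=list)
    true_phenotypes: PhenotypeTable | None = None
    gene_codons: dict[str, int] = field(default_factory=dict)


class _Node:
    __slots__ = ("parent", "children", "blen", "label")

    def __init__(self, parent=None):
        self.parent = parent
        self.children: list[_Node] = []
        self.blen = 0.0
        self.label: str | None = None


def _yule(n_strains: int, birth_rate: float,
          rng: np.random.Generator) -> _Node:
    root = _Node()
    root.children = [_Node(root), _Node(root)]
    active = list(root.children)
    while len(active) < n_strains:
        k = len(active)
        wait = rng.exponential(1.0 / (k * birth_rate))
        for nd in active:
            nd.blen += wait
        pick = active.pop(int(rng.integers(k)))
        pick.children = [_Node(pick), _Node(pick)]
        active.extend(pick.children)
    wait = rng.exponential(1.0 / (n_strains * birth_rate))
    for nd in active:
        nd.blen += wait
    # label leaves in traversal order
    width = max(3, len(str(n_strains)))
    counter = [0]

    def label(nd: _Node) -> None:
        if not nd.children:
            counter[0] += 1
            nd.label = f"strain_{counter[0]:0{width}d}"
        for c in nd.children:
            label(c)

    label(root)
    return root


def _to_newick(nd: _Node) -> str:
    if not nd.children:
        return f"{nd.label}:{nd.blen:.12g}"
    inner = ",".join(_to_newick(c) for c in nd.children)
    return (f"({inner}):{nd.blen:.12g}" if nd.parent is not None
            else f"({inner});")


def simulate_tree(n_strains: int, birth_rate: float = 1.0,
                  seed: int = 0) -> dendropy.Tree:
    """Rooted ultrametric Yule tree with leaves ``strain_001``..

    Lineages split at rate ``birth_rate`` each; the simulation stops when
    ``n_strains`` lineages exist and adds a final exponential epoch, so
    the expected root-to-tip depth is sum(1/(k*birth_rate)) for
    k = 2..n_strains.
    """
    if n_strains < 2:
        raise ValueError("n_strains must be >= 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    root = _yule(n_strains, birth_rate, rng)
    tree = dendropy.Tree.get(data=_to_newick(root), schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True
    return tree


def _edges(tree: dendropy.Tree):
    """(node, branch length) for every non-root node, preorder."""
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        yield node, (node.edge.length or 0.0)


def _survivors(node, remaining: float, loss_rate: float,
               rng: np.random.Generator) -> list[str]:
    """Leaves reached from a gain point without a loss event on the way."""
    if loss_rate > 0 and rng.exponential(1.0 / loss_rate) < remaining:
        return []
    if node.is_leaf():
        return [node.taxon.label]
    out: list[str] = []
    for child in node.child_nodes():
        out.extend(_survivors(child, child.edge.length or 0.0,
                              loss_rate, rng))
    return out


def simulate_gene_content(tree: dendropy.Tree, n_core: int,
                          gain_rate: float, loss_rate: float,
                          seed: int = 0,
                          n_accessory: int | None = None,
                          ) -> PresenceAbsenceMatrix:
    """Core columns plus accessory genes from a gain/loss process.

    Gains arise as a Poisson process at rate ``gain_rate`` per unit branch
    length (or, with ``n_accessory``, exactly that many gain events placed
    proportionally to branch length, i.e. the Poisson process conditioned
    on its total).  A gained gene is carried by the leaves below its gain
    point minus lineages that experience a loss event (rate
    ``loss_rate``).  Genes lost everywhere are discarded (resampled in
    fixed-count mode), so every column has at least one presence.
    """
    rng = np.random.default_rng(seed)
    strains = [lf.taxon.label for lf in tree.leaf_node_iter()]
    edges = list(_edges(tree))
    lengths = np.array([b for _, b in edges])
    patterns: list[list[str]] = []
    if n_accessory is None:
        for node, blen in edges:
            for _ in range(rng.poisson(gain_rate * blen)):
                pos = rng.uniform(0.0, blen)
                leaves = _survivors(node, blen - pos, loss_rate, rng)
                if leaves:
                    patterns.append(leaves)
    else:
        if lengths.sum() <= 0:
            raise ValueError("tree has no positive branch length")
        probs = lengths / lengths.sum()
        while len(patterns) < n_accessory:
            k = int(rng.choice(len(edges), p=probs))
            node, blen = edges[k]
            pos = rng.uniform(0.0, blen)
            leaves = _survivors(node, blen - pos, loss_rate, rng)
            if leaves:
                patterns.append(leaves)
    core_ids = [f"core{i:05d}" for i in range(1, n_core + 1)]
    acc_ids = [f"acc{i:05d}" for i in range(1, len(patterns) + 1)]
    mat = pd.DataFrame(0, index=strains, columns=core_ids + acc_ids,
                       dtype=int)
    if core_ids:
        mat[core_ids] = 1
    for cid, leaves in zip(acc_ids, patterns):
        mat.loc[leaves, cid] = 1
    return PresenceAbsenceMatrix(mat, mat.copy())


def plant_causal_island(pa: PresenceAbsenceMatrix, tree: dendropy.Tree,
                        island_size: int, seed: int = 0,
                        min_outside: int = 2,
                        ) -> tuple[PresenceAbsenceMatrix, SimTruth]:
    """Append ``island_size`` co-inherited columns under one internal branch.

    The island pattern is the leaf set of a uniformly chosen internal
    (non-root) node whose clade leaves at least ``min_outside`` strains
    outside it, mirroring a horizontally acquired genomic island fixed in
    one clade.  Star trees have no internal branch and are rejected.
    """
    rng = np.random.default_rng(seed)
    n = pa.n_strains
    candidates = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        if 2 <= len(leaves) <= n - min_outside:
            candidates.append(leaves)
    if not candidates:
        raise ValueError("tree has no suitable internal branch to carry "
                         "the island (star tree?)")
    leaves = candidates[int(rng.integers(len(candidates)))]
    ids = [f"isl{i:03d}" for i in range(1, island_size + 1)]
    presence = pa.presence.copy()
    copies = pa.copy_count.copy()
    for cid in ids:
        presence[cid] = 0
        presence.loc[leaves, cid] = 1
        copies[cid] = presence[cid]
    truth = SimTruth(tree=tree, causal_cluster_ids=set(ids),
                     strains_with_island=set(leaves))
    return PresenceAbsenceMatrix(presence, copies), truth


def plant_premature_stop(cds: str, codon_index: int) -> str:
    """Replace the (1-based) ``codon_index``-th codon by TAA.

    The index must point at an internal codon: neither the start codon
    nor the terminal stop.
    """
    if len(cds) % 3:
        raise ValueError("coding sequence length must be divisible by 3")
    n_codons = len(cds) // 3
    if not 1 < codon_index < n_codons:
        raise ValueError(
            f"codon_index must be internal (2..{n_codons - 1}), "
            f"got {codon_index}")
    i = (codon_index - 1) * 3
    return cds[:i] + "TAA" + cds[i + 3:]


def _quantize_down(x: float) -> float:
    return math.floor(x / SCORE_GRID_STEP + 1e-9) * SCORE_GRID_STEP


def _bm_character(tree: dendropy.Tree, strains: Sequence[str],
                  rng: np.random.Generator) -> pd.Series:
    value = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        blen = node.edge.length or 0.0
        value[id(node)] = (value[id(node.parent_node)]
                          + rng.normal(0.0, math.sqrt(blen)) if blen > 0
                          else value[id(node.parent_node)])
    leaf_vals = {lf.taxon.label: value[id(lf)]
                 for lf in tree.leaf_node_iter()}
    return pd.Series([leaf_vals[s] for s in strains], index=list(strains))


def simulate_phenotypes(truth: SimTruth, pa: PresenceAbsenceMatrix,
                        nonsense_fraction: float = 0.0, seed: int = 0,
                        ) -> tuple[PhenotypeTable, SimTruth]:
    """Derive trait scores from the planted island, planting gene decay.

    Nonsense mutations are planted only in causal genes of island-carrying
    strains: each (strain, causal gene) copy is hit with probability
    ``nonsense_fraction``, at a codon drawn uniformly from the central 80%
    of the gene.  Three traits are emitted:

    * ``island_trait`` — 1 iff the strain carries every causal cluster and
      none of its causal copies is pseudogenized;
    * ``island_activity`` — functional causal copies over island size,
      quantized *down* to the 0.25 grid;
    * ``null_bm`` — an independent Brownian-motion character thresholded
      at its median, carrying phylogenetic signal but no causal gene.
    """
    rng = np.random.default_rng(seed)
    strains = pa.strains
    causal = sorted(truth.causal_cluster_ids)
    if not causal:
        raise ValueError("truth has no causal island")
    for cid in causal:
        if cid not in truth.gene_codons:
            truth.gene_codons[cid] = int(rng.integers(300, 1501))
    stops = list(truth.planted_stops)
    if nonsense_fraction > 0:
        for s in sorted(truth.strains_with_island):
            for cid in causal:
                if pa.presence.loc[s, cid] and rng.random() < nonsense_fraction:
                    n_cod = truth.gene_codons[cid]
                    lo = max(2, int(0.1 * n_cod))
                    hi = min(n_cod - 1, int(0.9 * n_cod))
                    stops.append((s, cid, int(rng.integers(lo, hi + 1))))
    truth.planted_stops = stops
    broken = {(s, c) for s, c, _ in stops}
    binary, quant = [], []
    for s in strains:
        functional = sum(
            1 for cid in causal
            if pa.presence.loc[s, cid] and (s, cid) not in broken)
        binary.append(1.0 if functional == len(causal) else 0.0)
        quant.append(_quantize_down(functional / len(causal)))
    null_char = _bm_character(truth.tree, strains, rng)
    null = (null_char > null_char.median()).astype(float)
    table = PhenotypeTable(pd.DataFrame(
        {"island_trait": binary, "island_activity": quant,
         "null_bm": null.to_numpy()},
        index=strains))
    truth.true_phenotypes = table
    return table, truth


# ---------------------------------------------------------------------------
# sequence emission

_BASES = "ACGT"
_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# ancestral amino-acid usage biased towards Ala/Gly/Pro/Arg, as in high-GC
# actinobacterial proteomes; without this bias a 67% GC target would sit
# outside the range synonymous codon choice can reach
_AA_WEIGHTS = np.array([3.0 if aa in "AGPR" else 1.0 for aa in _AA_ALPHABET])
_AA_PROBS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


def _codon_choices(table_id: int = 11) -> dict[str, list[tuple[str, int]]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[tuple[str, int]]] = {}
    for codon, aa in table.forward_table.items():
        gc = sum(1 for b in codon if b in "GC")
        by_aa.setdefault(aa, []).append((codon, gc))
    for options in by_aa.values():
        options.sort()
    return by_aa


_CODONS = _codon_choices()


def _solve_gc_lambda(aa_counts: Mapping[str, int], target_fraction: float,
                     ) -> float:
    """Bisection for the synonymous-codon reweighting exponent.

    Codon weights are exp(lam * gc_of_codon); the expected GC fraction of
    the whole CDS is monotone in lam, so bisection pins the exponent that
    matches ``target_fraction`` (clipped to the attainable range).
    """

    def expected_gc(lam: float) -> float:
        num = den = 0.0
        for aa, count in aa_counts.items():
            options = _CODONS[aa]
            ws = [math.exp(lam * gc) for _, gc in options]
            z = sum(ws)
            e = sum(w * gc for w, (_, gc) in zip(ws, options)) / z
            num += count * e
            den += count * 3
        return num / den

    lo, hi = -30.0, 30.0
    if expected_gc(hi) <= target_fraction:
        return hi
    if expected_gc(lo) >= target_fraction:
        return lo
    for _ in range(60):
        mid = (lo + hi) / 2
        if expected_gc(mid) < target_fraction:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _protein_to_cds(protein: str, gc_target: float,
                    rng: np.random.Generator) -> str:
    counts: dict[str, int] = {}
    for aa in protein:
        counts[aa] = counts.get(aa, 0) + 1
    lam = _solve_gc_lambda(counts, gc_target / 100.0)
    # sample synonymous codons per residue class in one vectorized draw
    positions: dict[str, list[int]] = {}
    for i, aa in enumerate(protein):
        positions.setdefault(aa, []).append(i)
    codons: list[str] = [""] * len(protein)
    for aa, idxs in positions.items():
        options = _CODONS[aa]
        w = np.array([math.exp(lam * gc) for _, gc in options])
        cum = np.cumsum(w / w.sum())
        picks = np.searchsorted(cum, rng.random(len(idxs)))
        for i, k in zip(idxs, picks):
            codons[i] = options[min(int(k), len(options) - 1)][0]
    return "".join(codons) + "TAA"


@dataclass
class GeneSequence:
    gene_id: str
    strain_id: str
    cluster_id: str
    protein: str
    cds: str


@dataclass
class SimSequences:
    """Per-strain emitted sequences; genome holds the concatenated DNA."""

    genes: dict[str, list[GeneSequence]]           # strain -> genes
    genomes: dict[str, str]                        # strain -> genome DNA
    island_span: dict[str, tuple[int, int]]        # strain -> island interval


def emit_sequences(pa: PresenceAbsenceMatrix, tree: dendropy.Tree,
                   truth: SimTruth,
                   ortholog_identity_target: float = 85.0,
                   island_gc_offset: float = -10.0,
                   background_gc: float = 67.0,
                   cds_codons: tuple[int, int] = (300, 1500),
                   spacer_bp: tuple[int, int] = (50, 200),
                   seed: int = 0) -> SimSequences:
    """Per-strain protein/CDS/genome sequences matching the matrix.

    Each cluster gets a random ancestral protein; every carrying strain
    receives an independently mutated copy so that the expected pairwise
    protein identity is ``ortholog_identity_target`` percent (each copy is
    mutated with per-site probability 1 - sqrt(target), so two copies agree
    where neither mutated).  Codons are drawn from a synonymous pool
    reweighted towards the strain of GC required: ``background_gc`` for
    ordinary clusters, offset by ``island_gc_offset`` for causal island
    genes.  Genomes concatenate each strain's CDS with random spacers, the
    island genes forming one contiguous block.
    """
    if not 0 <= ortholog_identity_target <= 100:
        raise ValueError("ortholog_identity_target must be in [0, 100]")
    rng = np.random.default_rng(seed)
    strains = pa.strains
    clusters = pa.cluster_ids
    island = truth.causal_cluster_ids if truth else set()
    stops = {(s, c): idx for s, c, idx in (truth.planted_stops if truth else [])}
    q = 1.0 - math.sqrt(ortholog_identity_target / 100.0)
    ancestral: dict[str, str] = {}
    for cid in clusters:
        n_cod = truth.gene_codons.get(cid) if truth else None
        if n_cod is None:
            n_cod = int(rng.integers(cds_codons[0], cds_codons[1] + 1))
            if truth is not None:
                truth.gene_codons[cid] = n_cod
        aa = rng.choice(list(_AA_ALPHABET), size=n_cod - 1, p=_AA_PROBS)
        ancestral[cid] = "M" + "".join(aa)

    genes: dict[str, list[GeneSequence]] = {s: [] for s in strains}
    for cid in clusters:
        gc = background_gc + (island_gc_offset if cid in island else 0.0)
        anc = ancestral[cid]
        for s in strains:
            if not pa.presence.loc[s, cid]:
                continue
            prot = list(anc)
            if q > 0:
                hit = rng.random(len(prot)) < q
                hit[0] = False  # keep the start residue
                for i in np.flatnonzero(hit):
                    choices = _AA_ALPHABET.replace(prot[i], "")
                    prot[i] = choices[int(rng.integers(len(choices)))]
            prot = "".join(prot)
            cds = _protein_to_cds(prot, gc, rng)
            if (s, cid) in stops:
                cds = plant_premature_stop(cds, stops[(s, cid)])
            genes[s].append(GeneSequence(f"{s}|{cid}", s, cid, prot, cds))

    # genome: ordinary genes, then the island block, then the rest
    genomes: dict[str, str] = {}
    spans: dict[str, tuple[int, int]] = {}
    bg_frac = background_gc / 100.0

    def spacer() -> str:
        length = int(rng.integers(spacer_bp[0], spacer_bp[1] + 1))
        p = [(1 - bg_frac) / 2, bg_frac / 2, bg_frac / 2, (1 - bg_frac) / 2]
        return "".join(rng.choice(list(_BASES), size=length, p=p))

    for s in strains:
        ordinary = [g for g in genes[s] if g.cluster_id not in island]
        island_genes = [g for g in genes[s] if g.cluster_id in island]
        half = len(ordinary) // 2
        ordered = ordinary[:half] + island_genes + ordinary[half:]
        parts = []
        pos = 0
        start = end = None
        for g in ordered:
            sp = spacer()
            parts.append(sp)
            pos += len(sp)
            if g.cluster_id in island and start is None:
                start = pos
            parts.append(g.cds)
            pos += len(g.cds)
            if g.cluster_id in island:
                end = pos
        parts.append(spacer())
        genomes[s] = "".join(parts)
        if start is not None:
            spans[s] = (start, end)
    return SimSequences(genes, genomes, spans)


def write_sequences(seqs: SimSequences, outdir: str | Path) -> None:
    """FASTA writers: per-strain protein, CDS and genome files.

    The cluster tag is carried in the header as ``cluster=<id>`` — used
    only by truth-checking tests, never read by the pipeline itself.
    """
    outdir = Path(outdir)
    for kind in ("proteins", "cds", "genomes"):
        (outdir / kind).mkdir(parents=True, exist_ok=True)
    for strain, gene_list in seqs.genes.items():
        with open(outdir / "proteins" / f"{strain}.faa", "w") as fa, \
                open(outdir / "cds" / f"{strain}.fna", "w") as fn:
            for g in gene_list:
                fa.write(f">{g.gene_id} cluster={g.cluster_id}\n{g.protein}\n")
                fn.write(f">{g.gene_id} cluster={g.cluster_id}\n{g.cds}\n")
    for strain, genome in seqs.genomes.items():
        with open(outdir / "genomes" / f"{strain}.fa", "w") as fh:
            fh.write(f">{strain}\n")
            for i in range(0, len(genome), 80):
                fh.write(genome[i:i + 80] + "\n")


@dataclass
class SimPanel:
    config: SimConfig
    tree: dendropy.Tree
    pa: PresenceAbsenceMatrix
    truth: SimTruth
    phenotypes: PhenotypeTable
    sequences: SimSequences | None = None


def simulate_panel(config: SimConfig, with_sequences: bool = False,
                   ) -> SimPanel:
    """Run the whole generator: tree, gene content, island, phenotypes
    and (optionally) sequences."""
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(6)]
    tree = simulate_tree(config.n_strains, config.birth_rate, seeds[0])
    pa = simulate_gene_content(tree, config.n_core, config.gain_rate,
                               config.loss_rate, seeds[1],
                               n_accessory=config.n_decoy_accessory)
    pa, truth = plant_causal_island(pa, tree, config.island_size, seeds[2])
    len_rng = np.random.default_rng(seeds[3])
    for cid in pa.cluster_ids:
        truth.gene_codons[cid] = int(len_rng.integers(
            config.cds_codons[0], config.cds_codons[1] + 1))
    phenotypes, truth = simulate_phenotypes(
        truth, pa, config.nonsense_fraction, seeds[4])
    sequences = None
    if with_sequences:
        sequences = emit_sequences(
            pa, tree, truth,
            ortholog_identity_target=config.ortholog_identity_target,
            island_gc_offset=config.island_gc_offset,
            background_gc=config.background_gc,
            cds_codons=config.cds_codons, seed=seeds[5])
    return SimPanel(config, tree, pa, truth, phenotypes, sequences)
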