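"""Explain genotype-phenotype mismatches: gene decay and GC-atypical islands.

When a trait does not track gene presence, two genomic mechanisms are
screened for.  First, *pseudogenization*: a coding sequence interrupted by
a premature stop codon translates into truncated fragments (e.g. 198 + 248
aa instead of one 447-aa transporter) and the pathway loses function even
though the gene is "present".  Second, *horizontal acquisition*: genomic
islands recently acquired from another organism often sit several GC
points below the genome background and show up in a sliding-window GC
profile.

Translation uses the bacterial genetic code (NCBI table 11) by default.
All emitted intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = ["CodingSequence", "StopScanResult", "PseudogeneCall",
           "GCWindowProfile", "scan_premature_stops", "pseudogene_flag",
           "gc_island_screen", "phenotype_stats", "PhenotypeSummary"]


@dataclass(frozen=True)
class CodingSequence:
    gene_id: str
    strain_id: str
    sequence: str
    table_id: int = 11

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"{self.gene_id}: non-ACGTN characters {bad}")


@dataclass
class StopScanResult:
    """Premature-stop scan of one coding sequence.

    ``internal_stops`` holds 1-based codon indices; ``fragments`` the amino
    acid runs between stops (terminal stop excluded), so that
    sum(fragments) = full_length - len(internal_stops).
    """

    gene_id: str
    internal_stops: list[int]
    fragments: list[int]
    full_length: int
    frameshift_suspect: bool = False
    completeness_ratio: float | None = None

    @property
    def longest_fragment(self) -> int:
        return max(self.fragments) if self.fragments else 0

    @property
    def is_interrupted(self) -> bool:
        return bool(self.internal_stops)


def scan_premature_stops(cds: CodingSequence,
                         reference_length: int | None = None,
                         ) -> StopScanResult:
    """Translate codon-by-codon and record internal stop codons.

    A sequence whose length is not divisible by 3 is flagged
    frameshift-suspect and scanned on the trimmed frame.  The terminal
    stop codon, when present, is not an internal stop.
    """
    seq = cds.sequence.upper()
    suspect = False
    if len(seq) % 3:
        suspect = True
        logger.warning("%s: length %d not divisible by 3; scanning the "
                       "trimmed frame", cds.gene_id, len(seq))
        seq = seq[:len(seq) - len(seq) % 3]
    aa = str(Seq(seq).translate(table=cds.table_id))
    if aa.endswith("*"):
        body = aa[:-1]
    else:
        body = aa
    full_length = len(body)
    stops = [i + 1 for i, res in enumerate(body) if res == "*"]
    fragments = [len(run) for run in body.split("*")]
    ratio = None
    if reference_length:
        ratio = (max(fragments) if fragments else 0) / reference_length
    return StopScanResult(cds.gene_id, stops, fragments, full_length,
                          frameshift_suspect=suspect,
                          completeness_ratio=ratio)


@dataclass(frozen=True)
class PseudogeneCall:
    gene_id: str
    pseudogene: bool
    reference_length: float
    completeness_ratio: float
    reason: str = ""


def pseudogene_flag(scans: Mapping[str, StopScanResult],
                    min_fraction: float = 0.8,
                    ) -> dict[str, PseudogeneCall]:
    """Flag pseudogenized members of an orthologue cluster.

    The cluster reference length is the median full length of members
    without internal stops (falling back to the maximum full length with
    a warning when every member is interrupted).  A member is flagged
    when it carries an internal stop or its longest fragment is shorter
    than ``min_fraction`` of the reference.
    """
    if len(scans) < 2:
        raise ValueError("pseudogene_flag needs >= 2 cluster members")
    intact = [r.full_length for r in scans.values() if not r.is_interrupted]
    if intact:
        reference = statistics.median(intact)
    else:
        reference = max(r.full_length for r in scans.values())
        logger.warning("all cluster members carry internal stops; using "
                       "max full length %s as reference", reference)
    calls = {}
    for member, res in scans.items():
        ratio = res.longest_fragment / reference if reference else 0.0
        if res.is_interrupted:
            reason = f"{len(res.internal_stops)} internal stop(s)"
        elif ratio < min_fraction:
            reason = (f"longest fragment {res.longest_fragment} aa is "
                      f"{100 * ratio:.0f}% of reference {reference:g}")
        else:
            reason = ""
        calls[member] = PseudogeneCall(member, bool(reason), reference,
                                       ratio, reason)
    return calls


@dataclass
class GCWindowProfile:
    """Sliding-window GC profile with flagged low-GC regions."""

    sequence_id: str
    window: int
    stride: int
    starts: np.ndarray
    gc: np.ndarray                      # percent, per window
    genome_gc: float                    # percent
    regions: list[tuple[int, int, float]] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"start": self.starts,
                             "end": self.starts + self.window,
                             "gc_percent": self.gc})


def gc_island_screen(sequence: str, window: int = 1000, stride: int = 500,
                     min_offset: float = 5.0, min_span: int = 3000,
                     sequence_id: str = "genome") -> GCWindowProfile:
    """Flag maximal low-GC runs as candidate horizontally acquired islands.

    Windows whose GC falls at least ``min_offset`` percentage points below
    the sequence-wide GC are merged into maximal runs; runs spanning at
    least ``min_span`` bp are reported with their mean GC.  N bases are
    excluded from every GC denominator.
    """
    if window < 100:
        raise ValueError("window must be >= 100 bp")
    if stride > window or stride < 1:
        raise ValueError("need 1 <= stride <= window")
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_n = arr == ord("N")
    n_acgt = (~is_n).sum()
    genome_gc = 100.0 * is_gc.sum() / n_acgt if n_acgt else 0.0
    if len(seq) < window:
        logger.warning("sequence %s shorter than one window; empty profile",
                       sequence_id)
        return GCWindowProfile(sequence_id, window, stride,
                               np.empty(0, dtype=int), np.empty(0),
                               genome_gc)
    cum_gc = np.concatenate([[0], np.cumsum(is_gc)])
    cum_n = np.concatenate([[0], np.cumsum(is_n)])
    starts = np.arange(0, len(seq) - window + 1, stride)
    gc_counts = cum_gc[starts + window] - cum_gc[starts]
    denom = window - (cum_n[starts + window] - cum_n[starts])
    with np.errstate(invalid="ignore", divide="ignore"):
        gc = np.where(denom > 0, 100.0 * gc_counts / denom, np.nan)
    low = gc <= genome_gc - min_offset
    regions = []
    i = 0
    while i < len(low):
        if low[i]:
            j = i
            while j + 1 < len(low) and low[j + 1]:
                j += 1
            start = int(starts[i])
            end = int(starts[j]) + window
            if end - start >= min_span:
                span_gc = 100.0 * (cum_gc[end] - cum_gc[start]) / max(
                    (end - start) - (cum_n[end] - cum_n[start]), 1)
                regions.append((start, end, float(span_gc)))
            i = j + 1
        else:
            i += 1
    return GCWindowProfile(sequence_id, window, stride, starts, gc,
                           float(genome_gc), regions)


@dataclass
class PhenotypeSummary:
    per_strain_positive: pd.Series     # traits with score > 0, per strain
    per_trait_positive: pd.Series      # strains with score > 0, per trait
    universal_traits: list[str]        # positive in every strain
    never_traits: list[str]            # zero in every strain


def phenotype_stats(table: PhenotypeTable) -> PhenotypeSummary:
    """Per-strain and per-trait positivity summaries of a score table."""
    scores = table.scores
    positive = scores > 0
    per_strain = positive.sum(axis=1).astype(int)
    per_strain.name = "n_positive_traits"
    per_trait = positive.sum(axis=0).astype(int)
    per_trait.name = "n_positive_strains"
    universal = [t for t in scores.columns if bool(positive[t].all())]
    never = [t for t in scores.columns
             if bool((scores[t] == 0).all())]
    return PhenotypeSummary(per_strain, per_trait, universal, never)
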