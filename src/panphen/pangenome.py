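"""Presence/absence pan-genome and deduplicated phylogenetic profiles.

The pan-genome of a strain panel is the strains x clusters 0/1 matrix
(with per-cell copy counts retained for paralog-aware analyses).  Columns
partition into the *core* genome (present in every strain), the accessory
genome (absent somewhere) and, within the accessory, *strain-specific*
clusters present in exactly one strain.

For association testing, accessory columns are collapsed into unique
*phylogenetic profiles*: one 0/1 presence pattern over the ordered strain
panel together with all the clusters sharing it.  Following common
practice, clusters containing a single protein (necessarily
strain-specific singletons) and core columns are excluded before
collapsing; both exclusions are flags.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cluster import ClusterSet

__all__ = ["PresenceAbsenceMatrix", "PangenomePartition", "PhyloProfile",
           "build_presence_absence", "partition_pangenome", "dedup_profiles",
           "profile_id_for_pattern"]


@dataclass
class PresenceAbsenceMatrix:
    """Strains x clusters matrix: 0/1 presence plus integer copy counts."""

    presence: pd.DataFrame
    copy_count: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.presence.index.equals(self.copy_count.index):
            raise ValueError("presence/copy_count strain index mismatch")
        if not self.presence.columns.equals(self.copy_count.columns):
            raise ValueError("presence/copy_count cluster columns mismatch")
        p = self.presence.to_numpy()
        c = self.copy_count.to_numpy()
        if not ((p == 1) == (c >= 1)).all():
            raise ValueError("presence must be 1 exactly where copy_count >= 1")
        if (p.sum(axis=0) == 0).any():
            empty = self.presence.columns[p.sum(axis=0) == 0]
            raise ValueError(f"clusters present in no strain: {list(empty)}")

    @property
    def strains(self) -> list[str]:
        return list(self.presence.index)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_strains(self) -> int:
        return len(self.presence.index)


@dataclass
class PangenomePartition:
    core: list[str]
    accessory: list[str]            # includes strain-specific
    strain_specific: list[str]
    specific_per_strain: pd.Series  # strain -> number of specific clusters


@dataclass(frozen=True)
class PhyloProfile:
    """A unique presence pattern shared by one or more accessory clusters."""

    profile_id: str
    pattern: tuple[int, ...]
    member_cluster_ids: tuple[str, ...]

    @property
    def multiplicity(self) -> int:
        return len(self.member_cluster_ids)


def build_presence_absence(clusters: ClusterSet,
                           strains: Sequence[str]) -> PresenceAbsenceMatrix:
    """Tabulate cluster membership into the pan-genome matrix."""
    panel = list(strains)
    unknown = set(clusters.protein_strain.values()) - set(panel)
    if unknown:
        raise ValueError(f"proteins from strains outside the panel: {unknown}")
    ids = [c.cluster_id for c in clusters.clusters]
    counts = np.zeros((len(panel), len(ids)), dtype=int)
    pos = {s: i for i, s in enumerate(panel)}
    for j, c in enumerate(clusters.clusters):
        for strain, k in c.strain_counts.items():
            counts[pos[strain], j] = k
    copy_count = pd.DataFrame(counts, index=panel, columns=ids)
    presence = (copy_count >= 1).astype(int)
    return PresenceAbsenceMatrix(presence, copy_count)


def partition_pangenome(pa: PresenceAbsenceMatrix) -> PangenomePartition:
    """Split columns into core / accessory / strain-specific."""
    p = pa.presence
    n_present = p.sum(axis=0)
    core = list(p.columns[n_present == pa.n_strains])
    accessory = list(p.columns[n_present < pa.n_strains])
    specific = list(p.columns[n_present == 1])
    per_strain = p[specific].sum(axis=1) if specific else pd.Series(
        0, index=p.index)
    per_strain.name = "strain_specific_clusters"
    return PangenomePartition(core, accessory, specific, per_strain)


def profile_id_for_pattern(pattern: Sequence[int]) -> str:
    digest = hashlib.sha1("".join(map(str, pattern)).encode()).hexdigest()
    return f"P{digest[:10]}"


def dedup_profiles(pa: PresenceAbsenceMatrix,
                   exclude_singleton_clusters: bool = True,
                   exclude_core: bool = True,
                   exclude_strain_specific: bool = False,
                   ) -> list[PhyloProfile]:
    """Collapse accessory columns with identical presence patterns.

    ``exclude_singleton_clusters`` drops clusters containing exactly one
    protein (single-member, necessarily strain-specific);
    ``exclude_strain_specific`` drops *all* single-strain clusters
    regardless of copy number.  Profiles are sorted by decreasing
    multiplicity, then lexicographically by pattern.
    """
    p = pa.presence
    n_present = p.sum(axis=0)
    keep = pd.Series(True, index=p.columns)
    if exclude_core:
        keep &= n_present < pa.n_strains
    if exclude_singleton_clusters:
        keep &= pa.copy_count.sum(axis=0) > 1
    if exclude_strain_specific:
        keep &= n_present > 1
    cols = p.columns[keep]
    groups: dict[tuple[int, ...], list[str]] = {}
    arr = p[cols].to_numpy()
    for j, cid in enumerate(cols):
        pattern = tuple(int(v) for v in arr[:, j])
        groups.setdefault(pattern, []).append(cid)
    profiles = [
        PhyloProfile(profile_id_for_pattern(pat), pat, tuple(sorted(members)))
        for pat, members in groups.items()
    ]
    profiles.sort(key=lambda pr: (-pr.multiplicity, pr.pattern))
    return profiles


def write_presence_absence(pa: PresenceAbsenceMatrix, path: str | Path,
                           copy_path: str | Path | None = None) -> None:
    out = pa.presence.copy()
    out.index.name = "strain"
    out.to_csv(path, sep="\t")
    if copy_path is not None:
        out = pa.copy_count.copy()
        out.index.name = "strain"
        out.to_csv(copy_path, sep="\t")


def read_presence_absence(path: str | Path,
                          copy_path: str | Path | None = None,
                          ) -> PresenceAbsenceMatrix:
    presence = pd.read_csv(path, sep="\t", index_col=0)
    presence.index = presence.index.astype(str)
    if copy_path is not None:
        copy_count = pd.read_csv(copy_path, sep="\t", index_col=0)
        copy_count.index = copy_count.index.astype(str)
    else:
        copy_count = presence.copy()
    return PresenceAbsenceMatrix(presence.astype(int), copy_count.astype(int))


def write_profiles(profiles: Sequence[PhyloProfile], strains: Sequence[str],
                   path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("profile_id\tmultiplicity\tpattern\tmember_clusters\n")
        for pr in profiles:
            fh.write("\t".join((
                pr.profile_id, str(pr.multiplicity),
                "".join(map(str, pr.pattern)),
                ",".join(pr.member_cluster_ids),
            )) + "\n")


def read_profiles(path: str | Path) -> list[PhyloProfile]:
    profiles = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("profile_id\t"):
            raise ValueError(f"{path}: not a profile table")
        for line in fh:
            pid, _mult, pattern, members = line.rstrip("\n").split("\t")
            profiles.append(PhyloProfile(
                pid, tuple(int(c) for c in pattern),
                tuple(members.split(",")) if members else ()))
    return profiles
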