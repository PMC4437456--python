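"""Tabular file formats shared by the pipeline stages.

Phenotype tables are TSV files with a header row of trait names and strain
identifiers in the first column.  Scores follow the 5-level API 50CH-style
grid {0, 0.25, 0.5, 0.75, 1}; empty cells and the string ``NA`` both denote
a missing (undocumented) phenotype.

Similarity hits use the familiar 12-column tabular alignment dialect
extended with two trailing columns for query and subject sequence length:

    query subject pident length mismatch gapopen qstart qend sstart send
    evalue bitscore qlen slen

Coverage is never read from a file: it is always recomputed from the
alignment length and the two sequence lengths, so its definition is fixed
in one place (see :mod:`panphen.cluster`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .cluster import SimilarityHit

logger = logging.getLogger(__name__)

#: the admissible phenotype scores (API 50CH colorimetric grid)
SCORE_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)

HIT_COLUMNS = (
    "query", "subject", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "slen",
)


class FormatError(ValueError):
    """Raised when an input file does not follow the expected dialect."""


@dataclass
class PhenotypeTable:
    """A strain x trait table of 5-level phenotype scores.

    ``scores`` is a float DataFrame indexed by strain with one column per
    trait; missing phenotypes are NaN.
    """

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.scores.index
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate strain identifiers: {dupes}")
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate trait names")
        values = self.scores.to_numpy(dtype=float)
        ok = np.isnan(values)
        for g in SCORE_GRID:
            ok |= values == g
        if not ok.all():
            s, t = np.argwhere(~ok)[0]
            raise ValueError(
                f"score {values[s, t]!r} for strain {idx[s]!r}, trait "
                f"{self.scores.columns[t]!r} is not on the grid {SCORE_GRID}"
            )

    @property
    def strains(self) -> list[str]:
        return list(self.scores.index)

    @property
    def traits(self) -> list[str]:
        return list(self.scores.columns)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhenotypeTable):
            return NotImplemented
        return self.scores.equals(other.scores)


def read_phenotype_table(path: str | Path) -> PhenotypeTable:
    """Read and validate a strain x trait score TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA"],
                     keep_default_na=False)
    df.index = df.index.astype(str)
    for col in df.columns:
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()
                          & df[col].notna()]
            strain = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: malformed number {bad.iloc[0]!r} at strain "
                f"{strain!r}, trait {col!r}"
            ) from exc
    try:
        return PhenotypeTable(df)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_phenotype_table(table: PhenotypeTable, path: str | Path) -> None:
    df = table.scores.copy()
    df.index.name = "strain"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_similarity_hits(path: str | Path) -> Iterator[SimilarityHit]:
    """Stream similarity hits from an extended 14-column tabular file.

    Self-hits are retained (callers may use :attr:`SimilarityHit.is_self`).
    """
    path = Path(path)
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 14:
                if len(fields) >= 12:
                    raise FormatError(
                        f"{path}:{lineno}: only {len(fields)} columns; the "
                        "qlen/slen length columns are required to compute "
                        "alignment coverage"
                    )
                raise FormatError(
                    f"{path}:{lineno}: expected {len(HIT_COLUMNS)} "
                    f"tab-separated columns, got {len(fields)}"
                )
            try:
                hit = SimilarityHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    query_length=int(fields[12]),
                    subject_length=int(fields[13]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            n += 1
            yield hit
    if n == 0:
        logger.warning("%s: no similarity hits found", path)


def write_similarity_hits(hits: Iterable[SimilarityHit],
                          path: str | Path) -> None:
    """Write hits in the extended tabular dialect (unused fields zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            mism = round(h.aln_length * (1 - h.identity / 100))
            fh.write("\t".join(map(str, (
                h.query_id, h.subject_id, f"{h.identity:.2f}", h.aln_length,
                mism, 0, 1, h.aln_length, 1, h.aln_length,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
                h.query_length, h.subject_length,
            ))) + "\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path: str | Path,
                     index_name: str = "strain") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")
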