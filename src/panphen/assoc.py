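"""Phenotype vs gene-presence association testing.

Each binarized trait is tested against every unique phylogenetic profile
twice: with a two-sided Fisher exact test on the 2x2 occurrence table
(fast, but blind to shared ancestry) and with a generalized least-squares
fit y = b0 + b1 x + e, Cov(e) = sigma^2 V, where V is the Brownian-motion
covariance of the rooted strain tree.  The GLS coefficient and its t-test
on n - 2 degrees of freedom correct for the phylogenetic correlation that
can make an ordinary contingency test anti-conservative when both the
trait and the profile follow the tree.

Traits scored on the 0..1 grid are recoded to 0/1 (by default any
positive score counts as ability); strains with a missing score are
dropped, so every test runs on the documented subset only.  The scan
flags results at a stringent threshold (default 1e-5, a Bonferroni-style
guard for hundreds of profiles).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeTable
from .pangenome import PhyloProfile
from .phylo import BMCovariance

logger = logging.getLogger(__name__)

__all__ = ["BinaryTrait", "AssocResult", "ScanReport", "binarize_phenotype",
           "fisher_association", "gls_association", "run_association_scan"]

BINARIZE_RULES = ("any_positive", "strict")


@dataclass
class BinaryTrait:
    """A 0/1 recoding of one trait; NaN marks undocumented strains."""

    name: str
    values: pd.Series
    rule: str = "any_positive"

    @property
    def documented_strains(self) -> list[str]:
        return list(self.values.index[self.values.notna()])

    @property
    def n_positive(self) -> int:
        return int((self.values == 1).sum())

    @property
    def n_negative(self) -> int:
        return int((self.values == 0).sum())

    @property
    def testable(self) -> bool:
        return self.n_positive >= 2 and self.n_negative >= 2


def binarize_phenotype(table: PhenotypeTable, trait: str,
                       rule: str = "any_positive") -> BinaryTrait:
    """Recode grid scores to 0/1.

    ``any_positive``: any score above 0 counts as ability; ``strict``:
    only a full score of 1 does.  Missing scores stay missing.
    """
    if trait not in table.traits:
        raise KeyError(f"unknown trait {trait!r}")
    if rule not in BINARIZE_RULES:
        raise ValueError(f"unknown rule {rule!r}; expected {BINARIZE_RULES}")
    scores = table.scores[trait]
    cut = 0.999 if rule == "strict" else 0.0
    values = pd.Series(np.where(scores.isna(), np.nan,
                                (scores > cut).astype(float)),
                       index=scores.index)
    return BinaryTrait(trait, values, rule)


@dataclass
class AssocResult:
    trait: str
    profile_id: str
    method: str                  # "fisher" | "gls"
    coefficient: float
    statistic: float
    p_value: float
    n_used: int
    degenerate: bool = False


def _restrict(trait: BinaryTrait, profile: PhyloProfile,
              strains: Sequence[str]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pattern = pd.Series(profile.pattern, index=list(strains))
    used = [s for s in trait.documented_strains if s in pattern.index]
    missing = set(trait.documented_strains) - set(pattern.index)
    if missing:
        raise ValueError(f"documented strains absent from the profile "
                         f"panel: {sorted(missing)}")
    y = trait.values[used].to_numpy(dtype=float)
    x = pattern[used].to_numpy(dtype=float)
    return y, x, used


def fisher_association(trait: BinaryTrait, profile: PhyloProfile,
                       strains: Sequence[str]) -> AssocResult:
    """Two-sided Fisher exact test of trait vs presence.

    A profile constant on the documented strains is degenerate: p = 1 and
    the degenerate flag is set.
    """
    y, x, used = _restrict(trait, profile, strains)
    n = len(used)
    if x.min() == x.max():
        return AssocResult(trait.name, profile.profile_id, "fisher",
                           0.0, 0.0, 1.0, n, degenerate=True)
    a = int(((y == 1) & (x == 1)).sum())
    b = int(((y == 1) & (x == 0)).sum())
    c = int(((y == 0) & (x == 1)).sum())
    d = int(((y == 0) & (x == 0)).sum())
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    direction = 1.0 if a * d >= b * c else -1.0
    return AssocResult(trait.name, profile.profile_id, "fisher",
                       direction, float(odds), float(p), n)


def _solve_gls(y: np.ndarray, x: np.ndarray, V: np.ndarray,
               ) -> tuple[float, float, float, int]:
    """Closed-form GLS slope, t statistic and p-value (t on n-2 df)."""
    n = len(y)
    X = np.column_stack([np.ones(n), x])
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        V = V + 1e-8 * np.mean(np.diag(V)) * np.eye(n)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            pairs = [
                (i, j) for i in range(n) for j in range(i + 1, n)
                if abs(V[i, j] - V[i, i]) < 1e-12
                and abs(V[i, j] - V[j, j]) < 1e-12
            ]
            raise np.linalg.LinAlgError(
                "Brownian-motion covariance is singular even after jitter; "
                f"indistinguishable tip pairs (zero-length tips?): {pairs}")
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    if rss <= 1e-12 * (float(yw @ yw) + 1.0):
        rss = 0.0  # exact fit up to floating error
    sigma2 = rss / (n - 2)
    cov = sigma2 * np.linalg.inv(XtX)
    se = math.sqrt(max(cov[1, 1], 0.0))
    b1 = float(beta[1])
    if se == 0.0:
        # perfect fit: infinitely strong evidence unless the slope is null
        t = math.inf if b1 > 0 else (-math.inf if b1 < 0 else 0.0)
        p = 0.0 if b1 != 0 else 1.0
        return b1, t, p, n
    t = b1 / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return b1, t, float(p), n


def gls_association(trait: BinaryTrait, profile: PhyloProfile,
                    V: BMCovariance,
                    strains: Sequence[str] | None = None) -> AssocResult:
    """Brownian-motion GLS association of a trait with a profile.

    The covariance is restricted to the documented strains; a profile
    constant on them is degenerate (no test, p = 1).
    """
    panel = list(strains) if strains is not None else V.strains
    y, x, used = _restrict(trait, profile, panel)
    if len(used) < 3:
        raise ValueError("GLS needs at least 3 documented strains")
    if x.min() == x.max():
        return AssocResult(trait.name, profile.profile_id, "gls",
                           0.0, 0.0, 1.0, len(used), degenerate=True)
    Vr = V.restrict(used)
    b1, t, p, n = _solve_gls(y, x, Vr.values)
    return AssocResult(trait.name, profile.profile_id, "gls", b1, t, p, n)


@dataclass
class ScanReport:
    """All per-(trait, profile) results of one association scan."""

    results: pd.DataFrame
    alpha_scan: float
    untestable_traits: list[str] = field(default_factory=list)

    @property
    def significant(self) -> pd.DataFrame:
        return self.results[self.results["gls_p"] < self.alpha_scan]

    def top_hits(self, trait: str, k: int = 10) -> pd.DataFrame:
        sub = self.results[self.results["trait"] == trait]
        return sub.sort_values(["gls_p", "fisher_p"]).head(k)

    def write(self, path) -> None:
        self.results.to_csv(path, sep="\t", index=False)


def run_association_scan(profiles: Sequence[PhyloProfile],
                         table: PhenotypeTable,
                         V: BMCovariance,
                         strains: Sequence[str] | None = None,
                         alpha_scan: float = 1e-5,
                         rule: str = "any_positive") -> ScanReport:
    """Fisher + GLS for every testable trait against every profile.

    ``strains`` gives the panel order the profile patterns refer to
    (default: the covariance's own strain order).  Results are ranked per
    trait by GLS p-value; significance uses ``alpha_scan`` per method.
    """
    if not 0 < alpha_scan < 1:
        raise ValueError("alpha_scan must be in (0, 1)")
    panel = list(strains) if strains is not None else list(V.strains)
    unmatched = [s for s in panel if s not in V.strains]
    if unmatched:
        raise ValueError(f"strains missing from the tree/covariance: "
                         f"{unmatched}")
    rows = []
    untestable = []
    for trait_name in table.traits:
        trait = binarize_phenotype(table, trait_name, rule)
        doc_missing = [s for s in trait.documented_strains if s not in panel]
        if doc_missing:
            raise ValueError(
                f"trait {trait_name!r}: documented strains not in the "
                f"panel: {doc_missing}")
        if not trait.testable:
            untestable.append(trait_name)
            logger.info("trait %s untestable (%d positive / %d negative)",
                        trait_name, trait.n_positive, trait.n_negative)
            continue
        for profile in profiles:
            fres = fisher_association(trait, profile, panel)
            gres = gls_association(trait, profile, V, panel)
            rows.append({
                "trait": trait_name,
                "profile_id": profile.profile_id,
                "multiplicity": profile.multiplicity,
                "member_clusters": ",".join(profile.member_cluster_ids),
                "n_used": gres.n_used,
                "fisher_p": fres.p_value,
                "fisher_direction": fres.coefficient,
                "gls_coefficient": gres.coefficient,
                "gls_statistic": gres.statistic,
                "gls_p": gres.p_value,
                "degenerate": fres.degenerate or gres.degenerate,
            })
    df = pd.DataFrame(rows, columns=[
        "trait", "profile_id", "multiplicity", "member_clusters", "n_used",
        "fisher_p", "fisher_direction", "gls_coefficient", "gls_statistic",
        "gls_p", "degenerate"])
    if len(df):
        df["fisher_significant"] = df["fisher_p"] < alpha_scan
        df["gls_significant"] = df["gls_p"] < alpha_scan
        df["rank"] = df.groupby("trait")["gls_p"].rank(method="min")
        df = df.sort_values(["trait", "gls_p", "profile_id"],
                            kind="mergesort").reset_index(drop=True)
    else:
        for col in ("fisher_significant", "gls_significant", "rank"):
            df[col] = pd.Series(dtype=float)
    return ScanReport(df, alpha_scan, untestable)
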