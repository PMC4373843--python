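"""Set-overlap statistics for module annotation.

Supports two annotation questions: does a module's gene content overlap a
curated gene set (e.g. polycomb group targets), and does a module's CpG
content overlap a module from another study?  Both reduce to a 2x2 table
over a stated identifier universe, scored by the odds ratio and a
two-sided Fisher exact p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import fisher_exact

from .core import CoMethNetError, ParseError, ProbeManifest

logger = logging.getLogger("comethnet")


@dataclass
class GeneSetCollection:
    """Named identifier sets (genes or probes) over an optional universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is not None:
            for name, members in self.sets.items():
                extra = members - self.universe
                if extra:
                    raise CoMethNetError(
                        f"set {name!r} has {len(extra)} members outside the universe"
                    )

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class OverlapResult:
    """2x2 overlap table with odds ratio and Fisher exact p."""

    in_both: int
    a_only: int
    b_only: int
    neither: int
    odds_ratio: float
    p: float

    @property
    def universe_size(self) -> int:
        return self.in_both + self.a_only + self.b_only + self.neither


def fisher_overlap(set_a, set_b, universe) -> OverlapResult:
    """Two-sided Fisher exact test of the overlap of two sets.

    The two-sided p sums all tables with point probability at most that of
    the observed table (the standard convention).  The odds ratio is the
    sample odds ratio ``n11*n00 / (n10*n01)``, infinite when a denominator
    cell is zero while the numerator cells are positive.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if len(u) < 2:
        raise CoMethNetError("universe must contain at least 2 identifiers")
    if not (a | b) <= u:
        raise CoMethNetError("universe must contain both sets")
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(u) - n11 - n10 - n01
    _, p = fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    if n10 * n01 == 0:
        odds = float("inf") if n11 * n00 > 0 else float("nan")
    else:
        odds = (n11 * n00) / (n10 * n01)
    return OverlapResult(n11, n10, n01, n00, float(odds), float(p))


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and members"
                )
            name, desc, *members = fields
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def annotate_module_genes(members, manifest: ProbeManifest) -> set[str]:
    """Deduplicated gene symbols for a probe set; unannotated probes dropped."""
    genes = manifest.genes_for(list(members))
    missing = genes.isna() | (genes.astype(str).str.strip() == "")
    if missing.any():
        logger.warning(
            "%d probes without gene annotation excluded", int(missing.sum())
        )
    return set(genes[~missing].astype(str))


def overlap_report(results: dict[str, OverlapResult]) -> pd.DataFrame:
    """Tabulate overlap results (one row per tested set)."""
    rows = {
        name: {
            "in_both": r.in_both,
            "a_only": r.a_only,
            "b_only": r.b_only,
            "neither": r.neither,
            "odds_ratio": r.odds_ratio,
            "p": r.p,
        }
        for name, r in results.items()
    }
    return pd.DataFrame(rows).T
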