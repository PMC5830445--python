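"""CAZyme profiling: dbCAN hit filtering, class counts and novelty scoring.

The CAZy database groups carbohydrate-active enzymes into six classes:
glycoside hydrolases (GH), glycosyl transferases (GT), polysaccharide
lyases (PL), carbohydrate esterases (CE), auxiliary activities (AA) and
carbohydrate-binding modules (CBM, reported here as CB). dbCAN hits are
filtered with the standard cut-offs (long alignments need E < 1e-5, short
ones E < 1e-3, and >30 % HMM coverage either way); a protein is "known"
when its best database hit reaches the identity threshold (default 95 %),
otherwise novel.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import DomainHit

CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CB")


def cazy_class_of(family: str) -> str | None:
    """CAZy class from a family label prefix; CBM maps to CB."""
    m = re.match(r"([A-Z]+)", family)
    if not m:
        return None
    prefix = m.group(1)
    if prefix == "CBM":
        return "CB"
    return prefix if prefix in CAZY_CLASSES else None


@dataclass(frozen=True)
class CazyAssignment:
    protein_id: str
    family: str
    cazy_class: str
    genome_id: str = ""

    def __post_init__(self) -> None:
        if self.cazy_class not in CAZY_CLASSES:
            raise ValueError(f"unknown CAZy class {self.cazy_class!r}")


@dataclass(frozen=True)
class BestIdentity:
    """Best percent identity of a protein against each reference database."""

    protein_id: str
    per_database: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for db, ident in self.per_database.items():
            if not 0 <= ident <= 100:
                raise ValueError(
                    f"{self.protein_id}: identity {ident} vs {db} "
                    "outside [0,100]"
                )

    @property
    def max_identity(self) -> float:
        if not self.per_database:
            return math.nan
        return max(self.per_database.values())


@dataclass(frozen=True)
class DbcanCutoffs:
    """The standard dbCAN filtering thresholds; every number configurable."""

    long_ali_length: int = 80      # alignments longer than this are "long"
    long_max_evalue: float = 1e-5  # E-value cut for long alignments
    short_max_evalue: float = 1e-3 # E-value cut for short alignments
    min_coverage: float = 0.3      # HMM coverage floor, either branch


def apply_dbcan_filters(
    hits: Iterable[DomainHit],
    genome_of_protein: Mapping[str, str] | None = None,
    cutoffs: DbcanCutoffs = DbcanCutoffs(),
) -> list[CazyAssignment]:
    """Filter CAZy domain hits and emit one assignment per surviving hit.

    Keep iff (ali_length > 80 and evalue < 1e-5) or (ali_length <= 80 and
    evalue < 1e-3), and hmm_coverage > 0.3 (defaults). A protein with
    several surviving domains keeps them all.
    """
    out = []
    for h in hits:
        if h.source != "cazy":
            continue
        if not (h.hmm_coverage > cutoffs.min_coverage):
            continue
        if h.ali_length > cutoffs.long_ali_length:
            if not (h.evalue < cutoffs.long_max_evalue):
                continue
        else:
            if not (h.evalue < cutoffs.short_max_evalue):
                continue
        cls = cazy_class_of(h.base_family)
        if cls is None:
            continue
        genome = genome_of_protein.get(h.protein_id, "") if genome_of_protein else ""
        out.append(
            CazyAssignment(
                protein_id=h.protein_id,
                family=h.label,
                cazy_class=cls,
                genome_id=genome,
            )
        )
    return out


def class_counts(assignments: Iterable[CazyAssignment]) -> pd.DataFrame:
    """Per-genome counts of each CAZy class plus a ``total`` row.

    Counts include multi-domain multiplicity: a protein assigned GH10 and
    CE1 contributes one GH and one CE.
    """
    tallies: dict[str, dict[str, int]] = defaultdict(
        lambda: {c: 0 for c in CAZY_CLASSES}
    )
    for a in assignments:
        tallies[a.genome_id][a.cazy_class] += 1
    df = pd.DataFrame(
        [{"genome_id": g, **counts} for g, counts in sorted(tallies.items())],
        columns=["genome_id", *CAZY_CLASSES],
    ).set_index("genome_id")
    df.loc["total"] = df.sum()
    return df


def novelty_summary(
    identities: Iterable[BestIdentity],
    protein_ids: Iterable[str],
    threshold: float = 95.0,
) -> tuple[int, int, float]:
    """(n_known, n_novel, pct_known) over all proteins.

    A protein is known iff its max identity over databases reaches the
    threshold (inclusive); proteins absent from every hit table are novel.
    n_known + n_novel always equals the number of proteins.
    """
    best = {bi.protein_id: bi.max_identity for bi in identities}
    proteins = list(protein_ids)
    if not proteins:
        return 0, 0, math.nan
    n_known = sum(
        1
        for pid in proteins
        if not math.isnan(best.get(pid, math.nan))
        and best[pid] >= threshold
    )
    n_novel = len(proteins) - n_known
    return n_known, n_novel, 100.0 * n_known / len(proteins)


def identity_distribution_by_class(
    assignments: Iterable[CazyAssignment],
    identities: Iterable[BestIdentity],
) -> pd.DataFrame:
    """Median and quartiles of best-hit identity per CAZy class.

    Each protein contributes its max identity once to every class it is
    assigned to (not once per domain); proteins with no database hit are
    excluded. Classes with no contributing protein are absent from the
    result. Quantiles use the median-unbiased convention so that R and
    Python implementations agree.
    """
    best = {bi.protein_id: bi.max_identity for bi in identities}
    per_class: dict[str, set[str]] = defaultdict(set)
    for a in assignments:
        per_class[a.cazy_class].add(a.protein_id)
    rows = []
    for cls in CAZY_CLASSES:
        vals = [
            best[pid]
            for pid in per_class.get(cls, ())
            if pid in best and not math.isnan(best[pid])
        ]
        if not vals:
            continue
        q1, med, q3 = np.quantile(
            vals, [0.25, 0.5, 0.75], method="median_unbiased"
        )
        rows.append(
            {"cazy_class": cls, "n": len(vals), "q1": q1,
             "median": med, "q3": q3}
        )
    return pd.DataFrame(rows, columns=["cazy_class", "n", "q1", "median", "q3"])
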