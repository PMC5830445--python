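"""Genome-bin quality control.

Implements the study-style pass filter (completeness >= 80 %, contamination
<= 10 %, inclusive), the stricter high-quality draft tier (completeness
> 90 %, contamination < 5 %, strict, following the MIMAG draft criteria),
genus-based contig cleaning, and taxonomy-resolution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .annotations_io import TAXONOMY_RANKS, BinStats


class QualityTier(str, Enum):
    HIGH_QUALITY_DRAFT = "high_quality_draft"
    PASS_DRAFT = "pass_draft"
    FAIL = "fail"


@dataclass(frozen=True)
class ContigGenusCall:
    """Best-hit genus call for one contig, with its superkingdom."""

    contig_id: str
    genus: str
    superkingdom: str  # "Bacteria", "Archaea" or "other"


def _check_ranges(completeness: float, contamination: float) -> None:
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness {completeness} outside [0,100]")
    if contamination < 0:
        raise ValueError(f"contamination {contamination} < 0")


def filter_bins(
    stats: Iterable[BinStats],
    min_completeness: float = 80.0,
    max_contamination: float = 10.0,
) -> list[str]:
    """Genome ids passing completeness >= min AND contamination <= max.

    Both comparisons are inclusive; input order is preserved.
    """
    passing = []
    for s in stats:
        _check_ranges(s.completeness, s.contamination)
        if s.completeness >= min_completeness and s.contamination <= max_contamination:
            passing.append(s.genome_id)
    return passing


def quality_tier(completeness: float, contamination: float) -> QualityTier:
    """MIMAG-style tier for one genome.

    high_quality_draft requires completeness > 90 and contamination < 5
    (both strict); pass_draft is the inclusive >=80 / <=10 filter; anything
    else fails.
    """
    _check_ranges(completeness, contamination)
    if completeness > 90 and contamination < 5:
        return QualityTier.HIGH_QUALITY_DRAFT
    if completeness >= 80 and contamination <= 10:
        return QualityTier.PASS_DRAFT
    return QualityTier.FAIL


def make_genus_call(
    contig_id: str, genus: str, superkingdom_of_genus: Mapping[str, str]
) -> ContigGenusCall:
    """Build a genus call, deriving the superkingdom from a lookup table."""
    sk = superkingdom_of_genus.get(genus, "other")
    if sk not in ("Bacteria", "Archaea"):
        sk = "other"
    return ContigGenusCall(contig_id=contig_id, genus=genus, superkingdom=sk)


def clean_bin(
    contigs: Sequence[str],
    calls: Iterable[ContigGenusCall],
) -> tuple[list[str], list[str]]:
    """Split a bin's contigs into (kept, removed) by genus superkingdom.

    A contig is removed iff its genus call falls outside Bacteria/Archaea;
    contigs without a call are kept. Each contig may carry at most one call.
    """
    by_contig: dict[str, ContigGenusCall] = {}
    for call in calls:
        if call.contig_id in by_contig:
            raise ValueError(f"contig {call.contig_id} has two genus calls")
        by_contig[call.contig_id] = call
    kept, removed = [], []
    for contig in contigs:
        call = by_contig.get(contig)
        if call is not None and call.superkingdom not in ("Bacteria", "Archaea"):
            removed.append(contig)
        else:
            kept.append(contig)
    return kept, removed


def taxonomy_resolution_summary(stats: Iterable[BinStats]) -> dict[str, int]:
    """Count genomes resolved to at least each rank.

    The count at rank r is the number of genomes whose lineage is non-empty
    at r or any deeper rank; counts are monotone non-increasing from kingdom
    to species. Lineages violating top-down fill raise on construction.
    """
    counts = {rank: 0 for rank in TAXONOMY_RANKS}
    for s in stats:
        deepest = -1
        for i, value in enumerate(s.lineage):
            if value:
                deepest = i
        for i in range(deepest + 1):
            counts[TAXONOMY_RANKS[i]] += 1
    return counts


def phylum_breakdown(stats: Iterable[BinStats]) -> dict[str, float]:
    """Share of each phylum among genomes resolvable to phylum level."""
    phylum_idx = TAXONOMY_RANKS.index("phylum")
    tallies: dict[str, int] = {}
    total = 0
    for s in stats:
        phylum = s.lineage[phylum_idx]
        if phylum:
            tallies[phylum] = tallies.get(phylum, 0) + 1
            total += 1
    if total == 0:
        return {}
    return {p: 100.0 * n / total for p, n in sorted(tallies.items())}
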