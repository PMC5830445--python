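"""Cellulosome-candidate screening.

Scaffoldin proteins — the backbone of cellulosome complexes — carry
multiple repeated cohesin domains. This module counts non-overlapping
cohesin hits per protein and reports genomes encoding proteins with at
least ``min_domains`` of them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

from .annotations_io import DomainHit

#: Pfam cohesin domain family; overridable in both entry points.
DEFAULT_COHESIN_LABELS = frozenset({"PF00963"})


@dataclass(frozen=True)
class CohesinProfile:
    protein_id: str
    genome_id: str
    n_cohesin: int

    def __post_init__(self) -> None:
        if self.n_cohesin < 0:
            raise ValueError("n_cohesin must be >= 0")


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.env_end, b.env_end) - max(a.env_start, b.env_start) + 1)


def count_cohesin(
    hits: Iterable[DomainHit],
    cohesin_labels: frozenset[str] = DEFAULT_COHESIN_LABELS,
    max_overlap_frac: float = 0.5,
) -> int:
    """Count non-overlapping cohesin domains on one protein.

    Hits are taken greedily in descending bitscore order (ties by envelope
    position, then label, for order-independence); a hit is accepted iff its
    envelope overlaps every previously accepted envelope by at most
    ``max_overlap_frac`` of the shorter of the two.
    """
    cands = [h for h in hits if h.label in cohesin_labels]
    cands.sort(key=lambda h: (-h.bitscore, h.env_start, h.env_end, h.label))
    accepted: list[DomainHit] = []
    for h in cands:
        ok = True
        for a in accepted:
            shorter = min(
                h.env_end - h.env_start + 1, a.env_end - a.env_start + 1
            )
            if _overlap(h, a) > max_overlap_frac * shorter:
                ok = False
                break
        if ok:
            accepted.append(h)
    return len(accepted)


def cohesin_profiles(
    domains: Iterable[DomainHit],
    genome_of_protein: dict[str, str],
    cohesin_labels: frozenset[str] = DEFAULT_COHESIN_LABELS,
    max_overlap_frac: float = 0.5,
) -> list[CohesinProfile]:
    """Per-protein cohesin counts for every protein with >=1 cohesin hit."""
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in domains:
        if h.label in cohesin_labels:
            by_protein[h.protein_id].append(h)
    return [
        CohesinProfile(
            protein_id=pid,
            genome_id=genome_of_protein.get(pid, ""),
            n_cohesin=count_cohesin(hits, cohesin_labels, max_overlap_frac),
        )
        for pid, hits in sorted(by_protein.items())
    ]


def screen_genomes(
    profiles: Iterable[CohesinProfile],
    min_domains: int = 2,
) -> dict[str, list[CohesinProfile]]:
    """Genomes with >=1 protein at/above ``min_domains`` cohesin domains.

    Returns genome_id -> that genome's qualifying proteins, sorted by
    descending n_cohesin then protein_id; genome keys sorted.
    """
    hits: dict[str, list[CohesinProfile]] = defaultdict(list)
    for p in profiles:
        if p.n_cohesin >= min_domains:
            hits[p.genome_id].append(p)
    return {
        g: sorted(ps, key=lambda p: (-p.n_cohesin, p.protein_id))
        for g, ps in sorted(hits.items())
    }


def write_cohesin_table(
    screened: dict[str, list[CohesinProfile]], path
) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tprotein_id\tn_cohesin\n")
        for genome_id, profiles in screened.items():
            for p in profiles:
                fh.write(f"{genome_id}\t{p.protein_id}\t{p.n_cohesin}\n")
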