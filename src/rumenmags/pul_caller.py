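"""Polysaccharide utilization locus (PUL) calling.

A PUL is anchored by a tandem susC/susD-like gene pair (TonB-dependent
transporter plus outer-membrane glycan-binding lipoprotein, the diagnostic
pair of Bacteroidetes Sus systems) and grown outward by a moving-window
search over genes with CAZy homologues: from each boundary, up to ``window``
genes are scanned outward; if any carries a CAZy label, the boundary jumps
to the farthest such gene and the scan repeats; extension stops when a
window holds no CAZy gene or the contig ends.

The caller never crosses a contig boundary, merges extensions whose gene
ranges overlap (so susC-susD-susC chains are counted once), and renders a
strand-aware architecture signature such as
``GH43-GH10 | GH67-GH35-susC-susD-unc-GH10``, where ``|`` separates maximal
runs of genes on opposite strands and ``unc`` marks unclassified members.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations_io import DomainHit, GeneRecord

#: Pfam families recognising susC-like TonB-dependent transporters
#: (plug + beta-barrel domains) and susD-like lipoproteins. Overridable
#: via :class:`PulConfig`.
DEFAULT_SUSC_PFAMS = frozenset({"PF00593", "PF07715"})
DEFAULT_SUSD_PFAMS = frozenset({"PF07980", "PF12741", "PF12771", "PF14322"})


@dataclass(frozen=True)
class PulConfig:
    susc_pfams: frozenset[str] = DEFAULT_SUSC_PFAMS
    susd_pfams: frozenset[str] = DEFAULT_SUSD_PFAMS
    window: int = 5
    max_intergenic_gap: int | None = None  # bp between seed genes; None = any

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass(frozen=True)
class SusRole:
    protein_id: str
    role: str  # "susC_like", "susD_like" or "none"


@dataclass(frozen=True)
class Pul:
    """A called locus: ordered member genes with annotation labels."""

    pul_id: str
    genome_id: str
    contig_id: str
    genes: tuple[tuple[GeneRecord, str], ...]  # label in {susC, susD, family, unc}
    seeds: tuple[tuple[GeneRecord, GeneRecord], ...]  # (susC gene, susD gene)
    span: tuple[int, int]

    def __post_init__(self) -> None:
        labels = [lab for _, lab in self.genes]
        if "susC" not in labels or "susD" not in labels:
            raise ValueError(f"{self.pul_id}: PUL must contain susC and susD")
        if any(g.contig_id != self.contig_id for g, _ in self.genes):
            raise ValueError(f"{self.pul_id}: PUL crosses a contig boundary")
        lo = min(g.start for g, _ in self.genes)
        hi = max(g.end for g, _ in self.genes)
        if self.span != (lo, hi):
            raise ValueError(f"{self.pul_id}: span does not cover member genes")

    @property
    def seed(self) -> tuple[GeneRecord, GeneRecord]:
        return self.seeds[0]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def is_simple(self) -> bool:
        """True for a bare susC/susD pair with no other members."""
        return sorted(lab for _, lab in self.genes) == ["susC", "susD"]


# ---------------------------------------------------------------------------
# role assignment and seed pairing
# ---------------------------------------------------------------------------


def assign_sus_roles(
    domains: Iterable[DomainHit],
    config: PulConfig = PulConfig(),
) -> list[SusRole]:
    """Classify proteins as susC-like / susD-like from their Pfam hits.

    A protein hitting families from both sets takes the role of its
    higher-bitscore hit; ties resolve to susC_like.
    """
    best: dict[str, dict[str, float]] = defaultdict(lambda: {"susC": -1.0, "susD": -1.0})
    order: list[str] = []
    for hit in domains:
        if hit.source != "pfam":
            continue
        key = None
        if hit.label in config.susc_pfams:
            key = "susC"
        elif hit.label in config.susd_pfams:
            key = "susD"
        if key is None:
            continue
        if hit.protein_id not in best:
            order.append(hit.protein_id)
        scores = best[hit.protein_id]
        scores[key] = max(scores[key], hit.bitscore)
    roles = []
    for pid in order:
        scores = best[pid]
        if scores["susC"] >= scores["susD"]:  # tie -> susC
            roles.append(SusRole(pid, "susC_like"))
        else:
            roles.append(SusRole(pid, "susD_like"))
    return roles


def _role_map(roles: Iterable[SusRole]) -> dict[str, str]:
    return {r.protein_id: r.role for r in roles if r.role != "none"}


def find_seed_pairs(
    genes: Sequence[GeneRecord],
    roles: Iterable[SusRole],
    config: PulConfig = PulConfig(),
) -> list[tuple[GeneRecord, GeneRecord]]:
    """Tandem susC/susD pairs: consecutive genes in coordinate order, one of
    each role, in either order. A C-D-C chain yields both adjacent pairs.
    Returned as (susC gene, susD gene) regardless of their genomic order.
    """
    rmap = _role_map(roles)
    pairs = []
    for a, b in zip(genes, genes[1:]):
        if a.contig_id != b.contig_id:
            continue
        ra, rb = rmap.get(a.protein_id), rmap.get(b.protein_id)
        if {ra, rb} != {"susC_like", "susD_like"}:
            continue
        if config.max_intergenic_gap is not None:
            if b.start - a.end - 1 > config.max_intergenic_gap:
                continue
        pairs.append((a, b) if ra == "susC_like" else (b, a))
    return pairs


# ---------------------------------------------------------------------------
# window extension
# ---------------------------------------------------------------------------


def _extend_indices(
    is_cazy: Sequence[bool], lo: int, hi: int, window: int
) -> tuple[int, int]:
    """Grow [lo, hi] by the jump-and-rescan rule; returns the fixpoint."""
    n = len(is_cazy)
    while True:
        lo_win = range(max(0, lo - window), lo)
        hits = [i for i in lo_win if is_cazy[i]]
        if not hits:
            break
        lo = min(hits)  # farthest CAZy gene within the window
    while True:
        hi_win = range(hi + 1, min(n, hi + window + 1))
        hits = [i for i in hi_win if is_cazy[i]]
        if not hits:
            break
        hi = max(hits)
    return lo, hi


def _member_label(
    gene: GeneRecord,
    roles: Mapping[str, str],
    cazy_labels: Mapping[str, str],
) -> str:
    role = roles.get(gene.protein_id)
    if role == "susC_like":
        return "susC"
    if role == "susD_like":
        return "susD"
    return cazy_labels.get(gene.protein_id, "unc")


def extend_pul(
    genes: Sequence[GeneRecord],
    cazy_labels: Mapping[str, str],
    seed: tuple[GeneRecord, GeneRecord],
    window: int = 5,
    roles: Iterable[SusRole] | None = None,
    pul_id: str = "PUL",
) -> Pul:
    """Extend one seed pair into a full locus.

    ``genes`` is the ordered gene list of one contig; ``cazy_labels`` maps
    protein_id to its (base) CAZy family for every CAZy-annotated protein.
    All genes between the final boundaries become members; members without
    a sus role or CAZy label are labelled ``unc``.
    """
    index = {g.protein_id: i for i, g in enumerate(genes)}
    ic, id_ = index[seed[0].protein_id], index[seed[1].protein_id]
    if abs(ic - id_) != 1:
        raise ValueError("seed genes are not adjacent in gene order")
    rmap = _role_map(roles) if roles is not None else {
        seed[0].protein_id: "susC_like",
        seed[1].protein_id: "susD_like",
    }
    is_cazy = [g.protein_id in cazy_labels for g in genes]
    lo, hi = _extend_indices(is_cazy, min(ic, id_), max(ic, id_), window)
    members = tuple(
        (g, _member_label(g, rmap, cazy_labels)) for g in genes[lo : hi + 1]
    )
    return Pul(
        pul_id=pul_id,
        genome_id=genes[0].genome_id,
        contig_id=genes[0].contig_id,
        genes=members,
        seeds=(seed,),
        span=(
            min(g.start for g, _ in members),
            max(g.end for g, _ in members),
        ),
    )


# ---------------------------------------------------------------------------
# whole-genome calling
# ---------------------------------------------------------------------------


def cazy_label_map(domains: Iterable[DomainHit]) -> dict[str, str]:
    """protein_id -> best-scoring CAZy base family."""
    best: dict[str, tuple[float, str]] = {}
    for hit in domains:
        if hit.source != "cazy":
            continue
        fam = hit.base_family
        cur = best.get(hit.protein_id)
        if cur is None or hit.bitscore > cur[0]:
            best[hit.protein_id] = (hit.bitscore, fam)
    return {pid: fam for pid, (_, fam) in best.items()}


def call_puls(
    genes: Sequence[GeneRecord],
    domains: Iterable[DomainHit],
    config: PulConfig = PulConfig(),
) -> list[Pul]:
    """Call all PUL in one genome's annotation bundle.

    Seeds come from tandem sus pairs; each seed is extended independently;
    extensions whose gene-index ranges overlap on a contig are merged into
    one PUL (union of genes, all seeds recorded). PUL ids are deterministic:
    ``<genome>:<contig>:<left-to-right index>``.
    """
    domains = list(domains)
    roles = assign_sus_roles(domains, config)
    rmap = _role_map(roles)
    labels = cazy_label_map(domains)

    by_contig: dict[str, list[GeneRecord]] = defaultdict(list)
    for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.end)):
        by_contig[g.contig_id].append(g)

    puls: list[Pul] = []
    for contig_id in sorted(by_contig):
        cgenes = by_contig[contig_id]
        index = {g.protein_id: i for i, g in enumerate(cgenes)}
        is_cazy = [g.protein_id in labels for g in cgenes]
        seeds = find_seed_pairs(cgenes, roles, config)
        intervals: list[tuple[int, int, tuple[GeneRecord, GeneRecord]]] = []
        for seed in seeds:
            ic, id_ = index[seed[0].protein_id], index[seed[1].protein_id]
            lo, hi = _extend_indices(
                is_cazy, min(ic, id_), max(ic, id_), config.window
            )
            intervals.append((lo, hi, seed))
        # merge overlapping (or touching-by-overlap) gene-index ranges
        intervals.sort(key=lambda t: (t[0], t[1]))
        merged: list[tuple[int, int, list]] = []
        for lo, hi, seed in intervals:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi),
                              merged[-1][2] + [seed])
            else:
                merged.append((lo, hi, [seed]))
        genome_id = cgenes[0].genome_id
        for i, (lo, hi, seed_list) in enumerate(merged, 1):
            members = tuple(
                (g, _member_label(g, rmap, labels)) for g in cgenes[lo : hi + 1]
            )
            puls.append(
                Pul(
                    pul_id=f"{genome_id}:{contig_id}:{i}",
                    genome_id=genome_id,
                    contig_id=contig_id,
                    genes=members,
                    seeds=tuple(seed_list),
                    span=(
                        min(g.start for g, _ in members),
                        max(g.end for g, _ in members),
                    ),
                )
            )
    return puls


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def pul_summary(puls: Iterable[Pul]) -> pd.DataFrame:
    """Per-genome PUL summary.

    Columns: genome_id, n_puls, min_genes, max_genes (locus sizes),
    n_simple (bare susC/susD pairs) and n_multi (everything else);
    n_simple + n_multi == n_puls for every genome.
    """
    rows: dict[str, dict] = {}
    for p in puls:
        r = rows.setdefault(
            p.genome_id,
            {"genome_id": p.genome_id, "n_puls": 0, "min_genes": None,
             "max_genes": None, "n_simple": 0, "n_multi": 0},
        )
        r["n_puls"] += 1
        n = p.n_genes
        r["min_genes"] = n if r["min_genes"] is None else min(r["min_genes"], n)
        r["max_genes"] = n if r["max_genes"] is None else max(r["max_genes"], n)
        if p.is_simple:
            r["n_simple"] += 1
        else:
            r["n_multi"] += 1
    df = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["genome_id"]),
        columns=["genome_id", "n_puls", "min_genes", "max_genes",
                 "n_simple", "n_multi"],
    )
    return df


def enzyme_occurrence(puls: Iterable[Pul]) -> pd.DataFrame:
    """Occurrences of each CAZy enzyme label across PUL.

    Columns: enzyme, occurrences (member genes with that label) and n_puls
    (distinct loci containing it); sorted by occurrences descending, then
    label. susC/susD/unc members are not enzymes and are excluded.
    """
    occ: dict[str, int] = defaultdict(int)
    loci: dict[str, set[str]] = defaultdict(set)
    for p in puls:
        for _, label in p.genes:
            if label in ("susC", "susD", "unc"):
                continue
            occ[label] += 1
            loci[label].add(p.pul_id)
    rows = [
        {"enzyme": lab, "occurrences": occ[lab], "n_puls": len(loci[lab])}
        for lab in occ
    ]
    rows.sort(key=lambda r: (-r["occurrences"], r["enzyme"]))
    return pd.DataFrame(rows, columns=["enzyme", "occurrences", "n_puls"])


# ---------------------------------------------------------------------------
# architecture signatures
# ---------------------------------------------------------------------------


def architecture_signature(pul: Pul) -> str:
    """Strand-aware label string for a locus.

    Member labels in coordinate order joined by ``-``; maximal runs of genes
    on the strand opposite the seed susC's are set off with `` | ``. The
    string round-trips through :func:`parse_signature`.
    """
    blocks: list[list[str]] = []
    prev_strand = None
    for gene, label in pul.genes:
        if gene.strand != prev_strand:
            blocks.append([])
            prev_strand = gene.strand
        blocks[-1].append(label)
    return " | ".join("-".join(b) for b in blocks)


def parse_signature(signature: str) -> list[tuple[str, str]]:
    """Parse a signature back into an ordered (label, strand) gene list.

    The block containing ``susC`` anchors the reference strand ``+``;
    neighbouring blocks alternate strands (they are maximal same-strand
    runs, so adjacent blocks necessarily differ).
    """
    blocks = [blk.split("-") for blk in signature.split(" | ")]
    anchor = next(
        (i for i, blk in enumerate(blocks) if "susC" in blk),
        len(blocks) - 1,
    )
    out = []
    for i, blk in enumerate(blocks):
        strand = "+" if (i - anchor) % 2 == 0 else "-"
        out.extend((label, strand) for label in blk)
    return out


def write_pul_table(puls: Iterable[Pul], path) -> None:
    """PUL TSV: pul_id, genome, contig, span, n_genes, signature, simple."""
    with open(path, "w") as fh:
        fh.write(
            "pul_id\tgenome_id\tcontig_id\tstart\tend\tn_genes\t"
            "signature\tsimple\n"
        )
        for p in puls:
            fh.write(
                f"{p.pul_id}\t{p.genome_id}\t{p.contig_id}\t{p.span[0]}\t"
                f"{p.span[1]}\t{p.n_genes}\t{architecture_signature(p)}\t"
                f"{int(p.is_simple)}\n"
            )
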