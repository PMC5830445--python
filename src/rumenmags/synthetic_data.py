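"""Synthetic inputs with known truth for every pipeline stage.

Generates annotated gene grids with planted PUL (layout strings use the
architecture-signature grammar, so generator and caller are mutually
inverse on clean data), multi-cohesin proteins, per-contig coverage
profiles with multi-copy plasmid contigs, best-hit identity tables drawn
from a two-component mixture (a novel bulk and a high-identity "known"
component), small taxonomies with reference genomes, and error-bearing
community reads. Every generator is driven by a single
``numpy.random.Generator`` stream, so a seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotations_io import BinStats, ContigCoverage, DomainHit, GeneRecord
from .kmer_classifier import TaxonomyTree
from .pul_caller import (
    DEFAULT_SUSC_PFAMS,
    DEFAULT_SUSD_PFAMS,
    parse_signature,
)

#: Non-CAZy Pfam labels handed to spacer genes so "unc" handling is exercised.
SPACER_PFAMS = ("PF00005", "PF00072", "PF00115", "PF01370", "PF02518")
#: CAZy families used for decoy genes.
DECOY_FAMILIES = ("GH2", "GH3", "GH13", "GT2", "CE1", "PL1", "CBM50")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for all generators.

    ``planted_pul_specs`` use the signature grammar; the second default is
    the two-strand xylan-degradation architecture. Coverage defaults put
    plasmids at copy number 3 over a 25-contig chromosome background with
    10 % depth noise; reads are 150 bp (the study's read length) with a
    0.5 % substitution rate; the identity mixture puts ~9 % of proteins in
    a high-identity "known" component.
    """

    seed: int = 0
    n_genomes: int = 5
    genes_per_contig: int = 30
    contigs_per_genome: int = 25
    planted_pul_specs: tuple[str, ...] = (
        "susC-susD",
        "GH43-GH10 | GH67-GH35-susC-susD-unc-GH10",
    )
    decoy_cazy_rate: float = 0.0
    window: int = 5
    planted_cohesin_counts: tuple[int, ...] = ()
    base_depth: float = 20.0
    plasmid_copy_numbers: tuple[float, ...] = (3.0,)
    coverage_noise_cv: float = 0.1
    identity_mixture: tuple[tuple[float, float, float], ...] = (
        (70.0, 8.0, 0.913),   # (mean, sd, weight): the novel bulk
        (98.0, 1.5, 0.087),   # the known, near-identical component
    )
    read_length: int = 150
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        for _, _, w in self.identity_mixture:
            if not 0 <= w <= 1:
                raise ValueError("mixture weights must lie in [0,1]")
        for rate in (self.decoy_cazy_rate, self.error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0,1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedPul:
    """Ground truth for one planted locus."""

    contig_id: str
    gene_ids: tuple[str, ...]
    seed_gene_ids: tuple[str, str]  # (susC, susD)
    signature: str


@dataclass
class SimulatedGenome:
    genome_id: str
    genes: list[GeneRecord]
    domain_hits: list[DomainHit]
    truth_puls: list[PlantedPul]
    truth_cohesin: dict[str, int]  # protein_id -> planted domain count


# ---------------------------------------------------------------------------
# annotated genomes with planted PUL
# ---------------------------------------------------------------------------

_GENE_LEN = 900
_GENE_GAP = 100


def _pfam_hit(pid: str, label: str, bitscore: float) -> DomainHit:
    return DomainHit(
        protein_id=pid, source="pfam", label=label, evalue=1e-20,
        ali_length=200, hmm_coverage=0.9, env_start=1, env_end=200,
        bitscore=bitscore,
    )


def _cazy_hit(pid: str, family: str) -> DomainHit:
    return DomainHit(
        protein_id=pid, source="cazy", label=family, evalue=1e-20,
        ali_length=250, hmm_coverage=0.9, env_start=1, env_end=250,
        bitscore=180.0,
    )


def simulate_annotated_genome(
    config: SimConfig,
    genome_id: str = "G1",
    rng: np.random.Generator | None = None,
) -> SimulatedGenome:
    """One genome: one contig per planted layout, plus truth records.

    Each planted layout sits mid-contig with at least ``2 * window``
    non-CAZy spacer genes on either side; spacer genes carry random
    non-CAZy Pfam labels, and with probability ``decoy_cazy_rate`` a spacer
    gene outside the window-wide exclusion zone around each planted
    boundary also gets a CAZy label (so decoys can never leak into a
    planted locus). Layouts lacking susC or susD raise.
    """
    rng = config.rng() if rng is None else rng
    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    truth_puls: list[PlantedPul] = []
    truth_cohesin: dict[str, int] = {}

    for ci, spec in enumerate(config.planted_pul_specs, 1):
        layout = parse_signature(spec)
        labels = [lab for lab, _ in layout]
        if "susC" not in labels or "susD" not in labels:
            raise ValueError(f"layout {spec!r} lacks susC or susD")
        contig_id = f"{genome_id}_c{ci}"
        spacer = max(2 * config.window, config.genes_per_contig // 4)
        n_total = 2 * spacer + len(layout)
        plan: list[tuple[str, str]] = []  # (label, strand)
        for _ in range(spacer):
            plan.append(("spacer", "+" if rng.random() < 0.5 else "-"))
        plan.extend(layout)
        for _ in range(spacer):
            plan.append(("spacer", "+" if rng.random() < 0.5 else "-"))
        assert len(plan) == n_total

        pul_lo, pul_hi = spacer, spacer + len(layout) - 1
        member_ids: list[str] = []
        seed_c = seed_d = ""
        pos = 1
        for gi, (label, strand) in enumerate(plan):
            pid = f"{contig_id}_g{gi + 1:03d}"
            genes.append(
                GeneRecord(
                    contig_id=contig_id, start=pos, end=pos + _GENE_LEN - 1,
                    strand=strand, gene_id=pid, protein_id=pid,
                    genome_id=genome_id,
                )
            )
            pos += _GENE_LEN + _GENE_GAP
            in_pul = pul_lo <= gi <= pul_hi
            if in_pul:
                member_ids.append(pid)
            if label == "susC":
                hits.append(_pfam_hit(pid, sorted(DEFAULT_SUSC_PFAMS)[0], 300.0))
                seed_c = pid
            elif label == "susD":
                hits.append(_pfam_hit(pid, sorted(DEFAULT_SUSD_PFAMS)[0], 280.0))
                seed_d = pid
            elif label == "unc" or label == "spacer":
                pfam = SPACER_PFAMS[int(rng.integers(len(SPACER_PFAMS)))]
                hits.append(_pfam_hit(pid, pfam, 50.0))
                near_boundary = (
                    pul_lo - config.window <= gi < pul_lo
                    or pul_hi < gi <= pul_hi + config.window
                )
                if (
                    label == "spacer"
                    and not near_boundary
                    and rng.random() < config.decoy_cazy_rate
                ):
                    fam = DECOY_FAMILIES[int(rng.integers(len(DECOY_FAMILIES)))]
                    hits.append(_cazy_hit(pid, fam))
            else:  # a CAZy family label
                hits.append(_cazy_hit(pid, label))
        truth_puls.append(
            PlantedPul(
                contig_id=contig_id,
                gene_ids=tuple(member_ids),
                seed_gene_ids=(seed_c, seed_d),
                signature=spec,
            )
        )

    # multi-cohesin proteins live on their own contig, clear of any PUL
    if config.planted_cohesin_counts:
        contig_id = f"{genome_id}_coh"
        pos = 1
        for pi, n_domains in enumerate(config.planted_cohesin_counts, 1):
            pid = f"{contig_id}_p{pi}"
            genes.append(
                GeneRecord(
                    contig_id=contig_id, start=pos, end=pos + _GENE_LEN - 1,
                    strand="+", gene_id=pid, protein_id=pid,
                    genome_id=genome_id,
                )
            )
            pos += _GENE_LEN + _GENE_GAP
            for d in range(n_domains):
                start = 1 + 150 * d
                hits.append(
                    DomainHit(
                        protein_id=pid, source="pfam", label="PF00963",
                        evalue=1e-15, ali_length=100, hmm_coverage=0.8,
                        env_start=start, env_end=start + 99,
                        bitscore=90.0 - d,
                    )
                )
            truth_cohesin[pid] = n_domains

    return SimulatedGenome(
        genome_id=genome_id,
        genes=genes,
        domain_hits=hits,
        truth_puls=truth_puls,
        truth_cohesin=truth_cohesin,
    )


# ---------------------------------------------------------------------------
# coverage with plasmid contigs
# ---------------------------------------------------------------------------


def simulate_coverage(
    config: SimConfig,
    genome_id: str = "G1",
    rng: np.random.Generator | None = None,
) -> tuple[list[ContigCoverage], list[str]]:
    """Per-contig depths for one genome plus the true plasmid contig ids.

    Chromosome contigs draw from Normal(base_depth, cv * base_depth)
    truncated at 0; each entry of ``plasmid_copy_numbers`` adds one contig
    at copy_number * base_depth with the same coefficient of variation.
    """
    rng = config.rng() if rng is None else rng
    covs: list[ContigCoverage] = []
    cv = config.coverage_noise_cv
    for i in range(config.contigs_per_genome):
        mu = config.base_depth
        depth = mu if cv == 0 else max(0.0, rng.normal(mu, cv * mu))
        covs.append(
            ContigCoverage(
                contig_id=f"{genome_id}_c{i + 1}", genome_id=genome_id,
                depth=depth, length=int(rng.integers(5_000, 200_000)),
            )
        )
    plasmids: list[str] = []
    for j, copies in enumerate(config.plasmid_copy_numbers, 1):
        if copies < 1:
            raise ValueError("plasmid copy numbers must be >= 1")
        mu = copies * config.base_depth
        depth = mu if cv == 0 else max(0.0, rng.normal(mu, cv * mu))
        contig_id = f"{genome_id}_plasmid{j}"
        covs.append(
            ContigCoverage(
                contig_id=contig_id, genome_id=genome_id,
                depth=depth, length=int(rng.integers(2_000, 10_000)),
            )
        )
        plasmids.append(contig_id)
    return covs, plasmids


# ---------------------------------------------------------------------------
# identity tables
# ---------------------------------------------------------------------------


def simulate_identity_table(
    config: SimConfig,
    n_proteins: int,
    databases: Sequence[str] = ("nr", "trembl"),
    rng: np.random.Generator | None = None,
) -> tuple[list[str], list["BestIdentity"], list[int]]:
    """Best-hit identities from the configured mixture.

    Returns (protein_ids, identities, component_of_protein). The maximum
    identity is drawn from the mixture and assigned to one random database;
    other databases get strictly lower values. Component indices are the
    truth for novelty scoring.
    """
    from .cazy_profile import BestIdentity

    rng = config.rng() if rng is None else rng
    means = np.array([m for m, _, _ in config.identity_mixture])
    sds = np.array([s for _, s, _ in config.identity_mixture])
    weights = np.array([w for _, _, w in config.identity_mixture])
    weights = weights / weights.sum()
    protein_ids = [f"prot{i + 1:06d}" for i in range(n_proteins)]
    components = rng.choice(len(means), size=n_proteins, p=weights)
    identities = []
    for pid, comp in zip(protein_ids, components):
        best = float(np.clip(rng.normal(means[comp], sds[comp]), 0.0, 100.0))
        top_db = databases[int(rng.integers(len(databases)))]
        per_db = {}
        for db in databases:
            if db == top_db:
                per_db[db] = best
            else:
                per_db[db] = float(max(0.0, best - abs(rng.normal(5.0, 3.0))))
        identities.append(BestIdentity(protein_id=pid, per_database=per_db))
    return protein_ids, identities, [int(c) for c in components]


# ---------------------------------------------------------------------------
# bin statistics
# ---------------------------------------------------------------------------

_PHYLA = ("Firmicutes", "Bacteroidetes", "Actinobacteria",
          "Proteobacteria", "Euryarchaeota", "Spirochaetes")


def simulate_bin_stats(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[BinStats]:
    """Random bin-quality table with varying lineage resolution depths."""
    rng = config.rng() if rng is None else rng
    stats = []
    for i in range(config.n_genomes):
        completeness = float(rng.uniform(60, 100))
        contamination = float(rng.uniform(0, 15))
        depth = int(rng.integers(1, 8))  # resolved down to this many ranks
        phylum = _PHYLA[int(rng.integers(len(_PHYLA)))]
        full = ("Bacteria", phylum, f"class{i}", f"order{i}",
                f"family{i}", f"genus{i}", f"species{i}")
        lineage = tuple(
            full[r] if r < depth else "" for r in range(7)
        )
        stats.append(
            BinStats(
                genome_id=f"MAG{i + 1:03d}",
                completeness=completeness,
                contamination=contamination,
                n_contigs=int(rng.integers(10, 300)),
                mean_coverage=float(rng.uniform(5, 50)),
                lineage=lineage,
            )
        )
    return stats


# ---------------------------------------------------------------------------
# taxonomy, reference genomes, community reads
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_taxonomy(n_species: int, species_per_genus: int = 2) -> TaxonomyTree:
    """A small rooted taxonomy: root -> genera -> species leaves."""
    parent = {"root": "root"}
    rank = {"root": "kingdom"}
    name = {"root": "Bacteria"}
    for s in range(n_species):
        genus = f"g{s // species_per_genus + 1}"
        species = f"s{s + 1}"
        parent.setdefault(genus, "root")
        rank.setdefault(genus, "genus")
        name.setdefault(genus, genus)
        parent[species] = genus
        rank[species] = "species"
        name[species] = species
    return TaxonomyTree(parent=parent, rank=rank, name=name)


def simulate_reference_genomes(
    taxa: Sequence[str],
    genome_length: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """One random genome sequence per taxon (independent sequences)."""
    return [(random_sequence(genome_length, rng), taxon) for taxon in taxa]


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    sequence: str
    source: str  # name/taxon of the reference it was drawn from


def simulate_community_reads(
    references: Sequence[tuple[str, str]],
    abundances: Sequence[float],
    config: SimConfig,
    n_reads: int,
    rng: np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Draw reads from (sequence, name) references at given abundances.

    Start positions are uniform; substitution errors are i.i.d. at
    ``error_rate`` (no indels). Raises if any reference is shorter than the
    read length or abundances do not sum to 1.
    """
    rng = config.rng() if rng is None else rng
    if abs(sum(abundances) - 1.0) > 1e-9:
        raise ValueError("abundances must sum to 1")
    for seq, name in references:
        if len(seq) < config.read_length:
            raise ValueError(f"reference {name!r} shorter than read_length")
    reads = []
    L = config.read_length
    sources = rng.choice(len(references), size=n_reads, p=list(abundances))
    for i, ref_idx in enumerate(sources):
        seq, name = references[ref_idx]
        start = int(rng.integers(0, len(seq) - L + 1))
        frag = list(seq[start : start + L])
        if config.error_rate > 0:
            err = rng.random(L) < config.error_rate
            for j in np.flatnonzero(err):
                choices = [b for b in "ACGT" if b != frag[j]]
                frag[j] = choices[int(rng.integers(3))]
        reads.append(
            SimulatedRead(
                read_id=f"read{i + 1:06d}", sequence="".join(frag), source=name
            )
        )
    return reads


def write_reads_fastq(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} source={r.source}\n{r.sequence}\n+\n")
            fh.write("I" * len(r.sequence) + "\n")


def write_references_fasta(
    references: Sequence[tuple[str, str]], path
) -> None:
    with open(path, "w") as fh:
        for i, (seq, taxon) in enumerate(references, 1):
            fh.write(f">ref{i} taxon={taxon}\n")
            for j in range(0, len(seq), 80):
                fh.write(seq[j : j + 80] + "\n")
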