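"""Readers and writers for the annotation tables the pipeline consumes.

Everything downstream works on a handful of plain dataclasses defined here:
gene calls (from GFF3), domain hits (pfam_scan, hmmscan --domtblout, or the
dbCAN parser TSV), BLAST tabular hits (outfmt 6/7 with a configurable column
order), per-genome bin statistics, and per-contig coverage.

Coordinates are 1-based inclusive throughout (the GFF3 convention); use
:func:`to_zero_based` / :func:`from_zero_based` at the boundary if a
half-open view is needed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

logger = logging.getLogger("rumenmags")

TAXONOMY_RANKS = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Default 15-column blastn layout used for the plasmid screen.
BLAST15_COLUMNS = (
    "qseqid qlen sseqid sacc stitle slen qstart qend sstart send "
    "length evalue bitscore pident staxid"
).split()

#: Classic 12-column outfmt 6.
BLAST12_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore"
).split()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One called gene (CDS) on a contig; 1-based inclusive coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str = ""
    protein_id: str = ""
    genome_id: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """A domain/family assignment on a protein.

    ``source`` is ``"pfam"`` or ``"cazy"``; ``label`` holds the accession or
    family name (CAZy labels are normalised, e.g. ``GH67.hmm`` -> ``GH67``).
    ``hmm_coverage`` is the fraction of the HMM covered by the alignment when
    the table provides the spans, else NaN.
    """

    protein_id: str
    source: str
    label: str
    evalue: float = math.nan
    ali_length: int = 0
    hmm_coverage: float = math.nan
    env_start: int = 0
    env_end: int = 0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not math.isnan(self.evalue) and self.evalue < 0:
            raise ValueError(f"negative evalue on {self.protein_id}")
        if not math.isnan(self.hmm_coverage) and not 0 <= self.hmm_coverage <= 1:
            raise ValueError(f"hmm_coverage outside [0,1] on {self.protein_id}")
        if self.env_start and self.env_end and self.env_start > self.env_end:
            raise ValueError(f"env_start > env_end on {self.protein_id}")

    @property
    def base_family(self) -> str:
        """CAZy family with any subfamily suffix stripped (GH13_10 -> GH13)."""
        return re.sub(r"_\d+$", "", self.label)


@dataclass(frozen=True)
class BlastHit:
    """One row of BLAST tabular output; unprovided columns keep defaults."""

    qseqid: str = ""
    qlen: int = 0
    sseqid: str = ""
    sacc: str = ""
    stitle: str = ""
    slen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    length: int = 0
    evalue: float = math.nan
    bitscore: float = 0.0
    pident: float = math.nan
    staxid: str = ""

    def __post_init__(self) -> None:
        if not math.isnan(self.pident) and not 0 <= self.pident <= 100:
            raise ValueError(f"pident outside [0,100] on {self.qseqid}")


@dataclass(frozen=True)
class BinStats:
    """Per-genome quality statistics and taxonomy lineage.

    ``lineage`` is an ordered 7-tuple kingdom..species; absent ranks are
    empty strings and must fill top-down (no gaps below a filled rank).
    """

    genome_id: str
    completeness: float
    contamination: float
    n_contigs: int = 0
    mean_coverage: float = math.nan
    lineage: tuple[str, ...] = ("",) * 7

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"{self.genome_id}: completeness outside [0,100]")
        if self.contamination < 0:
            raise ValueError(f"{self.genome_id}: negative contamination")
        if len(self.lineage) != len(TAXONOMY_RANKS):
            raise ValueError(f"{self.genome_id}: lineage must have 7 ranks")
        seen_empty = False
        for value in self.lineage:
            if value == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"{self.genome_id}: lineage has a gap below a filled rank"
                )

    def deepest_rank(self) -> str | None:
        """Deepest non-empty rank name, or None for an unresolved lineage."""
        rank = None
        for name, value in zip(TAXONOMY_RANKS, self.lineage):
            if value:
                rank = name
        return rank


@dataclass(frozen=True)
class ContigCoverage:
    contig_id: str
    genome_id: str
    depth: float
    length: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"{self.contig_id}: negative depth")
        if self.length <= 0:
            raise ValueError(f"{self.contig_id}: non-positive length")


# ---------------------------------------------------------------------------
# coordinate converters
# ---------------------------------------------------------------------------


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def from_zero_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# ---------------------------------------------------------------------------
# gene calls (GFF3)
# ---------------------------------------------------------------------------


def read_gene_calls(
    gff3_path: str | Path,
    genome_id: str = "",
    id_attribute: str = "ID",
) -> list[GeneRecord]:
    """Parse CDS features from a GFF3 file into sorted :class:`GeneRecord`.

    Records with start > end are rejected with a logged warning; an unknown
    strand symbol raises. ``id_attribute`` selects the attribute holding the
    protein identifier (prodigal writes ``ID=contig_1``).
    """
    path = Path(gff3_path)
    records: list[GeneRecord] = []
    text = path.read_text()
    if text.strip():
        for feature in gffutils.iterators.DataIterator(str(path)):
            if feature.featuretype != "CDS":
                continue
            if feature.strand not in ("+", "-"):
                raise ValueError(
                    f"{path.name}: unknown strand {feature.strand!r} "
                    f"on {feature.seqid}:{feature.start}"
                )
            if feature.start > feature.end:
                logger.warning(
                    "%s: rejecting CDS with start>end at %s:%s-%s",
                    path.name, feature.seqid, feature.start, feature.end,
                )
                continue
            ids = feature.attributes.get(id_attribute, [])
            gene_id = ids[0] if ids else f"{feature.seqid}:{feature.start}"
            records.append(
                GeneRecord(
                    contig_id=feature.seqid,
                    start=feature.start,
                    end=feature.end,
                    strand=feature.strand,
                    gene_id=gene_id,
                    protein_id=gene_id,
                    genome_id=genome_id,
                )
            )
    records.sort(key=lambda g: (g.contig_id, g.start, g.end))
    return records


def write_gene_calls(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write gene records as a minimal GFF3 (CDS features, ID attribute)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig_id}\trumenmags\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# domain tables
# ---------------------------------------------------------------------------

DOMAIN_DIALECTS = ("pfam_scan", "hmmscan_domtbl", "dbcan_tsv")


def normalize_cazy_label(raw: str) -> str:
    """Strip the ``.hmm`` suffix dbCAN leaves on family names."""
    return raw[:-4] if raw.endswith(".hmm") else raw


def _coverage(hmm_from: int, hmm_to: int, hmm_len: int) -> float:
    if hmm_len <= 0:
        return math.nan
    return (hmm_to - hmm_from + 1) / hmm_len


def _parse_pfam_scan_row(parts: list[str]) -> DomainHit:
    # pfam_scan.pl: seq_id aln_start aln_end env_start env_end hmm_acc
    # hmm_name type hmm_start hmm_end hmm_length bitscore evalue
    # significance clan
    env_start, env_end = int(parts[3]), int(parts[4])
    hmm_start, hmm_end, hmm_len = int(parts[8]), int(parts[9]), int(parts[10])
    label = parts[5].split(".")[0]  # PF00963.20 -> PF00963
    return DomainHit(
        protein_id=parts[0],
        source="pfam",
        label=label,
        evalue=float(parts[12]),
        ali_length=int(parts[2]) - int(parts[1]) + 1,
        hmm_coverage=_coverage(hmm_start, hmm_end, hmm_len),
        env_start=env_start,
        env_end=env_end,
        bitscore=float(parts[11]),
    )


def _parse_domtbl_row(parts: list[str], source: str) -> DomainHit:
    # hmmscan --domtblout: target tacc tlen query qacc qlen E-value score bias
    # # of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to
    # env_from env_to acc description...
    label = parts[0]
    if source == "cazy":
        label = normalize_cazy_label(label)
    hmm_from, hmm_to, tlen = int(parts[15]), int(parts[16]), int(parts[2])
    ali_from, ali_to = int(parts[17]), int(parts[18])
    return DomainHit(
        protein_id=parts[3],
        source=source,
        label=label,
        evalue=float(parts[12]),  # i-Evalue, per-domain
        ali_length=ali_to - ali_from + 1,
        hmm_coverage=_coverage(hmm_from, hmm_to, tlen),
        env_start=int(parts[19]),
        env_end=int(parts[20]),
        bitscore=float(parts[13]),
    )


def _parse_dbcan_row(parts: list[str]) -> DomainHit:
    # dbCAN hmmscan-parser.sh output: family hmm_len query query_len evalue
    # hmm_from hmm_to ali_from ali_to coverage  (2-column minimum:
    # family, query)
    label = normalize_cazy_label(parts[0])
    if len(parts) >= 10:
        return DomainHit(
            protein_id=parts[2],
            source="cazy",
            label=label,
            evalue=float(parts[4]),
            ali_length=int(parts[8]) - int(parts[7]) + 1,
            hmm_coverage=float(parts[9]),
            env_start=int(parts[7]),
            env_end=int(parts[8]),
        )
    return DomainHit(protein_id=parts[1], source="cazy", label=label)


_DIALECT_MIN_COLUMNS = {"pfam_scan": 15, "hmmscan_domtbl": 22, "dbcan_tsv": 2}


def read_domain_table(
    path: str | Path,
    dialect: str,
    source: str | None = None,
) -> list[DomainHit]:
    """Read a domain-hit table in one of the supported dialects.

    ``dialect`` is one of ``pfam_scan``, ``hmmscan_domtbl`` or ``dbcan_tsv``.
    ``source`` overrides the hit source tag (defaults: pfam for pfam_scan,
    cazy for dbcan_tsv; required choice for hmmscan_domtbl defaults to cazy).
    Comment lines (``#``) and blank lines are skipped; a row with too few
    columns raises an error naming the line.
    """
    if dialect not in DOMAIN_DIALECTS:
        raise ValueError(f"unknown domain-table dialect {dialect!r}")
    if source is None:
        source = "pfam" if dialect == "pfam_scan" else "cazy"
    min_cols = _DIALECT_MIN_COLUMNS[dialect]
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t") if dialect == "dbcan_tsv" else line.split()
            if len(parts) < min_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected >={min_cols} columns, "
                    f"got {len(parts)}"
                )
            if dialect == "pfam_scan":
                hit = _parse_pfam_scan_row(parts)
                if source != "pfam":
                    hit = replace(hit, source=source,
                                  label=normalize_cazy_label(parts[6]))
            elif dialect == "hmmscan_domtbl":
                hit = _parse_domtbl_row(parts, source)
            else:
                hit = _parse_dbcan_row(parts)
                if source != "cazy":
                    hit = replace(hit, source=source)
            hits.append(hit)
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the 10-column dbCAN-parser TSV dialect."""
    with open(path, "w") as fh:
        for h in hits:
            cov = 0.0 if math.isnan(h.hmm_coverage) else h.hmm_coverage
            ev = 0.0 if math.isnan(h.evalue) else h.evalue
            fh.write(
                f"{h.label}\t0\t{h.protein_id}\t0\t{ev:g}\t0\t0\t"
                f"{h.env_start}\t{h.env_end}\t{cov:g}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular
# ---------------------------------------------------------------------------

_BLAST_INT = {"qlen", "slen", "qstart", "qend", "sstart", "send", "length"}
_BLAST_FLOAT = {"evalue", "bitscore", "pident"}


def read_blast_tab(
    path: str | Path,
    columns: Sequence[str] = BLAST15_COLUMNS,
) -> list[BlastHit]:
    """Read BLAST outfmt 6/7 with the given column order.

    ``#``-prefixed comment lines are skipped. Column names not in
    :class:`BlastHit` (e.g. ``mismatch``) are parsed and dropped.
    """
    known = set(BlastHit.__dataclass_fields__)
    hits: list[BlastHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(columns):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(columns)} columns, "
                    f"got {len(parts)}"
                )
            kwargs = {}
            for name, value in zip(columns, parts):
                if name not in known:
                    continue
                if name in _BLAST_INT:
                    kwargs[name] = int(value)
                elif name in _BLAST_FLOAT:
                    kwargs[name] = float(value)
                else:
                    kwargs[name] = value
            hits.append(BlastHit(**kwargs))
    return hits


def write_blast_tab(
    hits: Iterable[BlastHit],
    path: str | Path,
    columns: Sequence[str] = BLAST15_COLUMNS,
) -> None:
    with open(path, "w") as fh:
        for h in hits:
            values = []
            for name in columns:
                v = getattr(h, name)
                values.append(f"{v:g}" if isinstance(v, float) else str(v))
            fh.write("\t".join(values) + "\n")


# ---------------------------------------------------------------------------
# bin stats / coverage TSVs
# ---------------------------------------------------------------------------


def read_bin_stats(path: str | Path) -> list[BinStats]:
    """Read a bin-stats TSV with a header line.

    Required columns: genome_id, completeness, contamination. Optional:
    n_contigs, mean_coverage, and the seven rank columns kingdom..species.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("genome_id", "completeness", "contamination"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(row)
        lineage = tuple(d.get(rank, "") for rank in TAXONOMY_RANKS)
        out.append(
            BinStats(
                genome_id=d["genome_id"],
                completeness=float(d["completeness"]),
                contamination=float(d["contamination"]),
                n_contigs=int(d["n_contigs"]) if d.get("n_contigs") else 0,
                mean_coverage=(
                    float(d["mean_coverage"]) if d.get("mean_coverage")
                    else math.nan
                ),
                lineage=lineage,
            )
        )
    return out


def write_bin_stats(stats: Iterable[BinStats], path: str | Path) -> None:
    cols = ["genome_id", "completeness", "contamination", "n_contigs",
            "mean_coverage", *TAXONOMY_RANKS]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in stats:
            mc = "" if math.isnan(s.mean_coverage) else f"{s.mean_coverage:g}"
            fh.write(
                f"{s.genome_id}\t{s.completeness:g}\t{s.contamination:g}\t"
                f"{s.n_contigs}\t{mc}\t" + "\t".join(s.lineage) + "\n"
            )


def read_coverage(path: str | Path) -> list[ContigCoverage]:
    """Read a coverage TSV: contig_id, genome_id, length, depth (header)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("contig_id", "genome_id", "length", "depth"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    return [
        ContigCoverage(
            contig_id=str(r.contig_id),
            genome_id=str(r.genome_id),
            depth=float(r.depth),
            length=int(r.length),
        )
        for r in df.itertuples(index=False)
    ]


def write_coverage(covs: Iterable[ContigCoverage], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig_id\tgenome_id\tlength\tdepth\n")
        for c in covs:
            fh.write(f"{c.contig_id}\t{c.genome_id}\t{c.length}\t{c.depth:g}\n")


def read_hic_pairs(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a pre-digested Hi-C contig-pair TSV: contig_a, contig_b, n_pairs."""
    pairs = []
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("contig_a"):
            raise ValueError(f"{path}: expected header contig_a/contig_b/n_pairs")
        for line in fh:
            if not line.strip():
                continue
            a, b, n = line.rstrip("\n").split("\t")
            pairs.append((a, b, int(n)))
    return pairs


def write_hic_pairs(
    pairs: Iterable[tuple[str, str, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("contig_a\tcontig_b\tn_pairs\n")
        for a, b, n in pairs:
            fh.write(f"{a}\t{b}\t{n}\n")
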