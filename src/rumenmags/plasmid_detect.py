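"""Coverage-based plasmid detection and Hi-C link attribution.

Multi-copy plasmids sit at elevated read depth relative to their host
genome: contigs with depth strictly greater than ``factor`` times the
genome's mean coverage are extracted, their BLAST hits filtered (HSPs
shorter than 500 bp or covering less than 10 % of the query are dropped),
and contigs with a surviving hit whose subject title contains "plasmid"
are flagged. Hi-C read pairs then attribute flagged contigs to genome
clusters via a contig x cluster link-count matrix.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotations_io import BlastHit, ContigCoverage


def bin_mean_coverage(
    coverages: Sequence[ContigCoverage], weighted: bool = False
) -> float:
    """Mean depth of one genome's contigs.

    Unweighted arithmetic mean by default; ``weighted=True`` weights each
    contig by its length.
    """
    if not coverages:
        raise ValueError("genome has no contigs")
    if weighted:
        total = sum(c.length for c in coverages)
        return sum(c.depth * c.length for c in coverages) / total
    return sum(c.depth for c in coverages) / len(coverages)


def high_copy_contigs(
    coverages: Iterable[ContigCoverage],
    factor: float = 2.0,
    weighted: bool = False,
) -> list[str]:
    """Contigs with depth strictly > factor x their genome's mean coverage.

    The strict inequality means a uniform-depth genome yields nothing, and
    the selection is invariant under uniform scaling of all depths.
    """
    by_genome: dict[str, list[ContigCoverage]] = defaultdict(list)
    for c in coverages:
        by_genome[c.genome_id].append(c)
    flagged = []
    for genome_id in sorted(by_genome):
        contigs = by_genome[genome_id]
        mean = bin_mean_coverage(contigs, weighted=weighted)
        flagged.extend(c.contig_id for c in contigs if c.depth > factor * mean)
    return flagged


def filter_hsps(
    hits: Iterable[BlastHit],
    min_len: int = 500,
    min_qfrac: float = 0.10,
) -> list[BlastHit]:
    """Drop short HSPs: keep iff length >= min_len AND length/qlen >= min_qfrac.

    Boundary values survive (the removal rule is strictly-below on both).
    """
    kept = []
    for h in hits:
        if h.qlen <= 0:
            raise ValueError(f"{h.qseqid}: qlen must be > 0")
        if h.length >= min_len and h.length / h.qlen >= min_qfrac:
            kept.append(h)
    return kept


def flag_plasmid_contigs(hits: Iterable[BlastHit]) -> dict[str, BlastHit]:
    """Contigs with >=1 surviving hit whose title contains "plasmid".

    Case-insensitive substring match on ``stitle``. Returns contig_id ->
    its best (highest-bitscore) plasmid hit, keys sorted.
    """
    best: dict[str, BlastHit] = {}
    for h in hits:
        if "plasmid" not in h.stitle.lower():
            continue
        cur = best.get(h.qseqid)
        if cur is None or h.bitscore > cur.bitscore:
            best[h.qseqid] = h
    return dict(sorted(best.items()))


def hic_link_counts(
    pairs: Iterable[tuple[str, str, int]],
    clusters: Mapping[str, Iterable[str]],
    contigs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Hi-C link-count matrix: rows = contigs, columns = genome clusters.

    ``pairs`` are (contig_a, contig_b, n_pairs) rows; ``clusters`` maps
    cluster_id to its member contigs (a partition — a contig in two
    clusters raises; unclustered contigs are allowed). Cell (c, K) sums the
    pair counts linking c to any member of K, excluding links of a contig
    to itself. ``contigs`` selects/orders the rows (default: every contig
    appearing on either side of a pair, sorted).
    """
    cluster_of: dict[str, str] = {}
    for cid, members in clusters.items():
        for contig in members:
            if contig in cluster_of and cluster_of[contig] != cid:
                raise ValueError(
                    f"contig {contig} is in clusters "
                    f"{cluster_of[contig]} and {cid}"
                )
            cluster_of[contig] = cid
    pairs = list(pairs)
    if contigs is None:
        contigs = sorted({a for a, _, _ in pairs} | {b for _, b, _ in pairs})
    col_ids = sorted(clusters)
    mat = pd.DataFrame(0, index=list(contigs), columns=col_ids, dtype=int)
    rowset = set(contigs)
    for a, b, n in pairs:
        if n < 0:
            raise ValueError(f"negative pair count for ({a}, {b})")
        if a == b:
            continue
        for contig, mate in ((a, b), (b, a)):
            if contig not in rowset:
                continue
            k = cluster_of.get(mate)
            if k is not None:
                mat.loc[contig, k] += n
    return mat


def write_link_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="contig_id")


def plot_link_heatmap(matrix: pd.DataFrame, path) -> None:
    """Render the link matrix as a heatmap PNG (contigs x clusters)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * matrix.shape[1]), max(3, 0.4 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.values, aspect="auto", cmap="Reds")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    ax.set_xlabel("genome cluster")
    ax.set_ylabel("plasmid contig")
    fig.colorbar(im, ax=ax, label="Hi-C links")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
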