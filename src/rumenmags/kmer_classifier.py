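"""A minimal exact-k-mer LCA read classifier.

Kraken-style at toy scale: every canonical k-mer in the reference set maps
to the lowest common ancestor (LCA) of all genomes containing it; a read
is assigned the leaf-most taxon maximising the summed k-mer hit weight
along its root-to-node path. The point is an exact, bit-reproducible
re-implementation of the classification rule — no minimizers, no
compressed index — so database-augmentation experiments (adding reference
genomes and measuring the classification-rate gain) can be run on
synthetic communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("rumenmags")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


# ---------------------------------------------------------------------------
# taxonomy tree
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTree:
    """Rooted taxonomy with parent pointers.

    ``parent[root] == root``; every node must reach the root. Ranks run
    kingdom to species but arbitrary rank strings are accepted.
    """

    parent: dict[str, str]
    rank: dict[str, str] = field(default_factory=dict)
    name: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        roots = [n for n, p in self.parent.items() if p == n]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {roots}")
        self.root = roots[0]
        self._depth: dict[str, int] = {}
        for node in self.parent:
            self.depth(node)

    def depth(self, node: str) -> int:
        if node in self._depth:
            return self._depth[node]
        seen = []
        cur = node
        while cur not in self._depth and cur != self.root:
            seen.append(cur)
            cur = self.parent[cur]
            if len(seen) > len(self.parent):
                raise ValueError("taxonomy contains a cycle")
        base = 0 if cur == self.root else self._depth[cur]
        self._depth.setdefault(self.root, 0)
        for i, n in enumerate(reversed(seen), 1):
            self._depth[n] = base + i
        return self._depth[node]

    def path_to_root(self, node: str) -> list[str]:
        """node, parent, ..., root."""
        out = [node]
        while out[-1] != self.root:
            out.append(self.parent[out[-1]])
        return out

    def lca(self, a: str, b: str) -> str:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a, da = self.parent[a], da - 1
        while db > da:
            b, db = self.parent[b], db - 1
        while a != b:
            a, b = self.parent[a], self.parent[b]
        return a

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        """Read a taxonomy TSV: node_id, parent_id, rank, name (header)."""
        parent, rank, name = {}, {}, {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("node_id"):
                raise ValueError(f"{path}: expected node_id/parent_id/rank/name")
            for line in fh:
                if not line.strip():
                    continue
                node, par, rk, nm = line.rstrip("\n").split("\t")
                parent[node], rank[node], name[node] = par, rk, nm
        return cls(parent=parent, rank=rank, name=name)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_id\tparent_id\trank\tname\n")
            for node in sorted(self.parent):
                fh.write(
                    f"{node}\t{self.parent[node]}\t"
                    f"{self.rank.get(node, '')}\t{self.name.get(node, '')}\n"
                )


# ---------------------------------------------------------------------------
# index
# ---------------------------------------------------------------------------


def canonical_kmer(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    """Canonical k-mer -> LCA taxon over a taxonomy tree."""

    k: int
    tree: TaxonomyTree
    kmer_to_taxon: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k < 11 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 11")

    def add_genome(self, sequence: str, taxon: str) -> None:
        """Add one reference; existing keys move toward the root via LCA."""
        if taxon not in self.tree.parent:
            raise ValueError(f"taxon {taxon!r} not in taxonomy")
        seq = sequence.upper()
        table = self.kmer_to_taxon
        for i in range(len(seq) - self.k + 1):
            kmer = seq[i : i + self.k]
            if any(c not in "ACGT" for c in kmer):
                continue
            key = canonical_kmer(kmer)
            cur = table.get(key)
            table[key] = taxon if cur is None else self.tree.lca(cur, taxon)


def build_index(
    references: Iterable[tuple[str, str]],
    tree: TaxonomyTree,
    k: int = 21,
) -> KmerIndex:
    """Index (sequence, taxon) references; k-mers containing N are skipped.

    Order-independent: permuting the references yields the same index.
    """
    index = KmerIndex(k=k, tree=tree)
    for sequence, taxon in references:
        index.add_genome(sequence, taxon)
    return index


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_read(read: str, index: KmerIndex) -> str | None:
    """Assign a read to a taxon, or None when no k-mer hits the index.

    Each indexed k-mer of the read adds weight 1 to its stored taxon; the
    winning node maximises the summed weight on its root-to-node path.
    Ties break to the deeper node, then the lexicographically smaller id.
    """
    if len(read) < index.k:
        logger.warning("read shorter than k=%d: unclassified", index.k)
        return None
    seq = read.upper()
    weights: dict[str, int] = {}
    for i in range(len(seq) - index.k + 1):
        kmer = seq[i : i + index.k]
        if any(c not in "ACGT" for c in kmer):
            continue
        taxon = index.kmer_to_taxon.get(canonical_kmer(kmer))
        if taxon is not None:
            weights[taxon] = weights.get(taxon, 0) + 1
    if not weights:
        return None
    tree = index.tree
    best: tuple[int, int, list[str]] | None = None  # (-score, -depth, [id])
    best_node = None
    for node in weights:
        score = sum(weights.get(anc, 0) for anc in tree.path_to_root(node))
        key = (-score, -tree.depth(node), node)
        if best is None or key < best:
            best = key
            best_node = node
    return best_node


def classification_rate(
    reads: Iterable[str], index: KmerIndex
) -> float:
    """Percent of reads classified at any rank."""
    total = 0
    classified = 0
    for read in reads:
        total += 1
        if classify_read(read, index) is not None:
            classified += 1
    if total == 0:
        raise ValueError("empty read set")
    return 100.0 * classified / total


def augmentation_experiment(
    reads: Sequence[str],
    base_refs: Sequence[tuple[str, str]],
    added_ref_sets: Mapping[str, Sequence[tuple[str, str]]],
    tree: TaxonomyTree,
    k: int = 21,
    include_combined: bool = True,
) -> dict[str, float]:
    """Classification rate per cumulative database.

    Builds ``base``, then ``base+<name>`` for each named reference set and
    (optionally) ``base+all``. Nested databases obey weak monotonicity:
    adding references never lowers the rate.
    """
    rates: dict[str, float] = {}
    rates["base"] = classification_rate(reads, build_index(base_refs, tree, k))
    for name in added_ref_sets:
        refs = list(base_refs) + list(added_ref_sets[name])
        rates[f"base+{name}"] = classification_rate(
            reads, build_index(refs, tree, k)
        )
    if include_combined and len(added_ref_sets) > 1:
        refs = list(base_refs)
        for name in added_ref_sets:
            refs.extend(added_ref_sets[name])
        rates["base+all"] = classification_rate(
            reads, build_index(refs, tree, k)
        )
    return rates


def write_rates(rates: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("database\tclassification_rate_pct\n")
        for name, rate in rates.items():
            fh.write(f"{name}\t{rate:.4f}\n")
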