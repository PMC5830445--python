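# Methods

This note documents the models and procedures implemented in `rumenmags`,
the parameters that matter, the numerical and design choices made where
the procedure was genuinely underdetermined, and what the synthetic-data
generator does and does not emulate.

## Coordinates and input formats

All genomic coordinates are 1-based inclusive (the GFF3 convention)
throughout the package; converters to 0-based half-open intervals exist
only at the boundary (`to_zero_based`/`from_zero_based`). A single
convention internally eliminates off-by-one drift between modules.

Domain tables are accepted in three dialects — `pfam_scan` (15
whitespace-separated columns), `hmmscan_domtbl` (HMMER3 `--domtblout`),
and `dbcan_tsv` (the 10-column dbCAN parser output, with a 2-column
minimum) — because annotation pipelines in the wild emit all three. CAZy
labels are normalised by stripping the `.hmm` suffix; subfamily labels
(`GH13_10`) are retained on the hit, with the base family (`GH13`)
exposed through an accessor, since locus signatures and class counts are
reported at base-family resolution. BLAST tabular input takes a
configurable column order; the default is the 15-column layout
(`qseqid qlen sseqid sacc stitle slen qstart qend sstart send length
evalue bitscore pident staxid`) used by the plasmid screen.

`DomainHit` carries a `bitscore` field beyond the minimum needed for
filtering: both the sus-role tie-break and the cohesin greedy selection
are defined on bitscore, so the type must transport it. Rows from
dialects that lack it (minimal dbCAN tables) default it to 0.

## Bin quality control

Pass filter: completeness ≥ 80 % and contamination ≤ 10 %, both
inclusive; high-quality draft tier: completeness > 90 % and contamination
< 5 %, both strict. The mixed semantics deliberately mirror the
inequality symbols in which these conventions are conventionally printed;
every high-quality draft therefore also passes the default filter, and
the boundary genome (90.0, 5.0) is a pass-tier draft, not high-quality.

Genus-based cleaning takes the genus→superkingdom mapping as an input
table rather than embedding a taxonomy: the rule (drop contigs whose
best-hit genus is neither Bacteria nor Archaea; keep uncalled contigs)
is the package's contribution, the database is not. Taxonomy-resolution
counts treat a lineage as resolved to rank *r* if any rank at *r* or
deeper is non-empty; lineages must fill top-down, and the counts are
monotone from kingdom to species by construction. The phylum breakdown
is computed over genomes with a non-empty phylum only.

## PUL calling

Protein roles come from configurable Pfam sets: susC-like =
{PF00593, PF07715} (TonB-dependent receptor plug + beta-barrel),
susD-like = {PF07980, PF12741, PF12771, PF14322}. These are the
PULDB-convention families; the concept is standard but no single
canonical accession list exists, hence the configuration point. A protein
carrying labels from both sets takes the role of its higher-bitscore hit,
ties resolving to susC.

A seed is a *tandem* pair: two consecutive genes in coordinate order, one
of each role, in either orientation, regardless of strand; a C-D-C chain
yields both adjacent pairs. "Tandem" is not otherwise defined in the
field, so an optional maximum intergenic gap (default: unlimited) is
provided but off by default.

Extension runs independently in each direction with a window of *w* = 5
gene predictions. From the current boundary, up to *w* genes are scanned
outward; if any carries a CAZy label the boundary jumps to the **farthest**
such gene within the window and the scan repeats; extension ends when a
window holds no CAZy gene or the contig does. Jumping to the farthest
(rather than nearest) hit makes the result a unique fixpoint in one pass
per direction; the test suite verifies equivalence with an independent
iterate-to-fixpoint re-scanner on 1000 random contigs. Extensions whose
gene ranges overlap merge into a single locus (union of genes, all seeds
recorded) so overlapping seed chains are never double-counted. PUL
identifiers are deterministic: `<genome>:<contig>:<left-to-right index>`.

Signatures print member labels in coordinate order joined by `-`, with
maximal same-strand runs separated by ` | `; genes holding a sus role
print the role even when they also carry a CAZy label, and unannotated
members print `unc`. `parse_signature` inverts the grammar (the block
containing `susC` anchors the reference strand; adjacent blocks alternate
by maximality), which makes the generator's layout strings and the
caller's output mutually inverse — the property the planted-truth tests
rely on.

A locus is *simple* when its members are exactly one susC and one susD
gene. Per-genome summaries partition counts into simple and multi-gene
loci; enzyme occurrence counts member genes per CAZy label together with
the number of distinct loci containing the label.

## Cellulosome screen

Cohesin hits (Pfam PF00963 by default) are deduplicated greedily by
descending bitscore (ties by envelope position for order-independence): a
hit counts if it overlaps every previously accepted envelope by at most
half the shorter envelope's length. The 50 % rule is an explicit design
choice — repeated cohesin domains are long and well-separated in real
scaffoldins, and the threshold only matters for marginal double-hits of
one domain. "Multiple" domains means ≥ 2, since two-domain proteins are
conventionally included among scaffoldin candidates.

## Plasmid detection

Genome mean coverage is the unweighted arithmetic mean of per-contig
depths ("mean average coverage" carries no weighting; a length-weighted
variant is available by flag). High-copy selection is strictly greater
than `factor` × mean (default 2), so a contig at exactly twice the mean
is not selected, and the selection is invariant under uniform depth
scaling. HSP filtering removes hits strictly below 500 bp or strictly
below 10 % of the query length — boundary values survive, matching the
removal rule's complement. Plasmid flagging is a case-insensitive
substring match of "plasmid" in the subject title; each flagged contig
reports its best hit by bitscore.

The Hi-C link matrix counts read pairs between a contig and any member of
a genome cluster; cluster membership must be a partition (unclustered
contigs allowed), self-links are excluded, and the matrix is reproducible
from the pair table by a brute-force double loop (tested).

## CAZy profiling

dbCAN filtering uses the published dbCAN defaults — keep iff
(alignment > 80 aa and E < 1e-5) or (alignment ≤ 80 aa and E < 1e-3), and
HMM coverage > 0.3 — all four numbers configurable, since pipelines cite
"suggested cut-offs" without printing them. A protein may carry several
surviving domains; class counts include that multiplicity, while identity
distributions count each protein once per class. Novelty: a protein is
known iff its maximum best-hit identity over all searched databases
reaches the threshold (≥ 95 %, inclusive); proteins absent from every hit
table are novel, so known + novel always partitions the protein set. The
maximum over databases (with per-database columns retained) is used for
the per-class identity distributions. Quantiles use the median-unbiased
(Hyndman–Fan type 8) convention so R and Python implementations agree;
the tests check against a closed-form oracle.

## k-mer LCA classifier

The index maps each canonical k-mer (lexicographic minimum of the k-mer
and its reverse complement) to the lowest common ancestor of all source
genomes containing it; adding a genome only inserts keys or moves
existing values rootward, which makes construction order-independent.
Classification sums per-taxon hit weights along each candidate's
root-to-node path and returns the maximising node, breaking ties to the
deeper node and then the lexicographically smaller identifier — fixed so
results are bit-reproducible. Default k = 21 (odd, ≥ 11): shorter than
production classifiers use, keeping desk-scale indexes small while
preserving the algorithm's behaviour; there is no minimizer or
compression machinery because correctness at toy scale is the point.
Reads shorter than k, or with no indexed k-mer, are unclassified.

The augmentation experiment builds nested databases (base, base+each
named set, base+all) and reports classification rates per database; for
nested databases the rate is weakly monotone, which the tests assert.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions under which all
operating characteristics are measured:

- **Gene grids.** 900 bp genes with 100 bp spacing; one contig per
  planted layout; layouts are signature-grammar strings (default: a bare
  `susC-susD` pair and the two-strand xylan architecture
  `GH43-GH10 | GH67-GH35-susC-susD-unc-GH10`), placed mid-contig with at
  least 2 × window spacer genes on each side. Spacer genes carry random
  non-CAZy Pfam labels so `unc` handling is exercised. Decoy CAZy labels
  (probability `decoy_cazy_rate` per spacer gene, default 0) are excluded
  from a window-wide zone around each planted boundary, so planted truth
  is preserved at any decoy rate — decoys can form separate clutter but
  can never chain into a planted locus.
- **Coverage.** 25 chromosome contigs per genome at Normal(20, cv·20)
  truncated at zero (cv = 0.1), plus one contig per configured plasmid
  copy number at copy × 20 with the same cv. Twenty-five contigs is a
  realistic contig count for a draft MAG and gives the 2× rule enough
  dilution that a copy-3 plasmid raises the genome mean by only ~8 %:
  under these conditions detection is ≈ 99.8 % and the copy-1
  false-positive rate is ≪ 1 %, which the Monte-Carlo tests verify over
  1000 simulations.
- **Identities.** A two-component Gaussian mixture on 0–100: a novel bulk
  at 70 ± 8 (weight 0.913) and a known component at 98 ± 1.5 (weight
  0.087), mirroring the ~9 % known share observed in rumen CAZyme
  surveys; the best identity is assigned to one random database, others
  sit strictly lower.
- **Reads.** 150 bp (the platform read length of the underlying data),
  uniform start positions, i.i.d. substitutions at 0.5 % — no indels, no
  quality model.
- **Determinism.** Every generator call consumes a single
  `numpy.random.Generator` stream; a seed fully determines all outputs,
  and truth records are sufficient to score every downstream module.

What passing these tests does **not** show: real annotation noise
(fragmented genes at contig edges, chimeric bins, HMM score ambiguity),
compositional coverage bias, Hi-C ligation artefacts, or real database
identity structure. The synthetic conditions establish algorithmic
correctness and operating characteristics under the stated noise models,
not survey-level numbers on real data.

## Problem sizes

The test suite runs planted-PUL recovery over 500 genomes, oracle
equivalence over 1000 random contigs, and the coverage Monte-Carlo over
1000 simulations; `scripts/acceptance.py` uses 300/150 genomes for the
recovery rates, 1000 coverage simulations, 5000 proteins for novelty, 500
bins for QC rates, and a 7-member community with 1500 reads and 5 kb
genomes for the augmentation experiment. These sizes give sub-percent
Monte-Carlo error on every reported rate while keeping a full run within
seconds on one CPU.

## Known limitations

- The PUL window counts gene predictions, not base pairs, and seeds are
  strand-agnostic; both are configurable but the defaults are opinions
  where the convention is silent.
- The cohesin overlap rule deduplicates by envelope overlap only; it does
  not model split domains.
- The classifier loads all k-mers into a Python dict; it is a correctness
  reference, not a production tool.
- `clean_bin` expects at most one genus call per contig; resolving
  conflicting calls is upstream's job.
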