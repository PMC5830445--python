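"""Shared builders and independent oracles used across the test suite.

The oracles here are deliberately written in a different style from the
implementation (brute-force scans, set algebra, closed-form formulas) so
they can act as independent checks.
"""

from __future__ import annotations

from rumenmags.annotations_io import DomainHit, GeneRecord


def make_genes(labels, contig="c1", genome="G1", strands=None):
    """A gene grid plus domain hits from a label list.

    Labels: "susC", "susD", a CAZy family (e.g. "GH10"), or "x" for an
    unannotated spacer. Returns (genes, domain_hits).
    """
    genes, hits = [], []
    pos = 1
    for i, label in enumerate(labels):
        strand = strands[i] if strands else "+"
        pid = f"{contig}_g{i + 1}"
        genes.append(
            GeneRecord(contig_id=contig, start=pos, end=pos + 899,
                       strand=strand, gene_id=pid, protein_id=pid,
                       genome_id=genome)
        )
        pos += 1000
        if label == "susC":
            hits.append(DomainHit(protein_id=pid, source="pfam",
                                  label="PF00593", evalue=1e-30,
                                  ali_length=200, hmm_coverage=0.9,
                                  env_start=1, env_end=200, bitscore=300.0))
        elif label == "susD":
            hits.append(DomainHit(protein_id=pid, source="pfam",
                                  label="PF07980", evalue=1e-30,
                                  ali_length=200, hmm_coverage=0.9,
                                  env_start=1, env_end=200, bitscore=280.0))
        elif label != "x":
            hits.append(DomainHit(protein_id=pid, source="cazy", label=label,
                                  evalue=1e-20, ali_length=250,
                                  hmm_coverage=0.9, env_start=1, env_end=250,
                                  bitscore=180.0))
    return genes, hits


def fixpoint_extend_oracle(is_cazy, lo, hi, window):
    """Iterate interval expansion to a fixpoint (independent re-scanner).

    On each pass the interval absorbs the farthest CAZy gene within
    ``window`` genes of either end; stops when a whole pass changes
    nothing.
    """
    n = len(is_cazy)
    changed = True
    while changed:
        changed = False
        left = [i for i in range(max(0, lo - window), lo) if is_cazy[i]]
        if left and min(left) < lo:
            lo = min(left)
            changed = True
        right = [i for i in range(hi + 1, min(n, hi + window + 1)) if is_cazy[i]]
        if right and max(right) > hi:
            hi = max(right)
            changed = True
    return lo, hi
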