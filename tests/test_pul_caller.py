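"""PUL calling: sus roles, seed pairs, window extension, signatures."""

import pytest

from rumenmags.annotations_io import DomainHit
from rumenmags import pul_caller as pc
from rumenmags.pul_caller import PulConfig

from _helpers import fixpoint_extend_oracle, make_genes


def pfam(pid, label, bitscore=100.0):
    return DomainHit(protein_id=pid, source="pfam", label=label,
                     evalue=1e-10, bitscore=bitscore)


# ---------------------------------------------------------------------------
# assign_sus_roles
# ---------------------------------------------------------------------------


def test_cazy_only_protein_has_no_role():
    hits = [DomainHit(protein_id="p", source="cazy", label="GH10")]
    assert pc.assign_sus_roles(hits) == []


def test_susd_family_label_gives_susd_role():
    roles = pc.assign_sus_roles([pfam("p", "PF07980")])
    assert roles == [pc.SusRole("p", "susD_like")]


def test_dual_label_resolves_by_bitscore_tie_to_susc():
    both_tie = [pfam("p", "PF00593", 80.0), pfam("p", "PF07980", 80.0)]
    assert pc.assign_sus_roles(both_tie)[0].role == "susC_like"
    d_wins = [pfam("p", "PF00593", 80.0), pfam("p", "PF12741", 95.0)]
    assert pc.assign_sus_roles(d_wins)[0].role == "susD_like"


def test_roles_match_membership_oracle(rng):
    cfg = PulConfig()
    labels = ["PF00593", "PF07715", "PF07980", "PF12741", "GH10", "PF00005"]
    hits = []
    for i in range(20):
        lab = labels[int(rng.integers(len(labels)))]
        src = "cazy" if lab.startswith("GH") else "pfam"
        hits.append(DomainHit(protein_id=f"p{i}", source=src, label=lab,
                              evalue=1e-8, bitscore=float(rng.uniform(30, 200))))
    roles = {r.protein_id: r.role for r in pc.assign_sus_roles(hits, cfg)}
    for h in hits:
        if h.source != "pfam":
            assert h.protein_id not in roles or True
        elif h.label in cfg.susc_pfams:
            assert roles[h.protein_id] == "susC_like"
        elif h.label in cfg.susd_pfams:
            assert roles[h.protein_id] == "susD_like"
        else:
            assert h.protein_id not in roles


# ---------------------------------------------------------------------------
# find_seed_pairs
# ---------------------------------------------------------------------------


def seeds_for(labels, **kw):
    genes, hits = make_genes(labels, **kw)
    roles = pc.assign_sus_roles(hits)
    return genes, pc.find_seed_pairs(genes, roles)


def test_adjacent_pair_found_in_either_order():
    _, pairs = seeds_for(["susC", "susD"])
    assert len(pairs) == 1
    genes, pairs_rev = seeds_for(["susD", "susC"])
    assert len(pairs_rev) == 1
    # returned orientation is always (susC gene, susD gene)
    assert pairs_rev[0][0].protein_id == genes[1].protein_id


def test_intervening_gene_breaks_tandem():
    _, pairs = seeds_for(["susC", "GH10", "susD"])
    assert pairs == []


def test_cdc_chain_yields_both_adjacent_pairs():
    _, pairs = seeds_for(["susD", "susC", "susD"])
    assert len(pairs) == 2


def test_pairs_never_span_contigs():
    genes_a, hits_a = make_genes(["x", "susC"], contig="c1")
    genes_b, hits_b = make_genes(["susD", "x"], contig="c2")
    genes = genes_a + genes_b
    roles = pc.assign_sus_roles(hits_a + hits_b)
    assert pc.find_seed_pairs(genes, roles) == []


def test_max_intergenic_gap_filters_distant_pairs():
    genes, hits = make_genes(["susC", "susD"])  # 100 bp gap in the grid
    roles = pc.assign_sus_roles(hits)
    tight = PulConfig(max_intergenic_gap=50)
    loose = PulConfig(max_intergenic_gap=200)
    assert pc.find_seed_pairs(genes, roles, tight) == []
    assert len(pc.find_seed_pairs(genes, roles, loose)) == 1


# ---------------------------------------------------------------------------
# extend_pul
# ---------------------------------------------------------------------------


def extend(labels, window=5):
    genes, hits = make_genes(labels)
    roles = pc.assign_sus_roles(hits)
    (seed,) = pc.find_seed_pairs(genes, roles)
    labels_map = pc.cazy_label_map(hits)
    return pc.extend_pul(genes, labels_map, seed, window, roles=roles)


def test_isolated_pair_stays_bare():
    layout = ["x"] * 6 + ["susC", "susD"] + ["x"] * 6
    pul = extend(layout)
    assert pul.n_genes == 2 and pul.is_simple


def test_xylan_like_layout_with_gap_extends_to_nine_genes():
    layout = (["x"] * 6 + ["GH43", "GH10", "x", "GH67", "GH35", "susC",
               "susD", "x", "GH10"] + ["x"] * 6)
    pul = extend(layout)
    assert pul.n_genes == 9
    labels = [lab for _, lab in pul.genes]
    assert labels == ["GH43", "GH10", "unc", "GH67", "GH35", "susC",
                      "susD", "unc", "GH10"]


def test_boundary_jumps_to_farthest_cazy_in_window():
    # GH at distance 2 and 5 from the pair: one jump must absorb both
    layout = ["x"] * 6 + ["GH13", "x", "x", "GH10", "x", "susC", "susD"] + ["x"] * 6
    pul = extend(layout)
    assert [lab for _, lab in pul.genes] == [
        "GH13", "unc", "unc", "GH10", "unc", "susC", "susD"]


def test_non_adjacent_seed_raises():
    genes, hits = make_genes(["susC", "GH10", "susD"])
    labels_map = pc.cazy_label_map(hits)
    with pytest.raises(ValueError, match="adjacent"):
        pc.extend_pul(genes, labels_map, (genes[0], genes[2]), 5)


def test_extension_matches_fixpoint_oracle_on_random_contigs(rng):
    for _ in range(300):
        n = 30
        labels = ["x"] * n
        pos = int(rng.integers(0, n - 1))
        labels[pos], labels[pos + 1] = "susC", "susD"
        for i in range(n):
            if labels[i] == "x" and rng.random() < 0.3:
                labels[i] = "GH10"
        genes, hits = make_genes(labels)
        roles = pc.assign_sus_roles(hits)
        labels_map = pc.cazy_label_map(hits)
        seed = (genes[pos], genes[pos + 1])
        window = int(rng.integers(1, 7))
        pul = pc.extend_pul(genes, labels_map, seed, window, roles=roles)
        is_cazy = [g.protein_id in labels_map for g in genes]
        lo, hi = fixpoint_extend_oracle(is_cazy, pos, pos + 1, window)
        got = [g.protein_id for g, _ in pul.genes]
        assert got == [g.protein_id for g in genes[lo : hi + 1]]


def test_enlarging_window_never_shrinks_a_pul(rng):
    layout = ["x"] * 4 + ["GH2", "x", "x", "susC", "susD", "x", "x", "x",
                          "GH3"] + ["x"] * 4
    sizes = [extend(layout, window=w).n_genes for w in (1, 2, 3, 5, 8)]
    assert sizes == sorted(sizes)


def test_editing_genes_beyond_one_extension_round_is_local(rng):
    base = ["x"] * 8 + ["GH2", "susC", "susD"] + ["x"] * 12
    pul_a = extend(base)
    far = list(base)
    far[-1] = "GH13"  # far beyond boundary + window
    pul_b = extend(far)
    assert [lab for _, lab in pul_a.genes] == [lab for _, lab in pul_b.genes]


# ---------------------------------------------------------------------------
# call_puls
# ---------------------------------------------------------------------------


def test_contig_without_seeds_yields_nothing():
    genes, hits = make_genes(["GH10", "x", "GH13"])
    assert pc.call_puls(genes, hits) == []


def test_overlapping_extensions_merge_into_one_pul():
    labels = ["x"] * 6 + ["susC", "susD", "GH10", "susC", "susD"] + ["x"] * 6
    genes, hits = make_genes(labels)
    puls = pc.call_puls(genes, hits)
    assert len(puls) == 1
    assert len(puls[0].seeds) == 2
    assert puls[0].n_genes == 5


def test_pul_ids_are_deterministic_left_to_right():
    labels = (["x"] * 6 + ["susC", "susD"] + ["x"] * 12
              + ["susD", "susC"] + ["x"] * 6)
    genes, hits = make_genes(labels, contig="ctg", genome="G9")
    puls = pc.call_puls(genes, hits)
    assert [p.pul_id for p in puls] == ["G9:ctg:1", "G9:ctg:2"]
    assert puls[0].span[0] < puls[1].span[0]


def test_every_called_pul_satisfies_type_invariants(rng):
    for _ in range(50):
        n = 40
        labels = ["x"] * n
        for i in range(n):
            r = rng.random()
            if r < 0.1:
                labels[i] = "susC"
            elif r < 0.2:
                labels[i] = "susD"
            elif r < 0.4:
                labels[i] = "GH10"
        genes, hits = make_genes(labels)
        for pul in pc.call_puls(genes, hits):  # Pul.__post_init__ checks
            ids = [g.protein_id for g, _ in pul.genes]
            start = [g.protein_id for g in genes].index(ids[0])
            assert ids == [g.protein_id for g in genes[start : start + len(ids)]]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def call(labels, contig="c1", genome="G1"):
    genes, hits = make_genes(labels, contig=contig, genome=genome)
    return pc.call_puls(genes, hits)


def test_single_bare_pair_summary():
    df = pc.pul_summary(call(["x"] * 6 + ["susC", "susD"] + ["x"] * 6))
    row = df.iloc[0]
    assert (row.n_puls, row.n_simple, row.n_multi) == (1, 1, 0)
    assert row.min_genes == row.max_genes == 2


def test_summary_matches_groupby_oracle(rng):
    puls = []
    for g in range(4):
        for c in range(int(rng.integers(1, 4))):
            simple = rng.random() < 0.5
            labels = (["x"] * 6 + (["susC", "susD"] if simple
                      else ["GH10", "susC", "susD"]) + ["x"] * 6)
            puls += call(labels, contig=f"c{c}", genome=f"G{g}")
    df = pc.pul_summary(puls).set_index("genome_id")
    for gid in {p.genome_id for p in puls}:
        mine = [p for p in puls if p.genome_id == gid]
        row = df.loc[gid]
        assert row.n_puls == len(mine)
        assert row.n_simple == sum(p.is_simple for p in mine)
        assert row.n_simple + row.n_multi == row.n_puls
        assert row.min_genes == min(p.n_genes for p in mine)
        assert row.max_genes == max(p.n_genes for p in mine)


def test_enzyme_occurrence_counts_genes_and_loci():
    puls = call(["x"] * 6 + ["GH10", "susC", "susD", "GH10"] + ["x"] * 6)
    df = pc.enzyme_occurrence(puls)
    assert df.iloc[0].tolist() == ["GH10", 2, 1]


def test_enzyme_occurrence_ranks_most_frequent_first():
    # a fixture built so GH3 (beta-glucosidase family) dominates
    puls = (call(["x"] * 6 + ["GH3", "GH3", "susC", "susD", "GH2"] + ["x"] * 6)
            + call(["x"] * 6 + ["GH3", "susC", "susD"] + ["x"] * 6,
                   contig="c2"))
    df = pc.enzyme_occurrence(puls)
    assert df.iloc[0]["enzyme"] == "GH3"
    assert df.iloc[0]["occurrences"] == 3
    assert df.iloc[0]["n_puls"] == 2


# ---------------------------------------------------------------------------
# signatures
# ---------------------------------------------------------------------------


def test_bare_pair_signature():
    (pul,) = call(["x"] * 6 + ["susC", "susD"] + ["x"] * 6)
    assert pc.architecture_signature(pul) == "susC-susD"


def test_two_strand_xylan_signature():
    labels = ["x"] * 6 + ["GH43", "GH10", "GH67", "GH35", "susC", "susD",
                          "x", "GH10"] + ["x"] * 6
    strands = ["+"] * 6 + ["-", "-", "+", "+", "+", "+", "+", "+"] + ["+"] * 6
    genes, hits = make_genes(labels, strands=strands)
    (pul,) = pc.call_puls(genes, hits)
    assert (pc.architecture_signature(pul)
            == "GH43-GH10 | GH67-GH35-susC-susD-unc-GH10")


def test_signature_parse_back_recovers_gene_labels(rng):
    for _ in range(50):
        n = int(rng.integers(3, 10))
        labels = ["x"] * 6
        strands = [("+", "-")[int(rng.integers(2))] for _ in range(6)]
        core, core_strands = [], []
        pos = int(rng.integers(0, n - 1))
        for i in range(n):
            if i == pos:
                core += ["susC", "susD"]
                core_strands += ["+", "+"]
            else:
                fam = ("GH10", "GH2", "x")[int(rng.integers(3))]
                core.append(fam)
                core_strands.append(("+", "-")[int(rng.integers(2))])
        genes, hits = make_genes(labels + core + ["x"] * 6,
                                 strands=strands + core_strands + ["+"] * 6)
        puls = pc.call_puls(genes, hits)
        for pul in puls:
            sig = pc.architecture_signature(pul)
            parsed = pc.parse_signature(sig)
            assert [lab for lab, _ in parsed] == [lab for _, lab in pul.genes]
            # strands recovered up to a global flip
            truth = [g.strand for g, _ in pul.genes]
            got = [s for _, s in parsed]
            flipped = ["+" if s == "-" else "-" for s in got]
            assert got == truth or flipped == truth
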