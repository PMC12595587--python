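"""Boundary atlas, gene-body lengths, H/J/N/S classification, gazetteer."""

import pytest

from hlakit.atlas import (
    GAZETTEER_CATEGORIES,
    AtlasError,
    build_atlas,
    build_gazetteer,
    classify_fragment_features,
    gene_body_length,
    identity_pairing,
    leader_codons_from_prot,
)
from hlakit.fixtures import FixtureSpec, make_alignment_fixture
from hlakit.imgt_io import load_gene_metadata, parse_alignment


def _gen(text):
    return parse_alignment(text, "gen")


def _nuc(text):
    return parse_alignment(text, "nuc")


def test_nuc_boundary_codon_is_ceiling_of_cdna_over_three():
    # Exon 1 = 6 nt, marker after column 6 -> boundary (E.1, E.2, 6, 7, codon 2)
    table = _nuc(" cDNA     1\n A*01:01  ATGGCC|TTTAAA\n")
    atlas = build_atlas([table])
    (rec,) = atlas.boundaries("A", "nuc")
    assert (rec.left_feature, rec.right_feature) == ("E.1", "E.2")
    assert (rec.before_label, rec.after_label) == ("6", "7")
    assert rec.codon == 2


def test_nuc_boundary_codon_subtracts_leader_peptide():
    # boundary between cDNA 619 and 620 (mid-codon): raw codon
    # ceil(620/3)=207; with a 24-codon leader the mature-protein codon is
    # 183, the convention in which feature positions are reported
    seq = "ATG" * 208
    table = _nuc(f" cDNA     1\n G*01:01  {seq[:619]}|{seq[619:]}\n")
    atlas = build_atlas([table], leader_codons=24)
    (rec,) = atlas.boundaries("G", "nuc")
    assert (rec.before_label, rec.after_label) == ("619", "620")
    assert rec.codon == 183


def test_leader_codons_derived_from_protein_negative_positions():
    prot = parse_alignment(" Prot     -3\n G*01:01  MAVWGSHS\n", "prot")
    assert leader_codons_from_prot(prot) == 3
    assert prot.column_labels == ["-3", "-2", "-1", "1", "2", "3", "4", "5"]


def test_atlas_records_both_flanking_labels_in_order():
    table = _gen(" gDNA     -2\n A*01:01  GG|ACG|TTTT|ACA|CC\n")
    atlas = build_atlas([table])
    recs = atlas.boundaries("A", "gen")
    assert [(r.left_feature, r.right_feature) for r in recs] == [
        ("U.5", "E.1"), ("E.1", "I.1"), ("I.1", "E.2"), ("E.2", "U.3")
    ]
    assert recs[0].before_label == "-1" and recs[0].after_label == "1"


def test_boundary_at_alignment_edge_is_degenerate():
    table = _gen(" gDNA     1\n A*01:01  |GGACGTTT\n")
    with pytest.raises(AtlasError, match="edge"):
        build_atlas([table])


def test_atlas_json_roundtrip(gen_fixture):
    from hlakit.atlas import Atlas

    _, truth = gen_fixture
    atlas = build_atlas([truth])
    again = Atlas.from_json(atlas.to_json())
    assert again.entries == atlas.entries and again.version == atlas.version


# ---------------------------------------------------------------------------
# gene body


GEN_25NT = (
    " gDNA     -3\n"
    # 3 nt 5'UTR | 10 nt exon | 5 nt intron | 10 nt exon | 4 nt 3'UTR
    " A*01:01  GGG|ACGTACGTAC|TTTTT|ACGTACGTAC|CCCC\n"
    " A*02:01  ---|----------|-..-.|----------|----\n"
)


def test_gene_body_is_exons_plus_introns():
    table = _gen(GEN_25NT)
    assert gene_body_length(table, "A*01:01") == 25


def test_gene_body_skips_indels():
    table = _gen(GEN_25NT)
    assert gene_body_length(table, "A*02:01") == 22


def test_gene_body_requires_utr_boundaries():
    table = _nuc(" cDNA     1\n A*01:01  ATGGCC|TTTAAA\n")
    with pytest.raises(AtlasError, match="UTR"):
        gene_body_length(table, "A*01:01")


# ---------------------------------------------------------------------------
# fragment feature classification

REF_GEN = _gen(
    " gDNA     -4\n"
    #  U.5 4 | E.1 6 | I.1 8 | E.2 6 | U.3 4
    " C*01:01  GGGG|ACGTAC|TTTTGGGG|ACGTAC|CCCC\n"
)


def _fragment(body: str, name="R*01:01"):
    return _gen(f" gDNA     1\n {name}  {body}\n")


def test_full_feature_coverage_keeps_standard_label():
    # fragment = exactly reference Exon 2 (reference columns 18..23)
    frag = _fragment("ACGTAC")
    pairing = list(range(18, 24))
    fs = classify_fragment_features(frag, REF_GEN, pairing)
    assert fs.features == ["E.2"]


def test_proper_subset_is_a_segment():
    frag = _fragment("TTTTGG")  # 6 of the 8 nt of Intron 1
    fs = classify_fragment_features(frag, REF_GEN, list(range(10, 16)))
    assert fs.features == ["S.1"]
    assert "6 of 8" in fs.annotation["S.1"]


def test_join_spans_two_features_through_their_boundary():
    # all of Exon 1 plus the first 3 nt of Intron 1, contiguous
    frag = _fragment("ACGTACTTT")
    fs = classify_fragment_features(frag, REF_GEN, list(range(4, 13)))
    assert fs.features == ["J.1"]
    assert "6 nucleotides of E.1" in fs.annotation["J.1"]
    assert "3 nucleotides of I.1" in fs.annotation["J.1"]


def test_hybrid_mixes_novel_and_aligned_runs():
    # 4 novel nt then 5 nt aligning inside Intron 1
    frag = _fragment("GGGGGTTTTG")
    pairing = [None, None, None, None, None] + list(range(10, 15))
    fs = classify_fragment_features(frag, REF_GEN, pairing)
    assert fs.features == ["H.1"]
    assert "5 nucleotides of novel sequence" in fs.annotation["H.1"]


def test_fully_unaligned_feature_is_novel():
    frag = _fragment("GGGGG")
    fs = classify_fragment_features(frag, REF_GEN, [None] * 5)
    assert fs.features == ["N.1"]
    assert "5 nucleotides of novel sequence" in fs.annotation["N.1"]


def test_multi_feature_fragment_numbering_runs_5prime_to_3prime():
    # novel run | exact E.1 | join(I.1+E.2 start)
    frag = _gen(" gDNA     1\n R*01:01  GGG|ACGTAC|TTTTGGGGACG\n")
    pairing = [None] * 3 + list(range(4, 10)) + list(range(10, 21))
    fs = classify_fragment_features(frag, REF_GEN, pairing)
    assert fs.features == ["N.1", "E.1", "J.1"]


def test_identity_limit_recovers_standard_labels(gen_fixture):
    """A fragment identical to its reference gets the reference's labels."""
    _, truth = gen_fixture
    fs = classify_fragment_features(truth, truth, identity_pairing(truth, truth))
    assert fs.features == [lab for lab, _, _ in truth.feature_intervals()]
    assert fs.annotation == {}


def test_nonmonotonic_pairing_rejected():
    frag = _fragment("ACGTAC")
    with pytest.raises(AtlasError, match="monotonic"):
        classify_fragment_features(frag, REF_GEN, [8, 7, 9, 10, 11, 12])


def test_feature_lengths_sum_to_ungapped_row_length(gen_fixture):
    """Conservation: features partition the reference row exactly."""
    _, truth = gen_fixture
    row = truth.rows[truth.reference_allele]
    total = 0
    for _, s, e in truth.feature_intervals():
        total += sum(1 for sym in row[s : e + 1] if sym != ".")
    assert total == sum(1 for sym in row if sym != ".")


# ---------------------------------------------------------------------------
# gazetteer


def test_gazetteer_fixture_inventory():
    gaz = build_gazetteer(
        {"A": {"prot", "nuc", "gen", "codon"}, "N": {"gen"}},
        load_gene_metadata(),
        version="3.99.0",
    )
    assert gaz["prot"] == ["A"]
    assert gaz["gen"] == ["A", "N"]
    assert "N" in gaz["gene_fragment"]
    assert gaz["noprot"] == ["N"]
    assert gaz.version == "3.99.0"


def test_gazetteer_has_the_frozen_category_roster():
    gaz = build_gazetteer({"A": {"prot"}}, load_gene_metadata())
    assert len(GAZETTEER_CATEGORIES) == 19
    assert set(gaz.categories) == set(GAZETTEER_CATEGORIES)


def test_map_renders_merged_drb_clusters_once():
    gaz = build_gazetteer({}, load_gene_metadata())
    chromosomal = gaz["map"]
    assert "DRB3/4/5" in chromosomal and "DRB6/7" in chromosomal
    assert "DRB3" not in chromosomal and "DRB6" not in chromosomal
    assert chromosomal.count("DRB3/4/5") == 1


def test_map_places_hla_r_adjacent_to_hla_y():
    chromosomal = build_gazetteer({}, load_gene_metadata())["map"]
    assert abs(chromosomal.index("R") - chromosomal.index("Y")) == 1


def test_every_aligned_gene_has_exactly_one_status():
    inv = {"A": {"prot", "nuc", "gen"}, "N": {"gen"}, "DRB1": {"prot", "nuc"}}
    gaz = build_gazetteer(inv, load_gene_metadata())
    for gene in gaz["align"]:
        statuses = [
            c for c in ("expressed", "pseudogene", "gene_fragment") if gene in gaz[c]
        ]
        assert len(statuses) == 1, gene
    assert set(gaz["prot"]) <= set(gaz["nuc"]) <= set(gaz["align"])


def test_unknown_gene_in_inventory_is_named_in_error():
    with pytest.raises(AtlasError, match="ZZ9"):
        build_gazetteer({"ZZ9": {"gen"}}, load_gene_metadata())
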