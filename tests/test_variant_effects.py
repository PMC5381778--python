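"""Consequence annotation: survey variants, oracle agreement, invariants."""

import numpy as np
import pytest

from conftest import mirror, random_cds_snv, random_frameshift_indel, random_gene_and_contig
from hbbscan.gene_model import ReferenceContig
from hbbscan.variant_effects import (
    CDS_TERMS,
    Consequence,
    Variant,
    annotate_variant,
    classify_by_full_translation,
    format_protein_change,
    read_annotation_table,
    write_annotation_table,
)

# expected terms and protein-change labels for all 20 survey variants
SURVEY_EXPECTED = {
    "rs36020563": ({"synonymous"}, "His144His"),
    "rs113082294": ({"synonymous"}, "Val134Val"),
    "rs111645889": ({"missense"}, "Ala130Val"),
    "rs33971634": ({"stop_gained"}, "Gln128"),
    "rs33946267": ({"missense"}, "Glu122Gln"),
    "rs33958637": ({"missense"}, "Asn109His"),
    "rs193922562": ({"synonymous"}, "Gly108Gly"),
    "rs145669504": ({"synonymous"}, "Leu82Leu"),
    "rs281864900": ({"frameshift"}, "Phe42fs"),
    "rs11549407": ({"stop_gained"}, "Gln40"),
    "rs1135071": ({"splice_region", "missense"}, "Arg31Ser"),
    "rs33943001": ({"splice_acceptor", "intron"}, None),
    "rs33971440": ({"splice_donor", "intron"}, None),
    "rs35578002": ({"splice_region", "synonymous"}, "Gly30Gly"),
    "rs33950507": ({"missense"}, "Glu27Lys"),
    "rs33986703": ({"stop_gained"}, "Lys18"),
    "rs63750783": ({"stop_gained"}, "Trp16"),
    "rs334": ({"missense"}, "Glu7Val"),
    "rs33930165": ({"missense"}, "Glu7Lys"),
    "rs33912272": ({"missense"}, "Pro6Ser"),
}


@pytest.mark.parametrize("vid", sorted(SURVEY_EXPECTED))
def test_survey_variant_consequences(vid, hbb_annotations):
    terms, label = SURVEY_EXPECTED[vid]
    c = hbb_annotations[vid]
    assert set(c.terms) == terms
    if label is None:
        assert c.protein_change is None
    else:
        assert format_protein_change(c, "paper") == label


def test_survey_consequence_partition(hbb_annotations):
    """4 synonymous / 7 missense-only / 4 stop-gain / 1 frameshift / 4 splice-combined."""
    kinds = {
        "syn": sum(1 for c in hbb_annotations.values() if set(c.terms) == {"synonymous"}),
        "mis": sum(1 for c in hbb_annotations.values() if set(c.terms) == {"missense"}),
        "stop": sum(1 for c in hbb_annotations.values() if set(c.terms) == {"stop_gained"}),
        "fs": sum(1 for c in hbb_annotations.values() if set(c.terms) == {"frameshift"}),
        "splice": sum(1 for c in hbb_annotations.values() if c.terms & {"splice_region", "splice_donor", "splice_acceptor"}),
    }
    assert kinds == {"syn": 4, "mis": 7, "stop": 4, "fs": 1, "splice": 4}


def test_variant_far_outside_gene_is_intergenic(hbb_model, hbb_reference):
    pos = hbb_model.span[0] - 10_000
    v = Variant("chr11", pos, hbb_reference.base(pos), "A" if hbb_reference.base(pos) != "A" else "C")
    assert annotate_variant(v, hbb_model, hbb_reference).terms == frozenset({"intergenic"})


def test_ref_mismatch_raises(hbb_model, hbb_reference):
    base = hbb_reference.base(5248232)
    wrong = "G" if base != "G" else "C"
    with pytest.raises(ValueError, match="REF mismatch"):
        annotate_variant(Variant("chr11", 5248232, wrong, "A"), hbb_model, hbb_reference)


def test_in_frame_indel_rejected(hbb_model, hbb_reference):
    ref = hbb_reference.slice(5248220, 5248223)
    with pytest.raises(ValueError, match="in-frame"):
        annotate_variant(Variant("chr11", 5248220, ref, ref[0]), hbb_model, hbb_reference)


def test_oracle_agrees_on_all_survey_variants(hbb_variants, hbb_model, hbb_reference):
    for v in hbb_variants:
        a = annotate_variant(v, hbb_model, hbb_reference)
        o = classify_by_full_translation(v, hbb_model, hbb_reference)
        assert a.terms == o.terms, v.identifier
        if v.is_snv:
            assert a.protein_change == o.protein_change, v.identifier


def test_oracle_trivial_cases(hbb_model, hbb_reference):
    # a synonymous change leaves the proteins identical, a stop gain truncates
    syn = classify_by_full_translation(
        Variant("chr11", 5246840, "G", "A", "syn"), hbb_model, hbb_reference)
    assert "synonymous" in syn.terms
    stop = classify_by_full_translation(
        Variant("chr11", 5248004, "G", "A", "stop"), hbb_model, hbb_reference)
    assert "stop_gained" in stop.terms


def test_annotator_equals_oracle_on_random_genes():
    """Codon arithmetic must match the whole-protein-diff oracle on seeded
    random gene/variant pairs (SNVs and frameshift indels, any strand)."""
    rng = np.random.default_rng(202)
    checked = 0
    for _ in range(60):
        model, contig = random_gene_and_contig(rng)
        for _ in range(6):
            v = random_cds_snv(rng, model, contig)
            a = annotate_variant(v, model, contig)
            o = classify_by_full_translation(v, model, contig)
            assert a.terms == o.terms, (model, v)
            assert a.protein_change == o.protein_change, (model, v)
            checked += 1
        v = random_frameshift_indel(rng, model, contig)
        if v is not None:
            a = annotate_variant(v, model, contig)
            o = classify_by_full_translation(v, model, contig)
            assert a.terms == o.terms, (model, v)
            checked += 1
    assert checked > 350


def test_strand_mirror_invariance():
    """Reflecting gene, contig and SNV to the opposite strand must leave the
    consequence unchanged."""
    rng = np.random.default_rng(77)
    for _ in range(25):
        model, contig = random_gene_and_contig(rng)
        for _ in range(4):
            v = random_cds_snv(rng, model, contig)
            m_model, m_contig, m_v = mirror(model, contig, v)
            a = annotate_variant(v, model, contig)
            b = annotate_variant(m_v, m_model, m_contig)
            assert a.terms == b.terms
            assert a.protein_change == b.protein_change


def test_mirrored_gene_has_identical_spliced_cds(hbb_model, hbb_reference):
    from hbbscan.gene_model import spliced_cds

    v = Variant("chr11", 5248232, hbb_reference.base(5248232), "A", "rs334")
    m_model, m_contig, _ = mirror(hbb_model, hbb_reference, v)
    assert spliced_cds(m_model, m_contig) == spliced_cds(hbb_model, hbb_reference)


def test_term_structure_invariants(hbb_annotations):
    for vid, c in hbb_annotations.items():
        # intergenic never co-occurs; splice terms never stand alone
        assert "intergenic" not in c.terms
        assert c.terms - {"splice_donor", "splice_acceptor", "splice_region"}, vid
        # protein change present exactly for coding terms
        assert (c.protein_change is not None) == bool(set(c.terms) & CDS_TERMS)


def test_format_styles():
    mis = Consequence(frozenset({"missense"}), protein_change=("E", 7, "V"))
    assert format_protein_change(mis, "paper") == "Glu7Val"
    assert format_protein_change(mis, "hgvs-like") == "Glu7Val"
    stop = Consequence(frozenset({"stop_gained"}), protein_change=("Q", 40, "*"))
    assert format_protein_change(stop, "paper") == "Gln40"
    assert format_protein_change(stop, "hgvs-like") == "Gln40Ter"
    fs = Consequence(frozenset({"frameshift"}), protein_change=("F", 42, "fs"))
    assert format_protein_change(fs, "paper") == "Phe42fs"
    syn = Consequence(frozenset({"synonymous"}), protein_change=("H", 144, "H"))
    assert format_protein_change(syn, "paper") == "His144His"
    assert format_protein_change(syn, "hgvs-like") == "His144="
    with pytest.raises(ValueError):
        format_protein_change(Consequence(frozenset({"intron"})))


def test_annotation_table_round_trip(tmp_path, hbb_variants, hbb_annotations):
    rows = [(v, hbb_annotations[v.identifier]) for v in hbb_variants]
    write_annotation_table(rows, tmp_path / "ann.tsv")
    back = read_annotation_table(tmp_path / "ann.tsv")
    for v, c in rows:
        assert back[v.identifier].terms == c.terms
        assert back[v.identifier].is_pure_synonymous == c.is_pure_synonymous
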