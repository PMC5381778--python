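"""Bundled reconstruction of the published 1000-Genomes HBB variant survey.

The β-globin gene *HBB* sits on the minus strand of chromosome 11 (p15.5).
A survey of the 2,504-sample 1000 Genomes phase-3 cohort found 20 distinct
coding-region variants carried heterozygously by 209 individuals, together
with per-source pathogenicity labels from three clinical databases and five
in-silico predictors.  This module packages that survey as exact data — the
variant coordinates (hg19), alleles, per-population carrier counts, and raw
evidence labels — plus an HBB-like gene model whose exon layout reproduces
every published splice/consequence label:

* exon 1 CDS 5,248,160–5,248,251 (c.1–92),
* exon 2     5,247,807–5,248,029 (c.93–315),
* exon 3     5,246,831–5,246,956 (c.316–441),

441 coding bases = 146 residues + terminator, residues numbered with the
initiator Met as 1 (so the sickle variant rs334 is Glu7Val).

The reference contig is synthetic: only the bases pinned down by the survey
(codons hit by variants, REF alleles, splice dinucleotides) are fixed;
everything else is seeded-random.  The published amino-acid label for
rs35578002 ("Glu30Gly") is internally contradictory — the row is
synonymous, and no Glu codon is compatible with the site — so the fixture
encodes the synonymous change Gly30Gly and keeps the published label only
as metadata.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .consensus import EvidenceRecord
from .gene_model import GeneModel, ReferenceContig
from .synthetic_data import (
    CohortSpec,
    EvidenceSpec,
    VariantSpec,
    build_reference,
    simulate_cohort,
    write_inputs,
)

__all__ = [
    "POPULATIONS",
    "POPULATION_SIZES",
    "CONTIG_NAME",
    "CONTIG_LENGTH",
    "OVERRIDES",
    "gene_model",
    "cohort_spec",
    "evidence_spec",
    "reference",
    "variant_table",
    "write_fixture_inputs",
]

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

# 1000 Genomes phase-3 super-population sizes; they sum to 2,504 and
# reproduce the internally consistent per-population frequency cells of the
# survey (e.g. 17 alleles / 2*661 AFR samples = 0.0129).
POPULATION_SIZES = {"AFR": 661, "AMR": 347, "EAS": 504, "EUR": 503, "SAS": 489}

CONTIG_NAME = "chr11"
CONTIG_LENGTH = 5_249_000

_EXONS = ((5_246_831, 5_246_956), (5_247_807, 5_248_029), (5_248_160, 5_248_251))

# pos, id, ref, alt, {pop: het carriers}, published AA label, published type
_VARIANTS = (
    (5246840, "rs36020563", "G", "A", {"AFR": 1}, "His144His", "Synonymous"),
    (5246870, "rs113082294", "C", "G", {"AMR": 2, "EUR": 7}, "Val134Val", "Synonymous"),
    (5246883, "rs111645889", "G", "A", {"AFR": 1}, "Ala130Val", "Missense"),
    (5246890, "rs33971634", "G", "A", {"AMR": 1}, "Gln128", "Stop gained"),
    (5246908, "rs33946267", "C", "G", {"SAS": 3}, "Glu122Gln", "Missense"),
    (5246947, "rs33958637", "T", "G", {"EAS": 1}, "Asn109His", "Missense"),
    (5246948, "rs193922562", "G", "A", {"AFR": 1}, "Gly108Gly", "Synonymous"),
    (5247876, "rs145669504", "G", "T", {"EAS": 5}, "Leu82Leu", "Synonymous"),
    (5247992, "rs281864900", "CAAAG", "C", {"EAS": 5}, "Phe42fs", "Frameshift"),
    (5248004, "rs11549407", "G", "A", {"AMR": 1}, "Gln40", "Stop gained"),
    (5248029, "rs1135071", "C", "A", {"EUR": 1}, "Arg31Ser", "Splice region and missense"),
    (5248030, "rs33943001", "C", "G", {"SAS": 1}, None, "Splice acceptor and intron variant"),
    (5248159, "rs33971440", "C", "T", {"AMR": 1}, None, "Splice donor and intron variant"),
    (5248162, "rs35578002", "G", "T", {"AFR": 1}, "Glu30Gly", "Splice region and synonymous variant"),
    (5248173, "rs33950507", "C", "T", {"EAS": 8, "SAS": 6}, "Glu27Lys", "Missense"),
    (5248200, "rs33986703", "T", "A", {"EAS": 6}, "Lys18", "Stop gained"),
    (5248205, "rs63750783", "C", "T", {"SAS": 2}, "Trp16", "Stop gained"),
    (5248232, "rs334", "T", "A", {"AFR": 132, "AMR": 5}, "Glu7Val", "Missense"),
    (5248233, "rs33930165", "C", "T", {"AFR": 17}, "Glu7Lys", "Missense"),
    (5248236, "rs33912272", "G", "A", {"EUR": 1}, "Pro6Ser", "Missense"),
)

# Residue constraints pinning the CDS where a published consequence depends
# on it.  Codon 31 is the explicit codon AGG: CGG (also Arg, also ending in
# the required G) would make rs1135071 synonymous instead of Arg31Ser.
CODON_CONSTRAINTS = {
    6: "P", 7: "E", 16: "W", 18: "K", 27: "E", 30: "G", 31: "AGG",
    40: "Q", 42: "F", 43: "F", 82: "L", 108: "G", 109: "N",
    122: "E", 128: "Q", 130: "A", 134: "V", 144: "H",
}

_NE = "not-evaluated"

# Raw evidence labels: (CLINVAR, dbSNP, HbVar | POLYPHEN, PROVEAN, SIFT,
# PANTHER, MUTPRED), plus the published conclusion for reference.  The four
# pure-synonymous variants were excluded from pathogenicity evaluation and
# carry no labels.
_EVIDENCE = {
    "rs111645889": (("Other", "Other", "Benign"),
                    ("Benign", "Damaging", "Damaging", "Damaging", "Damaging"), "Conflict"),
    "rs33971634": (("Damaging", "Other", "Damaging"),
                   (_NE, "Damaging", _NE, _NE, _NE), "Damaging"),
    "rs33946267": (("Damaging", "Damaging", "Benign"),
                   ("Benign", "Benign", "Damaging", "Benign", "Damaging"), "Conflict"),
    "rs33958637": (("Other", _NE, "Benign"),
                   ("Probably damaging", "Damaging", "Damaging", "Benign", "Damaging"), "Conflict"),
    "rs281864900": (("Damaging", "Damaging", "Damaging"),
                    (_NE, "Damaging", _NE, _NE, _NE), "Damaging"),
    "rs11549407": (("Damaging", "Damaging", "Damaging"),
                   (_NE, _NE, _NE, _NE, _NE), "Damaging"),
    "rs1135071": (("Damaging", "Damaging", "Benign"),
                  ("Probably damaging", "Damaging", "Damaging", "Damaging", "Damaging"), "Damaging"),
    "rs33943001": (("Damaging", "Damaging", "Damaging"),
                   (_NE, _NE, _NE, _NE, _NE), "Damaging"),
    "rs33971440": (("Damaging", "Damaging", "Damaging"),
                   (_NE, _NE, _NE, _NE, _NE), "Damaging"),
    "rs35578002": ((_NE, _NE, "Damaging"),
                   ("Benign", "Benign", "Benign", "Benign", "Benign"), "Conflict"),
    "rs33950507": (("Damaging", "Damaging", "Damaging"),
                   ("Benign", "Damaging", "Damaging", "Damaging", "Damaging"), "Damaging"),
    "rs33986703": (("Damaging", "Damaging", "Damaging"),
                   (_NE, "Damaging", _NE, _NE, _NE), "Damaging"),
    "rs63750783": (("Damaging", "Damaging", "Damaging"),
                   (_NE, "Damaging", _NE, _NE, _NE), "Damaging"),
    "rs334": (("Damaging", "Damaging", "Damaging"),
              ("Benign", "Damaging", "Damaging", _NE, "Damaging"), "Damaging"),
    "rs33930165": (("Damaging", "Damaging", "Damaging"),
                   ("Benign", "Damaging", "Damaging", _NE, "Damaging"), "Damaging"),
    "rs33912272": (("Other", "Other", "Benign"),
                   ("Benign", "Benign", "Benign", _NE, "Damaging"), "Conflict"),
}

# The default class-wise majority rule reproduces every published conclusion
# except rs33912272 (computed Benign, published Conflict); that row ships as
# an explicit override rather than a guessed rule change.
OVERRIDES = {"rs33912272": "Conflict"}


def gene_model() -> GeneModel:
    return GeneModel(
        contig_name=CONTIG_NAME,
        strand="-",
        exons=_EXONS,
        cds_genomic_span=(_EXONS[0][0], _EXONS[-1][1]),
        gene_name="HBB",
    )


def cohort_spec(seed: int = 0) -> CohortSpec:
    return CohortSpec(
        population_names=POPULATIONS,
        population_sizes=dict(POPULATION_SIZES),
        variant_specs=tuple(
            VariantSpec(pos=pos, ref=ref, alt=alt, identifier=vid, carriers=dict(carriers))
            for pos, vid, ref, alt, carriers, _, _ in _VARIANTS
        ),
        seed=seed,
    )


def evidence_spec() -> EvidenceSpec:
    records = []
    for pos, vid, *_ in _VARIANTS:
        if vid in _EVIDENCE:
            dbs, preds, _ = _EVIDENCE[vid]
        else:
            dbs, preds = (_NE,) * 3, (_NE,) * 5
        records.append(
            EvidenceRecord(
                variant_id=vid,
                db_labels=dict(zip(("CLINVAR", "dbSNP", "HbVar"), dbs)),
                predictor_labels=dict(
                    zip(("POLYPHEN", "PROVEAN", "SIFT", "PANTHER", "MUTPRED"), preds)
                ),
            )
        )
    return EvidenceSpec(records=tuple(records), overrides=dict(OVERRIDES))


def reference(seed: int = 0) -> ReferenceContig:
    return build_reference(
        cohort_spec(seed),
        gene_model(),
        codon_constraints=CODON_CONSTRAINTS,
        contig_length=CONTIG_LENGTH,
    )


def variant_table() -> pd.DataFrame:
    """The survey's variant list with published labels, as a DataFrame."""
    rows = []
    for pos, vid, ref, alt, carriers, aa, vtype in _VARIANTS:
        published = _EVIDENCE.get(vid)
        rows.append(
            {
                "variant_id": vid,
                "position": pos,
                "ref": ref,
                "alt": alt,
                "published_aa_label": aa,
                "published_type": vtype,
                "published_verdict": published[2] if published else None,
                "total_carriers": sum(carriers.values()),
                **{f"carriers_{p}": carriers.get(p, 0) for p in POPULATIONS},
            }
        )
    return pd.DataFrame(rows)


def write_fixture_inputs(outdir, seed: int = 0) -> dict:
    """Generate the full on-disk reconstruction of the survey inputs."""
    spec = cohort_spec(seed)
    model = gene_model()
    contig = reference(seed)
    cohort = simulate_cohort(spec)
    return write_inputs(spec, cohort, contig, model, evidence_spec(), outdir)
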