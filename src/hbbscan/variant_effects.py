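"""Variant consequence annotation against a single-transcript gene model.

Classifies VCF-style variants (SNVs and anchored indels) into the standard
consequence vocabulary — synonymous, missense, stop_gained, frameshift,
splice_donor, splice_acceptor, splice_region, intron, intergenic — and names
the protein-level change.  Residues are numbered with the initiator Met as
residue 1.

Two classification routes are provided:

* :func:`annotate_variant` — direct codon arithmetic on the spliced CDS,
  the production path.
* :func:`classify_by_full_translation` — a brute-force oracle that applies
  the edit to the whole contig, re-splices, re-translates and diffs the two
  proteins.  It shares no codon arithmetic with the production path and
  exists to cross-check it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

from Bio.Seq import Seq

from .gene_model import (
    GeneModel,
    ReferenceContig,
    SpliceWindows,
    cds_to_genomic,
    genomic_to_cds,
    splice_windows,
    spliced_cds,
    translate,
)

__all__ = [
    "Variant",
    "Consequence",
    "annotate_variant",
    "classify_by_full_translation",
    "format_protein_change",
    "read_vcf_variants",
    "write_annotation_table",
    "read_annotation_table",
    "AnnotationSummary",
]

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

CDS_TERMS = frozenset({"synonymous", "missense", "stop_gained", "frameshift"})
SPLICE_TERMS = frozenset({"splice_donor", "splice_acceptor", "splice_region"})
ALL_TERMS = CDS_TERMS | SPLICE_TERMS | {"intron", "intergenic"}


@dataclass(frozen=True)
class Variant:
    """A VCF-style variant: 1-based position, anchored REF/ALT alleles."""

    contig: str
    pos: int
    ref: str
    alt: str
    identifier: str = "."

    def __post_init__(self):
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if set(self.ref + self.alt) - set("ACGT"):
            raise ValueError(f"alleles must be over ACGT: {self.ref}/{self.alt}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 == len(self.alt)


@dataclass(frozen=True)
class Consequence:
    """Effect terms plus optional protein- and codon-level change.

    ``protein_change`` is ``(ref_residue_1letter, residue_index, alt)`` where
    ``alt`` is a 1-letter residue, ``*`` for a gained terminator, or ``"fs"``
    for a frameshift.  It is present exactly when a coding term is present.
    """

    terms: frozenset
    protein_change: Optional[tuple] = None
    codon_change: Optional[tuple] = None

    def __post_init__(self):
        if not self.terms:
            raise ValueError("terms must be non-empty")
        unknown = set(self.terms) - ALL_TERMS
        if unknown:
            raise ValueError(f"unknown consequence terms: {unknown}")
        has_cds = bool(set(self.terms) & CDS_TERMS)
        if has_cds != (self.protein_change is not None):
            raise ValueError("protein_change must be present iff a coding term is present")

    @property
    def is_pure_synonymous(self) -> bool:
        return set(self.terms) == {"synonymous"}

    def terms_sorted(self) -> list:
        order = ["stop_gained", "frameshift", "missense", "synonymous",
                 "splice_donor", "splice_acceptor", "splice_region", "intron", "intergenic"]
        return [t for t in order if t in self.terms]


def _check_ref(v: Variant, ref: ReferenceContig) -> None:
    observed = ref.slice(v.pos, v.pos + len(v.ref) - 1)
    if observed != v.ref:
        raise ValueError(
            f"REF mismatch for {v.identifier} at {v.contig}:{v.pos}: "
            f"VCF says {v.ref!r}, contig has {observed!r}"
        )


def _changed_positions(v: Variant) -> list:
    """Genomic positions whose base is changed or deleted, after trimming the
    shared VCF anchor prefix."""
    ref, alt, pos = v.ref, v.alt, v.pos
    k = 0
    while k < len(ref) and k < len(alt) and ref[k] == alt[k]:
        k += 1
    if len(ref) == len(alt) == k:  # identical — excluded by Variant invariant
        return []
    if len(ref) > k:
        return list(range(pos + k, pos + len(ref)))
    # pure insertion: the edit lands between pos+k-1 and pos+k
    return [pos + k - 1, pos + k]


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _splice_terms_for(positions, windows_map) -> set:
    terms = set()
    for p in positions:
        for label, posset in windows_map.items():
            if p in posset:
                terms.add(label)
    return terms


def annotate_variant(
    v: Variant,
    model: GeneModel,
    ref: ReferenceContig,
    windows: SpliceWindows = SpliceWindows(),
) -> Consequence:
    """Classify a variant by codon arithmetic on the spliced CDS.

    SNVs in the CDS are classified by comparing the reference and alternate
    codons after strand adjustment; length-changing variants whose net length
    difference is not a multiple of 3 are frameshifts, labelled at the first
    CDS codon containing a changed base.  Positions inside splice windows add
    the corresponding splice terms; intronic positions outside any window are
    ``intron`` and positions outside the gene are ``intergenic``.
    """
    _check_ref(v, ref)
    changed = _changed_positions(v)
    if not any(model.contains(p) for p in changed):
        return Consequence(terms=frozenset({"intergenic"}))

    terms = _splice_terms_for(changed, splice_windows(model, windows))
    cds_positions = sorted(p for p in changed if model.in_cds(p))

    if not cds_positions:
        terms.add("intron")
        return Consequence(terms=frozenset(terms))

    cds = spliced_cds(model, ref)
    if v.is_snv:
        offset = genomic_to_cds(model, v.pos)
        codon_i = offset // 3
        within = offset % 3
        ref_codon = cds[codon_i * 3 : codon_i * 3 + 3]
        alt_base = v.alt if model.strand == "+" else _revcomp(v.alt)
        alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
        ref_aa = translate(ref_codon)
        alt_aa = translate(alt_codon)
        if alt_aa == ref_aa:
            terms.add("synonymous")
        elif alt_aa == "*":
            terms.add("stop_gained")
        else:
            terms.add("missense")
        return Consequence(
            terms=frozenset(terms),
            protein_change=(ref_aa, codon_i + 1, alt_aa),
            codon_change=(ref_codon, alt_codon),
        )

    net = len(v.alt) - len(v.ref)
    if net % 3 == 0:
        raise ValueError(
            f"in-frame indel {v.identifier} ({v.ref}/{v.alt}) is outside the "
            "supported consequence vocabulary"
        )
    terms.add("frameshift")
    first_offset = min(genomic_to_cds(model, p) for p in cds_positions)
    codon_i = first_offset // 3
    ref_aa = translate(cds[codon_i * 3 : codon_i * 3 + 3])
    return Consequence(
        terms=frozenset(terms),
        protein_change=(ref_aa, codon_i + 1, "fs"),
        codon_change=None,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle


def _shift_interval(iv, edit_pos, net):
    """Shift a genomic interval for an edit of net length change ``net``
    whose changed bases start after ``edit_pos``."""
    lo, hi = iv
    return (lo + net if lo > edit_pos else lo, hi + net if hi > edit_pos else hi)


def classify_by_full_translation(
    v: Variant,
    model: GeneModel,
    ref: ReferenceContig,
    windows: SpliceWindows = SpliceWindows(),
) -> Consequence:
    """Oracle classification by whole-contig editing and whole-protein diff.

    Applies the edit to the contig sequence, rebuilds the gene model with
    coordinates shifted across the edit, re-splices and re-translates both
    alleles, and derives the consequence from the protein diff alone.  The
    edit must not span an exon boundary (not exercised by anchored SNV/indel
    inputs whose changed bases lie in one exon or one intron).
    """
    _check_ref(v, ref)
    changed = _changed_positions(v)
    if not any(model.contains(p) for p in changed):
        return Consequence(terms=frozenset({"intergenic"}))

    terms = _splice_terms_for(changed, splice_windows(model, windows))
    if not any(model.in_cds(p) for p in changed):
        terms.add("intron")
        return Consequence(terms=frozenset(terms))

    edited_seq = ref.sequence[: v.pos - 1] + v.alt + ref.sequence[v.pos - 1 + len(v.ref) :]
    net = len(v.alt) - len(v.ref)
    anchor = v.pos + len(v.ref) - 1 - max(0, -net)  # last unshifted coordinate
    new_model = GeneModel(
        contig_name=model.contig_name,
        strand=model.strand,
        exons=tuple(_shift_interval(iv, anchor, net) for iv in model.exons),
        cds_genomic_span=_shift_interval(model.cds_genomic_span, anchor, net),
        gene_name=model.gene_name,
    )
    ref_prot = translate(spliced_cds(model, ref))
    alt_cds = spliced_cds(new_model, ReferenceContig(ref.name, edited_seq))
    if len(alt_cds) % 3 != 0:
        # frameshift: translate the in-frame prefix only
        alt_prot = translate(alt_cds[: len(alt_cds) - len(alt_cds) % 3])
        frame_ok = False
    else:
        alt_prot = translate(alt_cds)
        frame_ok = True

    if frame_ok and alt_prot == ref_prot:
        terms.add("synonymous")
        # locate the changed codon for the protein_change record
        off = min(genomic_to_cds(model, p) for p in changed if model.in_cds(p))
        i = off // 3
        protein_change = (ref_prot[i], i + 1, ref_prot[i])
    elif not frame_ok:
        terms.add("frameshift")
        i = next((k for k, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b), None)
        if i is None:
            off = min(genomic_to_cds(model, p) for p in changed if model.in_cds(p))
            i = off // 3
        protein_change = (ref_prot[i], i + 1, "fs")
    else:
        diffs = [k for k, (a, b) in enumerate(zip(ref_prot, alt_prot)) if a != b]
        i = diffs[0]
        if alt_prot[i] == "*":
            terms.add("stop_gained")
        else:
            terms.add("missense")
        protein_change = (ref_prot[i], i + 1, alt_prot[i])
    return Consequence(terms=frozenset(terms), protein_change=protein_change)


# ---------------------------------------------------------------------------
# Formatting and I/O


def format_protein_change(c: Consequence, style: str = "paper") -> str:
    """Render a protein change with three-letter residue codes, Met = 1.

    ``paper`` style prints stop gains as residue+index with no suffix
    (``Gln40``) and frameshifts as residue+index+``fs`` (``Phe42fs``);
    ``hgvs-like`` style appends ``Ter`` to stop gains and renders synonymous
    changes as ``residue+index+=``.
    """
    if c.protein_change is None:
        raise ValueError("consequence has no protein change")
    if style not in ("paper", "hgvs-like"):
        raise ValueError(f"unknown style {style!r}")
    ref_aa, idx, alt = c.protein_change
    ref3 = AA3[ref_aa]
    if alt == "fs":
        return f"{ref3}{idx}fs"
    if alt == "*":
        return f"{ref3}{idx}" if style == "paper" else f"{ref3}{idx}Ter"
    if alt == ref_aa:
        return f"{ref3}{idx}{AA3[alt]}" if style == "paper" else f"{ref3}{idx}="
    return f"{ref3}{idx}{AA3[alt]}"


def read_vcf_variants(path) -> list:
    """Read variants (first ALT allele per record) from a VCF file."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                out.append(
                    Variant(
                        contig=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        identifier=rec.id or ".",
                    )
                )
    return out


_TABLE_FIELDS = ["variant_id", "position", "ref", "alt", "terms", "protein_change", "codon_change"]


def write_annotation_table(rows, path) -> None:
    """Write (Variant, Consequence) pairs as a TSV annotation table."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_TABLE_FIELDS)
        for v, c in rows:
            w.writerow(
                [
                    v.identifier,
                    v.pos,
                    v.ref,
                    v.alt,
                    "&".join(c.terms_sorted()),
                    format_protein_change(c) if c.protein_change else ".",
                    "/".join(c.codon_change) if c.codon_change else ".",
                ]
            )


@dataclass(frozen=True)
class AnnotationSummary:
    """Terms-level view of a consequence, as read back from an annotation
    table (the protein change is kept as its rendered label only)."""

    terms: frozenset
    protein_change_label: Optional[str] = None

    @property
    def is_pure_synonymous(self) -> bool:
        return set(self.terms) == {"synonymous"}

    def terms_sorted(self) -> list:
        return Consequence.terms_sorted(self)  # same ordering rule


def read_annotation_table(path) -> dict:
    """Read an annotation TSV back as {variant_id: AnnotationSummary}."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["variant_id"]] = AnnotationSummary(
                terms=frozenset(row["terms"].split("&")),
                protein_change_label=None if row["protein_change"] == "." else row["protein_change"],
            )
    return out
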