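"""Gene models with exact strand-aware coordinate, codon, and splice arithmetic.

A :class:`GeneModel` is a single-transcript protein-coding gene on either
strand of a reference contig, described by 1-based inclusive genomic exon
intervals (the VCF/GFF3 convention).  Internally the spliced coding sequence
(CDS) is addressed by 0-based offsets in *transcript orientation*: for a
minus-strand gene, transcript order runs from the highest genomic coordinate
downward and every base is complemented.

The module also classifies junction-proximal positions into splice-site
windows (donor / acceptor / splice region), with configurable window sizes
following the convention of standard effect-annotation tools: the first two
intronic bases after an exon are the donor site, the last two intronic bases
before an exon are the acceptor site, and exonic bases 1-3 or intronic bases
3-8 from a junction form the splice region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Optional

from Bio.Seq import Seq

__all__ = [
    "ReferenceContig",
    "GeneModel",
    "SpliceWindows",
    "genomic_to_cds",
    "cds_to_genomic",
    "spliced_cds",
    "translate",
    "splice_windows",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
]

_DNA = frozenset("ACGT")


@dataclass(frozen=True)
class ReferenceContig:
    """A named DNA sequence over {A, C, G, T}."""

    name: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= len(self.sequence):
            raise ValueError(f"position {pos} outside contig {self.name!r} (length {len(self.sequence)})")
        return self.sequence[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Subsequence for the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(f"interval [{start}, {end}] outside contig {self.name!r}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript protein-coding gene.

    Parameters
    ----------
    contig_name : str
        Name of the contig the gene lies on.
    strand : {"+", "-"}
    exons : tuple of (start, end)
        1-based inclusive genomic intervals, sorted by genomic coordinate,
        non-overlapping and separated by at least one intronic base.
    cds_genomic_span : (start, end)
        Genomic interval covered by the coding sequence.
    gene_name : str
    """

    contig_name: str
    strand: str
    exons: tuple
    cds_genomic_span: tuple
    gene_name: str = "gene"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(a), int(b)) for a, b in self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "cds_genomic_span", tuple(int(x) for x in self.cds_genomic_span))
        for lo, hi in exons:
            if lo > hi:
                raise ValueError(f"malformed exon interval ({lo}, {hi})")
        for (alo, ahi), (blo, bhi) in zip(exons, exons[1:]):
            if blo <= ahi + 1:
                raise ValueError("exons must be sorted, non-overlapping and non-adjacent")

    @cached_property
    def cds_intervals(self) -> tuple:
        """CDS intervals (exon ∩ CDS span) in ascending genomic order."""
        lo, hi = self.cds_genomic_span
        out = []
        for elo, ehi in self.exons:
            s, e = max(elo, lo), min(ehi, hi)
            if s <= e:
                out.append((s, e))
        return tuple(out)

    @cached_property
    def cds_intervals_transcript_order(self) -> tuple:
        ivals = self.cds_intervals
        return tuple(reversed(ivals)) if self.strand == "-" else ivals

    @cached_property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def in_exon(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(lo <= pos <= hi for lo, hi in self.cds_intervals)


def genomic_to_cds(model: GeneModel, pos: int) -> Optional[int]:
    """Map a 1-based genomic position to its 0-based spliced-CDS offset.

    Returns ``None`` for positions outside the CDS (intronic, UTR-less
    flanks, intergenic).  For minus-strand genes, offset 0 is the
    highest-coordinate CDS base.
    """
    offset = 0
    for lo, hi in model.cds_intervals_transcript_order:
        if lo <= pos <= hi:
            return offset + (hi - pos if model.strand == "-" else pos - lo)
        offset += hi - lo + 1
    return None


def cds_to_genomic(model: GeneModel, offset: int) -> int:
    """Inverse of :func:`genomic_to_cds`; raises for out-of-range offsets."""
    if not 0 <= offset < model.cds_length:
        raise ValueError(f"CDS offset {offset} out of range [0, {model.cds_length})")
    for lo, hi in model.cds_intervals_transcript_order:
        n = hi - lo + 1
        if offset < n:
            return hi - offset if model.strand == "-" else lo + offset
        offset -= n
    raise AssertionError("unreachable")


def spliced_cds(model: GeneModel, ref: ReferenceContig) -> str:
    """Concatenated CDS in transcript orientation (reverse-complemented on '-')."""
    lo, hi = model.span
    if not (1 <= lo and hi <= len(ref)):
        raise ValueError(f"gene {model.gene_name!r} outside contig {ref.name!r}")
    seq = "".join(ref.slice(s, e) for s, e in model.cds_intervals)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def translate(cds: str) -> str:
    """Standard-code translation; the terminator is rendered as ``*``.

    The input length must be a multiple of 3.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return str(Seq(cds).translate())


@dataclass(frozen=True)
class SpliceWindows:
    """Window sizes for splice-site classification (all in bases).

    ``donor_len``/``acceptor_len`` count intronic bases flanking a junction;
    ``region_exonic`` counts exonic bases from a junction; the intronic
    splice region spans bases ``region_intron_start``..``region_intron_end``
    from the junction (bases 1..donor/acceptor length being the site itself).
    """

    donor_len: int = 2
    acceptor_len: int = 2
    region_exonic: int = 3
    region_intron_start: int = 3
    region_intron_end: int = 8

    def __post_init__(self):
        if min(self.donor_len, self.acceptor_len, self.region_exonic) < 1:
            raise ValueError("window sizes must be positive")


def splice_windows(model: GeneModel, windows: SpliceWindows = SpliceWindows()) -> dict:
    """Classify junction-proximal genomic positions of a gene.

    Returns a mapping with keys ``splice_donor``, ``splice_acceptor`` and
    ``splice_region``, each a set of genomic positions.  Single-exon genes
    have no junctions and yield three empty sets.
    """
    donor, acceptor = set(), set()
    region_exon, region_intron = set(), set()
    exons = list(model.exons)
    if model.strand == "-":
        exons = exons[::-1]
    # walk internal junctions in transcript order
    for up, down in zip(exons, exons[1:]):
        if model.strand == "+":
            exon_end, next_start = up[1], down[0]
            intron_after = range(exon_end + 1, exon_end + 1 + windows.donor_len)
            intron_before = range(next_start - windows.acceptor_len, next_start)
            region_intron_d = range(exon_end + windows.region_intron_start,
                                    exon_end + windows.region_intron_end + 1)
            region_intron_a = range(next_start - windows.region_intron_end,
                                    next_start - windows.region_intron_start + 1)
            region_exon_d = range(exon_end - windows.region_exonic + 1, exon_end + 1)
            region_exon_a = range(next_start, next_start + windows.region_exonic)
        else:
            exon_end, next_start = up[0], down[1]  # transcript-order ends
            intron_after = range(exon_end - windows.donor_len, exon_end)
            intron_before = range(next_start + 1, next_start + 1 + windows.acceptor_len)
            region_intron_d = range(exon_end - windows.region_intron_end,
                                    exon_end - windows.region_intron_start + 1)
            region_intron_a = range(next_start + windows.region_intron_start,
                                    next_start + windows.region_intron_end + 1)
            region_exon_d = range(exon_end, exon_end + windows.region_exonic)
            region_exon_a = range(next_start - windows.region_exonic + 1, next_start + 1)
        donor.update(intron_after)
        acceptor.update(intron_before)
        region_intron.update(region_intron_d, region_intron_a)
        region_exon.update(region_exon_d, region_exon_a)
    # windows are defined relative to a junction; clip to the correct side
    exonic = {p for lo, hi in model.exons for p in range(lo, hi + 1)}
    lo, hi = (model.span if model.exons else (0, -1))
    intronic = {p for p in range(lo, hi + 1) if p not in exonic} if model.exons else set()
    donor &= intronic
    acceptor &= intronic
    region = (region_exon & exonic) | ((region_intron & intronic) - donor - acceptor)
    return {"splice_donor": donor, "splice_acceptor": acceptor, "splice_region": region}


# ---------------------------------------------------------------------------
# FASTA / GFF3 I/O


def read_fasta(path) -> ReferenceContig:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceContig(name=rec.id, sequence=str(rec.seq).upper())


def write_fasta(contig: ReferenceContig, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{contig.name}\n")
        for i in range(0, len(contig.sequence), width):
            fh.write(contig.sequence[i : i + width] + "\n")


def write_gff3(model: GeneModel, path) -> None:
    """Write the gene as GFF3 gene/mRNA/exon/CDS features."""
    lo, hi = model.span
    gid = model.gene_name
    lines = [
        "##gff-version 3",
        f"{model.contig_name}\thbbscan\tgene\t{lo}\t{hi}\t.\t{model.strand}\t.\tID=gene:{gid};Name={gid}",
        f"{model.contig_name}\thbbscan\tmRNA\t{lo}\t{hi}\t.\t{model.strand}\t.\tID=tx:{gid};Parent=gene:{gid}",
    ]
    for i, (s, e) in enumerate(model.exons, 1):
        lines.append(
            f"{model.contig_name}\thbbscan\texon\t{s}\t{e}\t.\t{model.strand}\t.\tID=exon:{gid}.{i};Parent=tx:{gid}"
        )
    # CDS phase accumulates in transcript order
    phase = 0
    cds_lines = {}
    for s, e in model.cds_intervals_transcript_order:
        cds_lines[(s, e)] = phase
        phase = (3 - ((e - s + 1 - phase) % 3)) % 3
    for i, (s, e) in enumerate(model.cds_intervals, 1):
        lines.append(
            f"{model.contig_name}\thbbscan\tCDS\t{s}\t{e}\t.\t{model.strand}\t{cds_lines[(s, e)]}\t"
            f"ID=cds:{gid};Parent=tx:{gid}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path) -> GeneModel:
    """Read a single-gene GFF3 written in the gene/mRNA/exon/CDS layout."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique", keep_order=True)
    genes = list(db.features_of_type("gene"))
    if len(genes) != 1:
        raise ValueError(f"expected exactly one gene feature, found {len(genes)}")
    gene = genes[0]
    exons = sorted((f.start, f.end) for f in db.features_of_type("exon"))
    cds = sorted((f.start, f.end) for f in db.features_of_type("CDS"))
    if not exons or not cds:
        raise ValueError("gene model requires exon and CDS features")
    return GeneModel(
        contig_name=gene.seqid,
        strand=gene.strand,
        exons=tuple(exons),
        cds_genomic_span=(cds[0][0], cds[-1][1]),
        gene_name=gene.attributes.get("Name", [gene.id.split(":")[-1]])[0],
    )


def validate_model(model: GeneModel, ref: ReferenceContig) -> None:
    """Check the coding-gene invariants of a model against its contig.

    The CDS must be a multiple of 3 and at least two codons long, begin with
    Met, end with a terminator, and contain no internal stop or ambiguity
    codes.
    """
    if model.cds_length % 3 != 0 or model.cds_length < 6:
        raise ValueError(f"CDS length {model.cds_length} is not a valid coding length")
    cds = spliced_cds(model, ref)
    if set(cds) - _DNA:
        raise ValueError("CDS contains ambiguity codes")
    prot = translate(cds)
    if not prot.startswith("M"):
        raise ValueError("CDS does not begin with Met")
    if prot[-1] != "*" or "*" in prot[:-1]:
        raise ValueError("CDS must end with a single terminator and contain no internal stop")
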