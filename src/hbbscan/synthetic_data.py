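"""Seeded generators for every input the pipeline consumes.

Produces a reference contig whose coding sequence satisfies residue- and
base-level constraints, a diploid cohort with prescribed per-population
heterozygous-carrier counts, and the corresponding on-disk inputs (FASTA,
GFF3, VCF v4.2, population map, evidence tables).  All randomness is
confined to unconstrained reference bases and to carrier-to-sample
assignment, and is fully determined by the spec's seed: the same seed yields
byte-identical output files.

This emulates a 1000-Genomes-style cohort — five continental
super-populations of diploid samples, each carrier heterozygous for exactly
one variant — without any realistic linkage, mutation-rate or coalescent
modelling (see the package methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .consensus import (
    DB_SOURCES,
    PREDICTOR_SOURCES,
    EvidenceRecord,
    write_evidence_table,
)
from .gene_model import (
    GeneModel,
    ReferenceContig,
    cds_to_genomic,
    genomic_to_cds,
    spliced_cds,
    translate,
    validate_model,
    write_fasta,
    write_gff3,
)
from .population_stats import CohortGenotypes

__all__ = [
    "VariantSpec",
    "CohortSpec",
    "EvidenceSpec",
    "build_reference",
    "simulate_cohort",
    "write_inputs",
    "simulate_from_yaml",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_CODON_TABLE = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            _CODON_TABLE[_codon] = translate(_codon)

_STOP_CODONS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")

_AA1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}


@dataclass(frozen=True)
class VariantSpec:
    """One cohort variant: VCF-anchored alleles plus per-population
    heterozygous-carrier counts."""

    pos: int
    ref: str
    alt: str
    identifier: str
    carriers: Mapping[str, int]

    @property
    def total_carriers(self) -> int:
        return sum(self.carriers.values())


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: population names and sizes, variant specs, seed."""

    population_names: tuple
    population_sizes: Mapping[str, int]
    variant_specs: tuple
    seed: int = 0

    def __post_init__(self):
        for pop, n in self.population_sizes.items():
            if n <= 0:
                raise ValueError(f"population {pop} must have positive size")
        demand = {pop: 0 for pop in self.population_names}
        for vs in self.variant_specs:
            for pop, k in vs.carriers.items():
                if pop not in demand:
                    raise ValueError(f"variant {vs.identifier} names unknown population {pop!r}")
                demand[pop] += k
        for pop, k in demand.items():
            if k > self.population_sizes[pop]:
                raise ValueError(
                    f"population {pop} needs {k} carriers but has only "
                    f"{self.population_sizes[pop]} samples"
                )

    @property
    def n_samples(self) -> int:
        return sum(self.population_sizes[p] for p in self.population_names)


@dataclass(frozen=True)
class EvidenceSpec:
    """Per-variant raw evidence labels for the 8 sources."""

    records: tuple  # of EvidenceRecord
    overrides: Mapping[str, str] = field(default_factory=dict)


def _codon_candidates(constraint) -> list:
    """Codons compatible with a constraint: an explicit codon, a 1- or
    3-letter amino acid, ``'*'`` for a terminator, or ``None`` (any sense
    codon)."""
    if constraint is None:
        return sorted(set(_CODON_TABLE) - _STOP_CODONS)
    c = str(constraint)
    if len(c) == 3 and set(c) <= set("ACGT"):
        return [c]
    aa = _AA1.get(c, c)
    if aa not in set(_AA1.values()):
        raise ValueError(f"unknown codon constraint {constraint!r}")
    return sorted(codon for codon, a in _CODON_TABLE.items() if a == aa)


def build_reference(
    spec: CohortSpec,
    model: GeneModel,
    codon_constraints: Optional[Mapping[int, str]] = None,
    contig_length: Optional[int] = None,
    canonical_splice_sites: bool = True,
) -> ReferenceContig:
    """Build a contig satisfying the model, codon and ref-allele constraints.

    ``codon_constraints`` maps 1-based codon indices to a required amino
    acid (1- or 3-letter, ``'*'`` for the terminator) or an explicit codon.
    Bases at variant positions are fixed to the spec's REF alleles
    (strand-adjusted inside the CDS); intron 5'/3' dinucleotides are set to
    the canonical GT/AG unless a variant REF allele overrides them;
    everything else is seeded-random.  Raises ``ValueError`` when a REF
    allele is incompatible with a required codon.
    """
    codon_constraints = dict(codon_constraints or {})
    n_codons = model.cds_length // 3
    if model.cds_length % 3:
        raise ValueError("model CDS length is not a multiple of 3")
    codon_constraints.setdefault(1, "M")
    codon_constraints.setdefault(n_codons, "*")

    if contig_length is None:
        contig_length = model.span[1] + 500
    if contig_length < model.span[1]:
        raise ValueError("contig_length shorter than the gene span")

    rng = np.random.default_rng(spec.seed)
    genome = rng.choice(_BASES, size=contig_length)

    # --- base-level constraints from variant REF alleles (genomic strand)
    base_constraints: dict = {}
    for vs in spec.variant_specs:
        for i, b in enumerate(vs.ref):
            p = vs.pos + i
            if base_constraints.get(p, b) != b:
                raise ValueError(f"conflicting REF alleles at position {p}")
            base_constraints[p] = b

    # --- canonical splice dinucleotides (transcript orientation GT..AG)
    if canonical_splice_sites and len(model.exons) > 1:
        exons = list(model.exons)
        if model.strand == "-":
            exons = exons[::-1]
        for up, down in zip(exons, exons[1:]):
            if model.strand == "+":
                donor = {up[1] + 1: "G", up[1] + 2: "T"}
                acceptor = {down[0] - 2: "A", down[0] - 1: "G"}
            else:
                donor = {up[0] - 1: _COMPLEMENT["G"], up[0] - 2: _COMPLEMENT["T"]}
                acceptor = {down[1] + 2: _COMPLEMENT["A"], down[1] + 1: _COMPLEMENT["G"]}
            for p, b in {**donor, **acceptor}.items():
                base_constraints.setdefault(p, b)

    # --- solve the CDS codon by codon
    cds_base_constraint: dict = {}  # 0-based CDS offset -> transcript base
    for p, b in base_constraints.items():
        off = genomic_to_cds(model, p)
        if off is not None:
            cds_base_constraint[off] = b if model.strand == "+" else _COMPLEMENT[b]

    cds = []
    for i in range(1, n_codons + 1):
        cands = _codon_candidates(codon_constraints.get(i))
        if i < n_codons:
            cands = [c for c in cands if c not in _STOP_CODONS]
        for k in range(3):
            want = cds_base_constraint.get((i - 1) * 3 + k)
            if want is not None:
                cands = [c for c in cands if c[k] == want]
        if not cands:
            raise ValueError(
                f"codon {i}: constraint {codon_constraints.get(i)!r} is "
                "unsatisfiable with the REF alleles at its positions"
            )
        cds.append(cands[rng.integers(len(cands))])
    cds_seq = "".join(cds)

    # --- write the CDS back onto the genomic strand
    for off, base in enumerate(cds_seq):
        p = cds_to_genomic(model, off)
        genome[p - 1] = (base if model.strand == "+" else _COMPLEMENT[base]).encode()

    # --- non-CDS base constraints (intronic / intergenic REF alleles, splice sites)
    for p, b in base_constraints.items():
        if genomic_to_cds(model, p) is None:
            if p < 1 or p > contig_length:
                raise ValueError(f"constrained position {p} outside the contig")
            genome[p - 1] = b.encode()

    contig = ReferenceContig(name=model.contig_name, sequence=genome.tobytes().decode())
    validate_model(model, contig)
    return contig


def simulate_cohort(spec: CohortSpec) -> CohortGenotypes:
    """Assign each prescribed carrier to a distinct sample, heterozygous.

    Within each population, a seeded permutation of the samples is cut into
    consecutive blocks, one per variant, so no sample carries two variants
    (the bundled cohort's carrier counts sum exactly to its carrier total).
    All carriers are unphased heterozygotes (dosage 1); everyone else is
    homozygous reference.
    """
    sample_ids, populations = [], []
    index_of_pop: dict = {}
    for pop in spec.population_names:
        n = spec.population_sizes[pop]
        start = len(sample_ids)
        sample_ids.extend(f"{pop}{i:04d}" for i in range(1, n + 1))
        populations.extend([pop] * n)
        index_of_pop[pop] = np.arange(start, start + n)

    rng = np.random.default_rng(spec.seed)
    matrix = np.zeros((len(sample_ids), len(spec.variant_specs)), dtype=np.int8)
    cursor = {pop: 0 for pop in spec.population_names}
    perms = {pop: rng.permutation(index_of_pop[pop]) for pop in spec.population_names}
    for j, vs in enumerate(spec.variant_specs):
        for pop, k in vs.carriers.items():
            lo = cursor[pop]
            matrix[perms[pop][lo : lo + k], j] = 1
            cursor[pop] = lo + k

    return CohortGenotypes(
        sample_ids=sample_ids,
        populations=populations,
        variant_ids=[vs.identifier for vs in spec.variant_specs],
        matrix=matrix,
    )


def write_inputs(
    spec: CohortSpec,
    cohort: CohortGenotypes,
    contig: ReferenceContig,
    model: GeneModel,
    evidence: Optional[EvidenceSpec],
    outdir,
) -> dict:
    """Emit the full input set for a pipeline run; returns the file paths.

    Files: ``reference.fasta``, ``gene.gff3``, ``cohort.vcf`` (v4.2, GT-only
    FORMAT), ``populations.tsv``, and, when evidence is given,
    ``evidence.tsv`` plus ``overrides.tsv``.  Everything round-trips through
    the package's readers losslessly.
    """
    import pysam

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fasta",
        "gene_model": outdir / "gene.gff3",
        "vcf": outdir / "cohort.vcf",
        "pop_map": outdir / "populations.tsv",
    }
    write_fasta(contig, paths["reference"])
    write_gff3(model, paths["gene_model"])

    with open(paths["pop_map"], "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for s, p in zip(cohort.sample_ids, cohort.populations):
            fh.write(f"{s}\t{p}\n")

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig.name},length={len(contig)}>")
    header.formats.add("GT", 1, "String", "Genotype")
    for s in cohort.sample_ids:
        header.add_sample(s)
    by_id = {vs.identifier: j for j, vs in enumerate(spec.variant_specs)}
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vcf:
        for vs in sorted(spec.variant_specs, key=lambda v: v.pos):
            j = by_id[vs.identifier]
            rec = vcf.new_record(
                contig=contig.name,
                start=vs.pos - 1,
                stop=vs.pos - 1 + len(vs.ref),
                alleles=(vs.ref, vs.alt),
                id=vs.identifier,
            )
            col = cohort.matrix[:, j]
            for i, s in enumerate(cohort.sample_ids):
                dosage = int(col[i])
                rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[dosage]
                rec.samples[s].phased = False
            vcf.write(rec)

    if evidence is not None:
        paths["evidence"] = outdir / "evidence.tsv"
        write_evidence_table(evidence.records, paths["evidence"])
        paths["overrides"] = outdir / "overrides.tsv"
        with open(paths["overrides"], "w") as fh:
            fh.write("variant_id\tverdict\n")
            for vid, verdict in evidence.overrides.items():
                fh.write(f"{vid}\t{verdict}\n")
    return paths


def simulate_from_yaml(spec_path, outdir, seed: Optional[int] = None) -> dict:
    """Simulate a cohort described by a YAML spec and write its inputs.

    Expected keys: ``contig_name``, ``contig_length``, ``gene`` (``strand``,
    ``exons``, optional ``cds_span`` and ``name``), ``populations`` (name →
    size), ``variants`` (``pos``/``ref``/``alt``/``id``/``carriers``),
    optional ``codon_constraints`` and ``seed`` (overridden by the ``seed``
    argument when given).
    """
    import yaml

    with open(spec_path) as fh:
        data = yaml.safe_load(fh)
    gene = data["gene"]
    exons = tuple(tuple(iv) for iv in gene["exons"])
    model = GeneModel(
        contig_name=data.get("contig_name", "contig1"),
        strand=gene["strand"],
        exons=exons,
        cds_genomic_span=tuple(gene.get("cds_span", (exons[0][0], exons[-1][1]))),
        gene_name=gene.get("name", "gene"),
    )
    spec = CohortSpec(
        population_names=tuple(data["populations"]),
        population_sizes=dict(data["populations"]),
        variant_specs=tuple(
            VariantSpec(
                pos=v["pos"], ref=v["ref"], alt=v["alt"],
                identifier=v.get("id", f"v{i}"), carriers=dict(v.get("carriers", {})),
            )
            for i, v in enumerate(data.get("variants", []), 1)
        ),
        seed=seed if seed is not None else int(data.get("seed", 0)),
    )
    contig = build_reference(
        spec,
        model,
        codon_constraints={int(k): v for k, v in (data.get("codon_constraints") or {}).items()},
        contig_length=data.get("contig_length"),
    )
    cohort = simulate_cohort(spec)
    return write_inputs(spec, cohort, contig, model, None, outdir)
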