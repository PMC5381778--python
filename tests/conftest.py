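"""Shared fixtures: the bundled survey cohort (built once per session) and
seeded random toy-gene generators for property tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hbbscan import fixture as hbb_fixture
from hbbscan.consensus import batch_classify
from hbbscan.gene_model import GeneModel, ReferenceContig
from hbbscan.population_stats import burden_summary
from hbbscan.synthetic_data import CohortSpec, build_reference, simulate_cohort
from hbbscan.variant_effects import Variant, annotate_variant

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")

SEED = 11


@pytest.fixture(scope="session")
def hbb_model():
    return hbb_fixture.gene_model()


@pytest.fixture(scope="session")
def hbb_reference(hbb_model):
    return hbb_fixture.reference(seed=SEED)


@pytest.fixture(scope="session")
def hbb_spec():
    return hbb_fixture.cohort_spec(seed=SEED)


@pytest.fixture(scope="session")
def hbb_cohort(hbb_spec):
    return simulate_cohort(hbb_spec)


@pytest.fixture(scope="session")
def hbb_variants(hbb_spec):
    return [
        Variant(hbb_fixture.CONTIG_NAME, vs.pos, vs.ref, vs.alt, vs.identifier)
        for vs in hbb_spec.variant_specs
    ]


@pytest.fixture(scope="session")
def hbb_annotations(hbb_variants, hbb_model, hbb_reference):
    return {v.identifier: annotate_variant(v, hbb_model, hbb_reference) for v in hbb_variants}


@pytest.fixture(scope="session")
def hbb_verdicts(hbb_annotations):
    ev = hbb_fixture.evidence_spec()
    return batch_classify(ev.records, hbb_annotations, overrides=ev.overrides)


@pytest.fixture(scope="session")
def hbb_report(hbb_cohort, hbb_annotations, hbb_verdicts):
    return burden_summary(hbb_cohort, hbb_annotations, hbb_verdicts)


@pytest.fixture(scope="session")
def fixture_inputs(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("survey-inputs")
    return hbb_fixture.write_fixture_inputs(outdir, seed=SEED)


# ---------------------------------------------------------------------------
# Random toy genes for property tests


def random_gene_and_contig(rng: np.random.Generator, contig_name: str = "toy"):
    """A seeded random coding gene (1-3 exons, either strand, canonical
    splice sites) on a short contig."""
    n_exons = int(rng.integers(1, 4))
    strand = "+" if rng.integers(2) == 0 else "-"
    n_codons = int(rng.integers(10, 31))
    cds_len = 3 * n_codons
    # split cds_len into n_exons parts of at least 5 bases
    cuts = sorted(rng.choice(np.arange(5, cds_len - 5), size=n_exons - 1, replace=False).tolist()) if n_exons > 1 else []
    parts, prev = [], 0
    for c in cuts + [cds_len]:
        parts.append(c - prev)
        prev = c
    if min(parts) < 5:  # resample degenerate splits deterministically
        return random_gene_and_contig(rng, contig_name)
    exons, pos = [], int(rng.integers(30, 60))
    for length in parts:
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(20, 60))
    model = GeneModel(
        contig_name=contig_name,
        strand=strand,
        exons=tuple(exons),
        cds_genomic_span=(exons[0][0], exons[-1][1]),
        gene_name="toy",
    )
    spec = CohortSpec(
        population_names=("P",),
        population_sizes={"P": 1},
        variant_specs=(),
        seed=int(rng.integers(2**31)),
    )
    contig = build_reference(spec, model, contig_length=exons[-1][1] + 40)
    return model, contig


def random_cds_snv(rng, model, contig) -> Variant:
    off = int(rng.integers(model.cds_length))
    from hbbscan.gene_model import cds_to_genomic

    pos = cds_to_genomic(model, off)
    ref = contig.base(pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    return Variant(contig.name, pos, ref, alt, f"snv{off}")


def random_frameshift_indel(rng, model, contig):
    """An anchored deletion or insertion (net length not divisible by 3)
    whose changed bases lie within a single CDS exon; None if no room."""
    for _ in range(20):
        if rng.integers(2) == 0:  # deletion
            dlen = int(rng.choice([1, 2, 4]))
            lo, hi = model.cds_intervals[int(rng.integers(len(model.cds_intervals)))]
            if hi - lo + 1 < dlen + 1:
                continue
            anchor = int(rng.integers(lo, hi - dlen + 1))
            # keep translation-oracle simple: anchor may sit just outside CDS
            ref = contig.slice(anchor, anchor + dlen)
            return Variant(contig.name, anchor, ref, ref[0], "del")
        else:  # insertion
            ilen = int(rng.choice([1, 2, 4]))
            lo, hi = model.cds_intervals[int(rng.integers(len(model.cds_intervals)))]
            if hi - lo < 1:
                continue
            anchor = int(rng.integers(lo, hi))  # anchor and next base both in exon
            ref = contig.base(anchor)
            ins = "".join(rng.choice(list("ACGT"), size=ilen))
            return Variant(contig.name, anchor, ref, ref + ins, "ins")
    return None


def mirror(model: GeneModel, contig: ReferenceContig, v: Variant):
    """Reflect gene, contig and SNV onto the opposite strand."""
    from Bio.Seq import Seq

    L = len(contig)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    new_contig = ReferenceContig(contig.name, str(Seq(contig.sequence).reverse_complement()))
    new_model = GeneModel(
        contig_name=model.contig_name,
        strand="+" if model.strand == "-" else "-",
        exons=tuple(sorted((L - hi + 1, L - lo + 1) for lo, hi in model.exons)),
        cds_genomic_span=(L - model.cds_genomic_span[1] + 1, L - model.cds_genomic_span[0] + 1),
        gene_name=model.gene_name,
    )
    new_v = Variant(v.contig, L - v.pos + 1, comp[v.ref], comp[v.alt], v.identifier)
    return new_model, new_contig, new_v
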