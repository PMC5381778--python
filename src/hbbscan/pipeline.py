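"""End-to-end orchestration: annotate → classify → summarize → report.

A :class:`PipelineConfig` names the five inputs (reference FASTA, gene-model
GFF3, multi-sample VCF, sample→population map, evidence table, optional
overrides), the splice-window sizes, the consensus strategy and the display
style.  :func:`run_pipeline` executes the stages, writes the annotation,
verdict and frequency tables plus a JSON summary, and logs per-stage record
counts to standard error.  Given identical inputs and configuration the
outputs are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

from .consensus import (
    Verdict,
    batch_classify,
    read_evidence_table,
    read_overrides,
    write_verdict_table,
)
from .gene_model import SpliceWindows, read_fasta, read_gff3
from .population_stats import burden_summary, read_cohort, write_frequency_table
from .variant_effects import (
    annotate_variant,
    format_protein_change,
    read_vcf_variants,
    write_annotation_table,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "render_tables"]

log = logging.getLogger("hbbscan")


@dataclass
class PipelineConfig:
    reference: str
    gene_model: str
    vcf: str
    pop_map: str
    evidence: Optional[str] = None
    overrides: Optional[str] = None
    outdir: str = "hbbscan-out"
    splice_donor_len: int = 2
    splice_acceptor_len: int = 2
    splice_region_exon: int = 3
    splice_region_intron_start: int = 3
    splice_region_intron_end: int = 8
    consensus_strategy: str = "majority"
    display: str = "paper"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def splice_windows(self) -> SpliceWindows:
        return SpliceWindows(
            donor_len=self.splice_donor_len,
            acceptor_len=self.splice_acceptor_len,
            region_exonic=self.splice_region_exon,
            region_intron_start=self.splice_region_intron_start,
            region_intron_end=self.splice_region_intron_end,
        )


@dataclass
class PipelineResult:
    variants: list
    annotations: dict
    verdicts: dict
    report: "object"
    cohort: "object"
    paths: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute annotate → classify → summarize and write all artifacts.

    Writes ``annotation.tsv``, ``verdicts.tsv``, ``frequencies.tsv`` and
    ``summary.json`` under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage %s", name)
        return name

    try:
        stage("load")
        contig = read_fasta(config.reference)
        model = read_gff3(config.gene_model)
        variants = read_vcf_variants(config.vcf)
        cohort = read_cohort(config.vcf, config.pop_map)
        log.info("loaded %d variants, %d samples", len(variants), cohort.n_samples)
    except Exception as e:
        raise RuntimeError(f"[load] {e}") from e

    try:
        stage("annotate")
        windows = config.splice_windows
        annotations = {
            v.identifier: annotate_variant(v, model, contig, windows) for v in variants
        }
        write_annotation_table(
            [(v, annotations[v.identifier]) for v in variants], outdir / "annotation.tsv"
        )
        log.info("annotated %d variants", len(annotations))
    except Exception as e:
        raise RuntimeError(f"[annotate] {e}") from e

    try:
        stage("classify")
        if config.evidence:
            records = read_evidence_table(config.evidence)
            overrides = read_overrides(config.overrides) if config.overrides else None
            verdicts = batch_classify(
                records, annotations, overrides=overrides, strategy=config.consensus_strategy
            )
            # variants with no evidence row at all are NotEvaluated
            for vid in annotations:
                verdicts.setdefault(vid, Verdict(value="NotEvaluated"))
        else:
            verdicts = {vid: Verdict(value="NotEvaluated") for vid in annotations}
        write_verdict_table(verdicts, outdir / "verdicts.tsv")
        n_damaging = sum(1 for v in verdicts.values() if v.value == "Damaging")
        log.info("classified %d variants, %d Damaging", len(verdicts), n_damaging)
    except Exception as e:
        raise RuntimeError(f"[classify] {e}") from e

    try:
        stage("summarize")
        report = burden_summary(cohort, annotations, verdicts)
        write_frequency_table(report, outdir / "frequencies.tsv", display=config.display)
        report.to_json(outdir / "summary.json")
        log.info("summary: %d carriers of %d samples", report.n_carriers, report.n_samples)
    except Exception as e:
        raise RuntimeError(f"[summarize] {e}") from e

    paths = {
        "annotation": outdir / "annotation.tsv",
        "verdicts": outdir / "verdicts.tsv",
        "frequencies": outdir / "frequencies.tsv",
        "summary": outdir / "summary.json",
    }
    return PipelineResult(
        variants=variants,
        annotations=annotations,
        verdicts=verdicts,
        report=report,
        cohort=cohort,
        paths=paths,
    )


def _fmt_freq(x, pops_digits=4) -> str:
    return f"{x:.{pops_digits}f}".rstrip("0").rstrip(".") if x else "0"


def render_tables(result: PipelineResult, style: str = "paper") -> str:
    """Render the three survey-style text tables for side-by-side diffing.

    ``paper`` style prints total allele frequencies truncated at 5 decimals;
    ``exact`` prints full precision.  Returns one string with the three
    tables separated by blank lines.
    """
    if style not in ("paper", "exact"):
        raise ValueError(f"unknown style {style!r}")
    from .population_stats import allele_counts

    cohort = result.cohort
    pops = cohort.population_names
    import numpy as np

    pop_sizes = {p: int(sum(1 for q in cohort.populations if q == p)) for p in pops}
    ann = result.annotations
    by_id = {v.identifier: v for v in result.variants}

    lines1 = ["Position\tSNP ID\tNucleotide change\tAA alteration\tType of mutation\tN individuals"]
    lines2 = ["SNP ID\tNucleotide change\tAA alteration\tTotal individuals\t"
              + "\t".join(f"N/Freq {p}" for p in pops) + "\tTotal Allele Frequency"]
    lines3 = ["SNP ID\tDB call\tPredictor call\tConclusion pathogenicity"]

    for v in result.variants:
        c = ann[v.identifier]
        aa = format_protein_change(c) if c.protein_change else "#"
        type_label = " and ".join(c.terms_sorted()).replace("_", " ")
        counts = allele_counts(cohort, v.identifier)
        carriers = {
            p: int((cohort.matrix[:, cohort.variant_index(v.identifier)][
                np.asarray(cohort.populations) == p] > 0).sum())
            for p in pops
        }
        total_carriers = sum(carriers.values())
        lines1.append(
            f"{v.pos}\t{v.identifier}\t{v.ref}/{v.alt}\t{aa}\t{type_label}\t{total_carriers}"
        )
        if style == "paper":
            from .population_stats import truncate_ratio

            total_freq = truncate_ratio(counts["total"], 2 * cohort.n_samples, 5)
        else:
            total_freq = repr(counts["total"] / (2 * cohort.n_samples))
        cells = []
        for p in pops:
            n = carriers[p]
            cells.append(f"{n} ({_fmt_freq(counts[p] / (2 * pop_sizes[p]))})" if n else "0")
        lines2.append(
            f"{v.identifier}\t{v.ref}/{v.alt}\t{aa}\t{total_carriers}\t"
            + "\t".join(cells) + f"\t{total_freq}"
        )
        verdict = result.verdicts[v.identifier]
        lines3.append(
            f"{v.identifier}\t{verdict.db_class_call}\t{verdict.predictor_class_call}\t{verdict.value}"
        )

    return "\n".join(lines1) + "\n\n" + "\n".join(lines2) + "\n\n" + "\n".join(lines3) + "\n"
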