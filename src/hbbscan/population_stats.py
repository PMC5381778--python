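"""Cohort allele frequencies, carrier burden, and Hardy–Weinberg projection.

Works on a diploid sample × variant genotype matrix with population labels
(the five continental super-populations AFR, AMR, EAS, EUR, SAS in the
bundled cohort).  Frequencies are computed exactly as integer ratios;
display styles reproduce two printing conventions seen in the published
hemoglobinopathy-survey tables: per-variant frequencies and cohort
percentages are *truncated* (floored) at a fixed number of decimals, while
gene-frequency estimates are conventionally rounded.

The Hardy–Weinberg projection pools all mutant alleles of the gene into a
single frequency q; under random mating the probability that an offspring
receives two mutant alleles (homozygous or compound heterozygous) is q².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortGenotypes",
    "SummaryReport",
    "allele_counts",
    "allele_frequency",
    "truncate_ratio",
    "burden_summary",
    "hw_projection",
    "read_cohort",
    "read_population_map",
    "write_frequency_table",
]


def truncate_ratio(numerator: int, denominator: int, places: int, scale: int = 1) -> str:
    """Exact truncated decimal rendering of ``scale * numerator/denominator``.

    Truncation floors toward zero using integer arithmetic, avoiding binary
    floating-point surprises: ``truncate_ratio(137, 5008, 5) == '0.02735'``.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    units = numerator * scale * 10**places // denominator
    s = str(units).rjust(places + 1, "0")
    return f"{s[:-places]}.{s[-places:]}" if places else s


@dataclass
class CohortGenotypes:
    """Diploid genotype matrix with population labels.

    ``matrix[i, j]`` is the alternate-allele dosage (0, 1 or 2) of sample i
    at variant j.
    """

    sample_ids: Sequence[str]
    populations: Sequence[str]
    variant_ids: Sequence[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        n, m = self.matrix.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError("matrix shape does not match sample/variant lists")
        if len(self.populations) != n:
            raise ValueError("every sample needs a population label")
        if not np.isin(self.matrix, (0, 1, 2)).all():
            raise ValueError("genotype dosages must be 0, 1 or 2")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def population_names(self) -> list:
        return sorted(set(self.populations))

    def variant_index(self, variant_id: str) -> int:
        try:
            return list(self.variant_ids).index(variant_id)
        except ValueError:
            raise KeyError(f"unknown variant {variant_id!r}") from None

    def carriers_of(self, variant_ids: Iterable[str]) -> np.ndarray:
        """Boolean mask of samples carrying ≥1 alternate allele of any of
        the given variants."""
        idx = [self.variant_index(v) for v in variant_ids]
        if not idx:
            return np.zeros(self.n_samples, dtype=bool)
        return (self.matrix[:, idx] > 0).any(axis=1)


def allele_counts(cohort: CohortGenotypes, variant_id: str) -> dict:
    """Alternate-allele counts per population plus ``total`` for one variant.

    Heterozygotes contribute 1 allele, homozygous-alternate samples 2.
    """
    j = cohort.variant_index(variant_id)
    col = cohort.matrix[:, j]
    pops = np.asarray(cohort.populations)
    out = {pop: int(col[pops == pop].sum()) for pop in cohort.population_names}
    out["total"] = int(col.sum())
    return out


def allele_frequency(count: int, n_diploid: int, display: str = "exact"):
    """Allele frequency ``count / (2 * n_diploid)``.

    ``display='exact'`` returns a float; ``display='paper-truncated'``
    returns the 5-decimal truncated string used by the survey tables.
    """
    if n_diploid <= 0:
        raise ValueError("n_diploid must be positive")
    if not 0 <= count <= 2 * n_diploid:
        raise ValueError(f"allele count {count} outside [0, {2 * n_diploid}]")
    if display == "exact":
        return count / (2 * n_diploid)
    if display == "paper-truncated":
        return truncate_ratio(count, 2 * n_diploid, 5)
    raise ValueError(f"unknown display style {display!r}")


def hw_projection(q: float) -> float:
    """Random-mating probability of inheriting two mutant alleles: q²."""
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"allele frequency {q} outside [0, 1]")
    return q * q


@dataclass
class SummaryReport:
    """Per-variant frequencies plus cohort-level burden statistics.

    Counts are integers; ``q`` fields are exact floats.  ``display`` holds
    the table-convention renderings (truncated or rounded) of each headline
    quantity.
    """

    n_samples: int
    n_variants: int
    per_variant: pd.DataFrame  # variant_id, per-pop counts/freqs, total count/freq
    n_carriers: int
    n_nonsynonymous_carriers: int
    n_deleterious_carriers: int
    n_pure_synonymous_carriers: int
    n_pure_missense_carriers: int
    n_damaging_variants: int
    q_mutated: float
    q_deleterious: float

    @property
    def carrier_proportion(self) -> float:
        return self.n_carriers / self.n_samples if self.n_samples else 0.0

    @property
    def homozygote_projection(self) -> float:
        return hw_projection(self.q_mutated)

    @property
    def affected_projection(self) -> float:
        return hw_projection(self.q_deleterious)

    def display(self) -> dict:
        """Headline numbers under the published printing conventions.

        Proportions of the cohort / of carriers are truncated percentages;
        the pooled gene frequencies and their Hardy–Weinberg squares are
        rounded; the affected projection is also given per 10,000 births.
        """
        n2 = 2 * self.n_samples
        return {
            "carrier_percent": truncate_ratio(self.n_carriers, self.n_samples, 2, scale=100),
            "deleterious_percent": truncate_ratio(self.n_deleterious_carriers, self.n_samples, 1, scale=100),
            "pure_synonymous_percent_of_carriers": truncate_ratio(
                self.n_pure_synonymous_carriers, self.n_carriers or 1, 1, scale=100),
            "pure_missense_percent_of_carriers": truncate_ratio(
                self.n_pure_missense_carriers, self.n_carriers or 1, 1, scale=100),
            "q_mutated": f"{self.q_mutated:.3f}",
            "homozygote_projection": f"{self.homozygote_projection:.3f}",
            "q_deleterious": f"{self.q_deleterious:.3f}",
            "affected_per_10000": int(round(self.affected_projection * 10000)),
        }

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_variants": self.n_variants,
            "n_carriers": self.n_carriers,
            "n_nonsynonymous_carriers": self.n_nonsynonymous_carriers,
            "n_deleterious_carriers": self.n_deleterious_carriers,
            "n_pure_synonymous_carriers": self.n_pure_synonymous_carriers,
            "n_pure_missense_carriers": self.n_pure_missense_carriers,
            "n_damaging_variants": self.n_damaging_variants,
            "q_mutated": self.q_mutated,
            "q_deleterious": self.q_deleterious,
            "homozygote_projection": self.homozygote_projection,
            "affected_projection": self.affected_projection,
            "display": self.display(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _per_variant_frame(cohort: CohortGenotypes) -> pd.DataFrame:
    pops = cohort.population_names
    pop_sizes = {p: int((np.asarray(cohort.populations) == p).sum()) for p in pops}
    rows = []
    for vid in cohort.variant_ids:
        counts = allele_counts(cohort, vid)
        row = {"variant_id": vid, "total_count": counts["total"],
               "total_frequency": counts["total"] / (2 * cohort.n_samples),
               "total_frequency_truncated": truncate_ratio(counts["total"], 2 * cohort.n_samples, 5)}
        for p in pops:
            row[f"count_{p}"] = counts[p]
            row[f"freq_{p}"] = counts[p] / (2 * pop_sizes[p]) if pop_sizes[p] else 0.0
        rows.append(row)
    columns = (["variant_id", "total_count", "total_frequency", "total_frequency_truncated"]
               + [c for p in pops for c in (f"count_{p}", f"freq_{p}")])
    return pd.DataFrame(rows, columns=columns)


def burden_summary(
    cohort: CohortGenotypes,
    annotations: Mapping[str, "object"],
    verdicts: Mapping[str, "object"],
) -> SummaryReport:
    """Cohort-level burden statistics from genotypes + consequences + verdicts.

    * carriers: samples with ≥1 alternate allele of any variant;
    * non-synonymous carriers: carriers of any variant whose consequence
      term set is not exactly {synonymous};
    * deleterious carriers: carriers of any Damaging-verdict variant;
    * q: pooled mutant-allele frequency, all variants;
    * q_deleterious: same, Damaging variants only.
    """
    vids = list(cohort.variant_ids)
    missing = [v for v in vids if v not in annotations]
    if missing:
        raise KeyError(f"missing annotations for: {missing}")
    missing = [v for v in vids if v not in verdicts]
    if missing:
        raise KeyError(f"missing verdicts for: {missing}")

    pure_syn = [v for v in vids if annotations[v].is_pure_synonymous]
    nonsyn = [v for v in vids if v not in set(pure_syn)]
    pure_mis = [v for v in vids if set(annotations[v].terms) == {"missense"}]
    damaging = [v for v in vids if verdicts[v].value == "Damaging"]

    n2 = 2 * cohort.n_samples
    total_alt = int(cohort.matrix.sum())
    damaging_alt = int(sum(allele_counts(cohort, v)["total"] for v in damaging))

    return SummaryReport(
        n_samples=cohort.n_samples,
        n_variants=len(vids),
        per_variant=_per_variant_frame(cohort),
        n_carriers=int(cohort.carriers_of(vids).sum()),
        n_nonsynonymous_carriers=int(cohort.carriers_of(nonsyn).sum()),
        n_deleterious_carriers=int(cohort.carriers_of(damaging).sum()),
        n_pure_synonymous_carriers=int(cohort.carriers_of(pure_syn).sum()),
        n_pure_missense_carriers=int(cohort.carriers_of(pure_mis).sum()),
        n_damaging_variants=len(damaging),
        q_mutated=total_alt / n2 if n2 else 0.0,
        q_deleterious=damaging_alt / n2 if n2 else 0.0,
    )


# ---------------------------------------------------------------------------
# I/O


def read_population_map(path) -> dict:
    """Read a two-column sample→population TSV (header: sample_id, population)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "population"]:
        raise ValueError("population map must have columns sample_id, population")
    return dict(zip(df["sample_id"], df["population"]))


def read_cohort(vcf_path, popmap_path) -> CohortGenotypes:
    """Build a :class:`CohortGenotypes` from a multi-sample VCF + population map."""
    import pysam

    pop_of = read_population_map(popmap_path)
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        missing = [s for s in samples if s not in pop_of]
        if missing:
            raise ValueError(f"{len(missing)} samples missing from the population map")
        variant_ids, columns = [], []
        for rec in vcf:
            variant_ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            col = np.zeros(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                col[i] = sum(1 for a in gt if a not in (None, 0))
            columns.append(col)
    matrix = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return CohortGenotypes(
        sample_ids=samples,
        populations=[pop_of[s] for s in samples],
        variant_ids=variant_ids,
        matrix=matrix,
    )


def write_frequency_table(report: SummaryReport, path, display: str = "paper") -> None:
    """Write the per-variant frequency TSV (truncated or full-precision)."""
    df = report.per_variant.copy()
    if display == "paper":
        df["total_frequency"] = df["total_frequency_truncated"]
        df = df.drop(columns=["total_frequency_truncated"])
    df.to_csv(path, sep="\t", index=False)
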