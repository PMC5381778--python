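"""Pathogenicity consensus across clinical databases and in-silico predictors.

Each variant carries raw labels from three clinical databases (ClinVar,
dbSNP, HbVar) and five predictors (PolyPhen, PROVEAN, SIFT, PANTHER,
MutPred).  Labels are normalized to {damaging, benign, uninformative,
absent}; each source class is reduced to a class call by strict majority
among informative labels, and the two class calls combine into a verdict:
agreement (or one class silent) yields that call, disagreement yields
Conflict, and two silent classes yield NotEvaluated.  Pure-synonymous
variants are excluded from pathogenicity evaluation altogether, since they
do not alter the protein.

The combination rule is pluggable: the default ``majority`` strategy is the
class-wise strict majority described above; the stricter ``unanimous``
strategy flags any informative disagreement within or across classes as
Conflict.  Explicit per-variant overrides are supported and recorded.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "DB_SOURCES",
    "PREDICTOR_SOURCES",
    "EvidenceRecord",
    "Verdict",
    "normalize_label",
    "class_call",
    "consensus",
    "batch_classify",
    "read_evidence_table",
    "write_evidence_table",
    "read_overrides",
    "write_verdict_table",
]

DB_SOURCES = ("CLINVAR", "dbSNP", "HbVar")
PREDICTOR_SOURCES = ("POLYPHEN", "PROVEAN", "SIFT", "PANTHER", "MUTPRED")

_RAW_VOCAB = {
    "damaging": "damaging",
    "probably damaging": "damaging",
    "benign": "benign",
    "other": "uninformative",
    "not-evaluated": "absent",
    "not evaluated": "absent",
}


def normalize_label(raw: str) -> str:
    """Map a raw source label to {damaging, benign, uninformative, absent}."""
    key = raw.strip().lower()
    if key not in _RAW_VOCAB:
        raise ValueError(f"unknown evidence label {raw!r}")
    return _RAW_VOCAB[key]


def _norm_any(label: str) -> str:
    """Accept either raw or already-normalized labels."""
    key = label.strip().lower()
    if key in ("uninformative", "absent"):
        return key
    return normalize_label(label)


def class_call(labels: Iterable[str]) -> str:
    """Strict-majority call over normalized labels of one evidence class.

    Uninformative and absent labels are ignored; a tie or the absence of any
    informative label yields ``NoCall``.
    """
    counts = Counter(_norm_any(l) for l in labels)
    d, b = counts.get("damaging", 0), counts.get("benign", 0)
    if d > b:
        return "Damaging"
    if b > d:
        return "Benign"
    return "NoCall"


@dataclass(frozen=True)
class EvidenceRecord:
    """Raw labels for one variant, keyed by source name."""

    variant_id: str
    db_labels: Mapping[str, str]
    predictor_labels: Mapping[str, str]

    def __post_init__(self):
        for src in self.db_labels:
            if src not in DB_SOURCES:
                raise ValueError(f"unknown database source {src!r}")
        for src in self.predictor_labels:
            if src not in PREDICTOR_SOURCES:
                raise ValueError(f"unknown predictor source {src!r}")
        for raw in list(self.db_labels.values()) + list(self.predictor_labels.values()):
            normalize_label(raw)  # validates vocabulary


@dataclass(frozen=True)
class Verdict:
    value: str  # Damaging | Benign | Conflict | NotEvaluated
    db_class_call: str = "NoCall"
    predictor_class_call: str = "NoCall"
    overridden: bool = False


def _combine_majority(db_call: str, pred_call: str) -> str:
    if db_call == "NoCall" and pred_call == "NoCall":
        return "NotEvaluated"
    if db_call == "NoCall":
        return pred_call
    if pred_call == "NoCall":
        return db_call
    return db_call if db_call == pred_call else "Conflict"


def _combine_unanimous(rec: "EvidenceRecord") -> str:
    informative = {
        normalize_label(raw)
        for raw in list(rec.db_labels.values()) + list(rec.predictor_labels.values())
    } & {"damaging", "benign"}
    if not informative:
        return "NotEvaluated"
    if len(informative) == 2:
        return "Conflict"
    return "Damaging" if informative == {"damaging"} else "Benign"


def consensus(
    rec: EvidenceRecord,
    overrides: Optional[Mapping[str, str]] = None,
    strategy: str = "majority",
) -> Verdict:
    """Combine database and predictor class calls into a verdict.

    With the default ``majority`` strategy, the database and predictor
    classes each get a strict-majority call; agreement (or one silent class)
    decides, cross-class disagreement is a Conflict.  A variant present in
    ``overrides`` takes the override value with ``overridden=True``.
    """
    db_call = class_call(rec.db_labels.values())
    pred_call = class_call(rec.predictor_labels.values())
    if strategy == "majority":
        value = _combine_majority(db_call, pred_call)
    elif strategy == "unanimous":
        value = _combine_unanimous(rec)
    else:
        raise ValueError(f"unknown consensus strategy {strategy!r}")
    if overrides and rec.variant_id in overrides:
        return Verdict(
            value=overrides[rec.variant_id],
            db_class_call=db_call,
            predictor_class_call=pred_call,
            overridden=True,
        )
    return Verdict(value=value, db_class_call=db_call, predictor_class_call=pred_call)


def batch_classify(
    records: Iterable[EvidenceRecord],
    annotations: Mapping[str, "object"],
    overrides: Optional[Mapping[str, str]] = None,
    strategy: str = "majority",
) -> dict:
    """Classify a batch of evidence records, excluding pure-synonymous variants.

    ``annotations`` maps variant_id to its :class:`~hbbscan.variant_effects.
    Consequence` (or any object with ``is_pure_synonymous``).  Variants whose
    sole consequence term is ``synonymous`` are marked NotEvaluated and never
    voted on; all others go through :func:`consensus`.
    """
    out = {}
    for rec in records:
        if rec.variant_id not in annotations:
            raise KeyError(f"no annotation for variant {rec.variant_id!r}")
        ann = annotations[rec.variant_id]
        if ann.is_pure_synonymous:
            out[rec.variant_id] = Verdict(value="NotEvaluated")
        else:
            out[rec.variant_id] = consensus(rec, overrides=overrides, strategy=strategy)
    return out


# ---------------------------------------------------------------------------
# TSV I/O — long format: variant_id <TAB> source <TAB> label


def write_evidence_table(records: Iterable[EvidenceRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "source", "label"])
        for rec in records:
            for src in DB_SOURCES:
                if src in rec.db_labels:
                    w.writerow([rec.variant_id, src, rec.db_labels[src]])
            for src in PREDICTOR_SOURCES:
                if src in rec.predictor_labels:
                    w.writerow([rec.variant_id, src, rec.predictor_labels[src]])


def read_evidence_table(path) -> list:
    by_variant: dict = {}
    order = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            vid, src, label = row["variant_id"], row["source"], row["label"]
            if vid not in by_variant:
                by_variant[vid] = ({}, {})
                order.append(vid)
            dbs, preds = by_variant[vid]
            if src in DB_SOURCES:
                dbs[src] = label
            elif src in PREDICTOR_SOURCES:
                preds[src] = label
            else:
                raise ValueError(f"unknown evidence source {src!r}")
    return [
        EvidenceRecord(variant_id=vid, db_labels=by_variant[vid][0], predictor_labels=by_variant[vid][1])
        for vid in order
    ]


def read_overrides(path) -> dict:
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[row["variant_id"]] = row["verdict"]
    return out


def write_verdict_table(verdicts: Mapping[str, Verdict], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variant_id", "db_call", "predictor_call", "verdict", "overridden"])
        for vid, v in verdicts.items():
            w.writerow([vid, v.db_class_call, v.predictor_class_call, v.value, str(v.overridden).lower()])
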