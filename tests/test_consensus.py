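"""Label normalization, class calls, consensus verdicts, and their invariants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from hbbscan import fixture as hbb_fixture
from hbbscan.consensus import (
    DB_SOURCES,
    PREDICTOR_SOURCES,
    EvidenceRecord,
    batch_classify,
    class_call,
    consensus,
    normalize_label,
    read_evidence_table,
    read_overrides,
)

# published Table-of-verdicts conclusions for the 16 evaluated variants
PUBLISHED_VERDICTS = {
    "rs111645889": "Conflict", "rs33971634": "Damaging", "rs33946267": "Conflict",
    "rs33958637": "Conflict", "rs281864900": "Damaging", "rs11549407": "Damaging",
    "rs1135071": "Damaging", "rs33943001": "Damaging", "rs33971440": "Damaging",
    "rs35578002": "Conflict", "rs33950507": "Damaging", "rs33986703": "Damaging",
    "rs63750783": "Damaging", "rs334": "Damaging", "rs33930165": "Damaging",
    "rs33912272": "Conflict",
}


def _record(vid="v", dbs=(), preds=()):
    return EvidenceRecord(
        variant_id=vid,
        db_labels=dict(zip(DB_SOURCES, dbs)),
        predictor_labels=dict(zip(PREDICTOR_SOURCES, preds)),
    )


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Damaging", "damaging"),
        ("Probably damaging", "damaging"),
        ("Benign", "benign"),
        ("Other", "uninformative"),
        ("not-evaluated", "absent"),
    ],
)
def test_normalize_label(raw, expected):
    assert normalize_label(raw) == expected


def test_normalize_rejects_unknown_vocabulary():
    with pytest.raises(ValueError):
        normalize_label("pathogenic-ish")


def test_class_call_majority_tie_and_nocall():
    assert class_call(["damaging", "damaging", "benign"]) == "Damaging"
    assert class_call(["uninformative", "absent"]) == "NoCall"
    assert class_call(["damaging", "benign"]) == "NoCall"
    assert class_call([]) == "NoCall"


@pytest.mark.parametrize(
    "dbs,preds,expected",
    [
        # Glu27Lys: one benign predictor is outvoted
        (("Damaging", "Damaging", "Damaging"),
         ("Benign", "Damaging", "Damaging", "Damaging", "Damaging"), "Damaging"),
        # Glu122Gln: databases say damaging, predictors say benign
        (("Damaging", "Damaging", "Benign"),
         ("Benign", "Benign", "Damaging", "Benign", "Damaging"), "Conflict"),
        # Gln40: all predictors silent, databases decide
        (("Damaging", "Damaging", "Damaging"),
         ("not-evaluated",) * 5, "Damaging"),
        (("Benign", "Benign", "Benign"), ("Benign",) * 5, "Benign"),
        (("not-evaluated",) * 3, ("not-evaluated",) * 5, "NotEvaluated"),
    ],
)
def test_consensus_examples(dbs, preds, expected):
    assert consensus(_record(dbs=dbs, preds=preds)).value == expected


def test_override_applies_and_is_flagged():
    rec = _record(vid="rs33912272",
                  dbs=("Other", "Other", "Benign"),
                  preds=("Benign", "Benign", "Benign", "not-evaluated", "Damaging"))
    assert consensus(rec).value == "Benign"
    v = consensus(rec, overrides={"rs33912272": "Conflict"})
    assert v.value == "Conflict" and v.overridden


def test_default_rule_reproduces_15_of_16_published_verdicts(hbb_annotations):
    ev = hbb_fixture.evidence_spec()
    verdicts = batch_classify(ev.records, hbb_annotations)  # no overrides
    diffs = [vid for vid, want in PUBLISHED_VERDICTS.items()
             if verdicts[vid].value != want]
    assert diffs == ["rs33912272"]
    assert verdicts["rs33912272"].value == "Benign"


def test_shipped_override_reproduces_all_16_verdicts(hbb_verdicts):
    for vid, want in PUBLISHED_VERDICTS.items():
        assert hbb_verdicts[vid].value == want, vid
    assert hbb_verdicts["rs33912272"].overridden


def test_pure_synonymous_variants_not_evaluated(hbb_verdicts, hbb_annotations):
    pure_syn = {vid for vid, c in hbb_annotations.items() if c.is_pure_synonymous}
    assert len(pure_syn) == 4
    for vid in pure_syn:
        assert hbb_verdicts[vid].value == "NotEvaluated"
    damaging = [vid for vid, v in hbb_verdicts.items() if v.value == "Damaging"]
    assert len(damaging) == 11


def test_batch_classify_empty_and_missing_annotation():
    assert batch_classify([], {}) == {}
    with pytest.raises(KeyError):
        batch_classify([_record(vid="vX")], {})


_informative = st.sampled_from(["Damaging", "Probably damaging", "Benign", "Other", "not-evaluated"])


@given(dbs=st.lists(_informative, min_size=3, max_size=3),
       preds=st.lists(_informative, min_size=5, max_size=5),
       data=st.data())
def test_verdict_invariant_under_source_permutation(dbs, preds, data):
    base = consensus(_record(dbs=dbs, preds=preds)).value
    dbs2 = data.draw(st.permutations(dbs))
    preds2 = data.draw(st.permutations(preds))
    assert consensus(_record(dbs=dbs2, preds=preds2)).value == base


@given(dbs=st.lists(_informative, min_size=3, max_size=3),
       preds=st.lists(_informative, min_size=4, max_size=4),
       filler=st.sampled_from(["Other", "not-evaluated"]))
def test_uninformative_label_never_changes_verdict(dbs, preds, filler):
    with_filler = consensus(_record(dbs=dbs, preds=list(preds) + [filler])).value
    # drop the 5th predictor entirely instead
    without = consensus(_record(dbs=dbs, preds=preds)).value
    assert with_filler == without


@given(dbs=st.lists(_informative, min_size=3, max_size=3),
       preds=st.lists(_informative, min_size=5, max_size=5))
def test_flipping_benign_predictor_to_damaging_is_monotone(dbs, preds):
    """Strengthening the damaging evidence never moves Damaging to Benign."""
    before = consensus(_record(dbs=dbs, preds=preds)).value
    for i, p in enumerate(preds):
        if p == "Benign":
            flipped = list(preds)
            flipped[i] = "Damaging"
            after = consensus(_record(dbs=dbs, preds=flipped)).value
            assert not (before == "Damaging" and after == "Benign")


def test_unanimous_strategy_flags_any_disagreement():
    rec = _record(dbs=("Damaging", "Damaging", "Damaging"),
                  preds=("Benign", "Damaging", "Damaging", "Damaging", "Damaging"))
    assert consensus(rec).value == "Damaging"
    assert consensus(rec, strategy="unanimous").value == "Conflict"


def test_evidence_table_round_trip(tmp_path):
    ev = hbb_fixture.evidence_spec()
    from hbbscan.consensus import write_evidence_table

    write_evidence_table(ev.records, tmp_path / "e.tsv")
    back = read_evidence_table(tmp_path / "e.tsv")
    assert back == list(ev.records)
    with open(tmp_path / "o.tsv", "w") as fh:
        fh.write("variant_id\tverdict\nrs33912272\tConflict\n")
    assert read_overrides(tmp_path / "o.tsv") == {"rs33912272": "Conflict"}
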