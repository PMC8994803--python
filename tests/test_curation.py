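"""Curation: structure cleanup, AC50 -> IC50 conversion, activity labeling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tposcreen as tp
from tposcreen.curation import CurationLog, TableReadResult


# ---------------------------------------------------------------------------
# salt stripping / mixtures


@pytest.mark.parametrize(
    "smiles, expected",
    [
        ("CC(=O)O.[Na+]", "CC(=O)O"),  # sodium acetate -> acetic acid parent
        ("c1ccccc1", "c1ccccc1"),
        ("Nc1ccccc1.Cl", "Nc1ccccc1"),  # aniline hydrochloride
        ("CCN.OC(=O)C(F)(F)F", "CCN"),  # TFA salt of an organic base
        ("c1ccccc1.O.O", "c1ccccc1"),  # dihydrate
    ],
)
def test_strip_salts_keeps_the_organic_parent(smiles, expected):
    from rdkit import Chem

    assert tp.strip_salts_and_mixtures(smiles) == Chem.CanonSmiles(expected)


def test_two_organic_fragments_flagged_as_mixture():
    with pytest.raises(tp.MixtureError):
        tp.strip_salts_and_mixtures("CCO.CCN")


def test_unparseable_and_inorganic_inputs_are_errors():
    with pytest.raises(tp.CurationError):
        tp.strip_salts_and_mixtures("not_a_smiles")
    with pytest.raises(tp.CurationError):
        tp.strip_salts_and_mixtures("[Na+].[Cl-]")


# ---------------------------------------------------------------------------
# deduplication


def _pair(cid, smiles, **dr):
    return tp.CompoundRecord(id=cid, smiles=smiles), tp.DoseResponse(**dr)


def test_deduplicate_prefers_complete_curve_data_then_low_ac50():
    records = [
        _pair("1", "c1ccccc1O", max_inhibition=60.0),
        _pair("2", "Oc1ccccc1", max_inhibition=60.0, ac50=5.0, a_min_response=10.0,
              b_max_response=100.0, c_slope=1.0),
        _pair("3", "CCO", ac50=9.0),
        _pair("4", "OCC", ac50=2.0),
        _pair("5", "CC", max_inhibition=5.0),
    ]
    kept, removed = tp.deduplicate(records)
    assert removed == 2
    ids = [rec.id for rec, _ in kept]
    assert ids == ["2", "4", "5"]  # completeness wins for phenol, low AC50 for ethanol


def test_deduplicate_identity_and_idempotence(small_library):
    _, activity, _ = small_library
    records = [
        _pair(r.id, r.smiles, max_inhibition=r.max_inhibition)
        for r in activity.itertuples()
    ]
    once, removed = tp.deduplicate(records)
    assert removed == 0
    twice, removed2 = tp.deduplicate(once)
    assert removed2 == 0
    assert [r.id for r, _ in twice] == [r.id for r, _ in once]


# ---------------------------------------------------------------------------
# Eq.-style AC50 -> IC50 conversion


def test_full_range_curve_conversion_is_identity_in_both_modes():
    for mode in ("log", "linear"):
        assert tp.convert_ac50_to_ic50(5.0, a=0, b=100, c=1, mode=mode) == pytest.approx(5.0)


def test_partial_curve_conversion_hand_value():
    # factor = (20 - 50) / (50 - 100) = 0.6; log mode: 10 ** (log10(5) * 0.6)
    assert tp.convert_ac50_to_ic50(5.0, a=20, b=100, c=1) == pytest.approx(2.6265, abs=5e-4)
    assert tp.convert_ac50_to_ic50(5.0, a=20, b=100, c=1, mode="linear") == pytest.approx(3.0)


def test_curve_that_never_reaches_half_inhibition_is_not_convertible():
    with pytest.raises(tp.NotConvertibleError):
        tp.convert_ac50_to_ic50(5.0, a=60, b=100, c=1)
    with pytest.raises(ValueError):
        tp.convert_ac50_to_ic50(5.0, a=20, b=40, c=1)  # invalid top plateau


@settings(max_examples=200, derandomize=True)
@given(
    ac50=st.floats(1e-3, 1e3),
    a=st.floats(0, 40.0),
    b=st.floats(60.0, 120),
    c=st.floats(0.5, 3),
    mode=st.sampled_from(["log", "linear"]),
)
def test_conversion_round_trip(ac50, a, b, c, mode):
    ic50 = tp.convert_ac50_to_ic50(ac50, a, b, c, mode=mode)
    back = tp.invert_ic50_to_ac50(ic50, a, b, c, mode=mode)
    assert back == pytest.approx(ac50, rel=1e-9)


# ---------------------------------------------------------------------------
# activity labels


@pytest.mark.parametrize(
    "max_inh, ic50, expected",
    [
        (15, None, ("C", "C", "C")),
        (19.999, None, ("C", "C", "C")),
        (20, None, ("A", "B", "B")),
        (35, None, ("A", "B", "B")),
        (50, None, ("A", "B", "B")),
        (80, 2, ("A", "A", "A1")),
        (80, 10, ("A", "A", "A1")),  # the 10 uM cutoff is inclusive
        (80, 50, ("A", "A", "A2")),
    ],
)
def test_label_boundaries(max_inh, ic50, expected):
    labels = tp.assign_labels(tp.DoseResponse(max_inhibition=max_inh, ic50=ic50))
    assert (labels.binary, labels.ternary, labels.quaternary) == expected


def test_labels_consistent_over_exhaustive_grid():
    for mi in range(101):
        for ic50 in (0.1, 10.0, 10.1, 1000.0):
            labels = tp.assign_labels(tp.DoseResponse(max_inhibition=float(mi), ic50=ic50))
            # the ActivityLabelSet constructor enforces the consistency
            # invariants; spot-check the defining cutoffs too
            assert (labels.binary == "A") == (mi >= 20)
            assert (labels.ternary == "A") == (mi > 50)


def test_missing_ic50_for_strong_inhibitor_is_an_error():
    with pytest.raises(ValueError):
        tp.assign_labels(tp.DoseResponse(max_inhibition=80.0))


def test_inconsistent_label_set_rejected():
    with pytest.raises(ValueError):
        tp.ActivityLabelSet(binary="C", ternary="A", quaternary="A1")


# ---------------------------------------------------------------------------
# table reading and the full pipeline


def test_read_activity_table(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(
        "id,smiles,max_inhibition,a,b,c,ac50,extra\n"
        "1,Nc1ccccc1,80,20,100,1,5,x\n"
        "2,not_a_smiles,10,,,,,y\n"
        "3,CCO,,70,100,1,,z\n"
    )
    result = tp.read_activity_table(path)
    assert len(result) == 2
    assert len(result.errors) == 1 and "row 3" in result.errors[0]
    rec, dr = result.records[0]
    assert (rec.id, dr.ac50, dr.max_inhibition) == ("1", 5.0, 80.0)
    # max inhibition derived from the bottom plateau when absent
    assert result.records[1][1].max_inhibition == pytest.approx(30.0)
    assert list(result.extras.columns) == ["extra"]


def test_read_header_only_file(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("id,smiles,max_inhibition\n")
    assert len(tp.read_activity_table(path)) == 0


def test_read_missing_mandatory_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("id,smiles\n1,CCO\n")
    with pytest.raises(ValueError):
        tp.read_activity_table(path)


def test_curate_table_end_to_end(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(
        "id,smiles,max_inhibition,a,b,c,ac50\n"
        "1,Nc1ccccc1.Cl,80,20,100,1,5\n"  # salt; converts
        "2,CCO.CCN,10,,,,\n"  # mixture; dropped
        "3,Oc1ccccc1,35,,,,\n"  # moderate; no conversion needed
        "4,Nc1ccccc1,80,20,100,1,5\n"  # duplicate of 1 after desalting
    )
    df, log = tp.curate_table(path)
    assert list(df["id"]) == ["1", "3"]
    assert log.mixtures == ["2"] and log.n_duplicates_removed == 1 and log.desalted == ["1"]
    row = df.set_index("id").loc["1"]
    assert row["ic50_converted"] == pytest.approx(2.6265, abs=5e-4)
    assert (row["binary"], row["ternary"], row["quaternary"]) == ("A", "A", "A1")
    assert df.set_index("id").loc["3", "quaternary"] == "B"


def test_curation_is_idempotent(small_activity_csv, tmp_path):
    df1, _ = tp.curate_table(small_activity_csv)
    path2 = tmp_path / "again.csv"
    df1.to_csv(path2, index=False)
    df2, log2 = tp.curate_table(path2)
    assert log2.n_duplicates_removed == 0 and not log2.mixtures
    assert list(df1["smiles"]) == list(df2["smiles"])
    assert list(df1["quaternary"]) == list(df2["quaternary"])
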