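import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hehrisk.karyotype import (
    AUTOSOMES,
    CHROMOSOMES,
    MASKED_HYPODIPLOID_SUSPECT,
    MODAL_RANGE,
    UNPARSEABLE_TOKENS,
    Karyotype,
    KaryotypeParseError,
    gains_table,
    modal_category,
    parse_iscn,
    screen_cohort,
    sort_labels,
    to_iscn,
)


@pytest.mark.parametrize(
    "text, modal, gains, losses, structural",
    [
        (
            "55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+X",
            (55, 55),
            ("4", "6", "10", "14", "17", "18", "21", "21", "X"),
            (),
            False,
        ),
        ("46,XY", (46, 46), (), (), False),
        ("47,XX,+21", (47, 47), ("21",), (), False),
        ("45,XY,-7", (45, 45), (), ("7",), False),
        # structural tokens set the flag but are not gains/losses
        (
            "56,XY,+4,+6,+10,+14,+17,+18,+21,+21,+X,t(9;22)(q34;q11)",
            (56, 56),
            ("4", "6", "10", "14", "17", "18", "21", "21", "X"),
            (),
            True,
        ),
        # supernumerary sex chromosome inside the sex field
        ("56,XXY,+4,+6,+8,+10,+14,+17,+18,+21,+21", (56, 56),
         ("4", "6", "8", "10", "14", "17", "18", "21", "21", "X"), (), False),
        # cell counts stripped, sub-clones ignored
        ("55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+X[12]/46,XY[8]", (55, 55),
         ("4", "6", "10", "14", "17", "18", "21", "21", "X"), (), False),
    ],
)
def test_parse_iscn_examples(text, modal, gains, losses, structural):
    k = parse_iscn(text)
    assert (k.modal_low, k.modal_high) == modal
    assert k.gains == gains
    assert k.losses == losses
    assert k.has_structural == structural


def test_parse_modal_range_sets_flag():
    k = parse_iscn("51-53,XX,+4,+10,+17,+18,+21")
    assert (k.modal_low, k.modal_high) == (51, 53)
    assert MODAL_RANGE in k.flags
    assert not k.modal_unambiguous


@pytest.mark.parametrize("bad", ["XY,+4", "abc,XX", "", "   "])
def test_parse_errors_on_bad_modal_prefix(bad):
    with pytest.raises(KaryotypeParseError):
        parse_iscn(bad)


def test_unknown_tokens_flagged_not_fatal():
    k = parse_iscn("55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+X,foo?,+99")
    assert UNPARSEABLE_TOKENS in k.flags
    assert set(k.unknown_tokens) == {"foo?", "+99"}
    assert "99" not in k.gains


def test_masked_hypodiploid_doubled_clone_flagged():
    # a doubled 27-chromosome near-haploid clone: every gain tetrasomic
    k = parse_iscn("54,XX,+4,+4,+10,+10,+14,+14,+21,+21")
    assert MASKED_HYPODIPLOID_SUSPECT in k.flags
    # ordinary HeH with a single tetrasomy 21 is untouched
    k2 = parse_iscn("55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+X")
    assert MASKED_HYPODIPLOID_SUSPECT not in k2.flags


@pytest.mark.parametrize(
    "modal, expected",
    [
        ((55, 55), "54-57"),
        ((51, 51), "51-53"),
        ((53, 53), "51-53"),
        ((58, 58), "58-65"),
        ((65, 65), "58-65"),
        ((53, 55), "unclassifiable"),
        ((66, 67), "unclassifiable"),
        ((46, 46), "not_heh"),
        ((50, 50), "not_heh"),
        ((68, 70), "not_heh"),
        ((50, 51), "unclassifiable"),
    ],
)
def test_modal_category(modal, expected):
    k = Karyotype(raw_string="", modal_low=modal[0], modal_high=modal[1])
    assert modal_category(k) == expected


def test_screen_cohort_exclusions_and_partition():
    heh = parse_iscn("55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+X")
    fusion = parse_iscn("52,XX,+10,+14,+17,+18,+21,+21")
    masked = parse_iscn("54,XX,+4,+4,+10,+10,+14,+14,+21,+21")
    diploid = parse_iscn("46,XY")
    records = [(heh, None), (fusion, "ETV6-RUNX1"), (masked, None), (diploid, None)]
    res = screen_cohort(records)
    assert [k.raw_string for k in res.included] == [heh.raw_string]
    reasons = [r for _, r in res.excluded]
    assert reasons == ["fusion", "masked_hypodiploidy", "not_heh"]
    assert len(res.included) + len(res.excluded) == len(records)

    empty = screen_cohort([])
    assert empty.included == [] and empty.excluded == []


def test_gains_table_schema():
    karys = [parse_iscn("55,XY,+4,+6,+10,+14,+17,+18,+21,+21,+X")]
    tab = gains_table(karys, ids=["p1"])
    gain_cols = [c for c in tab.columns if c.startswith("gain_")]
    assert len(gain_cols) == 24
    assert tab.loc[0, "gain_4"] == 1 and tab.loc[0, "gain_5"] == 0
    assert tab.loc[0, "gain_X"] == 1 and tab.loc[0, "modal_low"] == 55


_label = st.sampled_from(CHROMOSOMES)


@settings(derandomize=True, max_examples=60)
@given(
    gains=st.lists(_label, max_size=8),
    losses=st.sets(st.sampled_from(sorted(AUTOSOMES)), max_size=3),
    sex=st.sampled_from(["XX", "XY"]),
)
def test_roundtrip_and_modal_arithmetic(gains, losses, sex):
    """Serialising and re-parsing a numeric karyotype is the identity, and
    the chromosome count arithmetic holds exactly."""
    gains = [g for g in gains if g not in losses]
    modal = 46 + len(gains) - len(losses)
    if modal < 1:
        return
    k = Karyotype(
        raw_string="",
        modal_low=modal,
        modal_high=modal,
        gains=sort_labels(gains),
        losses=sort_labels(losses),
        sex_field=sex,
    )
    back = parse_iscn(to_iscn(k))
    assert back.gains == k.gains
    assert back.losses == k.losses
    assert (back.modal_low, back.modal_high) == (modal, modal)
    assert not back.unknown_tokens
    # modal arithmetic invariant for fully numeric karyotypes
    assert back.modal_low == 46 + len(back.gains) - len(back.losses)
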