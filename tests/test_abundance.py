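"""Accounting arithmetic, the fold-change contaminant filter, and the
control-similarity flag."""

import pytest
from hypothesis import given, settings, strategies as st

from contamcheck.abundance import (AccountingRow, ControlFilterParams,
                                   control_filter, control_similarity_flag,
                                   percent)
from contamcheck.errors import ConfigurationError


# printed accounting-table cells: (numerator, denominator, percent)
PRINTED_CELLS = [
    (48_122, 167_841, 28.7),            # specimen DNA spike-in phage
    (7_504_441, 94_721_122, 7.9),       # specimen DNA low-quality removed
    (6_741_078, 7_228_089, 93.3),       # specimen RNA host of retained
    (87_724, 669_239, 13.1),            # specimen DNA phage of filtered
    (391_563, 1_102_827, 35.5),         # specimen RNA E. coli of filtered
    (89_478, 122_706, 72.9),            # specimen DNA phage of filtered
    (74_205_991, 77_298_225, 96.0),     # positive-control DNA E. coli
    (321_548, 1_573_515, 20.4),         # negative-control DNA human
]


@pytest.mark.parametrize("num,den,expected", PRINTED_CELLS)
def test_percent_reproduces_printed_cells(num, den, expected):
    assert percent(num, den) == expected


def test_percent_zero_denominator_warns_and_returns_zero():
    with pytest.warns(UserWarning):
        assert percent(5, 0) == 0.0
    assert percent(0, 1000) == 0.0


def test_percent_rejects_negative_counts():
    with pytest.raises(ValueError):
        percent(-1, 10)


@given(st.integers(0, 10**6), st.integers(1, 10**6), st.integers(1, 1000))
@settings(max_examples=100, derandomize=True, deadline=None)
def test_percent_is_scale_invariant(num, den, k):
    assert percent(num, den) == percent(num * k, den * k)


def test_accounting_row_percentages_use_dual_denominators():
    # retained = raw - removed; host over retained; taxa over host-filtered
    row = AccountingRow("C1_RNA", "RNA", raw_reads=8_554_736,
                        removed_reads=1_326_647, host_mapped=6_741_078,
                        taxon_counts={"phage": 23_255},
                        unassigned=487_011 - 23_255)
    assert row.retained_reads == 7_228_089
    assert row.host_percent == 93.3
    assert row.filtered_reads == 487_011
    assert row.taxon_percent("phage") == 4.8


def test_accounting_row_enforces_partition():
    with pytest.raises(ValueError):
        AccountingRow("s", "DNA", 100, 10, 50, {"t": 100}, unassigned=0)
    with pytest.raises(ValueError):
        AccountingRow("s", "DNA", 100, 10, 95, {}, unassigned=0)


def test_fold_threshold_boundary_is_strict():
    # log2 threshold of 2 means strictly more than 4-fold is kept
    verdicts = control_filter({"t": 4.0}, {"t": 1.0})
    assert not verdicts[0].kept
    kept = control_filter({"t": 5.0}, {"t": 1.0})
    assert kept[0].kept
    equal = control_filter({"t": 2.0}, {"t": 2.0})
    assert not equal[0].kept


def test_log2_threshold_two_equals_fourfold_rule():
    assert 2.0 ** ControlFilterParams().log2_fold_threshold == 4.0


def test_pseudocount_guards_zero_control():
    # control saw nothing; 1-read pseudocount on a 1000-read denominator
    verdicts = control_filter({"t": 5.0}, {"t": 0.0},
                              mean_denominator=1000, control_denominator=1000)
    assert verdicts[0].kept
    barely = control_filter({"t": 0.2}, {"t": 0.0},
                            mean_denominator=1000, control_denominator=1000)
    assert not barely[0].kept  # (0.2+0.1)/(0+0.1) = 3-fold < 4


def test_filter_monotone_in_threshold():
    mean = {"a": 10.0, "b": 4.5, "c": 0.5}
    ctrl = {"a": 1.0, "b": 1.0, "c": 1.0}
    kept_loose = {v.taxon for v in control_filter(mean, ctrl, ControlFilterParams(2.0))
                  if v.kept}
    kept_tight = {v.taxon for v in control_filter(mean, ctrl, ControlFilterParams(3.0))
                  if v.kept}
    assert kept_tight <= kept_loose


def test_filter_rejects_mismatched_taxon_sets():
    with pytest.raises(ConfigurationError):
        control_filter({"a": 1.0}, {"b": 1.0})


def test_sample_identical_to_control_is_flagged():
    control = {"x": 10.0, "y": 5.0}
    verdicts = control_similarity_flag({"s": dict(control)}, control)
    assert verdicts[0].flagged
    assert verdicts[0].supporting_taxa == ["x", "y"]


def test_sample_with_taxon_far_above_control_is_not_flagged():
    verdicts = control_similarity_flag({"s": {"x": 100.0, "y": 1.0}},
                                       {"x": 1.0, "y": 5.0})
    assert not verdicts[0].flagged
    assert verdicts[0].offending_taxa == ["x"]


def test_empty_profile_flagged_with_annotation():
    verdicts = control_similarity_flag({"s": {}}, {"x": 1.0})
    assert verdicts[0].flagged and verdicts[0].note == "no signal above control"


def test_missing_negative_control_raises():
    with pytest.raises(ConfigurationError):
        control_similarity_flag({"s": {"x": 1.0}}, None)
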