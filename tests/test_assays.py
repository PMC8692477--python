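"""Viability, ddCt, DEG filtering, GO tallies and group comparisons,
each checked against an independent brute-force computation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cellspray.assays import (
    absorbance_summary,
    deg_filter,
    delta_delta_ct,
    go_term_summary,
    group_compare,
    two_way_anova,
    viability_percent,
)


# -------------------------------------------------------------- viability


def test_viability_identity_and_homogeneity():
    control = [0.5, 0.6, 0.7]
    assert viability_percent(control, control) == pytest.approx(100.0)
    sample = [0.9 * v for v in control]
    assert viability_percent(sample, control) == pytest.approx(90.0)


def test_viability_matches_brute_force():
    rng = np.random.default_rng(21)
    for _ in range(20):
        sample = rng.uniform(0.1, 2.0, size=rng.integers(1, 8))
        control = rng.uniform(0.1, 2.0, size=rng.integers(1, 8))
        expected = 100.0 * (sum(sample) / len(sample)) / (sum(control) / len(control))
        assert viability_percent(sample, control) == pytest.approx(
            expected, rel=1e-12
        )


def test_viability_scale_invariant():
    sample, control = [0.4, 0.5], [0.6, 0.8]
    base = viability_percent(sample, control)
    scaled = viability_percent([7 * v for v in sample], [7 * v for v in control])
    assert scaled == pytest.approx(base, rel=1e-12)


def test_viability_errors():
    with pytest.raises(ValueError, match="non-empty"):
        viability_percent([], [0.5])
    with pytest.raises(ValueError, match="control mean"):
        viability_percent([0.5], [0.0])


# ------------------------------------------------------------------- ddCt


def _ct_table(rows):
    return pd.DataFrame(rows, columns=["sample", "gene", "ct"])


def test_ddct_trivial_folds():
    table = _ct_table([
        ("ctrl", "GAPDH", 18.0), ("ctrl", "ACAN", 26.0),
        ("trt", "GAPDH", 18.0), ("trt", "ACAN", 26.0),
    ])
    assert delta_delta_ct(table, "ACAN", "trt", "ctrl") == pytest.approx(1.0)
    table.loc[3, "ct"] = 23.0  # ddCt = -3 -> fold 8
    assert delta_delta_ct(table, "ACAN", "trt", "ctrl") == pytest.approx(8.0)


def test_ddct_matches_brute_force_and_inverts_on_swap():
    rng = np.random.default_rng(22)
    for _ in range(20):
        cts = rng.uniform(15, 35, size=4)
        table = _ct_table([
            ("ctrl", "GAPDH", cts[0]), ("ctrl", "G1", cts[1]),
            ("trt", "GAPDH", cts[2]), ("trt", "G1", cts[3]),
        ])
        ddct = (cts[3] - cts[2]) - (cts[1] - cts[0])
        expected = 2.0**-ddct
        fold = delta_delta_ct(table, "G1", "trt", "ctrl")
        assert fold == pytest.approx(expected, rel=1e-12)
        swapped = delta_delta_ct(table, "G1", "ctrl", "trt")
        assert swapped == pytest.approx(1.0 / fold, rel=1e-12)


def test_ddct_missing_cell_named():
    table = _ct_table([("ctrl", "GAPDH", 18.0), ("trt", "GAPDH", 18.0),
                       ("trt", "ACAN", 24.0)])
    with pytest.raises(ValueError, match="sample='ctrl', gene='ACAN'"):
        delta_delta_ct(table, "ACAN", "trt", "ctrl")


# ------------------------------------------------------------- DEG filter


def _deg_table(rows):
    return pd.DataFrame(rows, columns=["gene", "fold_change", "p_value"])


def test_deg_filter_boundaries():
    table = _deg_table([
        ("ACAN", 8.7, 0.01),       # clearly up
        ("G_LOW", 1.4, 0.001),     # below FC threshold despite tiny p
        ("G_EDGE", 1.5, 0.01),     # boundary fold: included (>= rule)
        ("G_P", 2.0, 0.05),        # boundary p: excluded (strict <)
        ("G_DN", 0.5, 0.02),       # down
    ])
    up, down = deg_filter(table)
    assert up == {"ACAN", "G_EDGE"}
    assert down == {"G_DN"}


def test_deg_filter_matches_brute_force_scan():
    rng = np.random.default_rng(23)
    table = _deg_table([
        (f"G{k}", 2.0 ** rng.normal(0, 1.5), rng.uniform(0, 1))
        for k in range(1000)
    ])
    up, down = deg_filter(table)
    brute_up, brute_down = set(), set()
    for _, row in table.iterrows():
        if row.p_value < 0.05:
            if row.fold_change >= 1.5:
                brute_up.add(row.gene)
            elif row.fold_change <= 1 / 1.5:
                brute_down.add(row.gene)
    assert up == brute_up and down == brute_down
    assert not (up & down)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    fc_thr=st.floats(1.0, 4.0),
    p_thr=st.floats(0.001, 0.2),
)
def test_deg_filter_monotone_in_thresholds(fc_thr, p_thr):
    rng = np.random.default_rng(24)
    table = _deg_table([
        (f"G{k}", 2.0 ** rng.normal(0, 1.5), rng.uniform(0, 1))
        for k in range(300)
    ])
    up, down = deg_filter(table, fc_thr, p_thr)
    up2, down2 = deg_filter(table, fc_thr + 0.5, p_thr / 2)
    assert up2 <= up and down2 <= down


def test_deg_filter_rejects_nonpositive_folds():
    with pytest.raises(ValueError, match="ratio scale"):
        deg_filter(_deg_table([("G", -1.0, 0.01)]))


# --------------------------------------------------------------- GO tally


def test_go_summary_partition_and_planted_tally():
    rows = [(f"UP{k}", 4.0, 0.001) for k in range(17)]
    rows += [(f"DN{k}", 0.4, 0.001) for k in range(3)]
    rows += [(f"NULL{k}", 1.0, 0.9) for k in range(100)]
    table = _deg_table(rows)
    members = [g for g, _, _ in rows[:20]]
    summary = go_term_summary(table, "CHONDROCYTE_DEVELOPMENT", members)
    assert (summary.n_up, summary.n_down, summary.n_unchanged) == (17, 3, 0)
    assert summary.n_up + summary.n_down + summary.n_unchanged == summary.n_members


def test_go_summary_absent_members_warn_as_unchanged():
    table = _deg_table([("G1", 2.0, 0.01)])
    with pytest.warns(UserWarning, match="absent"):
        summary = go_term_summary(table, "TERM", ["G1", "MISSING1", "MISSING2"])
    assert summary.n_up == 1
    assert summary.n_unchanged == 2


def test_go_summary_random_matches_brute_force():
    rng = np.random.default_rng(25)
    table = _deg_table([
        (f"G{k}", 2.0 ** rng.normal(0, 1.5), rng.uniform(0, 1))
        for k in range(200)
    ])
    members = [f"G{k}" for k in rng.choice(200, size=30, replace=False)]
    up, down = deg_filter(table)
    summary = go_term_summary(table, "T", members)
    assert summary.n_up == len(set(members) & up)
    assert summary.n_down == len(set(members) & down)


# ------------------------------------------------------------- absorbance


def test_absorbance_summary_ratios():
    table = pd.DataFrame({
        "group": ["control"] * 3 + ["treated"] * 3,
        "replicate": [1, 2, 3] * 2,
        "od": [0.2, 0.2, 0.2, 0.4, 0.4, 0.4],
    })
    out = absorbance_summary(table).set_index("group")
    assert out.loc["treated", "ratio_to_control"] == pytest.approx(2.0)
    assert out.loc["control", "ratio_to_control"] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="control"):
        absorbance_summary(table, control_group="nope")


# ---------------------------------------------------------- group compare


def test_identical_groups_not_significant():
    result = group_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
    assert result.p_value == pytest.approx(1.0)
    assert not result.significant


def test_separated_groups_significant():
    rng = np.random.default_rng(26)
    result = group_compare(
        {"a": rng.normal(0, 1, 10), "b": rng.normal(5, 1, 10)}
    )
    assert result.significant and result.p_value < 1e-4


def test_anova_with_tukey():
    rng = np.random.default_rng(27)
    groups = {
        "a": rng.normal(0, 1, 8),
        "b": rng.normal(0, 1, 8),
        "c": rng.normal(4, 1, 8),
    }
    result = group_compare(groups, design="anova", posthoc="tukey")
    assert result.significant
    assert result.posthoc is not None and len(result.posthoc) == 3


def test_anova_null_pvalues_roughly_uniform():
    """Equal-mean groups: the ANOVA p-value is U(0,1) under resampling."""
    rng = np.random.default_rng(28)
    pvals = [
        group_compare(
            {k: rng.normal(0, 1, 6) for k in "abc"}, design="anova"
        ).p_value
        for _ in range(200)
    ]
    # KS distance to uniform stays modest at 200 replicates
    from scipy import stats

    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_group_compare_errors():
    with pytest.raises(ValueError, match="two groups"):
        group_compare({"a": [1, 2]})
    with pytest.raises(ValueError, match="fewer than 2"):
        group_compare({"a": [1, 2], "b": [1]})
    with pytest.raises(ValueError, match="t-test requires"):
        group_compare({"a": [1, 2], "b": [1, 2], "c": [1, 2]}, design="t-test")


def test_two_way_anova_detects_main_effect():
    rng = np.random.default_rng(29)
    rows = []
    for potential in ("10kV", "15kV"):
        for day in ("d7", "d14"):
            shift = 3.0 if potential == "15kV" else 0.0
            for value in rng.normal(shift, 1, 6):
                rows.append({"value": value, "potential": potential, "day": day})
    table = two_way_anova(pd.DataFrame(rows), "value", "potential", "day")
    assert table.loc["C(potential)", "PR(>F)"] < 1e-4
    assert {"C(potential)", "C(day)", "C(potential):C(day)"} <= set(table.index)
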