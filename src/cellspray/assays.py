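"""Downstream assay quantification: LDH viability, ddCt expression, DEG
filtering, GO tallies, absorbance summaries and group comparisons.

Table schemas (CSV-friendly, column names fixed):

* OD table — ``group``, ``replicate``, ``od`` (+ optional ``wavelength_nm``
  metadata, never used in computation).
* Ct table — ``sample``, ``gene``, ``ct``; a reference gene (default GAPDH)
  must be present for every sample.
* DEG table — ``gene``, ``fold_change`` (ratio scale, < 1 means down),
  ``p_value``.

Conventions: a differentially expressed gene satisfies |fold change| > 1.5
read symmetrically on the ratio scale (fold >= 1.5 up, fold <= 1/1.5 down;
boundary inclusive on the fold threshold) with strict p < 0.05. Group
comparisons are thin wrappers over standard tests (t-test, one/two-way
ANOVA, Tukey HSD) included for pipeline completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

OD_COLUMNS = ("group", "replicate", "od")
CT_COLUMNS = ("sample", "gene", "ct")
DEG_COLUMNS = ("gene", "fold_change", "p_value")


def _check_columns(table: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = set(required) - set(table.columns)
    if missing:
        raise ValueError(f"{name} is missing columns: {sorted(missing)}")


def viability_percent(
    sample_ods: Sequence[float], control_ods: Sequence[float]
) -> float:
    """LDH viability: 100 x mean(sample OD) / mean(control OD)."""
    sample = np.asarray(sample_ods, dtype=float)
    control = np.asarray(control_ods, dtype=float)
    if sample.size == 0 or control.size == 0:
        raise ValueError("sample and control OD lists must be non-empty")
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError("control mean OD must be > 0")
    return 100.0 * sample.mean() / control_mean


def delta_delta_ct(
    table: pd.DataFrame,
    target_gene: str,
    treated_sample: str,
    calibrator_sample: str,
    reference_gene: str = "GAPDH",
) -> float:
    """Relative expression by the ddCt method: fold change = 2**(-ddCt).

    dCt = Ct(target) - Ct(reference) within each sample; ddCt is treated
    minus calibrator. A missing Ct raises an error naming the cell.
    """
    _check_columns(table, CT_COLUMNS, "Ct table")

    def ct(sample: str, gene: str) -> float:
        rows = table[(table["sample"] == sample) & (table["gene"] == gene)]
        if len(rows) == 0:
            raise ValueError(f"missing Ct value for sample={sample!r}, gene={gene!r}")
        value = float(rows["ct"].mean())
        if not np.isfinite(value):
            raise ValueError(f"non-finite Ct for sample={sample!r}, gene={gene!r}")
        return value

    dct_treated = ct(treated_sample, target_gene) - ct(treated_sample, reference_gene)
    dct_calib = ct(calibrator_sample, target_gene) - ct(
        calibrator_sample, reference_gene
    )
    return float(2.0 ** -(dct_treated - dct_calib))


def deg_filter(
    table: pd.DataFrame,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Split a DEG table into (upregulated, downregulated) gene sets.

    Up: fold_change >= fc_threshold and p < p_threshold.
    Down: fold_change <= 1/fc_threshold and p < p_threshold.
    """
    _check_columns(table, DEG_COLUMNS, "DEG table")
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1 (ratio-scale magnitude)")
    fc = table["fold_change"].to_numpy(dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold_change must be > 0 (ratio scale)")
    p = table["p_value"].to_numpy(dtype=float)
    sig = p < p_threshold
    up = set(table.loc[sig & (fc >= fc_threshold), "gene"])
    down = set(table.loc[sig & (fc <= 1.0 / fc_threshold), "gene"])
    return up, down


@dataclass(frozen=True)
class GoSummary:
    """Regulation tally of one gene-ontology term's member genes."""

    term: str
    n_members: int
    n_up: int
    n_down: int
    n_unchanged: int


def go_term_summary(
    table: pd.DataFrame,
    term: str,
    members: Sequence[str],
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> GoSummary:
    """Tally a term's member genes by their DEG-filter outcome.

    Members absent from the table count as unchanged (with a warning).
    """
    members = list(members)
    if not members:
        raise ValueError("term member list must be non-empty")
    up, down = deg_filter(table, fc_threshold, p_threshold)
    present = set(table["gene"])
    absent = [g for g in members if g not in present]
    if absent:
        warnings.warn(
            f"{len(absent)} member gene(s) of {term!r} absent from the DEG "
            f"table, counted as unchanged: {sorted(absent)[:5]}...",
            stacklevel=2,
        )
    n_up = sum(g in up for g in members)
    n_down = sum(g in down for g in members)
    return GoSummary(
        term=term,
        n_members=len(members),
        n_up=n_up,
        n_down=n_down,
        n_unchanged=len(members) - n_up - n_down,
    )


def absorbance_summary(
    table: pd.DataFrame, control_group: str = "control"
) -> pd.DataFrame:
    """Per-group OD mean +/- sd and the ratio of each mean to the control mean."""
    _check_columns(table, OD_COLUMNS, "OD table")
    groups = set(table["group"])
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not present in table")
    out = (
        table.groupby("group")["od"]
        .agg(n="count", mean_od="mean", sd_od=lambda s: s.std(ddof=1))
        .reset_index()
    )
    control_mean = float(out.loc[out["group"] == control_group, "mean_od"].iloc[0])
    out["ratio_to_control"] = out["mean_od"] / control_mean
    return out


@dataclass
class GroupComparison:
    design: str
    statistic: float
    p_value: float
    significant: bool  # at the study's p <= 0.05 criterion
    posthoc: pd.DataFrame | None = None


def group_compare(
    values_by_group: Mapping[str, Sequence[float]],
    design: str = "t-test",
    posthoc: str | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Standard group comparison: unpaired two-tailed t-test or one-way ANOVA,
    with optional Tukey HSD post-hoc."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")

    if design == "t-test":
        if len(arrays) != 2:
            raise ValueError("t-test requires exactly two groups")
        a, b = arrays.values()
        res = stats.ttest_ind(a, b)
    elif design == "anova":
        res = stats.f_oneway(*arrays.values())
    else:
        raise ValueError(f"unknown design {design!r} (use 't-test' or 'anova')")

    posthoc_table = None
    if posthoc == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate(list(arrays.values()))
        labels = np.concatenate(
            [np.full(arr.size, name) for name, arr in arrays.items()]
        )
        tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
        posthoc_table = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    elif posthoc is not None:
        raise ValueError(f"unknown posthoc {posthoc!r} (use 'tukey')")

    p = float(res.pvalue)
    return GroupComparison(
        design=design,
        statistic=float(res.statistic),
        p_value=p,
        significant=bool(p <= alpha),
        posthoc=posthoc_table,
    )


def two_way_anova(
    table: pd.DataFrame,
    value: str,
    factor_a: str,
    factor_b: str,
    interaction: bool = True,
) -> pd.DataFrame:
    """Two-way ANOVA table (type II) via an OLS fit."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    for col in (value, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
    op = "*" if interaction else "+"
    model = ols(f"{value} ~ C({factor_a}) {op} C({factor_b})", data=table).fit()
    return sm.stats.anova_lm(model, typ=2)
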