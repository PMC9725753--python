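"""Group-level statistics and proteomics enrichment reporting.

Per-cell metrics are compared across conditions the way the imaging field
reports them: one-way ANOVA with Tukey's HSD post hoc when more than two
conditions are compared, two-tailed Student's t tests for two, violin-plot
summaries (median and quartiles), and significance stars. A small helper
ranks proteins by WT/mutant enrichment from label-free quantitation (LFQ)
intensity tables averaged over technical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

#: Star convention: ns, **p<0.01, ***p<0.001, ****p<0.0001.
STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"))


def significance_stars(p: float) -> str:
    """Star annotation as a pure function of the p-value."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value out of range: {p}")
    for thr, stars in STAR_THRESHOLDS:
        if p < thr:
            return stars
    return "ns"


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    stars: str
    pairwise: pd.DataFrame | None = None  # ANOVA+Tukey: adjusted p per pair

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError(f"p-value out of range: {self.p_value}")


GroupTable = dict[str, "np.ndarray | list[float]"]


def _clean_groups(groups: GroupTable) -> dict[str, np.ndarray]:
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        out[name] = arr
    return out


def anova_tukey(groups: GroupTable) -> StatResult:
    """One-way ANOVA with Tukey's HSD pairwise comparisons.

    Returns the omnibus F and p plus a table of Tukey-adjusted p-values
    (studentized-range distribution) for every condition pair. Data with
    zero total variance return F = 0, p = 1 by convention.
    """
    g = _clean_groups(groups)
    if len(g) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    if sum(len(v) for v in g.values()) < 3:
        raise ValueError("ANOVA requires at least 3 observations")
    names = list(g)
    values = [g[n] for n in names]
    allv = np.concatenate(values)
    if np.allclose(allv, allv[0]):
        pairs = pd.DataFrame(
            [(a, b, 1.0) for i, a in enumerate(names) for b in names[i + 1:]],
            columns=["group_a", "group_b", "p_adj"],
        )
        return StatResult(test="anova_tukey", statistic=0.0, p_value=1.0,
                          stars="ns", pairwise=pairs)
    F, p = sps.f_oneway(*values)
    tk = sps.tukey_hsd(*values)
    rows = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            rows.append((a, names[j], float(tk.pvalue[i, j])))
    pairs = pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj"])
    pairs["stars"] = pairs["p_adj"].map(significance_stars)
    return StatResult(test="anova_tukey", statistic=float(F), p_value=float(p),
                      stars=significance_stars(float(p)), pairwise=pairs)


def t_test_two_tailed(a, b, equal_var: bool = True) -> StatResult:
    """Two-tailed two-sample t test (Student by default; Welch optional)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if np.allclose(np.concatenate([a, b]), a[0]):
        return StatResult(test="t_two_tailed", statistic=0.0, p_value=1.0, stars="ns")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatResult(test="t_two_tailed", statistic=float(t), p_value=float(p),
                      stars=significance_stars(float(p)))


def summarize_groups(groups: GroupTable) -> pd.DataFrame:
    """Violin-plot summary: n, median, Q1, Q3 per condition.

    Quartiles use the linear-interpolation convention (numpy default).
    """
    g = _clean_groups(groups)
    rows = []
    for name, vals in g.items():
        rows.append(dict(
            condition=name,
            n=len(vals),
            median=float(np.median(vals)),
            q1=float(np.percentile(vals, 25)),
            q3=float(np.percentile(vals, 75)),
        ))
    return pd.DataFrame(rows)


def lfq_enrichment(table: pd.DataFrame, wt_cols: list[str], mut_cols: list[str],
                   protein_col: str = "protein",
                   missing_floor_factor: float = 0.5) -> pd.DataFrame:
    """Rank proteins by WT / mutant enrichment of averaged LFQ intensities.

    Per protein, replicate intensities are averaged within each condition and
    the WT/mutant ratio taken; proteins are ranked by ratio, descending.
    Missing (NaN or zero) values are floor-imputed at `missing_floor_factor`
    times the smallest positive intensity in the table; proteins detected in
    only one condition are flagged ``one_sided``. Proteins absent from both
    conditions raise.
    """
    for col in [protein_col, *wt_cols, *mut_cols]:
        if col not in table.columns:
            raise KeyError(f"column {col!r} not in table")
    wt = table[wt_cols].astype(float).replace(0.0, np.nan)
    mut = table[mut_cols].astype(float).replace(0.0, np.nan)
    both_absent = wt.isna().all(axis=1) & mut.isna().all(axis=1)
    if both_absent.any():
        bad = table.loc[both_absent, protein_col].tolist()
        raise ValueError(f"proteins absent from both conditions: {bad}")
    positive = pd.concat([wt, mut], axis=1).to_numpy().ravel()
    positive = positive[np.isfinite(positive) & (positive > 0)]
    if positive.size == 0:
        raise ValueError("no positive intensities in the table")
    floor = missing_floor_factor * float(positive.min())
    one_sided = wt.isna().all(axis=1) | mut.isna().all(axis=1)
    out = pd.DataFrame({
        protein_col: table[protein_col],
        "mean_wt": wt.mean(axis=1).fillna(floor),
        "mean_mut": mut.mean(axis=1).fillna(floor),
    })
    out["ratio"] = out["mean_wt"] / out["mean_mut"]
    out["one_sided"] = one_sided.to_numpy()
    out = out.sort_values("ratio", ascending=False, kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
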