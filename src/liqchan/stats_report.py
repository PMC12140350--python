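"""Statistical comparisons and figure-style summaries.

Two-condition comparisons use Student's t tests (paired or unpaired,
pooled variance by default); three or more groups use one-way ANOVA with
Tukey's HSD for all pairwise comparisons.  Tests run on the displayed
points (cells / channel replicates), as in the source experiments; a
replicate-mean aggregation is available via :func:`aggregate_replicates`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "two_sample_t",
    "one_way_anova_tukey",
    "aggregate_replicates",
    "report",
]


@dataclass
class ComparisonResult:
    """Outcome of one statistical comparison."""

    test: str
    groups: list[str]
    statistic: float
    df: float
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)
    group_sd: dict[str, float] = field(default_factory=dict)
    pairwise_p: dict[tuple[str, str], float] = field(default_factory=dict)
    pairwise_p_adjusted: dict[tuple[str, str], float] = field(default_factory=dict)


def two_sample_t(
    a,
    b,
    paired: bool = False,
    equal_variance: bool = True,
    names: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sided Student's t test between two samples.

    Raises
    ------
    ValueError
        For n < 2 per group, length mismatch when paired, or zero variance
        in both groups (the t statistic is undefined).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length samples")
        if np.var(a - b) == 0 and not np.allclose(a, b):
            raise ValueError("zero variance of paired differences")
        if np.allclose(a, b):
            res_stat, res_p, dof = 0.0, 1.0, float(len(a) - 1)
        else:
            res = stats.ttest_rel(a, b)
            res_stat, res_p, dof = float(res.statistic), float(res.pvalue), float(res.df)
        test = "paired t"
    else:
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                raise ValueError("zero variance in both groups; t undefined")
            raise ValueError("zero variance in both groups with different means")
        res = stats.ttest_ind(a, b, equal_var=equal_variance)
        res_stat, res_p, dof = float(res.statistic), float(res.pvalue), float(res.df)
        test = "unpaired t (pooled)" if equal_variance else "Welch t"
    return ComparisonResult(
        test=test,
        groups=list(names),
        statistic=res_stat,
        df=dof,
        p_value=res_p,
        group_means={names[0]: float(np.mean(a)), names[1]: float(np.mean(b))},
        group_sd={names[0]: float(np.std(a, ddof=1)), names[1]: float(np.std(b, ddof=1))},
    )


def one_way_anova_tukey(groups: dict[str, np.ndarray] | list) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD multiple comparisons between every group.

    Raises
    ------
    ValueError
        For fewer than 3 groups (use :func:`two_sample_t`) or fewer than
        2 observations in any group.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i}": g for i, g in enumerate(groups)}
    names = list(groups)
    data = [np.asarray(groups[n], float) for n in names]
    if len(data) < 3:
        raise ValueError("fewer than 3 groups: use two_sample_t instead")
    if any(len(g) < 2 for g in data):
        raise ValueError("need at least 2 observations per group")

    df = float(len(data) - 1)
    pairwise_adj: dict[tuple[str, str], float] = {}
    pairwise_raw: dict[tuple[str, str], float] = {}
    if np.var(np.concatenate(data)) == 0:
        # all observations identical: no effect, no dispersion
        f_stat, p_val = 0.0, 1.0
        for i in range(len(data)):
            for j in range(i + 1, len(data)):
                pairwise_adj[(names[i], names[j])] = 1.0
                pairwise_raw[(names[i], names[j])] = 1.0
    else:
        f_stat, p_val = stats.f_oneway(*data)
        tukey = stats.tukey_hsd(*data)
        # unadjusted pairwise p on the same pooled within-group error the
        # Tukey procedure uses (Fisher LSD), so adjusted >= raw by design
        n_total = sum(len(g) for g in data)
        df_err = n_total - len(data)
        mse = sum(np.sum((g - g.mean()) ** 2) for g in data) / df_err
        for i in range(len(data)):
            for j in range(i + 1, len(data)):
                pair = (names[i], names[j])
                pairwise_adj[pair] = float(tukey.pvalue[i, j])
                se = np.sqrt(mse * (1.0 / len(data[i]) + 1.0 / len(data[j])))
                t_ij = (data[i].mean() - data[j].mean()) / se
                pairwise_raw[pair] = float(2.0 * stats.t.sf(abs(t_ij), df_err))
    return ComparisonResult(
        test="one-way ANOVA + Tukey HSD",
        groups=names,
        statistic=float(f_stat),
        df=df,
        p_value=float(p_val),
        group_means={n: float(np.mean(g)) for n, g in zip(names, data)},
        group_sd={n: float(np.std(g, ddof=1)) for n, g in zip(names, data)},
        pairwise_p=pairwise_raw,
        pairwise_p_adjusted=pairwise_adj,
    )


def aggregate_replicates(
    table: pd.DataFrame, value: str, group: str, replicate: str
) -> pd.DataFrame:
    """Collapse observations to replicate (e.g. donor) means per group."""
    return (
        table.groupby([group, replicate], as_index=False)[value]
        .mean()
        .rename(columns={value: value})
    )


def report(
    table: pd.DataFrame,
    value: str,
    group: str,
    replicate: str | None = None,
    paired: bool = False,
    outdir=None,
):
    """Run the appropriate comparison on a tidy table and draw a dot plot.

    Two groups get a t test (paired if requested), three or more a one-way
    ANOVA with Tukey HSD.  When ``replicate`` is given, points are shaded
    by replicate in the figure.  Returns ``(ComparisonResult, summary
    DataFrame, figure)``; with ``outdir`` set, writes ``summary.csv`` and
    ``comparison.svg`` there.

    Raises
    ------
    ValueError
        On an empty table or unknown columns.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        raise ValueError("empty measurement table")
    for col in filter(None, (value, group, replicate)):
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")

    names = list(pd.unique(table[group]))
    samples = {str(n): table.loc[table[group] == n, value].to_numpy(float) for n in names}
    if len(names) == 2:
        result = two_sample_t(
            samples[str(names[0])], samples[str(names[1])], paired=paired,
            names=(str(names[0]), str(names[1])),
        )
    else:
        result = one_way_anova_tukey(samples)

    summary = (
        table.groupby(group)[value]
        .agg(["count", "mean", "std"])
        .reset_index()
        .rename(columns={"count": "n", "std": "sd"})
    )

    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(names), 3.2))
    rng = np.random.default_rng(0)
    rep_levels = list(pd.unique(table[replicate])) if replicate else []
    cmap = plt.get_cmap("viridis", max(len(rep_levels), 1))
    for gi, n in enumerate(names):
        sub = table[table[group] == n]
        jitter = rng.uniform(-0.12, 0.12, len(sub))
        colors = (
            [cmap(rep_levels.index(r)) for r in sub[replicate]]
            if replicate
            else "k"
        )
        ax.scatter(gi + jitter, sub[value], s=18, c=colors, alpha=0.8)
        ax.hlines(sub[value].mean(), gi - 0.25, gi + 0.25, color="crimson")
    if paired and len(names) == 2:
        a = samples[str(names[0])]
        b = samples[str(names[1])]
        for va, vb in zip(a, b):
            ax.plot([0, 1], [va, vb], color="0.7", lw=0.6, zorder=0)
    ax.set_xticks(range(len(names)), [str(n) for n in names])
    ax.set_ylabel(value)
    ax.set_title(f"{result.test}: p = {result.p_value:.3g}")
    fig.tight_layout()

    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "summary.csv", index=False)
        fig.savefig(outdir / "comparison.svg")
    return result, summary, fig
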