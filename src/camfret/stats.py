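"""Statistical helper layer: one entry point for the designs used in the assays.

``stats_suite`` dispatches to the appropriate reference implementation
(scipy / statsmodels / pingouin) so every analysis module reports
p-values from the same vetted back-ends.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = ["DESIGNS", "stats_suite", "unpaired_t"]

DESIGNS = (
    "unpaired_t",
    "one_way_anova_dunnett",
    "two_way_anova_tukey",
    "repeated_measures_anova_tukey",
    "ks_two_sample",
)


def unpaired_t(a, b, welch: bool = False) -> dict:
    """Two-sample t test; Student's (equal variance) by default, Welch via flag."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("unpaired t test needs >= 2 observations per group")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "df": float(res.df),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "welch": welch,
    }


def _one_way_dunnett(samples: dict) -> dict:
    if "control" not in samples:
        raise StatsError("one_way_anova_dunnett needs a 'control' group")
    control = np.asarray(samples["control"], dtype=float)
    names = [k for k in samples if k != "control"]
    if len(names) < 1:
        raise StatsError("need at least one treatment group")
    groups = [np.asarray(samples[k], dtype=float) for k in names]
    for name, g in [("control", control)] + list(zip(names, groups)):
        if len(g) < 2:
            raise StatsError(f"group {name!r} has fewer than 2 replicates")
    f = sps.f_oneway(control, *groups)
    dun = sps.dunnett(*groups, control=control)
    contrasts = pd.DataFrame(
        {
            "group": names,
            "diff": [float(g.mean() - control.mean()) for g in groups],
            "p_adj": [float(p) for p in dun.pvalue],
        }
    )
    return {"anova_F": float(f.statistic), "anova_p": float(f.pvalue), "contrasts": contrasts}


def _two_way_tukey(data: pd.DataFrame, dv: str, factor_a: str, factor_b: str) -> dict:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = data.copy()
    df["_a"] = df[factor_a].astype(str)
    df["_b"] = df[factor_b].astype(str)
    model = ols(f"{dv} ~ C(_a) * C(_b)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    # Tukey on factor_a levels within each factor_b level
    rows = []
    for b_level, sub in df.groupby("_b"):
        levels = sorted(sub["_a"].unique())
        if len(levels) < 2:
            continue
        groups = [sub[sub["_a"] == lv][dv].to_numpy(dtype=float) for lv in levels]
        res = sps.tukey_hsd(*groups)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                rows.append(
                    {
                        factor_b: b_level,
                        "level_a": levels[i],
                        "level_b": levels[j],
                        "diff": float(np.mean(groups[j]) - np.mean(groups[i])),
                        "p_adj": float(res.pvalue[i, j]),
                    }
                )
    return {"anova": anova, "contrasts": pd.DataFrame(rows)}


def _rm_tukey(data: pd.DataFrame, dv: str, within: str, subject: str, between: str | None) -> dict:
    import pingouin as pg

    if between is not None and data[between].nunique() >= 2:
        anova = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject, between=between)
        grouping = between
    else:
        anova = pg.rm_anova(data=data, dv=dv, within=within, subject=subject)
        grouping = None
    anova = anova.rename(columns={"p-unc": "p_unc"})
    rows = []
    if grouping is not None:
        for w_level, sub in data.groupby(within):
            levels = sorted(sub[grouping].unique())
            groups = [sub[sub[grouping] == lv][dv].to_numpy(dtype=float) for lv in levels]
            res = sps.tukey_hsd(*groups)
            for i in range(len(levels)):
                for j in range(i + 1, len(levels)):
                    rows.append(
                        {
                            within: w_level,
                            "level_a": levels[i],
                            "level_b": levels[j],
                            "diff": float(np.mean(groups[j]) - np.mean(groups[i])),
                            "p_adj": float(res.pvalue[i, j]),
                        }
                    )
    return {"anova": anova, "contrasts": pd.DataFrame(rows)}


def stats_suite(samples, design: str, **options) -> dict:
    """Run one of the supported designs.

    ``samples`` is design-dependent: two arrays for ``unpaired_t`` /
    ``ks_two_sample``, a ``{name: array}`` mapping with a ``control`` key
    for ``one_way_anova_dunnett``, or a tidy DataFrame plus column names
    in ``options`` for the ANOVA designs.
    """
    if design not in DESIGNS:
        raise StatsError(f"unknown design {design!r}; supported: {DESIGNS}")
    if design == "unpaired_t":
        a, b = samples
        return unpaired_t(a, b, welch=options.get("welch", False))
    if design == "ks_two_sample":
        a, b = samples
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        res = sps.ks_2samp(a, b, method=options.get("method", "auto"))
        return {"ks_stat": float(res.statistic), "p": float(res.pvalue)}
    if design == "one_way_anova_dunnett":
        return _one_way_dunnett(samples)
    if design == "two_way_anova_tukey":
        return _two_way_tukey(
            samples,
            dv=options.get("dv", "response"),
            factor_a=options.get("factor_a", "genotype"),
            factor_b=options.get("factor_b", "conc"),
        )
    return _rm_tukey(
        samples,
        dv=options.get("dv", "peak_drr0"),
        within=options.get("within", "frequency_hz"),
        subject=options.get("subject", "neuron_id"),
        between=options.get("between", "genotype"),
    )
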