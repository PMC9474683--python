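"""Frequency tuning and pharmacological dose-response analyses.

Tuning curves collect per-neuron peak amplitudes across stimulation
frequencies (a mixed between/within design: frequency within neuron,
genotype between neurons); the half-maximal frequency F50 summarizes the
leftward shift of facilitated mutants.  The memantine analysis pairs
per-dose Dunnett contrasts against vehicle with a descriptive
four-parameter Hill inhibition fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

from .errors import DataError, StatsError

__all__ = [
    "TuningCurve",
    "InhibitionCurve",
    "build_tuning_curve",
    "half_max_frequency",
    "amplitude_vs_ca_plot",
    "fit_dose_inhibition",
    "dose_group_compare",
]


@dataclass
class TuningCurve:
    """Peak amplitude vs stimulation frequency for one genotype."""

    genotype: str
    frequencies: np.ndarray
    amplitudes: dict  # frequency -> per-neuron array
    means: np.ndarray
    sems: np.ndarray
    ns: np.ndarray


@dataclass
class InhibitionCurve:
    """Dose-inhibition summary with an optional Hill fit."""

    drug: str
    doses: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    ns: np.ndarray
    ic50: float = np.nan
    hill_slope: float = np.nan
    floor: float = np.nan
    ceiling: float = np.nan
    fit_cov: np.ndarray | None = None
    flags: list = field(default_factory=list)


def build_tuning_curve(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Assemble per-genotype tuning curves and run the mixed ANOVA.

    ``results`` is tidy with columns ``neuron_id``, ``genotype``,
    ``frequency_hz`` and ``peak_drr0``; every neuron should be measured
    at every frequency (repeated-measures within-factor), and neurons
    with missing cells are dropped with a warning.

    Returns ``curves`` (genotype -> :class:`TuningCurve`), ``anova``
    (mixed between/within table) and ``contrasts`` (per-frequency
    Tukey-adjusted genotype comparisons).
    """
    need = {"neuron_id", "genotype", "frequency_hz", "peak_drr0"}
    if need - set(results.columns):
        raise DataError(f"results table missing columns {sorted(need - set(results.columns))}")
    freqs = np.array(sorted(results["frequency_hz"].unique()), dtype=float)
    if len(freqs) < 2:
        raise StatsError("tuning analysis needs at least 2 frequencies")

    complete = results.groupby("neuron_id")["frequency_hz"].nunique()
    dropped = complete[complete < len(freqs)].index.tolist()
    if dropped:
        warnings.warn(f"neurons missing frequencies dropped from repeated-measures analysis: {dropped}")
    kept = results[~results["neuron_id"].isin(dropped)].copy()
    if kept.empty:
        raise StatsError("no neuron was measured at every frequency")

    curves = {}
    for g, sub in kept.groupby("genotype"):
        amps, means, sems, ns = {}, [], [], []
        for f in freqs:
            v = sub[sub["frequency_hz"] == f]["peak_drr0"].to_numpy()
            amps[float(f)] = v
            means.append(v.mean())
            sems.append(v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan)
            ns.append(len(v))
        curves[str(g)] = TuningCurve(
            genotype=str(g),
            frequencies=freqs,
            amplitudes=amps,
            means=np.array(means),
            sems=np.array(sems),
            ns=np.array(ns),
        )

    import pingouin as pg

    genotypes = sorted(kept["genotype"].unique())
    if len(genotypes) >= 2:
        anova = pg.mixed_anova(
            data=kept, dv="peak_drr0", within="frequency_hz", subject="neuron_id", between="genotype"
        )
    else:
        anova = pg.rm_anova(data=kept, dv="peak_drr0", within="frequency_hz", subject="neuron_id")
    anova = anova.rename(columns={"p-unc": "p_unc"})

    rows = []
    if len(genotypes) >= 2:
        for f in freqs:
            groups = [
                kept[(kept["genotype"] == g) & (kept["frequency_hz"] == f)]["peak_drr0"].to_numpy()
                for g in genotypes
            ]
            res = sps.tukey_hsd(*groups)
            for i in range(len(genotypes)):
                for j in range(i + 1, len(genotypes)):
                    p = float(res.pvalue[i, j])
                    rows.append(
                        {
                            "genotype_a": genotypes[i],
                            "genotype_b": genotypes[j],
                            "frequency_hz": float(f),
                            "diff": float(np.mean(groups[j]) - np.mean(groups[i])),
                            "p_adj": p,
                            "significant": p < alpha,
                        }
                    )
    return {"curves": curves, "anova": anova, "contrasts": pd.DataFrame(rows), "dropped_neurons": dropped}


def half_max_frequency(curve: TuningCurve):
    """Half-maximal frequency F50 by log-frequency linear interpolation.

    The curve of mean amplitudes is interpolated linearly in
    log10(frequency); F50 is the frequency at the first upward crossing
    of half the curve's maximum mean.  Returns None (undetermined) when
    the measured range does not span its own half-max.
    """
    m = np.asarray(curve.means, dtype=float)
    f = np.asarray(curve.frequencies, dtype=float)
    half = np.max(m) / 2.0
    if m[0] >= half:
        return None  # already above half at the lowest measured frequency
    for i in range(len(f) - 1):
        if m[i] < half <= m[i + 1]:
            frac = (half - m[i]) / (m[i + 1] - m[i])
            logf = np.log10(f[i]) + frac * (np.log10(f[i + 1]) - np.log10(f[i]))
            return float(10**logf)
    return None


def amplitude_vs_ca_plot(summary: pd.DataFrame, wt_label: str = "WT") -> pd.DataFrame:
    """Classify mutants against the WT reference line through the origin.

    ``summary`` has one row per genotype with columns ``genotype``,
    ``mean_dff0``, ``mean_drr0``, ``sem_drr0``.  The line connects the
    origin to the WT point in (Ca2+ amplitude, kinase amplitude) space;
    each mutant's signed relative offset from its line prediction is
    reported, with an above/on/below call using a +-1 pooled-SEM dead
    band.
    """
    need = {"genotype", "mean_dff0", "mean_drr0", "sem_drr0"}
    if need - set(summary.columns):
        raise DataError(f"summary missing columns {sorted(need - set(summary.columns))}")
    wt = summary[summary["genotype"] == wt_label]
    if len(wt) != 1:
        raise DataError(f"summary must contain exactly one {wt_label} row")
    wt = wt.iloc[0]
    if wt["mean_dff0"] <= 0 or wt["mean_drr0"] <= 0:
        raise DataError("WT reference point must be strictly positive")
    slope = wt["mean_drr0"] / wt["mean_dff0"]

    rows = []
    for _, r in summary.iterrows():
        if r["genotype"] == wt_label:
            continue
        pred = slope * r["mean_dff0"]
        offset = (r["mean_drr0"] - pred) / pred
        band = float(np.sqrt(r["sem_drr0"] ** 2 + wt["sem_drr0"] ** 2)) / pred
        if offset > band:
            call = "above"
        elif offset < -band:
            call = "below"
        else:
            call = "on"
        rows.append(
            {
                "genotype": r["genotype"],
                "line_prediction": float(pred),
                "offset": float(offset),
                "dead_band": band,
                "classification": call,
            }
        )
    return pd.DataFrame(rows)


def _hill_inhibition(d, floor, ceiling, ic50, hill):
    return floor + (ceiling - floor) / (1.0 + (d / ic50) ** hill)


def fit_dose_inhibition(values: pd.DataFrame, drug: str = "memantine") -> InhibitionCurve:
    """Four-parameter Hill inhibition fit with the ceiling anchored to vehicle.

    ``values`` is tidy with columns ``dose_um`` (vehicle = 0 present) and
    ``response``.  The ceiling is fixed to the vehicle mean; floor, IC50
    and Hill slope are fit by least squares on the individual points.
    Falls back to the isotonic per-dose summary (flagged) when the fit
    cannot converge; flags ``non_inhibitory`` when responses rise with
    dose and ``ic50_undetermined`` when response is dose-independent.
    """
    need = {"dose_um", "response"}
    if need - set(values.columns):
        raise DataError(f"values missing columns {sorted(need - set(values.columns))}")
    doses = np.array(sorted(values["dose_um"].unique()), dtype=float)
    if 0.0 not in doses or len(doses) < 4:
        raise DataError("need vehicle (dose 0) plus at least 3 distinct doses")

    agg = values.groupby("dose_um")["response"].agg(["mean", "sem", "count"]).sort_index()
    means = agg["mean"].to_numpy()
    curve = InhibitionCurve(
        drug=drug,
        doses=doses,
        means=means,
        sems=agg["sem"].to_numpy(),
        ns=agg["count"].to_numpy(),
        ceiling=float(means[0]),
    )

    nz = doses > 0
    sem_scale = float(np.nanmean(agg["sem"].to_numpy()))
    slope_trend = np.polyfit(np.log10(doses[nz]), means[nz], 1)[0]
    if means[nz].max() > means[0] + 2.0 * sem_scale and slope_trend > 0:
        curve.flags.append("non_inhibitory")
    span = means.max() - means.min()
    if span < 3.0 * sem_scale:
        curve.flags.append("ic50_undetermined")
        return curve

    d = values["dose_um"].to_numpy(dtype=float)
    y = values["response"].to_numpy(dtype=float)
    ceiling = float(means[0])

    def model(dd, floor, log_ic50, hill):
        return _hill_inhibition(dd, floor, ceiling, 10.0**log_ic50, hill)

    try:
        geo_mid = np.sqrt(doses[nz].min() * doses[nz].max())
        popt, pcov = curve_fit(
            model,
            d,
            y,
            p0=[float(means.min()), np.log10(geo_mid), 1.0],
            bounds=([-np.inf, -3.0, 0.1], [np.inf, 4.0, 10.0]),
            maxfev=10000,
        )
    except RuntimeError:
        curve.flags.append("fit_nonconvergent")
        return curve
    curve.floor = float(popt[0])
    curve.ic50 = float(10.0 ** popt[1])
    curve.hill_slope = float(popt[2])
    curve.fit_cov = pcov
    return curve


def dose_group_compare(values: pd.DataFrame, alpha: float = 0.05) -> dict:
    """One-way ANOVA plus Dunnett many-to-one contrasts against vehicle."""
    need = {"dose_um", "response"}
    if need - set(values.columns):
        raise DataError(f"values missing columns {sorted(need - set(values.columns))}")
    doses = sorted(values["dose_um"].unique())
    if 0.0 not in doses or len(doses) < 3:
        raise StatsError("need vehicle (dose 0) plus at least 2 doses")
    groups = {d: values[values["dose_um"] == d]["response"].to_numpy() for d in doses}
    small = [d for d, v in groups.items() if len(v) < 2]
    if small:
        raise StatsError(f"doses with fewer than 2 replicates: {small}")

    control = groups[0.0]
    treat_doses = [d for d in doses if d != 0.0]
    anova = sps.f_oneway(*groups.values())
    dun = sps.dunnett(*[groups[d] for d in treat_doses], control=control)
    contrasts = pd.DataFrame(
        {
            "dose_um": treat_doses,
            "diff": [float(np.mean(groups[d]) - np.mean(control)) for d in treat_doses],
            "p_adj": [float(p) for p in dun.pvalue],
        }
    )
    contrasts["significant"] = contrasts["p_adj"] < alpha
    return {
        "anova_F": float(anova.statistic),
        "anova_p": float(anova.pvalue),
        "contrasts": contrasts,
    }
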