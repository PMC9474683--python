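"""Plate-reader lysate FRET assay analysis.

A run is one well's CFP (ex 435 / em 485) and FRET (ex 435 / em 535)
time series with known added-CaM concentration and the frame indices at
which Ca2+ and then EGTA were added.  Analysis: blank (empty-vector
lysate) subtraction, probe-concentration equalization from a direct YFP
read (ex 510 / em 560), CFP/FRET ratio, and the dose-response point
defined as the mean ratio of the last three frames strictly before the
EGTA addition.  Genotype curves are compared by two-way ANOVA
(genotype x concentration) with Tukey contrasts within each
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, StatsError

__all__ = [
    "PlateReaderRun",
    "DoseResponseCurve",
    "subtract_blank",
    "equalize_probe_concentration",
    "fret_ratio_series",
    "extract_dose_point",
    "build_dose_response",
]


@dataclass
class PlateReaderRun:
    """One well's raw plate-reader time series and metadata."""

    well_id: str
    genotype: str
    cam_conc: float
    cfp_channel: np.ndarray
    fret_channel: np.ndarray
    frame_times: np.ndarray
    ca_add_index: int
    egta_add_index: int
    blank_cfp: np.ndarray | None = None
    blank_fret: np.ndarray | None = None
    probe_yfp_direct: float = np.nan
    blank_probe_yfp: float = 0.0
    group: str = "high_expression"
    blank_subtracted: bool = False
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.cfp_channel = np.asarray(self.cfp_channel, dtype=float)
        self.fret_channel = np.asarray(self.fret_channel, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        n = len(self.frame_times)
        if len(self.cfp_channel) != n or len(self.fret_channel) != n:
            raise DataError("plate channel series lengths differ from frame_times")
        if not (0 < self.ca_add_index < self.egta_add_index <= n):
            raise DataError(
                f"event order must satisfy 0 < ca_add ({self.ca_add_index}) < "
                f"egta_add ({self.egta_add_index}) <= n_frames ({n})"
            )

    @property
    def corrected_probe_yfp(self) -> float:
        return float(self.probe_yfp_direct - self.blank_probe_yfp)


@dataclass
class DoseResponseCurve:
    """Per-genotype CaM dose-response summary."""

    genotype: str
    cam_concs: np.ndarray
    means: np.ndarray
    sems: np.ndarray
    ns: np.ndarray
    group: str = "high_expression"


def subtract_blank(run: PlateReaderRun) -> PlateReaderRun:
    """Subtract the matched empty-vector well frame-wise from both channels.

    Negative values are permitted (low-signal wells) but flagged.
    """
    if run.blank_cfp is None or run.blank_fret is None:
        raise DataError(f"well {run.well_id}: blank series missing")
    blank_cfp = np.asarray(run.blank_cfp, dtype=float)
    blank_fret = np.asarray(run.blank_fret, dtype=float)
    if len(blank_cfp) != len(run.cfp_channel) or len(blank_fret) != len(run.fret_channel):
        raise DataError(f"well {run.well_id}: blank series length mismatch")
    cfp = run.cfp_channel - blank_cfp
    fret = run.fret_channel - blank_fret
    flags = list(run.flags)
    if np.any(cfp <= 0) or np.any(fret <= 0):
        flags = flags + ["nonpositive_after_blank"]
    return replace(run, cfp_channel=cfp, fret_channel=fret, blank_subtracted=True, flags=flags)


def equalize_probe_concentration(runs) -> dict[str, float]:
    """Scale factors normalizing probe amount to the dimmest run in the group.

    The wet protocol dilutes brighter lysates with empty-vector lysate, so
    dilution can only reduce signal: all factors are <= 1 and the dimmest
    run gets factor 1.0.  Keyed by ``well_id``.
    """
    probes = {}
    for run in runs:
        p = run.corrected_probe_yfp
        if not np.isfinite(p) or p <= 0:
            raise DataError(f"well {run.well_id}: non-positive blank-corrected probe signal {p}")
        probes[run.well_id] = p
    ref = min(probes.values())
    return {wid: ref / p for wid, p in probes.items()}


def fret_ratio_series(run: PlateReaderRun) -> np.ndarray:
    """Element-wise CFP / FRET-channel ratio (rises with kinase activation)."""
    if not run.blank_subtracted:
        raise DataError(f"well {run.well_id}: subtract the blank before taking ratios")
    bad = np.flatnonzero(run.fret_channel <= 0)
    if len(bad):
        raise DataError(
            f"well {run.well_id}: FRET channel non-positive at frame {int(bad[0])}; ratio undefined"
        )
    return run.cfp_channel / run.fret_channel


def extract_dose_point(run: PlateReaderRun) -> tuple[float, float]:
    """The dose-response point: mean ratio of the last three pre-EGTA frames.

    The EGTA-addition frame itself is excluded ("just before" the
    addition); the response uses frames ``egta_add_index - 3 .. - 1``.
    """
    if run.egta_add_index < 3:
        raise DataError(f"well {run.well_id}: fewer than 3 frames before EGTA addition")
    ratio = fret_ratio_series(run)
    sl = ratio[run.egta_add_index - 3 : run.egta_add_index]
    return float(run.cam_conc), float(np.mean(sl))


def build_dose_response(points: pd.DataFrame, alpha: float = 0.05):
    """Assemble dose-response curves and test genotype differences.

    Parameters
    ----------
    points:
        Tidy frame with columns ``genotype``, ``cam_conc``, ``response``
        (one row per well) and optionally ``group``.

    Returns
    -------
    dict with ``curves`` (list of :class:`DoseResponseCurve`), ``anova``
    (two-way ANOVA table, factors genotype and concentration) and
    ``contrasts`` (tidy per-concentration Tukey-adjusted genotype
    contrasts: genotype_a, genotype_b, conc, diff, p_adj, significant).
    """
    required = {"genotype", "cam_conc", "response"}
    missing = required - set(points.columns)
    if missing:
        raise DataError(f"points table missing columns: {sorted(missing)}")
    genotypes = sorted(points["genotype"].unique())
    concs = sorted(points["cam_conc"].unique())
    if len(genotypes) < 2:
        raise StatsError("need at least 2 genotypes for a dose-response comparison")
    counts = points.groupby(["genotype", "cam_conc"]).size()
    bad_cells = [
        (g, c) for g in genotypes for c in concs if counts.get((g, c), 0) < 2
    ]
    if bad_cells:
        raise StatsError(f"cells with fewer than 2 replicates: {bad_cells}")

    curves = []
    for g, sub in points.groupby("genotype"):
        agg = sub.groupby("cam_conc")["response"].agg(["mean", "sem", "count"]).sort_index()
        curves.append(
            DoseResponseCurve(
                genotype=str(g),
                cam_concs=agg.index.to_numpy(dtype=float),
                means=agg["mean"].to_numpy(),
                sems=agg["sem"].to_numpy(),
                ns=agg["count"].to_numpy(),
                group=str(sub["group"].iloc[0]) if "group" in sub else "high_expression",
            )
        )

    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = points.rename(columns={"cam_conc": "conc"}).copy()
    df["genotype"] = df["genotype"].astype(str)
    df["conc"] = df["conc"].astype(str)
    model = ols("response ~ C(genotype) * C(conc)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)

    rows = []
    for c in concs:
        sub = points[points["cam_conc"] == c]
        groups = [sub[sub["genotype"] == g]["response"].to_numpy() for g in genotypes]
        res = sps.tukey_hsd(*groups)
        for i in range(len(genotypes)):
            for j in range(i + 1, len(genotypes)):
                diff = float(np.mean(groups[j]) - np.mean(groups[i]))
                p = float(res.pvalue[i, j])
                rows.append(
                    {
                        "genotype_a": genotypes[i],
                        "genotype_b": genotypes[j],
                        "conc": c,
                        "diff": diff,
                        "p_adj": p,
                        "significant": p < alpha,
                    }
                )
    contrasts = pd.DataFrame(rows)
    return {"curves": curves, "anova": anova, "contrasts": contrasts}
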