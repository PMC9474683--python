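"""File readers and writers: trace CSV tables, TIFF stacks, result tables.

The trace table is a long-format CSV (one row per ROI per frame) with
columns ``roi_id, genotype, time_s, cfp, yfp, rfp`` plus optional
``background_cfp/yfp/rfp`` and ``is_artifact_truth``.  Protocol metadata
travels in a sidecar JSON (see :mod:`camfret.protocol`).  Malformed rows
are collected into an error report rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError
from .protocol import StimulusProtocol
from .records import TraceRecord

__all__ = [
    "REQUIRED_TRACE_COLUMNS",
    "read_trace_table",
    "write_trace_table",
    "read_tiff_stack",
    "write_tiff_stack",
    "kinetics_results_frame",
]

REQUIRED_TRACE_COLUMNS = ("roi_id", "genotype", "time_s", "cfp", "yfp", "rfp")
_NUMERIC = ("time_s", "cfp", "yfp", "rfp")


@dataclass
class TraceReadReport:
    records: list
    errors: pd.DataFrame = field(default_factory=pd.DataFrame)


def read_trace_table(
    path,
    column_map: dict | None = None,
    protocol: StimulusProtocol | None = None,
) -> TraceReadReport:
    """Read a long-format trace CSV into :class:`TraceRecord` objects.

    ``column_map`` renames external column names onto the required
    schema (``{"my_col": "cfp", ...}``).  Rows that fail numeric
    validation are excluded from the records and returned in the error
    report with their row number and reason.
    """
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"trace table {path} missing required columns: {missing}")

    def coerce(value):
        # python's float() is correctly rounded; pandas' to_numeric fast
        # path is off by one ulp on some inputs, breaking round-trips
        try:
            return float(value)
        except (TypeError, ValueError):
            return np.nan

    errors = []
    conv = df.copy()
    for col in _NUMERIC:
        conv[col] = df[col].map(coerce)
    bad_mask = conv[list(_NUMERIC)].isna().any(axis=1)
    for idx in conv.index[bad_mask]:
        bad_cols = [c for c in _NUMERIC if pd.isna(conv.loc[idx, c])]
        errors.append({"row": int(idx), "reason": f"non-numeric value in {bad_cols}"})
    good = conv[~bad_mask]

    records = []
    for roi_id, sub in good.groupby("roi_id", sort=False):
        sub = sub.sort_values("time_s")
        kwargs = {}
        for ch in ("cfp", "yfp", "rfp"):
            col = f"background_{ch}"
            if col in sub.columns:
                kwargs[f"background_{ch}"] = pd.to_numeric(sub[col], errors="coerce").fillna(0.0).to_numpy()
        art = None
        if "is_artifact_truth" in sub.columns:
            art = sub["is_artifact_truth"].astype(str).isin(("1", "True", "true")).to_numpy()
        records.append(
            TraceRecord(
                roi_id=str(roi_id),
                genotype=str(sub["genotype"].iloc[0]),
                protocol=protocol,
                frame_times=sub["time_s"].to_numpy(),
                cfp=sub["cfp"].to_numpy(),
                yfp=sub["yfp"].to_numpy(),
                rfp=sub["rfp"].to_numpy(),
                artifact_truth=art,
                **kwargs,
            )
        )
    return TraceReadReport(records=records, errors=pd.DataFrame(errors))


def write_trace_table(records, path) -> None:
    """Write records to the long-format CSV (floats at full repr precision)."""
    frames = []
    for rec in records:
        d = {
            "roi_id": rec.roi_id,
            "genotype": rec.genotype,
            "time_s": rec.frame_times,
            "cfp": rec.cfp,
            "yfp": rec.yfp,
            "rfp": rec.rfp,
        }
        for ch in ("cfp", "yfp", "rfp"):
            bg = getattr(rec, f"background_{ch}")
            d[f"background_{ch}"] = np.broadcast_to(np.asarray(bg, dtype=float), rec.frame_times.shape)
        if rec.artifact_truth is not None:
            d["is_artifact_truth"] = rec.artifact_truth.astype(int)
        frames.append(pd.DataFrame(d))
    # shortest-repr float formatting round-trips exactly through the reader
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tiff_stack(path, expected_pages: int | None = None) -> np.ndarray:
    """Read a multi-page TIFF into a (frames, H, W) array, dtype preserved."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if expected_pages is not None and arr.shape[0] != expected_pages:
        raise DataError(f"{path}: expected {expected_pages} pages, found {arr.shape[0]}")
    return arr


def write_tiff_stack(stack: np.ndarray, path) -> None:
    """Write a (frames, H, W) array as a multi-page TIFF (inverse of read)."""
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def kinetics_results_frame(results) -> pd.DataFrame:
    """Tabulate :class:`KineticsResult` objects (one row per recording)."""
    rows = []
    for r in results:
        rows.append(
            {
                "roi_id": r.roi_id,
                "genotype": r.genotype,
                "peak_drr0": r.peak_dRR0,
                "peak_time_s": r.peak_time,
                "half_rise_s": np.nan if r.half_rise is None else r.half_rise,
                "half_decay_s": np.nan if r.half_decay is None else r.half_decay,
                "peak_dff0": r.peak_dFF0,
                "ca_half_rise_s": np.nan if r.ca_half_rise is None else r.ca_half_rise,
                "ca_half_decay_s": np.nan if r.ca_half_decay is None else r.ca_half_decay,
                "qc_flags": ";".join(r.qc_flags),
            }
        )
    return pd.DataFrame(rows)
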