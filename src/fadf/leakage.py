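"""Compartmental MFI, Vascular Leakage, and the ratiometric Leakage Index.

For each frame the median fluorescence intensity (MFI) is measured inside and
outside the segmented vessels.  Per channel, the outside-to-inside ratio
``R(t) = mfi_out(t) / mfi_in(t)`` normalized to its pre-injection value gives
the Vascular Leakage ``VL(t) = R(t) / R(0)`` — dimensionless, equal to 1 at
baseline, and invariant to any constant rescaling of that channel.  The
Leakage Index ``LI(t) = VL_green(t) / VL_red(t)`` further normalizes the
leaking detection dye to the non-leaking reference dye: any gain applied
identically to both channels at a time point cancels exactly, which makes the
index insensitive to instrumental drift, clouding, and excretion-related
signal loss.  The 30-min endpoint ``LI(30)`` summarizes a session; cohorts are
compared longitudinally after normalizing each subject's endpoint to a
reference session.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_session import ChannelFrame
from .segmentation import CompartmentMasks

__all__ = [
    "MFIMeasurement",
    "LeakageSeries",
    "measure_mfi",
    "vascular_leakage",
    "leakage_index",
    "aggregate_longitudinal",
]


@dataclass(frozen=True)
class MFIMeasurement:
    """In/out median (or mean) fluorescence of one frame."""

    time_min: float
    channel: str
    mfi_in: float
    mfi_out: float
    n_in: int
    n_out: int


def measure_mfi(
    frame: ChannelFrame, masks: CompartmentMasks, statistic: str = "median"
) -> MFIMeasurement:
    """Measure compartment fluorescence under the vessel and EVS masks.

    ``statistic`` is ``"median"`` (robust default) or ``"mean"``.  Raises on
    an empty vessel or EVS mask: a session with no detectable vessels cannot
    be quantified and signals a segmentation failure.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    stat = np.median if statistic == "median" else np.mean
    n_in = int(masks.vessel.sum())
    n_out = int(masks.evs.sum())
    if n_in == 0:
        raise ValueError(f"no vessels detected at t={frame.time_min:g} ({frame.channel})")
    if n_out == 0:
        raise ValueError(f"empty extravascular mask at t={frame.time_min:g} ({frame.channel})")
    return MFIMeasurement(
        time_min=frame.time_min,
        channel=frame.channel,
        mfi_in=float(stat(frame.pixels[masks.vessel])),
        mfi_out=float(stat(frame.pixels[masks.evs])),
        n_in=n_in,
        n_out=n_out,
    )


def vascular_leakage(
    measurements: Iterable[MFIMeasurement], mode: str = "quotient"
) -> pd.DataFrame:
    """Per-time-point Vascular Leakage of one channel.

    Returns a frame with columns ``time_min, mfi_in, mfi_out, r, vl`` sorted
    by time, where ``r = mfi_out / mfi_in`` and ``vl = r / r(0)`` (default
    ``quotient`` mode, exactly 1 at t = 0) or ``r - r(0)`` in ``difference``
    mode (sensitivity analysis; exactly 0 at t = 0).  Requires a t = 0
    measurement and ``r(0) > 0``.
    """
    if mode not in ("quotient", "difference"):
        raise ValueError(f"mode must be 'quotient' or 'difference', got {mode!r}")
    ms = sorted(measurements, key=lambda m: m.time_min)
    if not ms:
        raise ValueError("no measurements given")
    channels = {m.channel for m in ms}
    if len(channels) > 1:
        raise ValueError(f"measurements mix channels {sorted(channels)}")
    if ms[0].time_min != 0:
        raise ValueError("baseline (t=0) measurement is required")
    for m in ms:
        if m.mfi_in <= 0:
            raise ValueError(f"mfi_in <= 0 at t={m.time_min:g}: division undefined")
    r = np.array([m.mfi_out / m.mfi_in for m in ms])
    if r[0] <= 0:
        raise ValueError("R(0) <= 0: baseline ratio undefined (segmentation failure?)")
    vl = r / r[0] if mode == "quotient" else r - r[0]
    return pd.DataFrame(
        {
            "time_min": [m.time_min for m in ms],
            "mfi_in": [m.mfi_in for m in ms],
            "mfi_out": [m.mfi_out for m in ms],
            "r": r,
            "vl": vl,
        }
    )


@dataclass(eq=False)
class LeakageSeries:
    """Joined green/red leakage series and the Leakage Index of one session.

    ``table`` has one row per time point with columns ``time_min, vl_green,
    vl_red, li``; ``li_30`` is the index at ``endpoint_min`` (the latest
    protocol time, 30 min by default).
    """

    table: pd.DataFrame
    li_30: float
    endpoint_min: float


def leakage_index(
    vl_green: pd.DataFrame, vl_red: pd.DataFrame, endpoint_min: float = 30.0
) -> LeakageSeries:
    """Ratio the detection-channel VL to the reference-channel VL.

    ``LI(t) = VL_green(t) / VL_red(t)``; exactly 1 at t = 0.  The two series
    must share their time grid.  ``li_30`` is LI at ``endpoint_min`` when
    present, else the last available time point with a warning.
    """
    tg = np.asarray(vl_green["time_min"], dtype=float)
    tr = np.asarray(vl_red["time_min"], dtype=float)
    if not np.array_equal(tg, tr):
        raise ValueError(f"mismatched time grids: green {tg} vs red {tr}")
    vg = np.asarray(vl_green["vl"], dtype=float)
    vr = np.asarray(vl_red["vl"], dtype=float)
    if np.any(vr == 0):
        raise ValueError("reference-channel VL contains zeros; index undefined")
    li = vg / vr
    table = pd.DataFrame({"time_min": tg, "vl_green": vg, "vl_red": vr, "li": li})

    if endpoint_min in tg:
        endpoint = float(endpoint_min)
    else:
        endpoint = float(tg[-1])
        warnings.warn(
            f"endpoint {endpoint_min:g} min absent; using last time point {endpoint:g} min"
        )
    li_30 = float(li[tg == endpoint][0])
    return LeakageSeries(table=table, li_30=li_30, endpoint_min=endpoint)


def aggregate_longitudinal(
    records: pd.DataFrame,
    reference_key,
    subject_col: str = "subject",
    session_col: str = "session",
    value_col: str = "li_30",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize per-session endpoints to a reference session and summarize.

    ``records`` holds one row per (subject, session) with the session's
    endpoint value.  Each subject's values are divided by that subject's value
    at ``reference_key`` (subjects lacking the reference session fall back to
    the cohort mean at the reference, so late-enrolled animals remain
    comparable).  Returns ``(per_subject, cohort)``: the per-subject table
    with a ``normalized`` column, and per-session cohort means, SEMs
    (ddof = 1; NaN for singleton sessions) and counts of the raw and
    normalized values.
    """
    for col in (subject_col, session_col, value_col):
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")
    ref = records[records[session_col] == reference_key]
    if ref.empty:
        raise ValueError(f"reference session {reference_key!r} absent from records")
    cohort_ref = float(ref[value_col].mean())

    per_subject = records.copy()
    ref_by_subject = ref.set_index(subject_col)[value_col]
    denom = per_subject[subject_col].map(ref_by_subject).fillna(cohort_ref)
    per_subject["normalized"] = per_subject[value_col] / denom
    per_subject = per_subject.sort_values([subject_col, session_col]).reset_index(drop=True)

    grouped = per_subject.groupby(session_col)
    cohort = grouped.agg(
        n=(value_col, "size"),
        mean=(value_col, "mean"),
        sem=(value_col, "sem"),
        mean_normalized=("normalized", "mean"),
        sem_normalized=("normalized", "sem"),
    ).reset_index()
    return per_subject, cohort
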