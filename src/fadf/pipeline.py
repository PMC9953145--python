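"""End-to-end per-session analysis: segmentation -> MFI -> VL -> LI -> caliber.

``analyze_session`` reproduces the acquisition protocol's analysis with its
stated defaults: per-channel vessel detection at 4 x noise SD (midpoint of the
3-5 range), median MFI inside/outside vessels at every time point with masks
recomputed per frame and no registration, quotient-form Vascular Leakage,
Leakage Index with the 30-min endpoint, and skeletal caliber from the first
post-injection green frame at 2 x SD (midpoint of 1-3).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .caliber import CaliberParams, CaliberSummary, measure_caliber
from .io_session import RESULT_COLUMNS, ImagingSession
from .leakage import LeakageSeries, leakage_index, measure_mfi, vascular_leakage
from .segmentation import estimate_noise, segment_pair

__all__ = ["RunConfig", "SessionResult", "analyze_session"]


@dataclass
class RunConfig:
    """All tunable analysis parameters with protocol defaults."""

    k_leakage: float = 4.0          # vessel detection, legal 3-5
    k_caliber: float = 2.0          # caliber selection, legal 1-3
    mfi_statistic: str = "median"   # or "mean" (figure-legend convention)
    vl_mode: str = "quotient"       # or "difference"
    mask_mode: str = "per_channel"  # or "shared_union" / "shared_green"
    boundary_exclusion_px: int = 0
    endpoint_min: float = 30.0
    min_object_px: float = 10
    max_hole_px: float = 25
    smooth_sigma: float = 0.0
    contrast_window_px: int = 255
    fine_filter_px: int = 3
    caliber_preprocess: bool = True
    measure_caliber: bool = True
    um_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.mfi_statistic not in ("median", "mean"):
            raise ValueError(f"mfi_statistic must be 'median' or 'mean', got {self.mfi_statistic!r}")
        if self.vl_mode not in ("quotient", "difference"):
            raise ValueError(f"vl_mode must be 'quotient' or 'difference', got {self.vl_mode!r}")
        if self.mask_mode not in ("per_channel", "shared_union", "shared_green"):
            raise ValueError(f"unknown mask_mode {self.mask_mode!r}")

    def caliber_params(self, image_shape: tuple[int, int] | None = None) -> CaliberParams:
        window = self.contrast_window_px
        if image_shape is not None:
            # keep the sliding window inside small frames (odd size)
            limit = min(image_shape)
            if window > limit:
                window = limit if limit % 2 else limit - 1
        return CaliberParams(
            k_threshold=self.k_caliber,
            contrast_window_px=window,
            fine_filter_px=self.fine_filter_px,
            um_per_px=self.um_per_px,
        )

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(eq=False)
class SessionResult:
    """Everything computed for one session."""

    subject: str
    session: str | float
    leakage: LeakageSeries
    mfi_table: pd.DataFrame
    caliber: CaliberSummary | None
    result_table: pd.DataFrame
    config: RunConfig

    @property
    def li_30(self) -> float:
        return self.leakage.li_30

    def summary_dict(self) -> dict:
        """JSON-serializable per-session summary."""
        t = self.leakage.table
        out = {
            "subject": self.subject,
            "session": self.session,
            "time_min": [float(v) for v in t["time_min"]],
            "vl_green": [float(v) for v in t["vl_green"]],
            "vl_red": [float(v) for v in t["vl_red"]],
            "leakage_index": [float(v) for v in t["li"]],
            "li_30": float(self.li_30),
            "endpoint_min": float(self.leakage.endpoint_min),
            "median_caliber_px": (
                None if self.caliber is None else float(self.caliber.median_caliber_px)
            ),
            "parameters": self.config.as_dict(),
        }
        return out


def analyze_session(session: ImagingSession, config: RunConfig | None = None) -> SessionResult:
    """Run the full leakage + caliber analysis on one session."""
    cfg = config or RunConfig()
    field = session.field_mask

    meas = {"green": [], "red": []}
    for t, green, red in session.frames:
        ng = estimate_noise(green, field)
        nr = estimate_noise(red, field)
        mg, mr = segment_pair(
            green,
            red,
            ng,
            nr,
            k=cfg.k_leakage,
            field_mask=field,
            mode=cfg.mask_mode,
            min_object_px=cfg.min_object_px,
            max_hole_px=cfg.max_hole_px,
            smooth_sigma=cfg.smooth_sigma,
            exclusion_px=cfg.boundary_exclusion_px,
        )
        meas["green"].append(measure_mfi(green, mg, cfg.mfi_statistic))
        meas["red"].append(measure_mfi(red, mr, cfg.mfi_statistic))

    vl_green = vascular_leakage(meas["green"], mode=cfg.vl_mode)
    vl_red = vascular_leakage(meas["red"], mode=cfg.vl_mode)
    series = leakage_index(vl_green, vl_red, endpoint_min=cfg.endpoint_min)

    caliber = None
    caliber_time = None
    if cfg.measure_caliber and len(session.frames) > 1:
        # noise and selection referenced to the first post-injection green frame
        caliber_time, g1, _ = session.frames[1]
        params = cfg.caliber_params(g1.shape)
        if cfg.caliber_preprocess:
            from .caliber import preprocess_for_caliber

            img = preprocess_for_caliber(g1, params)
        else:
            img = g1.pixels
        noise1 = estimate_noise(img, field)
        caliber, _, _ = measure_caliber(
            g1, noise1, params, field_mask=field, preprocess=cfg.caliber_preprocess
        )

    mfi_rows = []
    vl_by = {"green": vl_green, "red": vl_red}
    li_by_time = dict(zip(series.table["time_min"], series.table["li"]))
    for ch in ("green", "red"):
        vl_t = dict(zip(vl_by[ch]["time_min"], vl_by[ch]["vl"]))
        for m in meas[ch]:
            for comp, mfi, n in (("in", m.mfi_in, m.n_in), ("out", m.mfi_out, m.n_out)):
                mfi_rows.append(
                    {
                        "subject": session.subject_id,
                        "session": session.session_key,
                        "time_min": m.time_min,
                        "channel": ch,
                        "compartment": comp,
                        "mfi": mfi,
                        "n_pixels": n,
                        "vascular_leakage": vl_t[m.time_min],
                        "leakage_index": li_by_time[m.time_min],
                        "median_caliber_px": (
                            caliber.median_caliber_px
                            if caliber is not None and ch == "green" and comp == "in"
                            and m.time_min == caliber_time
                            else np.nan
                        ),
                    }
                )
    mfi_table = pd.DataFrame(mfi_rows)[RESULT_COLUMNS]

    return SessionResult(
        subject=session.subject_id,
        session=session.session_key,
        leakage=series,
        mfi_table=mfi_table,
        caliber=caliber,
        result_table=mfi_table,
        config=cfg,
    )
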