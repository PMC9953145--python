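"""Loading, validation and persistence of dual-channel angiography sessions.

A session is an ordered series of paired green/red fundus frames acquired at
known minutes post-injection, with the pre-injection baseline keyed exactly at
t = 0.  Frames travel as single-plane grayscale TIFFs; 24-bit RGB exports are
reduced to the channel-appropriate plane on load (each export carries a single
fluorophore's signal, so plane extraction — not luminance conversion — is the
correct reduction).  The manifest is a plain-text YAML key-value file.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "CHANNELS",
    "RESULT_COLUMNS",
    "ChannelFrame",
    "ImagingSession",
    "circular_field_mask",
    "load_session",
    "write_session",
    "write_results",
    "read_results",
]

CHANNELS = ("green", "red")

#: canonical column order of the long-format result table
RESULT_COLUMNS = [
    "subject",
    "session",
    "time_min",
    "channel",
    "compartment",
    "mfi",
    "n_pixels",
    "vascular_leakage",
    "leakage_index",
    "median_caliber_px",
]

#: plane index of each fluorophore in an RGB export
_RGB_PLANE = {"green": 1, "red": 0}


@dataclass
class ChannelFrame:
    """One grayscale frame of one channel at one acquisition time.

    Parameters
    ----------
    pixels
        2-D array of finite, non-negative intensities (arbitrary units).
    channel
        ``"green"`` (leakage-detection dye) or ``"red"`` (reference dye).
    time_min
        Minutes relative to tracer injection; 0 is the pre-injection baseline.
    """

    pixels: np.ndarray
    channel: str
    time_min: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"frame must be 2-D, got shape {self.pixels.shape}")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not np.isfinite(self.pixels).all():
            raise ValueError(f"non-finite intensities in {self.channel} frame at t={self.time_min:g}")
        if (self.pixels < 0).any():
            raise ValueError(f"negative intensities in {self.channel} frame at t={self.time_min:g}")
        self.time_min = float(self.time_min)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImagingSession:
    """An ordered series of paired-channel frames from one imaging run.

    ``frames`` is a list of ``(time_min, green ChannelFrame, red ChannelFrame)``
    with strictly increasing times starting at 0.  ``field_mask`` optionally
    restricts analysis to the imaged circular field of view; when ``None`` the
    entire frame is analyzed.
    """

    subject_id: str
    session_key: str | float
    frames: list[tuple[float, ChannelFrame, ChannelFrame]]
    field_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("session has no frames")
        times = [t for t, _, _ in self.frames]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError(f"times must be strictly increasing, got {times}")
        if times[0] != 0:
            raise ValueError(f"first time point must be 0 (baseline), got {times[0]:g}")
        shape = self.frames[0][1].shape
        for t, green, red in self.frames:
            for fr, ch in ((green, "green"), (red, "red")):
                if fr.channel != ch:
                    raise ValueError(f"frame at t={t:g} in the {ch} slot is labelled {fr.channel!r}")
                if fr.time_min != t:
                    raise ValueError(f"{ch} frame time {fr.time_min:g} does not match slot time {t:g}")
            if green.shape != red.shape:
                raise ValueError(
                    f"shape mismatch between channels at t={t:g}: {green.shape} vs {red.shape}"
                )
            if green.shape != shape:
                raise ValueError(f"frame shape changed at t={t:g}: {green.shape} vs {shape}")
        if self.field_mask is not None:
            self.field_mask = np.asarray(self.field_mask, dtype=bool)
            if self.field_mask.shape != shape:
                raise ValueError("field_mask shape does not match frames")

    @property
    def times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.frames], dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0][1].shape


def circular_field_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disk of ``radius`` pixels about ``center`` (row, col)."""
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def _reduce_to_plane(arr: np.ndarray, channel: str, path: Path) -> np.ndarray:
    """Reduce an RGB(A) TIFF to the plane carrying ``channel``; pass grayscale through."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        return arr[..., _RGB_PLANE[channel]]
    raise ValueError(f"unsupported TIFF layout {arr.shape} in {path}")


def load_session(manifest_path: str | Path) -> ImagingSession:
    """Load and validate a session from its YAML manifest.

    The manifest lists ``subject``, ``session``, an optional circular
    ``field_mask`` (``center`` [row, col] and ``radius``), and one entry per
    time point naming the green and red TIFF files (paths relative to the
    manifest).  Raises ``ValueError`` for a missing channel, non-monotone
    times, or shape mismatches between pair members.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict) or "frames" not in spec:
        raise ValueError(f"manifest {manifest_path} has no 'frames' section")

    frames = []
    for entry in spec["frames"]:
        if "time_min" not in entry:
            raise ValueError(f"manifest entry without time_min: {entry}")
        t = float(entry["time_min"])
        pair = []
        for ch in CHANNELS:
            if ch not in entry or entry[ch] is None:
                raise ValueError(f"missing {ch} channel at t={t:g}")
            path = manifest_path.parent / entry[ch]
            if not path.exists():
                raise ValueError(f"missing {ch} channel at t={t:g}: file {path} not found")
            arr = _reduce_to_plane(tifffile.imread(path), ch, path)
            pair.append(ChannelFrame(arr, ch, t))
        frames.append((t, pair[0], pair[1]))

    field_mask = None
    fm = spec.get("field_mask")
    if fm:
        field_mask = circular_field_mask(
            frames[0][1].shape, tuple(float(v) for v in fm["center"]), float(fm["radius"])
        )

    return ImagingSession(
        subject_id=str(spec.get("subject", manifest_path.parent.name)),
        session_key=spec.get("session", "0"),
        frames=frames,
        field_mask=field_mask,
    )


def write_session(
    session: ImagingSession,
    out_dir: str | Path,
    field_mask_spec: dict | None = None,
    provenance: dict | None = None,
) -> Path:
    """Write a session as per-time-point TIFF pairs plus a YAML manifest.

    Files are named ``t<minutes>_green.tif`` / ``t<minutes>_red.tif``.  Pixel
    data round-trips bit-exactly through :func:`load_session`.  Returns the
    manifest path.  ``field_mask_spec`` records an analytic circle
    (``{"center": [r, c], "radius": ...}``) so the mask survives the round
    trip without a raster file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for t, green, red in session.frames:
        entry = {"time_min": float(t)}
        for fr in (green, red):
            name = f"t{t:g}_{fr.channel}.tif"
            tifffile.imwrite(out_dir / name, fr.pixels)
            entry[fr.channel] = name
        entries.append(entry)
    manifest = {
        "subject": session.subject_id,
        "session": session.session_key,
        "frames": entries,
    }
    if field_mask_spec is not None:
        manifest["field_mask"] = field_mask_spec
    if provenance is not None:
        manifest["provenance"] = provenance
    manifest_path = out_dir / "session.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


_SORT_KEYS = ["subject", "session", "time_min", "channel", "compartment"]


def _canonical(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("result table is empty")
    missing = [c for c in _SORT_KEYS if c not in table.columns]
    if missing:
        raise ValueError(f"result table lacks key columns {missing}")
    out = table.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULT_COLUMNS]
    out = out.sort_values(_SORT_KEYS, kind="mergesort").reset_index(drop=True)
    dup = out.duplicated(_SORT_KEYS)
    if dup.any():
        raise ValueError(f"duplicated result keys:\n{out.loc[dup, _SORT_KEYS]}")
    return out


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a long-format result table as CSV with canonical column and row order.

    Rows are sorted by (subject, session, time, channel, compartment) so
    identical data always produce identical bytes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _canonical(table).to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result CSV written by :func:`write_results`."""
    return pd.read_csv(path)
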