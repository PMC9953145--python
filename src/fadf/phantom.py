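"""Synthetic dual-tracer angiography phantoms with known ground truth.

Everything downstream of image acquisition — noise estimation, vessel
segmentation, ratiometric leakage statistics, caliber measurement — is
validated against scenes generated here: a stylized radial vascular tree on a
dark circular field of view, compartment concentrations from a two-compartment
linear kinetic model, and controllable imaging artifacts (per-time-point gain
drift, smooth clouding fields, additive Gaussian or Poisson noise).

The kinetic model is the smallest one reproducing the observed dye dynamics:
the detection tracer is cleared from blood (``c_in' = -k_clear * c_in``) while
permeating into the extravascular space (``c_ev' = k_perm * (c_in - c_ev)``),
giving the characteristic rise, ~10-min peak and decline of a semi-permeable
dextran; the high-molecular-weight reference tracer has both rates zero and
stays flat in both compartments.  The model has a closed-form solution, so it
doubles as an analytic oracle for the whole pipeline.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.draw import disk, polygon

from .io_session import ChannelFrame, ImagingSession, write_session

__all__ = [
    "KineticParams",
    "PhantomConfig",
    "VesselTree",
    "PhantomTruth",
    "solve_kinetics",
    "generate_vessel_tree",
    "render_session",
    "simulate_session",
    "write_truth",
    "DEFAULT_DETECTION_KINETICS",
    "DEFAULT_REFERENCE_KINETICS",
]

#: acquisition protocol time grid (minutes post-injection)
PROTOCOL_TIMES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


@dataclass(frozen=True)
class KineticParams:
    """Two-compartment kinetics of a single tracer.

    Parameters
    ----------
    k_perm
        Permeability rate constant across the vessel wall (1/min, >= 0).
        Zero models a non-leaking reference tracer.
    k_clear
        Intravascular (renal) clearance rate constant (1/min, >= 0).
    c0
        Initial intravascular concentration (arbitrary units, > 0).
    """

    k_perm: float
    k_clear: float = 0.0
    c0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_perm", "k_clear"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if not (np.isfinite(self.c0) and self.c0 > 0):
            raise ValueError(f"c0 must be finite and positive, got {self.c0}")


#: semi-permeable detection dextran: extravascular peak near 9 min, then decline
DEFAULT_DETECTION_KINETICS = KineticParams(k_perm=0.2, k_clear=0.05, c0=1.0)
#: non-leaking high-M.W. reference dextran: flat in both compartments
DEFAULT_REFERENCE_KINETICS = KineticParams(k_perm=0.0, k_clear=0.0, c0=1.0)


def solve_kinetics(params: KineticParams, times) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form compartment concentrations of one tracer.

    ``c_in(t) = c0 * exp(-k_clear t)`` and
    ``c_ev(t) = c0 * k_perm * exp(-k_perm t) * expm1((k_perm - k_clear) t) / (k_perm - k_clear)``,
    written in the numerically stable ``expm1`` form whose ``k_perm == k_clear``
    limit is ``c0 * k_perm * t * exp(-k_perm t)``.  Both curves are
    non-negative for all t >= 0.

    Parameters
    ----------
    params
        Tracer rate constants (validated non-negative on construction).
    times
        Sorted acquisition times in minutes, starting at 0.

    Returns
    -------
    (c_in, c_ev)
        Arrays of intravascular and extravascular concentrations.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if t[0] != 0:
        raise ValueError(f"times must start at 0, got {t[0]:g}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    kp, kc, c0 = params.k_perm, params.k_clear, params.c0
    c_in = c0 * np.exp(-kc * t)
    if kp == 0.0:
        c_ev = np.zeros_like(t)
    else:
        d = kp - kc
        if d == 0.0:
            growth = t
        else:
            growth = np.expm1(d * t) / d
        c_ev = c0 * kp * np.exp(-kp * t) * growth
    return c_in, np.maximum(c_ev, 0.0)


@dataclass(eq=False)
class PhantomConfig:
    """Scene, protocol and artifact parameters of one synthetic session.

    Geometry defaults (512 x 512, six trunks, four branch levels, 8-px root
    caliber decaying by 0.6 per level) give a tree covering roughly a tenth of
    a circular field of view, comparable to the vascular area fraction of a
    mouse fundus frame; the full-resolution 1536 x 1636 acquisition format is
    available by setting ``image_shape``.  Intensities are arbitrary units:
    ``baseline`` is the non-vascular background fluorescence, ``gain`` converts
    tracer concentration to intensity, and ``evs_dilution`` down-weights the
    extravascular signal for the dilution of leaked dye into tissue (keeps
    vessels brighter than the surround throughout the session, as observed).
    """

    image_shape: tuple[int, int] = (512, 512)
    tree_seed: int = 0
    n_branch_levels: int = 4
    root_width_px: float = 8.0
    width_decay: float = 0.6
    n_trunks: int = 6
    time_points_min: tuple[float, ...] = PROTOCOL_TIMES
    noise_sd: float = 25.0
    noise_model: str = "gaussian"  # or "poisson"
    noise_seed: int = 0
    drift_profile: tuple[float, ...] | None = None
    clouding: np.ndarray | None = None  # (n_times, H, W) multiplicative fields
    field_radius_frac: float = 0.48
    gain: float = 1900.0
    baseline: float = 100.0
    evs_dilution: float = 0.3
    bit_depth: int = 16

    def __post_init__(self) -> None:
        t = np.asarray(self.time_points_min, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time_points_min must be strictly increasing and start at 0")
        if self.n_branch_levels < 1:
            raise ValueError("n_branch_levels must be >= 1")
        if self.root_width_px < 1:
            raise ValueError("root_width_px must be >= 1")
        if not (0 < self.width_decay <= 1):
            raise ValueError("width_decay must be in (0, 1]")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.drift_profile is not None and len(self.drift_profile) != t.size:
            raise ValueError(
                f"drift_profile length {len(self.drift_profile)} != {t.size} time points"
            )

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.time_points_min, dtype=float)

    @property
    def drift(self) -> np.ndarray:
        if self.drift_profile is None:
            return np.ones(self.times.size)
        return np.asarray(self.drift_profile, dtype=float)


@dataclass(eq=False)
class VesselTree:
    """Rasterized ground-truth geometry of one phantom scene.

    ``vessel_mask`` and ``evs_mask`` are disjoint and partition the circular
    ``field_mask``.  ``level_map`` labels each vessel pixel with its branch
    level (-1 outside vessels), and ``segments`` records every drawn segment's
    endpoints, nominal width and length (Euclidean and chessboard/raster).
    """

    vessel_mask: np.ndarray
    evs_mask: np.ndarray
    field_mask: np.ndarray
    level_map: np.ndarray
    segments: pd.DataFrame
    config: PhantomConfig


def _build_segments(config: PhantomConfig, rng: np.random.Generator):
    h, w = config.image_shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_field = config.field_radius_frac * min(h, w)
    r_disc = max(2.0, float(config.root_width_px))
    levels = config.n_branch_levels
    seg_len = (0.97 * r_field - r_disc) / levels
    if seg_len < 2.0:
        min_dim = int(np.ceil((r_disc + 2.0 * levels) / (0.97 * config.field_radius_frac)))
        raise ValueError(
            f"image {config.image_shape} too small to contain the root disc and "
            f"{levels} branch levels; need min dimension >= {min_dim} px"
        )

    rows = []
    frontier = []
    for k in range(config.n_trunks):
        ang = 2 * np.pi * k / config.n_trunks + rng.uniform(-0.25, 0.25)
        frontier.append((cy + r_disc * np.sin(ang), cx + r_disc * np.cos(ang), ang))

    for level in range(levels):
        width = config.root_width_px * config.width_decay**level
        nxt = []
        for y0, x0, ang in frontier:
            length = seg_len * rng.uniform(0.85, 1.0)
            y1, x1 = y0 + length * np.sin(ang), x0 + length * np.cos(ang)
            rows.append(
                {
                    "level": level,
                    "y0": y0,
                    "x0": x0,
                    "y1": y1,
                    "x1": x1,
                    "width_px": width,
                    "length_px": float(np.hypot(y1 - y0, x1 - x0)),
                    "raster_length_px": float(max(abs(y1 - y0), abs(x1 - x0))),
                }
            )
            if level + 1 < levels:
                for sgn in (-1.0, 1.0):
                    nxt.append((y1, x1, ang + sgn * rng.uniform(0.2, 0.5)))
        frontier = nxt
    return pd.DataFrame(rows), (cy, cx, r_disc, r_field)


def generate_vessel_tree(config: PhantomConfig) -> VesselTree:
    """Rasterize a deterministic radial branching tree for ``config.tree_seed``.

    A central disc of radius ``max(2, root_width_px)`` anchors ``n_trunks``
    trunks; each segment spawns two children with jittered angles, widths
    decaying geometrically by ``width_decay`` per level.  The mask is clipped
    to the circular field of view.  Raises ``ValueError`` naming the minimum
    image size when the scene cannot fit.
    """
    rng = np.random.default_rng(config.tree_seed)
    segments, (cy, cx, r_disc, r_field) = _build_segments(config, rng)
    shape = tuple(config.image_shape)

    vessel = np.zeros(shape, dtype=bool)
    level_map = np.full(shape, -1, dtype=np.int16)

    rr, cc = disk((cy, cx), r_disc, shape=shape)
    vessel[rr, cc] = True
    level_map[rr, cc] = 0

    for row in segments.itertuples():
        half = row.width_px / 2.0
        dy, dx = row.y1 - row.y0, row.x1 - row.x0
        norm = np.hypot(dy, dx)
        ny, nx = -dx / norm, dy / norm
        ys = [row.y0 + ny * half, row.y1 + ny * half, row.y1 - ny * half, row.y0 - ny * half]
        xs = [row.x0 + nx * half, row.x1 + nx * half, row.x1 - nx * half, row.x0 - nx * half]
        rr, cc = polygon(ys, xs, shape=shape)
        sel = level_map[rr, cc] == -1
        vessel[rr, cc] = True
        level_map[rr[sel], cc[sel]] = row.level
        # junction cap keeps parent->child transitions connected
        rr, cc = disk((row.y0, row.x0), max(half, 1.0), shape=shape)
        sel = level_map[rr, cc] == -1
        vessel[rr, cc] = True
        level_map[rr[sel], cc[sel]] = row.level

    yy, xx = np.ogrid[: shape[0], : shape[1]]
    field_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_field**2
    vessel &= field_mask
    level_map[~field_mask] = -1
    evs = field_mask & ~vessel
    return VesselTree(vessel, evs, field_mask, level_map, segments, config)


@dataclass(eq=False)
class PhantomTruth:
    """Ground truth accompanying a rendered phantom session.

    ``curves`` holds the analytic compartment concentrations per channel on the
    session time grid (columns ``c_in_green``, ``c_ev_green``, ``c_in_red``,
    ``c_ev_red``); masks are the rasterized compartments of the scene.
    """

    vessel_mask: np.ndarray
    evs_mask: np.ndarray
    field_mask: np.ndarray
    level_map: np.ndarray
    segments: pd.DataFrame
    curves: pd.DataFrame
    kin_detection: KineticParams
    kin_reference: KineticParams
    config: PhantomConfig

    def expected_intensity(self, channel: str, i: int) -> tuple[float, float]:
        """Noise-free (vessel, EVS) intensity at time index ``i``, drift included."""
        cfg = self.config
        ci = self.curves[f"c_in_{channel}"].to_numpy()[i]
        ce = self.curves[f"c_ev_{channel}"].to_numpy()[i]
        d = cfg.drift[i]
        return (
            d * (cfg.baseline + cfg.gain * ci),
            d * (cfg.baseline + cfg.gain * cfg.evs_dilution * ce),
        )


def render_session(
    tree: VesselTree,
    kin_detection: KineticParams = DEFAULT_DETECTION_KINETICS,
    kin_reference: KineticParams = DEFAULT_REFERENCE_KINETICS,
    subject_id: str = "phantom",
    session_key: str | float = "0",
) -> tuple[ImagingSession, PhantomTruth]:
    """Render paired green/red frames for every protocol time point.

    Pixel model: ``drift(t) * clouding(t, x) * (baseline + gain * signal) +
    noise`` where ``signal`` is ``c_in(t)`` on vessel pixels and
    ``evs_dilution * c_ev(t)`` on extravascular pixels, zero outside the field
    of view.  Drift and clouding are shared by both channels (they model
    detector/optical effects, so they scale the background too).  Gaussian
    noise of ``noise_sd`` is added (or Poisson counts drawn) from
    ``noise_seed``, making renders bit-reproducible.  Intensities beyond the
    output bit depth are clipped with a warning.
    """
    cfg = tree.config
    times = cfg.times
    drift = cfg.drift
    if cfg.clouding is not None and len(cfg.clouding) != times.size:
        raise ValueError("clouding must provide one field per time point")

    ci_g, ce_g = solve_kinetics(kin_detection, times)
    ci_r, ce_r = solve_kinetics(kin_reference, times)
    curves = pd.DataFrame(
        {
            "time_min": times,
            "c_in_green": ci_g,
            "c_ev_green": ce_g,
            "c_in_red": ci_r,
            "c_ev_red": ce_r,
        }
    )

    rng = np.random.default_rng(cfg.noise_seed)
    vmax = float(2**cfg.bit_depth - 1)
    vessel = tree.vessel_mask
    evs = tree.evs_mask
    clipped = False

    frames = []
    for i, t in enumerate(times):
        pair = []
        for ch, ci, ce in (("green", ci_g, ce_g), ("red", ci_r, ce_r)):
            img = np.zeros(cfg.image_shape, dtype=float)
            img[vessel] = cfg.baseline + cfg.gain * ci[i]
            img[evs] = cfg.baseline + cfg.gain * cfg.evs_dilution * ce[i]
            img *= drift[i]
            if cfg.clouding is not None:
                img *= np.asarray(cfg.clouding[i], dtype=float)
            if cfg.noise_model == "poisson":
                img = rng.poisson(np.maximum(img, 0.0)).astype(float)
            elif cfg.noise_sd > 0:
                img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
            if img.max() > vmax:
                clipped = True
            img = np.clip(img, 0.0, vmax)
            pair.append(ChannelFrame(img, ch, t))
        frames.append((float(t), pair[0], pair[1]))

    if clipped:
        warnings.warn(f"rendered intensities exceeded {cfg.bit_depth}-bit range and were clipped")

    session = ImagingSession(subject_id, session_key, frames, field_mask=tree.field_mask)
    truth = PhantomTruth(
        vessel_mask=vessel,
        evs_mask=evs,
        field_mask=tree.field_mask,
        level_map=tree.level_map,
        segments=tree.segments,
        curves=curves,
        kin_detection=kin_detection,
        kin_reference=kin_reference,
        config=cfg,
    )
    return session, truth


def simulate_session(
    config: PhantomConfig | None = None,
    kin_detection: KineticParams = DEFAULT_DETECTION_KINETICS,
    kin_reference: KineticParams = DEFAULT_REFERENCE_KINETICS,
    subject_id: str = "phantom",
    session_key: str | float = "0",
) -> tuple[ImagingSession, PhantomTruth]:
    """Generate tree geometry and render a full session in one call."""
    config = config or PhantomConfig()
    tree = generate_vessel_tree(config)
    return render_session(tree, kin_detection, kin_reference, subject_id, session_key)


def write_truth(truth: PhantomTruth, out_dir: str | Path) -> None:
    """Persist ground truth: masks as 8-bit TIFF, curves as CSV, parameters as YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out_dir / "truth_vessel_mask.tif", truth.vessel_mask.astype(np.uint8) * 255)
    tifffile.imwrite(out_dir / "truth_evs_mask.tif", truth.evs_mask.astype(np.uint8) * 255)
    truth.curves.to_csv(out_dir / "truth_curves.csv", index=False)
    truth.segments.to_csv(out_dir / "truth_segments.csv", index=False)
    params = {
        "detection": {"k_perm": truth.kin_detection.k_perm, "k_clear": truth.kin_detection.k_clear, "c0": truth.kin_detection.c0},
        "reference": {"k_perm": truth.kin_reference.k_perm, "k_clear": truth.kin_reference.k_clear, "c0": truth.kin_reference.c0},
        "tree_seed": truth.config.tree_seed,
        "noise_seed": truth.config.noise_seed,
        "noise_sd": truth.config.noise_sd,
        "gain": truth.config.gain,
        "baseline": truth.config.baseline,
        "evs_dilution": truth.config.evs_dilution,
    }
    with open(out_dir / "truth_params.yaml", "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=False)


def write_phantom_session(
    session: ImagingSession, truth: PhantomTruth, out_dir: str | Path
) -> Path:
    """Write session TIFFs + manifest + ground truth to ``out_dir``."""
    cfg = truth.config
    h, w = cfg.image_shape
    spec = {
        "center": [(h - 1) / 2.0, (w - 1) / 2.0],
        "radius": cfg.field_radius_frac * min(h, w),
    }
    prov = {
        "tree_seed": cfg.tree_seed,
        "noise_seed": cfg.noise_seed,
        "k_perm": truth.kin_detection.k_perm,
        "k_clear": truth.kin_detection.k_clear,
        "k_perm_ref": truth.kin_reference.k_perm,
        "k_clear_ref": truth.kin_reference.k_clear,
    }
    manifest = write_session(session, out_dir, field_mask_spec=spec, provenance=prov)
    write_truth(truth, Path(out_dir) / "truth")
    return manifest
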