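"""Vessel caliber from skeletonized green-channel segmentations.

The caliber chain is: local contrast adjustment (sliding-window min/max
rescaling, correcting the bright chromatic rim at vessel edges) -> "fine
filter" (small median filter for impulse noise) -> 1-3 x SD threshold
segmentation (noise referenced to the first post-injection image of the
session) -> topological skeletonization -> skeletal diameter.  The diameter
at a skeleton pixel is twice its Euclidean distance to the nearest background
pixel; per-object and per-image summaries are medians over skeleton pixels.
Units are pixels throughout (frames carry no spatial calibration); an
optional micrometers-per-pixel factor converts the summaries.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import label
from skimage.morphology import skeletonize

from .io_session import ChannelFrame
from .segmentation import CompartmentMasks, NoiseEstimate, segment_vessels

__all__ = [
    "CaliberParams",
    "CaliberSummary",
    "preprocess_for_caliber",
    "segment_for_caliber",
    "skeletonize_vessels",
    "skeletal_diameter",
    "measure_caliber",
    "caliber_longitudinal",
]


@dataclass(frozen=True)
class CaliberParams:
    """Parameters of the caliber measurement chain.

    ``k_threshold`` multiplies the noise SD for vessel selection (recommended
    1-3; a value outside warns).  ``contrast_window_px`` is the side of the
    sliding min/max window — it should exceed the typical inter-vessel
    spacing so that every window sees both background and vessel signal.
    ``fine_filter_px`` is the (odd) median-filter kernel.  ``um_per_px``
    optionally converts reported diameters to micrometers.
    """

    k_threshold: float = 2.0
    contrast_window_px: int = 255
    fine_filter_px: int = 3
    um_per_px: float | None = None

    def __post_init__(self) -> None:
        if not (1.0 <= self.k_threshold <= 3.0):
            warnings.warn(f"caliber k={self.k_threshold:g} outside the recommended range 1-3")
        if self.fine_filter_px % 2 == 0 or self.fine_filter_px < 1:
            raise ValueError(f"fine_filter_px must be odd and >= 1, got {self.fine_filter_px}")
        if self.contrast_window_px < 3:
            raise ValueError("contrast_window_px must be >= 3")


def preprocess_for_caliber(
    frame: ChannelFrame | np.ndarray, params: CaliberParams = CaliberParams()
) -> np.ndarray:
    """Local contrast adjustment followed by the fine (median) filter.

    Each pixel is rescaled by the min/max over its ``contrast_window_px``
    window, mapping locally dark background toward 0 and vessels toward 1;
    windows with no intensity range (flat scenes) map to 0.5 by convention.
    A ``fine_filter_px`` median filter then removes impulse noise.  Raises
    when the window exceeds the image.
    """
    px = frame.pixels if isinstance(frame, ChannelFrame) else np.asarray(frame, dtype=float)
    px = np.asarray(px, dtype=float)
    win = params.contrast_window_px
    if win > min(px.shape):
        raise ValueError(
            f"contrast window {win} px exceeds image dimensions {px.shape}"
        )
    lmin = ndi.minimum_filter(px, size=win, mode="nearest")
    lmax = ndi.maximum_filter(px, size=win, mode="nearest")
    rng = lmax - lmin
    out = np.where(rng > 0, (px - lmin) / np.where(rng > 0, rng, 1.0), 0.5)
    if params.fine_filter_px > 1:
        out = ndi.median_filter(out, size=params.fine_filter_px, mode="nearest")
    return out


def segment_for_caliber(
    processed: np.ndarray,
    noise: NoiseEstimate,
    params: CaliberParams = CaliberParams(),
    field_mask: np.ndarray | None = None,
    **kwargs,
) -> CompartmentMasks:
    """Threshold a (processed) green frame with the caliber-range k.

    Same threshold form and morphological cleanup as the leakage-stage
    segmentation, but with k in the 1-3 range (default 2): caliber analysis
    favors sensitivity at vessel edges over specificity, since skeletal
    diameters are measured at vessel centers.  ``noise`` should come from the
    first post-injection image of the session.
    """
    return segment_vessels(
        processed,
        noise,
        k=params.k_threshold,
        field_mask=field_mask,
        k_range=(1.0, 3.0),
        **kwargs,
    )


def skeletonize_vessels(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-px-wide skeleton of each connected component, with object labels.

    Returns ``(skeleton, labels)``: a boolean topological skeleton (no 2x2
    all-true block) and an integer label image assigning each skeleton pixel
    to its connected component ("object").  An empty mask warns and returns
    empty arrays.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn("empty vessel mask: skeleton is empty")
        return np.zeros_like(mask), np.zeros(mask.shape, dtype=np.int32)
    # Lee's thinning leaves no 2x2 all-true block, unlike the default method
    skel = skeletonize(mask, method="lee")
    labels = label(mask, connectivity=2).astype(np.int32)
    return skel, np.where(skel, labels, 0)


@dataclass(eq=False)
class CaliberSummary:
    """Skeletal-diameter distribution of one frame.

    ``diameters_px`` holds the local diameter (2 x Euclidean distance to the
    nearest background pixel) at every skeleton pixel; ``per_object`` the
    per-component statistic; ``median_caliber_px`` the pooled image summary.
    """

    diameters_px: np.ndarray
    per_object: pd.DataFrame
    median_caliber_px: float
    n_skeleton_px: int
    n_objects: int
    um_per_px: float | None = None

    @property
    def median_caliber_um(self) -> float | None:
        if self.um_per_px is None:
            return None
        return self.median_caliber_px * self.um_per_px


def skeletal_diameter(
    mask: np.ndarray,
    skeleton: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    statistic: str = "median",
    um_per_px: float | None = None,
) -> CaliberSummary:
    """Skeletal diameters of a vessel mask.

    The local diameter at each skeleton pixel is twice the Euclidean distance
    transform of the mask there; each object's caliber is the ``statistic``
    (median default, mean selectable) over its skeleton pixels, and the image
    summary is the median over all skeleton pixels.  Diameters are bounded
    below by 1 px (a skeleton pixel is inside the mask) and above by the
    mask's largest inscribed disk.
    """
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    mask = np.asarray(mask, dtype=bool)
    if skeleton is None or labels is None:
        skeleton, labels = skeletonize_vessels(mask)
    if skeleton.any() and not (mask[skeleton]).all():
        raise ValueError("skeleton is not contained in the mask")
    if not skeleton.any():
        return CaliberSummary(
            np.empty(0), pd.DataFrame(columns=["object", "n_px", "diameter_px"]),
            float("nan"), 0, 0, um_per_px,
        )

    edt = ndi.distance_transform_edt(mask)
    diam = 2.0 * edt[skeleton]
    obj = labels[skeleton]
    per_object = (
        pd.DataFrame({"object": obj, "diameter_px": diam})
        .groupby("object")["diameter_px"]
        .agg(n_px="size", diameter_px=statistic)
        .reset_index()
    )
    return CaliberSummary(
        diameters_px=diam,
        per_object=per_object,
        median_caliber_px=float(np.median(diam)),
        n_skeleton_px=int(skeleton.sum()),
        n_objects=int(per_object.shape[0]),
        um_per_px=um_per_px,
    )


def measure_caliber(
    frame: ChannelFrame | np.ndarray,
    noise: NoiseEstimate,
    params: CaliberParams = CaliberParams(),
    field_mask: np.ndarray | None = None,
    preprocess: bool = True,
) -> tuple[CaliberSummary, CompartmentMasks, np.ndarray]:
    """Run the full caliber chain on one green frame.

    Returns ``(summary, masks, skeleton)``.  With ``preprocess=False`` the
    threshold is applied to the raw frame (useful for noiseless validation
    scenes where local normalization is degenerate).
    """
    img = frame.pixels if isinstance(frame, ChannelFrame) else np.asarray(frame, dtype=float)
    if preprocess:
        img = preprocess_for_caliber(img, params)
    masks = segment_for_caliber(img, noise, params, field_mask=field_mask)
    skeleton, labels = skeletonize_vessels(masks.vessel)
    summary = skeletal_diameter(masks.vessel, skeleton, labels, um_per_px=params.um_per_px)
    return summary, masks, skeleton


def caliber_longitudinal(records) -> pd.DataFrame:
    """Box-and-whisker-ready caliber table across sessions.

    ``records`` is an iterable of ``(session_key, CaliberSummary)``; sessions
    are not registered to each other — the table compares pooled
    distributions, not individual vessels.  Columns: session, n_skeleton_px,
    n_objects, median, q1, q3, min, max (pixels).
    """
    rows = []
    for key, summary in records:
        d = summary.diameters_px
        if d.size:
            q1, med, q3 = np.percentile(d, [25, 50, 75])
            lo, hi = float(d.min()), float(d.max())
        else:
            q1 = med = q3 = lo = hi = float("nan")
        rows.append(
            {
                "session": key,
                "n_skeleton_px": summary.n_skeleton_px,
                "n_objects": summary.n_objects,
                "median_caliber_px": float(med),
                "q1_px": float(q1),
                "q3_px": float(q3),
                "min_px": lo,
                "max_px": hi,
            }
        )
    if not rows:
        raise ValueError("no caliber records given")
    return pd.DataFrame(rows)
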