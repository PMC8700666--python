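"""Three-phase segmentation and ice localization.

The frozen product images show three well-separated grey-level modes (air,
ice, starch), so phase segmentation reduces to two grey thresholds. The
starch phase is then morphologically closed with a digitized Euclidean ball
(default radius 16 voxels) to build the *matrix* — the filled starch phase
including embedded crystals and small gaps — and the ice phase is split by
simple boolean logic into ice **inside** the matrix and ice **outside** it
(on the pore walls, in contact with air).

Morphological dilation/erosion by a Euclidean ball are evaluated through the
exact Euclidean distance transform (a voxel is in the dilation of X by a ball
of radius r iff its distance to X is <= r), which is equivalent to the
Minkowski operations with the digitized ball but much faster for large radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .volio import AIR, ICE_OUTSIDE, ICE_INSIDE, STARCH, GreyVolume, LabelVolume

__all__ = [
    "ThresholdPair",
    "SegmentationResult",
    "DegenerateHistogramError",
    "estimate_thresholds",
    "segment_phases",
    "close_matrix",
    "partition_ice",
    "segment",
]

# temporary 3-phase codes used before ice localization
_P_AIR, _P_ICE, _P_STARCH = 0, 1, 2


class DegenerateHistogramError(ValueError):
    """Histogram does not show three separable modes; pass manual thresholds."""


@dataclass(frozen=True)
class ThresholdPair:
    t_air_ice: float
    t_ice_starch: float

    def __post_init__(self) -> None:
        if not self.t_air_ice < self.t_ice_starch:
            raise ValueError("thresholds must satisfy t_air_ice < t_ice_starch")


@dataclass
class SegmentationResult:
    labels: LabelVolume
    thresholds: ThresholdPair | None
    closing_radius_vx: int
    matrix_mask: np.ndarray


def _count_modes(grey: np.ndarray, nbins: int = 256) -> int:
    """Count detectable modes in a smoothed 256-bin histogram."""
    hist, _ = np.histogram(grey, bins=nbins)
    smooth = ndimage.gaussian_filter1d(hist.astype(float), 3.0, mode="constant")
    prominence = 0.01 * smooth.max()
    from scipy.signal import find_peaks

    # pad so modes at the histogram ends still count as peaks
    peaks, _ = find_peaks(np.pad(smooth, 1), prominence=prominence)
    return len(peaks)


def estimate_thresholds(grey: GreyVolume, nbins: int = 256) -> ThresholdPair:
    """Estimate the two phase thresholds from the grey-level histogram.

    Default method: three-class within-class variance minimization
    (multi-Otsu) on a 256-bin histogram. If the histogram does not show three
    detectable modes (constant volume, unfrozen air/starch-only sample),
    :class:`DegenerateHistogramError` is raised and manual thresholds should
    be supplied instead.
    """
    data = grey.data
    if np.ptp(data) == 0:
        raise DegenerateHistogramError("constant volume: no modes to separate")
    if _count_modes(data) < 3:
        raise DegenerateHistogramError(
            "fewer than three detectable histogram modes; supply manual thresholds"
        )
    try:
        t1, t2 = threshold_multiotsu(data, classes=3, nbins=nbins)
    except ValueError as exc:  # fewer distinct values than classes
        raise DegenerateHistogramError(str(exc)) from exc
    return ThresholdPair(float(t1), float(t2))


def segment_phases(grey: GreyVolume, thresholds: ThresholdPair) -> np.ndarray:
    """Threshold into three phases: air < t_air_ice <= ice < t_ice_starch <= starch.

    Boundaries are half-open, lower-inclusive on the brighter class (a voxel
    exactly at a threshold belongs to the brighter phase).
    """
    data = grey.data
    out = np.full(data.shape, _P_AIR, dtype=np.uint8)
    out[data >= thresholds.t_air_ice] = _P_ICE
    out[data >= thresholds.t_ice_starch] = _P_STARCH
    return out


def _ball_dilate(mask: np.ndarray, radius_vx: int) -> np.ndarray:
    if radius_vx == 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= radius_vx


def _ball_erode(mask: np.ndarray, radius_vx: int) -> np.ndarray:
    if radius_vx == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(mask)
    return dist > radius_vx


def close_matrix(starch_mask: np.ndarray, radius_vx: int = 16) -> np.ndarray:
    """Morphological closing of the starch phase with a Euclidean ball.

    Fills cavities (embedded ice crystals) and bridges gaps narrower than the
    ball, producing the *matrix* mask. The volume is padded with background by
    ``radius_vx`` voxels before dilation and cropped after erosion, so no
    artificial matrix is created at the volume faces. Closing is extensive
    (output contains the input) and idempotent.
    """
    if radius_vx < 0:
        raise ValueError("radius_vx must be >= 0")
    if radius_vx == 0:
        return starch_mask.copy()
    r = radius_vx
    padded = np.pad(starch_mask, r, mode="constant", constant_values=False)
    closed = _ball_erode(_ball_dilate(padded, r), r)
    closed = closed[r:-r, r:-r, r:-r]
    return closed | starch_mask  # guard extensivity at the faces


def partition_ice(ice_mask: np.ndarray, matrix_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split ice into (inside, outside) the closed matrix by and/not logic."""
    if ice_mask.shape != matrix_mask.shape:
        raise ValueError("masks must share shape")
    ice_inside = ice_mask & matrix_mask
    ice_outside = ice_mask & ~matrix_mask
    return ice_inside, ice_outside


@dataclass(frozen=True)
class SegmentationConfig:
    """Settings for the full segmentation chain.

    ``thresholds`` may be ``"auto"`` (multi-Otsu), a ``(t1, t2)`` pair, or a
    single value for unfrozen two-phase volumes (air/starch, no ice).
    """

    thresholds: str | tuple[float, float] | float = "auto"
    closing_radius_vx: int = 16


def segment(grey: GreyVolume, config: SegmentationConfig | None = None) -> SegmentationResult:
    """Full chain: threshold -> close starch -> localize ice.

    Returns a :class:`SegmentationResult` whose labels use the package-wide
    phase codes. With a single manual threshold, the volume is treated as
    two-phase (air/starch) and contains no ice.
    """
    config = config or SegmentationConfig()
    spec_t = config.thresholds
    if isinstance(spec_t, str):
        if spec_t != "auto":
            raise ValueError(f"unknown threshold mode {spec_t!r}")
        thresholds = estimate_thresholds(grey)
        phases = segment_phases(grey, thresholds)
    elif np.isscalar(spec_t):
        thresholds = None
        phases = np.where(grey.data >= float(spec_t), _P_STARCH, _P_AIR).astype(np.uint8)
    else:
        t1, t2 = spec_t
        thresholds = ThresholdPair(float(t1), float(t2))
        phases = segment_phases(grey, thresholds)

    starch = phases == _P_STARCH
    ice = phases == _P_ICE
    matrix = close_matrix(starch, config.closing_radius_vx)
    ice_in, ice_out = partition_ice(ice, matrix)

    labels = np.full(grey.shape, AIR, dtype=np.uint8)
    labels[starch] = STARCH
    labels[ice_in] = ICE_INSIDE
    labels[ice_out] = ICE_OUTSIDE
    return SegmentationResult(
        labels=LabelVolume(labels, grey.voxel_size),
        thresholds=thresholds,
        closing_radius_vx=config.closing_radius_vx,
        matrix_mask=matrix,
    )
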