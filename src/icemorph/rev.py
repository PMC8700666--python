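"""Representative elementary volume (REV) analysis.

A phase fraction measured on a sub-volume is only meaningful if the
sub-volume is large enough to be representative of the whole microstructure.
The REV curve tracks the mean phase fraction of centered cubic sub-volumes
of increasing edge length; the smallest representative size is the smallest
edge from which the curve stays inside a tolerance band around the
full-volume reference value (by default the reference mean ± its
across-replicate standard deviation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .volio import LabelVolume, PHASE_CODES, crop_subvolume

__all__ = ["RevCurve", "rev_curve", "smallest_representative_size"]

log = logging.getLogger(__name__)


@dataclass
class RevCurve:
    sizes: list[int]                 # cube edges, voxels, strictly increasing
    mean_fraction: np.ndarray        # mean over volumes, per size
    per_volume: np.ndarray           # (n_sizes, n_volumes) fractions, NaN if skipped
    reference_mean: float            # mean full-volume fraction
    reference_std: float             # std across volumes (0 when n=1)
    phase: str


def _phase_codes(phase) -> list[int]:
    if isinstance(phase, (str, int, np.integer)):
        phase = (phase,)
    return [PHASE_CODES[p] if isinstance(p, str) else int(p) for p in phase]


def _fraction(labels: LabelVolume, codes: list[int]) -> float:
    return float(np.isin(labels.data, codes).mean())


def rev_curve(volumes: list[LabelVolume], phase, sizes: list[int]) -> RevCurve:
    """Phase-fraction convergence over centered cubic sub-volumes.

    For each size, a single centered cube is cropped from each volume and the
    phase fraction computed; sizes that do not fit a given volume are skipped
    for that volume with a logged notice. The reference is the mean ± std of
    the fraction over the full volumes.
    """
    if not volumes:
        raise ValueError("need at least one volume")
    sizes = sorted(set(int(s) for s in sizes))
    if any(s < 1 for s in sizes):
        raise ValueError("sizes must be >= 1")
    codes = _phase_codes(phase)

    per_volume = np.full((len(sizes), len(volumes)), np.nan)
    for j, vol in enumerate(volumes):
        center = tuple((n - 1) // 2 for n in vol.shape)
        for i, size in enumerate(sizes):
            if any(size > n for n in vol.shape):
                log.info("size %d does not fit volume %d %s; skipped", size, j, vol.shape)
                continue
            sub = crop_subvolume(vol, center, size)
            per_volume[i, j] = _fraction(sub, codes)
    if np.isnan(per_volume).all(axis=1).all():
        raise ValueError("no admissible sub-volume size for any volume")
    if np.isnan(per_volume).all(axis=1).any():
        bad = [s for s, row in zip(sizes, per_volume) if np.isnan(row).all()]
        raise ValueError(f"sizes {bad} fit no volume")

    full = np.array([_fraction(v, codes) for v in volumes])
    with np.errstate(invalid="ignore"):
        mean_fraction = np.nanmean(per_volume, axis=1)
    return RevCurve(
        sizes=sizes,
        mean_fraction=mean_fraction,
        per_volume=per_volume,
        reference_mean=float(full.mean()),
        reference_std=float(full.std(ddof=0)) if len(volumes) > 1 else 0.0,
        phase=str(phase),
    )


def smallest_representative_size(curve: RevCurve, tolerance: float | str = "std") -> int | None:
    """Smallest size from which the curve stays within tolerance of the reference.

    ``tolerance`` is an absolute fraction band, or ``"std"`` for the
    reference ± one across-replicate standard deviation band. Returns
    ``None`` if no size qualifies.
    """
    if isinstance(tolerance, str):
        if tolerance != "std":
            raise ValueError(f"unknown tolerance mode {tolerance!r}")
        band = curve.reference_std
    else:
        band = float(tolerance)
    inside = np.abs(curve.mean_fraction - curve.reference_mean) <= band
    # qualify only if this size and every larger one are inside the band
    ok_from_here = np.logical_and.accumulate(inside[::-1])[::-1]
    for size, ok in zip(curve.sizes, ok_from_here):
        if ok:
            return size
    return None
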