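"""Count-curve persistence analysis of crista geometry.

The crista membrane plus intracristal space of a single mitochondrion is
dilated (or eroded) in subpixel steps; after every step the fuzzy state is
thresholded at 0.5 and the number of holes (dilation) or objects (erosion)
is counted.  The count-versus-iteration curve is an indirect shape
descriptor:

* the smoothed curve's **max location** is the filtration depth at which
  the most membrane surface comes into contact, i.e. half the average
  minimum distance across the region being dilated (inter-crista distance)
  or eroded (crista width);
* its **FWHM** grows with surface roughness/curvature, because uneven
  membranes make features appear earlier and persist longer.

Hole counting follows the bounded-complement convention: the binarized
dilation mask is clipped to the mitochondrion mask, inverted, and its
26-connected components are counted; one is subtracted for the component
that always surrounds the organelle.  Object counting after erosion counts
26-connected foreground components directly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import nan

import numpy as np
from scipy import ndimage

from .volumes_io import (
    LabelVolume,
    RunConfig,
    ValidationError,
    connectivity_structure,
)
from .subpixel_morphology import binarize, make_state, subpixel_step

MODES = ("dilation_holes", "erosion_objects")


@dataclass(frozen=True)
class CountCurve:
    """Per-iteration feature counts of one persistence run.

    ``counts[0]`` is the count before any morphology is applied.
    """

    mode: str
    lambda_step: float
    counts: np.ndarray           # int, length n_iters + 1
    smoothed: np.ndarray         # float, same length
    mito_id: int = 0
    voxel_size_nm: float = 5.0

    @property
    def max_raw_count(self) -> int:
        return int(self.counts.max()) if self.counts.size else 0


@dataclass(frozen=True)
class CurveSummary:
    """Max location and FWHM of a smoothed count curve, in iterations and nm."""

    mode: str
    mito_id: int
    max_location_iters: float
    max_location_rounds: float
    fwhm_iters: float
    fwhm_nm: float
    distance_nm: float
    half_distance_nm: float
    valid: bool
    truncated: bool


def count_holes(mask: np.ndarray, bounds: np.ndarray, connectivity: int = 26) -> int:
    """Number of cavities of ``mask`` once clipped to ``bounds``.

    Components of the inverted, bounds-clipped mask are counted with the
    given connectivity; the ever-present outer background component is
    subtracted and the result floored at zero.
    """
    mask = np.asarray(mask, dtype=bool)
    bounds = np.asarray(bounds, dtype=bool)
    if mask.shape != bounds.shape:
        raise ValidationError(f"shape mismatch: {mask.shape} vs {bounds.shape}")
    inverted = ~(mask & bounds)
    _, n = ndimage.label(inverted, structure=connectivity_structure(connectivity))
    return max(0, n - 1)


def count_objects(mask: np.ndarray, connectivity: int = 26) -> int:
    """Number of connected foreground components."""
    mask = np.asarray(mask, dtype=bool)
    _, n = ndimage.label(mask, structure=connectivity_structure(connectivity))
    return int(n)


def persistence_curve(
    instance: LabelVolume,
    mode: str,
    config: RunConfig | None = None,
    max_full_rounds: int | None = None,
    mito_id: int = 0,
) -> CountCurve:
    """Run the subpixel filtration on one mitochondrion and count per step.

    The seed is CM union ICS (labels 2 and 3) as a 0/1 field; the bounding
    mask for hole counting is the whole organelle (labels 1-3).  The fuzzy
    state carries over between iterations; only its 0.5-binarization is
    counted.  The run stops early once the fuzzy state reaches a fixed
    point (the remaining counts are constant by definition).
    """
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}")
    config = config or RunConfig()
    if max_full_rounds is None:
        max_full_rounds = config.max_full_rounds
    seed = instance.membrane_seed
    bounds = instance.mito_mask
    morph_mode = "dilation" if mode == "dilation_holes" else "erosion"
    state = make_state(seed, morph_mode, config.lambda_step, instance.voxel_size_nm)

    def _count(binary: np.ndarray) -> int:
        if mode == "dilation_holes":
            return count_holes(binary, bounds, config.connectivity)
        return count_objects(binary, config.connectivity)

    n_steps = max_full_rounds * config.iters_per_round
    counts = np.zeros(n_steps + 1, dtype=np.int64)
    counts[0] = _count(binarize(state.grid, config.binarize_threshold))
    for i in range(1, n_steps + 1):
        prev = state.grid.values
        state = subpixel_step(state)
        if np.array_equal(state.grid.values, prev):  # fixed point: pad and stop
            counts[i:] = counts[i - 1]
            break
        counts[i] = _count(binarize(state.grid, config.binarize_threshold))
    smoothed = ndimage.gaussian_filter1d(
        counts.astype(np.float64), sigma=config.smoothing_sigma_iters, mode="nearest"
    )
    return CountCurve(
        mode=mode,
        lambda_step=config.lambda_step,
        counts=counts,
        smoothed=smoothed,
        mito_id=mito_id,
        voxel_size_nm=instance.voxel_size_nm,
    )


def _interp_crossing(smoothed: np.ndarray, i: int, j: int, level: float) -> float:
    """Linear interpolation of the index where the curve crosses ``level``
    between samples i and j (j = i +/- 1)."""
    yi, yj = smoothed[i], smoothed[j]
    if yj == yi:
        return float(j)
    return i + (level - yi) / (yj - yi) * (j - i)


def summarize_curve(
    curve: CountCurve,
    config: RunConfig | None = None,
    voxel_size_nm: float | None = None,
) -> CurveSummary:
    """Extract max location and FWHM from the smoothed curve.

    Only iterations strictly beyond ``skip_subpixel_rounds`` (half a full
    round by default) are searched, as the earliest iterations are noise
    dominated.  Ties at the maximum resolve to the smallest iteration.
    Half-maximum crossings are located by linear interpolation; if the
    right crossing is never reached the summary is flagged ``truncated``.
    """
    config = config or RunConfig()
    if voxel_size_nm is None:
        voxel_size_nm = curve.voxel_size_nm
    lam = curve.lambda_step
    sm = curve.smoothed
    start = config.skip_subpixel_rounds + 1
    if start >= sm.size or not np.any(sm[start:] > 0):
        return CurveSummary(
            mode=curve.mode, mito_id=curve.mito_id,
            max_location_iters=nan, max_location_rounds=nan,
            fwhm_iters=nan, fwhm_nm=nan, distance_nm=nan, half_distance_nm=nan,
            valid=False, truncated=False,
        )
    max_idx = start + int(np.argmax(sm[start:]))
    peak = sm[max_idx]
    half = peak / 2.0

    # left crossing: walk down from the peak within the searched range
    left = float(start)
    for i in range(max_idx - 1, start - 1, -1):
        if sm[i] < half:
            left = _interp_crossing(sm, i, i + 1, half)
            break
    # right crossing: walk up from the peak
    truncated = True
    right = float(sm.size - 1)
    for i in range(max_idx + 1, sm.size):
        if sm[i] < half:
            right = _interp_crossing(sm, i - 1, i, half)
            truncated = False
            break
    fwhm_iters = right - left
    rounds = max_idx * lam
    return CurveSummary(
        mode=curve.mode,
        mito_id=curve.mito_id,
        max_location_iters=float(max_idx),
        max_location_rounds=rounds,
        fwhm_iters=fwhm_iters,
        fwhm_nm=fwhm_iters * lam * voxel_size_nm,
        distance_nm=2.0 * rounds * voxel_size_nm,
        half_distance_nm=rounds * voxel_size_nm,
        valid=True,
        truncated=truncated,
    )


def apply_validity_filters(
    summary: CurveSummary,
    curve: CountCurve,
    cm_volume_voxels: int,
    ics_volume_voxels: int,
) -> CurveSummary:
    """Apply the inclusion criteria for population statistics.

    Inter-crista distance (dilation/hole mode) requires a maximum raw hole
    count of at least 1 — there must be distinct membrane branches to
    measure between.  Crista width (erosion/object mode) requires both a
    non-empty crista membrane and a non-empty intracristal space.
    """
    valid = summary.valid
    if curve.mode == "dilation_holes":
        valid = valid and curve.max_raw_count >= 1
    else:
        valid = valid and cm_volume_voxels > 0 and ics_volume_voxels > 0
    return replace(summary, valid=valid)
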