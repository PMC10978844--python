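"""Multiplanar 2D-to-3D segmentation fusion.

A 3D volume is resliced into nine stacks of 2D images whose plane normals
are pairwise at least 45 degrees apart (the three axis-aligned planes plus
the six axis-pair diagonals).  A pluggable per-slice classifier turns each
stack into per-pixel class scores; the nine probabilistic stacks are
resampled back to the canonical grid, averaged voxel-wise (weighting out
samples that fell outside a stack's field of view), renormalised, and
arg-maxed into a single 3D labelling.  Structures ambiguous in one slicing
direction are usually unambiguous in another, so averaging acts as a
majority vote that suppresses independent per-plane errors.

The classifier itself is outside this module's scope: anything callable
that maps a resliced 2D stack to a :class:`ProbabilityStack` plugs in.
:func:`synthetic_predictor` provides a noisy oracle for testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np
from scipy import ndimage

from .volumes_io import LabelVolume, ValidationError

N_CLASSES = 4


@dataclass(frozen=True)
class PlaneSpec:
    """One reslicing orientation.

    ``rotation`` is a right-handed orthonormal matrix whose rows are the
    reslicing-frame axes expressed in canonical (z, y, x) coordinates; row
    0 is the slice normal.
    """

    id: int
    normal: np.ndarray
    rotation: np.ndarray


@dataclass(frozen=True)
class ProbabilityStack:
    """Per-plane class scores: array (slice, row, col, class) in [0, 1]."""

    plane: PlaneSpec
    probs: np.ndarray
    weight: np.ndarray | None = None  # in-volume support of each sample

    def __post_init__(self) -> None:
        p = np.asarray(self.probs)
        if p.ndim != 4:
            raise ValidationError("probs must be 4D (slice, row, col, class)")
        sums = p.sum(axis=-1)
        support = sums > 1e-6  # out-of-volume samples may carry zero mass
        if support.any() and not np.allclose(sums[support], 1.0, atol=1e-6):
            raise ValidationError("class scores must sum to 1 per pixel")


def _orthonormal_frame(normal: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal basis with the given first row."""
    n = np.asarray(normal, dtype=np.float64)
    n = n / np.linalg.norm(n)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, n)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    rot = np.stack([n, u, v])
    if np.linalg.det(rot) < 0:
        rot = np.stack([n, v, u])
    return rot


#: the canonical set of nine pairwise->=45-degree normals, (z, y, x) order
_NINE_NORMALS = [
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 0, 1),
    (1, 0, -1),
    (1, 1, 0),
    (1, -1, 0),
]


def nine_planes() -> list[PlaneSpec]:
    """The three axis-aligned plus six diagonal reslicing planes."""
    specs = []
    for i, raw in enumerate(_NINE_NORMALS):
        n = np.asarray(raw, dtype=np.float64)
        n /= np.linalg.norm(n)
        if i == 0:
            rot = np.eye(3)
        else:
            rot = _orthonormal_frame(n)
        specs.append(PlaneSpec(id=i, normal=n, rotation=rot))
    return specs


def _reslice_geometry(shape: tuple[int, int, int]) -> tuple[int, np.ndarray, float]:
    out_side = int(np.ceil(sqrt(sum(s**2 for s in shape)))) + 1
    # match the parity of the leading axis so axis-aligned reslicing uses
    # integer shifts (no rounding ambiguity under nearest interpolation)
    if (out_side - shape[0]) % 2:
        out_side += 1
    c_in = (np.asarray(shape, dtype=np.float64) - 1) / 2.0
    c_out = (out_side - 1) / 2.0
    return out_side, c_in, c_out


def reslice(
    volume: np.ndarray,
    plane: PlaneSpec,
    interpolation: str = "linear",
    return_weight: bool = False,
):
    """Resample a volume into a plane's frame (axis 0 = slice index).

    The output cube is large enough to contain the rotated volume; nearest
    interpolation is for label volumes, linear for grayscale/probability
    volumes.  With ``return_weight=True`` a second array gives each output
    sample's in-volume support in [0, 1].
    """
    if interpolation not in ("nearest", "linear"):
        raise ValidationError(f"unknown interpolation {interpolation!r}")
    order = 0 if interpolation == "nearest" else 1
    volume = np.asarray(volume)
    out_side, c_in, c_out = _reslice_geometry(volume.shape)
    matrix = plane.rotation.T  # plane-frame coords -> canonical coords
    offset = c_in - matrix @ np.full(3, c_out)
    out = ndimage.affine_transform(
        volume.astype(np.float64),
        matrix,
        offset=offset,
        output_shape=(out_side,) * 3,
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if order == 0:
        out = out.astype(volume.dtype)
    if not return_weight:
        return out
    weight = ndimage.affine_transform(
        np.ones(volume.shape),
        matrix,
        offset=offset,
        output_shape=(out_side,) * 3,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return out, weight


def reslice_back(
    stack_channel: np.ndarray, plane: PlaneSpec, canonical_shape: tuple[int, int, int]
) -> np.ndarray:
    """Resample one plane-frame channel back onto the canonical grid."""
    _, c_in, c_out = _reslice_geometry(canonical_shape)
    matrix = plane.rotation  # canonical coords -> plane-frame coords
    offset = np.full(3, c_out) - matrix @ c_in
    return ndimage.affine_transform(
        stack_channel,
        matrix,
        offset=offset,
        output_shape=canonical_shape,
        order=1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )


def fuse(
    stacks: list[ProbabilityStack],
    canonical_shape: tuple[int, int, int],
    voxel_size_nm: float = 5.0,
) -> LabelVolume:
    """Average per-plane class scores on the canonical grid and argmax.

    Each stack's channels are linearly resampled back to the canonical
    frame; out-of-view samples contribute zero weight rather than a
    background vote.  Scores are renormalised before the argmax.
    """
    if not stacks:
        raise ValidationError("at least one probability stack is required")
    n_classes = stacks[0].probs.shape[-1]
    acc = np.zeros((*canonical_shape, n_classes))
    wsum = np.zeros(canonical_shape)
    for stack in stacks:
        w = stack.weight
        if w is None:
            w = np.ones(stack.probs.shape[:3])
        for c in range(n_classes):
            acc[..., c] += reslice_back(
                stack.probs[..., c] * w, stack.plane, canonical_shape
            )
        wsum += reslice_back(w, stack.plane, canonical_shape)
    covered = wsum > 1e-6
    acc[covered] /= wsum[covered][..., np.newaxis]
    labels = np.where(covered, np.argmax(acc, axis=-1), 0).astype(np.uint8)
    return LabelVolume(labels, voxel_size_nm)


def synthetic_predictor(
    label_stack: np.ndarray,
    noise_rate: float,
    rng_seed: int,
    plane: PlaneSpec,
    n_classes: int = N_CLASSES,
    weight: np.ndarray | None = None,
) -> ProbabilityStack:
    """Noisy oracle classifier standing in for a trained 2D model.

    Ground-truth labels become one-hot scores; with probability
    ``noise_rate`` a pixel's vote is flipped to a uniformly chosen wrong
    class.  Deterministic under ``rng_seed``.
    """
    if not (0 <= noise_rate < 0.5):
        raise ValidationError("noise_rate must be in [0, 0.5)")
    labels = np.asarray(label_stack).astype(np.int64)
    rng = np.random.default_rng(rng_seed)
    flip = rng.random(labels.shape) < noise_rate
    if flip.any():
        shift = rng.integers(1, n_classes, size=labels.shape)
        labels = np.where(flip, (labels + shift) % n_classes, labels)
    probs = np.eye(n_classes, dtype=np.float64)[labels]
    return ProbabilityStack(plane=plane, probs=probs, weight=weight)


def multiplanar_segment(
    truth: LabelVolume,
    noise_rate: float,
    rng_seed: int,
    planes: list[PlaneSpec] | None = None,
) -> LabelVolume:
    """End-to-end synthetic pipeline: reslice, predict per plane, fuse."""
    planes = planes if planes is not None else nine_planes()
    stacks = []
    for i, plane in enumerate(planes):
        resliced, w = reslice(truth.labels, plane, "nearest", return_weight=True)
        stacks.append(
            synthetic_predictor(
                resliced, noise_rate, rng_seed + 1000 * i, plane, weight=w
            )
        )
    return fuse(stacks, truth.shape, truth.voxel_size_nm)
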