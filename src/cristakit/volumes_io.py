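"""Label-volume containers, configuration, and file I/O.

Volumes are 3D arrays indexed ``(z, y, x)`` with four voxel classes:

======  ==========================
label   structure
======  ==========================
0       background (cytosol)
1       mitochondrion interior (matrix + boundary membrane)
2       crista membrane (CM)
3       intracristal space (ICS)
======  ==========================

The *mitochondrion mask* is defined as ``labels >= 1``: the three internal
structures are mutually exclusive and nested inside the organelle.  Voxels
are isotropic with edge length ``voxel_size_nm`` (default 5 nm, the scale of
typical FIB-SEM acquisitions of brain tissue).

Supported on-disk formats are multi-page TIFF (uint8, one page per z slice)
and HDF5 (a 3D integer dataset named ``labels`` with attribute
``voxel_size_nm``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml
from scipy import ndimage

logger = logging.getLogger(__name__)

VALID_LABELS = (0, 1, 2, 3)
DEFAULT_VOXEL_SIZE_NM = 5.0

#: 26-connectivity structuring element used throughout the package.
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class ValidationError(ValueError):
    """Raised when a volume violates the label-volume contract."""


@dataclass(frozen=True)
class LabelVolume:
    """A validated 3D class-label volume with isotropic voxels.

    Parameters
    ----------
    labels : ndarray of int, shape (nz, ny, nx)
        Per-voxel class labels in {0, 1, 2, 3}.
    voxel_size_nm : float
        Isotropic voxel edge length in nanometres (> 0).
    validation_warnings : int
        Number of CM/ICS voxels found outside any region adjacent to
        mitochondrion interior (filled by :func:`validate_labels`).
    """

    labels: np.ndarray
    voxel_size_nm: float = DEFAULT_VOXEL_SIZE_NM
    validation_warnings: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValidationError(f"label volume must be 3D, got {arr.ndim}D")
        if self.voxel_size_nm <= 0:
            raise ValidationError("voxel_size_nm must be > 0")
        bad = np.setdiff1d(np.unique(arr), VALID_LABELS)
        if bad.size:
            raise ValidationError(f"invalid label {bad[0]}: labels must be in {VALID_LABELS}")
        object.__setattr__(self, "labels", arr)

    # -- derived masks -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def mito_mask(self) -> np.ndarray:
        """Binary mask of the whole organelle (labels 1, 2 or 3)."""
        return self.labels > 0

    @property
    def cm_mask(self) -> np.ndarray:
        return self.labels == 2

    @property
    def ics_mask(self) -> np.ndarray:
        return self.labels == 3

    @property
    def membrane_seed(self) -> np.ndarray:
        """CM union ICS — the seed of every persistence filtration."""
        return self.labels >= 2

    @property
    def voxel_volume_nm3(self) -> float:
        return float(self.voxel_size_nm) ** 3


@dataclass(frozen=True)
class ScalarGrid:
    """A 3D field of values in [0, 1]: the state of subpixel morphology."""

    values: np.ndarray
    voxel_size_nm: float = DEFAULT_VOXEL_SIZE_NM

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValidationError("scalar grid must be 3D")
        if self.voxel_size_nm <= 0:
            raise ValidationError("voxel_size_nm must be > 0")
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            raise ValidationError("scalar grid values must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RunConfig:
    """Global analysis parameters.

    ``lambda_step`` must divide 1 exactly so that a *full round* of
    morphology (one voxel layer added or removed) is a whole number of
    subpixel iterations.
    """

    lambda_step: float = 0.1
    binarize_threshold: float = 0.5
    skip_subpixel_rounds: int = 5
    smoothing_sigma_iters: float = 2.0
    connectivity: int = 26
    min_instance_side_voxels: int = 25
    max_full_rounds: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lambda_step <= 1):
            raise ValidationError("lambda_step must be in (0, 1]")
        inv = 1.0 / self.lambda_step
        if abs(inv - round(inv)) > 1e-9:
            raise ValidationError(
                f"1/lambda_step must be an integer (got lambda={self.lambda_step})"
            )
        if not (0 < self.binarize_threshold < 1):
            raise ValidationError("binarize_threshold must be in (0, 1)")
        if self.connectivity not in (6, 26):
            raise ValidationError("connectivity must be 6 or 26")

    @property
    def iters_per_round(self) -> int:
        return round(1.0 / self.lambda_step)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def connectivity_structure(connectivity: int = 26) -> np.ndarray:
    """3x3x3 structuring element for 6- or 26-connected labelling."""
    if connectivity == 26:
        return STRUCT_26
    return ndimage.generate_binary_structure(3, 1)


def validate_labels(labels: np.ndarray, voxel_size_nm: float) -> LabelVolume:
    """Build a :class:`LabelVolume`, counting stray CM/ICS voxels.

    A CM or ICS component that is nowhere 26-adjacent to mitochondrion
    interior (label 1) is suspicious — it floats in the background — and
    its voxel count is accumulated into ``validation_warnings``.
    """
    vol = LabelVolume(labels=labels, voxel_size_nm=voxel_size_nm)
    internal = vol.membrane_seed
    n_warn = 0
    if internal.any():
        comp, n = ndimage.label(internal, structure=STRUCT_26)
        near_interior = ndimage.binary_dilation(vol.labels == 1, structure=STRUCT_26)
        touching = np.unique(comp[near_interior & internal])
        floating = np.setdiff1d(np.arange(1, n + 1), touching)
        for lab in floating:
            n_warn += int(np.count_nonzero(comp == lab))
        if n_warn:
            logger.warning("%d CM/ICS voxels are not attached to any mitochondrion interior", n_warn)
    return replace(vol, validation_warnings=n_warn)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in {".h5", ".hdf5", ".hdf"}


def read_label_volume(path: str | Path, voxel_size_nm: float | None = None) -> LabelVolume:
    """Read a label volume from multi-page TIFF or HDF5.

    If ``voxel_size_nm`` is None, it is taken from file metadata when
    present, otherwise it defaults to 5 nm with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    meta_voxel: float | None = None
    if _is_hdf5(path):
        with h5py.File(path, "r") as fh:
            if "labels" not in fh:
                raise IOError(f"{path}: missing dataset 'labels'")
            dset = fh["labels"]
            arr = np.asarray(dset[...])
            if "voxel_size_nm" in dset.attrs:
                meta_voxel = float(dset.attrs["voxel_size_nm"])
    else:
        with tifffile.TiffFile(str(path)) as tif:
            arr = tif.asarray()
            meta = tif.shaped_metadata
            if meta and "voxel_size_nm" in meta[0]:
                meta_voxel = float(meta[0]["voxel_size_nm"])
    if arr.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    if voxel_size_nm is None:
        if meta_voxel is not None:
            voxel_size_nm = meta_voxel
        else:
            logger.warning("%s: no voxel size in metadata; assuming %.1f nm", path, DEFAULT_VOXEL_SIZE_NM)
            voxel_size_nm = DEFAULT_VOXEL_SIZE_NM
    return validate_labels(arr.astype(np.uint8, casting="unsafe"), voxel_size_nm)


def write_label_volume(volume: LabelVolume, path: str | Path) -> None:
    """Write a label volume to multi-page TIFF (uint8) or HDF5."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    arr = volume.labels.astype(np.uint8)
    if _is_hdf5(path):
        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("labels", data=arr)
            dset.attrs["voxel_size_nm"] = float(volume.voxel_size_nm)
    else:
        tifffile.imwrite(
            str(path),
            arr,
            photometric="minisblack",
            metadata={"voxel_size_nm": float(volume.voxel_size_nm), "axes": "ZYX"},
        )
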