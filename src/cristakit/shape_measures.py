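"""Instance extraction, cleanup, and classical 3D shape measurements.

Volumes are voxel counts scaled by the voxel volume (125 nm^3 at 5 nm
isotropic voxels); the matrix volume of an organelle is what remains after
subtracting the crista membrane and intracristal space volumes:

    matrix = mitochondrion - crista_membrane - intracristal_space

which holds exactly in voxel units for every instance by construction.
Surface areas come from the triangle mesh of the 0.5-level marching-cubes
surface, with the mask padded by one background voxel so surfaces close at
crop borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure as skmeasure

from .volumes_io import LabelVolume, RunConfig, ValidationError, connectivity_structure


@dataclass(frozen=True)
class InstanceRecord:
    """Per-mitochondrion measurement record."""

    mito_id: int
    bbox: tuple[int, int, int, int, int, int]
    mito_volume_nm3: float
    cm_volume_nm3: float
    ics_volume_nm3: float
    matrix_volume_nm3: float
    mito_surface_nm2: float
    cm_matrix_side_surface_nm2: float
    ics_surface_nm2: float
    mito_voxels: int
    cm_voxels: int
    ics_voxels: int
    touches_border: bool
    excluded_small: bool

    @property
    def included(self) -> bool:
        return not (self.touches_border or self.excluded_small)


def compute_volume(mask: np.ndarray, voxel_size_nm: float) -> float:
    """Voxel count times the voxel volume, in nm^3."""
    return float(np.count_nonzero(mask)) * float(voxel_size_nm) ** 3


def compute_surface_area(
    mask: np.ndarray, voxel_size_nm: float, smoothing_iterations: int = 3
) -> float:
    """Total triangle area of the 0.5-level marching-cubes mesh, in nm^2.

    The raw mesh of a binary volume is a chamfered staircase whose area
    overestimates smooth surfaces by ~9% (a digitized ball) while slightly
    underestimating blocky ones.  By default the mesh is therefore
    regularised with a few iterations of shrink-resistant (Humphrey/HC)
    Laplacian smoothing, which brings digitized balls within ~2% of the
    analytic sphere area.  Pass ``smoothing_iterations=0`` for the raw
    marching-cubes mesh (e.g. a single voxel is then exactly the
    sqrt(3)-area octahedron).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("cannot mesh an empty mask")
    padded = np.pad(mask, 1).astype(np.float64)
    verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5)
    if smoothing_iterations > 0:
        import trimesh

        mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
        trimesh.smoothing.filter_humphrey(
            mesh, alpha=0.1, beta=0.5, iterations=smoothing_iterations
        )
        area_voxels = float(mesh.area)
    else:
        area_voxels = float(skmeasure.mesh_surface_area(verts, faces))
    return area_voxels * float(voxel_size_nm) ** 2


def crista_surfaces(
    cm_mask: np.ndarray, ics_mask: np.ndarray, voxel_size_nm: float
) -> tuple[float, float]:
    """(matrix-side, intracristal-side) crista surface areas in nm^2.

    The matrix-facing surface is the boundary of CM union ICS; the
    intracristal-side surface is the boundary of the ICS alone (0 when the
    lumen is unresolved).
    """
    union = np.asarray(cm_mask, bool) | np.asarray(ics_mask, bool)
    matrix_side = compute_surface_area(union, voxel_size_nm) if union.any() else 0.0
    ics_side = (
        compute_surface_area(ics_mask, voxel_size_nm)
        if np.asarray(ics_mask, bool).any()
        else 0.0
    )
    return matrix_side, ics_side


def cleanup_segmentation(
    volume: LabelVolume,
    max_hole_size_voxels: int = 100,
    opening_radius: int = 1,
) -> LabelVolume:
    """Fill small enclosed cavities and remove segmentation specks.

    Background cavities that are fully enclosed by CM/ICS voxels and
    smaller than ``max_hole_size_voxels`` are relabelled intracristal
    space.  The organelle mask is then opened with a ball of
    ``opening_radius`` and any CM/ICS voxels falling outside the opened
    mask are cleared.
    """
    labels = volume.labels.copy()
    background = labels == 0
    comp, n = ndimage.label(background, structure=ndimage.generate_binary_structure(3, 1))
    if n:
        sizes = ndimage.sum_labels(background, comp, index=np.arange(1, n + 1))
        border = np.zeros_like(background)
        border[0, :, :] = border[-1, :, :] = True
        border[:, 0, :] = border[:, -1, :] = True
        border[:, :, 0] = border[:, :, -1] = True
        touches = np.unique(comp[border & background])
        membrane = labels >= 2
        for lab in range(1, n + 1):
            if lab in touches or sizes[lab - 1] >= max_hole_size_voxels:
                continue
            cavity = comp == lab
            rim = ndimage.binary_dilation(cavity, structure=connectivity_structure(26)) & ~cavity
            if np.all(membrane[rim]):
                labels[cavity] = 3

    if opening_radius > 0:
        r = opening_radius
        zz, yy, xx = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
        ball = zz**2 + yy**2 + xx**2 <= r**2
        mito = labels > 0
        opened = ndimage.binary_opening(mito, structure=ball)
        labels[~opened] = 0
    return LabelVolume(labels, volume.voxel_size_nm)


def extract_instances(
    volume: LabelVolume, config: RunConfig | None = None
) -> tuple[list[InstanceRecord], list[LabelVolume]]:
    """Split the organelle mask into 26-connected instances and measure each.

    Per-instance CM and ICS masks are obtained by intersecting the
    instance mask with the class masks (mask multiplication).  Instances
    touching any volume face are flagged ``touches_border``; instances
    smaller than ``min_instance_side_voxels**3`` voxels are flagged
    ``excluded_small``.  Both kinds are reported but marked excluded.

    Returns the records together with per-instance cropped
    :class:`LabelVolume` objects (one voxel of background margin).
    """
    config = config or RunConfig()
    vx = volume.voxel_size_nm
    comp, n = ndimage.label(volume.mito_mask, structure=connectivity_structure(26))
    min_voxels = config.min_instance_side_voxels**3
    records: list[InstanceRecord] = []
    instances: list[LabelVolume] = []
    slices = ndimage.find_objects(comp)
    shape = volume.shape
    for mito_id in range(1, n + 1):
        sl = slices[mito_id - 1]
        inst_mask = comp == mito_id
        cm = inst_mask & volume.cm_mask
        ics = inst_mask & volume.ics_mask
        mito_vox = int(np.count_nonzero(inst_mask))
        cm_vox = int(np.count_nonzero(cm))
        ics_vox = int(np.count_nonzero(ics))
        bbox = (sl[0].start, sl[0].stop, sl[1].start, sl[1].stop, sl[2].start, sl[2].stop)
        touches = any(s.start == 0 or s.stop == dim for s, dim in zip(sl, shape))
        small = mito_vox < min_voxels
        matrix_side, ics_side = crista_surfaces(cm, ics, vx)
        records.append(
            InstanceRecord(
                mito_id=mito_id,
                bbox=bbox,
                mito_volume_nm3=mito_vox * vx**3,
                cm_volume_nm3=cm_vox * vx**3,
                ics_volume_nm3=ics_vox * vx**3,
                matrix_volume_nm3=(mito_vox - cm_vox - ics_vox) * vx**3,
                mito_surface_nm2=compute_surface_area(inst_mask, vx),
                cm_matrix_side_surface_nm2=matrix_side,
                ics_surface_nm2=ics_side,
                mito_voxels=mito_vox,
                cm_voxels=cm_vox,
                ics_voxels=ics_vox,
                touches_border=touches,
                excluded_small=small,
            )
        )
        grow = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim)) for s, dim in zip(sl, shape)
        )
        crop = np.where(inst_mask[grow], volume.labels[grow], 0).astype(np.uint8)
        instances.append(LabelVolume(crop, vx))
    return records, instances


def instances_to_frame(records: list[InstanceRecord]) -> pd.DataFrame:
    """One row per mitochondrion, mirroring :class:`InstanceRecord`."""
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in r.__dataclass_fields__}
        d["bbox"] = ";".join(map(str, r.bbox))
        d["included"] = r.included
        rows.append(d)
    return pd.DataFrame(rows)
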