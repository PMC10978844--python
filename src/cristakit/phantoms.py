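"""Synthetic label volumes with known analytic geometry.

Every downstream stage (morphology, counting, shape measures, fusion,
stereology) is exercised on these phantoms, whose ground truth is computed
from the generating parameters — never from the voxelization.

Three families are provided:

* :func:`make_sphere` — a solid organelle for volume/surface calibration;
* :func:`make_plate_pair` — two parallel crista-membrane slabs a known
  number of matrix voxels apart, the canonical geometry for hole-count
  persistence (the hole appears as the dilating plates seal the gap and
  disappears when the gap is consumed, peaking at half the separation);
* :func:`make_crista_phantom` — a spherical organelle envelope containing
  a stack of lamellar cristae (1-voxel membrane around an intracristal
  interior), with optional deterministic sinusoidal surface undulation so
  that width and roughness recovery can be tested reproducibly.  A tubular
  variant (:func:`make_tubular_phantom`) models cylindrical cristae.

All generators are deterministic; an ``rng_seed`` only parameterises the
(deterministic) phase of the undulation pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi

import numpy as np
from scipy import ndimage

from .volumes_io import DEFAULT_VOXEL_SIZE_NM, LabelVolume


class PhantomParameterError(ValueError):
    """Raised when requested phantom geometry cannot fit the grid."""


@dataclass(frozen=True)
class Phantom:
    """A generated label volume plus its analytic ground truth."""

    volume: LabelVolume
    truth: dict = field(default_factory=dict)


def _centered_ball(side: int, radius: float) -> np.ndarray:
    c = (side - 1) / 2.0
    z, y, x = np.ogrid[:side, :side, :side]
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= radius**2


def make_sphere(
    radius_voxels: float,
    grid_side: int,
    voxel_size_nm: float = DEFAULT_VOXEL_SIZE_NM,
) -> Phantom:
    """Solid label-1 ball centred in the grid."""
    if radius_voxels < 3:
        raise PhantomParameterError("radius must be >= 3 voxels")
    if grid_side <= 2 * radius_voxels + 4:
        raise PhantomParameterError("sphere would touch the grid boundary")
    labels = _centered_ball(grid_side, radius_voxels).astype(np.uint8)
    truth = {
        "volume_nm3": 4.0 / 3.0 * pi * radius_voxels**3 * voxel_size_nm**3,
        "surface_nm2": 4.0 * pi * radius_voxels**2 * voxel_size_nm**2,
        "radius_voxels": float(radius_voxels),
    }
    return Phantom(LabelVolume(labels, voxel_size_nm), truth)


def make_plate_pair(
    separation_voxels: int,
    thickness_voxels: int = 2,
    lateral_side: int = 54,
    clearance_voxels: int = 3,
    corrugation_amplitude_voxels: float = 1.0,
    corrugation_period_voxels: float = 14.0,
    voxel_size_nm: float = DEFAULT_VOXEL_SIZE_NM,
) -> Phantom:
    """Two parallel crista-membrane slabs inside a cuboid organelle.

    The slabs (label 2) are normal to z with their facing surfaces a mean
    of ``separation_voxels`` of matrix (label 1) apart, and are inset from
    the envelope laterally and axially by ``clearance_voxels`` (>= 2).
    The envelope is inset 2 voxels from the grid so the instance does not
    touch the volume border.

    The second plate carries a deterministic zero-mean egg-carton
    corrugation (amplitude ``corrugation_amplitude_voxels``).  Biological
    membranes are never geometrically flat, and a perfectly constant gap
    is degenerate for hole counting: contact would happen simultaneously
    everywhere and no cavity would ever be enclosed.  With the corrugation
    the local gap varies symmetrically about ``separation_voxels`` and the
    hole-count curve peaks where most of the surface makes contact — half
    the mean separation.  Set the amplitude to 0 for truly flat plates.
    """
    if separation_voxels < 2:
        raise PhantomParameterError("separation must be >= 2 voxels")
    if thickness_voxels < 1:
        raise PhantomParameterError("thickness must be >= 1 voxel")
    if clearance_voxels < 2:
        raise PhantomParameterError("lateral clearance must be >= 2 voxels")
    if corrugation_amplitude_voxels >= separation_voxels - 1:
        raise PhantomParameterError("corrugation amplitude too large for the gap")
    amp = corrugation_amplitude_voxels
    z_extent = 2 * thickness_voxels + separation_voxels + 2 * clearance_voxels + int(np.ceil(2 * amp))
    side = max(lateral_side, z_extent) + 4  # envelope inset 2 on each face
    labels = np.zeros((side, side, side), dtype=np.uint8)
    labels[2:-2, 2:-2, 2:-2] = 1

    lat_lo = 2 + clearance_voxels
    lat_hi = side - 2 - clearance_voxels
    if lat_hi - lat_lo < 4:
        raise PhantomParameterError("plates do not fit laterally")
    zc = side // 2
    gap_lo = zc - separation_voxels // 2
    gap_hi = gap_lo + separation_voxels
    z, y, x = np.indices((side, side, side)).astype(np.float64)
    lateral = (y >= lat_lo) & (y < lat_hi) & (x >= lat_lo) & (x < lat_hi)
    k = 2 * pi / corrugation_period_voxels
    # the -0.5 centres the voxelization so the realised mean gap stays at
    # separation_voxels (plain ceil of a zero-mean field is biased +0.5)
    f = amp * np.sin(k * x) * np.sin(k * y) - 0.5
    plate_a = (z >= gap_lo - thickness_voxels) & (z < gap_lo) & lateral
    plate_b = (z >= gap_hi + f) & (z < gap_hi + thickness_voxels + f) & lateral
    if gap_lo - thickness_voxels < 2 + clearance_voxels or (
        gap_hi + thickness_voxels + amp > side - 2 - clearance_voxels
    ):
        raise PhantomParameterError("plates do not fit axially")
    labels[plate_a | plate_b] = 2
    truth = {
        "spacing_nm": separation_voxels * voxel_size_nm,
        "thickness_nm": thickness_voxels * voxel_size_nm,
        "separation_voxels": separation_voxels,
        "thickness_voxels": thickness_voxels,
        "corrugation_amplitude_voxels": float(amp),
    }
    return Phantom(LabelVolume(labels, voxel_size_nm), truth)


#: always-on surface corrugation of crista-phantom sheets, voxels.  A
#: perfectly planar stack is degenerate for count-curve persistence
#: (contact would be simultaneous everywhere, enclosing nothing), and real
#: crista membranes are never geometrically flat.
BASE_CORRUGATION_VOXELS = 0.75


def make_crista_phantom(
    envelope_radius: float = 26.0,
    sheet_width_voxels: int = 6,
    sheet_spacing_voxels: int = 6,
    n_sheets: int = 3,
    roughness_amplitude_voxels: float = 0.0,
    rng_seed: int = 0,
    voxel_size_nm: float = DEFAULT_VOXEL_SIZE_NM,
    roughness_period_voxels: float = 14.0,
    lateral_clearance_voxels: int | None = None,
    base_corrugation_voxels: float = BASE_CORRUGATION_VOXELS,
) -> Phantom:
    """Spherical organelle with a stack of lamellar cristae.

    Each crista is a slab normal to z of nominal total width
    ``sheet_width_voxels``: a 1-voxel label-2 membrane enclosing a label-3
    interior.  Facing surfaces of adjacent sheets are a mean of
    ``sheet_spacing_voxels`` of matrix apart.  Sheets are clipped to an
    inner ball inset ``lateral_clearance_voxels`` from the envelope
    (default ``max(4, sheet_spacing)``) so inter-sheet gaps close by mouth
    pinch-off rather than by sealing against the envelope.

    Every sheet surface carries a deterministic zero-mean egg-carton
    corrugation of amplitude ``base_corrugation_voxels +
    roughness_amplitude_voxels`` with quadrature phase offsets between
    consecutive surfaces, so both local width and local spacing vary
    symmetrically (by at most sqrt(2) times the amplitude) about their
    nominal values.  ``roughness_amplitude_voxels`` is the *added* surface
    roughness on top of the realism floor; raising it widens the window
    over which holes/objects appear and disappear (larger FWHM) without
    moving the mean geometry.  The overall phase derives from
    ``rng_seed``; generation is fully deterministic.
    """
    if sheet_width_voxels < 3 and n_sheets > 0:
        raise PhantomParameterError("sheet width must be >= 3 voxels (membrane + interior)")
    if n_sheets > 1 and sheet_spacing_voxels < 1:
        raise PhantomParameterError("sheet spacing must be >= 1 voxel")
    if n_sheets < 0:
        raise PhantomParameterError("n_sheets must be >= 0")
    amp = base_corrugation_voxels + roughness_amplitude_voxels
    wobble = np.sqrt(2.0) * amp  # max surface-to-surface variation
    if n_sheets > 0 and wobble >= sheet_width_voxels - 1:
        raise PhantomParameterError("corrugation amplitude too large for the sheet width")
    if n_sheets > 1 and wobble >= sheet_spacing_voxels - 0.5:
        raise PhantomParameterError("corrugation amplitude too large for the sheet spacing")
    clear = lateral_clearance_voxels
    if clear is None:
        clear = max(4, sheet_spacing_voxels)
    side = int(np.ceil(2 * envelope_radius)) + 6
    c = (side - 1) / 2.0
    envelope = _centered_ball(side, envelope_radius)
    labels = envelope.astype(np.uint8)

    if n_sheets > 0:
        stack_height = n_sheets * sheet_width_voxels + (n_sheets - 1) * sheet_spacing_voxels
        inner_r = envelope_radius - clear
        if stack_height / 2.0 + amp > inner_r - 1:
            raise PhantomParameterError("sheet stack does not fit inside the envelope")
        rng = np.random.default_rng(rng_seed)
        phase = rng.uniform(0, 2 * pi)
        k = 2 * pi / roughness_period_voxels
        z, y, x = np.indices((side, side, side)).astype(np.float64)
        yx_y, yx_x = np.mgrid[:side, :side].astype(np.float64)

        def surface(j: int) -> np.ndarray:
            # consecutive surfaces are in quadrature, so each width/gap
            # varies with amplitude sqrt(2)*amp, zero mean
            return amp * np.sin(k * yx_x + phase + j * pi / 2.0) * np.sin(k * yx_y + phase)

        inner = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= inner_r**2
        sheets = np.zeros((side, side, side), dtype=bool)
        z0 = c - stack_height / 2.0
        for i in range(n_sheets):
            lo = z0 + i * (sheet_width_voxels + sheet_spacing_voxels)
            bot = lo + surface(2 * i)[np.newaxis, :, :]
            top = lo + sheet_width_voxels + surface(2 * i + 1)[np.newaxis, :, :]
            sheets |= (z >= bot) & (z < top) & inner
        # 1-voxel enclosing membrane: boundary of each sheet under 6-connected erosion
        interior = ndimage.binary_erosion(
            sheets, structure=ndimage.generate_binary_structure(3, 1)
        )
        labels[sheets] = 2
        labels[interior] = 3

    truth = {
        "width_nm": sheet_width_voxels * voxel_size_nm if n_sheets else 0.0,
        "spacing_nm": sheet_spacing_voxels * voxel_size_nm if n_sheets > 1 else 0.0,
        "width_voxels": sheet_width_voxels if n_sheets else 0,
        "spacing_voxels": sheet_spacing_voxels if n_sheets > 1 else 0,
        "n_sheets": n_sheets,
        "rough": roughness_amplitude_voxels > 0,
        "roughness_amplitude_voxels": float(roughness_amplitude_voxels),
        "envelope_volume_nm3": 4.0 / 3.0 * pi * envelope_radius**3 * voxel_size_nm**3,
    }
    if n_sheets > 0 and amp <= 1.0:
        # corrugation this small changes the true area by < ~3%
        truth["sheet_areas_nm2"] = _flat_sheet_areas(
            envelope_radius - clear, sheet_width_voxels, sheet_spacing_voxels,
            n_sheets, voxel_size_nm,
        )
    return Phantom(LabelVolume(labels, voxel_size_nm), truth)


def _flat_sheet_areas(
    inner_r: float, width: int, spacing: int, n_sheets: int, voxel_nm: float
) -> dict:
    """Analytic outer (matrix-side) and inner (intracristal-side) areas of a
    flat sheet stack clipped to a ball of radius ``inner_r``.

    A clipped slab's boundary is two discs plus a spherical zone of the
    clipping ball; the interior (eroded by one voxel) is the same with the
    z-range shrunk by 1 and radii shrunk by 1.
    """
    stack = n_sheets * width + (n_sheets - 1) * spacing

    def slab_area(z1: float, z2: float, r: float) -> float:
        r1sq = max(r**2 - z1**2, 0.0)
        r2sq = max(r**2 - z2**2, 0.0)
        return pi * (r1sq + r2sq) + 2 * pi * r * (z2 - z1)

    outer = 0.0
    inner = 0.0
    z0 = -stack / 2.0
    for i in range(n_sheets):
        lo = z0 + i * (width + spacing)
        outer += slab_area(lo, lo + width, inner_r)
        inner += slab_area(lo + 1, lo + width - 1, inner_r - 1)
    return {
        "matrix_side_nm2": outer * voxel_nm**2,
        "intracristal_side_nm2": inner * voxel_nm**2,
    }


def make_tubular_phantom(
    envelope_radius: float = 26.0,
    tube_diameter_voxels: int = 6,
    tube_spacing_voxels: int = 6,
    n_tubes: int = 3,
    voxel_size_nm: float = DEFAULT_VOXEL_SIZE_NM,
    lateral_clearance_voxels: int | None = None,
) -> Phantom:
    """Cylindrical-crista variant: parallel tubes along y inside a ball.

    Each tube is a cylinder of the given diameter whose 1-voxel wall is
    label 2 around a label-3 lumen; tube axes lie in the central z-plane,
    spaced so facing walls are ``tube_spacing_voxels`` apart.
    """
    if tube_diameter_voxels < 3:
        raise PhantomParameterError("tube diameter must be >= 3 voxels")
    clear = lateral_clearance_voxels
    if clear is None:
        clear = max(4, tube_spacing_voxels)
    side = int(np.ceil(2 * envelope_radius)) + 6
    c = (side - 1) / 2.0
    labels = _centered_ball(side, envelope_radius).astype(np.uint8)
    inner_r = envelope_radius - clear
    span = n_tubes * tube_diameter_voxels + (n_tubes - 1) * tube_spacing_voxels
    if span / 2.0 > inner_r - 1:
        raise PhantomParameterError("tubes do not fit inside the envelope")
    z, y, x = np.indices((side, side, side)).astype(np.float64)
    inner = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= inner_r**2
    r_tube = tube_diameter_voxels / 2.0
    tubes = np.zeros_like(inner)
    x0 = c - span / 2.0 + r_tube
    for i in range(n_tubes):
        xi = x0 + i * (tube_diameter_voxels + tube_spacing_voxels)
        tubes |= ((z - c) ** 2 + (x - xi) ** 2 <= r_tube**2) & inner
    lumen = ndimage.binary_erosion(tubes, structure=ndimage.generate_binary_structure(3, 1))
    labels[tubes] = 2
    labels[lumen] = 3
    truth = {
        "width_nm": tube_diameter_voxels * voxel_size_nm,
        "spacing_nm": tube_spacing_voxels * voxel_size_nm if n_tubes > 1 else 0.0,
        "n_tubes": n_tubes,
        "kind": "tubular",
    }
    return Phantom(LabelVolume(labels, voxel_size_nm), truth)
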