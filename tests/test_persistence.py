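import numpy as np
import pytest
from scipy import ndimage

from cristakit import (
    CountCurve,
    RunConfig,
    ValidationError,
    apply_validity_filters,
    count_holes,
    count_objects,
    make_crista_phantom,
    persistence_curve,
    summarize_curve,
)
from cristakit.volumes_io import LabelVolume


def flood_fill_component_count(mask):
    """Independent counting oracle: morphological reconstruction from one
    seed at a time (no ndimage.label)."""
    mask = np.asarray(mask, dtype=bool).copy()
    struct = np.ones((3, 3, 3), dtype=bool)
    n = 0
    while mask.any():
        seed = np.zeros_like(mask)
        seed[tuple(np.argwhere(mask)[0])] = True
        comp = ndimage.binary_propagation(seed, structure=struct, mask=mask)
        mask &= ~comp
        n += 1
    return n


def _ball(side, r, center=None):
    c = (side - 1) / 2 if center is None else center
    z, y, x = np.ogrid[:side, :side, :side]
    cz, cy, cx = (c, c, c) if np.isscalar(c) else c
    return (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r**2


class TestCounting:
    def test_solid_ball_has_no_holes(self):
        bounds = np.ones((20, 20, 20), dtype=bool)
        assert count_holes(_ball(20, 6), bounds) == 0

    def test_hollow_shell_has_one_cavity(self):
        shell = _ball(24, 8) & ~_ball(24, 5)
        assert count_holes(shell, np.ones((24, 24, 24), bool)) == 1

    def test_two_hollow_shells_two_cavities(self):
        m = (_ball(40, 7, (10, 10, 10)) & ~_ball(40, 4, (10, 10, 10))) | (
            _ball(40, 7, (28, 28, 28)) & ~_ball(40, 4, (28, 28, 28))
        )
        assert count_holes(m, np.ones((40, 40, 40), bool)) == 2

    def test_mask_filling_bounds_has_no_holes(self):
        bounds = _ball(20, 7)
        assert count_holes(bounds, bounds) == 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            count_holes(np.ones((3, 3, 3), bool), np.ones((4, 4, 4), bool))

    def test_object_counts(self):
        assert count_objects(np.zeros((5, 5, 5), bool)) == 0
        m = np.zeros((10, 10, 10), bool)
        m[1:3, 1:3, 1:3] = True
        m[6:8, 6:8, 6:8] = True
        assert count_objects(m) == 2
        # corner-diagonal contact merges under 26-connectivity
        m = np.zeros((8, 8, 8), bool)
        m[1:3, 1:3, 1:3] = True
        m[3:5, 3:5, 3:5] = True
        assert count_objects(m) == 1
        assert count_objects(m, connectivity=6) == 2

    def test_counts_match_flood_fill_oracle_on_random_masks(self, rng):
        from conftest import random_blob_mask

        for _ in range(12):
            side = int(rng.integers(12, 28))
            mask = random_blob_mask(rng, side)
            bounds = _ball(side, side // 2 - 1)
            assert count_objects(mask) == flood_fill_component_count(mask)
            expected = max(0, flood_fill_component_count(~(mask & bounds)) - 1)
            assert count_holes(mask, bounds) == expected


class TestPersistenceCurve:
    def test_plate_pair_holes_rise_peak_and_vanish(self, plate_pair, config):
        curve = persistence_curve(plate_pair.volume, "dilation_holes", config, max_full_rounds=5)
        assert curve.counts[0] == 0
        assert curve.max_raw_count >= 1
        assert curve.counts[-1] == 0

    def test_single_plate_has_no_holes(self, config):
        labels = np.zeros((30, 30, 30), dtype=np.uint8)
        labels[2:-2, 2:-2, 2:-2] = 1
        labels[14:16, 6:24, 6:24] = 2
        curve = persistence_curve(LabelVolume(labels, 5.0), "dilation_holes", config, 4)
        assert curve.max_raw_count == 0

    def test_erosion_of_two_slabs_loses_thinner_first(self, config):
        """Slabs of thickness 4 and 6 vanish after ~2 and ~3 full rounds."""
        labels = np.zeros((30, 40, 40), dtype=np.uint8)
        labels[1:-1, 1:-1, 1:-1] = 1
        labels[6:10, 6:34, 6:34] = 2    # thickness 4
        labels[18:24, 6:34, 6:34] = 2   # thickness 6
        curve = persistence_curve(LabelVolume(labels, 5.0), "erosion_objects", config, 5)
        counts = curve.counts
        assert counts[0] == 2
        assert set(np.unique(counts)) == {0, 1, 2}
        first1 = int(np.argmax(counts == 1))
        first0 = int(np.argmax(counts == 0))
        # thinner slab (thickness 4) gone within round 2, thicker by round 3
        assert first1 <= 2 * config.iters_per_round + 1
        assert first0 <= 3 * config.iters_per_round + 1
        assert np.all(np.diff(counts.astype(int)) <= 0)

    def test_empty_seed_erosion_gives_zero_curve(self, config):
        labels = np.zeros((16, 16, 16), dtype=np.uint8)
        labels[4:12, 4:12, 4:12] = 1  # organelle without cristae
        curve = persistence_curve(LabelVolume(labels, 5.0), "erosion_objects", config, 3)
        assert curve.max_raw_count == 0
        assert not summarize_curve(curve, config).valid


class TestSummaries:
    def test_hand_computed_triangle_curve(self):
        """Smoothed sequence 0,1,3,5,3,1,0 beyond the skip: peak at the 5,
        half-max 2.5 crossed at 1.75 and 4.25 -> FWHM 2.5 by interpolation."""
        vals = np.array([0.0, 0.0, 1.0, 3.0, 5.0, 3.0, 1.0, 0.0])
        curve = CountCurve(
            mode="dilation_holes", lambda_step=0.1,
            counts=vals.astype(int), smoothed=vals, voxel_size_nm=5.0,
        )
        cfg = RunConfig(skip_subpixel_rounds=0)
        s = summarize_curve(curve, cfg)
        assert s.max_location_iters == 4
        assert s.fwhm_iters == pytest.approx(2.5)
        assert s.distance_nm == pytest.approx(2 * 0.4 * 5.0)
        assert s.half_distance_nm == pytest.approx(s.distance_nm / 2)

    def test_all_zero_curve_invalid(self, config):
        z = np.zeros(30)
        curve = CountCurve("dilation_holes", 0.1, z.astype(int), z)
        s = summarize_curve(curve, config)
        assert not s.valid
        assert np.isnan(s.max_location_iters)

    def test_truncated_flag_when_curve_never_falls(self, config):
        vals = np.concatenate([np.zeros(6), np.linspace(0, 5, 24)])
        curve = CountCurve("dilation_holes", 0.1, vals.astype(int), vals)
        s = summarize_curve(curve, config)
        assert s.truncated

    def test_plate_pair_distance_summary(self, plate_pair, config):
        """Facing surfaces 4 voxels apart at 5 nm voxels: the smoothed
        hole-count maximum sits at full round 2 +/- 0.5, i.e. a mean
        inter-membrane distance of 20 +/- 5 nm."""
        curve = persistence_curve(plate_pair.volume, "dilation_holes", config, 6)
        s = summarize_curve(curve, config)
        assert s.valid
        assert s.max_location_rounds == pytest.approx(2.0, abs=0.5)
        assert s.distance_nm == pytest.approx(20.0, abs=5.0)


class TestValidityFilters:
    def test_single_sheet_distance_invalid(self, config):
        ph = make_crista_phantom(n_sheets=1, rng_seed=0)
        # stay short of the envelope so nothing can pinch off against it
        curve = persistence_curve(ph.volume, "dilation_holes", config, 3)
        s = apply_validity_filters(summarize_curve(curve, config), curve, 1, 1)
        assert not s.valid

    def test_width_requires_both_compartments(self, crista_phantom, config):
        curve = persistence_curve(crista_phantom.volume, "erosion_objects", config, 5)
        s = summarize_curve(curve, config)
        cm = int(np.count_nonzero(crista_phantom.volume.cm_mask))
        ics = int(np.count_nonzero(crista_phantom.volume.ics_mask))
        assert apply_validity_filters(s, curve, cm, ics).valid
        assert not apply_validity_filters(s, curve, cm, 0).valid
        assert not apply_validity_filters(s, curve, 0, ics).valid

    def test_standard_phantom_both_modes_valid(self, crista_phantom, config):
        cm = int(np.count_nonzero(crista_phantom.volume.cm_mask))
        ics = int(np.count_nonzero(crista_phantom.volume.ics_mask))
        for mode in ("dilation_holes", "erosion_objects"):
            curve = persistence_curve(crista_phantom.volume, mode, config, 6)
            s = apply_validity_filters(summarize_curve(curve, config), curve, cm, ics)
            assert s.valid
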