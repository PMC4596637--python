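"""Generator correctness: determinism, geometry, EdU sampling, motion."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from pllptools import (PackingError, SyntheticSpec, generate_edu_channel,
                       generate_primordium, generate_timelapse)
from conftest import small_timelapse_spec


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_cells=0),
        dict(voxel_spacing=(1.0, -0.5, 0.5)),
        dict(domain_semi_axes=(0.0, 13.0, 28.0)),
        dict(edu_fraction=1.5),
        dict(membrane_peak=15.0, interior_level=20.0),  # peak below interior
        dict(noise_sigma=-1.0),
    ])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticSpec(**kwargs)

    def test_infeasible_packing_reports_achieved_count(self):
        # separation above the jamming limit cannot be satisfied
        spec = SyntheticSpec(n_cells=100, min_separation_factor=1.3)
        with pytest.raises(PackingError) as exc:
            generate_primordium(spec)
        assert 0 < exc.value.achieved < 100


class TestPrimordium:
    def test_exact_cell_count(self, primordium):
        _vol, gt = primordium
        labels = gt.labels.labels
        assert gt.n_cells == 100
        assert len(np.unique(labels[labels > 0])) == 100

    def test_fixed_seed_is_bit_identical(self):
        spec = SyntheticSpec(seed=42)
        v1, g1 = generate_primordium(spec)
        v2, g2 = generate_primordium(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(g1.labels.labels, g2.labels.labels)
        assert np.array_equal(g1.centers, g2.centers)

    def test_different_seeds_differ(self):
        v1, _ = generate_primordium(SyntheticSpec(seed=1))
        v2, _ = generate_primordium(SyntheticSpec(seed=2))
        assert not np.array_equal(v1.data, v2.data)

    def test_label_completeness_inside_ellipsoid(self, primordium):
        """Every voxel strictly inside the ellipsoid carries exactly one
        positive label; everything outside is background."""
        _vol, gt = primordium
        spec = SyntheticSpec(seed=7)
        ext = [(n - 1) * s for n, s in zip(spec.shape, spec.voxel_spacing)]
        coords = np.indices(spec.shape).astype(float)
        r2 = np.zeros(spec.shape)
        for ax in range(3):
            r2 += ((coords[ax] * spec.voxel_spacing[ax] - ext[ax] / 2)
                   / spec.domain_semi_axes[ax]) ** 2
        inside = r2 < 1.0
        assert np.array_equal(gt.labels.labels > 0, inside)

    def test_bright_voxels_lie_near_boundaries_without_optics(self):
        """With no PSF and no noise, supra-interior intensity only occurs
        within membrane_width of a ground-truth label boundary."""
        spec = SyntheticSpec(seed=3, psf_sigma=(0.0, 0.0, 0.0), noise_sigma=0.0)
        vol, gt = generate_primordium(spec)
        lab = gt.labels.labels
        boundary = np.zeros(lab.shape, dtype=bool)
        for ax in range(3):
            sl = np.swapaxes(lab, 0, ax)
            d = sl[1:] != sl[:-1]
            b = np.swapaxes(boundary, 0, ax)
            b[1:] |= d
            b[:-1] |= d
        boundary &= lab > 0
        dist = ndi.distance_transform_edt(~boundary, sampling=spec.voxel_spacing)
        bright = vol.data > spec.interior_level + 1e-9
        assert bright.any()
        assert np.all(dist[bright] <= spec.membrane_width + 1e-9)


class TestEdU:
    @pytest.mark.parametrize("fraction,expected", [(1.0, 100), (0.0, 0)])
    def test_degenerate_fractions(self, fraction, expected):
        spec = SyntheticSpec(seed=5, edu_fraction=fraction)
        _v, gt = generate_primordium(spec)
        _e, gt = generate_edu_channel(gt, spec)
        assert len(gt.edu_positive) == expected

    def test_positive_set_is_valid_label_subset(self, edu_acquisition):
        _vol, _edu, gt, _spec = edu_acquisition
        assert gt.edu_positive <= set(range(1, gt.n_cells + 1))

    def test_positive_fraction_matches_binomial_sampling(self):
        """Across 100 seeds the mean positive fraction is within 3 binomial
        standard errors of the generating probability."""
        spec0 = SyntheticSpec(seed=0, edu_fraction=0.3, n_cells=200)
        _v, gt = generate_primordium(spec0)
        fracs = []
        for seed in range(100):
            spec = SyntheticSpec(seed=seed, edu_fraction=0.3, n_cells=200)
            _e, gt_s = generate_edu_channel(gt, spec)
            fracs.append(len(gt_s.edu_positive) / 200)
        se = np.sqrt(0.3 * 0.7 / 200 / 100)
        assert abs(np.mean(fracs) - 0.3) < 3 * se

    def test_positive_cells_are_brighter_at_their_centers(self, edu_acquisition):
        _vol, edu, gt, spec = edu_acquisition
        lab = gt.labels.labels
        k = gt.n_cells
        sums = np.bincount(lab.ravel(), weights=edu.data.ravel(),
                           minlength=k + 1)[1:]
        sizes = np.bincount(lab.ravel(), minlength=k + 1)[1:]
        means = sums / sizes
        pos = np.array(sorted(gt.edu_positive)) - 1
        neg = np.setdiff1d(np.arange(k), pos)
        assert means[pos].min() > means[neg].max()


class TestTimelapse:
    def test_zero_speed_gives_identical_noisefree_frames(self):
        spec = small_timelapse_spec(speed=0.0)
        frames, gt = generate_timelapse(spec)
        assert gt.true_speed == 0.0
        for f in frames[1:]:
            assert np.array_equal(f.data, frames[0].data)

    def test_interframe_displacement_arithmetic(self, timelapse):
        """60 µm/hr at 10-min intervals displaces the intensity centroid by
        10 µm per frame along x."""
        (frames, gt), spec = timelapse
        assert spec.speed * spec.frame_interval / 60.0 == pytest.approx(10.0)
        xs = np.arange(spec.shape[2]) * spec.voxel_spacing[2]
        cents = []
        for f in frames:
            w = np.clip(f.data - spec.background_level, 0, None).sum(axis=(0, 1))
            cents.append((xs * w).sum() / w.sum())
        steps = np.diff(cents)
        assert np.allclose(steps, 10.0, atol=0.2)

    def test_centroid_regression_recovers_speed(self, timelapse):
        (frames, gt), spec = timelapse
        thresh = spec.interior_level
        t_hr = np.arange(spec.n_frames) * spec.frame_interval / 60.0
        cents = []
        for f in frames:
            m = f.data > thresh
            xs = np.argwhere(m)[:, 2] * spec.voxel_spacing[2]
            cents.append(xs.mean())
        slope = np.polyfit(t_hr, cents, 1)[0]
        assert slope == pytest.approx(gt.true_speed, rel=0.05)

    def test_translation_beyond_field_rejected(self):
        spec = small_timelapse_spec(speed=600.0, n_frames=20)
        with pytest.raises(ValueError, match="field of view"):
            generate_timelapse(spec)

    def test_fixed_seed_is_bit_identical(self):
        spec = small_timelapse_spec(noise_sigma=8.0)
        f1, _ = generate_timelapse(spec)
        f2, _ = generate_timelapse(spec)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.data, b.data)


def test_noise_makes_counting_harder_on_average():
    """Counting error does not trend downward as noise increases (5 noise
    levels, 10 seeds each)."""
    from pllptools.pipeline import count_pipeline

    levels = [0.0, 5.0, 10.0, 15.0, 20.0]
    mean_errs = []
    for ns in levels:
        errs = []
        for seed in range(10):
            vol, _ = generate_primordium(SyntheticSpec(seed=seed, noise_sigma=ns))
            errs.append(abs(count_pipeline(vol).count - 100))
        mean_errs.append(np.mean(errs))
    slope = np.polyfit(levels, mean_errs, 1)[0]
    assert slope >= 0.0
    assert mean_errs[-1] >= mean_errs[0]
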