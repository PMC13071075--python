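"""Phantom generator: geometry, rendering, cohorts, class separability."""

import numpy as np
import pytest
from scipy import ndimage

from nodulenet.io import load_mask, load_spacing, load_volume
from nodulenet.phantom import (
    GeometryError,
    PhantomSpec,
    generate_cohort,
    load_manifest,
    make_nodule_mask,
    render_phantom,
    sample_spec,
)


class TestNoduleMask:
    def test_smooth_sphere_volume_matches_analytic_ball(self):
        spec = PhantomSpec(nodule_radius_mm=5.0, spiculation_amplitude=0.0, seed=1)
        count = make_nodule_mask(spec).foreground_count()
        analytic = 4.0 / 3.0 * np.pi * 5.0**3
        assert abs(count - analytic) / analytic < 0.10

    def test_zero_perturbation_equals_discrete_ball(self):
        spec = PhantomSpec(nodule_radius_mm=4.0, spiculation_amplitude=0.0, seed=9)
        mask = make_nodule_mask(spec).data
        c = spec.center
        grids = np.meshgrid(*[np.arange(n) for n in spec.volume_shape], indexing="ij")
        d2 = sum((g - cc) ** 2 for g, cc in zip(grids, c))
        assert np.array_equal(mask, (d2 <= 16.0).astype(np.uint8))

    def test_same_seed_bitwise_identical(self):
        spec = PhantomSpec(nodule_radius_mm=7.0, spiculation_amplitude=0.3,
                           spike_count=9, seed=13)
        assert np.array_equal(make_nodule_mask(spec).data, make_nodule_mask(spec).data)

    def test_single_six_connected_component(self):
        spec = PhantomSpec(nodule_radius_mm=10.0, spiculation_amplitude=0.35,
                           spike_count=14, seed=2)
        mask = make_nodule_mask(spec).data
        _, n = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
        assert n == 1

    def test_spiculation_stays_within_radius_bounds(self):
        r0, a = 8.0, 0.3
        spec = PhantomSpec(nodule_radius_mm=r0, spiculation_amplitude=a,
                           spike_count=10, seed=4)
        mask = make_nodule_mask(spec).data
        idx = np.argwhere(mask)
        dist = np.linalg.norm(idx - np.array(spec.center), axis=1)
        assert dist.max() <= r0 * (1 + a) + 1e-9

    def test_boundary_violation_rejected(self):
        with pytest.raises(GeometryError):
            make_nodule_mask(PhantomSpec(
                nodule_radius_mm=14.0, volume_shape=(24, 24, 24), seed=0))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(nodule_radius_mm=0.5)
        with pytest.raises(ValueError):
            PhantomSpec(nodule_radius_mm=5.0, spiculation_amplitude=1.0)


class TestRender:
    def test_noiseless_render_has_exactly_two_values(self):
        spec = PhantomSpec(nodule_radius_mm=5.0, seed=3, noise_sigma_hu=0.0,
                           vessel_count=0, edge_sigma=0.0)
        vol = render_phantom(make_nodule_mask(spec), spec)
        assert set(np.unique(vol.data)) == {spec.background_hu, spec.nodule_hu}

    def test_mask_mean_concentrates_at_nodule_hu(self):
        spec = PhantomSpec(nodule_radius_mm=8.0, seed=6, noise_sigma_hu=40.0,
                           nodule_hu=20.0)
        mask = make_nodule_mask(spec)
        vol = render_phantom(mask, spec)
        n = mask.foreground_count()
        mean_fg = vol.data[mask.data.astype(bool)].mean()
        assert abs(mean_fg - spec.nodule_hu) < 3 * spec.noise_sigma_hu / np.sqrt(n)

    def test_same_seed_bitwise_identical(self):
        spec = PhantomSpec(nodule_radius_mm=6.0, seed=8)
        mask = make_nodule_mask(spec)
        assert np.array_equal(render_phantom(mask, spec).data,
                              render_phantom(mask, spec).data)

    def test_vessels_do_not_enter_mask(self):
        spec = PhantomSpec(nodule_radius_mm=6.0, seed=12, noise_sigma_hu=0.0,
                           vessel_count=4, edge_sigma=0.0, nodule_hu=50.0)
        mask = make_nodule_mask(spec)
        vol = render_phantom(mask, spec)
        assert np.all(vol.data[mask.data.astype(bool)] == spec.nodule_hu)
        # vessels exist somewhere in the background
        assert (vol.data[~mask.data.astype(bool)] > spec.background_hu + 100).any()


class TestCohort:
    def test_label_counts_and_round_trip(self, small_cohort, small_manifest):
        assert len(small_manifest) == 6
        assert small_manifest["label"].sum() == 3
        for _, row in small_manifest.iterrows():
            vol = load_volume(row["image_path"])
            mask = load_mask(row["mask_path"])
            assert vol.shape == mask.shape
            assert load_spacing(row["image_path"]) == (1.0, 1.0, 1.0)
            c = (row["center_z"], row["center_y"], row["center_x"])
            assert mask.data[tuple(int(v) for v in c)] == 1

    def test_determinism_of_cohort_generation(self, tmp_path):
        m1 = generate_cohort(4, 0.5, seed=77, out_dir=tmp_path / "a")
        m2 = generate_cohort(4, 0.5, seed=77, out_dir=tmp_path / "b")
        assert m1["label"].tolist() == m2["label"].tolist()
        v1 = load_volume(tmp_path / "a" / m1.iloc[0]["image_path"])
        v2 = load_volume(tmp_path / "b" / m2.iloc[0]["image_path"])
        assert np.array_equal(v1.data, v2.data)

    def test_malignant_nodules_larger_on_average(self):
        # class-conditional radii: compare mean mask volume over 50 specs
        vols = {0: [], 1: []}
        for i in range(50):
            label = i % 2
            spec = sample_spec(label, seed=1000 + i)
            vols[label].append(make_nodule_mask(spec).foreground_count())
        assert np.mean(vols[1]) > np.mean(vols[0])

    def test_volume_threshold_classifier_separates_classes(self):
        """A trivial foreground-count threshold classifier must exceed 80%
        accuracy on a default cohort, guaranteeing learnable class signal."""
        counts, labels = [], []
        for i in range(100):
            label = i % 2
            spec = sample_spec(label, seed=5000 + i)
            counts.append(make_nodule_mask(spec).foreground_count())
            labels.append(label)
        counts, labels = np.array(counts), np.array(labels)
        best = max(
            np.mean((counts >= t) == labels) for t in np.unique(counts)
        )
        assert best > 0.80

    def test_manifest_loader_requires_columns(self, tmp_path):
        (tmp_path / "bad.csv").write_text("case_id,image_path\nx,y\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_manifest(tmp_path / "bad.csv")
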