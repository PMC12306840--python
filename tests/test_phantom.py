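"""Phantom generator ground truth: signal levels, mask bookkeeping, analytic
ejection fraction vs a pixel-counting oracle, and container I/O."""

import json

import h5py
import numpy as np
import pytest

import cinedenoise.phantom as ph
from cinedenoise.noise import synth_gfactor_map
from cinedenoise.phantom import (
    FormatError,
    PhantomSpec,
    build_dataset,
    export_magnitude_nifti,
    generate_cine_phantom,
    phantom_ef,
    random_phantom_spec,
    read_series_container,
    write_series_container,
)


class TestGeneration:
    def test_signal_means_on_interior_pixels(self):
        spec = PhantomSpec()  # protocol matrix 256x144, 30 phases
        series, masks = generate_cine_phantom(spec)
        assert series.shape == (1, 1, 30, 256, 144)
        mag = series.magnitude()[0, 0]
        blood = mag[masks.interior(ph.LABEL_BLOOD)].mean()
        myo = mag[masks.interior(ph.LABEL_MYO)].mean()
        assert abs(blood - 105.7) / 105.7 < 0.01
        assert abs(myo - 37.0) / 37.0 < 0.01

    def test_static_phantom_when_no_contraction(self):
        spec = PhantomSpec(matrix=(64, 64), phases=5, endo_radii=(12, 10),
                           wall_thickness=5, contraction_amp=0.0)
        series, _ = generate_cine_phantom(spec)
        assert np.array_equal(
            np.broadcast_to(series.values[:, :, :1], series.shape),
            series.values,
        )

    def test_magnitude_unchanged_by_complex_phase(self):
        base = PhantomSpec(matrix=(64, 64), phases=3, endo_radii=(12, 10),
                           wall_thickness=5, seed=8)
        flat = ph.PhantomSpec(**{**base.__dict__, "phase_poly_scale": 0.0})
        a, _ = generate_cine_phantom(base)
        b, _ = generate_cine_phantom(flat)
        assert np.abs(a.magnitude() - b.magnitude()).max() < 1e-9
        assert np.abs(a.values.imag).max() > 0

    def test_mask_labels_partition_every_pixel(self, desk_phantom):
        _, _, masks = desk_phantom
        f, h, w = masks.labels.shape
        counts = (masks.mask(0).sum() + masks.mask(1).sum()
                  + masks.mask(2).sum())
        assert counts == f * h * w

    def test_blood_pool_inside_myocardial_ring(self, desk_phantom):
        from scipy.ndimage import binary_dilation

        _, _, masks = desk_phantom
        for t in range(masks.labels.shape[0]):
            grown = binary_dilation(masks.blood[t])
            touches = grown & ~masks.blood[t]
            assert masks.myocardium[t][touches].all()

    def test_cycle_is_periodic(self):
        spec = PhantomSpec()
        b = spec.contraction_bump(np.array([0.0, float(spec.phases)]))
        assert abs(b[0] - b[1]) < 1e-12

    def test_deterministic_from_seed(self):
        spec = PhantomSpec(matrix=(48, 48), phases=4, endo_radii=(10, 8),
                           wall_thickness=4, seed=5)
        a, _ = generate_cine_phantom(spec)
        b, _ = generate_cine_phantom(spec)
        assert np.array_equal(a.values, b.values)

    def test_infeasible_geometry_raises(self):
        spec = PhantomSpec(matrix=(64, 64), endo_radii=(20, 18),
                           wall_thickness=1.0, contraction_amp=0.0,
                           epi_contraction_frac=0.0)
        bad = ph.PhantomSpec(**{**spec.__dict__, "wall_thickness": 0.5,
                                "contraction_amp": 0.9,
                                "epi_contraction_frac": 1.2})
        with pytest.raises(ValueError):
            bad.radii_at(np.array([bad.systole_frac * bad.phases]))


class TestEjectionFraction:
    def test_zero_without_contraction(self):
        assert phantom_ef(PhantomSpec(contraction_amp=0.0)) == 0.0

    def test_half_when_radii_shrink_by_sqrt2(self):
        spec = PhantomSpec(contraction_amp=1.0 - 1.0 / np.sqrt(2.0))
        assert abs(phantom_ef(spec) - 0.5) < 1e-3

    def test_analytic_matches_pixel_counting_oracle(self):
        spec = PhantomSpec()
        _, masks = generate_cine_phantom(spec)
        areas = masks.blood.sum(axis=(1, 2)).astype(float)
        ef_pixels = (areas.max() - areas.min()) / areas.max()
        assert abs(phantom_ef(spec) - ef_pixels) / ef_pixels < 0.02


class TestDataset:
    def test_split_19_train_1_val(self, tmp_path):
        manifest = build_dataset(20, tmp_path / "ds", seed=3,
                                 matrix=(32, 32), phases=2)
        splits = [e["split"] for e in manifest["entries"]]
        assert splits.count("val") == 1 and splits.count("train") == 19

    def test_same_seed_identical_manifest(self, tmp_path):
        m1 = build_dataset(5, tmp_path / "a", seed=11, matrix=(32, 32),
                           phases=2)
        m2 = build_dataset(5, tmp_path / "b", seed=11, matrix=(32, 32),
                           phases=2)
        assert m1["entries"] == m2["entries"]

    def test_generated_specs_satisfy_invariants(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            spec = random_phantom_spec(rng, matrix=(64, 64), phases=4)
            endo_a, endo_b, epi_a, epi_b = spec.radii_at(
                np.linspace(0, spec.phases, 50)
            )
            assert np.all(epi_a > endo_a) and np.all(epi_b > endo_b)
            assert np.all(endo_a > 0)


class TestContainer:
    def test_lossless_roundtrip(self, tmp_path, desk_phantom, desk_gmap):
        spec, series, masks = desk_phantom
        path = tmp_path / "s.h5"
        write_series_container(path, series, desk_gmap, masks, spec)
        s2, g2, m2, sp2 = read_series_container(path)
        assert np.array_equal(s2.values, series.values)
        assert np.array_equal(g2.values, desk_gmap.values)
        assert np.array_equal(m2.labels, masks.labels)
        assert sp2 == spec

    def test_nifti_axes(self, tmp_path, desk_phantom):
        import nibabel as nib

        _, series, _ = desk_phantom
        path = tmp_path / "mag.nii"
        export_magnitude_nifti(series, path)
        img = nib.load(path)
        assert img.shape == (64, 64, 1, 8)
        assert np.allclose(np.asarray(img.dataobj)[..., 0, 3],
                           series.magnitude()[0, 0, 3], atol=1e-3)

    def test_missing_dataset_is_format_error(self, tmp_path, desk_phantom,
                                             desk_gmap):
        spec, series, masks = desk_phantom
        path = tmp_path / "broken.h5"
        write_series_container(path, series, desk_gmap, masks, spec)
        with h5py.File(path, "a") as fh:
            del fh["gmap"]
        with pytest.raises(FormatError):
            read_series_container(path)

    def test_future_minor_version_still_reads(self, tmp_path, desk_phantom,
                                              desk_gmap):
        spec, series, masks = desk_phantom
        path = tmp_path / "future.h5"
        write_series_container(path, series, desk_gmap, masks, spec)
        with h5py.File(path, "a") as fh:
            fh.attrs["version_minor"] = 99
            fh.create_dataset("extras/new_feature", data=np.arange(3))
        s2, _, _, sp2 = read_series_container(path)
        assert np.array_equal(s2.values, series.values)
        assert sp2 == spec

    def test_future_major_version_rejected(self, tmp_path, desk_phantom,
                                           desk_gmap):
        spec, series, masks = desk_phantom
        path = tmp_path / "major.h5"
        write_series_container(path, series, desk_gmap, masks, spec)
        with h5py.File(path, "a") as fh:
            fh.attrs["version_major"] = 2
        with pytest.raises(FormatError):
            read_series_container(path)
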