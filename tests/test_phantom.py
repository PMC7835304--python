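import numpy as np
import pytest

from nfq.errors import ConfigurationError, SizingError
from nfq.phantom import (
    REGION_CODES,
    REGIONS,
    default_cs_link,
    default_effect_profile,
    draw_cohort_truth,
    generate_atlas,
    generate_cohort,
    generate_fluorescence,
    generate_pet,
    generate_spio_mri,
    null_effect_profile,
)
from nfq.registration import resample
from nfq.transforms import RigidTransform, random_rigid
from nfq.volume import Volume3D


class TestGenerateAtlas:
    def test_reference_grid_has_exactly_seven_codes(self):
        atlas = generate_atlas((64, 64, 64), (0.2, 0.2, 0.2), seed=1)
        assert set(np.unique(atlas.labels.data)) == set(range(7))
        for name in REGIONS:
            assert atlas.region_mask(name).sum() > 0

    def test_deterministic_for_fixed_seed(self):
        a = generate_atlas((48,) * 3, (0.25,) * 3, seed=7)
        b = generate_atlas((48,) * 3, (0.25,) * 3, seed=7)
        assert np.array_equal(a.labels.data, b.labels.data)
        for n in a.landmarks.names:
            assert np.array_equal(a.landmarks.points[n], b.landmarks.points[n])

    def test_tiny_grid_raises_sizing_error(self):
        with pytest.raises(SizingError):
            generate_atlas((8, 8, 8), (0.2,) * 3, seed=1)

    def test_landmarks_outside_brain(self, atlas):
        for n in atlas.landmarks.names:
            vox = np.round(atlas.labels.world_to_voxel(atlas.landmarks.points[n])[0])
            assert atlas.labels.data[tuple(vox.astype(int))] == 0


class TestGeneratePET:
    def test_noiseless_psf_free_region_ratio_is_exact(self, atlas, suvr_profile):
        pet, _ = generate_pet(atlas, suvr_profile, psf_fwhm_mm=0.0, noise_sd=0.0, seed=1)
        frame = pet.frames[0].data
        cb = frame[atlas.region_mask("cerebellum")].mean()
        nc = frame[atlas.region_mask("neocortex")].mean()
        assert cb / nc == pytest.approx(2.4, abs=1e-12)

    def test_flat_profile_gives_uniform_frames(self, atlas):
        flat = {r: 1.0 for r in REGIONS}
        pet, _ = generate_pet(atlas, flat, psf_fwhm_mm=0.0, noise_sd=0.0,
                              background_ratio=1.0, seed=1)
        assert np.ptp(pet.frames[0].data) == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducibility_and_variation(self, atlas, suvr_profile):
        a, _ = generate_pet(atlas, suvr_profile, seed=5)
        b, _ = generate_pet(atlas, suvr_profile, seed=5)
        c, _ = generate_pet(atlas, suvr_profile, seed=6)
        assert np.array_equal(a.frames[0].data, b.frames[0].data)
        assert not np.array_equal(a.frames[0].data, c.frames[0].data)

    def test_missing_region_and_bad_reference(self, atlas, suvr_profile):
        partial = {k: v for k, v in suvr_profile.items() if k != "thalamus"}
        with pytest.raises(ConfigurationError):
            generate_pet(atlas, partial)
        off = dict(suvr_profile, neocortex=1.1)
        with pytest.raises(ConfigurationError):
            generate_pet(atlas, off)

    def test_frame_timing_default(self, atlas, suvr_profile):
        pet, _ = generate_pet(atlas, suvr_profile, psf_fwhm_mm=0, noise_sd=0)
        assert len(pet.frames) == 6
        assert pet.frame_times[0] == (20.0, 25.0)
        assert pet.frame_times[-1] == (45.0, 50.0)


class TestGenerateSpioMri:
    def test_realized_fraction_near_request_and_recorded_exactly(self, atlas):
        mri, _, truth = generate_spio_mri(atlas, {"cerebellum": 14.5}, seed=7)
        assert truth.true_lesion_fraction["cerebellum"] == pytest.approx(14.5, abs=0.5)
        # ground-truth consistency: recorded == recomputation from the mask
        ref = Volume3D(np.zeros(atlas.labels.shape, np.int16), atlas.labels.affine)
        native = resample(atlas.labels, RigidTransform.identity(), ref, "nearest").data
        mask = truth.true_lesion_mask.data.astype(bool)
        code = REGION_CODES["cerebellum"]
        recomputed = 100.0 * (mask & (native == code)).sum() / (native == code).sum()
        assert truth.true_lesion_fraction["cerebellum"] == recomputed

    def test_clean_phantom_is_constant_inside_brain(self, atlas):
        mri, _, truth = generate_spio_mri(
            atlas, {}, bias_amplitude=0.0, noise_sd=0.0, seed=3
        )
        brain_vals = mri.data[atlas.brain_mask]
        assert np.ptp(brain_vals) == pytest.approx(0.0, abs=1e-9)
        assert not truth.true_lesion_mask.data.any()

    def test_identity_misalignment_keeps_landmarks(self, atlas):
        _, lms, _ = generate_spio_mri(atlas, {}, misalignment=None, seed=1)
        for n in lms.names:
            assert np.allclose(lms.points[n], atlas.landmarks.points[n])

    def test_bias_field_properties(self, atlas, lesion_request):
        _, _, truth = generate_spio_mri(atlas, lesion_request, bias_amplitude=0.2, seed=4)
        field = truth.true_bias_field.data
        brain = atlas.brain_mask
        assert np.all(field > 0)
        assert field[brain].mean() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(field[brain] - 1.0).max() <= 0.25  # ~requested amplitude

    def test_invalid_contrast_rejected(self, atlas):
        with pytest.raises(ConfigurationError):
            generate_spio_mri(atlas, {}, lesion_contrast=1.5)


class TestGenerateCohort:
    def test_cohort_shape_and_labels(self):
        cohort = generate_cohort(n_eae=3, n_ctr=2, seed=9, grid_shape=(48,) * 3)
        assert len(cohort.animals) == 5
        assert sum(a.record.group == "EAE" for a in cohort.animals) == 3
        for a in cohort.animals:
            assert a.record.cs >= 0.0
            assert a.truth.true_suvr["neocortex"] == 1.0

    def test_monotone_cs_link_preserves_burden_ranks(self):
        link = lambda b: 4.0 * b / (b + 20.0)  # strictly monotone
        cohort = generate_cohort(n_eae=4, n_ctr=2, cs_link=link, seed=3,
                                 grid_shape=(48,) * 3)
        eae = [a for a in cohort.animals if a.record.group == "EAE"]
        burdens = [sum(a.truth.true_lesion_fraction.values()) for a in eae]
        cs = [a.record.cs for a in eae]
        assert np.array_equal(np.argsort(burdens), np.argsort(cs))

    def test_too_small_groups_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(n_eae=1, n_ctr=5)
        with pytest.raises(ConfigurationError):
            generate_cohort(n_eae=0, n_ctr=5)

    def test_truth_draw_layer_pins_reference_and_is_exchangeable_under_null(self):
        rng = np.random.default_rng(12)
        null = null_effect_profile()
        draws = draw_cohort_truth(null, 200, 200, rng)
        for d in draws[:5]:
            assert d.suvr["neocortex"] == 1.0
        eae = np.array([d.suvr["cerebellum"] for d in draws if d.group == "EAE"])
        ctr = np.array([d.suvr["cerebellum"] for d in draws if d.group == "CTR"])
        # same moments under the null profile
        assert eae.mean() == pytest.approx(ctr.mean(), abs=0.1)
        assert eae.std() == pytest.approx(ctr.std(), abs=0.08)

    def test_default_profile_on_group_summary_scale(self):
        prof = default_effect_profile()
        assert prof["cerebellum"].suvr_eae == 2.4
        assert prof["cerebellum"].spio_eae == 14.5
        assert default_cs_link(0.0) == 0.5
        assert default_cs_link(1000.0) == 4.0


class TestGenerateFluorescence:
    def test_all_double_gives_full_coloc(self):
        from nfq.histology import coloc_percent

        a, b, cells = generate_fluorescence(n_cells=30, frac_double=1.0, seed=2)
        res = coloc_percent(a, b)
        assert res.percent > 95.0
        assert cells["positive_a"].all() and cells["positive_b"].all()

    def test_no_double_gives_zero_coloc_on_cell_table(self):
        _, _, cells = generate_fluorescence(n_cells=30, frac_double=0.0, seed=2)
        assert not cells["positive_a"].any()

    def test_fraction_recovered_from_cell_table(self):
        _, _, cells = generate_fluorescence(n_cells=50, frac_double=0.4, seed=5)
        pct = 100.0 * cells["positive_a"].sum() / len(cells)
        assert pct == pytest.approx(40.0, abs=5.0)

    def test_distances_nonnegative_and_deterministic(self):
        a1, b1, c1 = generate_fluorescence(seed=11)
        a2, b2, c2 = generate_fluorescence(seed=11)
        assert (c1["distance_to_vessel_um"] >= 0).all()
        assert np.array_equal(a1, a2) and np.array_equal(b1, b2)
        assert c1.equals(c2)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_fluorescence(frac_double=1.2)


def test_spio_vol_monotone_in_lesion_burden(atlas):
    """Adding labelled voxels never decreases a containing region's fraction."""
    from nfq.spio import spio_fractional_volume

    rng = np.random.default_rng(0)
    lab = np.zeros(atlas.labels.shape, dtype=bool)
    region = atlas.region_mask("thalamus")
    coords = np.argwhere(region)
    prev = 0.0
    for n in (5, 20, 60):
        idx = coords[rng.choice(len(coords), size=n, replace=False)]
        lab[tuple(idx.T)] = True
        frac = spio_fractional_volume(
            Volume3D(lab, atlas.labels.affine), atlas, "thalamus"
        )
        assert frac >= prev
        prev = frac
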