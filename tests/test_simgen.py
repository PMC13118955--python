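"""Synthetic generator: determinism, planted linearity, channel consistency,
morphology statistics."""

import numpy as np
import pytest
from scipy import ndimage

from mesofluor import simgen
from mesofluor.simgen import (
    COMPACT,
    DISPERSED,
    NOISELESS,
    GroundTruthWell,
    NoiseParams,
    OpticsParams,
    generate_calibration_set,
    generate_dose_response_experiment,
    generate_spheroid_field,
    render_channel_image,
)


def uniform_truth(shape, value, media_background=0.0):
    return GroundTruthWell(
        fluorophore_map=np.full(shape, float(value)),
        thickness_map=np.zeros(shape),
        cluster_mask=np.zeros(shape, dtype=bool),
        administered_concentration=0.0,
        media_background=media_background,
    )


class TestSpheroidField:
    def test_identical_seeds_identical_output(self):
        a = generate_spheroid_field(COMPACT, (64, 64), 3.0, seed=7)
        b = generate_spheroid_field(COMPACT, (64, 64), 3.0, seed=7)
        np.testing.assert_array_equal(a.fluorophore_map, b.fluorophore_map)
        np.testing.assert_array_equal(a.cluster_mask, b.cluster_mask)

    def test_zero_concentration_is_media_background_only(self):
        t = generate_spheroid_field(COMPACT, (128, 128), 0.0, seed=7)
        assert np.all(t.fluorophore_map == t.media_background)
        assert t.cluster_mask.any()  # cells are present, just drug-free

    def test_emission_linear_in_concentration(self):
        t1 = generate_spheroid_field(COMPACT, (128, 128), 2.0, seed=7)
        t2 = generate_spheroid_field(COMPACT, (128, 128), 4.0, seed=7)
        drug1 = t1.fluorophore_map - t1.media_background
        drug2 = t2.fluorophore_map - t2.media_background
        np.testing.assert_allclose(drug2, 2.0 * drug1, rtol=1e-12)

    def test_emission_proportional_to_thickness_in_clusters(self):
        t = generate_spheroid_field(COMPACT, (128, 128), 3.0, seed=3)
        inside = t.cluster_mask
        expected = t.media_background + t.uptake_coefficient * 3.0 * t.thickness_map
        np.testing.assert_allclose(t.fluorophore_map[inside], expected[inside])

    def test_drawn_cluster_count_within_configured_range(self):
        lo, hi = DISPERSED.cluster_count_range
        for seed in range(20):
            t = generate_spheroid_field(DISPERSED, (256, 256), 3.0, seed=seed)
            assert lo <= t.n_clusters <= hi

    @pytest.mark.parametrize(
        "args", [((0, 64), 1.0, 0), ((64, 64), -1.0, 0)]
    )
    def test_invalid_arguments_rejected(self, args):
        shape, conc, seed = args
        with pytest.raises(ValueError):
            generate_spheroid_field(COMPACT, shape, conc, seed)

    def test_unknown_archetype_rejected(self):
        with pytest.raises(ValueError, match="archetype"):
            generate_spheroid_field("spiky", (64, 64), 1.0, 0)

    def test_mask_statistics_match_configuration_over_seeds(self):
        # empirical mean of drawn counts and mask area over 100 seeds vs the
        # configured distribution; overlap can only shrink the union area
        lo, hi = DISPERSED.cluster_count_range
        counts, areas = [], []
        for seed in range(100):
            t = generate_spheroid_field(DISPERSED, (256, 256), 3.0, seed=seed)
            counts.append(t.n_clusters)
            areas.append(int(t.cluster_mask.sum()))
        assert np.mean(counts) == pytest.approx((lo + hi) / 2.0, abs=0.75)
        no_overlap_area = (
            (lo + hi) / 2.0 * np.pi
            * (DISPERSED.radius_mean**2 + DISPERSED.radius_spread**2)
        )
        assert 0.5 * no_overlap_area < np.mean(areas) <= no_overlap_area

    def test_morphology_contrast_dispersed_more_variable(self):
        # over repeated seeds the dispersed archetype's connected-component
        # size distribution is more variable than the compact one's
        cvs = {}
        for arch in (COMPACT, DISPERSED):
            sizes = []
            for seed in range(30):
                t = generate_spheroid_field(arch, (256, 256), 3.0, seed=seed)
                lab, n = ndimage.label(t.cluster_mask)
                sizes += list(
                    ndimage.sum_labels(t.cluster_mask, lab, index=np.arange(1, n + 1))
                )
            sizes = np.asarray(sizes)
            cvs[arch.name] = sizes.std(ddof=1) / sizes.mean()
        assert cvs["dispersed"] > cvs["compact"]


class TestRenderChannelImage:
    def test_zero_fluorophore_no_leakage_is_dark_level(self):
        optics = OpticsParams(leakage_fraction=0.0, leakage_pattern=np.zeros((32, 32)))
        img = render_channel_image(
            uniform_truth((32, 32), 0.0), optics, NOISELESS, "fluorescence"
        )
        assert np.all(img.pixels == optics.dark_level)

    def test_uniform_fluorophore_times_gain(self):
        optics = OpticsParams(
            gain=2.0, leakage_fraction=0.0, dark_level=0.0,
            leakage_pattern=np.zeros((16, 16)),
        )
        img = render_channel_image(
            uniform_truth((16, 16), 7.0), optics, NOISELESS, "fluorescence"
        )
        np.testing.assert_allclose(img.pixels, 14.0)

    def test_channel_consistency_ratio_is_leakage_fraction(self):
        # noiseless zero-fluorophore: (F - dark) = g * (ND - dark) pixelwise
        optics = OpticsParams(leakage_fraction=0.91)
        truth = uniform_truth((64, 64), 0.0)
        f = render_channel_image(truth, optics, NOISELESS, "fluorescence")
        nd = render_channel_image(truth, optics, NOISELESS, "nd_reference")
        np.testing.assert_allclose(
            f.pixels - optics.dark_level,
            0.91 * (nd.pixels - optics.dark_level),
            rtol=1e-12,
        )

    def test_dark_role_ignores_scene(self):
        img = render_channel_image(
            uniform_truth((16, 16), 100.0), OpticsParams(), NOISELESS, "dark"
        )
        assert np.all(img.pixels == OpticsParams().dark_level)

    def test_unknown_role_rejected(self):
        with pytest.raises(ValueError):
            render_channel_image(
                uniform_truth((8, 8), 0.0), OpticsParams(), NOISELESS, "brightfield"
            )


class TestCalibrationSet:
    def test_repeatable_bit_for_bit(self):
        kwargs = dict(grid_shape=(32, 32))
        a = generate_calibration_set(OpticsParams(), NoiseParams(seed=1), 4, 5, **kwargs)
        b = generate_calibration_set(OpticsParams(), NoiseParams(seed=1), 4, 5, **kwargs)
        assert len(a.water_well_pairs) == 4
        for (f1, n1), (f2, n2) in zip(a.water_well_pairs, b.water_well_pairs):
            np.testing.assert_array_equal(f1.pixels, f2.pixels)
            np.testing.assert_array_equal(n1.pixels, n2.pixels)

    def test_noiseless_pairs_satisfy_exact_scaling(self):
        g = 0.77
        cal = generate_calibration_set(
            OpticsParams(leakage_fraction=g), NOISELESS, 3, 0, grid_shape=(32, 32)
        )
        dark = OpticsParams().dark_level
        for f, nd in cal.water_well_pairs:
            np.testing.assert_allclose(
                f.pixels - dark, g * (nd.pixels - dark), rtol=1e-12
            )
        assert cal.planted_leakage_fraction == g

    def test_rejects_no_wells(self):
        with pytest.raises(ValueError):
            generate_calibration_set(OpticsParams(), NOISELESS, 0, 0)


class TestDoseResponseExperiment:
    def test_rejects_bad_concentrations(self):
        for bad in ([], [-1.0]):
            with pytest.raises(ValueError):
                generate_dose_response_experiment(
                    bad, COMPACT, OpticsParams(), NOISELESS, 0
                )

    def test_design_layout(self, default_experiment):
        b = default_experiment
        roles = [w.role for w in b.wells]
        assert roles.count("treatment") == 4
        assert roles.count("control") == 1
        assert roles.count("blank") == 1
        # dox post + pop pre/post, each a fluorescence/ND pair
        assert len(b.wells[0].frames) == 6

    def test_planted_bleach_scales_pop_post_emission(self):
        b = generate_dose_response_experiment(
            [3.0], COMPACT, OpticsParams(), NOISELESS, 2, bleach_factor=0.85
        )
        w = b.treatment_wells()[0]
        pre = w.get_frame("pop", "fluorescence", "pre_activation")
        post = w.get_frame("pop", "fluorescence", "post_activation")
        dark = b.optics.dark_level
        inside = w.truth.cluster_mask
        drug_pre = (
            pre.pixels - dark
            - b.optics.leakage_fraction * b.optics.resolved_leakage(w.truth.shape)
            - b.optics.gain * w.truth.media_background
        )
        drug_post = (
            post.pixels - dark
            - b.optics.leakage_fraction * b.optics.resolved_leakage(w.truth.shape)
            - b.optics.gain * w.truth.media_background
        )
        np.testing.assert_allclose(drug_post[inside], 0.85 * drug_pre[inside], rtol=1e-9)

    def test_shared_field_seed_gives_identical_geometry(self):
        b = generate_dose_response_experiment(
            [1.0, 9.0], COMPACT, OpticsParams(), NOISELESS, 0, shared_field_seed=11
        )
        w1, w9 = b.treatment_wells()
        np.testing.assert_array_equal(w1.truth.cluster_mask, w9.truth.cluster_mask)
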