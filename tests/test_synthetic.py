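import numpy as np
import pytest

from treeclass import (ComponentLabel, SceneConfig, default_templates,
                       extract_features, generate_scene,
                       sample_component_geometry, synth_spectrum,
                       synthetic_panel, calibrate_reflectance)
from treeclass.features import FEATURE_NAMES
from treeclass.grid import DEFAULT_GRID


def small_config(**kw):
    counts = kw.pop(
        "counts",
        {
            ComponentLabel.UNRIPE_FRUIT: 10,
            ComponentLabel.RIPE_FRUIT: 10,
            ComponentLabel.WOOD: 10,
            ComponentLabel.LEAF: 10,
        },
    )
    return SceneConfig(counts=counts, **kw)


class TestTemplates:
    def test_wood_curve_is_monotonic(self):
        base = default_templates()[ComponentLabel.WOOD].base(DEFAULT_GRID.wavelengths)
        assert np.all(np.diff(base) >= 0)

    @pytest.mark.parametrize("label",
                             [ComponentLabel.LEAF, ComponentLabel.UNRIPE_FRUIT])
    def test_red_edge_classes_double_from_680_to_800(self, label):
        base = default_templates()[label].base(DEFAULT_GRID.wavelengths)
        assert base[DEFAULT_GRID.index(800)] >= 2 * base[DEFAULT_GRID.index(680)]

    def test_ripe_fruit_plateau_near_twenty_percent(self):
        base = default_templates()[ComponentLabel.RIPE_FRUIT].base(
            DEFAULT_GRID.wavelengths
        )
        window = base[DEFAULT_GRID.slice(600, 900)]
        assert np.all(np.abs(window - 0.20) <= 0.05)


class TestGeometry:
    def test_exact_per_component_counts(self):
        coords, labels, edge = sample_component_geometry(small_config(seed=0))
        assert len(coords) == 40
        for lab in ComponentLabel:
            assert (labels == lab).sum() == 10

    def test_zero_edge_fraction_sets_no_flags(self):
        _, _, edge = sample_component_geometry(small_config(seed=1,
                                                            edge_fraction=0.0))
        assert not edge.any()

    def test_empty_scene(self):
        config = small_config(counts={lab: 0 for lab in ComponentLabel})
        coords, labels, edge = sample_component_geometry(config)
        assert len(coords) == 0 and len(labels) == 0

    def test_edge_fraction_close_to_configured_across_seeds(self):
        # 5,000-point scenes, 10 seeds: fraction within 3 percentage points
        fractions = []
        for seed in range(10):
            _, _, edge = sample_component_geometry(SceneConfig(seed=seed))
            fractions.append(edge.mean())
        assert all(abs(f - 0.15) <= 0.03 for f in fractions)


class TestSpectra:
    def test_zero_noise_nonedge_returns_base_exactly(self):
        templates = default_templates(noise_sd=0.0)
        for lab, tpl in templates.items():
            spec = synth_spectrum(lab, False, tpl, 0)
            np.testing.assert_allclose(spec, tpl.base(DEFAULT_GRID.wavelengths))

    def test_zero_noise_unflattened_edge_is_pure_attenuation(self):
        templates = default_templates(noise_sd=0.0, edge_flattening=0.0)
        tpl = templates[ComponentLabel.WOOD]
        spec = synth_spectrum(ComponentLabel.WOOD, True, tpl, 0)
        base = tpl.base(DEFAULT_GRID.wavelengths)
        np.testing.assert_allclose(spec, base / (1 + tpl.edge_attenuation))
        # non-edge mean exceeds edge mean by exactly the attenuation
        assert base.mean() / spec.mean() - 1 == pytest.approx(tpl.edge_attenuation)

    def test_leaf_edge_deficit_matches_configured_percentage(self):
        # Monte-Carlo: non-edge mean reflectance over edge mean, leaf class
        tpl = default_templates()[ComponentLabel.LEAF]
        rng = np.random.default_rng(17)
        nonedge = np.mean(
            [synth_spectrum(ComponentLabel.LEAF, False, tpl, rng) for _ in range(1000)]
        )
        edge = np.mean(
            [synth_spectrum(ComponentLabel.LEAF, True, tpl, rng) for _ in range(1000)]
        )
        excess = nonedge / edge - 1
        assert excess == pytest.approx(0.1818, rel=0.02)

    def test_template_label_mismatch_rejected(self):
        tpl = default_templates()[ComponentLabel.LEAF]
        with pytest.raises(ValueError):
            synth_spectrum(ComponentLabel.WOOD, False, tpl, 0)


class TestScene:
    def test_same_seed_is_bit_identical(self):
        a = generate_scene(small_config(seed=9))
        b = generate_scene(small_config(seed=9))
        np.testing.assert_array_equal(a.cloud.coords, b.cloud.coords)
        np.testing.assert_array_equal(a.cloud.spectra, b.cloud.spectra)
        np.testing.assert_array_equal(a.edge_flags, b.edge_flags)

    def test_reflectance_kind_and_nonnegative(self):
        scene = generate_scene(small_config(seed=2))
        assert scene.cloud.spectra_kind == "reflectance"
        assert scene.cloud.spectra.min() >= 0

    def test_intensity_mode_round_trips_through_calibration(self):
        config = small_config(seed=3)
        reflect = generate_scene(config)
        intense = generate_scene(config, as_intensity=True)
        assert intense.cloud.spectra_kind == "intensity"
        back = calibrate_reflectance(intense.cloud, synthetic_panel())
        np.testing.assert_allclose(back.spectra, reflect.cloud.spectra, rtol=1e-9)

    def test_class_mean_index_ordering(self):
        # vegetation indices separate the components the way leaves,
        # fruit and bark separate in the field
        scene = generate_scene(SceneConfig(seed=4, edge_fraction=0.0))
        table = extract_features(scene.cloud)
        labels = scene.cloud.labels
        ndvi = table.values[:, FEATURE_NAMES.index("NDVI")]
        ci = table.values[:, FEATURE_NAMES.index("CI_red_edge")]
        assert ndvi[labels == ComponentLabel.LEAF].mean() > \
            ndvi[labels == ComponentLabel.WOOD].mean()
        assert ndvi[labels == ComponentLabel.UNRIPE_FRUIT].mean() > \
            ndvi[labels == ComponentLabel.WOOD].mean()
        assert ci[labels == ComponentLabel.RIPE_FRUIT].mean() < \
            ci[labels == ComponentLabel.LEAF].mean()

    def test_edge_points_have_lower_nir_average(self):
        scene = generate_scene(SceneConfig(seed=5))
        table = extract_features(scene.cloud)
        avg = table.values[:, FEATURE_NAMES.index("AVG_R760_R930")]
        labels, edge = scene.cloud.labels, scene.edge_flags
        for lab in ComponentLabel:
            sel = labels == lab
            assert avg[sel & ~edge].mean() > avg[sel & edge].mean()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SceneConfig(edge_fraction=1.0)
        with pytest.raises(ValueError):
            SceneConfig(counts={ComponentLabel.WOOD: -1})
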