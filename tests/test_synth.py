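"""Simulator: geometry, decay model, Poisson rendering, presets."""

import numpy as np
import pytest

import flimpheno as fp
from flimpheno.synth import CYTOSOL, MITO, NUCLEUS, ValidationError

from _oracles import direct_convolved_decay


class TestSceneGeometry:
    def test_zero_cells_gives_empty_maps(self):
        spec = fp.SceneSpec(shape=(64, 64), n_cells=0, seed=1)
        scene = fp.generate_scene(spec, list(fp.default_profiles().values()))
        assert scene.n_cells == 0
        assert not scene.cell_ids.any()
        assert not scene.compartments.any()

    def test_determinism_same_spec_same_scene(self):
        spec = fp.SceneSpec(shape=(96, 96), n_cells=5, seed=7)
        profs = [fp.default_profiles()["control"]]
        a = fp.generate_scene(spec, profs)
        b = fp.generate_scene(spec, profs)
        np.testing.assert_array_equal(a.cell_ids, b.cell_ids)
        np.testing.assert_array_equal(a.compartments, b.compartments)
        for ch in fp.CHANNELS:
            for p in a.true_params[ch]:
                np.testing.assert_array_equal(a.true_params[ch][p],
                                              b.true_params[ch][p])

    def test_requested_cells_each_with_interior_nucleus(self):
        spec = fp.SceneSpec(shape=(256, 256), n_cells=20, seed=3)
        scene = fp.generate_scene(spec, list(fp.default_profiles().values()))
        ids = np.unique(scene.cell_ids)
        assert set(ids[ids > 0]) == set(range(1, 21))
        for cid in range(1, 21):
            cell = scene.cell_ids == cid
            nuc = cell & (scene.compartments == NUCLEUS)
            assert nuc.any()
            assert nuc.sum() < cell.sum()  # nucleus strictly inside the cell

    def test_cells_do_not_overlap(self):
        spec = fp.SceneSpec(shape=(128, 128), n_cells=8, seed=5)
        scene = fp.generate_scene(spec, [fp.default_profiles()["control"]])
        # every nonzero pixel belongs to exactly one cell and one compartment
        inside = scene.cell_ids > 0
        assert (scene.compartments[inside] > 0).all()
        assert (scene.compartments[~inside] == 0).all()

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValidationError):
            fp.generate_scene(
                fp.SceneSpec(cell_radius=(5.0, 6.0), nucleus_radius=(6.0, 7.0)),
                [fp.default_profiles()["control"]])

    def test_mitochondria_brighter_than_cytosol(self):
        spec = fp.SceneSpec(shape=(128, 128), n_cells=6, seed=9)
        scene = fp.generate_scene(spec, [fp.default_profiles()["control"]])
        ph = scene.true_params["nadh"]["photons"]
        mito = ph[scene.compartments == MITO]
        cyto = ph[scene.compartments == CYTOSOL]
        assert mito.mean() > cyto.mean()


class TestModelDecay:
    def test_single_exponential_with_delta_irf(self, irf):
        d = fp.delta_irf()
        curve = fp.model_decay(1.0, 2.0, 3.0, 0.0, 1000.0, d)
        t = (np.arange(d.n_bins) + 0.5) * d.dt
        expected = np.exp(-t / 2.0)
        expected *= 1000.0 / expected.sum()
        np.testing.assert_allclose(curve, expected, rtol=1e-12)

    def test_zero_photons_zero_background_is_flat_zero(self, irf):
        assert not fp.model_decay(0.5, 0.5, 2.5, 0.0, 0.0, irf).any()

    def test_matches_direct_numerical_convolution(self, irf):
        curve = fp.model_decay(0.7, 0.5, 2.5, 0.3, 5000.0, irf)
        oracle = direct_convolved_decay(0.7, 0.5, 2.5, 0.3, 5000.0,
                                        irf.response, irf.dt)
        np.testing.assert_allclose(curve, oracle, rtol=1e-10)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 2.5), (0.5, -1.0, 2.5),
                                     (0.5, 0.5, 0.0)])
    def test_invalid_parameters_rejected(self, irf, bad):
        with pytest.raises(ValidationError):
            fp.model_decay(*bad, 0.0, 100.0, irf)


class TestRenderTCSPC:
    def test_total_counts_near_expectation(self, irf):
        spec = fp.SceneSpec(shape=(48, 48), n_cells=2, cell_radius=(8.0, 10.0),
                            nucleus_radius=(3.0, 4.0), seed=13)
        scene = fp.generate_scene(spec, [fp.default_profiles()["control"]])
        nadh, _ = fp.render_tcspc(scene, irf, rng_seed=1)
        inside = scene.compartments > 0
        expected = (scene.true_params["nadh"]["photons"][inside]
                    + scene.true_params["nadh"]["c"][inside] * irf.n_bins)
        realized = nadh.intensity[inside]
        # Poisson: mean realized ~ mean expected within 5 sigma of the mean
        se = np.sqrt(expected.sum()) / inside.sum()
        assert abs(realized.mean() - expected.mean()) < 5 * se

    def test_zero_photon_scene_is_all_zero(self, irf):
        spec = fp.SceneSpec(shape=(32, 32), n_cells=0, seed=1)
        scene = fp.generate_scene(spec, [fp.default_profiles()["control"]])
        nadh, fad = fp.render_tcspc(scene, irf, rng_seed=2)
        assert not nadh.counts.any() and not fad.counts.any()

    def test_fixed_seed_bit_identical(self, small_scene):
        scene, (nadh, fad), irf = small_scene
        nadh2, fad2 = fp.render_tcspc(scene, irf, rng_seed=12)
        np.testing.assert_array_equal(nadh.counts, nadh2.counts)
        np.testing.assert_array_equal(fad.counts, fad2.counts)


class TestPresets:
    def test_encoded_effect_directions(self):
        profs = fp.default_profiles()
        gly = profs["glycolysis_inhibited"]
        oxp = profs["oxphos_inhibited"]
        for comp in (NUCLEUS, CYTOSOL, MITO):
            g, o = gly.get("nadh", comp), oxp.get("nadh", comp)
            assert g.alpha1 < o.alpha1      # reduced free NAD(P)H fraction
            assert g.tau1 > o.tau1
            assert g.tau2 > o.tau2

    def test_profile_invariants(self):
        for prof in fp.default_profiles().values():
            for p in prof.params.values():
                assert 0 <= p.alpha1 <= 1
                assert 0 < p.tau1 < p.tau2
                assert p.photons > 0

    def test_pyruvate_preset_raises_bound_fad_fraction(self):
        profs = fp.default_profiles()
        assert (profs["high_pyruvate"].get("fad", CYTOSOL).alpha1
                > profs["control"].get("fad", CYTOSOL).alpha1)


class TestFastPaths:
    def test_sample_cell_features_columns_and_determinism(self):
        a = fp.sample_cell_features({"control": 20}, seed=4)
        b = fp.sample_cell_features({"control": 20}, seed=4)
        assert list(a.columns[3:]) == fp.FEATURE_NAMES
        assert a.equals(b)

    def test_feature_direction_matches_presets(self, feature_table):
        g = feature_table.groupby("group")[["nadh_a1", "nadh_tm"]].mean()
        assert (g.loc["glycolysis_inhibited", "nadh_a1"]
                < g.loc["oxphos_inhibited", "nadh_a1"])
        assert (g.loc["glycolysis_inhibited", "nadh_tm"]
                > g.loc["oxphos_inhibited", "nadh_tm"])

    def test_stack_geometry_and_masking(self):
        images, labels, names = fp.sample_cell_stacks(
            {"control": 4, "oxphos_inhibited": 4}, seed=6)
        assert images.shape == (8, 6, 40, 40)
        assert set(labels) == {"control", "oxphos_inhibited"}
        # background pixels zero in every channel
        intens = images[:, names.index("nadh_intensity")]
        assert ((images == 0).all(axis=1) == (intens == 0)).all()
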