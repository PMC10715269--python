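"""Derived maps, per-cell aggregation, control normalization."""

import numpy as np
import pandas as pd
import pytest

import flimpheno as fp
from flimpheno.fitting import FLIMImage
from flimpheno.segmentation import SegmentationLabels


def _const_flim(shape, alpha1, tau1, tau2, intensity, channel):
    ones = np.ones(shape)
    return FLIMImage(alpha1=alpha1 * ones, tau1=tau1 * ones, tau2=tau2 * ones,
                     c=0 * ones, chi2=ones, intensity=intensity * ones,
                     valid=np.ones(shape, bool), channel=channel)


class TestDerivedMaps:
    @pytest.mark.parametrize("a1,t1,t2,expected", [
        (0.7, 0.5, 2.5, 1.1),
        (1.0, 0.8, 3.0, 0.8),
        (0.0, 0.8, 3.0, 3.0),
    ])
    def test_mean_lifetime_formula(self, a1, t1, t2, expected):
        flim = _const_flim((2, 2), a1, t1, t2, 100, "nadh")
        np.testing.assert_allclose(fp.mean_lifetime_map(flim), expected)

    def test_redox_ratio_values_and_boundaries(self):
        nadh = np.array([[150.0, 0.0, 0.0]])
        fad = np.array([[50.0, 10.0, 0.0]])
        out = fp.redox_ratio_map(nadh, fad)
        assert out[0, 0] == pytest.approx(0.25)
        assert out[0, 1] == pytest.approx(1.0)
        assert np.isnan(out[0, 2])

    def test_redox_shape_mismatch(self):
        with pytest.raises(ValueError):
            fp.redox_ratio_map(np.ones((2, 2)), np.ones((3, 3)))

    def test_flirr_values_and_guards(self):
        nadh = _const_flim((1, 3), 0.75, 0.5, 2.5, 100, "nadh")
        fad = _const_flim((1, 3), 0.5, 0.3, 2.2, 100, "fad")
        nadh.alpha1 = np.array([[0.75, 1.0, 0.5]])
        fad.alpha1 = np.array([[0.5, 0.5, 0.0]])
        out = fp.flirr_map(nadh, fad)
        assert out[0, 0] == pytest.approx(0.5)
        assert out[0, 1] == pytest.approx(0.0)
        assert np.isnan(out[0, 2])

    def test_tau_m_between_components(self, fitted_scene):
        _, nadh, fad = fitted_scene
        for flim in (nadh, fad):
            tm = fp.mean_lifetime_map(flim)[flim.valid]
            assert (flim.tau1[flim.valid] <= tm + 1e-12).all()
            assert (tm <= flim.tau2[flim.valid] + 1e-12).all()


class TestAggregation:
    def _one_cell_labels(self, shape=(10, 10)):
        cells = np.zeros(shape, dtype=np.int32)
        cells[2:8, 2:8] = 1
        labels = SegmentationLabels(
            cells=cells, nuclei=np.zeros_like(cells), cytoplasm=cells.copy(),
            mitochondria=np.zeros(shape, bool), bboxes={1: (2, 2, 8, 8)})
        return labels

    def test_constant_maps_aggregate_exactly(self):
        nadh = _const_flim((10, 10), 0.75, 0.5, 2.5, 300.0, "nadh")
        fad = _const_flim((10, 10), 0.6, 0.3, 2.2, 100.0, "fad")
        table = fp.aggregate_cell_features(nadh, fad, self._one_cell_labels())
        assert len(table) == 1
        row = table.iloc[0]
        assert row["nadh_a1"] == pytest.approx(0.75)
        assert row["nadh_tm"] == pytest.approx(0.75 * 0.5 + 0.25 * 2.5)
        assert row["redox_ratio"] == pytest.approx(100 / 400)
        assert row["flirr"] == pytest.approx(0.25 / 0.6)
        assert row["fad_intensity"] == pytest.approx(100.0)

    def test_min_valid_pixel_drop(self):
        nadh = _const_flim((10, 10), 0.75, 0.5, 2.5, 300.0, "nadh")
        fad = _const_flim((10, 10), 0.6, 0.3, 2.2, 100.0, "fad")
        nadh.valid[:] = False
        nadh.valid[2:4, 2:4] = True  # only 4 jointly valid pixels
        table = fp.aggregate_cell_features(nadh, fad, self._one_cell_labels(),
                                           min_valid_pixels=10)
        assert table.empty

    def test_group_means_differ_in_preset_directions(self, fitted_scene):
        scene, nadh, fad = fitted_scene
        labels = fp.segment_cells(nadh.intensity)
        labels = fp.mitochondria_mask(labels, nadh.intensity)
        match = fp.match_to_truth(labels, scene.cell_ids)
        table = fp.aggregate_cell_features(nadh, fad, labels)
        det_to_true = {d: t for t, (d, _) in match["pairs"].items()}
        table["group"] = [scene.phenotypes.get(det_to_true.get(c), "unknown")
                          for c in table["cell_id"]]
        g = table[table.group != "unknown"].groupby("group")[
            ["nadh_a1", "nadh_tm"]].mean()
        assert (g.loc["glycolysis_inhibited", "nadh_a1"]
                < g.loc["oxphos_inhibited", "nadh_a1"])
        assert (g.loc["glycolysis_inhibited", "nadh_tm"]
                > g.loc["oxphos_inhibited", "nadh_tm"])

    def test_compartment_distinct_truth_recovered(self, fitted_scene):
        """Mitochondria carry a lower free fraction than cytosol by design."""
        scene, nadh, fad = fitted_scene
        labels = fp.segment_cells(nadh.intensity)
        labels = fp.mitochondria_mask(labels, nadh.intensity)
        mito = fp.aggregate_cell_features(nadh, fad, labels,
                                          compartment="mitochondria",
                                          min_valid_pixels=5)
        cyto = fp.aggregate_cell_features(nadh, fad, labels,
                                          compartment="cytosol")
        assert mito["nadh_a1"].mean() < cyto["nadh_a1"].mean()


class TestNormalizeByControl:
    def test_control_mean_becomes_one(self, feature_table):
        df = fp.sample_cell_features({"control": 50, "oxphos_inhibited": 50},
                                     seed=2)
        norm = fp.normalize_by_control(df, "control")
        ctrl_means = norm[norm.group == "control"][fp.FEATURE_NAMES].mean()
        np.testing.assert_allclose(ctrl_means, 1.0, rtol=1e-12)

    def test_double_control_value_maps_to_two(self):
        df = pd.DataFrame({"group": ["control", "control", "x"],
                           "batch": ["b"] * 3,
                           **{f: [1.0, 1.0, 2.0] for f in fp.FEATURE_NAMES}})
        norm = fp.normalize_by_control(df, "control")
        assert (norm.loc[2, fp.FEATURE_NAMES] == 2.0).all()

    def test_two_batches_identical_relative_shifts(self):
        df1 = fp.sample_cell_features({"control": 80, "oxphos_inhibited": 80},
                                      seed=3, batch="b1")
        df2 = fp.shifted_population(df1, 1.7, batch="b2")
        both = pd.concat([df1, df2], ignore_index=True)
        norm = fp.normalize_by_control(both, "control")
        m1 = norm[norm.batch == "b1"].groupby("group")[fp.FEATURE_NAMES].mean()
        m2 = norm[norm.batch == "b2"].groupby("group")[fp.FEATURE_NAMES].mean()
        pd.testing.assert_frame_equal(m1, m2, rtol=1e-10)

    def test_missing_control_errors(self, feature_table):
        with pytest.raises(ValueError):
            fp.normalize_by_control(feature_table, "control")
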