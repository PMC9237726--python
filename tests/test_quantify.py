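import math

import numpy as np
import pandas as pd
import pytest

import specmap as sm
from specmap.errors import AnnotationError, ConfigurationError, LabelError, WindowError

from conftest import gaussian


def flat_map(value, axis):
    return sm.SpectralMap(np.full((1, len(axis)), float(value)), axis)


class TestIntegrateBand:
    def test_rectangle(self):
        axis = np.arange(1000.0, 1101.0)
        q = sm.integrate_band(flat_map(1.0, axis), sm.BandWindow(1025, 1075))
        assert q.values[0] == pytest.approx(50.0)

    def test_chord_baseline_cancels_constant(self):
        axis = np.arange(1000.0, 1101.0)
        window = sm.BandWindow(1025, 1075, baseline="linear_endpoints")
        q = sm.integrate_band(flat_map(1.0, axis), window)
        assert q.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_area_matches_analytic(self):
        axis = np.arange(1000.0, 2001.0)
        m = sm.SpectralMap(gaussian(axis, 1500, 10)[None, :], axis)
        q = sm.integrate_band(m, sm.BandWindow(1400, 1600))
        exact = math.sqrt(2 * math.pi) * 10
        assert abs(q.values[0] - exact) / exact < 0.005

    def test_halving_spacing_shrinks_error(self):
        # window endpoints inside the band, where trapezoid error is O(h^2)
        exact = 10 * math.sqrt(2 * math.pi) * math.erf(1.5 / math.sqrt(2))
        errs = {}
        for h in (1.0, 0.5):
            axis = np.arange(1000.0, 2000.0 + h / 2, h)
            m = sm.SpectralMap(gaussian(axis, 1500, 10)[None, :], axis)
            q = sm.integrate_band(m, sm.BandWindow(1485, 1515))
            errs[h] = abs(q.values[0] - exact)
        assert errs[1.0] / errs[0.5] >= 3.0

    def test_linear_in_spectrum(self):
        axis = np.arange(1000.0, 1101.0)
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, axis.size))
        window = sm.BandWindow(1020, 1080)
        area = lambda v: sm.integrate_band(sm.SpectralMap(v[None, :], axis), window).values[0]
        assert area(2.5 * x - 1.5 * y) == pytest.approx(2.5 * area(x) - 1.5 * area(y), rel=1e-10)

    def test_too_few_points(self):
        axis = np.arange(1000.0, 1101.0, 10.0)
        with pytest.raises(WindowError):
            sm.integrate_band(flat_map(1.0, axis), sm.BandWindow(1001, 1005))


class TestAdjustWindow:
    def test_finds_shifted_peak(self):
        axis = np.arange(1600.0, 1721.0)
        m = sm.SpectralMap(gaussian(axis, 1660, 8)[None, :], axis)
        w = sm.adjust_window(m, nominal_center=1655, half_width=15, search_radius=10)
        assert (w.lo + w.hi) / 2 == pytest.approx(1660)

    def test_symmetric_peak_at_nominal(self):
        axis = np.arange(1600.0, 1721.0)
        m = sm.SpectralMap(gaussian(axis, 1655, 8)[None, :], axis)
        w = sm.adjust_window(m, 1655, 12, 10)
        assert (w.lo + w.hi) / 2 == pytest.approx(1655)

    def test_flat_spectrum_tie_resolves_to_nominal(self):
        axis = np.arange(1600.0, 1721.0)
        w = sm.adjust_window(flat_map(0.5, axis), 1655, 12, 10)
        assert (w.lo + w.hi) / 2 == pytest.approx(1655)

    def test_window_clipped_to_axis(self):
        axis = np.arange(1600.0, 1681.0)
        m = sm.SpectralMap(gaussian(axis, 1610, 5)[None, :], axis)
        w = sm.adjust_window(m, 1612, half_width=30, search_radius=5)
        assert w.lo >= axis[0] and w.hi <= axis[-1]
        assert any("clipped" in e for e in m.log)

    def test_search_region_outside_axis(self):
        axis = np.arange(1600.0, 1681.0)
        with pytest.raises(WindowError):
            sm.adjust_window(flat_map(1.0, axis), 1600, 10, 20)


class TestClusterMeanSpectra:
    def test_single_cluster_is_overall_mean(self, simple_map):
        means = sm.cluster_mean_spectra(simple_map, np.zeros(4, dtype=int))
        np.testing.assert_allclose(means[0], simple_map.absorbance.mean(0))

    def test_singleton_clusters_return_spectra(self, simple_map):
        two = simple_map.with_data(absorbance=simple_map.absorbance[:2],
                                   sample_ids=simple_map.sample_ids[:2])
        means = sm.cluster_mean_spectra(two, np.array([0, 1]))
        np.testing.assert_allclose(means, two.absorbance)

    def test_region_means_match_generative_signatures(
        self, default_scene, rendered_scene, qc_mask
    ):
        retained = sm.apply_mask(rendered_scene, qc_mask)
        truth = default_scene.region_map[qc_mask.keep]
        means = sm.cluster_mean_spectra(retained, truth)
        for c in range(3):
            sig = sum(
                gaussian(rendered_scene.axis, b.center, b.sigma, b.amplitude)
                for b in default_scene.class_signatures[c]
            )
            r = np.corrcoef(means[c], sig)[0, 1]
            assert r >= 0.99

    def test_misaligned_labels(self, simple_map):
        with pytest.raises(LabelError):
            sm.cluster_mean_spectra(simple_map, np.zeros(3, dtype=int))


class TestSecondaryStructure:
    def axis(self):
        return np.arange(1500.0, 1801.0)

    def test_pure_helix_band(self):
        m = sm.SpectralMap(gaussian(self.axis(), 1654, 3)[None, :], self.axis())
        fr = sm.estimate_secondary_structure(m)
        assert fr["alpha_helix"].iloc[0] >= 0.9

    def test_fifty_fifty_mixture(self):
        spec = gaussian(self.axis(), 1654, 3) + gaussian(self.axis(), 1630, 3)
        fr = sm.estimate_secondary_structure(
            sm.SpectralMap(spec[None, :], self.axis())
        )
        assert fr["alpha_helix"].iloc[0] == pytest.approx(0.5, abs=0.05)
        assert fr["beta_sheet"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_fractions_sum_to_one(self, rendered_scene, qc_mask):
        retained = sm.apply_mask(rendered_scene, qc_mask)
        fr = sm.estimate_secondary_structure(retained)
        sums = fr.sum(axis=1).to_numpy()
        defined = ~fr.isna().any(axis=1).to_numpy()
        np.testing.assert_allclose(sums[defined], 1.0, atol=1e-9)
        assert (fr.to_numpy()[defined] >= 0).all()

    def test_scale_invariance(self):
        spec = gaussian(self.axis(), 1654, 6) + gaussian(self.axis(), 1680, 5) * 0.4
        a = sm.estimate_secondary_structure(sm.SpectralMap(spec[None, :], self.axis()))
        b = sm.estimate_secondary_structure(sm.SpectralMap(37.0 * spec[None, :], self.axis()))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)

    def test_zero_pixel_flagged_missing(self):
        m = sm.SpectralMap(np.zeros((1, self.axis().size)), self.axis())
        fr = sm.estimate_secondary_structure(m)
        assert fr.iloc[0].isna().all()
        assert any("flagged as missing" in e for e in m.log)

    def test_no_overlap_raises(self):
        axis = np.arange(2800.0, 3001.0)
        m = sm.SpectralMap(np.ones((1, axis.size)), axis)
        with pytest.raises(ConfigurationError):
            sm.estimate_secondary_structure(m)

    def test_duplicate_class_names_rejected(self):
        with pytest.raises(ConfigurationError):
            sm.StructureCoefficients(classes=["a", "a"], bands={"a": [(1600.0, 1610.0)]})


class TestGroupValues:
    def quant(self, values, sids):
        return sm.BandQuantification(
            window=sm.BandWindow(1600, 1700),
            values=np.asarray(values, dtype=float),
            sample_ids=np.asarray(sids, dtype=object),
        )

    def ann(self):
        return pd.DataFrame({"sample_name": ["s1", "s2"], "group": ["case", "control"]})

    def test_four_pixels_two_samples(self):
        gv = sm.group_values(self.quant([1, 2, 3, 4], ["s1", "s1", "s2", "s2"]),
                             self.ann(), "group")
        assert list(gv["group"]) == ["case", "case", "control", "control"]
        assert list(gv["value"]) == [1, 2, 3, 4]

    def test_empty_quantification(self):
        gv = sm.group_values(self.quant([], []), self.ann(), "group")
        assert len(gv) == 0

    def test_partition_preserves_sample_counts(self):
        sids = ["s1"] * 3 + ["s2"] * 5
        gv = sm.group_values(self.quant(np.arange(8), sids), self.ann(), "sample_name")
        counts = gv.groupby("group")["value"].count()
        assert counts["s1"] == 3 and counts["s2"] == 5

    def test_unknown_variable(self):
        with pytest.raises(AnnotationError, match="age"):
            sm.group_values(self.quant([1], ["s1"]), self.ann(), "age")
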