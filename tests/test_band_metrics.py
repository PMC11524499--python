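"""Apex location, true peak heights, FWHM and the diagnostic ratios."""

import math

import numpy as np
import pandas as pd
import pytest

import ramclav as rc
from ramclav.band_metrics import (
    BandWindow,
    band_by_name,
    fwhm,
    locate_apex,
    rank_crystal_maturity,
    true_peak_height,
)

from conftest import gaussian_band, lorentzian_band

PHOS = band_by_name("phosphate")


class TestLocateApex:
    def test_on_grid_gaussian(self):
        apex = locate_apex(gaussian_band(center=960.0, sigma=5.0), PHOS)
        assert apex.position == pytest.approx(960.0, abs=0.1)
        assert apex.height == pytest.approx(1.0, abs=1e-6)
        assert not apex.at_edge

    def test_subgrid_center_refined(self):
        apex = locate_apex(gaussian_band(center=959.4, sigma=5.0), PHOS)
        assert apex.position == pytest.approx(959.4, abs=0.2)

    def test_monotone_ramp_flags_edge(self):
        x = np.arange(594.0, 1705.0)
        s = rc.RamanSpectrum(x, x * 0.01)
        apex = locate_apex(s, PHOS)
        assert apex.at_edge
        assert apex.position == 990.0

    def test_window_outside_axis_errors(self):
        s = gaussian_band(lo=1200.0, hi=1704.0, center=1450.0)
        with pytest.raises(ValueError, match="outside"):
            locate_apex(s, PHOS)


class TestTruePeakHeight:
    def test_global_mode_reads_corrected_intensity(self):
        s = gaussian_band(center=960.0, sigma=5.0, amplitude=0.08)
        assert true_peak_height(s, PHOS, "global") == pytest.approx(0.08, rel=1e-6)

    def test_local_chord_subtracts_offset(self):
        x = np.arange(594.0, 1705.0)
        y = np.full_like(x, 2.0)
        tri = np.maximum(0.0, 8.0 * (1 - np.abs(x - 960.0) / 20.0))
        s = rc.RamanSpectrum(x, y + tri)
        assert true_peak_height(s, PHOS, "local_chord") == pytest.approx(8.0, rel=1e-6)

    def test_height_linear_in_generative_amplitude(self, default_spec):
        """Height after full preprocessing is proportional to band amplitude."""
        from dataclasses import replace
        from ramclav.synthetic_cohort import noiseless_spectrum
        from ramclav.spectra_io import SpectrumMeta

        meta = SpectrumMeta("I01L", "I01", "13-18", "left", "lateral", 1)
        heights = []
        for factor in (1.0, 2.0, 4.0):
            # isolated bands well inside the range + polynomial background,
            # so the baseline fit is clean and heights reflect amplitudes
            bands = (
                rc.BandModel("phosphate", 960.0, 17.0, 0.7, 2000.0),
                rc.BandModel("carbonate", 1070.0, 22.0, 0.7, 320.0 * factor),
                rc.BandModel("ch2", 1450.0, 45.0, 0.7, 200.0),
            )
            spec = replace(
                default_spec, bands=bands, hump_amplitude=0.0
            )
            s = rc.preprocess_spectrum(noiseless_spectrum(spec, meta))
            heights.append(
                true_peak_height(s, band_by_name("carbonate"))
                / true_peak_height(s, PHOS)
            )
        assert heights[1] / heights[0] == pytest.approx(2.0, rel=0.02)
        assert heights[2] / heights[0] == pytest.approx(4.0, rel=0.02)


class TestFwhm:
    def test_gaussian_analytic(self):
        res = fwhm(gaussian_band(center=960.0, sigma=5.0), PHOS)
        assert res.value == pytest.approx(2 * math.sqrt(2 * math.log(2)) * 5, abs=0.05)

    def test_lorentzian_analytic(self):
        res = fwhm(lorentzian_band(center=960.0, gamma=6.0), PHOS)
        assert res.value == pytest.approx(12.0, abs=0.1)

    def test_missing_when_half_level_not_reached(self):
        res = fwhm(gaussian_band(center=960.0, sigma=40.0), PHOS)
        assert res.value is None
        assert res.reason == "no_crossing"

    def test_missing_for_non_positive_height(self):
        x = np.arange(594.0, 1705.0)
        s = rc.RamanSpectrum(x, -np.exp(-0.5 * ((x - 960) / 5.0) ** 2))
        res = fwhm(s, PHOS)
        assert res.value is None
        assert res.reason == "non_positive_height"

    def test_pseudo_voigt_width_recovered_on_grid(self):
        """Measured FWHM of generated bands matches the generative width."""
        from ramclav.synthetic_cohort import pseudo_voigt

        x = np.arange(594.0, 1705.0)
        for width in (12.0, 17.0, 24.0):
            y = 100.0 * pseudo_voigt(x, 960.0, width, 0.7)
            res = fwhm(rc.RamanSpectrum(x, y), PHOS)
            assert abs(res.value - width) < 1.0


class TestSpectrumMetrics:
    def test_equal_bands_give_unit_pc_ratio(self):
        x = np.arange(594.0, 1705.0)
        y = np.zeros_like(x)
        for c in (960.0, 1070.0):
            y += np.exp(-0.5 * ((x - c) / 5.0) ** 2)
        m = rc.spectrum_metrics(rc.RamanSpectrum(x, y))
        assert m.ratio_p_c == pytest.approx(1.0, rel=1e-6)

    def test_ratios_scale_invariant(self, cohort):
        s = cohort[0]
        a = rc.spectrum_metrics(rc.preprocess_spectrum(s))
        scaled = s.with_intensities(s.intensities * 37.0)
        b = rc.spectrum_metrics(rc.preprocess_spectrum(scaled))
        assert a.ratio_960_1450 == pytest.approx(b.ratio_960_1450, rel=1e-9)
        assert a.ratio_p_a == pytest.approx(b.ratio_p_a, rel=1e-9)
        assert a.ratio_p_c == pytest.approx(b.ratio_p_c, rel=1e-9)

    def test_missing_denominator_leaves_other_ratios(self):
        x = np.arange(594.0, 1705.0)
        y = np.exp(-0.5 * ((x - 960.0) / 5.0) ** 2)  # phosphate only
        y += 0.5 * np.exp(-0.5 * ((x - 1070.0) / 5.0) ** 2)
        m = rc.spectrum_metrics(rc.RamanSpectrum(x, y))
        assert m.ratio_960_1450 is None  # no CH2 band present
        assert m.ratio_p_c == pytest.approx(2.0, rel=1e-3)


class TestCohortMetrics:
    def test_one_row_per_spectrum(self, metrics_table):
        assert len(metrics_table) == 330
        assert metrics_table["ratio_960_1450"].notna().all()

    def test_grouped_by_age_has_three_rows(self, metrics_table):
        g = rc.grouped_summary(metrics_table, ["age_group"], ["ratio_p_a"])
        assert len(g) == 3
        assert set(g["age_group"]) == set(rc.AGE_GROUPS)
        assert (g["n"] == [120, 120, 90]).all()

    def test_empty_set_gives_header_only(self):
        table = rc.cohort_metrics(rc.SpectrumSet([]))
        assert table.empty
        assert "ratio_960_1450" in table.columns


class TestRankCrystalMaturity:
    def test_sorted_ascending_fwhm(self):
        t = pd.DataFrame(
            {"g": ["a", "b", "c"], "fwhm_960": [16.5, 16.0, 17.0]}
        )
        r = rank_crystal_maturity(t, ["g"])
        assert r.loc[r["rank"] == 1, "g"].iloc[0] == "b"
        assert r["mean_fwhm_960"].is_monotonic_increasing

    def test_ties_flagged_lexicographic(self):
        t = pd.DataFrame({"g": ["b", "a"], "fwhm_960": [16.0, 16.0]})
        r = rank_crystal_maturity(t, ["g"])
        assert r["tied"].all()
        assert r.loc[r["rank"] == 1, "g"].iloc[0] == "a"

    def test_row_order_invariant(self, metrics_table):
        a = rank_crystal_maturity(metrics_table, ["age_group"])
        shuffled = metrics_table.sample(frac=1.0, random_state=0)
        b = rank_crystal_maturity(shuffled, ["age_group"])
        pd.testing.assert_frame_equal(a, b)

    def test_all_missing_errors(self):
        t = pd.DataFrame({"g": ["a", "b"], "fwhm_960": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="missing"):
            rank_crystal_maturity(t, ["g"])

    def test_default_cohort_oldest_most_mature(self, metrics_table):
        """The narrower generative phosphate band of the oldest group ranks first."""
        r = rank_crystal_maturity(metrics_table, ["age_group"])
        assert r.loc[r["rank"] == 1, "age_group"].iloc[0] == "30-40"
        assert r.loc[r["rank"] == 3, "age_group"].iloc[0] == "18-30"

    def test_narrower_band_ranked_more_mature_across_seeds(self, default_spec):
        """Simulation oracle: group with narrower phosphate band wins the rank."""
        from dataclasses import replace as drep

        effects = rc.GroupEffectSpec(
            cv_individual=default_spec.effects.cv_individual,
            cv_measurement=default_spec.effects.cv_measurement,
            width_age={"phosphate": {"13-18": 0.96, "18-30": 1.0, "30-40": 1.04}},
        )
        layout = tuple(ind for ind in default_spec.layout if len(ind.sides) == 2)[:4]
        wins = 0
        for seed in range(100):
            spec = rc.SyntheticCohortSpec(
                bands=default_spec.bands, effects=effects,
                layout=layout, seed=seed,
            )
            table = rc.cohort_metrics(rc.preprocess_set(rc.simulate_cohort(spec)))
            r = rank_crystal_maturity(table, ["age_group"])
            wins += r.loc[r["rank"] == 1, "age_group"].iloc[0] == "13-18"
        assert wins >= 95
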