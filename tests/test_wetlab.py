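"""Calibration, mole-fraction conversion, replicates and cosolvency."""

import numpy as np
import pytest

from desolv.config import molar_mass
from desolv.simulate import gen_calibration_series
from desolv.systems import SolventSystem, enumerate_des_grid
from desolv.wetlab import (
    absorbance_to_mole_fraction,
    aggregate_replicates,
    cosolvency_analysis,
    fit_calibration,
)

IBU_SLOPE, IBU_INTERCEPT = 27.268, 0.001


class TestCalibration:
    def test_noiseless_fit_recovers_line_exactly(self):
        levels = gen_calibration_series(IBU_SLOPE, IBU_INTERCEPT, noise=0.0)
        curve = fit_calibration(levels)
        assert curve.slope == pytest.approx(IBU_SLOPE, abs=1e-9)
        assert curve.intercept == pytest.approx(IBU_INTERCEPT, abs=1e-12)
        assert curve.r2 == pytest.approx(1.0, abs=1e-12)
        assert curve.lod == pytest.approx(0.0, abs=1e-12)
        assert curve.loq == pytest.approx(0.0, abs=1e-12)

    def test_loq_to_lod_ratio_is_10_over_3p3(self):
        levels = gen_calibration_series(noise=0.01, seed=3)
        curve = fit_calibration(levels)
        assert curve.loq / curve.lod == pytest.approx(10.0 / 3.3, rel=1e-12)

    def test_monte_carlo_lod_matches_noise_over_slope_oracle(self):
        """With absorbance noise SD 0.0192 on the reference line, the
        mean LOD across seeds is ~3.3 * 0.0192 / 27.268 ~ 0.0023 mg/mL."""
        lods = []
        for seed in range(200):
            levels = gen_calibration_series(
                IBU_SLOPE, IBU_INTERCEPT, noise=0.0192, seed=seed
            )
            lods.append(fit_calibration(levels).lod)
        assert np.mean(lods) == pytest.approx(0.0023, rel=0.08)

    def test_zero_concentration_range_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(0.1, 1.0), (0.1, 1.1), (0.1, 0.9)])


class TestMoleFractionConversion:
    def _curve(self):
        return fit_calibration(
            gen_calibration_series(IBU_SLOPE, IBU_INTERCEPT, noise=0.0)
        )

    def test_absorbance_at_intercept_is_flagged(self):
        with pytest.raises(ValueError, match="intercept"):
            absorbance_to_mole_fraction(
                IBU_INTERCEPT,
                self._curve(),
                1.0,
                1.0,
                SolventSystem.neat("water"),
                molar_masses={"solute": 206.28},
            )

    def test_hand_arithmetic_water_example(self):
        """206.28 mg/mL of a MW-206.28 solute at density 1.03128 g/mL:
        1 mmol solute, 825 mg water -> x = 1/(1+45.795) ~ 0.02137."""
        curve = self._curve()
        absorbance = IBU_SLOPE * 206.28 + IBU_INTERCEPT
        x = absorbance_to_mole_fraction(
            absorbance,
            curve,
            1.0,
            1.03128,
            SolventSystem.neat("water"),
            molar_masses={"solute": 206.28, "water": 18.015},
        )
        assert x == pytest.approx(0.02137, abs=2e-5)

    def test_inversion_of_reference_line(self):
        curve = self._curve()
        assert curve.concentration(0.27368, 1.0) == pytest.approx(0.0100, abs=1e-4)

    def test_round_trip_concentration_absorbance(self):
        curve = self._curve()
        for c in (0.01, 0.02, 0.05):
            a = curve.slope * c + curve.intercept
            assert curve.concentration(a) == pytest.approx(c, abs=1e-12)

    def test_solvent_mass_inconsistency_detected(self):
        curve = self._curve()
        with pytest.raises(ValueError, match="density"):
            absorbance_to_mole_fraction(
                IBU_SLOPE * 900.0,
                curve,
                1.0,
                0.5,
                SolventSystem.neat("water"),
                molar_masses={"solute": 206.28},
            )


class TestReplicates:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((0.35, 0.35, 0.35), (0.35, 0.0)),
            ((1.0, 2.0, 3.0), (2.0, 1.0)),
            ((0.42,), (0.42, 0.0)),
        ],
    )
    def test_mean_and_sample_sd(self, values, expected):
        assert aggregate_replicates(values) == pytest.approx(expected)


class TestCosolvency:
    def test_monotone_series_peaking_at_neat_des_is_not_cosolvency(self):
        series = [(0.2, 0.05), (0.5, 0.15), (0.8, 0.28), (1.0, 0.35)]
        res = cosolvency_analysis(series)
        assert res.x_star_opt == 1.0
        assert res.classification == "none"

    def test_peak_below_neat_composition_detected(self):
        series = [(0.6, 0.2), (0.8, 0.3), (0.9, 0.40), (1.0, 0.35)]
        res = cosolvency_analysis(series)
        assert res.x_star_opt == 0.9
        assert res.classification == "apparent cosolvency"

    def test_flat_series_ties_toward_neat_des(self):
        series = [(0.5, 0.3), (0.8, 0.3), (1.0, 0.3)]
        res = cosolvency_analysis(series)
        assert res.x_star_opt == 1.0
        assert res.classification == "none"

    def test_invariant_to_series_ordering(self):
        series = [(0.6, 0.2), (1.0, 0.35), (0.9, 0.40), (0.8, 0.3)]
        assert cosolvency_analysis(series) == cosolvency_analysis(series[::-1])

    def test_duplicate_compositions_rejected(self):
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            cosolvency_analysis([(0.8, 0.1), (0.8, 0.2), (1.0, 0.3)])


class TestDesGrid:
    def test_study_grid_has_36_systems(self):
        assert len(enumerate_des_grid()) == 36

    def test_minimal_grid(self):
        assert len(enumerate_des_grid(["ChCl"], ["TEG"], [2.0])) == 1

    def test_duplicates_removed(self):
        systems = enumerate_des_grid(["ChCl"], ["TEG", "TEG"], [1.0, 2.0])
        assert len(systems) == 2


class TestMolarMasses:
    @pytest.mark.parametrize(
        "compound, printed",
        [("ibuprofen", 206.28), ("ketoprofen", 254.28)],
    )
    def test_structure_derived_masses_match_printed(self, compound, printed):
        assert molar_mass(compound) == pytest.approx(printed, abs=0.01)

    def test_des_component_masses(self):
        assert molar_mass("ChCl") == pytest.approx(139.62, abs=0.01)
        assert molar_mass("BI") == pytest.approx(117.15, abs=0.01)
        assert molar_mass("water") == pytest.approx(18.015, abs=0.01)

    def test_unknown_compound_rejected(self):
        with pytest.raises(KeyError):
            molar_mass("unobtainium")
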