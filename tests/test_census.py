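"""Cellular censuses: volume, protein, and ribosome quantitation."""

import math

import numpy as np
import pandas as pd
import pytest

from riboaccount import census as cen
from riboaccount import synthetic as syn
from riboaccount.constants import DEFAULT_CONSTANTS, PhysicalConstants


class TestVolume:
    @pytest.mark.parametrize(
        "d,v", [(0.0, 0.0), (10.0, 523.5988), (7.3, 203.6894)]
    )
    def test_spherical_volume(self, d, v):
        assert cen.volume_from_diameter(d).volume_fl == pytest.approx(v, rel=1e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cen.volume_from_diameter(-1)


class TestTrpStandardCurve:
    def test_exact_lines(self):
        c = cen.fit_trp_standard_curve([(0, 0), (1, 10)])
        assert (c.slope, c.intercept) == (pytest.approx(10), pytest.approx(0, abs=1e-12))
        c = cen.fit_trp_standard_curve([(0, 2), (1, 12), (2, 22)])
        assert c.slope == pytest.approx(10)
        assert c.intercept == pytest.approx(2)
        assert c.r_squared == pytest.approx(1.0)

    def test_through_origin(self):
        c = cen.fit_trp_standard_curve([(1, 10), (2, 20)], through_origin=True)
        assert c.slope == pytest.approx(10)
        assert c.intercept == 0.0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cen.fit_trp_standard_curve([(1, 10)])
        with pytest.raises(ValueError):
            cen.fit_trp_standard_curve([(1, 10), (1, 12)])

    def test_noisy_plate_slope_recovery(self):
        plate, truth = syn.gen_trp_plate(36.3, 2e6, [0, 5, 10, 20, 40], noise_sd=0.5, seed=3)
        standards = plate[plate.role == "standard"]
        c = cen.fit_trp_standard_curve(list(zip(standards.trp_amount_ng, standards.fluorescence)))
        assert c.slope == pytest.approx(truth.params["slope"], rel=0.03)


class TestProteinMass:
    def curve(self):
        return cen.LinearCalibration(slope=10.0, intercept=0.0, r_squared=1.0)

    def test_blank_equals_zero_mass(self):
        assert cen.protein_mass_per_cell(5.0, 5.0, self.curve(), 0.02, 1e6) == 0.0

    def test_inverse_proportional_to_cells(self):
        m1 = cen.protein_mass_per_cell(55.0, 5.0, self.curve(), 0.02, 1e6)
        m2 = cen.protein_mass_per_cell(55.0, 5.0, self.curve(), 0.02, 2e6)
        assert m1 == pytest.approx(2 * m2)

    def test_below_blank_rejected(self):
        with pytest.raises(ValueError, match="below blank"):
            cen.protein_mass_per_cell(4.0, 5.0, self.curve(), 0.02, 1e6)

    def test_round_trip_from_plate(self):
        plate, truth = syn.gen_trp_plate(36.3, 2e6, [0, 5, 10, 20, 40], noise_sd=0.5, seed=3)
        pc = cen.protein_census_from_plate(plate, sampled_fraction=0.02, n_cells=2e6)
        assert pc.mass_pg_per_cell == pytest.approx(36.3, rel=0.03)


class TestProteinCount:
    def test_worked_example(self):
        # 36.33 pg at 472 aa x 110 Da per protein is ~4.21e8 molecules
        assert cen.protein_count(36.33) == pytest.approx(4.21e8, rel=0.005)

    def test_linearity_and_zero(self):
        assert cen.protein_count(0.0) == 0.0
        assert cen.protein_count(5 * 36.33) == pytest.approx(5 * cen.protein_count(36.33))


class TestIntegrateElectropherogram:
    def test_flat_zero_trace(self):
        trace = pd.DataFrame({"position": np.linspace(0, 100, 201), "signal": 0.0})
        out = cen.integrate_electropherogram(trace, {"a": (10, 40), "b": (50, 90)})
        assert out["a"]["area"] == 0.0 and out["b"]["area"] == 0.0

    def test_single_gaussian_fraction_one(self):
        x = np.linspace(0, 200, 2001)
        trace = pd.DataFrame(
            {"position": x, "signal": np.exp(-0.5 * ((x - 100) / 5) ** 2)}
        )
        out = cen.integrate_electropherogram(trace, {"peak": (60, 140)})
        assert out["peak"]["fraction"] == 1.0
        assert out["peak"]["area"] == pytest.approx(5 * math.sqrt(2 * math.pi), rel=0.005)

    def test_overlapping_windows_rejected(self):
        trace = pd.DataFrame({"position": np.linspace(0, 100, 101), "signal": 1.0})
        with pytest.raises(ValueError, match="non-overlapping"):
            cen.integrate_electropherogram(trace, {"a": (10, 50), "b": (40, 90)})

    def test_window_outside_support_rejected(self):
        trace = pd.DataFrame({"position": np.linspace(0, 100, 101), "signal": 1.0})
        with pytest.raises(ValueError, match="support"):
            cen.integrate_electropherogram(trace, {"a": (50, 150)})


class TestRnaYield:
    def test_ratio_and_clip(self):
        assert cen.rna_yield(40, [40, 40]) == 1.0
        assert cen.rna_yield(30, [40, 40]) == pytest.approx(0.75)
        with pytest.warns(UserWarning, match="clipping"):
            assert cen.rna_yield(44, [40, 40]) == 1.0

    def test_bad_standards(self):
        with pytest.raises(ValueError):
            cen.rna_yield(30, [40])
        with pytest.raises(ValueError):
            cen.rna_yield(30, [40, 0])


class TestRrnaCopies:
    def test_worked_example(self):
        # 20 ng/ul x 50 ul x 0.5 / 1.6e6 g/mol x N_A / (0.8 x 1e6 cells)
        copies = cen.rrna_copies_per_cell(20, 0.5, 50, "28S", "mouse", 0.8, 1e6)
        assert copies == pytest.approx(2.35e5, rel=0.005)

    def test_zero_fraction(self):
        assert cen.rrna_copies_per_cell(20, 0.0, 50, "18S", "mouse", 1.0, 1e6) == 0.0

    def test_halving_yield_doubles_copies(self):
        a = cen.rrna_copies_per_cell(20, 0.5, 50, "28S", "mouse", 0.8, 1e6)
        b = cen.rrna_copies_per_cell(20, 0.5, 50, "28S", "mouse", 0.4, 1e6)
        assert b == pytest.approx(2 * a)

    def test_unknown_species(self):
        with pytest.raises(KeyError, match="unknown rRNA species"):
            cen.rrna_copies_per_cell(20, 0.5, 50, "16S", "mouse", 0.8, 1e6)


class TestFunctionalRibosomes:
    def test_min_rule(self):
        assert cen.functional_ribosomes(300000, 264000) == 264000
        assert cen.functional_ribosomes(5, 5) == 5
        assert cen.functional_ribosomes(0, 1e6) == 0


class TestCensusRoundTrip:
    def spec(self, noise_sd, seed=2):
        return syn.BioanalyzerSimSpec(
            copies_18s_per_cell=300e3,
            copies_28s_per_cell=264e3,
            n_cells=1e6,
            rna_yield=0.8,
            spike_in_ng=375.0,
            eluate_volume_ul=50.0,
            noise_sd=noise_sd,
            seed=seed,
        )

    def test_zero_noise_exact(self):
        sample, standard, truth = syn.gen_electropherogram(self.spec(0.0))
        rc = cen.ribosome_census_from_traces(
            sample, standard, cen.DEFAULT_RRNA_WINDOWS, 50.0, 1e6
        )
        assert rc.copies_18s_per_cell == pytest.approx(300e3, rel=1e-6)
        assert rc.copies_28s_per_cell == pytest.approx(264e3, rel=1e-6)
        assert rc.rna_yield == pytest.approx(0.8, rel=1e-6)

    def test_noisy_within_two_percent(self):
        sample, standard, truth = syn.gen_electropherogram(self.spec(noise_sd=0.002))
        rc = cen.ribosome_census_from_traces(
            sample, standard, cen.DEFAULT_RRNA_WINDOWS, 50.0, 1e6
        )
        assert rc.copies_18s_per_cell == pytest.approx(300e3, rel=0.02)
        assert rc.copies_28s_per_cell == pytest.approx(264e3, rel=0.02)
        assert rc.functional_ribosomes_per_cell == rc.copies_28s_per_cell

    def test_default_subunit_ratio_in_stated_range(self):
        ratio = 264e3 / 300e3
        assert 0.75 <= ratio <= 0.90


def test_constants_validation():
    with pytest.raises(ValueError, match="keys"):
        PhysicalConstants(rrna_molar_mass_g_per_mol={"mouse_18S": 6.4e5})
    assert DEFAULT_CONSTANTS.avg_protein_mass_g == pytest.approx(472 * 110 * 1.66054e-24)
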