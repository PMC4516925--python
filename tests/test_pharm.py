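"""Hill and Boltzmann fitting, I-V normalisation, gating-shift statistics."""

import numpy as np
import pandas as pd
import pytest

from venomseq.pharm import (
    activation_shift,
    boltzmann_current,
    fit_activation,
    fit_hill,
    hill_fraction,
    inhibition_vs_voltage,
    normalize_iv,
)
from venomseq.simulate import gen_iv, gen_tevc

GRID = tuple(range(-60, 71, 10))


def dose_df(conc, frac):
    return pd.DataFrame({"conc_nM": conc, "fraction": frac})


class TestFitHill:
    def test_ic50_definition_half_block(self):
        assert hill_fraction(100.0, 100.0, 1.0) == 0.5

    def test_noiseless_closed_form_three_points(self):
        # 100 nM -> 0.5 and 300 nM -> 0.25 force IC50 = 100, nH = 1
        conc = [100.0, 300.0, 1000.0]
        frac = [0.5, 0.25, 1.0 / 11.0]
        fit = fit_hill(dose_df(conc, frac))
        assert fit.ic50 == pytest.approx(100.0, rel=1e-4)
        assert fit.nh == pytest.approx(1.0, rel=1e-4)
        assert fit.reliable

    def test_noiseless_generated_data_exact_recovery(self):
        df = gen_tevc(360.0, 1.2, noise_sd=0.0, seed=0)
        fit = fit_hill(df)
        assert fit.ic50 == pytest.approx(360.0, rel=1e-6)
        assert fit.nh == pytest.approx(1.2, rel=1e-6)

    def test_noisy_recovery_within_15_percent(self):
        df = gen_tevc(360.0, 1.2, noise_sd=0.03, seed=11)
        fit = fit_hill(df)
        assert abs(fit.ic50 - 360.0) / 360.0 < 0.15

    def test_fewer_than_three_concentrations_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_hill(dose_df([100.0, 100.0, 300.0], [0.5, 0.52, 0.25]))

    def test_out_of_range_ic50_flagged(self):
        # essentially flat data at full current: IC50 far above range
        df = dose_df([10.0, 30.0, 100.0], [0.999, 0.998, 0.999])
        fit = fit_hill(df)
        assert not fit.reliable

    def test_parameter_recovery_study(self):
        """Median relative IC50 error <= 10% over simulated datasets."""
        rng = np.random.default_rng(99)
        errors = []
        n_sim = 120
        for i in range(n_sim):
            true_ic50 = float(10 ** rng.uniform(np.log10(50), np.log10(1000)))
            nh = float(rng.choice([0.9, 1.4, 2.2]))
            df = gen_tevc(true_ic50, nh, noise_sd=0.03, seed=int(rng.integers(2**31)))
            fit = fit_hill(df)
            errors.append(abs(fit.ic50 - true_ic50) / true_ic50)
        assert np.median(errors) <= 0.10

    def test_steep_and_shallow_slopes_separate(self):
        """Fitted nH distributions for nH=2.2 vs 1.0 do not overlap (IQR)."""
        steep, shallow = [], []
        for i in range(25):
            steep.append(fit_hill(gen_tevc(333.0, 2.2, noise_sd=0.03, seed=500 + i)).nh)
            shallow.append(fit_hill(gen_tevc(360.0, 1.0, noise_sd=0.03, seed=900 + i)).nh)
        q1_steep = np.percentile(steep, 25)
        q3_shallow = np.percentile(shallow, 75)
        assert q1_steep > q3_shallow


class TestNormalizeIv:
    def make_family(self):
        rows = []
        for rep, scale in ((0, 1.0), (1, 2.0)):
            for v in GRID:
                i = boltzmann_current(v, 1.0, -18.0, 4.5, 65.0) * scale
                rows.append((v, i, "control", rep))
                rows.append((v, 0.5 * i, "peptide", rep))
        return pd.DataFrame(rows, columns=["potential_mV", "current", "condition", "replicate"])

    def test_control_peak_maps_to_minus_one(self):
        out = normalize_iv(self.make_family())
        for rep, grp in out.groupby("replicate"):
            ctrl = grp[grp["condition"] == "control"]["current"]
            assert ctrl.abs().max() == pytest.approx(1.0)
            assert ctrl.min() == pytest.approx(-1.0)  # inward sign preserved

    def test_scale_invariance_per_oocyte(self):
        fam = self.make_family()
        out1 = normalize_iv(fam)
        fam2 = fam.copy()
        mask = fam2["replicate"] == 0
        fam2.loc[mask, "current"] *= 2.0
        out2 = normalize_iv(fam2)
        pd.testing.assert_frame_equal(out1, out2)

    def test_peptide_rows_share_control_denominator(self):
        out = normalize_iv(self.make_family())
        for rep, grp in out.groupby("replicate"):
            c = grp[grp["condition"] == "control"].set_index("potential_mV")["current"]
            p = grp[grp["condition"] == "peptide"].set_index("potential_mV")["current"]
            assert np.allclose(p, 0.5 * c)

    def test_missing_control_rejected(self):
        fam = self.make_family()
        fam = fam[fam["condition"] != "control"]
        with pytest.raises(ValueError, match="control"):
            normalize_iv(fam)


class TestFitActivation:
    def test_noiseless_recovery_both_routes_agree(self):
        df = gen_iv(v05=-18.0, k=6.0, vrev=65.0, noise_sd=0.0, n_reps=1, seed=0)
        via_i = fit_activation(df, "control", vrev=65.0, via="current")
        via_g = fit_activation(df, "control", vrev=65.0, via="conductance")
        for fit in (via_i, via_g):
            assert fit.v05 == pytest.approx(-18.0, abs=1e-5)
            assert fit.k == pytest.approx(6.0, abs=1e-5)
        assert via_i.v05 == pytest.approx(via_g.v05, abs=1e-6)

    def test_noisy_v05_recovery(self):
        errs = []
        for i in range(60):
            df = gen_iv(v05=-18.0, k=6.0, noise_sd=0.02, seed=3000 + i)
            errs.append(fit_activation(df, "control").v05 - (-18.0))
        assert np.all(np.abs(errs) <= 1.5)

    def test_translation_equivariance(self):
        df = gen_iv(v05=-18.0, k=4.5, noise_sd=0.01, seed=5)
        base = fit_activation(df, "control", vrev=65.0)
        shifted = df.copy()
        shifted["potential_mV"] += 25.0
        moved = fit_activation(shifted, "control", vrev=90.0)
        assert moved.v05 - base.v05 == pytest.approx(25.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        df = gen_iv(noise_sd=0.0, n_reps=1, seed=0, grid=(0, 10, 80, 90))
        with pytest.raises(ValueError, match="fewer than 4"):
            fit_activation(df, "control", vrev=65.0)


class TestShiftAndInhibition:
    def test_identical_fits_zero_shift(self):
        df = gen_iv(noise_sd=0.0, n_reps=1, seed=0)
        fit = fit_activation(df, "control")
        assert activation_shift(fit, fit) == 0.0

    def test_imposed_eleven_mv_shift_recovered(self):
        df = gen_iv(v05=-18.0, k=4.5, shift_mV=11.0, scale=0.7, noise_sd=0.02, seed=21)
        ctrl = fit_activation(df, "control")
        pep = fit_activation(df, "peptide")
        assert 10.0 <= activation_shift(ctrl, pep) <= 12.0

    def test_imposed_four_mv_shift_recovered(self):
        df = gen_iv(v05=-18.0, k=4.5, shift_mV=4.0, scale=0.85, noise_sd=0.02, seed=22)
        ctrl = fit_activation(df, "control")
        pep = fit_activation(df, "peptide")
        assert activation_shift(ctrl, pep) == pytest.approx(4.0, abs=1.0)

    def test_gating_modifier_inhibition_decreases_with_voltage(self):
        df = gen_iv(v05=-18.0, k=4.5, shift_mV=11.0, scale=0.7, noise_sd=0.0,
                    n_reps=1, seed=0)
        ctrl = df[df["condition"] == "control"]
        pep = df[df["condition"] == "peptide"]
        out = inhibition_vs_voltage(ctrl, pep)
        rising = out[(out["potential_mV"] >= -30) & (out["potential_mV"] <= 10)]
        assert np.all(np.diff(rising["fraction_inhibited"]) < 0)

    def test_proportional_block_is_flat(self):
        df = gen_iv(v05=-18.0, k=4.5, shift_mV=0.0, scale=0.6, noise_sd=0.0,
                    n_reps=1, seed=0)
        ctrl = df[df["condition"] == "control"]
        pep = df[df["condition"] == "peptide"]
        out = inhibition_vs_voltage(ctrl, pep)
        assert np.allclose(out["fraction_inhibited"], 0.4, atol=1e-9)

    def test_identical_families_zero_everywhere(self):
        df = gen_iv(noise_sd=0.0, n_reps=1, seed=0)
        ctrl = df[df["condition"] == "control"]
        out = inhibition_vs_voltage(ctrl, ctrl)
        assert np.allclose(out["fraction_inhibited"], 0.0)

    def test_grid_mismatch_rejected(self):
        a = gen_iv(noise_sd=0.0, n_reps=1, seed=0)
        b = gen_iv(noise_sd=0.0, n_reps=1, seed=0, grid=tuple(range(-50, 71, 10)))
        with pytest.raises(ValueError, match="grids differ"):
            inhibition_vs_voltage(a[a.condition == "control"], b[b.condition == "control"])
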