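"""Synthetic-data generators: analytic limits, oracles, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from splitkin import (
    GroundTruth,
    NoiseSpec,
    gen_bli_sensorgrams,
    gen_ec50_dataset,
    gen_gaussian_profile,
    gen_labeling_timecourse,
    gen_melt_curve,
    gen_nnk_reads,
    gen_saturation_binding,
    second_order_fp,
)
from splitkin.synth import (
    NNK_CODONS,
    bli_response,
    gaussian_profile,
    k_app_of_conc,
    melt_ratio,
    saturation_fp,
)

TRUTH = GroundTruth()


class TestLabelingTimecourse:
    def test_zero_rate_gives_constant_fp_free(self):
        tc = gen_labeling_timecourse(TRUTH, k_app=0.0, dead_time=0.0)
        assert np.allclose(tc.fp, TRUTH.fp_free)

    def test_analytic_limits_of_the_model(self):
        t = np.array([0.0, 1e9])
        fp = second_order_fp(t, 1e5, TRUTH.fp_free, TRUTH.fp_bound, TRUTH.a0, TRUTH.b0)
        assert fp[0] == pytest.approx(TRUTH.fp_free)
        # b0 > a0: all substrate is consumed eventually
        assert fp[1] == pytest.approx(TRUTH.fp_bound, rel=1e-9)

    def test_equal_concentration_numeric_limit(self):
        """The a0 == b0 branch is the limit of the general form as b0 -> a0."""
        t = np.linspace(0.0, 36000.0, 50)
        a0 = 1e-9
        exact = second_order_fp(t, 1e5, 50.0, 350.0, a0, a0)
        for eps in (1e-6, -1e-6):
            near = second_order_fp(t, 1e5, 50.0, 350.0, a0, a0 * (1.0 + eps))
            assert np.allclose(near, exact, rtol=1e-6)

    def test_negative_noise_sd_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(sd=-1.0)

    def test_monotone_and_bounded(self):
        tc = gen_labeling_timecourse(TRUTH, k_app=1e5, dead_time=0.0)
        assert np.all(np.diff(tc.fp) >= 0)
        assert tc.fp.min() >= TRUTH.fp_free - 1e-9
        assert tc.fp.max() <= TRUTH.fp_bound + 1e-9


class TestEC50Dataset:
    def test_default_design_is_twofold_1000_to_1_nM(self):
        table = gen_ec50_dataset(TRUTH)
        concs = np.sort(table.data["condition"].unique())[::-1]
        assert len(concs) == 11
        assert concs[0] == pytest.approx(1000e-9)
        assert concs[-1] == pytest.approx(0.9765625e-9)
        assert np.allclose(concs[:-1] / concs[1:], 2.0)

    def test_rate_at_ec50_is_half_max(self):
        assert k_app_of_conc(TRUTH, TRUTH.ec50) == pytest.approx(TRUTH.k_app_max / 2.0)

    def test_seeded_regeneration_is_bit_identical(self):
        a = gen_ec50_dataset(TRUTH, noise=NoiseSpec(sd=6.0, seed=1, replicate_count=2))
        b = gen_ec50_dataset(TRUTH, noise=NoiseSpec(sd=6.0, seed=1, replicate_count=2))
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_increasing_series_rejected(self):
        with pytest.raises(ValueError):
            gen_ec50_dataset(TRUTH, dilution=np.array([1e-9, 2e-9, 4e-9, 8e-9, 16e-9, 32e-9]))


class TestSaturation:
    def test_midpoint_and_saturation(self):
        kd = 6.5e-9
        mid = saturation_fp(np.array([kd]), kd, 300.0, 60.0)[0]
        assert mid == pytest.approx((300.0 + 60.0) / 2.0)
        hi = saturation_fp(np.array([kd * 1e6]), kd, 300.0, 60.0)[0]
        assert hi == pytest.approx(300.0, rel=1e-5)

    def test_against_independent_formula(self):
        """Double-implementation oracle at hand-picked concentrations."""
        kd, top, bottom = 6.5e-9, 300.0, 60.0
        for c in (1e-10, 1e-9, 6.5e-9, 5e-8, 1e-6):
            theta = c / (kd + c)  # fractional occupancy, independent coding
            expected = bottom * (1.0 - theta) + top * theta
            assert saturation_fp(np.array([c]), kd, top, bottom)[0] == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            gen_saturation_binding(kd=0.0)


class TestBLI:
    def test_zero_concentration_is_flat_zero(self):
        t = np.linspace(0.0, 600.0, 100)
        r = bli_response(t, 0.0, TRUTH.kon, TRUTH.koff, 1.0, 300.0)
        assert np.allclose(r, 0.0)

    def test_zero_koff_dissociation_is_constant(self):
        t = np.linspace(0.0, 600.0, 601)
        r = bli_response(t, 50e-9, 1e5, 0.0, 1.0, 300.0)
        dissoc = r[t > 300.0]
        assert np.allclose(dissoc, dissoc[0])

    def test_matches_ode_integration(self):
        """dR/dt = kon*c*(rmax - R) - koff*R reproduces the analytic trace."""
        c, kon, koff, rmax = 50e-9, 5e4, 2e-4, 1.2

        def rhs(t, r):
            return kon * c * (rmax - r) - koff * r

        t_assoc = np.linspace(0.0, 300.0, 61)
        sol = solve_ivp(rhs, (0.0, 300.0), [0.0], t_eval=t_assoc, rtol=1e-10, atol=1e-14)
        analytic = bli_response(t_assoc, c, kon, koff, rmax, 300.0)
        assert np.allclose(sol.y[0], analytic, rtol=1e-6)

    def test_invalid_association_time_rejected(self):
        with pytest.raises(ValueError):
            gen_bli_sensorgrams(TRUTH, t_assoc=0.0)

    def test_phases_labeled_and_deterministic(self):
        a = gen_bli_sensorgrams(TRUTH, noise=NoiseSpec(sd=0.01, seed=2))
        b = gen_bli_sensorgrams(TRUTH, noise=NoiseSpec(sd=0.01, seed=2))
        pd.testing.assert_frame_equal(a.data, b.data)
        assert set(a.data["phase"]) == {"baseline", "association", "dissociation"}


class TestGaussianProfile:
    def test_peak_at_center(self):
        table = gen_gaussian_profile(TRUTH, pixel_nm=2.0)
        x = table.data["time"].to_numpy()
        y = table.data["value"].to_numpy()
        assert abs(x[np.argmax(y)]) <= 1.0

    def test_half_maximum_crossings_one_fwhm_apart(self):
        x = np.arange(-300.0, 300.0, 1.0)
        omega = TRUTH.fwhm / np.sqrt(2 * np.log(2))
        y = gaussian_profile(x, 10.0, 5000.0, 0.0, omega)
        half = 10.0 + (y.max() - 10.0) / 2.0
        above = x[y >= half]
        assert above.max() - above.min() == pytest.approx(TRUTH.fwhm, abs=2.0)

    def test_integrated_area_matches_parameter(self):
        area = 5000.0
        table = gen_gaussian_profile(TRUTH, amplitude_area=area, offset=0.0,
                                     pixel_nm=1.0, window_nm=6 * TRUTH.fwhm)
        x = table.data["time"].to_numpy()
        y = table.data["value"].to_numpy()
        assert np.trapezoid(y, x) == pytest.approx(area, rel=0.01)

    def test_bad_pixel_rejected(self):
        with pytest.raises(ValueError):
            gen_gaussian_profile(TRUTH, pixel_nm=0.0)


class TestMeltCurve:
    def test_derivative_maximal_at_mT(self):
        T = np.linspace(20.0, 95.0, 2000)
        y = melt_ratio(T, 46.3, 0.8)
        dy = np.gradient(y, T)
        assert T[np.argmax(dy)] == pytest.approx(46.3, abs=0.1)

    def test_default_grid_is_one_degree_20_to_95(self):
        table = gen_melt_curve()
        T = table.data["time"].to_numpy()
        assert T[0] == 20.0 and T[-1] == 95.0
        assert np.allclose(np.diff(T), 1.0)

    def test_sigmoid_symmetry_with_flat_baselines(self):
        mT = 50.0
        for d in (1.0, 5.0, 12.0):
            lo = melt_ratio(np.array([mT - d]), mT, 0.7)[0]
            hi = melt_ratio(np.array([mT + d]), mT, 0.7)[0]
            mid = melt_ratio(np.array([mT]), mT, 0.7)[0]
            assert lo + hi == pytest.approx(2 * mid, rel=1e-12)

    def test_bad_slope_rejected(self):
        with pytest.raises(ValueError):
            gen_melt_curve(slope=-1.0)


TEMPLATE = "ATGGCTAAACCTGGTTGGACT"  # 7 codons


class TestNNKReads:
    def test_randomized_codons_end_in_G_or_T(self):
        reads = gen_nnk_reads(TEMPLATE, [2, 4], [{"K": 0.5, "L": 0.5}, {"R": 1.0}],
                              n=500, seed=7)
        for _, seq, _ in reads:
            assert seq[8] in "GT" and seq[14] in "GT"

    def test_concentrated_profile_fixes_residue(self):
        reads = gen_nnk_reads(TEMPLATE, [2], [{"W": 1.0}], n=100, seed=3)
        assert all(seq[6:9] == "TGG" for _, seq, _ in reads)

    def test_stop_symbol_uses_amber_codon_only(self):
        assert NNK_CODONS["*"] == ["TAG"]
        reads = gen_nnk_reads(TEMPLATE, [2], [{"*": 1.0}], n=50, seed=1)
        assert all(seq[6:9] == "TAG" for _, seq, _ in reads)

    def test_empirical_frequencies_match_profile(self):
        """Binomial sampling oracle at n = 50,000."""
        n = 50_000
        profile = {2: {"G": 0.6, "W": 0.3, "K": 0.1}}
        reads = gen_nnk_reads(TEMPLATE, [2], profile, n=n, seed=42)
        from splitkin.synth import _CODON_TABLE

        counts = {"G": 0, "W": 0, "K": 0}
        for _, seq, _ in reads:
            counts[_CODON_TABLE[seq[6:9]]] += 1
        for aa, p in profile[2].items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[aa] / n - p) < 3 * se

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError):
            gen_nnk_reads(TEMPLATE, [7], [{"G": 1.0}], n=10, seed=0)
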