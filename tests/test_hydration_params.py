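import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import md_from_tfn
from hydromelt.errors import InvalidInputError, MissingHighTError, UndefinedRatioError
from hydromelt.hydration_params import (
    first_shell_fraction,
    heterogeneity_measure,
    heterogeneity_ratio,
    heterogeneity_ratio_error,
    heterogeneity_ratio_n,
    heterogeneous_fraction,
    summarize,
    waters_per_molecule,
)
from hydromelt.md_model import detect_plateau, fit_md, integrate_dmd, dmd_analytic
from hydromelt.melting_diagram import SampleSpec
from hydromelt.synthetic_data import generate_md, presets
from hydromelt.units_scales import calibrate_c


class TestHeR:
    @pytest.mark.parametrize(
        "t_fno, t_fne, expected",
        [
            (0.832, 0.961, 0.23),  # globular reference, rounded as printed
            (0.5, 1.0, 0.0),  # plateau reaching the bulk melting point
            (0.7, 0.7, 1.0),  # no plateau: fully heterogeneous IDP limit
        ],
    )
    def test_reference_values(self, t_fno, t_fne, expected):
        assert round(heterogeneity_ratio(t_fno, t_fne), 2) == expected

    def test_undefined_at_unit_t_fno(self):
        with pytest.raises(InvalidInputError):
            heterogeneity_ratio(1.0, 0.9)

    @settings(deadline=None)
    @given(
        t_fno=st.floats(0.01, 0.99),
        delta=st.floats(0.0, 1.0),
    )
    def test_bounded_and_monotone(self, t_fno, delta):
        t_fne = t_fno + (1.0 - t_fno) * min(delta, 1.0)
        her = heterogeneity_ratio(t_fno, t_fne)
        assert 0.0 <= her <= 1.0
        if t_fne + 1e-3 < 1.0:
            # decreasing in t_fne, increasing in t_fno
            assert heterogeneity_ratio(t_fno, min(t_fne + 1e-3, 1.0)) <= her + 1e-12
        if t_fno + 1e-3 < t_fne:
            assert heterogeneity_ratio(t_fno + 1e-3, t_fne) >= her - 1e-12

    def test_error_propagation_magnitude(self):
        """Propagated HeR uncertainty from boundary errors of a few
         1e-3 lands within a factor 2 of the published 0.02."""
        err = heterogeneity_ratio_error(0.832, 0.961, 0.004, 0.005)
        assert 0.01 <= err <= 0.04


class TestFractions:
    def test_constant_plateau(self):
        t = np.linspace(0.84, 0.96, 10)
        n_ho, err = first_shell_fraction(md_from_tfn(t, np.full(10, 0.05)), (t[0], t[-1]))
        assert n_ho == 0.05 and err == 0.0

    def test_two_point_plateau_mean(self):
        t = np.array([0.84, 0.85, 0.86, 0.87, 0.88])
        n = np.array([0.0, 0.018, 0.020, 0.05, 0.08])
        n_ho, _ = first_shell_fraction(md_from_tfn(t, n), (0.845, 0.865))
        assert n_ho == pytest.approx(0.019)

    def test_preset_plateau_level_recovered(self):
        truth = presets("ubiquitin_like", noise_sd=0.002, seed=6)
        md = generate_md(truth)
        plateau = detect_plateau(md)
        n_ho, err = first_shell_fraction(md, plateau)
        assert n_ho == pytest.approx(truth.A, rel=0.05)

    def test_heterogeneous_zero_when_no_rise(self):
        t = np.linspace(0.84, 0.99, 10)
        md = md_from_tfn(t, np.full(10, 0.05))
        n_he, _, _ = heterogeneous_fraction(md, 0.05)
        assert n_he == 0.0

    def test_heterogeneous_requires_high_point(self):
        t = np.linspace(0.80, 0.90, 10)
        with pytest.raises(MissingHighTError):
            heterogeneous_fraction(md_from_tfn(t, np.full(10, 0.05)), 0.05)

    def test_erd10_fractions_recovered(self):
        truth = presets("erd10_like", noise_sd=0.002, seed=13)
        md = generate_md(truth)
        plateau = detect_plateau(md)
        n_ho, e_ho = first_shell_fraction(md, plateau)
        n_he, _, t_used = heterogeneous_fraction(md, n_ho, e_ho)
        assert n_ho == pytest.approx(0.0157, rel=0.05)
        # the generator's curve reaches C*(t_used - t_fne)^2 at the readout point
        expected_he = truth.C * (t_used - truth.t_fne) ** 2
        assert n_he == pytest.approx(expected_he, rel=0.08)


class TestHeRnHeM:
    @pytest.mark.parametrize(
        "n_ho, n_he, expected",
        [(226.0, 102.0, 0.3), (5.0, 0.0, 0.0), (0.0, 5.0, 1.0)],
    )
    def test_bond_count_ratio(self, n_ho, n_he, expected):
        assert round(heterogeneity_ratio_n(n_ho, n_he), 1) == expected

    def test_undefined_for_double_zero(self):
        with pytest.raises(UndefinedRatioError):
            heterogeneity_ratio_n(0.0, 0.0)

    @settings(deadline=None)
    @given(
        n_ho=st.floats(0.001, 1e4),
        n_he=st.floats(0.0, 1e4),
        k=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, n_ho, n_he, k):
        assert heterogeneity_ratio_n(k * n_ho, k * n_he) == pytest.approx(
            heterogeneity_ratio_n(n_ho, n_he), rel=1e-9
        )

    @pytest.mark.parametrize(
        "B, C, t_fne, expected",
        [(0.0, 0.0, 0.9, 0.0), (1.0, 0.0, 0.5, 2.0), (0.0, 0.0, 1.0, 0.0)],
    )
    def test_hem(self, B, C, t_fne, expected):
        assert heterogeneity_measure(B, C, t_fne) == expected

    def test_hem_recovered_from_fit(self):
        truth = presets("erd10_like", noise_sd=0.002, seed=17)
        fit = fit_md(generate_md(truth))
        truth_hem = (truth.B + 2 * truth.C) / (1 - truth.t_fne)
        fitted_hem = heterogeneity_measure(fit.B, fit.C, fit.t_fne)
        assert fitted_hem == pytest.approx(truth_hem, rel=0.35)


class TestWaterCounts:
    def test_erd10_first_shell_count(self):
        spec = SampleSpec("ERD10", 50.0, 29400.0, 260, water_molarity=55.35)
        count = waters_per_molecule(0.0157, spec)
        assert count == pytest.approx(511.0, rel=0.005)
        assert count == pytest.approx(514.0, rel=0.01)  # published value

    def test_zero_fraction(self):
        spec = SampleSpec("x", 50.0, 10000.0, 100)
        assert waters_per_molecule(0.0, spec) == 0.0

    def test_equal_molarity_consistency(self):
        # fraction 1 with protein molarity equal to water molarity gives 1
        spec = SampleSpec("x", 55.35, 1.0, 1, water_molarity=55.35)
        assert waters_per_molecule(1.0, spec) == pytest.approx(1.0)


class TestSummarize:
    @pytest.fixture(scope="class")
    def ubq_summary(self):
        truth = presets("ubiquitin_like", noise_sd=0.002, seed=8)
        md = generate_md(truth)
        fit = fit_md(md)
        spec = SampleSpec("UBQ", 50.0, 8565.0, 76)
        return truth, fit, md, summarize(fit, md, spec, calibrate_c())

    def test_totals_and_ratios_consistent(self, ubq_summary):
        truth, fit, md, params = ubq_summary
        assert params.total_bound_count == pytest.approx(
            params.n_ho_count + params.n_he_count
        )
        assert params.her_n == pytest.approx(
            params.n_he_fraction / (params.n_he_fraction + params.n_ho_fraction)
        )
        assert params.n_he_is_lower_bound
        assert params.waters_per_residue == pytest.approx(params.n_ho_count / 76)

    def test_excitation_energies_scale_with_boundaries(self, ubq_summary):
        truth, fit, md, params = ubq_summary
        cal = calibrate_c()
        expected = cal.c * 8.317 * fit.t_fno * 273.15 / 1000.0
        assert params.e_at_tfno == pytest.approx(expected, rel=1e-9)
        assert params.e_at_tfne > params.e_at_tfno

    def test_self_check_against_dmd_area(self, ubq_summary):
        """The high-temperature readout of n_he agrees with the DMD
        area over the heterogeneous region (the method's self-check)."""
        truth, fit, md, params = ubq_summary
        t_used = params.provenance["n_he_read_at_t_fn"]
        dmd = dmd_analytic(fit, np.linspace(fit.onset_t_fn, 0.999, 500))
        area = integrate_dmd(dmd, fit.t_fne, t_used)
        combined = 3 * np.sqrt(0.002**2 + params.uncertainties["n_he_fraction"] ** 2)
        assert abs(params.n_he_fraction - area) < combined + 1e-3
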