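import numpy as np
import pytest

from conftest import md_from_tfn
from hydromelt.errors import InvalidInputError, NoMeltingError, NoOnsetError
from hydromelt.md_model import (
    MdFit,
    detect_onset,
    detect_plateau,
    dmd_analytic,
    dmd_numeric,
    fit_md,
    fit_melting_model,
    integrate_dmd,
    model_n,
)
from hydromelt.synthetic_data import generate_md, presets, truth_curve


def make_fit(**kwargs):
    defaults = dict(
        onset_t_fn=0.8316, A=0.019, t_fno=0.832, t_fne=0.961,
        B=0.0, C=7.785, t_fn1=0.961, t_fn2=0.961,
        fit_window=(0.832, 0.9963),
    )
    defaults.update(kwargs)
    return MdFit(**defaults)


class TestOnset:
    def test_exact_step_on_dense_grid(self):
        t = np.linspace(0.80, 0.90, 501)
        n = np.where(t < 0.832, 0.0, 0.02)
        onset = detect_onset(md_from_tfn(t, n), threshold=0.005)
        assert onset.t_fn == pytest.approx(0.832, abs=2.5e-4)

    def test_recovery_on_noisy_preset(self):
        truth = presets("ubiquitin_like", noise_sd=0.001, seed=12)
        onset = detect_onset(generate_md(truth))
        assert abs(onset.t_fn - truth.onset_t_fn) < 0.005

    def test_bulk_water_onset_near_one(self):
        truth = presets("bulk_water_like", noise_sd=0.001, seed=5)
        onset = detect_onset(generate_md(truth))
        assert abs(onset.t_fn - 1.0) < 0.01

    def test_all_frozen_raises(self):
        t = np.linspace(0.75, 0.95, 10)
        with pytest.raises(NoMeltingError):
            detect_onset(md_from_tfn(t, np.zeros(10)), threshold=0.01)

    def test_all_molten_raises(self):
        t = np.linspace(0.75, 0.95, 10)
        with pytest.raises(NoOnsetError):
            detect_onset(md_from_tfn(t, np.full(10, 0.5)), threshold=0.01)


class TestPlateau:
    def test_flat_curve_spans_whole_window(self):
        t = np.linspace(0.80, 0.96, 20)
        n = np.where(t < 0.82, 0.0, 0.05)
        plateau = detect_plateau(md_from_tfn(t, n))
        assert plateau.t_fno == pytest.approx(t[t >= 0.82][0])
        assert plateau.t_fne == pytest.approx(t[-1])

    def test_steep_curve_degenerates_to_onset(self):
        """Slope far above tolerance everywhere: the no-plateau IDP
        limit, returned as a degenerate plateau rather than an error."""
        t = np.linspace(0.80, 0.96, 20)
        n = np.clip((t - 0.82) * 5.0, 0.0, None)
        plateau = detect_plateau(md_from_tfn(t, n), slope_tol=0.05)
        assert plateau.degenerate
        assert plateau.t_fno == plateau.t_fne == plateau.onset.t_fn

    @pytest.mark.parametrize("name", ["ubiquitin_like", "erd10_like"])
    def test_boundary_recovery_single_seed(self, name):
        truth = presets(name, noise_sd=0.002, seed=4)
        plateau = detect_plateau(generate_md(truth))
        assert abs(plateau.t_fno - truth.t_fno) < 0.01
        assert abs(plateau.t_fne - truth.t_fne) < 0.015


class TestFit:
    def test_exact_quadratic_self_consistency(self):
        """Noiseless data generated from the model itself returns the
        parameters to numerical precision."""
        A, C, t_fno, t_fne = 0.019, 8.0, 0.832, 0.961
        t = np.linspace(0.80, 0.9963, 60)
        n = np.where(
            t < 0.8316, 0.0, np.where(t <= t_fne, A, A + C * (t - t_fne) ** 2)
        )
        fit = fit_melting_model(md_from_tfn(t, n), (t_fno, t_fne), onset=0.8316)
        assert fit.A == pytest.approx(A, abs=1e-9)
        assert fit.B == pytest.approx(0.0, abs=1e-6)
        assert fit.C == pytest.approx(C, abs=1e-5)
        assert fit.t_fn1 == fit.t_fn2 == t_fne

    def test_plateau_only_data(self):
        t = np.linspace(0.84, 0.96, 15)
        n = np.full(15, 0.021)
        fit = fit_melting_model(md_from_tfn(t, n), (t[0], t[-1]), onset=t[0])
        assert fit.B == 0.0 and fit.C == 0.0
        assert fit.A == pytest.approx(0.021)

    def test_continuity_at_plateau_end(self):
        truth = presets("erd10_like", noise_sd=0.002, seed=9)
        fit = fit_md(generate_md(truth))
        assert model_n(fit, fit.t_fne) == pytest.approx(fit.A, abs=1e-12)

    def test_linear_truth_yields_negligible_curvature(self):
        t = np.linspace(0.85, 0.99, 30)
        t_fne = 0.90
        n = np.where(t <= t_fne, 0.02, 0.02 + 1.0 * (t - t_fne))
        fit = fit_melting_model(md_from_tfn(t, n), (t[0], t_fne), onset=t[0])
        assert fit.B == pytest.approx(1.0, abs=1e-6)
        assert fit.C == pytest.approx(0.0, abs=1e-4)

    def test_joint_and_mean_statistics_agree(self):
        truth = presets("ubiquitin_like", noise_sd=0.002, seed=21)
        md = generate_md(truth)
        plateau = detect_plateau(md)
        fit_mean = fit_melting_model(md, plateau, plateau_stat="mean")
        fit_joint = fit_melting_model(md, plateau, plateau_stat="joint")
        assert fit_mean.A == pytest.approx(fit_joint.A, rel=0.05)
        assert fit_mean.plateau_mean == fit_mean.A


class TestDmd:
    def test_zero_coefficients_give_flat_dmd(self):
        fit = make_fit(B=0.0, C=0.0)
        grid = np.linspace(0.85, 0.99, 100)
        dmd = dmd_analytic(fit, grid)
        assert np.all(dmd.dn_dtfn == 0.0)

    def test_linear_model_constant_derivative(self):
        fit = make_fit(B=1.0, C=0.0)
        grid = np.linspace(0.965, 0.99, 50)
        dmd = dmd_analytic(fit, grid)
        assert np.allclose(dmd.dn_dtfn, 1.0)

    def test_onset_bar_area_equals_plateau_level(self):
        fit = make_fit()
        grid = np.linspace(0.82, 0.99, 400)
        dmd = dmd_analytic(fit, grid)
        bar = next(s for s in dmd.segments if s["name"] == "onset")
        assert bar["area"] == pytest.approx(fit.A)

    def test_numeric_constant_slope(self):
        t = np.linspace(0.85, 0.99, 20)
        dmd = dmd_numeric(md_from_tfn(t, 0.5 * t))
        assert np.allclose(dmd.dn_dtfn, 0.5)

    def test_numeric_matches_analytic_on_quadratic(self):
        # centered differences are exact for quadratics on uniform grids
        fit = make_fit(C=7.785)
        t = np.linspace(0.962, 0.9963, 40)
        md = md_from_tfn(t, model_n(fit, t))
        num = dmd_numeric(md)
        ana = dmd_analytic(fit, t)
        assert np.max(np.abs(num.dn_dtfn - ana.dn_dtfn[1:-1])) < 1e-10

    def test_numeric_converges_at_second_order(self):
        """On a cubic model (non-vanishing third derivative) centered
        differences converge to the analytic DMD at order 2."""
        fit = make_fit(B=0.05, C=2.0, D=40.0, order=3)
        errors = []
        for m in (20, 40, 80):
            t = np.linspace(0.962, 0.9963, m + 1)
            num = dmd_numeric(md_from_tfn(t, model_n(fit, t)))
            ana = dmd_analytic(fit, t)
            errors.append(np.max(np.abs(num.dn_dtfn - ana.dn_dtfn[1:-1])))
        assert errors[0] / errors[1] == pytest.approx(4.0, rel=0.2)
        assert errors[1] / errors[2] == pytest.approx(4.0, rel=0.2)

    def test_numeric_agrees_with_analytic_under_noise(self):
        truth = presets("erd10_like", noise_sd=0.002, seed=2)
        md = generate_md(truth)
        fit = fit_md(md)
        num = dmd_numeric(md)
        ana = dmd_analytic(fit, md.t_fn)
        h = np.median(np.diff(md.t_fn))
        sd = np.sqrt(2.0) * 0.002 / (2 * h)
        # compare only where the centered difference does not straddle
        # the onset step or the plateau boundary
        inner = (num.t_fn > fit.t_fne + h) & (num.t_fn < md.t_fn[-1] - h)
        diff = np.abs(num.dn_dtfn[inner] - ana.dn_dtfn[1:-1][inner])
        assert np.all(diff < 3 * sd + 0.05)


class TestIntegrate:
    def test_constant_curve_area(self):
        from hydromelt.md_model import DmdCurve

        t = np.linspace(0.0, 1.0, 11)
        dmd = DmdCurve(t_fn=t, dn_dtfn=np.full(11, 2.0), kind="numeric")
        assert integrate_dmd(dmd, 0.2, 0.7) == pytest.approx(2.0 * 0.5)
        assert integrate_dmd(DmdCurve(t_fn=t, dn_dtfn=np.zeros(11), kind="numeric"), 0, 1) == 0

    def test_reversed_bounds_rejected(self):
        fit = make_fit()
        dmd = dmd_analytic(fit, np.linspace(0.83, 0.99, 50))
        with pytest.raises(InvalidInputError):
            integrate_dmd(dmd, 0.9, 0.8)

    def test_heterogeneous_area_is_rise_of_n(self):
        """Fundamental-theorem identity: the DMD area over [t_fne, 1]
        equals n(1) - A."""
        fit = make_fit()
        dmd = dmd_analytic(fit, np.linspace(0.83, 0.999, 300))
        area = integrate_dmd(dmd, fit.t_fne, 1.0)
        assert area == pytest.approx(model_n(fit, 1.0) - fit.A, abs=1e-12)

    def test_conservation_from_onset(self):
        fit = make_fit()
        dmd = dmd_analytic(fit, np.linspace(0.82, 0.999, 300))
        area = integrate_dmd(dmd, fit.onset_t_fn, 1.0)
        assert area == pytest.approx(model_n(fit, 1.0), abs=1e-9)


def test_pipeline_noiseless_round_trip():
    """With zero noise the pipeline returns the generator parameters:
    A, B, C, t_fne to numerical precision; onset and t_fno to the grid
    resolution (the data cannot localize them more finely)."""
    for name in ("ubiquitin_like", "erd10_like"):
        truth = presets(name, noise_sd=0.0)
        md = generate_md(truth)
        fit = fit_md(md)
        h = np.median(np.diff(truth.grid))
        assert fit.A == pytest.approx(truth.A, rel=1e-9)
        assert fit.t_fne == pytest.approx(truth.t_fne, abs=1e-6)
        assert fit.B == pytest.approx(truth.B, abs=1e-5)
        assert fit.C == pytest.approx(truth.C, rel=1e-4)
        assert abs(fit.t_fno - truth.t_fno) <= h
        assert abs(fit.onset_t_fn - truth.onset_t_fn) <= h
        # and the fitted curve reproduces the truth curve everywhere
        tt = np.linspace(truth.t_fno + h, 0.9963, 200)
        np.testing.assert_allclose(model_n(fit, tt), truth_curve(truth, tt), atol=1e-6)
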