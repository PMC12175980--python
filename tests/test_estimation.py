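"""Basis-function least-squares estimation: recovery, constraints, invariances."""

import numpy as np
import pytest

import flowpet as fp
from flowpet._kinetics import cumtrapz0, resample_uniform, shift_right, frame_average
from flowpet.core import forward_tac
from flowpet.estimation import fit_weights


# -- weights --------------------------------------------------------------

def test_fit_weights_schemes(htr_schedule):
    tac = fp.TimeActivityCurve(htr_schedule, np.full(90, 4.0))
    assert np.allclose(fit_weights(tac, "uniform"), 1.0)
    wd = fit_weights(tac, "frame_duration")
    assert np.allclose(wd[:60], 1.0) and np.allclose(wd[60:], 2.0)
    wv = fit_weights(tac, "inverse_variance")
    assert np.allclose(wv, htr_schedule.durations / 4.0)
    with pytest.raises(ValueError):
        fit_weights(tac, "poisson")


# -- basis structure ------------------------------------------------------

def test_basis_degenerate_nodes(default_aif, htr_schedule):
    """Tc=0 kills the vascular regressor and reduces the tissue regressor to
    the S1TC one; k2=0 turns the tissue regressor into a running integral."""
    grid = fp.GridConfig(k2=np.array([0.0, 0.5]),
                         tc=np.array([0.0, 5.0]),
                         td=np.array([0.0, 2.0]))
    aath = fp.build_basis(default_aif, htr_schedule, grid, "aath")
    s1tc = fp.build_basis(default_aif, htr_schedule, grid, "s1tc")

    b1, b2 = aath.regressors(i_k2=1, i_tc=0, i_td=1)       # Tc = 0 node
    assert np.allclose(b1, 0.0, atol=1e-12)
    s1, s2 = s1tc.regressors(i_k2=1, i_tc=None, i_td=1)
    assert np.allclose(b2, s2, rtol=1e-12)

    # k2 = 0: tissue regressor equals the running integral of the shifted AIF
    _, b2k0 = aath.regressors(i_k2=0, i_tc=0, i_td=0)
    t, ca = resample_uniform(default_aif.times, default_aif.values, 0.1)
    I = cumtrapz0(ca, 0.1)
    oracle = frame_average(t, I, htr_schedule.starts, htr_schedule.ends) / 60.0
    assert np.allclose(b2k0, oracle, rtol=1e-6)


def test_basis_impulse_boxcar(htr_schedule):
    """For a near-delta AIF the vascular regressor of a (Tc, td=0) node is a
    frame-averaged boxcar of height area/60 on [0, Tc)."""
    dt = 0.1
    t = np.arange(0, 130, dt)
    vals = np.zeros(t.size)
    vals[1] = 50.0
    area = 50.0 * dt
    aif = fp.ArterialInput(t, vals)
    grid = fp.GridConfig(k2=np.array([0.5]), tc=np.array([4.0]),
                         td=np.array([0.0]))
    basis = fp.build_basis(aif, htr_schedule, grid, "aath")
    b1, _ = basis.regressors(0, 0, 0)
    assert np.allclose(b1[1:4], area / 60.0, rtol=0.02)    # inside the boxcar
    assert np.allclose(b1[10:], 0.0, atol=1e-12)           # past the transit


# -- recovery -------------------------------------------------------------

@pytest.mark.parametrize("F,E,ik2,tc,td", [
    (0.507, 0.27, 6, 4.5, 1.0),    # cortex-like
    (2.0, 0.04, 4, 4.0, 0.5),      # lung-like, low extraction
    (0.15, 0.9, 2, 7.0, 2.0),      # low-flow, high extraction
])
def test_noiseless_aath_recovery(default_aif, htr_schedule, small_grid,
                                 aath_basis_small, F, E, ik2, tc, td):
    """Noiseless on-grid truths are recovered to machine precision."""
    p = fp.AATHParams(F=F, K1=E * F, k2=float(small_grid.k2[ik2]), Tc=tc, td=td)
    tac = forward_tac("aath", p, default_aif, htr_schedule)
    fit = fp.fit_tac(tac, aath_basis_small)
    assert fit.params.F == pytest.approx(p.F, rel=1e-6)
    assert fit.params.K1 == pytest.approx(p.K1, rel=1e-6)
    assert fit.params.k2 == p.k2
    assert fit.params.Tc == p.Tc
    assert fit.params.td == p.td
    sy2 = float(fit.weights @ tac.values ** 2)
    assert fit.rss <= 1e-10 * sy2


def test_noiseless_s1tc_recovery(default_aif, htr_schedule, small_grid,
                                 s1tc_basis_small):
    p = fp.S1TCParams(vb=0.04, K1=0.13, k2=float(small_grid.k2[5]), td=1.5)
    tac = forward_tac("s1tc", p, default_aif, htr_schedule)
    fit = fp.fit_tac(tac, s1tc_basis_small)
    assert fit.params.vb == pytest.approx(p.vb, rel=1e-6)
    assert fit.params.K1 == pytest.approx(p.K1, rel=1e-6)
    assert fit.params.k2 == p.k2 and fit.params.td == p.td
    assert fit.rss <= 1e-10 * float(fit.weights @ tac.values ** 2)


def test_all_zero_tac(aath_basis_small, s1tc_basis_small, htr_schedule,
                      small_grid):
    """A flat-zero TAC yields zero coefficients, zero RSS, and the
    deterministic first grid node (smallest td, Tc, k2)."""
    z = fp.TimeActivityCurve(htr_schedule, np.zeros(90))
    fa = fp.fit_tac(z, aath_basis_small)
    assert fa.params.F == 0.0 and fa.params.K1 == 0.0 and fa.rss == 0.0
    assert fa.grid_indices == {"k2": 0, "tc": 0, "td": 0}
    fs = fp.fit_tac(z, s1tc_basis_small)
    assert fs.params.vb == 0.0 and fs.params.K1 == 0.0 and fs.rss == 0.0


def test_scale_equivariance(htr_schedule, small_grid):
    """Scaling the TAC and AIF together leaves every parameter unchanged."""
    aif = fp.generate_aif(fp.AIFModelParams())
    p = fp.AATHParams(F=0.5, K1=0.15, k2=float(small_grid.k2[5]), Tc=4.5, td=1.0)
    tac = forward_tac("aath", p, aif, htr_schedule)
    noisy = tac.with_values(tac.values
                            + np.random.default_rng(3).normal(0, 0.1, 90))
    s = 7.5
    aif_s = fp.ArterialInput(aif.times, s * aif.values)
    tac_s = fp.TimeActivityCurve(htr_schedule, s * noisy.values)
    f1 = fp.fit_tac(noisy, fp.build_basis(aif, htr_schedule, small_grid, "aath"))
    f2 = fp.fit_tac(tac_s, fp.build_basis(aif_s, htr_schedule, small_grid, "aath"))
    for attr in ("F", "K1", "k2", "Tc", "td"):
        assert getattr(f1.params, attr) == pytest.approx(
            getattr(f2.params, attr), rel=1e-9)


def test_grid_refinement_never_increases_rss(default_aif, htr_schedule):
    coarse = fp.GridConfig(k2=np.geomspace(0.05, 2.0, 5),
                           tc=np.arange(0.0, 12.1, 2.0),
                           td=np.arange(0.0, 4.1, 2.0))
    fine = fp.GridConfig(k2=np.unique(np.concatenate(
                             [coarse.k2, np.geomspace(0.07, 1.5, 7)])),
                         tc=np.arange(0.0, 12.1, 1.0),
                         td=np.arange(0.0, 4.1, 1.0))
    p = fp.AATHParams(F=0.6, K1=0.2, k2=0.33, Tc=5.3, td=1.2)
    tac = forward_tac("aath", p, default_aif, htr_schedule)
    noisy = tac.with_values(tac.values
                            + np.random.default_rng(5).normal(0, 0.15, 90))
    r_coarse = fp.fit_tac(noisy, fp.build_basis(default_aif, htr_schedule,
                                                coarse, "aath")).rss
    r_fine = fp.fit_tac(noisy, fp.build_basis(default_aif, htr_schedule,
                                              fine, "aath")).rss
    assert r_fine <= r_coarse + 1e-12


def test_fitted_parameters_stay_physical(default_aif, htr_schedule,
                                         aath_basis_small):
    """Noisy fits always satisfy 0 <= E <= 1 and 0 <= vb <= 1."""
    rng = np.random.default_rng(11)
    truth = fp.AATHParams(F=0.12, K1=0.11, k2=0.4, Tc=8.0, td=1.0)  # E ~ 0.92
    clean = forward_tac("aath", truth, default_aif, htr_schedule)
    for _ in range(15):
        noisy = clean.with_values(clean.values + rng.normal(0, 0.08, 90))
        f = fp.fit_tac(noisy, aath_basis_small)
        assert 0.0 <= f.params.E <= 1.0
        assert 0.0 <= f.params.vb <= 1.0
        assert f.params.K1 <= f.params.F + 1e-12
        assert f.rss >= 0.0


def test_fit_input_validation(aath_basis_small, htr_schedule):
    tac = fp.TimeActivityCurve(htr_schedule, np.ones(90))
    with pytest.raises(ValueError):
        fp.fit_tac(tac, aath_basis_small, weights=np.zeros(90))
    other = fp.FrameSchedule.from_durations(np.full(10, 12.0))
    with pytest.raises(ValueError):
        fp.fit_tac(fp.TimeActivityCurve(other, np.ones(10)), aath_basis_small)


def test_fitted_curve_matches_coefficients(default_aif, htr_schedule,
                                           aath_basis_small):
    """The stored fitted curve equals the forward model at the fitted node."""
    truth = fp.AATHParams(F=0.5, K1=0.14, k2=0.35, Tc=4.5, td=1.0)
    clean = forward_tac("aath", truth, default_aif, htr_schedule)
    noisy = clean.with_values(clean.values
                              + np.random.default_rng(2).normal(0, 0.1, 90))
    fit = fp.fit_tac(noisy, aath_basis_small)
    re_fwd = forward_tac("aath", fit.params, default_aif, htr_schedule)
    assert np.allclose(fit.fitted.values, re_fwd.values, rtol=1e-8, atol=1e-10)
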