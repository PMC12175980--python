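"""Impulse responses, parameter identities, and the convolution forward model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import flowpet as fp
from flowpet.core import forward_tac


# -- schedules and containers --------------------------------------------

def test_htr_protocol_constant():
    s = fp.FrameSchedule.htr_early_dynamic()
    assert s.n_frames == 90
    assert np.allclose(s.durations[:60], 1.0)
    assert np.allclose(s.durations[60:], 2.0)
    assert s.starts[0] == 0.0 and s.ends[-1] == 120.0
    assert s.is_contiguous()


@pytest.mark.parametrize("starts,ends", [
    ([0.0], [1.0]),                       # fewer than 2 frames
    ([0.0, 1.0], [1.0, 0.5]),             # end before start
    ([0.0, 0.5], [1.0, 1.5]),             # overlapping
    ([-1.0, 1.0], [0.0, 2.0]),            # negative time
])
def test_schedule_validation(starts, ends):
    with pytest.raises(ValueError):
        fp.FrameSchedule(starts, ends)


def test_arterial_input_validation():
    t = np.arange(0, 130, 0.1)
    with pytest.raises(ValueError):
        fp.ArterialInput(t, -np.ones(t.size))
    with pytest.raises(ValueError):
        fp.ArterialInput(np.arange(0, 260, 1.0), np.ones(260))   # 1 s spacing
    with pytest.raises(ValueError):
        fp.ArterialInput(np.array([0.0, 0.1, 0.3]), np.zeros(3))  # non-uniform


def test_tac_length_mismatch(htr_schedule):
    with pytest.raises(ValueError):
        fp.TimeActivityCurve(htr_schedule, np.zeros(10))
    with pytest.raises(ValueError):
        fp.TimeActivityCurve(htr_schedule, np.full(90, np.nan))


# -- impulse responses ----------------------------------------------------

def test_s1tc_irf_values():
    p = fp.S1TCParams(vb=0.05, K1=0.2, k2=0.693)
    assert fp.s1tc_irf(0.0, p) == pytest.approx(0.05)
    assert fp.s1tc_irf(60.0, fp.S1TCParams(vb=0.05, K1=0.2, k2=0.0)) == \
        pytest.approx(0.2)
    # one clearance half-life after one minute: 0.2 * exp(-0.693)
    assert fp.s1tc_irf(60.0, p) == pytest.approx(0.1, rel=1e-3)
    with pytest.raises(ValueError):
        fp.s1tc_irf(-1.0, p)


def test_aath_irf_values():
    p = fp.AATHParams(F=0.6, K1=0.2, k2=0.8, Tc=5.0)
    assert fp.aath_irf(2.0, p) == pytest.approx(0.6)        # vascular phase
    assert fp.aath_irf(5.0, p) == pytest.approx(0.2)        # right-continuous
    p0 = fp.AATHParams(F=0.6, K1=0.2, k2=0.0, Tc=0.0)
    assert fp.aath_irf(30.0, p0) == pytest.approx(0.2)      # degenerate transit
    with pytest.raises(ValueError):
        fp.aath_irf(-0.5, p)


def test_aath_params_invariants():
    with pytest.raises(ValueError):
        fp.AATHParams(F=0.5, K1=0.6, k2=0.1, Tc=5.0)        # E > 1
    with pytest.raises(ValueError):
        fp.AATHParams(F=2.0, K1=0.5, k2=0.1, Tc=40.0)       # vb > 1
    p = fp.AATHParams(F=0.5, K1=0.25, k2=0.1, Tc=6.0)
    assert p.E == pytest.approx(0.5)
    assert p.vb == pytest.approx(0.05)


def test_extraction_fraction():
    assert fp.extraction_fraction(1.0, 1.0) == pytest.approx(1.0)
    assert fp.extraction_fraction(2.0, 0.0) == pytest.approx(0.0)
    assert fp.extraction_fraction(0.507, 0.136) == pytest.approx(0.2682, abs=1e-4)
    with pytest.raises(ValueError):
        fp.extraction_fraction(0.5, 0.6)
    with pytest.raises(ValueError):
        fp.extraction_fraction(0.0, 0.0)


def test_vascular_transit_time():
    assert fp.vascular_transit_time(0.05, 1.0) == pytest.approx(3.0)
    assert fp.vascular_transit_time(0.0, 1.0) == pytest.approx(0.0)
    assert fp.vascular_transit_time(0.036, 0.507) == pytest.approx(4.26, abs=0.01)
    with pytest.raises(ValueError):
        fp.vascular_transit_time(0.05, 0.0)


# -- forward model --------------------------------------------------------

def _constant_aif(c=10.0, duration=600.0, dt=0.5):
    t = np.arange(0.0, duration + 1e-9, dt)
    return fp.ArterialInput(t, np.full(t.size, c))


def test_constant_input_plateau_aath():
    """With a constant input c the TAC settles at c*(vb + K1/k2)."""
    c = 10.0
    aif = _constant_aif(c)
    sched = fp.FrameSchedule.from_durations(np.full(120, 5.0))
    p = fp.AATHParams(F=0.6, K1=0.2, k2=2.0, Tc=5.0)
    tac = forward_tac("aath", p, aif, sched)
    expected = c * (p.vb + p.K1 / p.k2)
    assert tac.values[-1] == pytest.approx(expected, rel=1e-3)


def test_constant_input_plateau_s1tc():
    c = 10.0
    aif = _constant_aif(c)
    sched = fp.FrameSchedule.from_durations(np.full(120, 5.0))
    p = fp.S1TCParams(vb=0.05, K1=0.2, k2=2.0)
    tac = forward_tac("s1tc", p, aif, sched)
    assert tac.values[-1] == pytest.approx(c * (p.vb + p.K1 / p.k2), rel=1e-3)


def test_zero_aif_gives_zero_tac(htr_schedule):
    t = np.arange(0, 130, 0.1)
    aif = fp.ArterialInput(t, np.zeros(t.size))
    p = fp.AATHParams(F=0.5, K1=0.1, k2=0.3, Tc=5.0, td=2.0)
    assert np.allclose(forward_tac("aath", p, aif, htr_schedule).values, 0.0)


def test_aif_too_short_raises():
    t = np.arange(0, 60, 0.1)
    aif = fp.ArterialInput(t, np.ones(t.size))
    p = fp.AATHParams(F=0.5, K1=0.1, k2=0.3, Tc=5.0)
    with pytest.raises(ValueError):
        forward_tac("aath", p, aif, fp.FrameSchedule.htr_early_dynamic())


def test_impulse_input_recovers_impulse_response(htr_schedule):
    """A near-delta input reproduces the frame-averaged impulse response."""
    dt = 0.1
    t = np.arange(0, 130, dt)
    vals = np.zeros(t.size)
    vals[1] = 50.0                       # triangle pulse at 0.1 s, area 50*dt
    area = 50.0 * dt
    aif = fp.ArterialInput(t, vals)
    p = fp.AATHParams(F=0.6, K1=0.3, k2=0.6, Tc=5.0)
    tac = forward_tac("aath", p, aif, htr_schedule)
    # oracle: analytic impulse response, shifted by the pulse center,
    # frame-averaged by direct numerical integration
    fine = np.arange(0, 120.0001, 0.01)
    r = fp.aath_irf(np.maximum(fine - 0.1, 0.0), p) * (fine >= 0.1)
    expected = np.empty(htr_schedule.n_frames)
    for i, (a, b) in enumerate(zip(htr_schedule.starts, htr_schedule.ends)):
        m = (fine >= a) & (fine < b)
        expected[i] = r[m].mean() * area / 60.0
    # skip frames containing the response discontinuities (0 and Tc)
    keep = np.ones(90, bool)
    keep[0] = keep[4] = keep[5] = False
    assert np.allclose(tac.values[keep], expected[keep], rtol=0.02)


def test_forward_superposition(default_aif, htr_schedule):
    """The TAC is linear in (F, K1) at fixed (k2, Tc, td)."""
    kw = dict(k2=0.5, Tc=4.5, td=1.0)
    q1 = forward_tac("aath", fp.AATHParams(F=0.4, K1=0.1, **kw),
                     default_aif, htr_schedule).values
    q2 = forward_tac("aath", fp.AATHParams(F=0.3, K1=0.2, **kw),
                     default_aif, htr_schedule).values
    q12 = forward_tac("aath", fp.AATHParams(F=0.7, K1=0.3, **kw),
                      default_aif, htr_schedule).values
    assert np.allclose(q1 + q2, q12, rtol=1e-10, atol=1e-12)


def test_time_shift_equivariance(htr_schedule):
    """Shifting the AIF by delta while reducing td by delta leaves Q fixed."""
    delta = 2.0
    base = fp.AIFModelParams(arrival_time_s=15.0)
    shifted = fp.AIFModelParams(arrival_time_s=15.0 + delta)
    p_late = fp.AATHParams(F=0.5, K1=0.15, k2=0.4, Tc=5.0, td=delta)
    p_zero = fp.AATHParams(F=0.5, K1=0.15, k2=0.4, Tc=5.0, td=0.0)
    q1 = forward_tac("aath", p_late, fp.generate_aif(base), htr_schedule).values
    q2 = forward_tac("aath", p_zero, fp.generate_aif(shifted), htr_schedule).values
    assert np.allclose(q1, q2, rtol=1e-6, atol=1e-9)


@given(st.floats(0.1, 2.0), st.floats(0.05, 0.95), st.floats(0.01, 2.0),
       st.floats(0.0, 15.0), st.floats(0.0, 5.0))
def test_forward_nonnegative(F, E, k2, Tc, td):
    """Non-negative AIF and valid parameters yield a non-negative TAC."""
    aif = test_forward_nonnegative.aif
    sched = test_forward_nonnegative.sched
    p = fp.AATHParams(F=F, K1=E * F, k2=k2, Tc=Tc, td=td)
    q = forward_tac("aath", p, aif, sched).values
    assert np.all(q >= -1e-9)


test_forward_nonnegative.aif = fp.generate_aif(fp.AIFModelParams())
test_forward_nonnegative.sched = fp.FrameSchedule.htr_early_dynamic()


def test_tc_to_zero_limit(default_aif, htr_schedule):
    """At fixed vb = F*Tc/60, the AATH TAC converges to the S1TC TAC."""
    vb, K1, k2 = 0.05, 0.12, 0.5
    s1 = forward_tac("s1tc", fp.S1TCParams(vb=vb, K1=K1, k2=k2),
                     default_aif, htr_schedule).values
    errs = []
    for tc in (4.0, 2.0, 1.0, 0.1):
        p = fp.AATHParams(F=60.0 * vb / tc, K1=K1, k2=k2, Tc=tc)
        q = forward_tac("aath", p, default_aif, htr_schedule).values
        errs.append(np.max(np.abs(q - s1)))
    # convergence is first order in Tc (error ~ vb*Tc/2 * max|Ca'|)
    assert all(a > b for a, b in zip(errs, errs[1:]))
    assert errs[-1] < 0.02 * np.max(np.abs(s1))
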