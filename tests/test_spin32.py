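"""Spin-3/2 simulator: rate formulas, propagation oracles, steady states."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from na_contrast.operators import BASIS_KEYS, spin_operators, tensor_basis
from na_contrast.spin32 import (
    EnvironmentRelaxation,
    PulseEvent,
    SequenceSpec,
    SpinState,
    equilibrium_state,
    evolve,
    redfield_rates,
    relaxation_weighting,
    sequence_presets,
    steady_state_signal,
)


# ---------------------------------------------------------------------------
# Redfield rates
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "J0,J1,J2,expected",
    [
        (50, 50, 50, (100, 100, 100, 100)),  # isotropic mono-exponential limit
        (560, 60, 40, (620, 100, 120, 80)),
    ],
)
def test_redfield_rates_formula(J0, J1, J2, expected):
    r = redfield_rates(EnvironmentRelaxation("e", J0, J1, J2))
    assert (r.R2f, r.R2s, r.R1f, r.R1s) == pytest.approx(expected)
    assert (r.a2f, r.a2s, r.a1f, r.a1s) == (0.6, 0.4, 0.2, 0.8)


def test_unordered_spectral_densities_rejected():
    with pytest.raises(ValueError):
        EnvironmentRelaxation("bad", J0=10, J1=20, J2=5)
    with pytest.raises(ValueError):
        EnvironmentRelaxation("bad", J0=10, J1=5, J2=-1)


@given(
    st.floats(0, 1000),
    st.floats(0, 1000),
    st.floats(0, 1000),
)
def test_rates_ordered_and_positive(a, b, c):
    J2, J1, J0 = sorted((a, b, c))
    r = redfield_rates(EnvironmentRelaxation("e", J0, J1, J2))
    assert r.R2f >= r.R2s >= 0
    assert r.R1f >= 0 and r.R1s >= 0


# ---------------------------------------------------------------------------
# propagation against an independent Hilbert-space ODE oracle
# ---------------------------------------------------------------------------

def _oracle_trajectory(env, state0, t_s, n_eval=7):
    """Integrate the density operator in 4x4 Hilbert space directly."""
    T = tensor_basis()
    ops = spin_operators()
    rho0 = sum(state0.coeffs[i] * T[k] for i, k in enumerate(BASIS_KEYS))
    rho_eq = state0.m0 * T[(1, 0)]
    Iz2 = ops["Iz"] @ ops["Iz"]
    wq = 2 * np.pi * env.fQ
    Js = {0: env.J0, 1: env.J1, -1: env.J1, 2: env.J2, -2: env.J2}

    def deriv(t, y):
        rho = y.reshape(4, 4)
        d = -1j * (wq / 2) * (Iz2 @ rho - rho @ Iz2)
        for q in (-2, -1, 0, 1, 2):
            A = T[(2, q)]
            Ah = A.conj().T
            dr = rho - rho_eq
            inner = Ah @ dr - dr @ Ah
            d = d - Js[q] * (A @ inner - inner @ A)
        return d.ravel()

    sol = solve_ivp(
        deriv,
        (0, t_s),
        rho0.ravel().astype(complex),
        t_eval=np.linspace(0, t_s, n_eval),
        rtol=1e-11,
        atol=1e-13,
    )
    return sol.t, [sol.y[:, i].reshape(4, 4) for i in range(sol.y.shape[1])]


@pytest.mark.parametrize(
    "J0,J1,J2,fq",
    [(560, 60, 40, 0.0), (200, 150, 12, 0.0), (800, 100, 30, 350.0)],
)
def test_free_evolution_matches_ode_oracle(J0, J1, J2, fq):
    env = EnvironmentRelaxation("e", J0, J1, J2, fQ=fq)
    T = tensor_basis()
    start = evolve(equilibrium_state(), env, rf=PulseEvent(90, 0.0, shape="hard"))
    ts, rhos = _oracle_trajectory(env, start, 8e-3)
    for t, rho in zip(ts, rhos):
        got = evolve(start, env, duration=t * 1e3)
        want = np.array(
            [np.trace(T[k].conj().T @ rho) for k in BASIS_KEYS], dtype=complex
        )
        assert np.allclose(got.coeffs, want, atol=1e-8)


def test_biexponential_transverse_fractions():
    env = EnvironmentRelaxation("e", 560, 60, 40)
    r = redfield_rates(env)
    st_ = evolve(equilibrium_state(), env, rf=PulseEvent(90, 0.0, shape="hard"))
    for t_ms in (0.1, 0.5, 1.7, 4.0, 9.0):
        s = evolve(st_, env, duration=t_ms)
        t = t_ms * 1e-3
        pred = 0.6 * np.exp(-r.R2f * t) + 0.4 * np.exp(-r.R2s * t)
        assert abs(s.transverse_signal) == pytest.approx(pred, abs=1e-9)


def test_biexponential_longitudinal_fractions():
    env = EnvironmentRelaxation("e", 560, 60, 40)
    r = redfield_rates(env)
    for t_ms in (1.0, 5.0, 20.0, 60.0):
        s = evolve(SpinState(), env, duration=t_ms)
        t = t_ms * 1e-3
        pred = 1 - (0.2 * np.exp(-r.R1f * t) + 0.8 * np.exp(-r.R1s * t))
        assert s.longitudinal == pytest.approx(pred, abs=1e-9)


def test_quadrupole_beat_60_40():
    """After an ideal 90 pulse with splitting fQ and no relaxation the
    satellite (60%) and central (40%) coherences beat as
    |0.6 cos(2 pi fQ t) + 0.4|."""
    fq = 500.0
    env = EnvironmentRelaxation("q", 0, 0, 0, fQ=fq)
    st_ = evolve(equilibrium_state(), env, rf=PulseEvent(90, 0.0, shape="hard"))
    for t_ms in (0.13, 0.5, 0.77, 1.0, 1.9):
        s = evolve(st_, env, duration=t_ms)
        pred = abs(0.6 * np.cos(2 * np.pi * fq * t_ms * 1e-3) + 0.4)
        assert abs(s.transverse_signal) == pytest.approx(pred, abs=1e-6)


@pytest.mark.parametrize("theta", [30, 64, 90, 110])
def test_hard_pulse_nutation(theta):
    env = EnvironmentRelaxation("none", 0, 0, 0)
    s = evolve(equilibrium_state(), env, rf=PulseEvent(theta, 0.0, shape="hard"))
    assert abs(s.transverse_signal) == pytest.approx(np.sin(np.deg2rad(theta)), abs=1e-12)


def test_zero_duration_is_identity():
    env = EnvironmentRelaxation("e", 100, 50, 20)
    s0 = evolve(equilibrium_state(), env, rf=PulseEvent(47, 0.3))
    s1 = evolve(s0, env, duration=0.0)
    assert np.array_equal(s0.coeffs, s1.coeffs)


def test_propagation_is_divisible():
    """One 2 ms step equals two 1 ms steps (constant-generator exactness);
    the rect-pulse propagator is therefore step-size independent."""
    env = EnvironmentRelaxation("e", 300, 80, 25, fQ=200)
    rf = PulseEvent(110, 4.0)
    full = evolve(equilibrium_state(), env, rf=rf, duration=2.0)
    half = evolve(evolve(equilibrium_state(), env, rf=rf, duration=1.0), env, rf=rf, duration=1.0)
    assert np.allclose(full.coeffs, half.coeffs, atol=1e-12)


def test_hermiticity_preserved():
    env = EnvironmentRelaxation("e", 420, 90, 33, fQ=260)
    s = evolve(equilibrium_state(), env, rf=PulseEvent(70, 1.2))
    s = evolve(s, env, duration=3.3)
    assert s.hermiticity_defect() < 1e-10


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def test_steady_state_closed_form_saturation():
    """Ideal pulses + mono-exponential relaxation reduce to the spoiled
    gradient-echo saturation formula sin(t)(1-E1)/(1-cos(t)E1)."""
    for J, theta, TR in [(25, 40, 30), (12, 75, 50), (40, 25, 18)]:
        env = EnvironmentRelaxation("m", J, J, J)
        seq = SequenceSpec(
            "t", excitation=PulseEvent(theta, 0.0, shape="hard"), TE=1e-9, TR=TR
        )
        E1 = np.exp(-TR * 1e-3 * 2 * J)
        th = np.deg2rad(theta)
        pred = np.sin(th) * (1 - E1) / (1 - np.cos(th) * E1)
        assert abs(steady_state_signal(seq, env)) == pytest.approx(pred, abs=1e-6)


def test_fully_relaxed_90_gives_m0():
    env = EnvironmentRelaxation("m", 20, 20, 20)  # R1 = 40/s, T1 = 25 ms
    seq = SequenceSpec(
        "t", excitation=PulseEvent(90, 0.0, shape="hard"), TE=1e-9, TR=400
    )
    assert abs(steady_state_signal(seq, env)) == pytest.approx(1.0, abs=1e-6)


def test_inversion_recovery_null():
    """A mono-exponential fluid inverted with a short pulse and read at the
    recovery null TI = T1 ln 2 yields almost no signal."""
    J = 10.0  # T1 = 50 ms
    T1_ms = 1e3 / (2 * J)
    env = EnvironmentRelaxation("fluid", J, J, J)
    seq = SequenceSpec(
        "ir",
        excitation=PulseEvent(64, 1e-4),
        TE=0.01,
        TR=40 * T1_ms,
        inversion=PulseEvent(180, 1e-4),
        TI=np.log(2) * T1_ms,
    )
    assert abs(steady_state_signal(seq, env)) < 5e-3


def test_relaxation_free_weighting_is_one(sequences):
    env = EnvironmentRelaxation("none", 0, 0, 0)
    for name in ("NaDW", "NaPACMAN"):
        assert relaxation_weighting(sequences[name], env) == pytest.approx(1.0, abs=1e-9)


def test_weighting_monotone_in_J0(sequences):
    rws = [
        relaxation_weighting(
            sequences["NaDW"], EnvironmentRelaxation("e", J0, 60, 20)
        )
        for J0 in (60, 200, 600, 2000, 6000)
    ]
    assert all(a >= b - 1e-12 for a, b in zip(rws, rws[1:]))


def test_powder_average_splitting_loses_signal(sequences):
    """Orientation-averaged splitting still causes net signal loss relative
    to the isotropic case, and the average stays physical."""
    powder = EnvironmentRelaxation("m", 300, 60, 20, fQ=400, fQ_model="powder-average")
    none = EnvironmentRelaxation("m", 300, 60, 20)
    seq = sequences["NaPACMAN"]
    rw_powder = relaxation_weighting(seq, powder)
    rw_none = relaxation_weighting(seq, none)
    assert 0.0 < rw_powder < rw_none


# ---------------------------------------------------------------------------
# presets and the calibrated weighting table
# ---------------------------------------------------------------------------

def test_sequence_presets_timings(sequences):
    dw, pm, si = sequences["NaDW"], sequences["NaPACMAN"], sequences["NaSIRFLA"]
    assert (dw.TR, dw.excitation.flip_nominal, dw.excitation.tau_rf, dw.TE) == (85, 30, 0.11, 0.11)
    assert (pm.TR, pm.excitation.flip_nominal, pm.excitation.tau_rf, pm.TE) == (25, 110, 4.0, 2.5)
    assert (si.TR, si.TI, si.excitation.flip_nominal, si.TE) == (150, 37, 64, 0.22)
    assert si.inversion.flip_nominal == 180 and si.inversion.tau_rf == 5.0
    for seq in sequences.values():
        assert seq.TE < seq.TR


def test_calibrated_defaults_reproduce_published_weightings(sequences, environments):
    """The shipped environment calibration reproduces the published
    relaxation-weighting grid (3 sequences x intra/extra/myelin/edema)."""
    from na_contrast.signal_model import PRINTED_RW

    for sname, row in PRINTED_RW.items():
        for ename, target in row.items():
            rw = relaxation_weighting(sequences[sname], environments[ename])
            assert rw == pytest.approx(target, abs=0.02), (sname, ename)


def test_environment_config_roundtrip(tmp_path, environments):
    from na_contrast.environments import load_environments

    text = "environments:\n  myelin:\n    J0: 500\n    J1: 50\n    J2: 10\n    fQ_hz: 300\n"
    cfg = tmp_path / "envs.yaml"
    cfg.write_text(text)
    envs = load_environments(cfg)
    assert envs["myelin"].fQ == 300 and envs["myelin"].J0 == 500
    assert set(environments) >= {"intra", "extra", "myelin", "edema", "csf", "agar"}
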