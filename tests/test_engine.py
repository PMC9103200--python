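"""R-neuron dynamics: kernels, summation, SMO, WTA, heterosynaptic LTD."""

import math

import numpy as np
import pytest

from tempsep import (InputPattern, ModelConfig, apply_hsltd,
                     build_connectivity, calibrate_threshold, dendritic_drive,
                     epsp_kernel, kernel_peak_time, make_spike_train,
                     run_trial, smo_trace, smo_value, somatic_drive,
                     sublinear_factor)
from tempsep.patterns import default_frequency_assignment, rounded_isi


# -- EPSP kernel -----------------------------------------------------------

def test_kernel_zero_at_onset_and_known_value():
    assert epsp_kernel(0.0, w=2.0, k=0.8, g=1.35) == 0.0
    assert epsp_kernel(1.0, w=2.0, k=0.8, g=1.35) == pytest.approx(1.6 / 1.35)


@pytest.mark.parametrize("g,expected_peak", [(1.35, 3.332), (2.7, 1.007)])
def test_kernel_peak_at_tau_over_ln_g(g, expected_peak):
    assert kernel_peak_time(g) == pytest.approx(expected_peak, abs=0.001)
    t = np.linspace(0, 30, 30001)
    vals = epsp_kernel(t, w=1.0, k=1.0, g=g)
    assert t[np.argmax(vals)] == pytest.approx(expected_peak, abs=0.01)


def test_kernel_decay_ratio_between_neuron_types_is_two():
    # g=1.35 decays with tau/ln g ~ 3.33 ms, g=2.7 with ~1.01 ms
    assert kernel_peak_time(1.35) / kernel_peak_time(2.7) == pytest.approx(
        math.log(2.7) / math.log(1.35))


def test_non_decaying_kernel_rejected():
    with pytest.raises(ValueError):
        epsp_kernel(1.0, w=1.0, k=1.0, g=1.0)


# -- sublinear branch summation --------------------------------------------

def test_sublinear_factor_endpoints():
    assert sublinear_factor(1) == 1.0
    assert sublinear_factor(8) == pytest.approx(5 / 12)   # 8th EPSP at ~40%
    assert sublinear_factor(13) == 0.0
    with pytest.raises(ValueError):
        sublinear_factor(14)
    with pytest.raises(ValueError):
        sublinear_factor(0)


# -- subthreshold membrane potential oscillation ----------------------------

def test_smo_zero_and_ascending_at_reference_time():
    assert smo_value(200.0, h=8.0, fq=5.0, ref_time=200.0) == pytest.approx(0.0)
    assert smo_value(201.0, h=8.0, fq=5.0, ref_time=200.0) > 0


def test_smo_period_is_1000_over_fq():
    t = np.arange(0, 400)
    a = smo_value(t, h=8.0, fq=5.0, ref_time=200.0)
    b = smo_value(t + 200.0, h=8.0, fq=5.0, ref_time=200.0)
    assert np.allclose(a, b)


def test_smo_landmarks_for_anchor_200():
    # anchored at 200 ms, a 5 Hz 8 mV SMO bottoms at 150 and peaks at 250
    assert smo_value(150.0, 8.0, 5.0, 200.0) == pytest.approx(-8.0)
    assert smo_value(250.0, 8.0, 5.0, 200.0) == pytest.approx(8.0)


def test_default_smo_trough_follows_input_onset(cfg):
    # default anchor 75 ms: trough at 25 ms, just after the 10 ms onset,
    # rising to the peak at 125 ms -- the input arrives in the low phase
    smo = smo_trace(cfg)
    assert np.argmin(smo[:150]) == 25
    assert np.argmax(smo[:200]) == 125


# -- somatic summation ------------------------------------------------------

def test_somatic_drive_applies_delay_and_attenuation():
    traces = np.zeros((2, 50))
    traces[0, 10] = 4.0
    traces[1, 10] = 4.0
    out = somatic_drive(traces, delays_ms=np.array([2.0, 4.0]), u_pass=0.5)
    assert out[12] == pytest.approx(2.0)       # branch 1 arrives at +2
    assert out[14] == pytest.approx(2.0)       # branch 2 at +4
    assert out[:12].sum() == 0.0


def test_empty_pattern_produces_zero_drive(single_r_cfg, dense_conn):
    pat = InputPattern(frozenset({7}), {7: 1.0})   # one spike at 1 Hz, beyond t_max
    drive = dendritic_drive(dense_conn, pat, single_r_cfg)
    assert drive.shape == (1, single_r_cfg.n_steps)
    assert np.all(drive == 0.0)


def test_drive_superposition_matches_per_event_oracle(single_r_cfg, dense_conn):
    """The engine's scattered drive equals a brute-force per-event kernel sum."""
    cfg, conn = single_r_cfg, dense_conn
    pat = InputPattern(frozenset({1, 4, 8}), default_frequency_assignment(8))
    got = dendritic_drive(conn, pat, cfg)[0]

    T = cfg.n_steps
    expected = np.zeros(T)
    for b in range(conn.n_branches):
        # gather (arrival bin, weight, slot) for active synapses on branch b
        events = []
        for s in range(conn.synapses_per_branch):
            i = conn.presyn[0, b, s]
            if i not in pat.active_set:
                continue
            tr = make_spike_train(pat.freq_map[i], cfg.input_onset, cfg.t_max,
                                  neuron_id=i)
            for t_spike in tr.times:
                events.append((t_spike + cfg.delay_IR, s))
        delay = cfg.branch_delay_step * (b + 1)
        for arrival, slot in events:
            rank = 1 + sum(1 for a, s2 in events
                           if a == arrival and s2 < slot)
            factor = max(0.0, 1.0 - (rank - 1) / cfg.sublinear_k)
            w = conn.weights[0, b, slot]
            soma_onset = arrival + delay
            for t in range(int(soma_onset), T):
                expected[t] += cfg.u_pass * factor * epsp_kernel(
                    t - soma_onset, w, cfg.k_dend, cfg.g_R, cfg.tau)
    # engine truncates kernel tails below 1e-6 of peak; allow that much slack
    assert np.allclose(got, expected, atol=0.01)


# -- trial execution --------------------------------------------------------

def test_repeated_trial_is_bit_identical(single_r_cfg, dense_conn):
    pat = InputPattern(frozenset({2, 3, 5, 6}), default_frequency_assignment(8))
    out1, tr1 = run_trial(pat, dense_conn, single_r_cfg, record_trace=True)
    out2, tr2 = run_trial(pat, dense_conn, single_r_cfg, record_trace=True)
    assert out1.key() == out2.key()
    assert np.array_equal(tr1.total, tr2.total)


def test_trace_bookkeeping_identity(single_r_cfg, dense_conn):
    pat = InputPattern(frozenset({1, 2, 3, 4, 5}), default_frequency_assignment(8))
    _, trace = run_trial(pat, dense_conn, single_r_cfg, record_trace=True)
    assert np.allclose(trace.total,
                       trace.dendritic + trace.smo - trace.inhibition)
    df = trace.to_frame()
    assert set(df.columns) >= {"neuron", "t_ms", "dendritic_mV", "total_mV"}


def test_smo_alone_stays_subthreshold(single_r_cfg):
    smo = smo_trace(single_r_cfg)
    assert smo.max() < single_r_cfg.theta_R


def test_winners_share_first_crossing_bin():
    cfg = ModelConfig(expansion_factor=2.0)
    conn = build_connectivity(cfg, "dense", np.random.default_rng(4))
    pat = InputPattern(frozenset({1, 2, 5, 6, 7}), default_frequency_assignment(8))
    out, _ = run_trial(pat, conn, cfg)
    assert not out.silent
    assert len(set(out.times)) == 1
    assert len(out.winners) < cfg.n_R        # WTA sparseness


def test_stronger_input_never_fires_later(cfg):
    """With full wiring and a common frequency, latency is non-increasing in
    the number of active inputs."""
    run_cfg = cfg.replace(expansion_factor=1 / 8)
    conn = build_connectivity(run_cfg, "full", np.random.default_rng(0))
    freq = {i: 90.0 for i in range(1, 9)}
    times = []
    for n in range(1, 9):
        out, _ = run_trial(InputPattern(frozenset(range(1, n + 1)), freq),
                           conn, run_cfg)
        assert not out.silent
        times.append(min(out.times))
    assert all(a >= b for a, b in zip(times, times[1:]))


def test_wta_inhibition_recorded_after_spike(single_r_cfg, dense_conn):
    pat = InputPattern(frozenset({4, 5, 6, 7, 8}), default_frequency_assignment(8))
    out, trace = run_trial(pat, dense_conn, single_r_cfg, record_trace=True)
    t_win = int(min(out.times) + single_r_cfg.input_onset)
    assert np.all(trace.inhibition[:t_win + 1] == 0.0)
    assert np.all(trace.inhibition[t_win + 1:] == single_r_cfg.wta_drop)


# -- heterosynaptic LTD -----------------------------------------------------

def test_hsltd_depresses_only_inactive_synapses(single_r_cfg, dense_conn):
    pat = InputPattern(frozenset({1, 2, 3}), default_frequency_assignment(8))
    new = apply_hsltd(dense_conn, winner=1, pattern=pat, hs=0.3)
    active_mask = np.isin(new.presyn[0], [1, 2, 3])
    assert np.all(new.weights[0][active_mask] == single_r_cfg.w_IR)
    assert np.all(new.weights[0][~active_mask]
                  == pytest.approx(0.3 * single_r_cfg.w_IR))
    # original untouched (copy semantics)
    assert np.all(dense_conn.weights == single_r_cfg.w_IR)


def test_hsltd_stacks_multiplicatively(single_r_cfg, dense_conn):
    pat = InputPattern(frozenset({1, 2, 3}), default_frequency_assignment(8))
    once = apply_hsltd(dense_conn, 1, pat, 0.3)
    twice = apply_hsltd(once, 1, pat, 0.3)
    inactive = ~np.isin(twice.presyn[0], [1, 2, 3])
    assert np.all(twice.weights[0][inactive] == pytest.approx(2.0 * 0.3 * 0.3))


# -- calibration -------------------------------------------------------------

def test_calibrated_threshold_matches_shipped_default(cfg):
    theta = calibrate_threshold(cfg)
    assert theta == cfg.theta_R
    assert theta > cfg.smo_amplitude_h
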