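"""Discrete-time (1 ms) dynamics of the representation neurons.

Each input spike instantiates an alpha-function EPSP on the dendritic branch
its synapse sits on.  EPSPs arriving on the same branch sum sublinearly (the
x-th concurrently active EPSP is scaled by 1 - (x-1)/k); branch totals travel
to the soma with a per-branch delay (2 ms per branch index) and a passive
attenuation u_pass.  The somatic potential is the attenuated dendritic drive
plus a theta-band subthreshold membrane potential oscillation (SMO).  The
first time bin in which any R-neuron reaches threshold defines the trial's
output: every neuron at or above threshold in that bin spikes (joint
winners), and a global 20 mV inhibition then silences the population for the
rest of the trial (winner-takes-all).  Optionally, heterosynaptic LTD then
weakens the winner's synapses from I-neurons that were silent in the trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import Connectivity, ModelConfig, build_connectivity
from .patterns import InputPattern, pattern_trains


# --------------------------------------------------------------------------
# kernels and modulation
# --------------------------------------------------------------------------

def epsp_kernel(delta_t, w: float, k: float, g: float, tau: float = 1.0):
    """Alpha-function EPSP: k * w * dt * g**(-dt/tau), in mV.

    Zero at dt = 0, single interior maximum at dt = tau/ln(g).  ``delta_t``
    may be a scalar or array of times (ms) since EPSP onset.
    """
    if g <= 1:
        raise ValueError("decay base g must exceed 1")
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("delta_t must be non-negative")
    out = k * w * delta_t * g ** (-delta_t / tau)
    return float(out) if out.ndim == 0 else out


def kernel_peak_time(g: float, tau: float = 1.0) -> float:
    """Time of the kernel maximum, tau / ln(g) (ms)."""
    if g <= 1:
        raise ValueError("decay base g must exceed 1")
    return tau / math.log(g)


def sublinear_factor(x: int, k: int = 12) -> float:
    """Scale of the x-th concurrently summed EPSP on a branch: 1 - (x-1)/k.

    The first EPSP is unscaled; the factor reaches 0 at x = k+1 and is an
    error beyond that (a negative EPSP is meaningless).
    """
    if x < 1:
        raise ValueError("EPSP rank x starts at 1")
    if x > k + 1:
        raise ValueError(f"rank {x} exceeds k+1 = {k + 1} (negative factor)")
    return 1.0 - (x - 1) / k


def smo_value(t, h: float, fq: float, ref_time: float):
    """Subthreshold membrane potential oscillation, h*sin(2*pi*fq*(t-ref)/1000) mV.

    ``ref_time`` anchors the ascending zero-crossing; the trough precedes it
    by a quarter period (250/fq ms) and the peak follows it by the same.
    """
    if h < 0:
        raise ValueError("amplitude must be non-negative")
    if fq <= 0:
        raise ValueError("frequency must be positive")
    t = np.asarray(t, dtype=float)
    out = h * np.sin(2.0 * np.pi * fq * (t - ref_time) / 1000.0)
    return float(out) if out.ndim == 0 else out


def smo_peak_time(cfg: ModelConfig) -> float:
    """First SMO maximum at or after the input onset."""
    period = 1000.0 / cfg.smo_freq
    peak = cfg.smo_ref_time + period / 4.0
    while peak < cfg.input_onset:
        peak += period
    return peak


def _kernel_shape(k: float, g: float, tau: float, dt: float) -> np.ndarray:
    """Sampled kernel k*dt*g**(-dt/tau) on the grid.

    Truncated once the tail falls below 1e-6 of the peak, so the summed
    truncation error stays negligible even with hundreds of overlapping
    EPSPs per trial.
    """
    peak = k * kernel_peak_time(g, tau) * g ** (-kernel_peak_time(g, tau) / tau)
    d, vals = 0, []
    while True:
        v = k * d * dt * g ** (-(d * dt) / tau)
        if d > 0 and v < 1e-6 * peak:
            break
        vals.append(v)
        d += 1
    return np.asarray(vals)


def active_window(g: float, tau: float = 1.0, dt: float = 1.0) -> float:
    """How long an EPSP counts as active for sublinear rank ordering (ms).

    An EPSP is active while its kernel is at least 1% of its own peak.
    """
    peak_t = kernel_peak_time(g, tau)
    peak = peak_t * g ** (-peak_t / tau)
    d = peak_t
    while d * g ** (-d / tau) >= 0.01 * peak:
        d += dt
    return d - dt


# --------------------------------------------------------------------------
# trial containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OutputPattern:
    """Winners of one trial and their shared first-spike time.

    ``first_spikes`` maps the 1-based R-neuron index to its first-spike time
    in ms relative to the input onset; all winners share the earliest
    crossing bin, so the values are identical.  Empty means a silent trial.
    """

    first_spikes: dict[int, float]
    onset: float
    label: str | None = None
    package: int | None = None

    @property
    def silent(self) -> bool:
        return not self.first_spikes

    @property
    def winners(self) -> frozenset[int]:
        return frozenset(self.first_spikes)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(sorted(self.first_spikes.values()))

    def key(self) -> tuple:
        return tuple(sorted(self.first_spikes.items()))


@dataclass
class MembraneTrace:
    """Per-bin bookkeeping: total = dendritic + smo - inhibition, exactly."""

    t: np.ndarray             #: (T,) ms
    dendritic: np.ndarray     #: (n_R, T) attenuated somatic drive, mV
    smo: np.ndarray           #: (T,) mV
    inhibition: np.ndarray    #: (T,) accumulated WTA inhibition, mV

    @property
    def total(self) -> np.ndarray:
        return self.dendritic + self.smo[None, :] - self.inhibition[None, :]

    def to_frame(self) -> pd.DataFrame:
        n_r, T = self.dendritic.shape
        total = self.total
        rows = {
            "neuron": np.repeat(np.arange(1, n_r + 1), T),
            "t_ms": np.tile(self.t, n_r),
            "dendritic_mV": self.dendritic.ravel(),
            "smo_mV": np.tile(self.smo, n_r),
            "total_mV": total.ravel(),
        }
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# drive assembly
# --------------------------------------------------------------------------

def _branch_events(conn: Connectivity, pattern: InputPattern, cfg: ModelConfig):
    """Flatten all EPSP events into (r_idx, soma_onset_bin, amplitude) arrays.

    The sublinear rank is an EPSP's position among the EPSPs arriving on the
    same branch in the same time bin (spatial summation within a branch is
    sublinear; temporal summation is carried by the kernel decay), so with
    full 8-input wiring the rank spans 1..8.  Amplitude folds in the synaptic
    weight and the rank factor (floored at 0 beyond rank k+1), but not the
    kernel gain or the passive attenuation.
    """
    dt = cfg.dt
    arrivals = {}  # i-neuron -> dendritic EPSP onset bins
    for tr in pattern_trains(pattern, cfg.input_onset, cfg.t_max, dt):
        arrivals[tr.neuron_id] = (
            np.round((np.asarray(tr.times) + cfg.delay_IR) / dt).astype(int)
        )
    delays = np.round(cfg.branch_delays() / dt).astype(int)

    ev_r, ev_t, ev_a = [], [], []
    n_r, n_b, n_s = conn.presyn.shape
    for r in range(n_r):
        for b in range(n_b):
            onsets, weights, slots = [], [], []
            for s in range(n_s):
                i = conn.presyn[r, b, s]
                if i not in arrivals:
                    continue
                t_arr = arrivals[i]
                onsets.append(t_arr)
                weights.append(np.full(t_arr.size, conn.weights[r, b, s]))
                slots.append(np.full(t_arr.size, s))
            if not onsets:
                continue
            o = np.concatenate(onsets)
            w = np.concatenate(weights)
            sl = np.concatenate(slots)
            order = np.lexsort((sl, o))
            o, w = o[order], w[order]
            # rank = 1 + number of same-bin EPSPs already placed on the branch
            rank = np.arange(o.size) - np.searchsorted(o, o, side="left") + 1
            factor = np.maximum(0.0, 1.0 - (rank - 1) / cfg.sublinear_k)
            ev_r.append(np.full(o.size, r))
            ev_t.append(o + delays[b])
            ev_a.append(w * factor)
    if not ev_r:
        return (np.empty(0, int), np.empty(0, int), np.empty(0))
    return np.concatenate(ev_r), np.concatenate(ev_t), np.concatenate(ev_a)


def dendritic_drive(conn: Connectivity, pattern: InputPattern,
                    cfg: ModelConfig) -> np.ndarray:
    """Attenuated somatic drive (n_R, T): branch EPSP sums, delayed, x u_pass."""
    T = cfg.n_steps
    shape = _kernel_shape(cfg.k_dend, cfg.g_R, cfg.tau, cfg.dt)
    D = shape.size
    ev_r, ev_t, ev_a = _branch_events(conn, pattern, cfg)
    width = max(T, int(ev_t.max()) + 1 if ev_t.size else T) + D
    drive = np.zeros((conn.n_R, width))
    if ev_r.size:
        cols = ev_t[:, None] + np.arange(D)[None, :]
        vals = cfg.u_pass * ev_a[:, None] * shape[None, :]
        np.add.at(drive, (np.repeat(ev_r, D), cols.ravel()), vals.ravel())
    return drive[:, :T]


def somatic_drive(branch_traces: np.ndarray, delays_ms: np.ndarray,
                  u_pass: float, dt: float = 1.0) -> np.ndarray:
    """Linear soma summation: sum over branches of u_pass * trace(t - delay).

    ``branch_traces`` is (n_branches, T); the result is the somatic drive
    trace of one neuron.  Used mostly as an oracle-friendly reference path;
    the trial runner assembles the same quantity event-wise.
    """
    n_b, T = branch_traces.shape
    out = np.zeros(T)
    for b in range(n_b):
        d = int(round(delays_ms[b] / dt))
        if d < T:
            out[d:] += u_pass * branch_traces[b, : T - d]
    return out


# --------------------------------------------------------------------------
# trial execution
# --------------------------------------------------------------------------

def smo_trace(cfg: ModelConfig) -> np.ndarray:
    t = np.arange(cfg.n_steps) * cfg.dt
    return smo_value(t, cfg.smo_amplitude_h, cfg.smo_freq, cfg.smo_ref_time)


def run_trial(pattern: InputPattern, conn: Connectivity, cfg: ModelConfig,
              record_trace: bool = False,
              package: int | None = None):
    """Simulate one stimulus presentation; returns (OutputPattern, trace).

    The trial's representational content is the set of joint winners at the
    first threshold crossing and their shared latency (relative to the input
    onset).  When ``record_trace`` is set the full membrane bookkeeping is
    returned (with the post-spike WTA inhibition applied to later bins);
    otherwise the trace is None.
    """
    drive = dendritic_drive(conn, pattern, cfg)
    smo = smo_trace(cfg)
    total = drive + smo[None, :]
    crossing = total >= cfg.theta_R
    cols = np.flatnonzero(crossing.any(axis=0))
    if cols.size == 0:
        out = OutputPattern({}, onset=cfg.input_onset, label=pattern.label,
                            package=package)
        t_win = None
    else:
        t_win = int(cols[0])
        winners = np.flatnonzero(crossing[:, t_win])
        t_rel = t_win * cfg.dt - cfg.input_onset
        out = OutputPattern({int(r) + 1: t_rel for r in winners},
                            onset=cfg.input_onset, label=pattern.label,
                            package=package)
    trace = None
    if record_trace:
        inhibition = np.zeros(cfg.n_steps)
        if t_win is not None:
            inhibition[t_win + 1:] = cfg.wta_drop
        trace = MembraneTrace(t=np.arange(cfg.n_steps) * cfg.dt,
                              dendritic=drive, smo=smo, inhibition=inhibition)
    return out, trace


def apply_hsltd(conn: Connectivity, winner: int, pattern: InputPattern,
                hs: float, inplace: bool = False) -> Connectivity:
    """Heterosynaptic LTD: scale the winner's synapses from inactive inputs by hs.

    ``winner`` is 1-based.  Synapses whose presynaptic I-neuron fired in the
    trial are untouched; repeated wins stack multiplicatively.
    """
    if not (0 < hs <= 1):
        raise ValueError("hs must lie in (0, 1]")
    if not inplace:
        conn = conn.copy()
    r = winner - 1
    inactive = ~np.isin(conn.presyn[r], sorted(pattern.active_set))
    conn.weights[r][inactive] *= hs
    return conn


# --------------------------------------------------------------------------
# threshold calibration
# --------------------------------------------------------------------------

def calibrate_threshold(cfg: ModelConfig, n_wirings: int = 20,
                        step: float = 0.5, theta_max: float = 40.0,
                        min_fire_fraction: float = 0.9,
                        seed: int = 12345) -> float:
    """Pick the smallest threshold compatible with the protocol.

    The threshold must (a) exceed the SMO amplitude, so the oscillation alone
    never fires a neuron, and (b) let the weakest protocol stimulus (the 3
    slowest I-neurons, dense wiring) fire before the SMO peak in at least
    ``min_fire_fraction`` of ``n_wirings`` seeded wirings.  The search walks
    a ``step``-mV grid upward from amplitude + step.
    """
    weakest = InputPattern(frozenset({1, 2, 3}),
                           {i: 90.0 + 10.0 * (i - 1) for i in range(1, cfg.n_input + 1)})
    single = cfg.replace(expansion_factor=1.0 / cfg.n_input)
    peak = smo_peak_time(cfg)
    conns = [
        build_connectivity(single, "dense", np.random.default_rng(seed + i))
        for i in range(n_wirings)
    ]
    theta = cfg.smo_amplitude_h + step
    while theta <= theta_max:
        trial_cfg = single.replace(theta_R=theta)
        fired = 0
        for conn in conns:
            out, _ = run_trial(weakest, conn, trial_cfg)
            if not out.silent and min(out.times) + cfg.input_onset <= peak:
                fired += 1
        if fired / n_wirings >= min_fire_fraction:
            return theta
        theta += step
    raise RuntimeError("no threshold on the grid lets the weakest pattern fire")
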