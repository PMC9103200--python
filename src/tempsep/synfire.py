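"""Time-to-space conversion by a synfire chain.

A trigger neuron (T) launches a spike wave along a chain of timing neurons
(ET), one chain step per millisecond.  Each ET-neuron also contacts one
place-code neuron (E), which additionally receives the R-neuron's output
spike.  Either input alone stays subthreshold at E; only their coincidence
fires it, so the R-neuron's first-spike latency selects exactly one E-neuron
-- a latency code re-expressed as a place code.

Two conversion modes are provided.  The default ``exact`` mode implements
the coincidence on the simulation grid directly (fire iff the R spike and
the ET spike share a time bin), which is the idealised conversion the
metrics use.  The ``physical`` mode sums the two alpha-function EPSPs at the
E soma against a calibrated threshold and reproduces the same mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import OutputPattern, epsp_kernel


@dataclass
class SynfireConfig:
    n_chain: int = 100          #: number of ET/E pairs
    t_start: float = 10.0       #: T-neuron launch time (ms)
    step_delay: float = 1.0     #: ET->ET propagation delay (ms)
    w_etet: float = 5.8         #: ET->ET weight (suprathreshold alone)
    w_re: float = 2.0           #: R->E and ET->E weight (subthreshold alone)
    k_soma: float = 5.6         #: kernel gain at E/ET somata
    g_E: float = 2.7            #: kernel decay base at E/ET
    tau: float = 1.0
    dt: float = 1.0
    theta_E: float | None = None   #: E/ET threshold; calibrated when None

    def __post_init__(self):
        if self.n_chain < 1:
            raise ValueError("n_chain must be positive")
        if self.step_delay <= 0 or self.dt <= 0:
            raise ValueError("step_delay and dt must be positive")
        if self.theta_E is None:
            self.theta_E = calibrate_theta_e(self)


@dataclass(frozen=True)
class EPattern:
    """Fired place-code neurons: E index -> spike time (ms, absolute)."""

    spikes: dict[int, float]
    unrepresentable: tuple[float, ...] = ()   #: R spike times beyond the chain

    @property
    def indices(self) -> frozenset[int]:
        return frozenset(self.spikes)

    def to_frame(self, trial_id: int = 0) -> pd.DataFrame:
        return pd.DataFrame({
            "trial_id": trial_id,
            "e_neuron": sorted(self.spikes),
            "time_ms": [self.spikes[i] for i in sorted(self.spikes)],
        })


def _grid_kernel_max(cfg: SynfireConfig, w: float, offset_bins: int = 0) -> float:
    """Max over grid times of one kernel (offset 0) or of two kernels offset apart."""
    d = np.arange(0, 30) * cfg.dt
    k1 = epsp_kernel(d, w, cfg.k_soma, cfg.g_E, cfg.tau)
    if offset_bins == 0:
        return float(k1.max())
    k2 = np.zeros_like(k1)
    k2[offset_bins:] = k1[: k1.size - offset_bins]
    return float((k1 + k2).max())


def calibrate_theta_e(cfg: SynfireConfig) -> float:
    """Threshold midway between the best non-coincident and the coincident drive.

    Coincident R and ET EPSPs must fire E; an R spike one or more bins away
    from the ET spike must not; and a single ET->ET EPSP must stay
    suprathreshold so the chain keeps propagating.
    """
    coincident = 2.0 * _grid_kernel_max(cfg, cfg.w_re)
    near_miss = max(_grid_kernel_max(cfg, cfg.w_re, offset_bins=k)
                    for k in (1, 2, 3))
    theta = 0.5 * (near_miss + coincident)
    chain_peak = _grid_kernel_max(cfg, cfg.w_etet)
    if not (near_miss < theta < coincident <= chain_peak + coincident):
        raise RuntimeError("inconsistent synfire calibration")
    if chain_peak <= theta:
        raise RuntimeError("ET->ET weight is subthreshold; the wave would die")
    return theta


def run_chain(cfg: SynfireConfig, t_max: float | None = None) -> np.ndarray:
    """ET spike times: ET_i fires at t_start + i * step_delay, i = 1..n_chain."""
    times = cfg.t_start + cfg.step_delay * np.arange(1, cfg.n_chain + 1)
    if t_max is not None and times[-1] < t_max - cfg.step_delay:
        # the chain ends before the trial does: later R spikes have no slot
        pass
    return times


def convert(r_output: OutputPattern, cfg: SynfireConfig,
            mode: str = "exact") -> EPattern:
    """Map each distinct R first-spike time onto its coincident E-neuron.

    Times are matched in absolute trial time (the output pattern stores
    latencies relative to its onset).  R spikes that fall outside the chain's
    coverage are reported in ``unrepresentable`` rather than mapped.
    """
    if mode not in ("exact", "physical"):
        raise ValueError(f"unknown conversion mode {mode!r}")
    if r_output.silent:
        return EPattern({})
    spikes: dict[int, float] = {}
    unrep: list[float] = []
    et_times = run_chain(cfg)
    for t_rel in sorted(set(r_output.first_spikes.values())):
        t_abs = t_rel + r_output.onset
        if mode == "exact":
            idx_f = (t_abs - cfg.t_start) / cfg.step_delay
            idx = int(round(idx_f))
            if abs(idx_f - idx) > 1e-9 or not (1 <= idx <= cfg.n_chain):
                unrep.append(t_abs)
                continue
            spikes[idx] = t_abs
        else:
            fired = _physical_coincidence(t_abs, et_times, cfg)
            if fired is None:
                unrep.append(t_abs)
            else:
                idx, t_spike = fired
                spikes[idx] = t_spike
    return EPattern(spikes, unrepresentable=tuple(unrep))


def _physical_coincidence(t_r: float, et_times: np.ndarray,
                          cfg: SynfireConfig):
    """Sum R and ET EPSPs at each E soma; return the first (index, spike time)."""
    horizon = 20.0  # ms past the R spike; both kernels have decayed by then
    t = np.arange(0.0, horizon, cfg.dt)
    r_epsp = epsp_kernel(t, cfg.w_re, cfg.k_soma, cfg.g_E, cfg.tau)
    for i, t_et in enumerate(et_times, start=1):
        lag = t_r - t_et
        if abs(lag) > horizon:
            continue
        pot = np.zeros_like(t)
        pot += r_epsp
        delta = t + lag  # time since the ET spike, at absolute time t_r + t
        valid = delta >= 0
        pot[valid] += epsp_kernel(delta[valid], cfg.w_re, cfg.k_soma,
                                  cfg.g_E, cfg.tau)
        above = np.flatnonzero(pot >= cfg.theta_E)
        if above.size:
            return i, float(t_r + t[above[0]])
    return None


def roundtrip_time(e_index: int, cfg: SynfireConfig) -> float:
    """Recover the absolute R spike time encoded by an E index."""
    return cfg.t_start + e_index * cfg.step_delay
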