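"""The simulation protocols: package runs, sweeps, and the derived statistics.

The default protocol presents 20 random input patterns to each of 20
"packages".  Within a package the random I->R wiring is fixed; each new
package draws fresh wiring (and fresh patterns).  With 20 patterns a package
contributes C(20,2) = 190 pattern pairs, so the default protocol aggregates
3,800 comparisons.  Separation power is averaged over packages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import OutputPattern, apply_hsltd, run_trial
from .metrics import SPResult, distinct_time_count, ensemble_sp, input_reliability
from .network import Connectivity, ModelConfig, build_connectivity
from .patterns import (InputPattern, default_frequency_assignment,
                       object_catalogue, sample_pattern)
from .synfire import EPattern, SynfireConfig, convert

DEFAULT_EF_LIST = (0.125, 1.0, 2.0, 16.0)


@dataclass
class ProtocolSpec:
    """One experiment's run conditions."""

    n_packages: int = 20
    patterns_per_package: int = 20
    regime: str = "dense"
    expansion_factor: float = 0.125
    hsltd: bool = False
    seed: int = 0
    name: str = "protocol"

    @property
    def n_comparisons(self) -> int:
        m = self.patterns_per_package
        return self.n_packages * (m * (m - 1)) // 2


def package_seed(master_seed: int, package_index: int) -> int:
    """Fixed seed-splitting rule: one child seed per package."""
    return int((master_seed + package_index) % (2 ** 31 - 1))


def run_package(cfg: ModelConfig, regime: str, pkg_seed: int,
                hsltd: bool = False, n_patterns: int = 20,
                patterns: Sequence[InputPattern] | None = None,
                freq_map: Mapping[int, float] | None = None,
                package_id: int | None = None):
    """One connectivity package: fixed wiring, sequential pattern presentation.

    When heterosynaptic LTD is on, each winning trial weakens the winners'
    synapses from inactive inputs; the depression accumulates across the
    package and is discarded with the wiring.  Returns (patterns, outputs,
    final connectivity).
    """
    rng = np.random.default_rng(pkg_seed)
    conn = build_connectivity(cfg, regime, rng)
    if patterns is None:
        patterns = [sample_pattern(rng, cfg.n_input, freq_map=freq_map)
                    for _ in range(n_patterns)]
    work = conn.copy() if hsltd else conn
    outputs = []
    for pat in patterns:
        out, _ = run_trial(pat, work, cfg, package=package_id)
        outputs.append(out)
        if hsltd and not out.silent:
            for winner in out.winners:
                apply_hsltd(work, winner, pat, cfg.hs, inplace=True)
    return list(patterns), outputs, work


def run_protocol(cfg: ModelConfig, spec: ProtocolSpec,
                 freq_map: Mapping[int, float] | None = None):
    """All packages of one protocol; per-package spatial and temporal SP.

    Returns (long-format table, summary dict).  Packages in which fewer than
    two usable pairs remain are skipped and counted.
    """
    run_cfg = cfg.replace(expansion_factor=spec.expansion_factor,
                          hsltd_enabled=spec.hsltd)
    rows = []
    results: dict[str, list[SPResult]] = {"spatial": [], "temporal": []}
    skipped = 0
    for p in range(spec.n_packages):
        patterns, outputs, _ = run_package(
            run_cfg, spec.regime, package_seed(spec.seed, p),
            hsltd=spec.hsltd, n_patterns=spec.patterns_per_package,
            freq_map=freq_map, package_id=p)
        try:
            for kind in ("spatial", "temporal"):
                res = ensemble_sp(patterns, outputs, kind=kind)
                results[kind].append(res)
                for metric, value in (("mean_oi", res.mean_oi),
                                      ("mean_or", res.mean_or),
                                      ("sp_percent", res.sp_percent)):
                    rows.append((spec.name, spec.expansion_factor, spec.regime,
                                 spec.hsltd, p, f"{kind}_{metric}", value))
        except ValueError:
            skipped += 1
    if not results["temporal"]:
        raise RuntimeError("every package was silent; threshold miscalibrated")
    table = pd.DataFrame(rows, columns=["experiment", "ef", "regime", "hsltd",
                                        "package", "metric", "value"])
    summary = {"n_packages": spec.n_packages - skipped, "skipped": skipped}
    for kind, lst in results.items():
        summary[f"{kind}_sp"] = float(np.mean([r.sp_percent for r in lst]))
        summary[f"{kind}_mean_oi"] = float(np.mean([r.mean_oi for r in lst]))
        summary[f"{kind}_mean_or"] = float(np.mean([r.mean_or for r in lst]))
    summary["n_silent_pairs"] = int(sum(r.n_excluded_silent
                                        for r in results["temporal"]))
    return table, summary


def ef_sweep(cfg: ModelConfig, ef_list: Sequence[float] = DEFAULT_EF_LIST,
             regimes: Sequence[str] = ("dense",), n_packages: int = 20,
             hsltd: bool = False, seed: int = 0):
    """Separation power across expansion factors and wiring regimes."""
    tables, rows = [], []
    for regime in regimes:
        for ef in ef_list:
            spec = ProtocolSpec(n_packages=n_packages, regime=regime,
                                expansion_factor=ef, hsltd=hsltd, seed=seed,
                                name="ef_sweep")
            table, summary = run_protocol(cfg, spec)
            tables.append(table)
            rows.append({"ef": ef, "regime": regime, "hsltd": hsltd,
                         "spatial_sp": summary["spatial_sp"],
                         "temporal_sp": summary["temporal_sp"],
                         "mean_oi": summary["temporal_mean_oi"]})
    return pd.concat(tables, ignore_index=True), pd.DataFrame(rows)


def _single_r_full(cfg: ModelConfig) -> ModelConfig:
    return cfg.replace(expansion_factor=1.0 / cfg.n_input)


#: branch count of the complete-connectivity SP comparison: a single R-neuron
#: whose 3 dendritic branches each receive all 8 inputs
FULL_CONN_BRANCHES = 3


def full_connectivity_protocol(cfg: ModelConfig, n_packages: int = 20,
                               seed: int = 0):
    """Default protocol under complete I->R wiring (single R-neuron, 3 branches).

    Complete connectivity removes the random-wiring diversity, so only the
    temporal code separates; the wiring is identical in every package and only
    the pattern draw varies.
    """
    run_cfg = cfg.replace(n_branches=FULL_CONN_BRANCHES)
    spec = ProtocolSpec(n_packages=n_packages, regime="full",
                        expansion_factor=1.0 / cfg.n_input, seed=seed,
                        name="full_connectivity")
    return run_protocol(run_cfg, spec)


def _experiment_chain(cfg: ModelConfig) -> SynfireConfig:
    """A chain long enough to represent every latency the trial can produce."""
    n = int(round((cfg.t_max - cfg.input_onset) / cfg.dt))
    return SynfireConfig(n_chain=n, t_start=cfg.input_onset, dt=cfg.dt)


def counting_experiment(cfg: ModelConfig) -> pd.DataFrame:
    """First-spike latency vs. number of active inputs (full wiring, 90 Hz).

    A single fully connected R-neuron receives n = 1..8 I-neurons all firing
    at 90 Hz; the latency decreases with the count, so the count can be read
    off the coincident E-neuron index after synfire conversion.
    """
    run_cfg = _single_r_full(cfg)
    conn = build_connectivity(run_cfg, "full", np.random.default_rng(0))
    chain = _experiment_chain(run_cfg)
    freq_map = {i: 90.0 for i in range(1, cfg.n_input + 1)}
    rows = []
    for n in range(1, cfg.n_input + 1):
        pat = InputPattern(frozenset(range(1, n + 1)), freq_map,
                           label=f"n{n}")
        out, _ = run_trial(pat, conn, run_cfg)
        if out.silent:
            raise RuntimeError(f"silent trial for n_active={n}; "
                               "threshold miscalibrated")
        t = min(out.times)
        ep = convert(out, chain)
        rows.append({"n_active": n, "first_spike_ms": t,
                     "e_neuron": min(ep.indices) if ep.indices else None})
    return pd.DataFrame(rows)


def frequency_experiment(cfg: ModelConfig,
                         freqs: Sequence[float] = tuple(range(50, 151, 10)),
                         n_active: int = 3) -> pd.DataFrame:
    """First-spike latency vs. common input frequency (full wiring, 3 inputs)."""
    run_cfg = _single_r_full(cfg)
    conn = build_connectivity(run_cfg, "full", np.random.default_rng(0))
    chain = _experiment_chain(run_cfg)
    rows = []
    for fq in freqs:
        freq_map = {i: float(fq) for i in range(1, cfg.n_input + 1)}
        pat = InputPattern(frozenset(range(1, n_active + 1)), freq_map,
                           label=f"f{fq}")
        out, _ = run_trial(pat, conn, run_cfg)
        if out.silent:
            raise RuntimeError(f"silent trial at {fq} Hz; "
                               "threshold miscalibrated")
        ep = convert(out, chain)
        rows.append({"freq_hz": fq, "first_spike_ms": min(out.times),
                     "e_neuron": min(ep.indices) if ep.indices else None})
    return pd.DataFrame(rows)


def object_experiment(cfg: ModelConfig, n_packages: int = 20,
                      seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """The 18-object catalogue on a single R-neuron with doubled input weights.

    Each package presents all 18 objects plus 2 repeats (20 presentations)
    on fresh dense wiring; reliability, the number of distinct latencies, and
    temporal SP are averaged over packages.
    """
    run_cfg = cfg.replace(expansion_factor=1.0 / cfg.n_input,
                          w_IR=2.0 * cfg.w_IR)
    catalogue = object_catalogue()
    rows = []
    for p in range(n_packages):
        pkg_seed = package_seed(seed, p)
        rng = np.random.default_rng(pkg_seed)
        repeats = [catalogue[i] for i in rng.choice(len(catalogue), size=2,
                                                    replace=False)]
        patterns = catalogue + repeats
        _, outputs, _ = run_package(run_cfg, "dense", pkg_seed,
                                    patterns=patterns, package_id=p)
        reliability = input_reliability(list(zip(patterns, outputs)))
        distinct = distinct_time_count(outputs[:len(catalogue)])
        res = ensemble_sp(patterns, outputs, kind="temporal")
        rows.append({"package": p, "reliability": reliability,
                     "distinct_times": distinct,
                     "temporal_sp": res.sp_percent, "mean_oi": res.mean_oi,
                     "n_silent": sum(o.silent for o in outputs)})
    table = pd.DataFrame(rows)
    summary = {
        "mean_reliability": float(table["reliability"].mean()),
        "mean_distinct_times": float(table["distinct_times"].mean()),
        "mean_temporal_sp": float(table["temporal_sp"].mean()),
        "mean_input_overlap": float(table["mean_oi"].mean()),
    }
    return table, summary


def robustness_experiment(cfg: ModelConfig, n_packages: int = 20,
                          seed: int = 0) -> dict:
    """Temporal SP under slower theta (3 Hz) and a lower gamma band (60-130 Hz)."""
    spec = ProtocolSpec(n_packages=n_packages, expansion_factor=1.0 / cfg.n_input,
                        seed=seed, name="robustness_default")
    _, default_summary = run_protocol(cfg, spec)
    variant_cfg = cfg.replace(smo_freq=3.0)
    variant_freqs = {i: 60.0 + 10.0 * (i - 1) for i in range(1, cfg.n_input + 1)}
    variant_spec = dataclasses.replace(spec, name="robustness_variant")
    _, variant_summary = run_protocol(variant_cfg, variant_spec,
                                      freq_map=variant_freqs)
    default_sp = default_summary["temporal_sp"]
    variant_sp = variant_summary["temporal_sp"]
    return {
        "default_temporal_sp": default_sp,
        "variant_temporal_sp": variant_sp,
        "sp_reduction_percent": 100.0 * (default_sp - variant_sp) / default_sp,
    }


def hsltd_comparison(cfg: ModelConfig,
                     ef_list: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
                     n_packages: int = 20, seed: int = 0) -> pd.DataFrame:
    """Spatial and temporal SP with heterosynaptic LTD on vs. off, per EF."""
    rows = []
    for ef in ef_list:
        for hsltd in (False, True):
            spec = ProtocolSpec(n_packages=n_packages, expansion_factor=ef,
                                hsltd=hsltd, seed=seed, name="hsltd")
            _, summary = run_protocol(cfg, spec)
            rows.append({"ef": ef, "hsltd": hsltd,
                         "spatial_sp": summary["spatial_sp"],
                         "temporal_sp": summary["temporal_sp"]})
    return pd.DataFrame(rows)
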