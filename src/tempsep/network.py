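"""Model configuration and input-to-representation wiring.

The network has three feedforward stages: input neurons (I), representation
neurons (R) whose first-spike latency carries the separated code, and an
optional synfire-chain stage (T/ET/E) that converts latency back into a
place code.  This module holds every numeric parameter of the R-stage and
builds the random I->R connectivity under three regimes:

dense
    3 synapses per dendritic branch, drawn without replacement within each
    branch; with 6 branches this gives 18 synapses per R-neuron (on average
    2.25 contacts per I-neuron for 8 inputs).
sparse
    1 synapse per branch (6 per R-neuron, 0.75 contacts per I-neuron).
full
    every branch contacts every I-neuron (complete connectivity).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

REGIMES = ("dense", "sparse", "full")

#: synapses formed per dendritic branch, by wiring regime ("full" resolved
#: at build time to n_input)
SYNAPSES_PER_BRANCH = {"dense": 3, "sparse": 1}


@dataclass
class ModelConfig:
    """Every numeric parameter of the R-neuron stage.

    All potentials are in mV relative to a 0 mV resting baseline, all times
    in ms on the ``dt`` grid.  Weights and kernel gains are dimensionless
    multipliers of the alpha-function EPSP kernel.
    """

    n_input: int = 8
    n_branches: int = 6
    expansion_factor: float = 1.0       #: n_R / n_input
    w_IR: float = 2.0                   #: initial I->R weight (alternate 0.4)
    k_dend: float = 0.8                 #: kernel gain at R dendrites
    k_soma: float = 5.6                 #: kernel gain at E/ET somata
    g_R: float = 1.35                   #: kernel decay base, R-neurons (~3.3 ms decay)
    g_E: float = 2.7                    #: kernel decay base, E/ET-neurons (~1 ms decay)
    tau: float = 1.0                    #: kernel time constant (ms)
    sublinear_k: int = 12               #: within-branch sublinear-summation constant
    u_pass: float = 0.5                 #: passive dendro-somatic attenuation
    branch_delay_step: float = 2.0      #: ms per branch index (branch i delayed 2*i ms)
    delay_IR: float = 1.0               #: I->R propagation delay (ms)
    smo_amplitude_h: float = 8.0        #: subthreshold oscillation amplitude (mV)
    smo_freq: float = 5.0               #: theta frequency (Hz)
    smo_ref_time: float = 75.0          #: phase anchor (ms); trough at ref-50, peak at ref+50
    theta_R: float = 8.5                #: spiking threshold above baseline (mV, calibrated)
    wta_drop: float = 20.0              #: global inhibition after a winner spikes (mV)
    hs: float = 0.3                     #: heterosynaptic LTD retention factor
    hsltd_enabled: bool = False
    dt: float = 1.0                     #: time resolution (ms)
    t_max: float = 300.0                #: trial length (ms)
    input_onset: float = 10.0           #: time the input trains are switched on (ms)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------

    @property
    def n_R(self) -> int:
        """Representation-population size, round(EF * n_input)."""
        return int(round(self.expansion_factor * self.n_input))

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max / self.dt)) + 1

    def branch_delays(self) -> np.ndarray:
        """Dendro-somatic delay per branch: 2, 4, ..., 2*n_branches ms."""
        return self.branch_delay_step * np.arange(1, self.n_branches + 1)

    # -- validation / io -----------------------------------------------------

    def validate(self) -> None:
        if self.n_input < 1 or self.n_branches < 1:
            raise ValueError("n_input and n_branches must be positive")
        if self.n_R < 1:
            raise ValueError(
                f"expansion_factor {self.expansion_factor} yields zero R-neurons"
            )
        for name in ("w_IR", "k_dend", "k_soma", "tau", "u_pass",
                     "smo_amplitude_h", "smo_freq", "dt", "wta_drop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.g_R <= 1 or self.g_E <= 1:
            raise ValueError("kernel decay bases must exceed 1 (decaying EPSP)")
        if not (0 < self.hs <= 1):
            raise ValueError("hs must lie in (0, 1]")
        n = self.t_max / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("dt must divide t_max")
        if self.theta_R <= self.smo_amplitude_h:
            raise ValueError(
                "theta_R must exceed the SMO amplitude or the oscillation "
                "alone would fire the neuron"
            )

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class Connectivity:
    """I->R wiring: per R-neuron, per branch, an ordered list of synapses.

    ``presyn[r, b, s]`` is the 1-based index of the I-neuron feeding synapse
    slot ``s`` of branch ``b`` (0-based internally) of R-neuron ``r``;
    ``weights`` has the same shape.  Weights start uniform at ``w_IR`` and
    only heterosynaptic LTD moves them (downward).
    """

    presyn: np.ndarray        #: int array (n_R, n_branches, synapses_per_branch), 1-based
    weights: np.ndarray       #: float array, same shape
    regime: str
    n_input: int

    @property
    def n_R(self) -> int:
        return self.presyn.shape[0]

    @property
    def n_branches(self) -> int:
        return self.presyn.shape[1]

    @property
    def synapses_per_branch(self) -> int:
        return self.presyn.shape[2]

    def copy(self) -> "Connectivity":
        return Connectivity(self.presyn.copy(), self.weights.copy(),
                            self.regime, self.n_input)

    def connections_per_input(self) -> float:
        """Mean number of synapses per I-neuron per R-neuron."""
        return self.presyn[0].size / self.n_input if self.n_R else 0.0

    def validate(self) -> None:
        if self.presyn.shape != self.weights.shape:
            raise ValueError("presyn/weights shape mismatch")
        if self.presyn.min() < 1 or self.presyn.max() > self.n_input:
            raise ValueError("presynaptic index outside [1, n_input]")
        if np.any(self.weights <= 0):
            raise ValueError("non-positive synaptic weight")

    def to_table(self) -> pd.DataFrame:
        """Long-format table: r_neuron, branch, synapse_slot, i_neuron, weight."""
        n_r, n_b, n_s = self.presyn.shape
        r, b, s = np.meshgrid(np.arange(1, n_r + 1), np.arange(1, n_b + 1),
                              np.arange(1, n_s + 1), indexing="ij")
        return pd.DataFrame({
            "r_neuron": r.ravel(), "branch": b.ravel(),
            "synapse_slot": s.ravel(), "i_neuron": self.presyn.ravel(),
            "weight": self.weights.ravel(),
        })

    def to_tsv(self) -> str:
        buf = io.StringIO()
        self.to_table().to_csv(buf, sep="\t", index=False)
        return buf.getvalue()

    @classmethod
    def from_table(cls, df: pd.DataFrame, regime: str, n_input: int) -> "Connectivity":
        df = df.sort_values(["r_neuron", "branch", "synapse_slot"])
        n_r = df["r_neuron"].max()
        n_b = df["branch"].max()
        n_s = df["synapse_slot"].max()
        presyn = df["i_neuron"].to_numpy().reshape(n_r, n_b, n_s)
        weights = df["weight"].to_numpy().reshape(n_r, n_b, n_s)
        return cls(presyn.astype(int), weights.astype(float), regime, n_input)


def build_connectivity(config: ModelConfig, regime: str,
                       rng: np.random.Generator) -> Connectivity:
    """Draw the I->R wiring for one connectivity package.

    Dense and sparse regimes draw each branch's presynaptic partners
    uniformly without replacement within the branch; the full regime wires
    every branch to every I-neuron.  The draw is fully determined by ``rng``.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    n_r, n_b, n_i = config.n_R, config.n_branches, config.n_input
    if regime == "full":
        per_branch = np.arange(1, n_i + 1)
        presyn = np.broadcast_to(per_branch, (n_r, n_b, n_i)).copy()
    else:
        spb = SYNAPSES_PER_BRANCH[regime]
        if spb > n_i:
            raise ValueError(
                f"{regime} regime needs {spb} distinct inputs per branch "
                f"but only {n_i} I-neurons exist"
            )
        presyn = np.empty((n_r, n_b, spb), dtype=int)
        for r in range(n_r):
            for b in range(n_b):
                presyn[r, b] = rng.choice(n_i, size=spb, replace=False) + 1
    weights = np.full(presyn.shape, config.w_IR, dtype=float)
    conn = Connectivity(presyn, weights, regime, n_i)
    conn.validate()
    return conn


def expansion_sweep_sizes(config: ModelConfig,
                          ef_list: Sequence[float]) -> list[int]:
    """Population sizes n_R = round(EF * n_input) for each expansion factor."""
    sizes = []
    for ef in ef_list:
        n = int(round(ef * config.n_input))
        if n < 1:
            raise ValueError(f"expansion factor {ef} yields zero R-neurons")
        sizes.append(n)
    return sizes
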