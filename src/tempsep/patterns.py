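"""Input generation: gamma-regular spike trains, random patterns, objects.

An input pattern activates 3-6 of the 8 I-neurons; each active neuron fires
a perfectly regular train at its own gamma frequency (90-160 Hz by default),
starting one interspike interval after the common onset.  The object
catalogue maps 3 shapes x 3 colors x 2 sizes onto fixed I-neuron triples:
neurons 1-3 encode shape, 4-6 color, 7-8 size.
"""

from __future__ import annotations

import io
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class InputPattern:
    """A set of active I-neurons with their firing frequencies (Hz)."""

    active_set: frozenset[int]
    freq_map: Mapping[int, float]
    label: str | None = None

    def __post_init__(self):
        if not self.active_set:
            raise ValueError("active_set must be non-empty")
        missing = self.active_set - set(self.freq_map)
        if missing:
            raise ValueError(f"no frequency for active neurons {sorted(missing)}")
        if any(f <= 0 for f in self.freq_map.values()):
            raise ValueError("frequencies must be positive")

    def key(self) -> tuple:
        """Identity of the stimulus (active neurons and their frequencies)."""
        return tuple(sorted((i, self.freq_map[i]) for i in self.active_set))


@dataclass(frozen=True)
class SpikeTrain:
    neuron_id: int
    times: tuple[float, ...]    #: ms, strictly increasing, on the dt grid

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("spike times must be strictly increasing")


@dataclass(frozen=True)
class ObjectSpec:
    """A simplified visual object: one shape, one color, one size."""

    shape: int
    color: int
    size: int

    def __post_init__(self):
        if self.shape not in (1, 2, 3) or self.color not in (1, 2, 3):
            raise ValueError("shape and color must be in {1,2,3}")
        if self.size not in (1, 2):
            raise ValueError("size must be in {1,2}")


def rounded_isi(freq: float, dt: float = 1.0) -> float:
    """Interspike interval 1000/freq, rounded to the dt grid (at least dt)."""
    return max(dt, round(1000.0 / freq / dt) * dt)


def make_spike_train(freq: float, onset: float, t_max: float,
                     dt: float = 1.0, neuron_id: int = 0) -> SpikeTrain:
    """Regular gamma train: spikes at onset + ISI, onset + 2*ISI, ... <= t_max.

    The first spike falls one (grid-rounded) ISI after onset, so higher
    frequencies both start earlier and fire more often.
    """
    if freq <= 0:
        raise ValueError("frequency must be positive")
    if onset < 0:
        raise ValueError("onset must be non-negative")
    if 1000.0 / freq < dt:
        raise ValueError(f"ISI of {freq} Hz falls below the {dt} ms grid")
    isi = rounded_isi(freq, dt)
    n = int(np.floor((t_max - onset) / isi))
    times = tuple(onset + isi * k for k in range(1, n + 1))
    return SpikeTrain(neuron_id=neuron_id, times=times)


def default_frequency_assignment(n_input: int = 8) -> dict[int, float]:
    """I-neuron i fires at 90 + 10*(i-1) Hz, spanning the 90-160 Hz gamma band."""
    return {i: 90.0 + 10.0 * (i - 1) for i in range(1, n_input + 1)}


def sample_pattern(rng: np.random.Generator, n_input: int = 8,
                   n_active_range: tuple[int, int] = (3, 6),
                   freq_map: Mapping[int, float] | None = None,
                   label: str | None = None) -> InputPattern:
    """Draw a random pattern: |active| uniform in the range, then a uniform subset."""
    lo, hi = n_active_range
    if not (1 <= lo <= hi <= n_input):
        raise ValueError(f"active-count range {n_active_range} outside [1, {n_input}]")
    if freq_map is None:
        freq_map = default_frequency_assignment(n_input)
    size = int(rng.integers(lo, hi + 1))
    active = frozenset(int(i) + 1 for i in rng.choice(n_input, size=size, replace=False))
    return InputPattern(active_set=active, freq_map=dict(freq_map), label=label)


def encode_object(obj: ObjectSpec,
                  freq_map: Mapping[int, float] | None = None) -> InputPattern:
    """Map an object onto its 3 active I-neurons: shape->1..3, color->4..6, size->7..8."""
    if freq_map is None:
        freq_map = default_frequency_assignment(8)
    active = frozenset({obj.shape, 3 + obj.color, 6 + obj.size})
    label = f"s{obj.shape}c{obj.color}z{obj.size}"
    return InputPattern(active_set=active, freq_map=dict(freq_map), label=label)


def object_catalogue(freq_map: Mapping[int, float] | None = None) -> list[InputPattern]:
    """All 18 objects (3 shapes x 3 colors x 2 sizes), in a stable order."""
    return [
        encode_object(ObjectSpec(shape=s, color=c, size=z), freq_map=freq_map)
        for s, c, z in itertools.product((1, 2, 3), (1, 2, 3), (1, 2))
    ]


def pattern_trains(pattern: InputPattern, onset: float, t_max: float,
                   dt: float = 1.0) -> list[SpikeTrain]:
    """Spike trains of the pattern's active neurons, sorted by neuron id."""
    return [
        make_spike_train(pattern.freq_map[i], onset, t_max, dt, neuron_id=i)
        for i in sorted(pattern.active_set)
    ]


def trains_to_csv(trains: Iterable[SpikeTrain]) -> str:
    rows = [(tr.neuron_id, t) for tr in trains for t in tr.times]
    df = pd.DataFrame(rows, columns=["neuron_id", "time_ms"])
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()


def catalogue_to_csv(catalogue: Iterable[InputPattern] | None = None) -> str:
    if catalogue is None:
        catalogue = object_catalogue()
    rows = []
    for k, pat in enumerate(catalogue, start=1):
        rows.append((k, pat.label, " ".join(str(i) for i in sorted(pat.active_set))))
    df = pd.DataFrame(rows, columns=["object_id", "label", "active_neurons"])
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()
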