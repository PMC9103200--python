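"""Overlap and separation-power statistics.

Overlap is measured in Dice form: shared elements are counted once in each
of the two patterns, over the total element count, so two patterns with 4
and 5 active neurons sharing 3 overlap by 2*3/(4+5) = 0.667.  Separation
power (SP) is the percentage reduction of mean output overlap relative to
mean input overlap, (OI - OR)/OI.  Output overlap comes in two flavours:
spatial (which neurons spiked) and temporal (how many output spikes landed
in the same time bin, regardless of neuron identity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .engine import OutputPattern
from .patterns import InputPattern


def spatial_overlap(set1: Iterable[int], set2: Iterable[int]) -> float:
    """Dice overlap of two index sets: 2*|intersection| / (|set1| + |set2|)."""
    s1, s2 = set(set1), set(set2)
    if not s1 and not s2:
        raise ValueError("overlap of two empty sets is undefined")
    return 2.0 * len(s1 & s2) / (len(s1) + len(s2))


def _match_times(t1: Sequence[float], t2: Sequence[float]) -> int:
    """Greedy multiset matching of two sorted spike-time lists (same-bin pairs)."""
    i = j = matched = 0
    a, b = sorted(t1), sorted(t2)
    while i < len(a) and j < len(b):
        if a[i] == b[j]:
            matched += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return matched


def temporal_overlap(out1: OutputPattern, out2: OutputPattern,
                     match_identity: bool = False) -> float:
    """Dice overlap of two output spike-event multisets matched by time bin.

    By default synchrony alone counts: an event of one pattern matches any
    unmatched event of the other in the same bin.  With ``match_identity``
    only the same neuron spiking at the same time counts as shared.
    """
    if out1.silent or out2.silent:
        raise ValueError("temporal overlap of a silent trial is undefined")
    n1, n2 = len(out1.first_spikes), len(out2.first_spikes)
    if match_identity:
        matched = len(set(out1.first_spikes.items())
                      & set(out2.first_spikes.items()))
    else:
        matched = _match_times(out1.times, out2.times)
    return 2.0 * matched / (n1 + n2)


def separation_power(mean_oi: float, mean_or: float) -> float:
    """(OI - OR)/OI as a percentage; negative if the output overlaps more."""
    if mean_oi <= 0:
        raise ValueError("separation power is undefined for zero input overlap")
    return 100.0 * (mean_oi - mean_or) / mean_oi


@dataclass(frozen=True)
class PairScore:
    id1: int
    id2: int
    oi: float
    or_value: float


@dataclass(frozen=True)
class SPResult:
    """Ensemble separation summary for one overlap kind."""

    kind: str                 #: "spatial" or "temporal"
    mean_oi: float
    mean_or: float
    sp_percent: float
    n_pairs: int
    n_excluded_identical: int = 0
    n_excluded_silent: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind, "mean_oi": self.mean_oi, "mean_or": self.mean_or,
            "sp_percent": self.sp_percent, "n_pairs": self.n_pairs,
            "n_excluded": self.n_excluded_identical + self.n_excluded_silent,
        })


def ensemble_sp(patterns: Sequence[InputPattern],
                outputs: Sequence[OutputPattern],
                kind: str = "temporal",
                match_identity: bool = False) -> SPResult:
    """Average OI and OR over all unordered pairs of non-identical inputs.

    Pairs whose input patterns are identical are excluded (they measure
    reliability, not separation), as are pairs involving a silent trial.
    """
    if kind not in ("spatial", "temporal"):
        raise ValueError(f"unknown overlap kind {kind!r}")
    if len(patterns) != len(outputs):
        raise ValueError("patterns and outputs must align")
    n = len(patterns)
    oi_sum = or_sum = 0.0
    n_pairs = n_ident = n_silent = 0
    keys = [p.key() for p in patterns]
    for i in range(n):
        for j in range(i + 1, n):
            if keys[i] == keys[j]:
                n_ident += 1
                continue
            if outputs[i].silent or outputs[j].silent:
                n_silent += 1
                continue
            oi_sum += spatial_overlap(patterns[i].active_set,
                                      patterns[j].active_set)
            if kind == "spatial":
                or_sum += spatial_overlap(outputs[i].winners, outputs[j].winners)
            else:
                or_sum += temporal_overlap(outputs[i], outputs[j],
                                           match_identity=match_identity)
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no non-identical, non-silent pattern pairs to compare")
    mean_oi = oi_sum / n_pairs
    mean_or = or_sum / n_pairs
    return SPResult(kind=kind, mean_oi=mean_oi, mean_or=mean_or,
                    sp_percent=separation_power(mean_oi, mean_or),
                    n_pairs=n_pairs, n_excluded_identical=n_ident,
                    n_excluded_silent=n_silent)


def input_reliability(trials: Sequence[tuple[InputPattern, OutputPattern]]) -> float:
    """Fraction of repeated-input pairs that reproduced the exact same output."""
    n = len(trials)
    total = same = 0
    for i in range(n):
        for j in range(i + 1, n):
            if trials[i][0].key() != trials[j][0].key():
                continue
            total += 1
            if trials[i][1].key() == trials[j][1].key():
                same += 1
    if total == 0:
        raise ValueError("no repeated input patterns to assess")
    return same / total


def distinct_time_count(outputs: Sequence[OutputPattern]) -> int:
    """Number of distinct first-spike time signatures among non-silent outputs."""
    return len({out.times for out in outputs if not out.silent})
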