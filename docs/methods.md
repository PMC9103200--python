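# Methods

## Model summary

`tempsep` simulates a three-stage feedforward spiking network at a fixed
1 ms resolution.  All membrane potentials are in mV relative to a 0 mV
resting baseline; no conductances, cable properties, or axonal dynamics are
modelled — every mechanism is an explicit algebraic rule on the time grid.

### Input stage

An input pattern is a set of active I-neurons (3–6 of 8 under the default
protocol) with a frequency map.  Active neurons fire perfectly regular
trains; neuron *i* defaults to 90 + 10(*i*−1) Hz, spanning the 90–160 Hz
high-gamma band.  Interspike intervals are rounded to the grid
(`ISI = max(dt, round(1000/f))`), so 120 Hz and 130 Hz both yield 8 ms
trains — frequency resolution is limited by the grid, which matters for the
frequency-separation experiment (at most 9 of the 11 swept frequencies can
produce distinct trains).  The first spike falls one ISI after the common
onset (10 ms); there is no jitter, no phase offset between neurons, and no
rate adaptation.

### Representation stage

Wiring is drawn per "package": for each R-neuron branch, presynaptic
I-neurons are sampled uniformly without replacement (dense 3, sparse 1 per
branch), or all 8 are attached (full).  Each input spike, after a 1 ms
propagation delay, evokes an alpha-function EPSP on its branch,

    f(Δt) = k · w · Δt · g^(−Δt/τ),  k = 0.8, w = 2.0, g = 1.35, τ = 1 ms,

which peaks at τ/ln g ≈ 3.3 ms.  E/ET-neurons use k = 5.6 and g = 2.7
(≈ 1 ms decay, half the R-neuron time constant).  Kernels are sampled on
the grid and truncated below 10⁻⁶ of peak, keeping the accumulated
truncation error of a full trial below ~10⁻² mV.

EPSPs arriving on the same branch **in the same time bin** sum sublinearly:
the x-th simultaneous EPSP is scaled by 1 − (x−1)/12, floored at zero.
This is a spatial-summation saturation; temporal interaction between
volleys is carried entirely by the kernel decay.  Under complete 8-input
wiring the rank spans exactly 1–8 (the 8th EPSP retains 5/12 ≈ 42%).
Branch totals propagate to the soma with a delay of 2 ms × branch index
(2–12 ms for 6 branches) and are attenuated by U_pass = 0.5, then added
linearly.

The soma also carries a subthreshold membrane potential oscillation,

    SMO(t) = h · sin(2π · f_θ · (t − t_ref)/1000),  h = 8 mV, f_θ = 5 Hz,

with t_ref = 75 ms: the trough (−8 mV) falls at 25 ms, just after input
onset, and the peak (+8 mV) at 125 ms.  Input therefore arrives during the
rising, low-excitability phase, and the ~100 ms ascent stretches
first-spike times: strong drive crosses threshold early, weak drive only
near the peak.  Patterns whose drive never reaches θ − 8 mV within the
trial are *silent*; silent trials are excluded pairwise from overlap
statistics and counted separately.

At the first bin where any R-neuron's potential (dendritic drive + SMO)
reaches threshold, every neuron at or above threshold spikes — joint
winners share the bin — and a global 20 mV subtraction models the
winner-takes-all feedback inhibition for the rest of the trial.  The
trial's representational content is the winner set and its latency; the
simulation records but does not act on later dynamics.

**Threshold calibration.** The spiking threshold is not free: it must
exceed the SMO amplitude (otherwise the oscillation alone fires the
neuron), yet be low enough that the weakest protocol stimulus still fires
before the SMO peak.  `calibrate_threshold` walks a 0.5 mV grid upward
from h + 0.5 and accepts the first value at which the 3 slowest inputs
(90/100/110 Hz) fire before the peak in ≥ 90% of 20 seeded dense wirings.
This yields θ = 8.5 mV, the shipped default.

**Heterosynaptic LTD.** After a winning trial, each winner's synapses from
I-neurons *not* in the active set are multiplied by hs = 0.3; active
synapses are untouched.  Depression accumulates across a package and is
discarded with the wiring.  This "immunises" past winners against winning
again for different inputs, which helps spatial separation once the
population is large enough (EF > 1) for an alternative winner to exist.

### Synfire stage

A trigger neuron launches a spike wave at 10 ms that advances one ET-neuron
per millisecond.  Each E-neuron receives its ET-neuron and the R-neuron
output, both with weight 2.0 — each alone subthreshold, together
suprathreshold — while ET→ET uses 5.8 (suprathreshold, so the wave
propagates).  The E/ET threshold is calibrated midway between the best
non-coincident two-EPSP drive and the coincident drive, making the mapping
latency → E-index exactly injective.  The default conversion implements the
coincidence directly on the grid (`mode="exact"`); the kernel-summation
mode (`mode="physical"`) reproduces the same mapping and is tested against
it.  The ET→E weight is not independently specified in the source
parameterisation; using the R→E value is the only choice consistent with
the single-source-subthreshold constraint.

## Metrics

Overlap uses the Dice form 2|A∩B|/(|A|+|B|): the worked example — patterns
of 4 and 5 neurons sharing 3 — gives 6/9 = 0.667.  Temporal output overlap
matches spike events greedily by time bin, ignoring neuron identity (a
strict same-neuron variant is available).  SP = (OI − OR)/OI, reported in
percent, negative when output overlap exceeds input overlap (a single
always-winning neuron has spatial OR = 1 and hence strongly negative
spatial SP — reported as computed, never clamped).  Ensemble SP excludes
pairs with identical inputs (those measure *reliability*: the fraction of
repeated presentations reproducing the identical output) and pairs with a
silent member.

With multi-winner trials the temporal overlap counts events (two joint
winners at one bin are two events), while the synfire conversion maps
distinct *times* to E-neurons; the exact temporal-to-spatial overlap
equivalence therefore holds for single-winner ensembles, which is where
the model makes that claim.

## Experiment protocols and problem sizes

- **Default protocol**: 20 packages × 20 patterns (190 pairs each, 3,800
  comparisons); package *p* uses child seed `master + p`.
- **EF sweep**: the protocol at EF ∈ {0.125, 1, 2, 16} (1–128 R-neurons).
- **Complete connectivity**: the protocol on a single R-neuron whose 3
  dendritic branches each receive all 8 inputs.  Three branches (not the
  6 of the random regimes) is the model's complete-connectivity variant;
  with 6 fully wired branches the dendritic drive is so strong that
  latencies collapse into the first input volley and temporal separation
  drops by ~20 points.
- **Counting / frequency**: a fully connected single R-neuron (default
  branch count); latency vs. number of active inputs (all 90 Hz) and vs.
  common frequency (50–150 Hz, 3 active inputs).  Latencies quantise to
  the input-volley grid, so neighbouring conditions can share a bin (7 vs
  8 active inputs; frequencies whose ISIs round identically).
- **Objects**: 18 objects (3 shapes × 3 colors × 2 sizes, each a fixed
  3-neuron triple: shape → 1–3, color → 4–6, size → 7–8) plus 2 repeats per
  package, on a single R-neuron with doubled input weights (3-active
  patterns otherwise fire at the very end of the theta ascent).  Reported:
  reliability, distinct latencies per 18 objects, temporal SP.
- **Robustness**: the single-R protocol rerun with 3 Hz theta and a
  60–130 Hz gamma band; the variant reduces temporal SP only mildly
  (~2% relative at the default seeds).

## Design choices where the design was open

- **SMO anchor**: t_ref = 75 ms places the trough immediately after input
  onset and the peak at 125 ms, which is required for the rising-ramp
  latency code and matches the latency ranges the experiments produce; the
  anchor is a config field.
- **w_IR = 2.0** by default, with 0.4 documented as an alternate; the
  object experiment doubles whatever is set.
- **Pattern sampling**: |active| uniform on {3,…,6}, then a uniform subset.
  Exact enumeration gives a mean non-identical pairwise overlap of 0.5425
  under this generator; empirical protocol draws land at 54–56%.
- **Tie handling**: joint threshold crossings in one bin all win; the
  greedy temporal matcher operates on sorted times (order-independent for
  equal bins).
- **Crossing rule**: potential ≥ θ on the sampled grid; no sub-bin
  interpolation, so latencies are integers and collisions between very
  similar drives are possible by construction.

## What the generator does and does not emulate

Inputs are noiseless, perfectly periodic, and synchronised at onset; the
model's "100% input reliability" is a direct consequence (the engine is
fully deterministic given seed and config).  Real spike trains carry
jitter, rate drift, and phase dispersion, so passing tests here demonstrate
the *mechanism* — latency coding on a rising theta ramp with WTA — not
robustness to biological noise.  Apart from the explicit robustness
experiment, no parameter noise is modelled.

## Known limitations

- Latencies are 1 ms-quantised; conditions separated by less than the bin
  width are indistinguishable in principle (counting saturates at 7
  distinct latencies for 8 input counts under the calibrated threshold).
- The frequency experiment inherits the ISI-rounding degeneracy
  (120/130 Hz and 140/150 Hz identical) and, with the sparse 3-branch
  drive, latency can alias to the volley grid rather than decrease
  strictly with frequency.
- Spatial SP for a single R-neuron is structurally −(1−OI)/OI; only the
  temporal code is meaningful below EF = 1.
- hsLTD is the only plasticity; there is no STDP, no structural
  plasticity, and the depression never recovers within a package.
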