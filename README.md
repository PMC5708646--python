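# blmchan

Single-channel planar lipid bilayer (BLM) electrophysiology in Python:
simulation and analysis of single-molecule voltage-clamp recordings of a
NaChBac-like voltage-gated sodium channel.

Purified ion channels reconstituted into a planar bilayer produce picoampere
current steps as single molecules stochastically open and close. Analyzing
such recordings means turning noisy, low-pass-filtered current traces into
biophysical quantities: which conducting sub-states the channel visits, how
large their unitary conductances are, how open probability depends on
voltage, and how selective the pore is between cations. `blmchan` implements
that full chain, together with a stochastic gating simulator that generates
recordings with known ground truth, so every stage of the analysis can be
validated by parameter recovery.

## The model and the statistics

**Gating.** Each channel copy is a Markov chain with one closed state and L
conducting sub-states (the NaChBac-like default has three, at 26, 93 and
268 pS). Opening rates are scaled by a Boltzmann activation factor
B(V) = 1/(1+exp(−(V−V½)/s)); closing rates are voltage-independent.
Open-channel current is ohmic per level, g·(V−E_rev), plus Gaussian noise
and an 8-pole Bessel low-pass (12.5 kHz sampling, 1 kHz cutoff by default).

**Idealization.** Events are detected by the half-amplitude threshold
criterion with a symmetric dead time: openings shorter than the filter can
resolve are discarded and equally short closures are bridged.

**Sub-states and open probability.** The all-points amplitude histogram is
decomposed into Gaussian components (BIC-selected mixture); component
weights are state occupancies. With N channels in the bilayer, the
single-channel open probability follows from the multi-channel correction

    p_o = 1 − (1 − p_a)^(1/N),

where p_a is the probability that at least one channel is open.

**Conductance.** Level-assigned events pool into per-level I–V relations;
the unitary conductance is the zero-voltage slope of a weighted
least-squares fit (a quadratic term is used when an F-test says the I–V
rectifies).

**Selectivity.** Bi-ionic voltage ramps (Na⁺ on one side, K⁺ or Ca²⁺ on the
other, equal concentrations) are averaged; the reversal potential E_rev is
the x-intercept of the averaged trace, and relative permeabilities follow
from the GHK bi-ionic equations

    P_Na/P_K  = ([Na]/[K]) · e^(−F·E_rev/RT)
    P_Na/P_Ca = (4[Ca]/[Na]) · e^(F·E_rev/RT) · (1 + e^(F·E_rev/RT)).

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Simulate the single-channel step experiment (hold −80 mV, 10 s test steps,
5 repeats per voltage) and recover the sub-state conductances, then run a
bi-ionic ramp experiment:

```python
from blmchan import sim, pipeline

fx = sim.make_fixture("nachbac_default")
res = pipeline.sublevel_conductance_pipeline(
    fx.model, [30, 40, 50, 60, 70, 80], seed=1
)
print(res.summary())
for key in ("na_k", "na_ca"):
    print(pipeline.bi_ionic_pipeline(fx, key, seed=1, n_sweeps=100).summary())
```

prints

```
Sub-conductance analysis: 30 traces, 2215 events, 3 levels
  level 1: g =   24.9 +/- 0.0 pS (267 events)
  level 2: g =   91.9 +/- 1.1 pS (1018 events)
  level 3: g =  261.6 +/- 1.9 pS (187 events)
Bi-ionic selectivity
  sweeps averaged : 100
  E_rev           : -1.57 mV
  temperature     : 295 K
  P_Na/P_K        : 1.064
Bi-ionic selectivity
  sweeps averaged : 100
  E_rev           : -31.20 mV
  temperature     : 295 K
  P_Na/P_Ca       : 1.516
```

The three recovered conductances sit within a few pS of the simulator's
true 26/93/268 pS sub-states; the averaged-ramp x-intercepts recover the
true reversal potentials (−1.0 and −30.3 mV) to ~1 mV, giving permeability
ratios near the encoded 1.04 (Na/K) and 1.58 (Na/Ca) — the channel conducts
Na⁺, K⁺ and Ca²⁺ to a similar extent.

## Command line

A thin CLI wraps the same library calls:

```sh
blmchan simulate --fixture nachbac_default --protocol protocol.yaml \
        --seed 3 --out-dir traces/
blmchan idealize --in traces/sweep_000.csv --out events.tsv
blmchan gating   --in traces/sweep_000.csv --n-channels 1 --out gating.tsv
blmchan iv       --in events.tsv --out iv.tsv
blmchan selectivity --in sweeps/ --na-in 150 --k-in 150 --out sel.tsv
blmchan run      --config run.yaml --out-dir out/   # full demo + manifest
```

Traces are plain CSV with a `#` metadata header, events are TSV, protocols
and channel models are YAML; every stochastic run records its seed, and
`run` writes a manifest with output hashes so identical configs reproduce
outputs bit-exactly.

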