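# Methods

`blmchan` simulates and analyzes single-molecule voltage-clamp recordings of
a NaChBac-like bacterial voltage-gated sodium channel reconstituted in a
planar lipid bilayer (BLM). This note documents the model, the analysis
procedures, the defaults and why they were chosen, and what the synthetic
data do and do not emulate.

## Gating model

Each channel copy is a continuous-time Markov chain observed on the sampling
grid (dt = 1/sample_rate, default 12.5 kHz), with one closed state and L
conducting sub-states. Per time step:

* closed → level ℓ with probability `k_open[ℓ] · B(V) · dt`, where
  `B(V) = 1 / (1 + exp(−(V − v_half)/slope))` is a Boltzmann activation
  factor. Voltage dependence enters the *opening* rates only: depolarization
  activates the channel chiefly by raising its opening probability, which is
  what the single-channel data show.
* level ℓ → closed with probability `k_close[ℓ] · dt` (voltage-independent).
* level ℓ → level m directly at an optional `inter_level_rate` (default 0).
  Level switches are then closed-mediated, matching the observation that the
  vast majority of openings start from the closed state while direct
  level-to-level transitions are rare. The rate is exposed so both regimes
  can be exercised.

Paths are sampled exactly by geometric dwell times per state; along voltage
ramps, where the opening hazard varies sample to sample, candidate
transitions are drawn at the maximal hazard and accepted by thinning. This
is equivalent in distribution to stepping the chain sample by sample and
costs O(#events) instead of O(#samples). A guard rejects any `k·dt > 0.1`,
where the discrete-time approximation to the exponential dwell would start
to distort; the remedy is a higher sample rate.

Open-channel current is ohmic per level, `g_ℓ (V − E_rev,ℓ)/1000` pA with g
in pS and V in mV. White Gaussian noise (SD `noise_sd_pA`, default 0.6 pA)
is added before filtering; the same zero-phase Bessel low-pass used by the
analysis then stands in for the acquisition chain (8-pole hardware filter at
1 kHz). GHK rectification of the open-channel I–V is *not* simulated;
rectification is treated purely as an analysis-side diagnostic (slope ratio
between polarities).

### Seed contract

`simulate_experiment` / `simulate_bi_ionic_ramp` derive the gating seed of
repeat/sweep r as `seed + r` and the noise seed as `seed + r + 1_000_003`
(separate generators so gating and noise streams are independent).
Identical configuration + seed reproduces output bit-exactly; the pipeline
manifest records seeds and output hashes so this is checkable.

## Fixtures: what the defaults encode

`nachbac_default` encodes the study conditions the analysis is meant to
recover:

* Sub-state conductances 26 / 93 / 268 pS (L1/L2/L3), reversal 0 mV in the
  symmetric 150/150 mM NaCl condition.
* Kinetic rates are **not** reported for this channel; they are free
  parameters chosen once for realism, not claimed as NaChBac kinetics:
  `k_open = (4, 6, 1.2) /s` at saturating depolarization reproduces the
  reported occupancy ordering L2 > L1 > L3; `k_close = 20 /s` gives
  long-lived (~50 ms) sub-state dwells and per-voltage event counts in the
  reported tens-per-trace range; `v_half = +20 mV`, `slope = 8 mV`
  concentrates openings at ≥ +30 mV as observed.
* Noise 0.6 pA pre-filter ≈ 0.2–0.25 pA RMS after the 1 kHz low-pass,
  a typical BLM baseline.
* Bi-ionic conditions carry the *true* reversal potentials implied by the
  reported permeability ratios at 150/150 mM and 295 K: Na⁺/K⁺ ratio 1.04 →
  E_rev = −(RT/F)·ln(1.04) ≈ −1.0 mV, and Na⁺/Ca²⁺ ratio 1.58 → ≈ −30.3 mV
  (closed-form inversion of the divalent bi-ionic equation).
* Ramp sweeps use a gating variant (`ramp_model`) that is effectively
  voltage-independent (`v_half = −300 mV`) and more active
  (`k_open = (8, 12, 2.4) /s`). The bi-ionic recordings themselves show
  gating that is *not* suppressed at negative voltages — if anything the
  opposite — and a Boltzmann-activated ramp would carry no current below
  0 mV, leaving the x-intercept unmeasurable. The variant reproduces the
  qualitative appearance of the averaged ramp data.

`two_state_toy` (one 100 pS level, k_open = k_close = 10/s, saturated
activation) has closed-form occupancy 1/2 and is the oracle for dwell and
occupancy statistics. `macroscopic_n5` is the default channel with five
independent copies, for the multi-channel correction and event-count band
checks.

## Trace conditioning and idealization

* **Filter**: digital low-pass Bessel (order 8 default, 4 available),
  designed with `scipy.signal.bessel(norm="mag")` and normalized to DC gain
  exactly 1, applied zero-phase (forward–backward) so event boundaries are
  not delayed. The hardware stage it emulates is single-pass causal; the
  zero-phase choice is a deliberate deviation that trades realism for
  unbiased event boundaries. Measured 10–90% step rise time of the
  zero-phase order-8 design is ≈ 0.48/cutoff (the classic 0.33/cutoff rule
  applies to the single-pass filter).
* **Baseline**: among peaks of the all-points histogram of comparable
  height, the closed level is the one nearest 0 pA; a two-component Gaussian
  split restricted to that mode's neighbourhood (±8 robust SDs) gives the
  baseline mean and noise SD. Restricting the split keeps higher conducting
  levels from dragging it; if the two components overlap heavily the sample
  moments of the window are reported instead. A constant trace degenerates
  to (constant, 0).
* **Event detection**: half-amplitude threshold criterion. An event opens
  when |current − baseline| crosses 50% of the nominal amplitude
  `threshold_amplitude` and closes when it re-crosses below. A dead time
  (default `2 × 0.33/cutoff`) is imposed **symmetrically**: events shorter
  than it are discarded and closures shorter than it are bridged — gaps the
  filter cannot resolve are treated exactly like events it cannot resolve.
  Without the symmetric treatment, noise dips through the threshold shred
  long openings into fragments. Events spanning a command-voltage step are
  split at the boundary because amplitudes are voltage-dependent. A
  threshold below 3 baseline SDs logs a false-event warning but is not an
  error.

## All-points histogram and level decomposition

Histograms span [min, max] of the current in uniform bins (default width
`max(baseline SD/5, 0.01 pA)`); dividing counts by (total × bin width)
gives the probability density. For step-protocol traces the mixture is
fitted to the *test-step samples only*: an amplitude histogram admits a
conductance interpretation at a single driving force, and hold-segment
samples (tail currents of openings that persist into the return hold)
would otherwise masquerade as extra levels. For the same reason the
conductance pipeline keeps only events recorded at the trace's test-step
voltage — tail events ride on the filter transient of a large voltage jump
and their amplitudes are unreliable. A Gaussian mixture is fitted to the raw
samples (deterministically subsampled above 40 000 points), with the
number of components selected by BIC over 1..max_components (default 4 =
closed + 3 levels). For each k two seeded initializations are tried —
smoothed-histogram peaks and k-means — and the better BIC wins; this keeps
low-occupancy levels (a few % of samples) from being absorbed by broad
components.

Roles: the component nearest the baseline is *closed*; others are
*conducting* if their mean is more than 3 closed-SDs away, otherwise their
weight is absorbed into the closed component (the type contract requires
exactly one closed component, and such components are indistinguishable
from baseline). Components several times broader than the closed component
(> 5× SD) are treated as filter-smeared transition artifacts and excluded
from level counting and conductance pooling — a discrete level is as narrow
as the baseline noise.

Open probability: `p_a = 1 − w_closed` is the probability that at least one
of N channels is open; the single-channel open probability follows from the
multi-channel correction `p_o = 1 − (1 − p_a)^(1/N)`. Per-level
probabilities are the conducting-component weights (accumulated open
duration of each level over the tested period). When N is unknown it can be
estimated from the deepest observed stacking of unitary openings (a high
quantile of |current − baseline| divided by the unitary current).

Events are assigned to the conducting component with the nearest mean
(relative to the closed mean, so baseline-subtracted amplitudes compare
directly); exact ties go to the lower level, and events farther than 3
component SDs from every mean stay unassigned. Level identities are merged
across traces by greedy 1-d clustering of component conductances at 25%
relative tolerance — the reported conductance SEMs are themselves ≈ 17–23%,
so tighter merging would split genuine levels.

## I–V and unitary conductance

Level-assigned events pool into one I–V point per (voltage, level), with
voltages holding fewer than `min_events_per_voltage` (default 5) events
dropped. Points whose *expected* unitary current (cluster conductance ×
driving voltage) fails to clear the detection threshold with a 30% margin
are also dropped: events at such points are threshold-truncated and
selection-biased (only upward noise excursions get detected), so their mean
amplitude distorts the slope.

The unitary conductance is the zero-voltage slope of a weighted
least-squares line (weights = event counts), `g = slope × 1000` pS, with
the x-intercept `−intercept/slope` as an internal consistency check. When a
quadratic term significantly improves the fit (F-test, α = 0.05, given ≥ 4
points) — the signature of rectification — the zero-voltage slope is the
linear coefficient of the quadratic fit. Rectification is additionally
summarized as |slope(V>0)| / |slope(V<0)| from separate per-polarity fits.
Conductance vs salt concentration is ordinary least squares over ≥ 3
distinct concentrations, duplicates averaged, never forced through the
origin.

## Drug block and bi-ionic selectivity

The block workflow averages repeated step sweeps: sweeps whose mean excess
current during the activating step (most depolarized segment) stays below a
classifier threshold (default 3 × baseline SD) are *inactivated*; their
pointwise mean is the baseline, subtracted from the mean of the active
sweeps. Inactivated sweeps are emulated by the simulator as null sweeps
(opening rates zeroed with probability `p_null`, default 0.2 in the block
workflow only).

For selectivity, ramp sweeps (−100 → +100 mV at 100 mV/s, default 100
sweeps) are averaged pointwise, never discarding low-conductance sweeps —
the stochastic-selectivity observation depends on keeping them. The
reversal potential is the x-intercept of the averaged trace: the current is
binned in 2 mV voltage bins along the ramp, the sign change of the binned
means located, and a straight line fitted to all samples within ±20 mV of
the crossing (window configurable; a local fit because the averaged trace
is noisiest near zero current). Relative permeabilities then follow from
the bi-ionic GHK forms (concentrations in mol/l, E_rev in volts,
F = 96485.3 s·A/mol, R = 8.314 J/K/mol, T default 295 K — room temperature;
the temperature is exposed as configuration):

    P_Na/P_K  = ([Na]_in/[K]_in) · exp(−F·E_rev/RT)
    P_Na/P_Ca = (4[Ca]_out/[Na]_in) · exp(F·E_rev/RT) · (1 + exp(F·E_rev/RT))

Both are implemented exactly in these printed forms. The monovalent
prefactor uses the in/in subscripts as printed; under the equal
150/150 mM bi-ionic setup the prefactor is 1, so the subscript convention
has no numeric effect there — flagged here rather than silently changed.
The inverse mappings (ratio → E_rev) are closed-form: a logarithm for
Na/K, a quadratic in exp(F·E/RT) for Na/Ca.

## Problem sizes and numerical choices

* The conductance-recovery workflow runs 17 voltage steps (−80..+80 mV,
  10 mV), 5 × 10.4 s repeats each, three seeded replicates — about one
  minute per replicate on a single core. These sizes give hundreds of
  events per level, comfortably inside the reported per-voltage event range
  (tens per trace), and replicate-mean conductances that are stable to a
  few pS.
* Bi-ionic recovery uses 100 sweeps × 2 s per replicate, three replicates
  per condition; the reversal estimate is reproducible to well under 1 mV
  at that depth.
* Mixture fits use `reg_covar = 1e-10` (noiseless fixtures would otherwise
  degenerate) and at most 40 000 subsampled points; baseline GMMs subsample
  above 100 000 points.
* Ties and degenerate inputs: exact assignment ties go to the lower level;
  an exactly-linear I–V keeps the linear model (the F-test is skipped when
  the linear residual is at rounding level); `p_a = 1` with finite N returns
  `p_o = 1` with a warning.

## What the generator does not emulate

Synthetic traces omit capacitive transients (no cancellation step is
modeled), baseline drift, 50/60 Hz interference, open-channel excess noise,
GHK open-channel rectification, and any inactivation kinetics (null sweeps
stand in for inactivated traces purely as a baseline source). Passing
recovery tests therefore demonstrates correctness of the analysis chain
under idealized stationary recordings, not robustness to every artifact of
real bilayer data. Dwell-time *distribution* fitting and kinetic rate
estimation are out of scope (no reference kinetics exist to recover), as is
reading vendor binary acquisition formats.
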