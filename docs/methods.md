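# Methods

## The gating model

The package models phosphorylated CFTR gating in saturating ATP as a
continuous-time Markov chain over five states:

```
 IB  --k_open-->  B1_O  --k_1-->  B2_O  --k_2-->  IB
 IB  <--k_minus1-- B1_O/B1_Cf
 within B1 and B2:  O --k_OC--> C_f,   C_f --k_CO--> O
```

IB is the inward-facing interburst closed state; B₁ the prehydrolytic and B₂
the posthydrolytic outward-facing (bursting) state; O/C_f are the conducting
and flickery-closed pore conformations within a burst. All rates are in 1/s
at 25 °C unless stated.

**Assumptions.**

1. *Burst exits are flicker-independent*: `k_1`, `k_minus1` and `k_2` fire
   identically from the O and C_f substates. The flicker is a local pore
   motion that leaves the NBD dimer (and the interfacial contacts that
   control burst termination) intact, so the NBD gate and the flicker gate
   are treated as independent. This makes the aggregated burst lifetime
   exactly exponential with rate `k_1 + k_minus1` and the closed forms below
   exact. Whether flickers from B₂ occur at exactly the B₁ rates is not
   experimentally constrained; independence is assumed, and none of the
   analyzed quantities depends on it (B₂ lives 20 ms and contributes ~7% of
   τ_b in the WT preset, nothing in the `k_1 = 0` presets).
2. *Unidirectional cycle*: hydrolysis is irreversible and post-hydrolytic
   closure does not revisit B₁.
3. *ATP removal only zeroes `k_open`*: all other rates are ATP-independent.
   ATP-concentration dependence of opening is out of scope (saturating ATP
   throughout).

**Closed-form summaries.** Mean burst duration
`τ_b = 1/(k_1+k_minus1) + [k_1/(k_1+k_minus1)]/k_2` (exactly `1/k_minus1`
when `k_1 = 0`); coupling ratio `CR = k_1/(k_1+k_minus1)`; intraburst open
probability `P_o|B = k_CO/(k_CO+k_OC)` with `K_eq|B = P_o|B/(1−P_o|B)`;
stationary bursting fraction `τ_b/(1/k_open + τ_b)`. These serve as the
independent oracles for the stochastic machinery: the Gillespie simulator is
validated against them, never the reverse.

**Simulation.** Exact event-driven sampling (Gillespie direct method), not
time discretization, so dwell statistics are unbiased at any rate ratio.
A single user-supplied integer seed controls every run; independent
substreams are derived with `numpy.random.SeedSequence` spawn keys, and all
derived seeds are kept below 2³¹.

## Genotype presets

`data/presets.json` stores one rate set per genotype with a per-rate
provenance tag: `measured` (published experimental estimate), `derived`
(computed from published fold-relations), `assumed` (package choice where no
measurement exists). The load-bearing values: WT `k_1 = 4`,
`k_minus1 = 0.03`; hE1371S and hK1250A `k_minus1 = 0.03`; hE1371Q
`k_minus1 = 0.0025`; hD1370N `k_minus1 = 0.5` (lower end of the published
0.5–1 /s range); double mutants follow the published fold-relations
(hK1250A+E1371Q 5× slower than hK1250A; hD1370N+E1371Q 16× slower than
hD1370N); G576-deletion constructs 20× (Q background) and 2× (S background)
faster. Assumed values: `k_open = 1` (the ~1 s interburst), `k_2 = 50`
(B₂ must merely satisfy `k_2 ≫ k_1`; 20 ms keeps it visible in
trajectories), flicker rates `k_CO = 100` (~10 ms flickers) with
`k_OC = 9.9` chosen to give the measured `P_o|B = 0.91`. Intraburst rates
are shared across genotypes (published K_eq|B values of the cycle constructs
agree within ~2-fold).

## The synthetic recording chain

What it emulates: inside-out patches of N independent channels, unitary
current −0.5 pA (inward negative, −80 mV), additive Gaussian baseline noise
(SD 0.05 pA), an acquisition low-pass at 2 kHz, 10 kHz sampling, and the
ATP-removal protocol. The acquisition filter is implemented as a Gaussian
low-pass (kernel SD `0.1325/f_c` giving −3 dB at f_c) rather than a Bessel
filter: the Gaussian is the standard analysis-side approximation and is
exactly what the idealizer's dead-time theory assumes.

What it does *not* emulate — and hence what passing tests cannot certify
about real recordings: seal-leak drift and rundown, capacitance transients,
finite solution-exchange time (the fit window guard exists for it, but the
synthetic switch is instantaneous), subconductance levels, correlated
(1/f or excess) noise, and PKA/phosphorylation kinetics. Estimator behavior
under those nuisances must be established on real data.

**Macroscopic fast path.** For patches with more than 100 channels the
renderer does not run per-channel Gillespie. The number of bursting channels
at removal is a binomial draw from the stationary bursting fraction, each
terminal closing time is an exact phase-type draw (residual Exp(k₁+k₋₁) in
B₁, plus Exp(k₂) for the CR-weighted hydrolytic exits, with the B₁/B₂ split
taken from stationary within-burst occupancy), and the fast O/C_f telegraph
is replaced by its mean `P_o|B`. For the relaxation quantities analyzed
(ensemble decay, normalized amplitudes) this is distributionally identical;
what it suppresses is within-trace flicker noise and pre-removal gating
fluctuations, which the relaxation fit never uses. Patches with ≤ 100
channels are rendered channel-by-channel from exact trajectories.

**Problem sizes.** Macroscopic relaxations are rendered at 100 Hz sampling
(fixtures) or 50 Hz (the 1600 s E1371Q records), with the anti-alias cutoff
scaled accordingly — kinetics on the seconds-to-minutes scale carry no
information at 10 kHz, and this keeps full-pipeline runs to seconds.
Single-channel/intraburst work keeps the full 10 kHz / 2 kHz chain, since
the 10 ms flickers live near the resolution limit.

## Idealization

Recordings are Gaussian-filtered at an analysis bandwidth of 100 Hz,
thresholded at half the unitary amplitude (`baseline + i_unit/2`), and
events shorter than the dead time `T_d = 0.179/f_c` (the duration whose
filtered peak just reaches half amplitude) are merged into the flanking
level, globally shortest first, ties to the earlier event; edge events merge
into their single neighbor. Crossings are located at sample resolution —
at 10 kHz sampling and 100 Hz bandwidth, sub-sample interpolation is
immaterial. The baseline defaults to the median of the terminal second of
the segment (the channel has closed by then).

**Last-channel windows.** After ATP removal channels cannot reopen, so once
the idealized open-channel count last drops from 2 to 1, every subsequent
closure of the surviving channel except the terminal one is a flicker. The
window start adds a small settle guard (50 ms default) so the penultimate
channel's terminal transition is not scored as intraburst gating; the
terminal closed event is excluded from τ_flicker. The published analyses do
not state an operational window rule; this one is a reconstruction with the
same intent.

**Bias budget.** Flickers shorter than T_d ≈ 1.8 ms (~16% of a 10 ms
exponential population) are missed, which lengthens measured open times;
surviving flickers are length-biased (mean ≈ T_d + 10 ms). The two biases
nearly cancel in `K_eq|B = τ_open/τ_flicker` and `P_o|B`: simulated
segments recover P_o|B ≈ 0.91 within ±0.01 of design. This cancellation is
a property of exponential dwells and need not hold for other dwell shapes.

## Relaxation fitting

Traces are normalized by the mean current in a window just before removal,
then fitted with `A·exp(−(t−t_off)/τ)`, offset fixed at zero (the published
normalization admits no offset; residual leak is handled by subtracting the
post-decay plateau median when the record outlasts 5τ). The fit window
starts two filter rise times after removal to skip the transient. Initial
guesses: A from the first fitted sample, τ from the time to fall to A/e,
with a ×{0.1, 1, 10} grid fallback.

**Uncertainty.** For an ensemble relaxation the residuals are a correlated
survival path, so the raw least-squares covariance understates the error by
orders of magnitude. When the channel count N is supplied, the standard
error instead comes from exponential-lifetime counting statistics:
`SE(τ) = τ/√n_closed` with `n_closed ≈ N·min(A,1)·(1−e^(−T/τ))` closures in
the fitted window. Across-seed scatter of the estimator matches this SE
(tested); replicate aggregation (mean ± SD/√n across patches, as in the
published figures) is available independently. Rate CIs are computed
symmetrically on the log scale, as appropriate for a scale parameter.

## Mutant-cycle thermodynamics

Barrier shifts `ΔΔG⁰ = −ln(r′/r)` (kT units) from closing rates, ground-state
shifts `−ln(K′/K)` from intraburst equilibria; the interaction energy is the
difference between the two parallel-side ΔΔG⁰ values,
`ΔΔG_int = ln(A·B/(bg·double))` in corner notation. This cycle sum is
invariant to which single is labelled A and to which diagonal corner is
called background; it flips sign only when the roles of the
{background, double} and {single, single} pairs are exchanged. With the
background carrying the intact candidate interaction, positive ΔΔG_int on a
rate cycle means the interaction stabilizes B₁ relative to the transition
state (+2.3 kT for the Q1371/G576 cycle).

**Error propagation.** Corner estimates are replicate means with SEMs;
moments of `ln X` for normal X come from the Taylor series of `ln(1+cv·Z)`
integrated term-by-term against the standard normal:
`E[ln X] = ln μ − cv²/2 − (3/4)cv⁴ − (5/2)cv⁶ − (105/8)cv⁸`,
`Var[ln X] = cv² + (5/2)cv⁴ + (32/3)cv⁶ + 65·cv⁸`. The series is verified
against Monte-Carlo integration in the tests (≤ 2% of the variance for
cv ≤ 0.2); it is asymptotic and is refused at cv ≥ 0.5, where a bootstrap
is the honest alternative. The cycle SEM adds the four corner log-variances;
significance is an unpaired two-sample t on the two sides with Σn − 4
degrees of freedom. (The published analysis reports a paired t test, but no
pairing structure between independently recorded patch populations is
described; the unpaired choice is recorded in the output.)

**Temperature extrapolation.** Rates scale as
`k(T₂) = k(T₁)·exp(−(ΔH‡/R)(1/T₂ − 1/T₁))` with transition-specific
activation enthalpies (defaults 70 kJ/mol for B₁→B₂, 40 kJ/mol for B₁→IB₁),
from which the coupling ratio at any temperature follows. Energies are
reported in kT units to match the field's convention; `in_kJ_per_mol()`
converts for display.

## Numerical and design choices

* Offset-free exponential fits with bounds `τ > 0`; non-convergence raises
  with the initial guesses and data summary rather than returning garbage.
* The fit warns (does not fail) when the record covers < 3 fitted time
  constants.
* `K_eq|B` with no flickers (`k_OC = 0`) returns `P_o|B = 1` with an
  explicit infinite-K sentinel rather than raising.
* Trace/event TSV dialects carry their metadata in `#`-prefixed headers,
  are written with fixed formatting (byte-reproducible under a fixed seed),
  and tolerate CRLF.
* Degenerate inputs fail loudly: zero-length last-channel windows, traces
  whose steady state is indistinguishable from zero, cycles mixing rates
  with equilibria, sub-2-replicate aggregation.

## Known limitations

* The B₂ lifetime (20 ms) and the shared flicker rates are assumptions; any
  quantity sensitive to them beyond `k_2 ≫ k_1` is outside the validated
  envelope.
* The macroscopic fast path omits pre-removal gating fluctuations, so it
  cannot be used to study steady-state noise (variance/mean analysis).
* The idealizer handles a single conductance level; multi-channel overlap
  is used only for counting, not joint idealization, and burst delimitation
  in the presence of ATP (t_crit analysis) is not implemented — the
  post-removal protocol makes it unnecessary.
* Counting-statistics SEs assume independent channels and complete, or
  exponentially censored, observation of closures.
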