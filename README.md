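# cftrgate

Quantitative kinetics of the CFTR gating cycle: stochastic simulation of the
ATP-driven conformational cycle, synthetic patch-clamp recordings,
single-channel dwell-time analysis, macroscopic relaxation fitting, and
thermodynamic mutant-cycle analysis with error propagation and temperature
extrapolation.

CFTR, the chloride channel mutated in cystic fibrosis, is the one ABC protein
whose conformational cycle is observable one molecule at a time in
patch-clamp recordings. A phosphorylated channel cycles between a long
(~1 s) interburst closed state (IB, inward-facing, rate constant
`k_open` for opening) and a bursting state (B, outward-facing,
NBD-dimerized). The prehydrolytic burst state B₁ is terminated either by ATP
hydrolysis (`k₁ ≈ 4 /s` at 25 °C, via a short-lived posthydrolytic state B₂,
`k₂ ≫ k₁`) or by non-hydrolytic NBD-dimer dissociation (`k₋₁`). Within a
burst the pore flickers between open (O) and flickery-closed (C_f) on the
~10 ms scale without disturbing the NBD dimer. Two quantities summarize the
energetics:

* the **coupling ratio** `CR = k₁ / (k₁ + k₋₁)` — the fraction of bursts
  terminated productively by hydrolysis;
* the **mean burst duration** `τ_b = 1/(k₁+k₋₁) + [k₁/(k₁+k₋₁)]·(1/k₂)`.

`k₋₁` is invisible in wild-type records (hydrolysis dominates) and is
estimated from catalytic-site mutants with `k₁ = 0`, whose macroscopic
current after ATP washout decays as a single exponential with
`τ = 1/k₋₁`. Published non-hydrolytic closing rates span ~200-fold across
mutants (E1371Q ~0.0025 /s … D1370N ~0.5–1 /s); the package's genotype
presets encode these values, the ~20-fold vs ~2-fold accelerations caused by
deleting D-loop residue G576 in the E1371Q vs E1371S backgrounds, and the
resulting mutant-cycle interaction energy of ~2.3 kT that identifies the
non-native Q1371–G576 hydrogen bond. With measured activation enthalpies
(ΔH‡ ≈ 70 kJ/mol for B₁→B₂, ≈ 40 kJ/mol for B₁→IB₁), Arrhenius scaling
extrapolates `CR ≈ 0.99` at 25 °C to `≈ 0.995` at 37 °C.

Because every analysis consumes synthetic recordings rendered from the known
gating scheme (exact Gillespie trajectories → unitary currents → Gaussian
noise → acquisition filter), every estimator in the package can be checked
against ground truth.

## Worked example

Temperature extrapolation and the Q1371/G576 mutant cycle from the
command line:

```sh
$ cftrgate extrapolate --k1 4 --km1 0.03 --t-celsius 37
{"T_K": 310.15, "k1_per_s": 11.928113116511222, "km1_per_s": 0.056010678096175597,
 "CR": 0.9953262600540409, "CR_ref": 0.9925558312655086}
```

At 37 °C hydrolysis runs ~3× faster (~12 /s) and non-hydrolytic closure
~1.9× faster (~0.06 /s), so the coupling ratio rises from ~0.99 to ~0.995:
only one burst in ~200 ends unproductively at body temperature.

The same library calls in Python, running the full synthetic pipeline
(8 replicate 1000-channel relaxations per corner genotype, fitted and fed
into the mutant cycle):

```python
import cftrgate as cg

bundle = cg.run_pipeline(cg.RunConfig(
    seed=11,
    genotypes=["hE1371Q", "hE1371Q_G576del", "hE1371S", "hE1371S_G576del"],
    output_dir="scratch/demo", n_channels=1000, n_replicates=8,
    fs=50.0, f_acq=10.0, window=5.0))
cyc = bundle["mutant_cycle"]
print(round(cyc["ddG_int_kT"], 2), "+/-", round(cyc["sem_kT"], 2), "kT")
# 2.3 +/- 0.02 kT  (ground truth ln 10 = 2.30)
```

The recovered interaction energy ~2.3 kT says the G576-deletion penalty is
~10-fold larger in the Q background than in the S background — the
energetic signature of a hydrogen bond present in B₁ and broken in the
transition state for non-hydrolytic closure.

## Package layout

| module | contents |
| --- | --- |
| `cftrgate.gating` | gating scheme, closed-form summaries (τ_b, CR, P_o\|B), exact Gillespie simulation |
| `cftrgate.presets` | provenance-tagged genotype rate presets (`data/presets.json`) |
| `cftrgate.synth` | trace rendering, macroscopic ensembles, fixture generation |
| `cftrgate.idealize` | Gaussian filtering, half-amplitude idealization, last-channel windows, intraburst statistics |
| `cftrgate.relaxation` | steady-state normalization, single-exponential fits, replicate aggregation |
| `cftrgate.thermo` | mutant cycles, log-moment error propagation, Arrhenius extrapolation |
| `cftrgate.pipeline`, `cftrgate.cli`, `cftrgate.io` | end-to-end runs, command line, TSV/CSV/JSON dialects |

See `docs/methods.md` for the model, the estimators, numerical choices and
known limitations.
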