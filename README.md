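# casfret

Single-molecule FRET (smFRET) kinetic analysis of Cas9–guide-RNA target
recognition and rejection, paired with a synthetic trajectory simulator so
that every analysis stage can be validated by parameter recovery against a
known ground truth.

## Who this is for

Single-molecule biophysicists analyzing camera-based smFRET trajectories of
CRISPR–Cas9 (or similar bimolecular binding) experiments: two-channel
donor/acceptor intensity traces at ~0.1 s time resolution, from which
binding/dissociation kinetics are extracted per DNA target. Because raw
experimental data of this kind are rarely shareable, the package ships a
first-class simulator whose presets encode the measured kinetics of an SpCas9
guide against a panel of mismatched DNA targets, so the entire pipeline is
testable end to end.

## The model

Cas9–RNA binding to a surface-immobilized DNA target is modeled as a
three-state continuous-time Markov chain:

* **U** — unbound DNA (FRET ≈ 0),
* **S** — a transient, sequence-nonspecific *sampling* mode (FRET ≈ 0.42),
  interpreted as PAM surveillance, with lifetime ~0.1 s,
* **H** — the RNA:DNA heteroduplex (R-loop) state (FRET ≈ 0.92).

Binding is bimolecular (U-exit rates scale with [Cas9–RNA]); photobleaching
is a single exponential clock (~3 min) that truncates the observable trace.
The analysis chain mirrors standard practice:

1. **Correction** — FRET `E = I_A / (I_D + I_A)` from background- and
   leakage-corrected intensities; photobleach detection; FRET histograms with
   bound fraction = share of points with `E > 0.75`.
2. **Idealization** — per-molecule three-state Gaussian hidden Markov model,
   Viterbi-decoded; transition density plots; transition-probability rates
   `k(A→B) = T_p(A→B) × sampling rate`.
3. **Dwell kinetics** — bound dwells (mid + high merged, `E > 0.2`) fitted by
   maximum likelihood with a single- or double-exponential survival model
   `A₁ exp(−t/τ₁) + A₂ exp(−t/τ₂)`; the amplitude-weighted lifetime
   `τ_avg = A₁τ₁ + A₂τ₂`; photobleach correction
   `k_actual = k_observed − k_photobleach`, `τ_avg = 1/k_actual`; the
   bimolecular association constant `k_on` from the unbound-state decay rate
   versus concentration.
4. **Genome counting** — occurrences of a PAM-plus-seed query (IUPAC
   `{A,C,G,T,N}`) in any FASTA genome, both strands, overlapping matches
   included, versus the random-sequence expectation
   `probabilistic count = (¼)ⁿ × L`.

## Worked example

Simulate 100 molecules of the `9-20_mm` target (mismatches at positions 9–20
counted from the PAM; ground-truth bound lifetime 16 s) at 20 nM for 300 s,
then run the full pipeline:

```python
import casfret as cf

summary = cf.run_pipeline(cf.RunConfig(
    out_dir="run", preset="9-20_mm",
    n_molecules=100, duration_s=300.0, seed=12, use_hmm=True))
print("bound_fraction:", round(summary["bound_fraction"], 3))
print("state_means:", [round(m, 3) for m in summary["state_means"]])
print("tau_avg_s:", round(summary["tau_avg_s"], 2))
print("k_photobleach_s:", round(summary["k_photobleach_s"], 5))
print(f"k_on_M_s: {summary['k_on_M_s']:.2e}")
```

prints

```
bound_fraction: 0.657
state_means: [-0.004, 0.424, 0.923]
tau_avg_s: 18.15
k_photobleach_s: 0.00605
k_on_M_s: 5.51e+06
```

Reading: about 66% of pooled early frames sit above FRET 0.75 (the
equilibrium high-state occupancy at 20 nM); the fitted FRET state means
recover the emission truth (0 / 0.42 / 0.92); the photobleach-corrected
amplitude-weighted bound lifetime is ~18 s against a ground truth of 16 s
(HMM-route dwells at n = 100); the recovered photobleach rate matches the
simulated 1/180 s⁻¹; and the association constant is ~6 × 10⁶ M⁻¹ s⁻¹.
The run directory contains the dataset (`traces.tsv`, `manifest.json`), the
histogram, idealized paths, dwell table, fits and a `summary.json`.

The same stages are available from the shell:

```bash
casfret simulate --preset 5-20_mm --n-molecules 100 --duration 120 --seed 1 --out ds
casfret correct  --dataset ds --out hist
casfret dwells   --dataset ds --out dwells.tsv
casfret fit      --dwells dwells.tsv --dwell-class bound
casfret count    --fasta genome.fa --query GGTACCTANGG
```

The last command prints, for a 100 kb random genome,

```
{"query": "GGTACCTANGG", "n_specified": 10, "actual_count": 0,
 "probabilistic_count": 0.19073486328125, "genome_length_bp": 100000,
 "convention": "actual: both strands; probabilistic: both strands"}
```

i.e. a 10-specified-base query is expected ~0.2 times in 2 × 100 kb of
random sequence and indeed does not occur.

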