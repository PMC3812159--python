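# degronkinetics

Kinetic analysis of degron-based substrate ubiquitination from
gel-band time courses.

## What this is for

Degrons are short amino-acid sequences recognized by E3 ubiquitin
ligases; incorporated into a reporter peptide, a good degron targets
the reporter to the proteasome.  A practical way to compare candidate
degrons is to incubate degron-bearing fluorescent peptides in
cytosolic lysate, quantify the mono- through tetra-ubiquitinated gel
bands over time, and fit a kinetic model to the band intensities.  The
key figure of merit is whether a substrate is ubiquitinated faster
than cytosolic peptidases destroy it.

This package provides that full analysis for people running (or
re-analyzing) such assays:

* forward simulation of first-order multi-monoubiquitination and
  polyubiquitination (capped-chain) reaction networks;
* reading, validation, normalization and replicate-averaging of
  quantified band-intensity tables;
* rate-constant estimation by MCMC minimization of the cumulative
  squared deviation (cSSD) between model and data, with per-species
  Pearson goodness-of-fit;
* model comparison between the two network topologies;
* ranking of degrons by the k1/k5 ubiquitination-vs-degradation
  metric;
* a synthetic gel-densitometry generator with known ground truth, so
  every estimation claim is testable without experimental data.

## The model

The state x = (C₀, C₁, C₂, C₃, C₄, D) — parent, 1–4× ubiquitinated
species and a degradation sink, all relative to the initial parent
amount C₀(0) = 1 — evolves by mass-action kinetics:

    dC₀/dt = −(k₁ + k₅) C₀
    dCᵢ/dt = kᵢ Cᵢ₋₁ − (kᵢ₊₁ + k₅₊ᵢ) Cᵢ      i = 1..3
    dC₄/dt = k₄ C₃ − k₉ C₄
    dD/dt  = k₅ C₀ + k₆ C₁ + k₇ C₂ + k₈ C₃ + k₉ C₄

k₁–k₄ (per minute) are successive ubiquitin additions, k₅–k₉
peptidase degradation of each form.  Fitting minimizes

    cSSD = Σ_species Σ_times ( model − data )²

over the four ubiquitinated species, via random-walk Metropolis in
log-parameter space (see `docs/methods.md` for the sampler, the
capped-chain polyubiquitination variant, and all numerical choices).
A degron with k₁/k₅ > 1 is classified favorable for proteasome
targeting.

## Worked example

Generate a noisy synthetic time course from the built-in Bonger-degron
reference constants, refit it, and rank the reference table:

```python
from degronkinetics import (
    FitConfig, REFERENCE_RATE_CONSTANTS, aggregate_replicates,
    generate_timecourse, k1_over_k5, mcmc_fit, normalize_to_parent,
    rank_degrons, reference_parameters,
)

truth = reference_parameters("Bonger")
table = generate_timecourse(truth, seed=42)          # 6 times, n=3, 10% CV
data = aggregate_replicates(normalize_to_parent(table))
result = mcmc_fit(data, config=FitConfig(iterations=50_000, seed=7))

print(f"fitted k1 = {result.params.k1 * 1e3:.2f} x10^-3 / min  (truth 8.1)")
print(f"fitted k5 = {result.params.k5 * 1e3:.2f} x10^-3 / min  (truth 4.0)")
print(f"k1/k5     = {k1_over_k5(result.params):.2f}            (truth 2.03)")
print(f"cSSD      = {result.cssd:.4f}")
print(f"Pearson r (mono) = {result.pearson['mono']:.3f}")

ranking = rank_degrons(dict(REFERENCE_RATE_CONSTANTS))
print(ranking.frame[["degron", "k1", "k5", "k1_over_k5", "favorable"]].to_string(index=False))
```

Output:

```
fitted k1 = 8.02 x10^-3 / min  (truth 8.1)
fitted k5 = 2.79 x10^-3 / min  (truth 4.0)
k1/k5     = 2.88            (truth 2.03)
cSSD      = 0.0004
Pearson r (mono) = 0.999
   degron   k1  k5  k1_over_k5  favorable
      TAZ  6.1 2.3        2.65       True
   Bonger  8.1 4.0        2.03       True
     iNOS  6.8 4.2        1.62       True
β-Catenin  6.2 4.0        1.55       True
      p53 13.1 8.7        1.51       True
   IFNAR1  7.2 7.5        0.96      False
Cyclin D1  3.4 7.2        0.47      False
   HIF-1α  2.6 7.0        0.37      False
     SRC3  2.8 8.5        0.33      False
```

The fitted mono-ubiquitination rate k₁ lands within ~1% of truth on
this draw; k₅ is less identifiable from six noisy time points (the
parent band itself is not observable in a pull-down), which inflates
the refitted ratio — across 20 seeds the favorable/unfavorable
classification is nonetheless correct every time.  The ranking table
shows rate constants on the conventional ×10³ display scale and the
five degrons whose ubiquitination outpaces degradation.

The same pipeline is scriptable from the shell:

```sh
degronkinetics generate --degron Bonger --seed 1 --out bonger.csv
degronkinetics fit --data bonger.csv --seed 2 --name Bonger --outdir fit/
degronkinetics rank --fits fit/fit_result.txt --out ranking.csv
```

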