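# Methods

## The system being modeled

A short fluorescent peptide carrying a degron (an E3-ligase recognition
sequence) is incubated in cytosolic lysate supplying the E1–E2–E3
ubiquitin-transfer cascade and endogenous peptidases.  Over a 0–240 min
incubation the substrate acquires up to four ubiquitins, visible as
discrete gel bands (mono, di, tri, tetra), while every form — modified
or not — is simultaneously destroyed by peptidases.  Deubiquitination
and proteasomal degradation are pharmacologically inhibited in the
assay this package models (ubiquitin aldehyde and MG-132
respectively), so neither appears in the network.  Band intensities are
quantified relative to a reference lane of unreacted parent substrate,
putting data and model on the common unitless scale C_i/C_o.

## Kinetic model

All reactions are first order, so the state vector
x = (parent, mono, di, tri, tetra, degraded) obeys a linear,
time-invariant ODE system dx/dt = M·x with x(0) = (1, 0, 0, 0, 0, 0).
Nine rate constants (per minute) parameterize M:

* k1–k4 — successive ubiquitin additions (parent→mono, …, tri→tetra);
* k5 — peptidase degradation of the unmodified parent;
* k6–k9 — degradation of the mono- through tetra-ubiquitinated forms.

Degradation flows into an explicit `degraded` sink state so that total
mass is conserved exactly; this makes conservation a testable invariant
rather than an implicit assumption.

Two topologies are implemented:

**multi_mono** — each ubiquitin goes onto a fresh lysine of the
substrate; every band species acquires its next ubiquitin at the full
rate constant.  This is the six-state chain above.

**poly** (capped-chain) — higher bands arise by elongating a chain on
a single attached ubiquitin.  The assay supplies methylated ubiquitin
(MeUb, all lysines blocked) in >100-fold excess over native ubiquitin,
so each *added* ubiquitin is chain-extendable native Ub only with
probability φ (default 1/101) and a chain-terminating MeUb otherwise.
Internally each chain length i = 1..3 splits into an extendable pool
u_i and a capped pool m_i; elongation proceeds only from u_i (at the
full k_{i+1}, with the φ / 1−φ split applied to the outcome), both
pools degrade at k_{5+i}, and the observable band is u_i + m_i.
Chains are only tracked to length four, so tetra needs no split.  At
φ = 1 the capped pools receive no flux and the variant reduces
*exactly* to multi_mono (the implementation then uses the identical
six-state matrix, so the equivalence is bit-for-bit).

An earlier, simpler reconstruction of the poly variant — multiplying
the elongation constants k2–k4 by φ in the six-state chain — was
implemented and rejected.  Because φ·k = exp(log k + log φ), that
variant is an exact translation of the fitting objective in
log-parameter space; with the translated optimum still inside the
default bounds, both topologies reach the same minimum cSSD and model
comparison degenerates to sampler noise (measured: 11/20 wins for the
generating topology).  The capped-chain model is not a
reparametrization: reproducing a tri band through a φ-starved chain
would require k3 of order φ⁻² above the upper bound, so a poly fit to
multi-mono-generated data genuinely fails (measured: 20/20 wins, with
~40-fold cSSD separation).

## Solvers

`simulate` integrates the ODEs with LSODA (stiff-capable, as is
standard for chemical kinetics) at rtol 1e-10 / atol 1e-12.
`simulate_closed_form` evaluates the exact solution expm(M·t)·x(0) and
serves as an independent oracle; the two agree to better than 1e-8 on
the unit-normalized concentration scale across random networks (the
per-element *relative* error is not meaningful at the integrator's
absolute floor, so agreement is measured on the scale of C_o = 1).
Tolerances sit two decades below that bound so integration error never
dominates the comparison.

The fitting loop uses a third, much faster route (`states_at`): M is
lower triangular, so its eigenvalues are its diagonal; when they are
well separated a spectral decomposition yields all time points at once
(~50 µs per objective evaluation).  Near-degenerate spectra —
measure-zero under continuous MCMC proposals but common in hand-picked
fixtures — fall back to chained matrix-exponential propagators.  The
fast path is cross-checked against `simulate_closed_form` to 1e-10 in
the test suite.

Tiny negative excursions from the integrator are clipped to zero on
output; raw values are retained on the trajectory for diagnostics.

## Data handling

Input is long-format delimited text (`time_min, species, replicate,
intensity`) with `# key: value` header metadata carrying the parent
reference intensity.  Normalization divides by that reference (a
separate unreacted lane, not the t = 0 sample).  Replicates are
averaged per (time, species) with the sample (n−1) standard deviation;
a lone replicate yields sd = 0 plus a warning flag.  Absent cells
propagate as NaN and are skipped by the objective, never imputed.

## Fitting

The objective is the cumulative sum of squared deviations (cSSD)
between model and data over the four ubiquitinated species at every
data time point; the parent band is excluded (it is not observable in
a ubiquitin pull-down), and all cells carry equal weight (an
sd-weighted variant was deliberately not made the default, since the
objective is defined as plain squared deviations).

Rate constants are explored by random-walk Metropolis in natural-log
parameter space targeting exp(−cSSD/T):

* start: the geometric mean of the bounds (all nine coordinates);
* proposal: jointly Gaussian, sd 0.15 per log-coordinate;
* bounds: [1e-5, 1] per minute, enforced by reflection, so the chain
  can never leave the box.  The floor doubles as the resolution limit
  for unidentifiable degradation constants;
* temperature: calibrated once before the main run by doubling/halving
  until the acceptance fraction over a 100-step pilot falls in
  30–50%, then held fixed;
* estimate: the minimum-cSSD point over all evaluated proposals — the
  sampler is used as a stochastic minimizer returning a point
  estimate, which is why no credible intervals are reported;
* default 50,000 iterations (≈4 s per fit); burn-in (default 20%) and
  thinning apply only to the stored chain, not to the minimum;
* all randomness flows from one integer seed (temperature pilot and
  main chain use independent spawned streams), making fits
  reproducible bit-for-bit.

Goodness of fit is additionally scored by the sample Pearson
correlation between model and data per species; zero-variance series
raise an error rather than silently reporting 0.

Model comparison fits both topologies with the identical seed protocol
and declares the lower-cSSD topology; exact ties (guaranteed at φ = 1)
are flagged, not broken.

## The k1/k5 metric and reporting

k1/k5 compares mono-ubiquitination against parent degradation; a ratio
above 1 marks a degron favorable as a proteasome-reporter targeting
motif.  Ratios are reported to two decimals, rounded half away from
zero, and the quotient is computed in decimal arithmetic on the
printed representation of the constants so that e.g. 8.1/4.0 reports
as 2.03 (binary-float rounding would give 2.02).  Rate constants are
displayed ×10³ at the reporting boundary only; everything internal is
per-minute.  Rankings order by ratio descending with alphabetical
tie-break.

## Synthetic data generator

The generator emulates quantified fluorescence gels: the noiseless
model trajectory sampled at {10, 30, 60, 120, 180, 240} min (a
plausible grid for a 240-min endpoint assay), three replicates, and
multiplicative Gaussian noise with a 10% coefficient of variation
truncated at zero (a lognormal alternative is available for strictly
positive data).  The CV is a stand-in chosen to be realistic for gel
densitometry; real error bars for such assays are only available
graphically.  Parent reference is 1, so intensities are already on the
relative scale.  Generation parameters are embedded as header metadata
for provenance.

What the generator does *not* emulate: band overlap and migration
artifacts, molecular-weight calibration error, correlated noise within
a gel (each cell is perturbed independently), pull-down efficiency
differences between mono- and poly-ubiquitinated species, and
day-to-day lysate activity variation.  Passing recovery tests on this
generator therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to every
artifact of real gel data.

## Problem sizes used in validation

The validation suite uses 1,000 random networks for the solver
cross-check, 100 for conservation, and 20 seeded datasets × 50,000
MCMC iterations each for parameter recovery and for model
discrimination (the discrimination check fits both topologies, 40
fits).  Under these conditions the recovery run achieves a median
fitted k1 within a few percent of truth (the acceptance bound is
±20%), 20/20 correct favorable/unfavorable classifications, and 20/20
correct topology selections.

## Known limitations

* Degradation constants k6–k9 are weakly identified when the
  corresponding bands are faint; fits report whatever value the floor
  and the data allow, which is why reference tables show repeated
  floor-level entries.
* With all-zero ubiquitination data the objective becomes flat in
  k2–k4 once k1 reaches the floor; only k1 is meaningfully driven to
  the bound.
* The Metropolis minimizer reports a point estimate; uncertainty
  quantification (posterior widths, multi-chain diagnostics) is out of
  scope.
* cSSD values depend on the number of observed cells and are
  comparable across fits of the same dataset, not across datasets.
* The initial condition is fixed at pure parent (c0 = 1); absolute
  concentrations are never needed because data are normalized to the
  unreacted parent reference.
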