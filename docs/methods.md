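# Methods

## The model

Each quality attribute splits the circulating drug into an *original* and a
*modified* form. Both forms follow a two-compartment disposition model —
central (plasma, volume V) and peripheral (tissue) spaces with first-order
exchange — with elimination from the central compartment and a first-order
conversion original → modified acting in both compartments:

```
dAC0/dt   = −(kCP + ktr + kcl0)·AC0   + kPC·AP0
dAP0/dt   = −(kPC + ktr)·AP0          + kCP·AC0
dACmod/dt = −(kCP + kclmod)·ACmod     + ktr·AC0 + kPC·APmod
dAPmod/dt = −kPC·APmod                + ktr·AP0 + kCP·ACmod
```

States are amounts; observed central concentrations are amounts over V,
with V shared by both forms. An IV bolus enters the central compartment
split by the batch's initial modified fraction f: `AC0(0) = (1−f)·Dose`,
`ACmod(0) = f·Dose`, peripheral compartments empty. The conversion gain
terms in the modified-form equations (`ktr·AC0`, `ktr·AP0`) are implemented
exactly as written, i.e. conversion also operates in the peripheral
compartment; whether that is physiologically intended is unknowable from
the model statement alone, so the equations are taken verbatim.

Assumptions inherited from the modeling framework: first-order kinetics
throughout; one attribute at a time (no interactions between attributes);
distribution rates kCP, kPC identical for both forms; V identical for both
forms. Two archetypes constrain the generic model:

* **deamidation-like** — `kclmod = kcl0`. Conversion then acts as a uniform
  relabelling, so the total drug follows a plain two-compartment model and
  the central modified fraction obeys the closed form
  `1 − (1−f)·e^(−ktr·t)` regardless of the distribution rates.
* **man5-like** — `ktr = 0` with `kclmod > kcl0` free. The forms decouple
  into two independent two-compartment systems, each a biexponential
  `A·e^(−λ1 t) + B·e^(−λ2 t)` with
  `λ1,2 = ((a+b) ± √((a+b)² − 4·b·kcl))/2`, `a = kCP+kcl`, `b = kPC`,
  `A = (λ1−kPC)/(λ1−λ2)`.

Both closed forms are implemented in `pk_model` and used as oracles against
the numerical integrator (agreement ≤ 1e−6 relative on a 0–42 d grid is
asserted in the test suite).

### Reference parameter set

`reference_params()` carries the published best-fit values used throughout
as defaults and as synthetic ground truth (rates d⁻¹, V in L):

| parameter | deamidation | man5 |
|---|---|---|
| kCP | 0.17 | 0.18 |
| kPC | 0.093 | 0.096 |
| ktr | 0.01 | 0 |
| kcl0 | 0.13 | 0.127 |
| kclmod | 0.13 (= kcl0) | 0.295 |
| V | 3.34 | 3.32 |

The implied terminal half-life of total drug is ln2/λ2 ≈ 20.6 d, consistent
with the study's ~3-week scale.

## Numerical choices

* **Integrator**: LSODA (stiff-capable) at rtol 1e−10, atol 1e−13·Dose —
  tighter than needed for the data, so oracle comparisons at 1e−6–1e−8 are
  solver-noise free. The analytic eigen-solution of the linear system
  (`simulate_analytic`) is the fast path used inside fitting; tests pin it
  against the integrator.
* **AUC**: cumulative integrals of C0 and Cmod ride along as two augmented
  ODE states, so windowed AUCs carry no sampling-grid error. Day-based
  integrals are converted to the reported h×(mass/mL) units by an explicit
  ×24 at the reporting layer; all internal time is days.
* **Degenerate eigenvalues**: a repeated eigenrate (discriminant 0) is a
  measure-zero parameter set where the biexponential form breaks down; it
  raises `DegenerateEigenvaluesError` rather than returning garbage.
* **Absolute exposure scale**: the study's absolute AUC table implies a
  concentration scale (dose, V, unit bookkeeping) that cannot be fixed from
  first principles, so absolute AUCs are reported only after
  `calibrate_scale` pins one reference total AUC; relative AUCs never need
  it (dose- and V-invariance is asserted to ≤1e−8).

## Quantitation rules

* Charge states of one peptide form are summed before any ratio is formed;
  conflicting duplicate rows are rejected, not silently merged.
* Relative level = modified-form area / summed areas of all forms of the
  reporter peptide. Per time point the form percentages sum to 100 by
  construction; an all-zero denominator (pre-dose) is flagged missing (NaN),
  never imputed as 0.
* Absolute concentration = (light/heavy) × 2.5 µg / 12.5 µL → µg/mL by
  default. Zero heavy area → missing; a nonzero ratio below the
  quantitation floor (default 1e−4) → missing; a ratio of exactly 0
  (pre-dose) is a valid zero.
* Reference panel: peptides with any modified form or any nonzero pre-dose
  light signal (carryover) are excluded; the rest are ranked by median
  light intensity (ties broken lexicographically) and the top 20 averaged
  unweighted. The panel is then screened against its own provisional mean:
  peptides whose log(peptide/total) slope is below −0.01 d⁻¹ with p < 0.05
  are dropped (one-sided — rising ratios never flag). In the default
  synthetic study this removes the degrading light-chain N-terminal
  analogue, as the screen is designed to.

## Estimation

Likelihood: Gaussian, proportional error on concentrations
(sd = cv·ŷ, cv defaulting to the study's peak-area CV) and additive error
on fractions (sd default 0.01). Weights are fixed rather than profiled:
the upstream error model is known in the synthetic setting, the noise-free
objective is then exactly 0 at the truth, and duplicating the data exactly
doubles the objective. Pre-dose points carry no drug signal and are
excluded; with dose fixed at its known value, V is identified from the
concentration scale, and f is fixed to the batch's measured initial level
(it is an observable, not a parameter).

Each attribute is fitted to its reporter peptide's summed-forms absolute
concentration plus its fraction series, pooled over subjects with one
shared parameter set. Because the attribute-specific models describe the
drug independently per attribute, the reporter-derived series is the
self-consistent target; the 20-peptide panel mean remains the study-level
concentration artifact (the ELISA-comparable output).

Optimization: log-parameter space (positivity by construction), start 0 at
a data-driven center (V from the earliest concentration), subsequent starts
perturbed lognormally (σ = 1 in log space), Nelder-Mead then L-BFGS-B
polish per start, best finite optimum wins; everything is seeded and
reproducible. CV% per free parameter comes from the inverse observed
information (central-difference Hessian of the NLL at the optimum, natural
space); a seeded parametric bootstrap is the independent cross-check and
agrees within a factor of 2 on synthetic data. Constrained parameters carry
no CV of their own.

## The synthetic generator

`default_config()` encodes the emulated study: 3 subjects, one IV bolus,
11 sampling times (pre-bleed, 10 min, 1 h, 4 h, 12 h, days 2/4, weeks
1/2/3/6), a 25-peptide clean panel plus one reporter peptide per attribute,
one carryover-contaminated peptide and one terminally degrading peptide,
and four attributes with ground-truth kinetics:

* deamidation: reference parameters, f = 0.05 (level rises 5% → 38%);
* Man5: reference parameters, f = 0.03 (falls 3% → 0.6%);
* pyroGlu: deamidation-like, ktr = 0.08 d⁻¹, f = 0.96 (96% → 99.9%);
* Fc Met-ox: man5-like, kclmod = 0.15 vs kcl0 = 0.13, f = 0.085
  (8.5% → 6.8%).

The pyroGlu and Met-ox rate values are the package's own choices, fixed
once to land the trajectory endpoints the emulated study shows; they are
not fitted anywhere. Ionization factors are log-uniform in [0.3, 3] per
peptide, seeded. Noise is multiplicative lognormal on every light and heavy
area with configured CV (default 0.10), mean-1 parameterization. The heavy
calibrant is modeled as fully unmodified and 100% pure (a purity correction
is out of scope); heavy area therefore appears only on unmodified-form
rows. The default dose is 700 mg — a realistic single high IV dose that
puts light/heavy ratios at 0.05–1 against the 2.5 µg/12.5 µL calibrant,
inside the assay's demonstrated linear range. Pre-dose samples carry zero
drug light signal, so the measured fraction at t = 0 is missing by design
and f enters the fit from the batch configuration instead.

What the generator does **not** emulate: raw spectra, chromatographic or
retention-time structure, digestion artifacts, inter-subject parameter
variability (subjects share true parameters and differ only in noise,
consistent with the emulated study's observation that trajectories are
similar across patients), assay drift, and below-floor censoring beyond the
simple ratio cutoff. Passing tests therefore demonstrate correctness of the
computational chain under the declared error model, not robustness to every
real-data pathology.

## Problem sizes

The test suite and acceptance script run the clinical design itself
(11 × 3 samples per attribute). Parameter-recovery checks use 10–12 seeded
replicates per attribute with 8 optimization starts per fit — the pooled
median relative error at 10% noise is ~5%, far inside the 25% envelope, so
the reduced replicate count does not strain the conclusion. The bootstrap
cross-check uses 30 replicates at 2 warm starts.

## Known limitations

* The likelihood weights are assumed known, not estimated; with misstated
  error CVs the point estimates remain consistent but the CV% are scaled.
* The asymptotic CVs come from a fixed-weight least-squares information
  matrix; they slightly understate uncertainty relative to a full
  variance-estimating likelihood.
* Attribute models are fitted independently; joint multi-attribute models
  and attribute interactions are out of scope by design.
* Absolute AUCs are meaningful only relative to a calibrated reference;
  the package never claims an absolute concentration scale from the model
  alone.
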