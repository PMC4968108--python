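# qapk — quality-attribute pharmacokinetics for therapeutic antibodies

Therapeutic antibodies circulate as a mixture of variants: a fraction of
every dose carries post-translational modifications (PTMs) such as Fc
deamidation or high-mannose (Man5) glycans, and each variant can convert or
clear at its own rate. Standard ELISA-based pharmacokinetics (PK) sees only
total drug, so it cannot say whether a quality attribute's in vivo level is
driven by the batch's initial content or by what happens in circulation —
the question that decides how tightly that attribute must be controlled in
manufacturing.

`qapk` implements the full analysis chain for answering it from
affinity-purification LC-MS peptide-mapping data:

1. **Quantitation** (`qapk.quantitation`). Light peptides come from
   circulating drug, heavy peptides from a stable-isotope-labelled internal
   calibrant spiked into every serum sample (2.5 µg in 12.5 µL). An
   attribute's relative level is `area(modified form) / Σ area(all forms)`
   of its reporter peptide; absolute concentration is
   `(light/heavy) × calibrant amount / serum volume`. Total drug is the
   unweighted mean over a reference panel of high-intensity peptides with no
   modifications or pre-dose carryover, screened for peptides that degrade
   faster than the total drug (log-ratio slope regression).
2. **Mechanistic PK model** (`qapk.pk_model`). Original (`0`) and modified
   (`mod`) forms each follow a two-compartment model with shared
   distribution rates and an in vivo conversion `0 → mod`:

   ```
   dAC0/dt   = −(kCP + ktr + kcl0)·AC0   + kPC·AP0
   dAP0/dt   = −(kPC + ktr)·AP0          + kCP·AC0
   dACmod/dt = −(kCP + kclmod)·ACmod     + ktr·AC0 + kPC·APmod
   dAPmod/dt = −kPC·APmod                + ktr·AP0 + kCP·ACmod
   ```

   with IV-bolus initial conditions `AC0(0) = (1−f)·Dose`,
   `ACmod(0) = f·Dose` (`100·f` is the attribute's *initial level*).
   Deamidation-like attributes impose `kclmod = kcl0` (modification does not
   change clearance); Man5-like attributes impose `ktr = 0` (no formation in
   circulation). Both cases admit closed-form solutions that the package
   exposes as independent oracles.
3. **Estimation** (`qapk.estimation`). Seeded multi-start maximum
   likelihood (proportional error on concentrations, additive on fractions)
   with asymptotic and bootstrap CV%.
4. **Exposure** (`qapk.exposure`). Windowed AUCs of each form by ODE-state
   augmentation; relative AUC = attribute/total × 100% is dose- and
   volume-invariant, and initial-level sweeps map batch quality to patient
   exposure.
5. **Synthetic studies** (`qapk.synthetic`). A ground-truth-known generator
   emulating the clinical design — 3 subjects, 11 sampling times (pre-bleed
   to week 6), four attribute trajectories, lognormal peak-area noise — so
   every stage is testable without clinical data.

## Worked example

```sh
qapk simulate --attribute man5 --levels 0,3,6,14.9 --reference-total-auc 212.8 --out man5.csv
```

```
 initial_level_pct  attribute_auc  total_auc  relative_auc_pct
               0.0       0.000000 212.800000               0.0
               3.0       3.194055 209.610055               1.5
               6.0       6.388109 206.420109               3.1
              14.9      15.863805 196.956605               8.1
```

Reading: a batch with 14.9% Man5 exposes the patient to a Man5 share of
8.1% of total AUC over days 0–42, and — because the Man5 form clears 2.3×
faster than unmodified drug — total exposure drops from 212.8 to
197.0 h×mg/mL. Running the deamidation model the same way shows the
opposite regime: total AUC stays at 209.7 h×mg/mL at every initial level
(equal clearance), and doubling the initial level from 5.6% to 11.2% moves
the deamidated share only from 15.3% to 20.3%, because in vivo conversion
(ktr = 0.01 d⁻¹), not batch content, dominates.

The same results come from the library:

```python
from qapk import reference_params, relative_auc_sweep

sweep = relative_auc_sweep(reference_params("deamidation"), [0.0, 0.056, 0.112, 0.278])
print([round(s.relative_auc_pct, 1) for s in sweep])   # [10.2, 15.3, 20.3, 35.2]
```

The `analysis/` scripts run the full narrative end to end on synthetic
data — `01_generate_study.py` (study generation), `02_quantify_attributes.py`
(quantitation + degradation screen), `03_fit_pk_models.py` (model fits with
CV%), `04_simulate_exposure.py` (exposure tables and simulated PK curves) —
writing their tables under `results/`. `qapk run-all --seed 17 --out run/`
does the same through a single manifest-tracked entry point.

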