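# iasmark

Early-warning biomarkers for treatment failure under **intermittent androgen
suppression (IAS)** of advanced prostate cancer, built on an evolutionary
**cell-quota (Droop) model** of tumor dynamics.

Androgen deprivation therapy (ADT) reliably shrinks prostate tumors — until
castration-resistant clones take over. Applied past that point, the drug's
value is lost permanently. `iasmark` is for modellers and translational
researchers who want to detect *impending* resistance from routine serum
labs (PSA and androgen) collected during on/off treatment cycling, using
two per-patient indicators:

* a **model-based q2 ratio**, from sequential calibration of a mechanistic
  ODE model, and
* a **model-free androgen/PSA ratio**, computed directly from serum data.

## The model

Tumor volume is split into castration-sensitive (`x1`) and
castration-resistant (`x2`) subclones whose proliferation is gated by the
intracellular androgen quota `Q` (bound androgen receptors) relative to
each clone's minimum cell quota (`q1 > q2`):

```
dx1/dt = max{ mu (1 - q1/Q) x1, 0 } - d x1 (x1 + x2) - c K/(Q + K) x1
dx2/dt = max{ mu (1 - q2/Q) x2, 0 } - d x2 (x1 + x2) + c K/(Q + K) x1
dA/dt  = gamma1 u(t) (1 - A/A0) + gamma2 - delta A
dQ/dt  = m (A - Q) - [mu (Q - q1) x1 + mu (Q - q2) x2] / (x1 + x2)
dP/dt  = b Q + max{ sigma1 (1 - q1/Q) x1, 0 }
             + max{ sigma2 (1 - q2/Q) x2, 0 } - eps P
```

`u(t)` is 0 while ADT suppresses testicular androgen production and 1 off
treatment. PSA secretion is proportional to proliferative activity (cells
that cannot proliferate do not secrete), with a baseline term `b Q` from
healthy prostate tissue; a variant with secretion linear in tumor volume is
available via `psa_law="linear"`.

Resistance evolution appears as a **declining q2** across treatment cycles:
the resistant clone needs ever less androgen. Hence the first biomarker,
`q2(first segment) / q2(last segment)`, grows with resistance — values above
a threshold predict failure. Its model-free shadow is the mean
androgen / mean PSA ratio over the final on-treatment cycle (capped at
200 days): resistant tumors keep secreting PSA at castrate androgen, so the
ratio collapses — values below a threshold predict failure. Thresholds are
set by exhaustive accuracy maximisation ("Max") or a linear soft-margin SVM
on the 1-D biomarker, and vetted with replicated stratified 5-fold
cross-validation.

Because no clinical dataset ships with the package, a **virtual cohort
generator** produces IAS patients with a PSA-triggered on/off protocol,
responder and resistant archetypes (known per-cycle q2 ground truth),
irregular visits, multiplicative lab noise and an androgen detection floor.

## Worked example

Generate one resistant virtual patient, calibrate the model segment by
segment, and read off both biomarkers:

```python
import iasmark as im

patient = im.generate_patient(im.resistant_archetype(), seed=43, patient_id="P001")
results = im.fit_patient(patient.series)     # two-phase calibration
print(results.summary())
print(f"q2 ratio (initial/final): {im.q2_ratio(results):.2f}")
ap = im.androgen_psa_ratio(patient.series, mode="final")
print(f"androgen/PSA ratio, final on-treatment cycle: {ap.value:.3f}")
```

```
Calibration results: patient P001
  segments fitted: 7
  fixed: q1=0.62 gamma1=0.629 delta=0.0424 b=0.0001 sigma1=1 eps=0.0223
  seg  on   mu        q2        d         sigma2    objective
    0  on   0.0900    0.1438    0.1666    0.0011    0.01274
    1  off  0.0900    0.1438    0.2731    1.0000    0.1787
    2  on   0.0010    0.4100    0.1179    1.0000    0.02694
    3  off  0.0900    0.4100    0.1796    1.0000    0.2253
    4  on   0.0010    0.0766    0.0174    0.7188    0.02618
    5  off  0.0510    0.0766    0.0610    0.9996    0.3346
    6  on   0.0792    0.0451    0.0069    0.0377    0.01139

q2 ratio (initial/final): 3.19
androgen/PSA ratio, final on-treatment cycle: 0.096
```

The fitted q2 falls from 0.14 to 0.045 nmol across the record (this
patient's hidden per-cycle truth declines by a factor 0.56 per cycle), so
the q2 ratio is well above 1; the final-cycle androgen/PSA ratio of 0.096
is deep in the failure range — both indicators flag the impending failure
this archetype is constructed to suffer.

Cohort-level classification mirrors statsmodels' model/results idiom:

```python
cohort = im.generate_cohort(71, seed=1)        # 51 failures / 20 successes
# ... fit patients, collect ratios and labels ...
model = im.ThresholdModel(ratios, labels, kind="q2_ratio")
res = model.fit(method="max")                  # or "svm"
print(res.summary())                           # threshold + confusion matrix
report = res.cross_validate(k=5, replicates=100, seed=0)
```

The same steps are scriptable from the shell: `iasmark synth`,
`iasmark fit`, `iasmark biomarker`, `iasmark classify`, `iasmark simulate`
(see `iasmark --help`).

## Layout

| module | contents |
| --- | --- |
| `iasmark.model` | parameters, treatment schedules, ODE right-hand side, simulation |
| `iasmark.cohort` | patient series, cohort CSV I/O, segment extraction |
| `iasmark.calibration` | two-phase segment-wise fitting (`PatientCalibration` → `CalibrationResults`) |
| `iasmark.biomarkers` | q2 ratio, q2 trend, androgen/PSA ratio |
| `iasmark.classify` | Max/SVM thresholds, confusion metrics, cross-validation (`ThresholdModel` → `ThresholdResults`) |
| `iasmark.synth` | virtual IAS cohort generator with hidden ground truth |

See `docs/methods.md` for modelling assumptions, parameter defaults,
numerical choices and known limitations.
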