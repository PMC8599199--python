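# critattract

Tools for studying **criterion attraction** in external-noise confidence
paradigms: when observers keep separate decision/confidence criteria for two
interleaved task contexts, the two criterion sets drift toward each other,
producing large differences in reported confidence between contexts that are
matched in objective accuracy and response time.

The package is aimed at researchers in perceptual decision making and
metacognition who want to simulate, analyze, or re-analyze data from the
two-condition orientation-distribution task:

- On each trial a grating orientation is drawn from one of two overlapping
  normal distributions (D1 biased counter-clockwise, D2 clockwise) and the
  observer reports the generating distribution plus a 1–4 confidence rating.
- Two conditions alternate in 50-trial blocks: **low variability**
  (means ±2.4°, SD 6°) and **high variability** (means ±7.2°, SD 18°) — an
  exact 3× scaling, so both conditions share the same ideal decision rule
  (CW vs CCW of vertical) and the same maximum sensitivity
  d′ = 2μ/σ = 0.8.

Because the discriminated feature is physical orientation, criterion
locations can be estimated directly in stimulus space,

t_i = −½ (Φ⁻¹(HR_i) + Φ⁻¹(FAR_i)) · σ,  i = −3 … 3,

where HR_i/FAR_i are nested cumulative hit/false-alarm rates over choice ×
confidence (D2 as target) and σ is the condition's generating SD.  Absent
attraction, each confidence criterion should sit 3× further out in the
high-variability condition (r_i = t_i,high / t_i,low = 3).  The attraction
model couples the two sets through a single factor α: the low-variability
criteria move outward to α·t_i and the high-variability criteria inward to
3·t_i/α, so the realized offset is r_i = 3/α².  α = 1 means independent
criteria, α = √3 ≈ 1.732 full collapse onto one shared set.  α is estimated
per subject by maximizing the multinomial log-likelihood
Σ n_ijk · log p_ijk over the 16 response types (choice i, confidence j,
condition k), with p_ijk evaluated on the actual stimulus orientations the
subject encountered.

## Worked example

Simulate eight observers with subject-varying attraction (mean α = 1.244,
SD 0.1), estimate criteria, fit the model, and report:

```sh
critattract simulate --subjects 8 --alpha 1.244 --alpha-sd 0.1 --seed 42 --out cohort.csv
critattract analyze  --in cohort.csv --out analysis.json
critattract fit      --in cohort.csv --out fits.json --restarts 10 --seed 1
critattract report   --in cohort.csv --fits fits.json --out report.json
```

which prints

```
wrote 6400 trials (8 subjects) to cohort.csv
n=8  d' low/high = 0.877/0.881  confidence effect = 2.28 (Cohen's d)
mean fitted alpha = 1.233 over 8 subjects
confidence low/high = 1.94/2.43  mean ratios = r_-3=2.01, r_-2=2.05, r_-1=2.21, r_1=1.98, r_2=2.01, r_3=2.00
```

Read: sensitivity is matched across conditions (both near the 0.8 ceiling)
while mean confidence differs by ~0.5 points — a confidence–accuracy
dissociation.  The criterion ratios sit near 3/1.244² ≈ 1.94 rather than 3,
and the fitted attraction factor recovers the generating α.  In
`report.json`, the per-subject confidence effect correlates with fitted α
(here r = 0.98) but not with the d′ effect (r = −0.27, p = 0.52), showing
the confidence difference is driven by criterion placement, not
performance.

The same `analyze`/`fit`/`report` commands accept any trial-level CSV in
the native schema or the Confidence Database dialect
(`--dialect confidence_db`), so deposited datasets can be run through the
identical pipeline.

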