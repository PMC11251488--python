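# hdprog — modifiable factors in presymptomatic Huntington's disease

Huntington's disease (HD) is an autosomal-dominant neurodegeneration caused
by a CAG-repeat expansion in *HTT*; carriers decline over decades, and the
only factors shown to matter before symptom onset are environmental ones.
`hdprog` is an analysis pipeline for asking, on longitudinal cohort data of
presymptomatic mutation carriers: *which sociodemographic factors, health
behaviours and health-history variables are associated with the trajectory
of the composite UHDRS (cUHDRS), and how do they interact?*

It is written for biostatisticians and epidemiologists working with
Enroll-HD-style visit data. Because the real cohort is access-gated, the
package ships a calibrated synthetic-cohort generator with known ground
truth, so every stage is testable end to end.

The pipeline:

1. **Scoring** — the composite
   `cUHDRS = (TFC−10.4)/1.9 − (TMS−29.7)/14.9 + (SDMT−28.4)/11.3 + (SWR−66.1)/20.1 + 10`
   (lower = more advanced disease), per-subject change rates
   ΔcUHDRS/time, and the slow/fast decliner split at the cohort threshold
   T = |mean ΔcUHDRS/time|.
2. **Staging** — a linear mixed model fitted to family controls (random
   intercept + age slope); a carrier is presymptomatic when its baseline
   cUHDRS exceeds the lower bound of the control model's 95% prediction
   interval, `x'β − 1.96·√(x'Cov(β)x + zDz' + σ²)`; then the selection
   flowchart (complete data, above bound, no off-norm trajectory,
   ≥ 2 visits).
3. **Trajectory model** — a mixed-effects random forest (MERF):
   `y = f(x) + b0 + b1·(age−40) + ε`, alternating a regression forest on
   de-trended responses with closed-form BLUP/variance updates, monitored by
   the generalized log-likelihood.
4. **Explanation** — permutation Shapley values with exact local accuracy
   (`base + Σφ = f(x)`), mean(|φ|) importance, Monte-Carlo Shapley
   interaction values, and (stratified) partial dependence.

## Worked example

Run the numbered drivers (each writes its tables under `results/run/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_stage_presymptomatic.py
python analysis/03_decliners_table_one.py
python analysis/04_fit_merf.py
python analysis/05_explain_factors.py
python analysis/06_report.py
```

Output of a full run (seeded, so exactly reproducible):

```
simulated 4900 subjects (2600 carriers), 21843 visits -> results/run/cohort
control model: sigma2=0.250, D00=0.640, D11=0.00252
flowchart: {"missing_core_data": 0, "below_bound": 1396,
            "missing_behavior_data": 27, "off_norm_trajectory": 10,
            "single_visit": 169, "retained": 998}
threshold |mean dcUHDRS/yr| = 0.158; 521 slow, 477 fast
30 iterations; sigma2=0.211; D00=0.504
train MAE=0.325 MSE=0.166; validation MAE=0.792 MSE=0.982
SHAP base value (adjusted mean cUHDRS): 17.47
top factors by mean(|shap|):
             age: 0.470
           isced: 0.319
             cag: 0.040
PD(age): 18.14 at 18y -> 16.47 at 74y
```

Reading this: of 2,600 simulated carriers, 998 are presymptomatic survivors
of the flowchart (most exclusions are baseline scores already below the
control norm). Their mean time-adjusted decline is ≈ −0.16 cUHDRS/yr, and
the split at |−0.16| gives 521 slow vs 477 fast decliners. The MERF explains
visit-level cUHDRS to 0.33 points MAE in training and 0.79 held-out; the
variance components say ~0.5 cUHDRS² of between-subject intercept spread
remains after the fixed effects. The Shapley ranking recovers age as the
dominant factor, then education; the CAG effect is strongly attenuated in
the *staged* cohort because staging removes carriers whose decline has
started — the full-cohort recovery tests (`tests/test_acceptance.py`) show
age and CAG ranked top-2 with the age×CAG pair topping the interaction
ranking in ≥ 95% of seeded replicates. The age partial-dependence curve
falls ~1.7 points over ages 18–74 in the staged cohort.

The same stages are scriptable via the CLI (`hdprog simulate | score |
stage | fit | report`, or `hdprog run-all --seed 7 --out run/`), and the
library functions under `hdprog.*` are the API the tests exercise.

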