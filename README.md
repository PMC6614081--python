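# psyepi

Episode-of-care construction and competing-risks length-of-stay analysis for
psychiatric admission claims, with a calibrated synthetic claims generator.

## The problem

Japanese health-insurance claims record psychiatric hospitalisations as one
row per patient × hospital × ward stay. A patient transferred between
psychiatric hospitals therefore appears as two "admissions", and the
transferring hospital never observes the eventual discharge — which is
exactly how the annual facility census (the "630 survey") counts admissions
and discharges. For policy questions ("what share of newly admitted patients
return to the community within a year?") the meaningful unit is the
*admission episode*: the continuous period from admission to a psychiatric
ward (from home or a general ward) until discharge to the community, with
transfer to a general ward and in-ward death as competing risks.

`psyepi` is a tested pipeline for that analysis, aimed at epidemiologists
working with claims-style stay records:

* **episode linkage** — chains stays of one patient whose dates meet within a
  configurable gap (`gap_days=1` by default) into single episodes, and applies
  the new-admission cohort rules (prevalent-at-window-start exclusion,
  enrollment verification, exclusion of patients simultaneously present in
  two hospitals — an identification-code-error signature);
* **competing-risks estimation** — the Aalen-Johansen estimator of the
  cause-specific cumulative incidence function, written from first
  principles:

  S(t_j) = S(t_{j-1}) (1 − Σ_k d_kj / n_j),  
  CIF_k(t_j) = CIF_k(t_{j-1}) + S(t_{j-1}) d_kj / n_j,

  with administrative censoring at the earlier of the data boundary and 365
  days after admission;
* **seasonal trend** — a log-linear Poisson model with linear trend and first
  seasonal harmonic, fitted by IRLS, summarising the monthly admission series
  by its amplitude and peak calendar month;
* **aggregation** — cohort-characteristics tables, cumulative incidence by
  ward-fee type, and hospital-level 90-day discharge-rate quintiles/tertiles;
* **concordance** — prefecture-level indicators under the episode definition
  versus the single-hospital definition, compared with Pearson correlations;
* **synthetic claims generator** — emits stay records, enrollment markers
  and general-ward stays from a latent episode cohort with known
  piecewise-constant cause-specific hazards (change-points at 90/180/270
  days), seasonal admission intensity, inter-hospital transfers, a withheld
  publicly-funded subpopulation and prevalent patients, so that every
  pipeline stage can be validated against closed-form truth. A calibration
  helper inverts target cumulative-incidence profiles into hazards exactly.

## Worked example

```python
import psyepi as pe

gen = pe.GeneratorConfig(n_patients=20_000, seed=11)
episodes, log, claims = pe.synthetic_cohort(gen)   # generate → link → filter
print(log.as_frame().to_string(index=False))

d, e = pe.sample_from_episodes(episodes)
curve = pe.aalen_johansen(d, e)
for t in (90, 180, 270, 360):
    print(f"community CIF at {t:>3} d: {100 * pe.cif_at(curve, 'community', t):.1f}%")

fit = pe.fit_seasonal_poisson(
    pe.monthly_counts(episodes, (gen.window_start, gen.window_end))
)
print(f"seasonal peak month: {fit.peak_month}, amplitude: {fit.amplitude:.3f}")
```

prints

```
                           rule  count
                          input  21000
              removed_prevalent   1000
          removed_out_of_window      0
  removed_enrollment_unverified      0
removed_same_day_multi_hospital      0
                       retained  20000
community CIF at  90 d: 64.6%
community CIF at 180 d: 79.4%
community CIF at 270 d: 83.5%
community CIF at 360 d: 85.8%
seasonal peak month: 7, amplitude: 0.116
```

The 1,000 prevalent patients (already hospitalised at the window start) are
excluded by the cohort filters; the estimated cumulative incidence of
community discharge recovers the generator's calibrated profile (64.1% at 90
days, 85.7% at 360 days) within Monte-Carlo error; and the fitted seasonal
component peaks in July, matching the generator's admission intensity.

A command-line interface wraps the same pipeline:

```bash
psyepi simulate --outdir out --seed 1        # synthetic claims + full report
psyepi analyze  --outdir out2 \
    --stays out/stays.csv --enrollment out/enrollment.csv \
    --general-ward out/general_ward_stays.csv
```

Each run writes the cohort table, cumulative incidence by fee type, hospital
rate rank groups, prefecture indicator correlations, the monthly admission
series, plot-ready cumulative-incidence curves, the exclusion log, and a
manifest with the config hash — identical seeds give byte-identical bundles.

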