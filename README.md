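# hrvpipe

Heart-rate-variability (HRV) complexity analysis for two-group
longitudinal intervention trials, built for the setting of a prenatal
mind-body intervention study: two groups (intervention / control), two
visits (first / last), and begin/end 10-minute analysis windows per
recording.

The package takes raw RR-interval series (beat time + interval duration)
through:

1. **Signal preparation** — instantaneous heart rate HR = 60000/RR,
   low-pass averaging over τ = 2 s windows resampled at 20 Hz, a signal
   quality index (SQI ∈ [0, 1]) per window, and extraction of the
   begin (minutes 10–20, falling back to 20–30) and end (final 10 min,
   falling back to the penultimate 10 min) windows, excluding any window
   with SQI < 0.9.
2. **Entropy biomarkers** — Sample Entropy
   (SampEn = −ln(A/B), Chebyshev templates, m = 2, r = 0.2·SD) and the
   **entropy rate** of the smoothed HR signal X(t),

   h(τ) = H(X(t), X(t−τ)) − H(X(t−τ)) = H(X(t) | X(t−τ)),

   estimated with the Kozachenko–Leonenko k-nearest-neighbour
   differential-entropy estimator (k = 5).  Differential entropies can
   be negative; higher values mean a less predictable, more complex
   heart-rate signal.
3. **A 94-metric HRV battery** across four domains (25 temporal, 6
   frequency, 54 complexity/information, 9 specialized) with a registry
   mapping each metric to its domain, units and provenance.
4. **Harmonization** — per-metric OLS residualization on maternal age,
   gestational age and BMI, then z-scoring, validated by requiring
   |r| < 0.1 between every adjusted metric and every covariate.
5. **Timepoint-specific PCA** — a separate PCA per measurement timepoint,
   keeping the minimal set of components explaining ≥ 80% cumulative
   variance, and a **unified HRV index** = the sum of a subject's scores
   on those components; plus correlation-structure summaries and
   per-domain loading contributions.
6. **Inference** — delta (last − first) analyses with Shapiro–Wilk-gated
   one-sided t / Mann–Whitney tests, Fisher/chi-squared categorical
   tests, Cohen's d and effect-size r, random-intercept mixed models
   (`unified_hrv_index ~ group × timepoint + (1 | subject)`), and
   noncentral-t power / sample-size calculations.
7. **A synthetic cohort generator** with known ground truth (group
   baseline shift, group × time interaction, covariate slopes, latent
   factor count), so every downstream stage is testable end to end.

## Worked example

```python
import hrvpipe as hp

# a-priori design arithmetic
print(round(hp.power_two_sample(14, 0.83, 0.05), 3))          # 0.561
print(hp.sample_size_two_sample(0.83, 0.025, 0.8, "normal_approx"))  # 28

# synthetic cohort with a 1-z group-by-time complexity effect
design = hp.TrialDesign(n_per_group=14, seed=1)
truth = hp.GroundTruth(group_baseline_shift=0.5,
                       group_time_interaction=1.0,
                       latent_factor_count=3, noise_sd=0.5)
mats, cohort = hp.generate_metric_matrix(design, truth, seed=11)
long = hp.unified_index_long_table(mats, cohort)
res = hp.fit_mixed_model(long)
print(res.fixed_effects.round(3))
```

prints

```
              estimate     se  p_value
intercept       -2.561  1.964    0.204
group            5.121  2.777    0.077
time            -4.451  2.640    0.104
group_x_time     8.901  3.734    0.025
```

The `group_x_time` row is the intervention test: the designed positive
complexity interaction surfaces as a positive coefficient on the
unified index (significant in this draw; across replicates the sign is
recovered in essentially every draw and p < 0.05 in roughly three in
five at this effect size and n).

The same stages are scriptable from a shell:

```sh
hrvpipe simulate-cohort --n-per-group 14 --seed 7 --out data/
hrvpipe prep --data data/ --out prepped/ --sqi-threshold 0.9
hrvpipe entropy --windows prepped/ --out entropy.csv
hrvpipe battery --data data/ --out matrix.csv
hrvpipe power --d 0.83 --alpha 0.025 --power 0.8
```

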