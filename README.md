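# actibigram

Activity-bigram phenotyping of minute-epoch accelerometer data.

Epidemiological analyses of accelerometry usually reduce a week of
recording to a handful of summaries — mean counts per minute (mCPM) and
time spent sedentary or in moderate-vigorous activity. Those summaries
discard how activity changes from one minute to the next: two children can
spend identical total time in moderate activity while one accumulates it in
sustained blocks and the other in scattered single minutes. `actibigram`
borrows the bag-of-n-grams idea from text mining to capture exactly that
moment-to-moment structure, and provides the regression machinery to relate
it to a continuous outcome such as BMI.

## The method

1. **States.** Each 1-min epoch's activity count is categorized as
   Sedentary (0–100 counts/min), Low (101–2019), Moderate (2020–5998) or
   Vigorous (5999+). Runs of zero counts longer than 60 epochs are treated
   as non-wear and masked; participants need ≥3 days with ≥8 h wear and a
   wear-time mean ≤1500 counts/min.

2. **Bigrams.** For states A, B the bigram frequency per day over D
   recorded days is

   ```
   b(A,B) = (1/D) Σ_{i=1..n-1} 1[x_i = A ∧ x_{i+1} = B]
   ```

   Adjacent epoch pairs overlap, so the 16 bigram frequencies do not map to
   fixed amounts of time. The unordered (u-)bigram pools reciprocal
   bigrams: `bu[AB] = b(A,B) + b(B,A)` for A ≠ B, `bu[AA] = b(A,A)` — 10
   u-bigrams in all.

3. **Swap models.** A day holds a fixed budget of minutes (nd = 1440) and
   of epoch pairs (nd − 1), so one feature can only rise if others fall.
   With baseline S and comparison M states, the transfer-of-time model is

   ```
   outcome = β1·Md + β2·r + ε,     r = nd − (Md + Sd)
   ```

   and with baseline SS, comparison SL bigrams, the frequency-swap model is

   ```
   outcome = β1·b(S,L) + β2·rb + ε,  rb = (nd − 1) − b(S,L) − b(S,S)
   ```

   β1 is the outcome difference per unit transferred from baseline to
   comparison, reported ×10 or per 1 SD of the baseline feature, with 95%
   t-intervals. Exchanging baseline and comparison reparametrizes the same
   design, so the estimate negates exactly. Adjustment sets: model 1
   unadjusted; model 2 plus named confounders; model 3 additionally the
   four state durations; model 4 additionally mCPM.

4. **Synthetic cohorts.** A first-order Markov simulator generates
   count sequences whose expected bigram frequencies are known in closed
   form (π_A·P[A→B] per pair), with configurable non-wear insertion,
   confounders and a linear outcome model — so the whole pipeline is
   testable without any restricted cohort data.

## Worked example

```python
import actibigram as ab

cfg = ab.SyntheticCohortConfig(n_participants=300, seed=7)
cohort = ab.simulate_sequences(cfg)            # 300 x 7-day count series
features = ab.cohort_features(cohort)          # bigrams, u-bigrams, Sd..Vd
table = ab.simulate_outcomes(features, cfg)    # adds the BMI outcome

spec = ab.SwapModelSpec(kind="ubigram_swap", baseline="[SS]",
                        comparison="[MV]", adjustment="model1")
res = ab.fit_bigram_swap(table, spec, outcome="BMI")
print(f"beta per 10-pair swap: {res.beta_scaled:.3f} "
      f"(95% CI {res.ci_low:.3f}, {res.ci_high:.3f}), n={res.n_used}")
```

prints

```
beta per 10-pair swap: -4.327 (95% CI -7.867, -0.788), n=300
```

i.e. replacing ten sedentary-sedentary epoch pairs per day with ten
moderate↔vigorous pairs is associated with a 4.3-unit lower BMI in this
simulated cohort. The default generator also gives moderate-activity
minutes a direct effect, which the unadjusted contrast partly absorbs;
re-fitting with `adjustment="model3"` (state durations adjusted) gives
−2.887 (95% CI −8.744, 2.969) — closer to the configured direct [MV]
effect of −1.3 per 10 pairs, with the wider interval that conditioning on
correlated durations implies.

The same steps are available from the shell:

```
actibigram simulate --seed 7 --n 300 --out-counts counts.csv --out-phenotypes pheno.csv
actibigram features --counts counts.csv --out features.tsv
actibigram associate --features features.tsv --phenotypes pheno.csv --out results.tsv
actibigram run --config pipeline.yaml     # preprocess -> features -> associate
```

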