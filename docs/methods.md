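# Methods notes

This note records the modelling conventions, parameter choices and known
limitations behind `nocturne`, in the order the pipeline runs.

## Segment model and preprocessing

A nocturnal segment is the half-open window [00:00, 06:00) discretized into
72 slots of 5 minutes (slot *i* at *i*·5 min after midnight). Readings are
snapped to the nearest slot centre, ties going to the earlier slot, and
readings more than 90 s from every centre are dropped (`cadence_tol_s`);
when two readings snap to one slot the closer one wins and a warning is
logged. Input files use a plain CSV dialect
(`patient_id,timestamp,glucose_mmol_l`, ISO-8601 timestamps). Glucose
`0.0` is treated as missing — device exports zero-code dropped readings,
and 0 is below the sensor floor anyway. Values outside the device range
2.2–22.0 mmol/L are treated as missing by default (`oor_policy` can clamp
or reject instead).

Exclusion is evaluated on the raw missingness pattern *before* any filling
(imputing first would make the gap rule vacuous): a segment is dropped if
it has a run of ≥3 consecutive missing slots, or strictly more than 10% of
slots missing — with 72 slots that means ≥8, since 7 missing is 9.7% and 8
is 11.1%. Surviving gaps are then at most 2 slots long and are filled with
the arithmetic mean of the nearest observed neighbours on each side;
leading/trailing gaps copy the nearest observed value. Observed values are
never altered, and the imputation mask is kept for auditing. Excluded
segments stay in the output manifest with their reason.

Standardization is per night (not pooled per patient) and uses the
population (divide-by-n) standard deviation, so "unit variance" is exact.
A constant night (zero variance) raises an error and is flagged for manual
exclusion rather than silently dropped. No automatic outlier rule is
applied: candidate rules (e.g. extreme-change nights) were considered and
rejected because any specific choice would be arbitrary; the hook is the
exclusion manifest, which an operator can extend.

## NH detection

An NH episode is a maximal run of consecutive readings strictly below
3.9 mmol/L covering at least 15 min; at the 5-min cadence that is ≥3
readings (a 2-reading run is 10 min and does not qualify). A reading
exactly at 3.9 breaks a run, and runs are not merged across brief
recoveries — no merging rule is defensible without a clinical convention,
and the maximal-run definition is the conservative reading. Episodes may
begin at slot 0 (glucose already low at midnight). Detection runs on the
imputed mmol/L series; imputed slots count toward episodes, but episodes
touching imputed slots are flagged in the episode table. Detection never
sees standardized values.

## Clustering

Standardized series are clustered with Ward's minimum-variance criterion on
Euclidean distances (Ward requires Euclidean geometry; merge heights are
then monotone). Clustering and silhouette scores operate on standardized
series; all mmol/L summaries (initial/final glucose as means of the first/
last three readings, change = final − initial, NH start times) operate on
the original series — the two scales must not be mixed. Cluster labels are
renumbered by decreasing size so cluster 1 is always the most common
pattern. Quartiles use the linear-interpolation convention
(`numpy.percentile` default); medians and quartiles of summaries depend on
it. The medoid (member minimizing summed Euclidean distance to the rest,
ties to the lowest index) is computed in the standardized geometry used for
clustering.

k is chosen as the silhouette argmax over a scanned range, default 2–15
(wide enough to bracket both observed optima with margin); exact ties (or
scores within an optional `tie_tol`) resolve to the smaller k. Expert
judgement is replaced by an explicit, recorded override (`k_override_*`),
so a pinned k is reproducible. Points in singleton clusters score 0 by
convention. A degenerate cut that cannot produce k distinct clusters (all
merge heights tied at zero) yields silhouette NaN rather than an error.

## Monte Carlo reliability test

The null model is a single multivariate Gaussian N(E, C): E is the per-slot
sample mean vector (the only reading of "sample mean" consistent with the
dimensionality of N(E, C)), and C is Toeplitz with first row
(m₀, m₁, m₂, m₃, 0, …, 0) from the mean per-series autocovariances at lags
0–3. Retaining low-lag autocovariance makes null series serially correlated
like glucose traces; an i.i.d. null would be far too easy to beat. The test
statistic is the silhouette of the Ward partition at the same k as the real
data (one test per group at its selected k); with `n_reps` = 100 null
datasets (configurable), structure is declared reliable when the real
silhouette exceeds the 0.95 null quantile, and the empirical p-value is the
plain fraction of null scores ≥ the real score (granularity 1/n_reps; an
add-one convention was considered and rejected to keep p consistent with
the quantile rule).

Two numerical details matter:

- **Positive semi-definiteness.** The banded truncation of a valid
  autocovariance sequence need not be PSD. If the smallest eigenvalue falls
  below ε·m₀ (ε = 1e-8) the spectrum is clipped there and the matrix
  reassembled; the `psd_adjusted` flag is surfaced in every report. The
  repair perturbs the matrix by exactly the clipped eigenvalue mass in
  Frobenius norm.
- **Estimator bias.** The per-series autocovariance uses the divide-by-T
  convention with per-series mean subtraction, which shrinks every lag by
  roughly (1 − h/T)·(c(h) − Var(x̄)). Left uncorrected, the fitted null
  generates rougher series than the data and the test rejects far too often
  (we measured type-I error above 40% at n = 100 series of length 24 under
  strong correlation). `fit_null_model` therefore inverts the shrinkage by
  a short fixed-point iteration (assuming the banded structure) before
  building C. With the correction the measured type-I error is 5–8% across
  series lengths 24–72 and lag-1 correlations 0.1–0.7; a small residual
  inflation remains at extreme correlation because the correction assumes
  autocovariance vanishes beyond lag 3. The raw estimator remains available
  (`bias_correct=False`).

Null generation draws from N(E, C) with the eigendecomposition method (PSD
robust) and is reproducible from a seed. Generated null series are
clustered as-is, without re-standardizing each draw: the null already
matches the standardized data's first- and second-moment structure, and no
re-standardization step is part of the procedure being tested.

## Synthetic data generator

Each archetype is a piecewise-linear mean trajectory over the night plus
stationary AR(1) noise, clamped to [2.2, 22.0] mmol/L *after* noise
addition (mimicking sensor saturation). Noise defaults: marginal SD
0.6 mmol/L, lag-1 coefficient 0.8 — chosen so short-range serial
correlation is material (m₁/m₀ well above 0 on standardized output, which
exercises the banded null) while night-to-night spread of the 3-reading
anchor means stays near what the published quartile ranges suggest.
Missingness is injected per segment as one of three scenarios (1–2
imputable slots; a run of ≥3, excluded; ≥8 scattered, excluded) with
configurable probabilities; defaults in the worked example reproduce the
~17% exclusion rate of real sensor data. The default study recipe splits
nights 2263:256 (≈10% NH) evenly across the archetypes within each group —
per-pattern prevalences are not published, so equal within-group counts is
the neutral choice.

The 16 shipped archetypes anchor their initial/final levels (mean of slots
0–2 / 69–71) at the published per-cluster medians, and NH archetypes cross
3.9 mmol/L for ≥3 consecutive slots inside their published episode window.
Interior trajectory shapes are *not* published; they were chosen
numerically, holding anchors, NH windows and a non-NH purity floor
(trajectory ≥ 3.9 + 2.5·noise SD) fixed, to minimize pairwise cosine
similarity between standardized trajectories (max 0.38 within the non-NH
group, 0.31 within NH). The reason is geometric: per-series standardization
removes level and scale, so two patterns that differ only in level (e.g.
"stable at 6" vs "stable at 13") are *identical* directions afterwards and
no clustering method could separate them. Distinct patterns must be
distinct shape directions. The cost is realism: the generator's "stable"
patterns carry intra-night excursions of ~2 mmol/L where a clinician would
draw a flatter line. Consequently, passing recovery tests shows the
pipeline recovers planted structure of realistic amplitude and noise; it
does not show that real CGM cohorts contain structure this clean — on real
data silhouettes are far lower and expert review of the k choice remains
essential.

Within-patient correlation across nights is deliberately not modelled (the
analysis clusters nights, not patients), and the generator contains no
physiological insulin–glucose dynamics; it is a statistical emulator only.

## Problem sizes used in the checks

The test suite and the acceptance script run on simulated studies of 40
nights per archetype (400 non-NH / 240 NH series) for structure recovery
and the reliability test, 500 nights per archetype for anchor-recovery
statistics, and 200 trials of 100 series × 24 slots for type-I calibration
of the Monte Carlo test — sizes at which the targeted effects are resolved
with comfortable Monte Carlo margins.

## Known limitations

- The exclusion filter's "10% of all values" rule is hard-wired to the
  72-slot night through the segment type; other windows need a config
  change, not just a different input.
- The banded debiasing of autocovariances is approximate (it assumes the
  banded model in computing Var(x̄)); under very strong long-range
  correlation the test stays slightly anti-conservative.
- Archetype label purity is near-certain, not certain: ~1% of non-NH
  nights can cross the NH threshold by noise, which is realistic but means
  generated group sizes fluctuate around their nominal counts.
- The silhouette maximum is a blunt instrument on real data (scores near
  zero, shallow curves); the override exists precisely because automatic
  argmax selection should not be trusted unsupervised there.
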