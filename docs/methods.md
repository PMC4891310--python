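# Methods

## Statistical procedures

**Differences and orientation.** All agreement statistics work on
per-pair differences oriented reference − test (the convention of
method-comparison tables where the reference is written first);
`orientation="test_minus_ref"` flips the sign throughout. Percent
differences are taken relative to the reference reading,
100·(ref − test)/ref, because agreement "as a percentage" is
conventionally expressed against the reference method.

**Bland–Altman.** Bias = mean difference; SD uses the n−1 denominator;
limits of agreement (LoA) are bias ± 1.96·SD with 1.96 as a fixed
constant, not a t quantile — that is the standard LoA definition and the
one used in the validation literature this package serves. The 95 % CI
of the bias *does* use the t quantile (bias ± t₀.₉₇₅,ₙ₋₁·SD/√n), since
it is a genuine small-sample interval. Percentage LoA are Bland–Altman
applied to the per-pair percent differences (mean ± 1.96·SD of
100·d/ref): published percentage LoA in this literature are not
recoverable as 100·LoA/mean_ref, and the pair-level definition is the
only one consistent with expressing each pair's disagreement against
its own reference value. Zero variance is valid (LoA collapse to the
bias); fewer than 2 pairs is an error.

**Percentage error.** 100·1.96·SD(d) divided by the pooled mean
(mean_ref + mean_test)/2, with a configurable 30 % acceptability bound.
`percentage_error_from_loa` reconstructs the same quantity from a
published bias/LoA/means row using the LoA half-width as 1.96·SD, which
is how a reader audits a printed table.

**Normality gate and test pairing.** A one-sample Kolmogorov–Smirnov
test against a normal with the sample's estimated mean and SD (the
classic SPSS-style one-sample KS) at α = 0.05, applied to each monitor's
values. Both pass → paired t + Pearson; otherwise → Wilcoxon signed-rank
+ Spearman. This is the statistically standard pairing (parametric with
parametric); the gate outcome (both p values and the branch taken) is
reported so either branch is auditable. Degenerate inputs: identical
samples give KS p = 1 (no evidence against normality) and location
p = 1 on the t branch; all-zero differences on the Wilcoxon branch raise
a degenerate-test error, since the statistic is undefined there.

**Polar trending.** For each subject, changes between *consecutive
available* time points (gaps bridged) per monitor give vectors
(Δ_ref, Δ_test). With s = (Δ_ref + Δ_test)/2: points with s < 0 are
reflected through the origin (the half-circle convention), the radius is
|s| — the mean change, not the Euclidean norm, so the radius carries the
variable's units — and the angle is the vector direction minus 45°,
confined to (−90°, +90°] (an exact −90° is mapped to +90°, the same
line). The central exclusion zone is radius < fraction×(reference mean),
fraction 0.10 by default, overridable by an absolute threshold; the
boundary radius is included (exclusion is strict <) and a zero radius is
always excluded, since a null mean change carries no trend direction —
this also makes `--exclusion-fraction 0` exclude exactly the zero-radius
points. The mean angular deviation is the arithmetic mean of the signed
angles (angles live on a half-circle, so no circular mean is needed);
concordance counts |angle| ≤ 30° boundary-inclusive; good trending
requires ≥ 95 %.

**Heart-rate back-calculation.** HR = CI·1000/SVI applied to the test
monitor's CI and SVI, compared against the reference monitor's measured
HR through the same agreement machinery (variable name `hr_calc`).

## Quality control

Three rules, all *flagging* rather than deleting so decisions stay
reversible and the QC accounting reconciles exactly with the input:

- **Replicate resolution** (reference method only): the cardiac-index
  injection series is scanned in order for the first consecutive pair
  within 10 % relative discrepancy (|a−b|/pair mean — the symmetric
  denominator standard for repeatability); the summary is that pair's
  mean (all variables averaged over the same two replicates). No
  qualifying pair within `max_replicate_draws` (6) replicates →
  `replicate_unresolved`. The test monitor's summary is the plain mean
  of its first two readings, matching the protocol of simultaneous
  pulse-contour registration.
- **Systolic-pressure discrepancy**: |SBP_ref − SBP_test|/SBP_ref > 10 %
  (reference denominator, since rejection percentages are expressed
  against the reference method).
- **dP/dt resonance**: baseline test-monitor dP/dt > 1.7 flags *all* of
  that subject's samples. The rule is read as subject-level because the
  resonance concern is a property of the catheter/waveform, not of one
  time point; the flag (not deletion) keeps the narrower
  baseline-only reading reachable by filtering.

Tightening any limit can only shrink the analysis-ready set
(property-tested).

## The synthetic study generator

What it emulates: a 24-subject two-monitor study with baseline plus
15/30/60-minute post-resuscitation time points, ~50 % survival, a
reference monitor that repeats injections until two consecutive readings
agree within 10 %, and a biased, noisier, partially decorrelated test
monitor.

Structure, per subject i: baseline latent cardiac index
B_i ~ N(4.5, 1.0²) L/min/m² (resampled to stay positive; the truncation
is negligible at these settings), trajectory CI_t = B_i·m_t with
multipliers m = (1, 0.75, 0.85, 0.95) — post-arrest depression with
recovery; fixed multipliers, not a dynamical model, because only the
statistical structure matters downstream. Survival is Bernoulli(0.5);
non-survivors contribute baseline only, with no imputation.

The reference monitor observes CI_t with multiplicative log-normal noise
of CV 10 % per injection (hemodynamic quantities are positive and
CV-scaled, hence log-normal with mean exactly 1), re-injecting until two
consecutive readings agree within 10 % (up to 6). The test monitor's
latent signal is the convex mixture M = f·B_i + (1−f)·B'_i with an
independent latent draw B'_i and fidelity f = 0.3 — a dial that spans
near-zero inter-monitor correlation to perfect agreement — then scaled
(×1.0), shifted (−0.5 L/min/m², i.e. the test monitor reads low) and
observed twice with 25 % CV noise. Test CI replicates are floored at
0.01 L/min/m² (a large negative bias could otherwise produce a
non-positive reading; probability ~10⁻⁶ under defaults).

Secondary variables are internally coherent per monitor: SVI =
1000·CI/HR from the monitor's own CI and displayed HR (so back-
calculated HR recovers the display exactly), SVRI = 79.92·(0.75·SBP −
5)/CI (the resistance identity with MAP ≈ 0.75·SBP and CVP 5 mmHg), SVV
with its own noise around a N(17, 4²) latent. HR baseline N(150, 20²)
bpm with 2 % inter-monitor jitter; SBP N(90, 15²) mmHg with 4 %
per-monitor jitter, which makes the SBP rejection rule fire for roughly
8 % of pairs; dP/dt log-normal (location 0.2102, scale 0.25) placed so
~10 % of subjects exceed the 1.7 limit. These rates make both QC filters
exercise themselves at realistic frequencies without dominating the
sample.

What it does **not** emulate: arterial waveforms, thermodilution curves,
within-subject autocorrelated physiology beyond the shared latent
baseline, time-varying heart rate, or the specific 24/11/11/12
per-time-point attrition of any real cohort. Passing parameter-recovery
tests therefore shows the *statistics* are computed correctly under the
assumed error model, not that any real monitor pair behaves this way.

**Analytic expectations.** With s = test_scale, b = test_bias, f =
fidelity, and per-time-point latent mean μ_t and variance σ_t², the
population bias on the reference−test scale is (1−s)·E[L] − b and the
difference variance pools, over stratum weights (baseline 1, each
post-arrest point p_rosc), the mixture-attenuated latent spread
2(1−f)²σ_t² (at s = 1), both monitors' replicate-mean noise
(E[X²]·CV²/2 each), and any between-stratum bias heterogeneity. The
acceptance conditioning of the reference injection pair does not bias
the pair *mean* (for near-Gaussian noise the pair mean and pair
difference are nearly independent), so the closed form is accurate to
well under the test tolerances. Trending concordance has no convenient
closed form; `expected_summaries` computes it by a vectorized
high-precision simulation of the same latent/noise algebra on a fixed
internal stream, making it a property of the configuration rather than
of any dataset seed.

A deliberate numerical choice: zero-CV noise still consumes one random
draw, so configurations differing only in a noise level share aligned
random streams — monotonicity checks (e.g. percentage error
non-decreasing in test noise) then compare under common random numbers.

## Pipeline and determinism

`run_analysis` analyses five variables (ci, svi, svri, svv, hr_calc)
across overall + four time-point strata; strata with fewer than 2 pairs
(agreement) or 3 (tests) are reported as unavailable rows, never
dropped. All randomness flows from a single seed into the generator;
the analysis stages are seed-free, so identical inputs give
byte-identical report CSVs (floats written with a fixed `%.10g` format;
the run timestamp lives only in `provenance.json`). Problem sizes used
in the validation suite: 500 subjects × 20 fixed seeds for parameter
recovery, 1000 random instances for each oracle-equivalence check,
2000 subjects for the large-sample moment check.

## Known limitations

- Pooling pairs across time points ignores within-subject correlation,
  exactly as the plain Bland–Altman method does on repeated measures;
  no repeated-measures LoA adjustment is offered. Reported CIs of the
  bias are therefore anti-conservative on pooled strata.
- The published percentage bias of a study ("bias (x %)") may be either
  the mean of per-pair percent differences or a ratio of means; this
  package reports the mean of per-pair percent differences
  (`bias_pct`) and labels it as such.
- The KS normality gate with estimated moments is anti-conservative
  (Lilliefors would correct it); it is kept because it reproduces the
  SPSS-style gate used in the validation literature.
- No four-quadrant concordance plot or radial LoA bands; trending is
  summarised by the mean angular deviation and the ±30° rate.
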