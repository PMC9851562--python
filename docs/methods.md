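# Methods

`stroop-trace` re-implements, as a tested pipeline, the analysis of a
mouse-tracking colour-word Stroop experiment: participants click a start box,
a word appears in colour, and they move the cursor to one of four response
boxes (two mirrored pairs: red–green, blue–yellow). Six stimulus types span
the congruency continuum — standard colour-incongruent (SI), non-response-set
(NRS), colour-associated incongruent (AI), colour-neutral (N, the reference),
colour-associated congruent (AC) and standard colour-congruent (SC). The
pipeline produces, per measure, six marginal means and the eight Stroop
components defined as differences of those means:

```
total_stroop          = SI − SC
interference          = SI − N          facilitation          = N − SC
response_conflict     = SI − NRS        response_facilitation = AC − SC
semantic_conflict     = AI − N          semantic_facilitation = N − AC
semantic_relevance    = NRS − AI
```

Because each component is a contrast of one set of marginal means, the
telescoping identities `interference + facilitation = total_stroop`,
`response_conflict + semantic_relevance + semantic_conflict = interference`
and `response_facilitation + semantic_facilitation = facilitation` hold to
machine precision for every fitted model; the pipeline reports the residuals
as a structural self-check.

## Synthetic trajectory generator

No raw data accompany the study, so every stage is validated against a
generator with known ground truth (`stroop_trace.simulate`). One trial is a
two-attractor co-activation path sampled at 100 Hz: after an initiation dwell
(Gaussian, mean 168 ms, SD 40 ms, clipped to 60–450 ms under the 500 ms
initiation deadline), the cursor moves along

    p(s) = start + s · (T(s) − start),
    T(s) = (1 − w(s)) · correct_box + w(s) · incorrect_box,

where `s` is the fraction of movement time elapsed and the incorrect
attractor is always the mirror box of the correct one (the stimulus pairing
guarantees this symmetry). The co-activation weight holds at its initial
value `w0` until a per-trial onset fraction drawn uniformly from
[0.25, 0.60], then decays geometrically to a small terminal value (0.03
ordinary, 0.015 partial-error trials) so the movement lands in the correct
box. A pure geometric decay from `s = 0` cannot produce mid-movement
deviations of the reported size (maximum deviations of 0.4–0.7 normalized
units) without crossing onto the incorrect side on every trial; the
plateau-then-decay shape keeps the blended-attractor mechanism and yields
deviation profiles peaking a little past the middle of the movement, as
observed.

Two regimes per trial: with probability `pull_prob[condition]` the trial is a
*partial error* (`w0 = 1`: the cursor genuinely heads to the incorrect box
before a late correction, dipping to x ≈ −0.25…−0.55 in aligned units);
otherwise `w0` is drawn around `pull_amplitude[condition]` (≤ ~0.5, a
centre-biased launch that bows toward the incorrect side without materially
crossing it). The regime flag is stored on each trial (`pe_regime`) as the
ground truth for the clustering detector. Smoothed Gaussian positional noise
(SD 12 px, 9-sample moving average) is added after movement onset.

RT is realized as `(rt_base + rt_offsets[c]) · exp(b_p) · exp(e_t)` with the
participant factor `b_p` and trial factor `e_t` log-normal and mean-corrected
so that E[RT] equals the configured value exactly — the configured offsets
are therefore exact ground-truth component values. Error and omission trials
are independent Bernoulli draws (0.58% / 0.34%); omissions drift slowly and
time out at 2500 ms.

Defaults are calibrated to the published Table-1-scale conditions: 80
participants, 32 trials/condition, `rt_base` 1070 ms, offsets (+119, +41, +5,
0, −25, −41) ms, `pull_prob` set to the reported partial-error percentages
(36.7 … 22.3%), and `pull_amplitude` (0.55 … 0.38) chosen so mean maximum
deviations approximate the reported per-condition values (the generator
slightly underproduces the most extreme SI deviations; orderings and scales
are preserved). The generator does not model word frequency, associative
priming, trial-sequence effects, or velocity profiles of real reaching —
passing tests demonstrate pipeline correctness under this mechanism, not
behavioural realism.

## Preprocessing

Omissions and errors are removed first; then, within each participant ×
condition cell of *correct* trials, RTs outside the cell mean ± 3 SD
(self-inclusive, SD with ddof=1) are excluded. Cells with fewer than two
trials skip the rule and are logged. Computing the SD after error removal
prevents a wild error trial from inflating the threshold.

Alignment: if the correct box lies left of the start box, x is mirrored about
the start x (rightward remapping — for right-side trials the map is the
identity). A translation plus independent x/y scalings then sends the first
sample exactly to (0, 0) and the last to (1, 1.5). The y scale factor carries
the sign of the movement direction, so screen-pixel input (y down) comes out
with y increasing toward the boxes without a separate flip. Rotation is
deliberately not applied: the x-axis sign convention (x < 0 ⇔
incorrect-response side) requires unrotated x. Degenerate paths (zero net
displacement on an axis) raise an alignment error.

Time normalization interpolates (x, y) linearly at 101 equally spaced times
from the start-box click to the response — the pre-initiation dwell is
included, so step `s` sits at ≈ (s−1)% of the total response duration. Space
normalization resamples the polyline at 100 equal arc-length increments
(zero-length dwell segments are collapsed first). Linear interpolation is
adequate at 100 Hz; higher-order schemes change nothing at this sampling
density.

## Kinematic measures

The signed orthogonal deviation of a point q from the direct path is
`d = (p_x q_y − p_y q_x)/|p|` with `p = (1, 1.5)`; positive values lie above
the direct line, i.e. toward the incorrect-response side after remapping.
`md_above` is the maximum of d over the raw-resolution aligned path — kept
signed, so a path that never rises above the line yields md ≤ 0 rather than
being floored at zero. The 101-step profiles take d_t and x_t from the
time-normalized path; the anchors force d_1 = d_101 = 0, x_1 = 0, x_101 = 1.
Initiation time is the first sample displaced beyond a configurable threshold
(default 0 px: any movement); response time is the last sample time.

## Partial-error detection

Space-normalized trajectories, concatenated as 200-dimensional (x…, y…)
vectors, are clustered agglomeratively (Ward linkage, Euclidean distance,
k = 8 — all configurable). The published analysis identified partial-error
clusters by inspection; here the call is an explicit rule: a cluster is
partial-error iff its mean path's minimum x falls below −0.05 (i.e. the mean
movement materially enters the incorrect-response side). Raising the
threshold can only shrink the labelled set. A trial counts as a partial error
by cluster membership, even if its own path never crosses x < 0 (cluster-
level definition). Partial-error rates are percentages per participant ×
condition; empty cells are reported as missing.

## Mixed models and components

Each measure is modelled as a Gaussian linear mixed model with the five
condition dummies (colour-neutral reference) as fixed effects and
by-participant random effects: an intercept plus independent (diagonal)
random slopes for the dummies. The parsimony procedure starts from all five
slopes and repeatedly drops the smallest-variance slope while the fit is
singular (slope variance < 1e−6 × residual variance) or non-convergent, or
while a likelihood-ratio test at α = 0.20 does not support keeping it; the
intercept is always retained. With one observation per participant ×
condition cell (the partial-error rates) only the intercept is estimable and
is chosen directly. Partial-error rates are modelled as Gaussian LMMs on
percentages — faithful to the original analysis — rather than binomial GLMMs,
which would be statistically preferable but answer a different question.

Estimation is profiled REML (`stroop_trace.reml`): with
`V = σ²(I + Z diag(θ) Z′)`, β and σ² profile out and the criterion is
optimized over the variance ratios θ (bounded scalar search for the intercept
model, bounded Powell for slope models). Woodbury-reduced per-participant
sufficient statistics make one likelihood evaluation O(number of
participants), which keeps the 101-per-timecourse and replicated-study fits
fast, and the criterion stays finite on the θ = 0 boundary. The solver is
exact REML for this model family and is cross-validated against statsmodels
MixedLM in the test suite; statsmodels remains available as an alternative
backend. Exactly collinear (zero-residual) data short-circuit to OLS with
zero variances.

Marginal means are intercept/offset sums with delta-method standard errors
from the fixed-effect covariance. Confidence intervals use the normal
approximation, recorded as `df_method="normal"` on every estimate: the
backend does not provide Satterthwaite degrees of freedom, and at this
design's sizes (reported df between ~100 and ~15,000) the t-vs-z difference
is at most a few percent of the interval width. Global components use 99%
CIs (the Bonferroni-style correction for the five lower-rank comparisons);
time-course steps use 95%.

## Time courses

For each step t ∈ 1…101 of the deviation or x-coordinate profile, a mixed
model is fitted with a simplified random-structure choice: by-participant
intercept, plus the single slope for the contrasted condition when a
likelihood-ratio test at α = 0.20 supports it (for contrasts involving the
reference level, the non-reference condition's slope is used). Steps 1 and
101 are constant by construction (anchored endpoints) and are reported as
zero-width estimates; a step whose fit fails is flagged and treated as a CI
containing zero — conservative for run detection. Sustained effects are
maximal runs of steps whose 95% CI excludes zero, reported at length ≥ 10
(10% of movement duration; 5 is conventional for plotting), with no further
multiplicity correction — the run-length criterion is the correction. Peaks
are the step of maximal |estimate| for deviation and of the most negative
estimate for the x coordinate (its expected direction), ties breaking to the
earliest step.

## Validation studies and problem sizes

`stroop_trace.calibration` re-runs the full machinery on fresh simulations:

* **CI coverage** — 100 replicates at the study size (80 × 32 × 6); each RT
  component's 99% CI must cover its configured ground truth in ≥ 90
  replicates. The random structure is selected on the first replicate and
  reused; on this generator the selection is stable and re-running it per
  replicate changes nothing but runtime.
* **Null calibration** — 500 replicates of a 20-participant × 8-trial null
  simulation (all offsets and pull differences removed); 99% CIs should
  exclude zero in ≈ 1% of replicates. The binomial acceptance band is applied
  to the mean count across the eight (strongly correlated) components.
* **Run-length calibration** — 50 null replicates of the per-step analysis,
  measuring how often a spurious ≥ 10-step significant run appears. The
  per-step 95% CIs are well calibrated (≈ 4–5% of steps falsely exclude zero,
  marginally), but under this generator the measured *run* rate lands around
  10–15%, not below the 5% one might hope the heuristic buys: trajectory noise
  is strongly correlated across normalized time — a chance imbalance of
  partial-error trials between two conditions displaces the entire
  mid-movement contrast — so false exclusions arrive in blocks longer than
  10 steps more often than a step-independence intuition suggests. Requiring
  runs of more than 10 steps (≥ 11) barely changes this. The check is kept at
  the 5% level and reported as measured; the result is a caution about the
  run-length criterion itself, which trades formal family-error control for
  simplicity.
* **Detection** — on a 12-participant default simulation the labelled
  clusters must capture > 80% of ground-truth partial-error trials, and the
  detected rate must increase across pull probabilities 0.05 / 0.25 / 0.55.
* **Geometry** — the signed-deviation formula matches a brute-force
  projection oracle to 1e−9 on 1000 random polylines.

These sizes were chosen as the smallest that make each check statistically
meaningful; all are arguments, so larger studies are one call away.

## Known limitations

* The generator's trajectory mechanism is a minimal model: it reproduces RT
  shifts, mid-movement deviation peaks and partial errors, not the full
  richness of human reaching (no sub-movements, velocity asymmetries, or
  sequential effects). Its extreme-deviation tail is lighter than the
  reported data's.
* Normal-approximation CIs are very slightly anticonservative relative to
  Satterthwaite t intervals at small participant counts.
* The ≥ 10-consecutive-step criterion is a heuristic multiplicity control:
  with cross-step correlated noise its family error is measurably above the
  nominal per-step level (see the run-length calibration above). Sustained
  intervals should be read as descriptive summaries, not as tests with a
  guaranteed 5% family error.
* The partial-error labelling rule is a threshold on cluster mean paths; with
  k small or thresholds near a cluster's minimum x, labels can be sensitive
  to the clustering granularity (the original analysis faced the same issue
  by inspection).
* The 3 SD outlier rule assumes raw (not log) RTs, and omission/error
  exclusion precedes the SD computation; neither detail is fully pinned down
  in the original description.
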