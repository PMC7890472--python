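# Methods

`dyadwarp` quantifies interviewer–interviewee nonverbal coordination from
body-worn gyroscope streams and runs the statistical analyses that such a
study design calls for. This note documents the model and procedure, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Measurement model

Each interactant wears four sensors (head, torso, left and right wrist)
streaming 3-axis gyroscope readings at a nominal 120 Hz. The gyroscope
magnitude trace is treated as a concise summary of how much a body part is
moving at each instant; coordination is operationalized as the similarity in
shape of the two interactants' traces under a constrained time warp, which
tolerates the short, variable delay with which interactional mimicry occurs.

### Screening (four steps, in this order)

1. **Impossible-value removal.** Samples with any axis outside the device's
   representable range (`valid_range`, default ±500 device counts) are
   electronic recording errors — roughly 0.5% of samples — and are dropped.
2. **Alignment.** Devices do not begin recording at the same moment.
   Timestamps share the capture host's clock, so both streams of a pair are
   cut to start at the first timestamp covered by both recordings.
3. **Down-sampling to 5 frames/s.** Per-axis means over 200 ms bins keep
   the two streams on a common grid after error samples were removed.
   Bin-mean aggregation (rather than decimation) was chosen because it is
   robust to removed samples; frame k covers [t0+200k, t0+200(k+1)) ms, the
   trailing partial bin is dropped, and an interior bin emptied by error
   removal is filled by linear interpolation of its neighbours (more than
   10% empty bins is fatal). A 4 s segment at 120 Hz yields exactly 20
   frames.
4. **Standardization.** Per axis, z-scores with the sample SD (n−1),
   multiplied by 1000 and rounded to integers (half away from zero). This
   removes the placement- and mounting-dependent scale of raw device units.
   Standardization is computed per task segment, so each segment enters the
   alignment unit-scaled; per-interview standardization would differ only by
   a segment-level affine map, to which the z-scores are invariant.

The two screened streams of a pair are truncated to equal frame counts
(residual length differences after aligned capture are artifacts).

### Dynamic time warping

Coordination is measured with anchored DTW between the two standardized
(n, 3) frame sequences. The local metric is the Euclidean distance over the
three axes. Legal path moves come from the Rabiner–Juang taxonomy of local
continuity constraints (types I–VII with slope weightings a–d and optional
smoothing); the pipeline default is **type VI, weighting c, unsmoothed**
("RJ-VI-c"):

```
g[i,j] = min(
    g[i-1,j-1] + d[i,j] ,
    g[i-3,j-2] + d[i-2,j-1] + d[i-1,j] + d[i,j] ,
    g[i-2,j-3] + d[i-1,j-2] + d[i,j-1] ,
)
```

Type VI permits at most two diagonal steps followed by one horizontal or
vertical step, confining the local slope to [2/3, 3/2]. For equal-length
inputs this caps the instantaneous index offset at (L−1)/5 ≈ 0.2·L (a bound
the test suite verifies empirically); in practice measured offsets stay well
below it. The geometry is symmetric in the two sequences — it presumes no
leader and no follower. The weighting (c) assigns each elementary step its
reference-axis increment, which leaves the terminal step of the vertical
chain unweighted; as a consequence the *cost* is only approximately
swap-symmetric (median relative asymmetry ≈2% on uncoupled noise pairs,
measured in the test suite), while weighting (d) is exactly symmetric. The
engine exposes both; the default follows the VI-c recursion as tabulated.

The reported **normalized distance** divides the accumulated cost by the
number of aligned index pairs on the optimal path — the average pairwise
distance at each aligned data point. Alternative normalizations (reference
length N, query length M, N+M) are available per call. Ties between
equal-cost transitions resolve toward the diagonal, making output
deterministic. An optional Sakoe–Chiba band can be layered on top; none is
applied by default because the slope bounds already confine the path.

Correctness is pinned by `brute_force_dtw`, an independent top-down
exhaustive search over legal paths (pure Python, memoized per cell), which
the test suite compares against the dynamic-programming engine on every
pair of 1-D sequences of length ≤ 6 over the alphabet {0, 1, 2} for three
different step patterns.

### Coordination scores

A body part's score is **−1 × normalized DTW distance**, so larger (less
negative) means more coordination and 0 is the maximum. The main analysis
uses four pairings — head, torso, left↔left and right↔right wrist — and
summarizes a dyad×task by their arithmetic mean; when a part is missing
(sensor failure) the mean of the available parts is used. Cross-hand
pairings (left↔right, right↔left) are exploratory outputs and never enter
the aggregate.

## Statistical layer

* **Judgement coding.** Interviewer truthfulness ratings (1–7) code as
  correct for 5–7 on truths and 1–3 on lies; 4 is always incorrect.
* **Contingency analyses.** Pearson χ² without continuity correction
  (Yates' correction would not reproduce the printed statistics of the
  motivating study); effect size Φ / Cramér's V = √(χ²/(n·min(r−1, c−1))),
  non-negative by definition — direction is read off the table.
* **Difficulty model.** Linear mixed model of the aggregate score with a
  per-dyad random intercept (REML). Task difficulty is coded 1–4 in the
  empirically established order *easy lie < truth < difficult lie < very
  difficult lie* with equal spacing. The fit reports (a) an omnibus Wald F
  over the task levels, (b) the linear-trend slope over the numeric coding
  with its t-test, and (c) paired-t contrasts (default: each lie against
  the truth) with Cohen's d = mean(diff)/SD(diff) and a Bonferroni-corrected
  α (0.05/k, reported to 3 decimals). Denominator degrees of freedom use the
  containment rule `n_obs − n_dyads − rank(X)`; with 43 dyads contributing
  129 scores this yields the familiar F(3, 82) structure. Satterthwaite
  approximations are not offered. The effect size r for the trend is
  √(t²/(t²+df)), labelled as trend-based. Singular or non-converged fits
  are flagged, never silently accepted.
* **Suspicion model.** The same random-intercept model with a continuous
  predictor (interviewer suspicion, the inverted truthfulness rating).
* **Mixed ANOVA.** The 3 (attention instruction, between) × 3 (task,
  within) design uses the classical mixed-design decomposition with partial
  η² = SS_effect/(SS_effect+SS_error); dyads missing a task level are
  removed listwise with a warning. All p-values are two-sided.

## Synthetic dyads

The generator produces full studies — sessions, judgements and ground truth
— with the statistical structure the analysis assumes:

* **Movement kernel.** Per body site, the latent angular-velocity signal is
  a stationary Ornstein–Uhlenbeck process (mean reversion θ = 1 s⁻¹, unit
  stationary SD; exact discretization). Nothing downstream depends on this
  choice: a kernel-swap test repeats the coupling check with a smoothed
  white-noise kernel.
* **Coupling.** The interviewee's latent signal is
  κ·leader(t−τ(t)) + √(1−κ²)·independent, with lag
  τ(t) = 0.5 + 0.2·sin(2πt/60) s. The construction preserves unit variance
  for every κ ∈ [0, 1]. Default coupling by task —
  easy 0.20 < truth 0.30 < difficult 0.45 < very difficult 0.60 — encodes
  the qualitative ordering the pipeline must detect; these values are
  generator conventions, not measured quantities. A per-dyad normal shift
  on κ (SD 0.1, clipped to [0, 1]) plays the role of the random intercept.
* **Device capture.** Latent signals are scaled by 100 counts/unit and
  quantized; Gaussian sensor noise (SD 0.05 latent units) is added; each
  sample is independently replaced by an out-of-range spike with
  probability 0.005; each device starts recording with an independent delay
  of 0–1.5 s. Each simulated questioning segment lasts 30 s per task (a
  representative stationary excerpt) at 120 Hz, with 5 s pauses between
  tasks.
* **Designs.** `exp1`: every dyad provides a truth and an easy lie, half a
  difficult lie and half a very difficult lie (22/21 at n = 43), order
  counterbalanced. `exp2`: truth, easy and very difficult lie for everyone,
  with a between-dyad attention instruction allocated 12:14:16. Veracity
  judgements are drawn directly at a target coded-accuracy per task (the
  observed detection rates by default) — no psychological judgement model is
  implied; only the coding and contingency machinery needs exercising.
* **Reproducibility.** Every output is a pure function of (parameters,
  seed); per-dyad randomness derives from counter-based seed sequences, so
  enlarging a study never perturbs the dyads already generated.

What the generator does **not** emulate: gesture kinematics and posture
(the latent process is a generic smooth stationary signal, not biomechanics),
non-stationarity within a task, cross-site dependence within a person, lead
–follow asymmetry, and any relation between movement and the judgement
ratings beyond their task labels. Passing tests therefore demonstrate that
the pipeline recovers coupling structure of this linear-lagged form at
realistic noise levels — not that real interview data contain such structure.

## Problem sizes in tests and the acceptance script

Simulation-based checks use: 100 studies of 43 dyads for trend-sign
recovery; 500 studies of 12 dyads (10 s segments, head and torso) for null
calibration of the trend test (measured rejection rate 0.048); 50 dyads per
coupling level for the κ-monotonicity check; the exhaustive short-sequence
suites described above for DTW oracle equivalence. Slope recovery in the
acceptance script averages 20 replicate datasets of 40 dyads, since a single
dataset's estimate carries an SE of about 0.07.

## Known limitations

* The VI-c cost asymmetry under interactant swap (above) is inherited from
  the slope-weighting definition; use weighting d where exact symmetry is
  required.
* Containment denominator df are exact for balanced random-intercept
  designs but approximate otherwise; no Satterthwaite/Kenward–Roger option.
* The missing-part rule (mean of available parts) changes the aggregate's
  variance across dyads; no reweighting is applied.
* `brute_force_dtw` is limited to sequences of length ≤ 10 by design.
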