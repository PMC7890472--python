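# dyadwarp

Interviewer–interviewee nonverbal coordination from body-worn motion
sensors: screening, step-pattern-constrained dynamic time warping,
coordination scoring, and the associated statistics.

People in conversation coordinate their body movements, usually within a
short, variable delay. In investigative-interview research this matters
because coordination appears to *increase* with the cognitive load of the
interviewee's task (e.g. telling harder lies), making it a candidate
behavioural cue. `dyadwarp` is for researchers who record both interactants
with wearable gyroscopes (4 body sites × 2 people at ~120 Hz) and want a
reproducible path from raw streams to per-dyad coordination scores and
study-level statistics — plus a synthetic dyad generator with known ground
truth, so the entire pipeline can be exercised and validated without any
recorded data.

## Method in brief

Raw per-site gyroscope segments are screened in four steps: out-of-range
recording errors removed, the two devices' streams aligned at the first
timestamp covered by both recordings, down-sampled to 5 frames/s by 200 ms
bin means, and standardized per axis (z × 1000, integer). Each body-site
pair is then aligned by anchored dynamic time warping under the
Rabiner–Juang type VI-c step pattern, which permits at most two diagonal
steps before a horizontal or vertical one (local slope within [2/3, 3/2])
and presumes neither interactant leads. With d(i, j) the Euclidean distance
between standardized frames,

    g[i,j] = min( g[i-1,j-1] + d[i,j],
                  g[i-3,j-2] + d[i-2,j-1] + d[i-1,j] + d[i,j],
                  g[i-2,j-3] + d[i-1,j-2] + d[i,j-1] )

and the normalized distance is the accumulated cost averaged over the
aligned index pairs of the optimal path. A body part's coordination score
is −1 × that distance (higher = more coordinated); a dyad×task aggregate is
the mean of head, torso and the two same-label hand scores, using the
available parts when a sensor failed.

The statistical layer covers the study designs this measure is used in:
correct/incorrect coding of 7-point veracity judgements (5–7 correct for
truths, 1–3 for lies, 4 incorrect), Pearson χ² with Φ / Cramér's V, linear
mixed-effects models of coordination on task difficulty (random dyad
intercept, REML; difficulty ordered easy lie < truth < difficult lie < very
difficult lie) with paired contrasts and Bonferroni-corrected α, a
suspicion model, and the 3 × 3 mixed ANOVA with partial η². See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
from dyadwarp import simulate_study, score_table, fit_difficulty_model

sessions, judgements, truth = simulate_study(n_dyads=12, design="exp1", seed=42)
scores = score_table(sessions)
print(scores.head(3)[["dyad_id", "task", "head", "torso", "aggregate"]].round(1))

fit = fit_difficulty_model(scores)
print(f"omnibus F({fit.df_num},{fit.df_den}) = {fit.F:.2f}, p = {fit.p:.2g}")
print(f"linear trend: slope = {fit.slope:.1f} per difficulty step, "
      f"t({fit.slope_df}) = {fit.slope_t:.2f}, r = {fit.effect_r:.3f}")
```

Output:

```
dyad_id          task    head   torso  aggregate
dyad000         truth -1288.7 -1184.4    -1282.6
dyad000      easy_lie -1230.2 -1408.6    -1285.9
dyad000 difficult_lie -1025.9 -1068.2    -1031.8
omnibus F(3,20) = 101.46, p = 2.9e-12
linear trend: slope = 124.5 per difficulty step, t(22) = 12.41, r = 0.935
```

Scores are inverted normalized DTW distances on the z×1000 scale, so
−1283 (truth) vs −1032 (difficult lie) for `dyad000` means this dyad moved
more similarly during the harder task. The generator couples the simulated
interactants more strongly as difficulty rises, and the fitted positive
trend (≈ +125 per difficulty step, t(22) = 12.4) recovers exactly that.
Everything is reproducible from the seed.

The same pipeline is scriptable from a shell:

```sh
dyadwarp simulate --design exp1 --n 43 --seed 7 --out study/
dyadwarp score --sessions study/ --out scores.csv
dyadwarp analyze --scores scores.csv --judgements study/judgements.csv --out report.json
# or everything in one reproducible run:
dyadwarp run --seed 7 --out run/
```

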