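# Methods

## Motion metrics

A run's motion is the 6-parameter rigid-body series (3 rotations in
radians, 3 translations in mm, one row per volume). Two summaries are
derived.

**Framewise displacement (FD).** For consecutive volumes,
`FD_t = Σ_axes |Δtranslation| + r · Σ_axes |Δrotation|`, with head
radius `r = 50` mm converting angles to arc length (small-angle
approximation; `r` is configurable). The series has length `N − 1` — no
displacement is defined for the first volume — and the run mean is taken
over these `N − 1` values. Outlier flagging is strict (`FD > threshold`)
and flagged fractions are computed over the `N − 1` FD frames, not the
`N` volumes; at the 20% resting-state cap the two denominators differ by
at most one frame in ~140.

**Absolute displacement (AD).** Per volume and axis,
`AD[t, axis] = |translation[t, axis] − translation[ref, axis]|` with the
middle volume `ref = ⌊N/2⌋` (0-based) as default reference. AD is
reported per axis in mm and deliberately uses translations only;
rotations enter FD alone. Both metrics are invariant under constant
offsets of the parameters and scale linearly with motion amplitude.

Subject-level motion is the unweighted mean of run means over the
available task + resting-state fMRI runs; absent runs are excluded,
never imputed. Across-run consistency is Cronbach's alpha with runs as
items and listwise-complete subjects.

## Quality control

All thresholds are strict inequalities, exactly as the QC protocol
states them:

| rule | pass condition |
|---|---|
| task fMRI run | max per-axis AD < 3 mm |
| resting-state run | flagged-frame fraction < 20% (0.3 mm stringent / 0.5 mm lenient flags), or the 3 mm task rule |
| rated scan (T1, DTI) | Excellent/Good (stringent) or Excellent/Good/Doubtful (lenient); Failed never passes |

*Scan quantity* counts completed protocol runs, 0–9. *Scan quality*
counts included **quality units**, 0–8: the nine runs collapse to eight
units because the two DTI runs receive one joint rating. Both
denominators are protocol-driven and configurable, since the 9-run /
8-unit convention is a design choice of this protocol. A DTI unit counts
as completed only when both constituent runs were completed. The quality
*fraction* divides included by completed units and is undefined (not
zero) for children who never started.

Motion strata nest: minimal (mean FD < 0.3 mm **and** mean AD < 1 mm)
⊂ moderate (mean FD < 1 mm **and** mean AD < 3 mm) ⊂ all. Session
windows hold the first four task runs (30 min), all five task runs plus
the T1 (45 min), or all eight units (60 min); a window passes only if
every unit in it was completed and included.

## Twin statistics

Within-twin Pearson correlations are computed over (twin 1, twin 2)
ordered by birth order, one entry per pair; a double-entry intraclass
variant is available behind a flag for sensitivity checks. p-values use
the t transform with `n − 2` df. Two independent correlations are
compared with the Fisher r-to-z statistic
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`. Distress–outcome
correlation tables are flagged at the Bonferroni-adjusted level
`0.05/m` (six tests by default, adjusted α ≈ 0.0083). The
repeated-measures F for distress across the three measurement moments is
a one-way within-subject ANOVA (statsmodels `AnovaRM`) on listwise-
complete subjects, with Bonferroni-corrected paired follow-ups; data
with zero within-subject error variance raise an error rather than an
unbounded F (unless the effect is also zero, in which case F = 0).

## ACE model

Each pair is modeled bivariate normal with common mean μ and covariance
`V·[[1, ρ_g], [ρ_g, 1]]` where `V = a² + c² + e²` and
`ρ_g = (φ_g a² + c²)/V`, `φ = 1` for MZ and `0.5` for DZ pairs (shared
environment correlates at 1 in both). A single grand mean and a common
total variance are assumed across zygosity groups and birth order; the
model reports standardized shares `A² + C² + E² = 1`.

Numerics. The likelihood depends on the data only through per-group
sufficient statistics `(n, Σ(x+y), Σ(x²+y²), Σxy)`, so evaluations are
O(1); given the two group correlations, μ and V have closed-form
maximizers. The fit is deterministic multi-start: the Falconer point
(`A = 2(r_MZ − r_DZ)`, `C = 2r_DZ − r_MZ`, `E = 1 − r_MZ`, clipped to
[0, 1] and renormalized) plus four fixed simplex corners, each optimized
over unconstrained path coefficients `(a, c, e, μ)` by L-BFGS-B
(objective tolerance 1e-10), followed by a Nelder-Mead polish on the
(A², C²) simplex with μ and V profiled out. Squaring the path
coefficients enforces non-negativity without constrained optimization;
the sign ambiguity is resolved by reporting squares. E² is always
positive for data with within-pair disagreement (ρ_MZ = 1 has zero
likelihood there). Validated against a brute-force 0.005-step grid
search over the share simplex (agreement within 1e-3 whenever the ML
solution keeps E² ≥ ~0.1; nearer the boundary the *grid's* own
discretization error grows with curvature ∝ n/E⁴).

Confidence intervals are profile-likelihood: the target share is fixed,
the split of the remaining mass between the other two components is
re-optimized (1-D bounded search; μ, V closed form), and the endpoints
are where twice the log-likelihood drop crosses χ²₁(0.95) = 3.841,
clipped to [0, 1]. A share estimated at 0 reports a lower bound of
exactly 0. Monte-Carlo coverage at the study's sample size (129 MZ /
108 DZ pairs) is 94–98% across components and generating triples. A
pair-resampling bootstrap CI is available for comparison. No AE/CE/E
submodel selection is performed; the full ACE decomposition is always
reported.

Known limitation: at these sample sizes the non-negativity constraint
biases the point estimates when a true share lies on the boundary — with
a true C² = 0 the fitted C² averages ≈ +0.05 and A² correspondingly
≈ −0.06 (the unconstrained variance-component fit is unbiased, and the
constrained fit matches the likelihood grid, so this is a property of
the estimator, not of the optimizer). E² is essentially unbiased.

## Synthetic cohort generator

The generator emulates the study design end to end: `n_pairs = 256`
same-sex pairs aged 7–9, 55% MZ (`round(256·0.55) = 141` pairs, half-up),
and the fixed 9-run protocol (SNAT 148/142/141 volumes, PCG 2×136, T1,
2×DTI, resting-state 142 volumes; TR 2.2 s). All randomness flows from
one root seed through named substreams (demographics, propensity,
distress, attrition, ratings, traces), so stages are independently
reproducible and outputs are byte-identical under a fixed seed.

**Motion.** A latent *motion propensity* per child follows the ACE pair
model on the log scale (default shares 0.65/0/0.35, log-SD 1.0): motion
amplitudes are multiplied by `exp(propensity)`, which makes observed
motion non-negative and right-skewed as real summaries are. Each trace
is AR(1) jitter (coefficient 0.8; rotations scaled by the 50 mm radius
so both channels contribute equally to FD) plus a 0.01 mm/volume z
drift, plus 1 mm spikes at 0.01/frame, all linear in the amplitude.
Amplitudes grow by 10% per protocol position (children tire) and carry
per-run lognormal jitter (log-SD 0.6). These defaults were calibrated
once against the study's printed descriptives — subject mean FD ≈ 0.8 mm
with SD larger than the mean and a long right tail, mean AD ≈ 2.2 mm,
across-run alpha ≈ 0.85–0.9, motion rising over the session.

Heritability on the observed mm scale is *attenuated* relative to the
generating log-scale shares: exponentiation shrinks twin correlations
toward 0 (at log-SD 1.0, latent r_MZ = 0.65 maps to ≈ 0.51 raw), and
trace-level noise adds unique-environment variance. Pipeline-recovered
A² for raw mean AD therefore centers near 0.4–0.5, not 0.65; this is a
property of the lognormal link, not an estimation failure, and is the
main reason full-chain recovery of the latent shares at ±0.15 succeeds
only in a minority of seeds.

**Distress.** Child tension/excitement on a bounded 1–6 scale (smiley
VAS; bounds configurable since real anchors are unknown) at three
moments, with means following the study's observed trend (tension
3.84 → 3.28 → 2.62; excitement 4.72 → 5.10 → 4.95), a pair-shared trait
share of 0.3, trait–moment loading 0.7, tension–excitement correlation
−0.34, and researcher/parent ratings correlated 0.75 with the child's;
no parent rating exists after the scan (parents are absent there).

**Attrition.** Monotone dropout: a never-start probability (0.047) and
per-run hazards that jump after the anatomical scan (0.005 → 0.03), all
multiplied by `exp(0.5·z_tension)` so tense children complete fewer runs
(and, through the negative tension–excitement correlation, excited
children complete more). Structural ratings are drawn from the study's
marginal rating distributions through a probit link correlated 0.5 with
motion propensity.

**What the generator does not emulate** — and hence what passing tests
do not certify about real data: FD and AD share a single amplitude, so
their subject-level correlation is ≈ 0.99 (observed: 0.88); dropout is
strictly monotone (real children occasionally skipped DTI but completed
rest); raters are unbiased copies of the child score (real adults rate
children's tension higher); scan quantity carries no genetic component
(its twin resemblance here is purely shared-environmental via distress,
whereas the study estimated A² ≈ 0.45); and there is no physiological
noise, scanner drift or DVARS-style signal metric.

## Validation problem sizes

The validation suites use: 25 random small datasets (≤ 40 pairs) for the
grid-oracle check; 200 replicates per generating triple at 129/108 pairs
for recovery and CI coverage; randomized property checks over ~20–200
draws for metric invariances and QC monotonicity; and 50 simulated
256-pair cohorts for full-pipeline recovery (30 in the acceptance
script). These sizes give Monte-Carlo standard errors well inside the
asserted tolerances while keeping the full suite around a minute of
compute.
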