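# Methods

This note documents the statistical procedures `gelheterosis` implements, the
parameters that matter, the synthetic-data model used to validate them, and
the design choices made where more than one defensible option existed.

## The analysis

The package operates on replicate-level densitometry of 2-DE protein spots
from a classical heterosis design: inbred parent lines and their F1 hybrids
sampled at ordered developmental stages (for maize silk, days after silk
emergence), with three biological replicates per genotype × stage — each
replicate one physical gel.

### Normalization

Each gel is normalized by *total quantity in valid spots*: every spot
intensity is divided by the sum of all spot intensities on its gel and
multiplied by `ppm_scale` (default 10⁶), expressing spots in ppm of gel
volume. This removes loading and staining differences between gels. Its
premise is that the summed spot volume of a gel is biologically invariant;
this holds on real gels because differentially accumulated spots are a small
fraction of total spot volume. Per-gel sums after normalization equal
`ppm_scale` to a relative tolerance of 10⁻⁹; a gel whose total is zero is an
error, not a silent drop. This is the single normalization implemented; no
log-ratio or local-regression alternatives are offered, keeping results a
deterministic function of the inputs.

### Differential screening

Two screens, both gated on classical fixed-effects one-way ANOVA (all
replicate values enter individually, so df_within = N − k) with no
multiple-testing correction across spots — a deliberate fidelity choice to
the source procedure and a documented statistical limitation (at α = 0.05 and
hundreds of spots, dozens of false positives are expected; the fold filter
removes most of them at realistic noise levels).

* **Inbred time-course** (per genotype): a spot passes iff
  (1) the *same-trend rule* holds — the up/flat/down sign of every
  consecutive stage-to-stage change is identical in all replicates, where a
  change is flat when |Δ| ≤ `trend_epsilon` × mean of the two values
  (default 2%, preventing sign flapping from numerical noise; the source
  procedure states no tolerance);
  (2) ANOVA p < α across stages; and
  (3) max(stage means)/min(stage means) strictly exceeds `fc_inbred`
  (default 1.5).
* **Triad** (F1 vs its two parents at one stage): ANOVA p < α across the
  three genotypes and max/min of the three genotype means strictly above
  `fc_triad` (default 2). The same-trend rule does not apply here.

Fold changes are computed on group means of normalized intensities, not
per-replicate, and thresholds are strict inequalities ("more than
1.5-fold"). A spot at exactly the threshold does not pass. Missing
replicates are an input error rather than being imputed.

### Heterotic-pattern classification

For each spot, with HP/LP the larger/smaller parental mean and
MP = (mean(P1) + mean(P2))/2, three two-sided two-sample tests are run at α:
F1 replicates against (a) per-replicate mid-parent pseudovalues
(p1ᵢ + p2ᵢ)/2, (b) the HP parent's replicates, (c) the LP parent's
replicates. Testing against pseudovalues rather than the scalar MP keeps a
variance estimate on both sides of the comparison. Welch's unequal-variance t
is the default (robust with n = 3; the pooled form is available via
`equal_var=True`). The decision sequence:

1. not significant vs MP → **A** (additive);
2. significant vs HP *and* above it → **++** (over-dominant);
3. significant vs LP *and* below it → **−−** (under-dominant);
4. not significant vs HP → **+** (high-parent-like);
5. not significant vs LP → **−** (low-parent-like);
6. otherwise → **+−** (partially dominant: differs from MP, HP and LP and
   lies strictly between the parents).

Checking ++/−− before +/− makes beyond-parent calls unambiguous when the F1
differs from both MP and HP in the same direction. Ties are broken
deterministically by this listed order. When the parental means coincide
exactly, "between the parents" is empty and any significant deviation is
called ++ (above) or −− (below). Every triad with non-degenerate variance
receives exactly one label, and the label is invariant to swapping the
parent vectors.

Mid-parent heterosis of a phenotype is MPH% = 100 × (F1 − MP)/MP, reported
to one decimal.

### Phenotype statistics

Seed setting rate is filled seeds / total spikelets in the scored ear region.
(The originating study's prose describes the inverted ratio, which
contradicts every value it reports; the package computes filled/total.)
Rates are analyzed on the raw proportion scale without arcsine transform — a
documented simplification. Stage-course differences use the same one-way
ANOVA; post-hoc grouping uses Fisher's LSD with pooled MSE,
LSDᵢⱼ = t(1−α/2, df_within) · √(MSE(1/nᵢ + 1/nⱼ)) (per-pair n for unbalanced
designs), summarized as a compact letter display by the standard
descending-mean sweep: start a letter at the largest unlettered mean, extend
it to every mean within LSD, repeat. This is equivalent to exhaustive
pairwise pooled-MSE t-tests at the same α, which the test suite verifies.

## Synthetic data

The generators produce the study's structure with known truth: triads and
time-courses, three replicates, multiplicative log-normal noise
(σ_log = ln(1 + cv), so cv = 0 reproduces means exactly), seeded and fully
deterministic.

* **Triads**: parents at 100 and 300 ppm-scale units (a 3-fold parental
  effect, comfortably detectable at the default cv = 5%, n = 3); F1 placed at
  MP (A), HP (+), LP (−), 1.6 × HP (++), 0.6 × LP (−−), or midway between MP
  and HP (+−); a `null` class puts all three genotypes at the same mean for
  type-I-error measurement. The ±60% beyond-parent and midpoint placements
  are conventions chosen to be detectable at n = 3, exposed in
  `SyntheticSpec`.
* **Time-courses**: `changing` spots follow monotone geometric trends
  spanning `inbred_fold` (default 3) across the stages, alternating risers
  and fallers; `null` spots are flat.
* **Background**: every synthetic gel also carries an invariant
  high-abundance background (default 50 spots sharing a total of 5 × 10⁶),
  standing in for the bulk proteome that dominates a real gel. This is what
  makes total-quantity normalization valid: without it the planted
  differential spots would themselves move each gel's total, and
  normalization would systematically rescale F1 gels relative to parent
  gels, distorting the very effects that were planted. With the background,
  planted spots are a few percent of gel volume, as on a real gel.
* **Seed-set tables**: binomial draws of filled seeds per ear (default 10
  ears per replicate, 176 spikelets per ear ≈ 16 kernels × 11 scored
  rounds), aggregated per replicate.

What the generators do *not* emulate: spot detection/matching errors,
missing-spot dropout, spatially correlated gel artifacts, or heavy-tailed
outliers. Passing recovery tests therefore demonstrates the statistical
machinery under the stated noise model, not robustness to gel-processing
failures.

Measured under the default conditions (200 spots per class, cv 5%, n = 3,
generate → normalize → classify), per-class recovery is 93–100% for A, +, −,
++ and −− across seeds, and the null rejection rate of the screen ANOVA is
within three binomial standard errors of the nominal 5% on ~2000 null spots.
These are recomputed, not asserted, by `scripts/acceptance.py` and the test
suite.

## Numerical choices and degenerate inputs

* All-identical observations in an ANOVA give F = 0, p = 1 (no evidence of
  difference); zero within-group variance with differing means is an error.
* Two constant equal samples in a t comparison give p = 1; constant unequal
  samples are an error.
* Fold change requires strictly positive means.
* Pattern labels serialize exactly as `A`, `+`, `-`, `++`, `--`, `+-`.
* Stage order is declared by the caller, never inferred lexically
  ("D10" < "D6" as strings).
* Percentage shares are reported both as raw fractions and integers rounded
  half-up; phenotype means to one decimal.
* Reported problem sizes: the bundled pattern survey has 215 spots; synthetic
  validation uses 200 spots/class for classification recovery, 2000 null
  spots for type-I calibration, and 100 changing + 400 null spots over four
  stages for the time-course screen.

## Known limitations

* Raw per-spot p-values (no FDR control), inherited from the procedure being
  implemented.
* n = 3 gives the pattern tests little power; "similar to a parent" calls
  (+/−) are acceptances of a null at low power, and the classifier's own
  per-class misassignment rate is a few percent even at cv 5%.
* Proportions analyzed without variance-stabilizing transform.
* One intensity per biological replicate is expected; averaging technical
  replicates upstream is the caller's responsibility.
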