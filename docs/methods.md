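# Methods

## Pipeline model

An exam is a stack of 2D slices with a binary lesion mask per slice. The
pipeline maps each exam to a word over a 15-symbol action alphabet
(5 features × 3 levels), represents the word as a nil-terminated CCS prefix
process, and decides disease risk by model-checking a fixed mu-calculus
property on the process's chain LTS. There is no training step: the property
is data-independent, and classification is a purely deductive verdict.

## Feature definitions and numerical choices

**First-order.** Skewness = m₃/m₂^1.5 and kurtosis = m₄/m₂² with mₖ the k-th
central sample moment over n (population denominators). Kurtosis is
non-excess: a normal distribution scores 3. Both are invariant under
positive affine intensity maps, so they survive z-normalization unchanged.
Fewer than two values or zero variance is a degenerate-input error.

**Preprocessing.** With normalization on, a slice is z-scored over the whole
grid and then clipped to ±σ (default σ = 3). Clipping is used for outlier
handling because it is deterministic and keeps the pixel count intact; the
alternative (dropping outlier voxels) would change the sample the moments
are computed on. Resampling to the target in-plane spacing (default
0.6 × 0.6 mm) uses an order-3 spline for the image and nearest-neighbour for
the mask, which is re-binarized afterwards; there is no through-plane
resampling. The intensity-histogram bin count (default 50) is carried in
the configuration for provenance but is inert — it only affects gray-level
texture features, none of which this pipeline computes. The CSV ingestion
path bypasses preprocessing entirely: precomputed feature values are taken
as-is.

**2D shape.** The mask contour is the marching-squares isoline at 0.5 in
physical coordinates (the mask is zero-padded so boundary components close).
Mesh surface is the shoelace area of the contour polygons, summed with sign
so holes subtract; for a single pixel this gives the diamond area
d₁·d₂/2. Perimeter is the contour length measured after a light circular
moving average of the polygon vertices (window ≈ 1/32 of the vertex count,
none for short contours): the raw marching-squares polyline overstates the
length of a smooth boundary by a resolution-independent ~5–6% staircase
bias, while the smoothed estimate converges to the true perimeter as
resolution grows and leaves tiny contours exact. Sphericity is
2·sqrt(π·area)/perimeter (1 for a circle). Elongation is
sqrt(λ_minor/λ_major) of the physical-coordinate covariance of the
foreground pixel centres; a single pixel (λ_major = 0) is defined as 1,
an isotropic point. Multi-component masks are treated as a union: areas and
perimeters sum, the covariance pools all pixels.

## Discretization

Bins are equal-width over the *cohort-wide* min/max of each feature (all
slices, all patients). Per-exam bins would make levels incomparable across
patients, which a shared property cannot tolerate. Conventions, all tested:
a value equal to an interior edge falls in the upper bin; the maximum maps
to level 3; values outside a stored scheme's range are clamped (a persisted
scheme must classify unseen exams); a constant feature column is degenerate
and always maps to the basal level 2. Within a slice, actions are emitted
in the fixed order sphericity, kurtosis, skewness, elongation, meshsurface;
slices ascend by index.

## Process calculus and logic dialect

Only the action-prefix fragment of CCS is supported (prefix and nil) — the
patient models use nothing else, so choice, parallel composition and
restriction are deliberately out of scope. The concrete syntax is
CWB-flavoured (`proc NAME = a.b.….nil`, one process per line, `#`
comments) for easy diffing, and serialization is bijective on this
fragment.

The property language has tt/ff, disjunction, least fixpoints, named
acyclic macro references, and three modalities: `<a,b>φ` (existential step
over a listed action set), `<-a,b>φ` (existential step over the
complement; `<->` = any step) and `[-]φ` (universal step; `[-]ff`
characterizes deadlock). Greatest fixpoints, conjunction and negation are
rejected with explicit "unsupported" errors rather than silently
misparsed. Fixpoint-variable lookup is case-insensitive because printed
property tables bind `min x` and recurse on `X`. The lexer normalizes `∨`,
the Unicode minus and non-breaking spaces, so properties can be pasted from
typeset text.

Semantics are standard: least fixpoints by Knaster–Tarski iteration from ∅,
which on a finite LTS stabilizes in at most |states|+1 steps; iteration
monotonicity and the equivalence of `min X = φ ∨ <->X` with a direct
suffix scan on chains are property-tested, and the evaluator is checked
against two independent oracles (naive re-evaluation, and powerset
enumeration of prefixed points on tiny systems).

**Witnesses and failure notes.** A true verdict is accompanied by an action
path reconstructed by rank-restricted fixpoint unfolding (a variable
occurrence may only appeal to strictly earlier iteration stages, making the
recursion well-founded); universal obligations contribute no actions. For a
false verdict the note names the sub-property deepest in the macro graph
whose satisfying set is non-empty and the slice of its last satisfying
state — "how far the obligations got before stalling". Localization maps
each named sub-property to the slice indices owning at least one satisfying
state; a chain state belongs to the slice of the action it is about to
consume, and the final (deadlock) state to the last slice.

**The bundled property.** Entry `F0 = F1 ∨ F10`. The F1–F4 chain demands
four occurrences of the consecutive pair (high sphericity, low kurtosis);
the first two may be reached by unrestricted recursion, the last two only
through actions outside {b3of3sphericity, b1of3kurtosis} — stray pattern
actions abort the restricted phase. The F10–F14 chain interleaves
sphericity/kurtosis steps with meshsurface/elongation steps and terminates
in a basal meshsurface-or-elongation action immediately before deadlock.
One structural consequence, faithfully preserved here: with the fixed
within-slice action order, F10's third diamond expects a
meshsurface/elongation action immediately after the kurtosis action, where
a skewness action always sits, so on well-formed 5-actions-per-slice models
the F10 branch is unsatisfiable and `F0` is decided by `F1` alone. The
checker implements the written property as-is; the synthetic generator
therefore plants the F1 pattern in its satisfiers.

## Synthetic cohorts

The generator's defaults are the reference study conditions: 21 group-A and
26 group-B patients, per-group pattern rates 7/21 and 21/26, and 5–20
slices per exam (a plausible stack depth for extremity MRI; not dictated by
any data source). Satisfier flags are Bernoulli by default; with
`fixed_satisfier_counts` the counts are exactly round(p·n), which realizes
the reference confusion matrix deterministically.

Sequence-mode satisfiers embed four pattern pairs at random slice
positions, with all other slices avoiding the two pattern actions so the
restricted recursion phase stays clean wherever the pairs fall;
non-satisfiers are drawn uniformly and accepted only when the checker
rejects them (bounded rejection sampling — the property's negation has no
convenient closed form). Ground truth therefore agrees with the checker for
every generated patient, by construction and by test.

Image mode draws one centred ellipse per slice — axis ratio in [0.4, 1]
(drives elongation and sphericity), area in [50, 500] mm² (drives mesh
surface), random orientation — filled with skew-normal intensities
(location 100, scale 20, shape in [−5, 5], driving skewness and kurtosis)
over a Gaussian background (mean 60, sd 15). The nonzero background mean
emulates surrounding-tissue signal and keeps lesion intensities inside the
post-normalization clipping range, so in-mask variance survives
preprocessing. Image mode exercises extraction and the downstream stages
through known monotone relationships; it does *not* attempt to realize a
prescribed discretized pattern through images (an inverse problem), so
image-mode group labels carry no property guarantee. What passing tests on
synthetic data show is that the machinery is correct at the stated
operating points — not that the bundled property generalizes to real MRI
texture, scanner heterogeneity or irregular lesion shapes, none of which
the generator emulates.

## Metrics

Group B is the positive class. Sensitivity, specificity, accuracy, PPV and
NPV follow the usual definitions; a zero denominator marks the metric
undefined rather than raising. CUI+ = Se·PPV and CUI− = Sp·NPV are graded
excellent (≥ 0.81), good (≥ 0.64), satisfactory/fair (≥ 0.49), poor
(< 0.49), very poor (≤ 0.36); the two lowest printed bands overlap, and the
resolution here is: very poor iff ≤ 0.36, else poor — consistent with the
band ordering. Display rounding is half-up at 2 decimals (3 for CUIs); raw
values are kept. Spearman intercorrelation uses average ranks on ties;
constant columns yield undefined entries.

## Problem sizes

The bundled experiments use cohorts of 47 patients (deterministic panel)
and 470 patients (sampled rates), chain models of 25–100 actions, and
oracle cross-checks on 1000 random chains of up to 40 states with formulas
of depth up to 4 — sizes chosen so the full suite and the acceptance script
each run in well under a minute of CPU apiece while still covering every
code path at cohort scale.

## Known limitations

* Feature extraction is 2D-only by design; no texture-matrix features, no
  DICOM ingestion, no bias-field correction.
* The resampler is scipy's spline interpolation; bit-level agreement with
  other toolchains' B-spline resamplers is not a goal.
* The logic dialect covers exactly what the bundled property needs; no
  greatest fixpoints, conjunction, negation or alternation depth > 1.
* Counterexample reporting is a furthest-progress heuristic, not a full
  refutation proof object.
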