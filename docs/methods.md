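# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of quadgait. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Interlimb phase and its transformation

The phase of a step is the left limb's initial-contact time expressed as a
fraction of the enclosing right (reference) stride cycle. Strides with zero
or multiple left contacts (missed or double steps) are flagged and excluded
from phase statistics but retained in diagnostics, so the 1:1 hind:fore
step-ratio check stays meaningful. A flag swaps the moving/reference
convention.

Transformed phase is `T(φ) = max(φ, 1 − φ)`, mapping onto [0.5, 1.0]. The
mirror is the only reading of "convert values <0.5 to their counterpart
>0.5" that lands in that interval (a multiplicative reciprocal would leave
the unit interval). Conventions: `T` accepts the closed interval [0, 1]
(0 maps to 1, which is a fixed point, making `T` idempotent); φ = 0.5 maps
to itself.

Irregularity is control-referenced: pooled control transformed phases
(steps pooled across animals and control time points, not animal-weighted)
give mean and sample (n−1) SD; a step is irregular iff `T(φ)` is *strictly*
greater than mean + k·SD (k = 2 by default). A value exactly at the cutoff
is regular. Before the rule is fit, values beyond 3 SD within each time
point are removed iteratively (drop, recompute, repeat until stable).

Per-step change uses raw phases by default, `|φ_{n+1} − φ_n|` within a
pass, never across pass boundaries; a circular variant
`min(|Δ|, 1 − |Δ|)` sits behind a flag because the raw-vs-circular choice
is genuinely open — the raw default matches the linear presentation of the
change data, the circular variant is more defensible when phases wrap.

COV is per-animal: 100·SD/mean of that animal's phases across all steps in
a condition pool, then summarised as group mean ± SD. Both raw and
transformed variants are computed.

## Circular statistics

Mean direction and resultant length use the standard embedding
θ = 2πφ. The two-sample Watson U² is computed from cumulative fractions
around the circle with tie-group weighting: equal pooled values form one
group whose cumulative difference term is weighted by its multiplicity.
This reduces exactly to the classic formulation for tie-free data and
keeps the statistic well-defined for frame-rate-quantised event times. U²
is invariant (to 1e-12 numerically) under common rotation of both samples
and under sample relabelling.

The primary p-value is a seeded permutation p with the add-one convention,
`(1 + #{U*² ≥ U²}) / (1 + B)`, B = 10 000 by default; when the number of
label assignments C(n+m, n) is at most B the test switches to exact
enumeration. A significance range against the large-sample critical points
(0.152, 0.187, 0.268, 0.385 at α = 0.10, 0.05, 0.01, 0.001) is also
reported, mirroring the convention of quoting p as a range from tabulated
critical values. The standard statistic is non-negative by construction;
this package makes no attempt to reproduce published negative U² values,
which are not possible for the standard formulation.

## Proportion and association tests

The two-proportion z test uses the unpooled standard error and no
continuity correction; this reproduces the reference comparisons at their
printed precision (e.g. 3/84 vs 15/84 → z = 3.08, where the pooled variant
gives 2.99). The pooled variant is available behind a flag. Two-sided
p-values throughout. The z statistic is antisymmetric in its arguments and
undefined (raises) when both proportions sit at the same boundary.

KS comparisons delegate to `scipy.stats.ks_2samp`; Spearman correlations to
`scipy.stats.spearmanr` with R²% ≡ 100·r_s²; part correlations controlling
for speed to `pingouin.partial_corr` on animal-averaged data; prediction
intervals to statsmodels OLS `get_prediction` (95% observation intervals).
Bonferroni across the gait-parameter family is the only multiplicity
correction. Group-level ANOVA/t/Levene contracts are thin audited
delegations to scipy/pingouin and are not re-derived.

## Kinematics

Four landmarks — iliac crest (I), hip (H), ankle (A), toe (T) — define
segments I–H, H–A, A–T and two interior angles (proximal I–H–A at the hip,
distal H–A–T at the ankle), computed from arccosine of normalised segment
vectors, in degrees in (0, 180]. Analysis is in the sagittal plane; 3-D
capture is reduced to its sagittal projection, a documented
simplification. Angle computation is invariant to translation, rotation,
and uniform scaling of the coordinates; frames with a zero-length segment
are flagged invalid and skipped.

Peak detection: 5-frame moving-average smoothing then prominence-gated
extrema (default 5°), with same-sign runs merged keeping the more extreme
value so peaks and troughs strictly alternate. The smoothing and
prominence defaults are package choices; source analyses of this kind
rarely state a detector.

Intralimb phase: for each distal peak-to-peak interval containing exactly
one proximal peak, phase = (t_prox − d_k)/(d_{k+1} − d_k). Intervals with
zero or multiple proximal peaks are flagged and skipped rather than
averaged, keeping the statistic well-defined. At a 100 Hz frame rate the
quantisation of a single event is about 1% of a 0.35 s cycle; tests that
assert ±0.01 recovery of a constructed lag therefore simulate at 400 Hz.

## Gait events

Strides pair consecutive same-limb contacts: stance = liftoff − contact,
swing = next contact − liftoff, so stance + swing = stride time and
stance% + swing% = 100 hold exactly; stride length is the contact-position
difference, so speed × stride time = stride length is exact as well.
Records with liftoff at or after the next contact are rejected with a
diagnostic. Pass-level overall speed uses the right hindlimb's first/last
contacts by default (configurable). Stride intervals are half-open
`[c_k, c_{k+1})`; units are seconds and centimetres.

SSP classification is a pure function on 4-footfall windows: the six
canonical orders (alternate a/b, cruciate a/b, rotate a/b) map to their
labels; the other 18 permutations, repeated limbs, and short windows are
unclassified. The rotate orders follow the standard quadruped footfall
taxonomy, an assumption documented here because rotary patterns are rare
in normal overground stepping and their order is seldom printed. Tallying
starts each window at a forelimb footfall (subtypes are defined by the
initiating forelimb); a classified window consumes all four footfalls,
while after an unclassified window the sequence re-initiates at the next
forelimb footfall — without re-initiation a single aberrant step would
desynchronise every subsequent window. Both subtype-resolved and pooled
per-pattern percentages are emitted because the pooling convention in
published tallies is ambiguous.

## The synthetic generator

The generator's defaults are the study conditions the analysis assumes;
they are not tuned per run.

* **Phase noise** is von Mises on the circle (θ = 2πφ), the circular
  analogue of a Gaussian.
* **Control**: each animal carries a fixed lead-limb bias of magnitude
  0.06 (random sign) plus within-animal von Mises noise with κ = 21
  (circular SD ≈ 0.035 phase units). The bias structure is deliberate: the
  transformation exists precisely because animals have preferred lead
  limbs, and folding a distribution centred exactly at 0.5 would give a
  half-normal transformed distribution whose tail beyond mean + 2 SD is
  ~4.5%, incompatible with a Gaussian-style 2-SD rule. With the bias, the
  transformed phases are approximately folded-normal N(0.06, 0.035):
  analytic mean ≈ 0.561, SD ≈ 0.033, and P(T > 0.63) ≈ 0.023 — the 2-SD
  calibration the irregularity rule assumes (the tests compute these from
  simulation).
* **Silenced**: a mixture of von Mises at 0.5 with low concentration
  (κ = 1) and a synchrony component near 0/1 (stationary weight 0.2)
  arriving in persistent bouts (two-state chain, stickiness 0.7), plus a
  per-step random-walk drift (SD 0.02/step). The synchrony component is
  centred at phase 0.03 — during hopping the left limb trails the
  reference slightly — which makes hop bouts produce the
  forelimb–forelimb–hindlimb–hindlimb (cruciate) footfall order.
* **Forelimbs** use high concentration (κ = 28, bias 0.04) in both
  conditions: the modelled perturbation spares forelimb coupling.
  **Swimming** is condition-independent (κ = 10, no bias), so stroke
  alternation persists under silencing.
* **Timing/geometry**: stride time follows T(v) = 0.35 s ·(60/v)^0.4 with
  0.02 s per-step jitter (consistent stride durations), pass speeds are
  uniform on 40–100 cm/s (spanning the 90 cm/s walk–trot / gallop–bound
  boundary), contact positions advance at the pass speed exactly, stance
  occupies 55% of the stride at 40 cm/s decreasing by 0.1%/(cm/s), the
  forelimbs touch down 12 cm ahead of the hindlimbs, and a 150 cm walkway
  caps the cycles per pass (typically 5–7 at these speeds, matching the
  4–5 contiguous cycles per pass of overground tank recordings). Each limb
  receives a lead-in contact so all four limbs have equal stride counts —
  the hind:fore step ratio is exactly 1 by construction.
* **Markers** are generated at 100 Hz from smooth periodic proximal/distal
  angle templates phase-locked to each hindlimb's strides (distal peak at
  contact, proximal peak lagging by the configurable intralimb lag), with
  positions constructed so the interior angles reproduce the templates
  exactly; Gaussian position noise and a condition-dependent vertical hip
  oscillation (0.3 cm control, 0.8 cm silenced) are configurable.
* All randomness flows through one `numpy` generator per dataset, seeded
  from the config; a fixed seed reproduces tables byte-identically.

What the generator does **not** emulate: anatomical joint constraints or
skin slip, speed-dependent gait switching (the phase law does not change
with speed within a condition), exploratory pauses, asymmetric stance
between left and right, or forelimb kinematic markers. Passing tests
therefore demonstrate correctness of the analysis machinery on data with
the assumed statistical structure, not robustness to every artefact of
real video-tracked recordings.

## Problem sizes and numerical choices

Simulation-backed tests use roughly: 84–300 steps for condition contrasts
(about 6 animals × 10–14 cycles, the scale of a per-time-point pool),
1000 phases for resultant-length recovery, ~5600 steps for the tail
calibration, 2000 null replicates (199 permutations each) for Watson type-I
calibration, and 10 seeded replicates for COV ordering. These sizes give
the quoted tolerances comfortable Monte-Carlo margins while keeping the
default suite fast.

Tolerances follow the source of error: exact identities are asserted
exactly (stride identities, antisymmetry, R² = 100r²); analytic round
trips at 1e-9 to 1e-12; Monte-Carlo quantities at 2–3 standard errors of
the simulation. Permutation tests use the add-one p-value convention,
which is slightly conservative and valid at finite B.

## Known limitations

* The irregularity rule assumes the transformed control distribution is
  roughly Gaussian; heavily skewed control data would shift the effective
  false-positive rate of the 2-SD cutoff (the generator's lead-limb bias
  makes this assumption hold by design).
* Watson U² p-value ranges from asymptotic critical points are approximate
  for small samples; the permutation p is primary.
* Estimating the control cutoff and the control irregular count from the
  same sample induces a small positive bias in null condition-contrast z
  values (visible as occasional null z near 2 in small swim samples).
* The SSP window re-initiation rule is one of several defensible
  conventions; tallies are convention-dependent for disordered stepping.
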