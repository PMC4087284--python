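# Methods

## Model and assumptions

The method treats each expression profile as an ordinal object: the only
information used downstream of preprocessing is the within-sample ranking
of differential values. This buys robustness — any strictly increasing
distortion of a profile (scanner calibration, batch scaling, lab protocol)
leaves its signature and every pairwise distance unchanged, a property the
test suite asserts directly — at the cost of discarding magnitude
information.

Assumptions on the input:

- intensities are **linear-scale and strictly positive** (the differential
  transform divides by a per-probe mean; log-scale input is the user's
  responsibility to undo, and is not auto-detected);
- probes with any missing value are dropped outright rather than imputed;
- the cohort contains both phenotypes in reasonable numbers, since the
  virtual control is the plain arithmetic mean over *all* samples and the
  feature screen needs both groups.

## Procedure and numerical choices

**Differential transform.** Each profile is divided probe-wise by the
virtual control (per-probe mean over all samples). Division by a positive
per-probe constant preserves within-probe sample ordering, so the
Mann-Whitney screen gives identical results on raw and differential values
(asserted as a property test); the transform matters only for the
*within-sample* ranking that defines signatures.

**Feature screen.** Two-sided Mann-Whitney U per probe, control vs
affected, selected iff p ≤ α (inclusive; a strict-inequality mode is
provided). α defaults to 0.1 — nonstringent by design, with no
multiple-testing correction: the screen's job is to discard the diluting
mass of uninformative probes on ~1000-probe arrays, not to claim per-probe
significance. The p-value is exact when both groups have ≤ 12 untied
observations, otherwise the normal approximation with tie and continuity
corrections (scipy); both regimes are deterministic.

**Signature.** Probes ranked by descending differential value, ties broken
by ascending probe ID (deterministic and platform-independent; ties are
vanishingly rare with real-valued intensities). The signature is the first
n₁ and last n₂ IDs; n₁ + n₂ may not exceed the selected-probe count.
Defaults n₁ = n₂ = 25.

**Enrichment score.** The unweighted (Kolmogorov–Smirnov-style) running-sum
statistic: +1/m on a hit, −1/(G−m) on a miss, ES = the excursion of maximum
absolute magnitude, signed. A value-weighted variant would reintroduce
magnitude sensitivity and defeat the rank-only robustness, so it is
deliberately not offered. Implementation detail: the running sum is
evaluated only at its 2m candidate extremes (just after / just before each
hit) using integer arithmetic on the common denominator m(G−m), so results
are exact and the tie rule — return the positive excursion when magnitudes
tie exactly — is decided correctly (naive float accumulation mis-resolves
such ties; the tests compare against an exact-rational walk oracle).

**Orientation conventions.** The bottom part of a signature is scored
against the *reversed* ranking of the other sample, so concordant
under-expression contributes positively; a signature scored against its own
profile gives exactly +1 and against its mirror image −1. Similarity is
the average of the four part-scores (two parts × two directions), and
distance is the affine map d = (1 − s)/2, chosen as the simplest
order-reversing map onto [0, 1].

**Map.** The K = ⌈N/100 · n(n−1)/2⌉ smallest pairwise distances become
edges (default N = 10%; N = 20% suits small 40-sample cohorts). Ties
straddling the cutoff are resolved by lexicographic pair ID so exactly K
edges are kept. An absolute-distance threshold mode exists as an
alternative filter. Edge weight is 1 − d.

**Communities and labels.** Greedy agglomerative modularity maximization
(Clauset–Newman–Moore, networkx) on edge weights; edgeless graphs
short-circuit to singleton communities; community IDs are assigned by each
community's smallest member label so partitions are reproducible. Each
community takes the majority phenotype of its anchor (known-label)
members; an anchor tie or an anchor-free community stays unlabeled.

**Diagnosis.** A sample's neighbors vote with their phenotype labels, one
vote each, or 1/max(d, ε) votes in the weighted variant (ε = 1e−12 guards
zero distances). Strict majority wins; an exact tie or an isolated node is
an *abstention*, recorded as its own outcome but scored as an error.
Evaluation is leave-one-out: every node is diagnosed from its neighbors'
true labels with its own hidden (a node is never its own neighbor, so one
map build suffices). Sensitivity is the recall of the affected class,
specificity of the control class. The unweighted rule is the default; the
weighted rule rarely changes calls and is not invariant to monotone
distance rescaling (asserted).

**Prediction for new samples** follows the transductive protocol: the query
profiles are appended to the reference cohort, the virtual control and
feature screen are recomputed over the combined set (query samples carry no
label and do not influence the screen's test, only the control mean), the
map is rebuilt, and the query nodes are diagnosed from their labeled
neighbors. `recompute_control=False` gives a strictly inductive variant
(frozen control profile and feature set) for sklearn-style workflows where
predictions must not depend on the composition of the query batch.

## Synthetic cohorts

The generator emulates two-group miRNA cohorts: per-probe baselines drawn
log-uniformly on [100, 10000] (arbitrary intensity units, spanning the
dynamic range of bead-array scanners), a fraction `frac_diff` of probes
planted with a multiplicative `fold` effect in the affected group (half up,
half down), and i.i.d. lognormal(0, σ) noise multiplying every cell —
the natural noise model for positive intensities entering a ratio
transform. Presets:

- **zhao-like** — 1134 probes, 20 + 20 samples, frac_diff = 0.05,
  fold = 4, σ = 0.3: a clearly separable plasma-scale cohort.
- **bianchi-like** — 141 probes, 70 + 54 samples, frac_diff = 0.35,
  fold = 2.5, σ = 0.4: a harder serum-panel regime. The effect fraction
  was set so the α = 0.1 screen retains ≈ 55 of 141 probes — enough to
  carry a 25 + 25 signature on a small panel while leaving the groups
  imperfectly separated, which is the regime where the majority-vote rule
  (rather than eyeballing communities) earns its keep.

What the generator does **not** emulate: batch structure, probe-probe
correlation, platform-specific intensity distributions, or missing-value
patterns beyond what tests inject explicitly. Passing end-to-end tests
therefore demonstrate the machinery and its statistical behaviour under a
clean two-group model, not performance on any real cohort.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
the preset scales above (plus a 2000-probe null cohort for screen
calibration and exhaustive enrichment-score enumeration up to G = 7);
a full preset pipeline takes a few seconds on one core.

## Known limitations

- **Selection optimism.** The feature screen is fit on the labeled cohort
  that is subsequently mapped and scored. Under a pure null (no true
  effect) the screen retains exactly the most group-discriminating noise
  probes, so the map can reconstruct the training labels and leave-one-out
  accuracy is optimistically biased — hiding a sample's label at voting
  time does not remove it from the screen. Cohort-level accuracies from
  this protocol should be read as in-sample figures; honest generalization
  estimates require held-out queries through `predict` (or an outer
  resampling loop around the whole pipeline, which this package does not
  automate).
- The virtual control is a plain mean, so a heavily imbalanced cohort
  shifts every differential profile toward the majority group.
- No GEO/SOFT parsing: inputs are plain TSV, converted externally.
- Signature lengths are user-set; no automatic length selection.
- Map rendering is delegated to external viewers via GraphML export; the
  package computes no layout.
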