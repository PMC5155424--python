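# Methods

## Model

The package treats a subset of CYP21A2 missense variants — those with no
plausible functional mechanism other than fold destabilization — as points on
a single log-linear relation between predicted stability change and residual
enzyme activity:

    ln(activity %) = a + b · ∆∆G,    b < 0

∆∆G is the folding free-energy change of the mutant relative to wild type in
kcal/mol (positive = destabilizing), taken as the mean of replica runs of an
empirical-force-field stability predictor (canonically five replicas; the
package aggregates any count ≥ 1 and warns when it is not five). The model
assumes: (i) activity loss in this subset is mediated by the folded fraction
or cellular availability of the enzyme, so it is monotone in ∆∆G; (ii) the
assay scale saturates at both ends — activities cannot be measured below ~0%
or meaningfully above wild type.

Both saturations are handled by capping, not by changing the model:

* **Fitting cap (5.5 kcal/mol).** Mutants destabilized beyond ~5.5 kcal/mol
  all have activities indistinguishable from 0%, so their exact ∆∆G carries
  no information about the line. Before fitting, every x-value is replaced by
  min(∆∆G, 5.5). The cap does **not** apply to prediction inputs: predictions
  use the raw ∆∆G, which is why two strongly destabilized variants (e.g. 7.55
  vs 12.31 kcal/mol) still receive distinct (tiny) predicted activities.
* **Activity cap (100%).** Predictions above 100% (stabilizing ∆∆G) are
  clamped and displayed as "≥100". A large predicted stabilization is not
  interpreted as a gain of function; it can itself perturb degradation or
  dynamics, so the call is "normal-like", nothing stronger.

Zero or negative activities have no logarithm; such assay values are dropped
from fitting with a logged reason. The near-0% regime is represented through
the fitting cap instead.

## Thresholds and calls

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| destabilization threshold | 1.6 | kcal/mol | twice the stability predictor's SD (0.8); mean ∆∆G strictly above it = significantly destabilizing |
| fitting cap | 5.5 | kcal/mol | x-clamp during fitting only |
| activity cap | 100 | % | prediction clamp, displayed "≥100" |
| non-pathogenic threshold | 75 | % | predicted activity strictly above → non-pathogenic |
| severity bands | <1 / 1–5 / 10–60 / >75 | % | SW-like / SV-like / NC-like / normal-like; the gaps (5–10, 60–75) are indeterminate |

Threshold semantics are strict ("above" = `>`): a mean ∆∆G of exactly
1.6 kcal/mol is not called destabilizing, and a predicted activity of exactly
75% is not called non-pathogenic. Band edges are configurable
(`SeverityBands`); the clinical anchors are the classical genotype–phenotype
bands of 21-hydroxylase deficiency (salt-wasting ≈ complete loss,
simple-virilizing ≈ 2%, non-classical 10–60%).

## Fit diagnostics and significance

The fit is unweighted least squares of ln(activity%) on capped ∆∆G
(`scipy.stats.linregress`); R² comes from the same fit. Monotonicity is
summarised by Spearman's rank correlation with midrank ties; a constant x or
y vector returns an explicit degenerate result rather than a number.
Significance of both the correlation and the slope uses two-sided
label-permutation tests: for n ≤ 7 all n! permutations are enumerated and the
p-value is exact (#{|stat| ≥ |observed|}/n!); for larger n, `n_perm` seeded
draws (default 10,000) with the add-one estimator (1+k)/(1+N). α = 0.05 is
the conventional significance level. All sampling uses
`numpy.random.default_rng` seeded explicitly; identical inputs and seed give
identical p-values.

## Structural classification

Variant classes are assigned by a fixed precedence: truncating lesions →
low-resolution exclusions → heme/ligand contact → POR interface → degradation
motif → meander/ERR-triad motif → stability (default). Functional categories
outrank stability because their activity loss is not mediated by folding
energetics, and heme outranks POR because a cofactor contact is the stronger
functional claim. Classification is total: every parsed variant gets exactly
one class, and a missense at a position absent from the structure is excluded
with a "not resolved" tag.

Geometric conventions (all configurable in `GeometryConfig`):

* **Heme/ligand contact**: minimum heavy-atom distance from the side chain
  (Cα proxy for glycine) to the heme ∪ ligand atom set ≤ 5.0 Å, **and** the
  residue points at the group. "Pointing towards" is formalised as the
  Cα-centred angle between (Cα → side-chain centroid) and (Cα → nearest
  heme/ligand atom) being ≤ 90°; the evidence record exposes distance, angle
  and nearest atom so the rule is auditable. Distances exactly at the cutoff
  count as contact.
* **POR interface**: the nine core residues always qualify; additionally a
  charged residue (Arg/Glu) qualifies when its side chain is within 8.0 Å of
  the core set, its relative solvent exposure is ≥ 0.25, and it faces the
  same surface (positive projection of its outward vector — side-chain
  centroid minus protein centre of geometry — onto the core set's mean
  outward vector). The 8.0 Å / 0.25 values are package choices for "close
  proximity" and "exposed"; no published distance defines them.
* **Exposure** is the Shrake–Rupley accessible surface of the residue
  (computed on the whole first model, heme and ligand included, with
  Biopython) normalised by the residue type's theoretical maximum ASA (Tien
  et al. 2013) and clamped to [0, 1].
* Coordinates are used as-is: first model of multi-model files, no symmetry
  expansion. Heme heteroatom names default to {HEM}; ligand het codes are
  configuration (depositions differ for progesterone / 17-OHP).

Degradation, meander and ERR-triad positions are curated annotations, not
derivable from geometry; they are supplied as a config mapping and default to
empty sets.

## Double variants in cis

For two variants on the same allele the additive expectation is the exact sum
of the single ∆∆G means; the synergy score is `∆∆G_double − (∆∆G₁ + ∆∆G₂)`
(positive = worse than additive). `∆∆G_double` must come from an actual
combined-mutant predictor run; the package never extrapolates it. Scenarios
are assigned by a first-match cascade against the cutoff T = 1.6 kcal/mol
(documented in `classify_double`): both singles above T; rescue (≥1 single
above but the effective combined value at or below T); subthreshold synergy
(nothing above T except the combined estimate); negative/positive synergy
(sum and combined on opposite sides of T with |synergy| above the tolerance);
otherwise additive (non-)pathogenic by the effective combined value. The
published scenario descriptions do not partition the (∆∆G₁, ∆∆G₂, ∆∆G_double)
space, so the cascade order — and the rule that positive synergy with neither
single above T is reported as the subthreshold class — is a package decision
that makes classification total and mutually exclusive (property-tested on a
grid around the cutoff).

The synergy tolerance defaults to 0.8 kcal/mol — one predictor SD, half the
significance cutoff — because no published rule defines when a deviation from
additivity is meaningful; it is explicit and configurable. A "near-cutoff"
flag marks effective combined values within tolerance/2 of T (the situation
of the p.K102R + p.S268T polymorphism pair at 1.55 vs 1.6 kcal/mol).

## Reference dataset and the refit calibration

`cyp21stab.datasets` ships the published 32-variant in-silico survey (bovine
template ∆∆G and display-rounded predicted activities) and the 10-variant in
vitro validation set. The original ~30-pair training assays were never
published in full, so the original regression cannot be refit directly.
Instead, the survey's own (∆∆G, predicted activity) pairs — which lie on the
published line up to display rounding — are used: keeping activities in
[0.05, 100) and ∆∆G ≤ 5.5 (19 rows; printed "100" is cap-saturated and values
below 0.05 are rounding-degenerate, neither constrains the line) recovers
a ≈ 5.39, b ≈ −1.55. Back-predictions reproduce every printed cell at display
precision. The published R²/Spearman values of the original training fit
(0.79/−0.894 bovine, 0.60/−0.829 human) are not reproducible without those
unpublished pairs and are not claimed; the statistical machinery is instead
verified against independent brute-force oracles.

Display convention for activities: one decimal ≥ 0.1, two decimals < 0.1,
exact integers bare, "≥100" for capped — matching the mixed precision of the
published tables.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (parameters, seed) and exist so every
stage is testable offline:

* **Calibration pairs**: ∆∆G uniform on (−2, 10) kcal/mol (the span observed
  across the reference tables), activity = exp(a + b·∆∆G + ε) with ε ~
  N(0, 0.35²) by default (a = 5.35, b = −1.53, near the refit line; the
  0.35 ln-units scatter is cosmetic realism, not an inference target).
  Activities above 100% are clamped and flagged capped — censored, like a
  wild-type-level assay readout. Parameter-recovery tests fit only the
  uncensored pairs with ∆∆G within the fitting cap, mirroring the real
  fit-set construction.
* **Replicas**: N(true ∆∆G, 0.8²), five by default.
* **Toy structures**: minimal PDB files with a seven-atom heme proxy at the
  origin and residues whose three-atom side-chain proxies sit at requested
  distances, pointing towards or away from the heme (Cα placed behind or in
  front of the side chain). The construction is verified numerically at
  generation time (±0.01 Å) and infeasible placements raise. These fixtures
  make predicate truth values controllable; they are not physically
  realistic proteins — no rotamers, no packing, no secondary structure — so
  geometric tests certify the predicates, not biological accuracy on real
  structures.
* **Double-variant sets**: each scenario's region of ∆∆G-triple space is
  parameterised directly (rejection-free); the classifier recovers the
  requested scenario for every generated record.

Consequently, passing tests demonstrate correctness of the arithmetic,
geometry and decision rules under the stated conventions — not the biological
validity of the stability→activity hypothesis on unseen real variants.

## Numerical choices and degenerate inputs

* Sample (n−1) standard deviation for replica aggregation; SD = 0 for a
  single replica. Published "±" values do not state their convention.
* Fit requires ≥ 3 pairs and at least two distinct x-values; otherwise a
  `CalibrationError`.
* Equality at boundaries: distance ≤ cutoff is a contact; ∆∆G > threshold is
  destabilizing; activity > 75% is non-pathogenic.
* Permutation comparisons use |stat| ≥ |observed| − 1e-12 to absorb float
  noise in rank arithmetic.
* Duplicate variant+substrate table rows: last wins, logged.
* A structure without heme heteroatoms is usable; heme predicates answer
  False with a logged warning. Residues lacking side-chain atoms (other than
  glycine, which uses its Cα) raise on geometric queries rather than guess.
* The protein-length bound on variant positions defaults to 495 (the
  reference protein is 494–495 residues depending on isoform convention) and
  is configurable.
* All CLI randomness derives from one top-level `--seed`; per-stage sub-seeds
  are the first four bytes of SHA-256(seed:stage), keeping every derived seed
  below 2³¹.

## Problem sizes

Default test and acceptance runs are desk-scale: the 19-pair refit with
10,000-draw permutation tests, synthetic fits up to n = 1000, exhaustive
permutation enumeration up to n = 7 (5040 permutations), toy structures of a
handful of residues. All complete in seconds to a few minutes on one CPU.

## Known limitations

* The calibration transfers a template-specific fit; ∆∆G values from a
  different predictor, force field or template need refitting.
* Only missense stability effects are modelled; catalytic, membrane-anchor,
  splicing and expression effects are out of reach by design, as are
  homology-model building and predictor execution.
* The severity bands overlap clinically; band calls are heuristics around the
  published genotype–phenotype anchors, not diagnoses.
* PDB input only (no mmCIF); protein-level variant labels only (no
  genomic/cDNA HGVS — such strings are carried as opaque annotations).
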