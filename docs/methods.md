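# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `colpep`.

## Data model and conventions

A *peptide record* is a modified-sequence string (uppercase residues;
lowercase `p` = hydroxyproline, `m` = methionine sulfoxide) plus a sparse
map participant → signal amplitude. An amplitude of exactly zero, a blank
cell, or a missing key all mean *not detected*: CE-MS reports only
detected signals, and the detection frequency (number of participants
with signal) is a first-class quantity — peptides detected in fewer than
`min_frequency` (default 100) participants are dropped before any
analysis. Stored intensities are therefore strictly positive by
invariant.

Coordinates are 1-based and inclusive on the full precursor everywhere in
the API; only the BED export uses 0-based half-open intervals (the BED
convention). The default region annotation is the collagen alpha-1(I)
precursor layout: signal peptide 1–22, N-propeptide 23–161, mature chain
162–1218, C-propeptide 1219–1464.

## Hydroxyproline-variant consolidation

Variants sharing one backbone are candidates for aggregation because
proline hydroxylation is not expected to change the abundance of the
underlying degradation fragment. The decision is empirical: pairwise
Spearman ρ between variant intensity vectors, merge threshold 0.5.

* **Merge-set selection.** With more than two variants the all-pairs
  condition defines a clique problem. The implementation builds the
  clique greedily: seed with the most frequent variant, then add variants
  in decreasing frequency while every pair stays at or above the
  threshold. This is deterministic and favours well-observed variants;
  it is not guaranteed to be the maximum clique, which matters only for
  groups ≥ 4 variants with borderline correlation structure.
* **Aggregation.** Default is the participant-wise *sum* of detected
  intensities (absent = 0 within the merge set): the merged entity
  represents total abundance of the backbone across hydroxylation
  states. A mean aggregate is available by configuration.
* **Unmerged groups.** When no clique of size ≥ 2 exists, the single
  most frequent variant represents the backbone. Ties are broken by
  higher total summed intensity, then lexicographically smaller modified
  sequence, making output order-invariant.
* **Undefined correlations** (fewer than 3 usable paired observations,
  or a constant vector) count as below threshold — conservative
  non-merging.

The consolidation report records every stage count (inputs, singleton /
multi-variant split, merged peptides and sequences, discarded
group-mates, representatives, final total), and the partition invariant —
every input peptide lands in exactly one of those bins — is asserted in
the test suite.

The Δ-PTM profile takes all unordered variant pairs within multi-variant
groups (pairs with equal hydroxyproline counts are excluded) and
summarises ρ per count difference by n, median and quartiles.

## Association screen

Spearman's ρ with average ranks on ties; p-values from the
t-distribution approximation (adequate for the cohort sizes this package
targets; at n in the thousands the exact permutation null is
indistinguishable). One Benjamini–Hochberg family per covariate run, over
exactly the peptides with defined ρ — undefined peptides are excluded
*before* adjustment so the family size reflects testable peptides.
Classes: `strong_pos` iff adjusted p < α and ρ > +0.3; `strong_neg`
symmetric; otherwise `significant_moderate` when adjusted p < α;
otherwise `not_significant` (significance gates strength). Top-k ranking
orders by |ρ| descending, then adjusted p ascending, then sequence.

**Missing-data policy.** The default `zero_fill` scores undetected
intensities as 0, i.e. the tied lowest rank: detection in CE-MS is
abundance-dependent, so absence is informative, and discarding it would
bias associations toward the well-detected stratum. `complete_case` is
provided for sensitivity analysis. This is the single largest judgment
call in the package; it is surfaced in the configuration rather than
buried in code.

## Age/eGFR disentanglement

* **Age-corrected eGFR**: `egfr + slope · max(0, age − onset)` with
  defaults slope = 1 mL/min/1.73 m² per year, onset = 30 years — the
  standard assumption of physiological GFR loss. Continuous in age,
  identity below the onset.
* **Age bins**: <30, 30–40, …, >70; interior bins left-closed/right-open
  (40.0 → "40–50"; the convention is configurable and documented because
  no universal standard exists).
* **Matching**: the reference bin is the smallest (ties: youngest);
  `n_per_bin` (default 160) members are drawn uniformly (seeded), then
  walked in ascending eGFR, each matched in every other bin to the unused
  member with minimal |ΔeGFR| (ties: smaller id). With a single matching
  covariate, raw |ΔeGFR| distance is monotone-equivalent to a
  one-covariate propensity score, so this is an equivalent-intent,
  dependency-free reimplementation of propensity-style 1:1 nearest-
  neighbour matching, not a bit-exact port of any particular package.
  Balance is reported as Spearman ρ (age, eGFR) within the matched set.

## Synthetic cohort generator

The generator is the package's stand-in for the non-public study-scale
database and defines the conditions under which everything is tested.

* **Cohort margins**: age truncated-normal (mean 55.8 y, SD 15.8, range
  18–95), eGFR truncated-normal (mean 81, SD 25, range 15–150
  mL/min/1.73 m²), matching the reported study demographics. Age–eGFR
  confounding is planted through a Gaussian copula at a target Spearman
  ρ, default −0.4 — a moderate, realistic confounding strength (the SD
  the margins imply for a strict 1 mL/min/year decline would correspond
  to ρ ≈ −0.6; users emulating exact cancellation by the age correction
  should set `age_egfr_rho = -0.6`).
* **Effect calibration**: a target Spearman ρ is converted to the latent
  Gaussian correlation g = 2 sin(πρ/6); variant latents are
  g·z_cov + √(1−g²)·u, and intensities are a log-normal (monotone)
  transform, so the planted rank correlation is calibrated regardless of
  the intensity scale. Effect classes default to 35% strong-positive
  (target ρ +0.5), 5% strong-negative (−0.5), 60% null — reflecting the
  empirical predominance of positive eGFR associations among collagen
  fragments. Age effects default to arising solely through the planted
  confounding; explicit per-class age targets are solvable through the
  same copula when configured.
* **Variant structure**: fragments are true substrings of the reference
  sampled within the mature region (length 8–45, requiring enough
  prolines for the variant set); hydroxyproline counts rise in steps of
  1–2; inter-variant Spearman targets follow a linear decay,
  ρ(Δ) = 0.8 − 0.15·Δ, implanted through a jointly Gaussian residual
  whose correlation matrix is eigenvalue-clipped to the nearest valid
  correlation matrix when needed.
* **Censoring** is value-based: the bottom `censor_quantile` (default
  0.2) of each peptide's intensities is reported as not detected,
  mimicking detection limits rather than random missingness. Zero-fill
  ranking therefore attenuates planted ρ slightly (≈ 0.5 → ≈ 0.47 at 20%
  censoring); tests account for nothing beyond ordinary sampling error
  plus this attenuation.
* **`fig1_scenario`** plants an exact group structure — singletons,
  multi-variant groups with near-perfect correlation (latent pairwise
  0.95, far above threshold at the default 200–300 participants) and
  groups of independent variants (far below) — so consolidation counts
  are forced by construction. At the default (359, 55, 89) structure the
  peptide totals default to the published 119/229 split across
  multi-variant tiers.

What passing tests on this generator do *not* show: robustness to
batch effects or inter-run normalisation artefacts (inputs are assumed
pre-normalised), to peptide misidentification, to non-monotone
covariate effects, or to missingness that is not a pure detection limit.

## Numerical and testing choices

* Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from explicit integers; matching and consolidation tie-breaks
  are total orders, so reruns are byte-identical (verified on manifest
  digests).
* The BH implementation is delegated to statsmodels and cross-checked in
  the tests against an independently hand-rolled step-up oracle; peptide
  location is cross-checked against an exhaustive position-by-position
  scan.
* Problem sizes in the test suite and acceptance script (250–5000
  participants, 10–400 fragments, 10 matching seeds) were chosen so the
  whole suite completes in seconds while keeping Monte-Carlo error well
  inside the asserted tolerances (Fisher-z SE at n = 2000 is ≈ 0.022).
* Hotspot calls are a descriptive heuristic (residue runs where ≥
  `min_count` strong-positive peptides stack, optional moving-average
  smoothing), not a formal scan statistic.

## Reference scaffold

The bundled FASTA is a synthetic 1464-residue collagen-alpha-1(I)-like
precursor: published urinary-fragment coordinates are embedded at their
reported positions, the remaining helical region (179–1192) is filled
with a Gly-X-Y pattern (Gly at every third position, X/Y drawn from a
proline/alanine-rich pool), and the propeptides with seeded pseudorandom
residues. `scripts/build_reference_scaffold.py` rebuilds it and verifies
that every embedded fragment's leftmost occurrence is unique and equals
its reported coordinate and that the helical Gly frame is consistent.
The scaffold supports exact-location and coverage arithmetic; it must not
be used for any conclusion about the natural sequence outside the
embedded fragments.

## Known limitations

* Greedy nearest-neighbour matching cannot repair support mismatch: when
  the eGFR distributions of extreme age bins barely overlap, a residual
  age–eGFR correlation remains after matching (reduced, but possibly
  still significant at large n). The balance check reports exactly this.
* The merge rule treats variants as distinguished by hydroxyproline
  count only; positional isomers are indistinguishable in the input
  representation and are not modelled.
* Exact matching only: a peptide that differs from the reference by one
  substitution is reported unmapped rather than aligned.
* Spearman p-values rely on the t approximation; below n ≈ 10 they are
  unreliable, and such inputs are better served by exact methods.
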