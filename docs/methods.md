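# Methods

This note records the models and procedures implemented in `surreg`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that matter for interpreting the
output.

## Motif model and scanning

SurR recognition sites are modelled as block-and-spacer consensus patterns:
fixed base triplets separated by spacers of unconstrained content. Two
patterns are scanned by default —

| name  | consensus        | canonical span | edit budget |
|-------|------------------|----------------|-------------|
| short | `GTTn3AAC`       | 9 bp           | 1           |
| long  | `GTTn3AACn5GTT`  | 17 bp          | 2           |

— plus an optional alternative short consensus `GTTn3ATC` that can be
compiled on request (the literature quotes both forms of the short site; the
site tables this package reproduces use `GTTn3AAC`, so that is the default,
and the alternative is exposed without taking a position on which the
original screen used).

An *alignment* of a pattern is an offset, an orientation, and a realized
spacer-length vector with each spacer within ±1 (`spacer_flex`) of canonical.
Its edit cost is the Hamming distance over block positions plus the total
absolute spacer deviation; alignments above the pattern's budget are
discarded. The budgets were set to admit exactly the observed variant
classes upstream of the *T. barophilus* energy-metabolism clusters —
1-mismatch short (`ATTn3AAC`, `GTTn3ACC`, `GTTn3AAT`), up-to-2-mismatch long
(`GTAn3AACn5TTT`) and 2-spacer-shift long (`GTTn2AACn6GTT`) — and nothing
more degenerate. Both budgets and flex are configurable.

**Site collapse.** Alignments sharing (offset, pattern) describe one
physical site read different ways, so they collapse to the best-ranked one:
lowest edit cost, then fewest block mismatches, then smallest total spacer
deviation, then lexicographically smallest spacer vector. Preferring fewer
mismatches on cost ties is what makes a spacer-shifted site report as
`GTTn2AACn6GTT` (0 mismatches, 2 spacer units) rather than as a 2-mismatch
canonical-spacing reading of the same bases — matching how such sites are
conventionally annotated. A consequence worth knowing: a spacer-shifted site
*always* carries an in-budget canonical-spacing shadow alignment at the same
offset; without the collapse it would be double-counted.

**Nesting.** The long pattern's leading two blocks are themselves a short
instance; a short hit whose footprint coincides with the leading-two-block
footprint of a long hit (in that hit's reading orientation) is suppressed so
one bound site is reported once. Overlapping hits with distinct starts are
all reported — real promoters here contain long sites only 8 bp apart.

**Strand labels.** The exact short pattern is its own reverse complement, so
every exact short site matches both orientations and is labelled
`Forward/reverse`. Inexact hits report the cheaper orientation; on ties the
forward orientation is reported. Two properties follow and are asserted in
the tests: (i) at alignment level, scanning a reverse complement reflects
the match set exactly (spacer vectors reversing with the coordinates);
(ii) the collapsed site report is *not* exactly reflection-symmetric,
because collapse groups alignments by their start and reflection maps starts
onto ends — site counts and costs still mirror in practice, but the
guaranteed invariant is the alignment-level one. Similarly, budget
monotonicity (raising budgets never loses a match) holds for the match
relation; in the nested report a long hit appearing at a looser budget can
newly swallow an embedded short.

**Distances and coordinates.** Upstream distance counts the bases strictly
between the hit edge nearest the CDS and the first base of the start codon
(a site "2 bp upstream" has 2 intervening bases). Genomic coordinates are
1-based inclusive throughout; BED output converts to 0-based half-open, with
score = budget − edit cost and `Forward/reverse` sites written as strand
`.`. Promoter extraction returns the window on the gene's coding strand
ending at position −1; for reverse-strand genes the window lies at higher
genomic coordinates and is reverse-complemented. The default window is
300 bp (the farthest reported site sits 257 bp upstream); extraction does
not stop at neighbouring genes and truncates only at contig edges.

**Background flagging.** At these budgets random sequence matches easily
(a ≤ 1-mismatch short alignment hits a random offset/orientation with
probability 19/4096; a 300 bp window carries a Poisson-mean ≈ 5 of chance
hits across both patterns). The promoter report therefore flags any region
whose hit count exceeds the 99th percentile of the analytic Poisson
expectation; flags never change counts. Whole-genome BED tracks are emitted
unfiltered.

## Growth-rate estimation

The specific growth rate μ (h⁻¹) is the slope of ln(counts) vs time during
exponential phase. The estimator slides all contiguous windows of at least
`min_window = 4` points, keeps those whose linear fit reaches
`min_r2 = 0.95`, and returns the slope of the best-fitting window (highest
R², longest on ties, steepest among those). On noiseless exponentials every
window fits perfectly and the generating rate is returned to numerical
precision; lag and plateau points depress a window's R² below the purely
exponential stretch and are excluded exactly. Ranking by fit quality rather
than by maximum slope matters under noise: with 10% multiplicative counting
error, the steepest qualifying 4-point window is a noise artifact and
maximizing slope inflates μ by ≈ +0.06 h⁻¹, whereas the R²-ranked estimator
measures bias ≈ 0.007 h⁻¹ (200 simulations, μ = 0.4, 9 hourly points). If no
window reaches the floor, the best-R² window's slope is returned with a
`low_quality` flag; a perfectly flat curve returns μ = 0 with R² = NaN,
flagged. Estimates are invariant to count rescaling and time shifts.

Rate grids report the per-replicate mean ± sample SD per strain × (pressure,
sulfur) cell, with an optional pooled fit over merged replicate points —
published per-cell rates could be either convention, so both are emitted
and neither is asserted to be "the" published one.

**Growth classes.** Qualitative classes relative to the parental strain use
configurable thresholds: `-` when μ < 0.05 h⁻¹ (an order of magnitude below
parental rates, i.e. essentially no growth) or final density < 10% of
parental; `+++` when μ ≥ 80% of parental and density ≥ 80%; `++` when
μ ≥ 40% of parental; `+` otherwise. Applied to the published rate grids
(with density ratios defaulted to 1 because raw densities are not
published), this rule reproduces 12 of the 18 *T. barophilus* cells of the
published qualitative summary; the six discrepancies all sit near the 40%/80%
boundaries at 40–70 MPa, where the published classes plainly encode final
density information the rate tables do not carry. The class matrix is a
calibration report, not a validated classifier.

## ΔΔCt quantification

Classic 2^−ΔΔCt with amplification efficiency fixed at 100% (fold base 2);
an efficiency scalar E is exposed for sensitivity checks (base = 1 + E).
Technical replicates are averaged to one Ct per biological replicate; the
expression ratio of a gene to the reference within a group is the geometric
mean over biological replicates of 2^−ΔCt (ΔCt is the natural additive
scale, so the geometric mean is the unbiased central estimate), reported
with both the ratio-scale SD and the log2-scale SD because error bars can be
drawn either way. Fold change between groups is 2^−ΔΔCt on group-mean ΔCt;
a configurable unchanged band (default fold ∈ [0.5, 2]) assigns direction
labels. Folds are exactly reciprocal when numerator and denominator swap,
and all quantities are invariant to uniform Ct shifts within a group.

Reference-gene choice ranks candidates (default pcna, S13, S19) by the SD of
their mean Ct across all strain × condition groups, most stable first; exact
ties break alphabetically and are flagged. This simple dispersion metric
matches how reference stability is described for this dataset; pairwise
geNorm/NormFinder-style measures were deliberately not implemented.
Replicates missing the reference measurement are dropped with a logged
warning; genes absent from a comparison produce NA rows rather than
aborting a run.

## Synthetic data

The generator produces the three input classes with truth sidecars:

* **Promoters/genomes.** Backgrounds are uniform i.i.d. {A,C,G,T}; motif
  variants are planted at their stated upstream distances (reverse plants as
  the reverse complement of the variant string). The finished sequence is
  exhaustively scanned and any occurrence beyond the planted set —
  background chance hits, or partial matches seeded by a plant's own blocks
  extending into neighbouring bases — is destroyed by re-randomizing the
  unconstrained bases beneath it and rescanning, until found = planted
  exactly. Chance hits are frequent enough (Poisson mean ≈ 5 per 300 bp at
  default budgets) that this scan-and-repair loop, rather than whole-window
  rejection sampling, is what makes verification tractable. Plants may
  overlap: where two variants demand different bases at a shared block
  position, every demanded base is tried and the first assignment keeping
  all plants within budget (without forcing any unplanted occurrence into
  existence) wins; the absorbed extra mismatches are charged to the affected
  plants' realized costs and recorded in the truth file. The eight-cluster
  *T. barophilus* site layout ships as a preset (`SURR_SITE_PLANS`); its two
  overlapping pairs (8 bp apart upstream of Mrp-Mbh 1 and Mrp-Mbs) realize
  at costs (1,2,1,2) and (2,1,1,1) respectively — two printed cost-1
  variants cannot literally coexist on one sequence, and the conflict
  resolution spreads the unavoidable extra edits while preserving every
  count and distance. Dummy CDSs (ATG…TAA) and random gaps assemble plans
  into contigs so that extracting each gene's upstream window returns
  exactly the verified promoter.
* **Growth curves.** counts(t) = min(capacity, n₀·e^(μ·max(0, t − lag)))
  with median-preserving lognormal noise of CV 10% by default (chamber
  counting is multiplicative); n₀ defaults to 2×10⁶ cells/mL, the standard
  inoculation density.
* **Ct tables.** Per biological replicate the reference Ct is drawn
  Normal(ref_ct = 20, sd_bio = 0.3); each target gene adds −log₂(true ratio)
  plus its own Normal(0, sd_bio); every well receives Normal(0,
  sd_tech = 0.15) per technical replicate, 3 × 3 replicates by default.
  Zero-noise tables recover planted ratios exactly.

What the generator does **not** emulate: genomic base composition (GC skew,
codon structure — irrelevant once backgrounds are verified hit-free),
intergenic architecture (promoters are placed immediately 5′ of their CDS),
real growth-curve pathologies (death phases, diauxie, replicate-correlated
noise), and qPCR artifacts (efficiency drift, melt failures, inhibition).
Passing recovery tests therefore demonstrates correctness of the estimators
under the stated noise models, not robustness to every failure mode of real
cultures or plates.

## Problem sizes and determinism

All fixtures are generated at analysis scale: promoter windows of
200–320 bp, whole synthetic contigs of a few kb, growth curves of 9–16
points × 3 replicates, Ct tables of ≤ a few hundred wells. Recovery
statistics use 200 seeded growth simulations and 500 seeded qPCR
simulations; scanner correctness is checked against an independent
exhaustive enumeration on 100 random sequences up to 1 kb. Every stochastic
component takes an explicit seed (numpy `default_rng`), and every CLI run is
byte-reproducible from its config plus inputs.

## Known limitations

* Exact reproduction of the published site table from the real chromosome
  depends on the original screen's unstated window and curation rules; the
  package reproduces the table from its printed content on synthetic
  sequence and treats a real-genome scan as a calibration exercise.
* The growth-class thresholds are a documented invention (none are
  published) and intentionally simple.
* ΔΔCt assumes equal amplification efficiency across genes; dilution-series
  efficiency estimation is out of scope.
* The scanner is exact but naive (full enumeration per offset); it scans a
  2 Mb genome in minutes, not seconds, and no index structure is provided.
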