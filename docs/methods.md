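# Methods

`mosaicweb` analyzes spatio-temporal mosaics of small bipartite
plant–flower-visitor networks: a grid of altitude levels crossed with
consecutive months, each cell holding one interaction matrix. The package
has two halves — a metric/inference pipeline that would apply unchanged to
real field records, and a seeded generator that produces mosaics with the
statistical structure such campaigns exhibit, giving every pipeline stage a
known ground truth.

## Data model and admission

An `InteractionMatrix` is a labeled plants × insects nonnegative matrix,
binary (presence of an interaction) or counts (event multiplicities).
Records-based constructors reject species without any interaction: a species
enters the data only by being seen interacting. Units are matrices stamped
with altitude (masl), month index and monthly precipitation (mm).

Matrices with fewer than two species on either side carry no pairwise
structure (no pairs to score for nestedness, no groups to compare), so a
unit is **admitted** to the metric and inference stages only when P ≥ 2 and
A ≥ 2 (equivalently M = P·A ≥ 4). Inadmissible units stay in storage and in
the turnover stage, which needs only occurrences.

## Topology indices

Descriptive quantities per admitted matrix: P, A, S = P + A, M = P·A,
A:P, I (filled cells), connectance C = I/M, and links per species
L = I/S, L_P = I/P, L_A = I/A. **L counts each link once** (I/S, not
2I/S); with the doubled convention the index would be the mean degree,
which is not what is reported here. A species with exactly one partner is a
specialist; specialist fractions are reported per side.

**NODF** scores nestedness on 0–100 through decreasing fill and paired
overlap: for every unordered pair of rows (and of columns), the pair
contributes 0 unless its degrees strictly differ (ties fail the
decreasing-fill condition), otherwise 100 × the fraction of the poorer
member's partners shared with the richer member. The score averages over
*all* pairs — zero-scored pairs stay in the denominator. Orienting each
pair by its own margins makes the score invariant to row/column
permutations. The binary implementation agrees exactly with a brute-force
pair enumeration on random matrices and with `vegan::nestednodf` (R) on
fixtures. The **weighted** variant requires strictly decreasing marginal
totals and counts only cells of the poorer row that are positive and
strictly smaller than the matching cell of the richer row; note `vegan`
gates weighted pairs by binary fill instead, so the two weighted variants
differ by design. A consequence of the strict-inequality rule: every binary
matrix has WNODF = 0.

**Quantitative linkage density** is the marginal-weighted mean effective
partner count, LD = ½[Σ_j (c_j/T)·2^{H_j} + Σ_i (r_i/T)·2^{H_i}], with H
the base-2 Shannon entropy of each species' conditional interaction
distribution; **weighted connectance** is LD/S. The all-ones n×n matrix
gives 0.5 for every n; a uniform diagonal gives 1/(2n).

**Interaction strength asymmetry** averages, over realized links, the
normalized difference between the visitor's dependence on the plant
(a_ij/c_j) and the plant's dependence on the visitor (a_ij/r_i), scaled by
the larger of the two. Positive values mean the higher trophic level is the
more dependent side. The value lies in [−1, 1] by construction.

**H2′** standardizes the two-dimensional Shannon entropy of the
interaction distribution between its margin-constrained extrema:
H2′ = (H_max − H2)/(H_max − H_min), 0 = interactions follow the marginal
expectation, 1 = maximal partner partitioning. The extrema are taken over
*integer* tables with the observed row/column totals: exact pruned
enumeration when the table has ≤ 16 cells and total ≤ 24, otherwise
deterministic greedy fills (concentrating for H_min, evening for H_max)
refined by margin-preserving 2×2 transfers (single-unit and full-block)
until no move improves the entropy. Because the observed table is itself
feasible, it clamps the bounds. Two caveats follow from the integer
constraint: (a) H2′ is only *approximately* invariant under uniform scaling
of counts — the feasible lattice refines as totals grow; and (b) matrices
whose margins admit a single entropy value (e.g. a unit-weight diagonal,
where every feasible table is a permutation matrix) have degenerate bounds,
and H2′ is then defined as 0 with a logged note. On binary matrices the
observed table attains H_max, so binary H2′ is 0; the index is informative
on count data.

## Null model

The randomization conserves exactly what the observed matrix fixes about
sampling intensity and nothing else: I cells are chosen uniformly among the
M available, each receives one event, and the remaining T − I events are
scattered uniformly over the chosen cells. Shape, fill (hence connectance)
and grand total are conserved in every replicate; marginal totals are not.
Binary input (T = I) reduces to a uniform placement of I ones. A
`fixed_cells` switch instead redistributes events over the observed cells,
for the reading of the procedure in which the link set is kept.

`compare_to_null` reports, per index, the observed value against the
ensemble with a two-sided one-sample t contrast. That contrast's standard
error shrinks as replicates grow, so it detects *any* offset between the
observed value and the null mean at high enough replication — it answers
"is the observed value the null's center", not "is it a typical draw". The
calibrated typicality question is answered by the also-provided two-sided
empirical exceedance probability (`NullComparison.empirical_p`), which
rejects a null-generated observation at its nominal rate; the distributional
stability test uses it. Replicates on which an index is undefined are
dropped (at most 10% before erroring, with a logged count).

## Statistical layer

Per network index and grid factor (altitude, time), residuals from group
means are tested with Shapiro–Wilk and groups with Levene (mean-centered);
both passing at α = 0.05 routes to one-way ANOVA (F reported), otherwise
Kruskal–Wallis (χ² reported). Routing is a pure function of the two
assumption p-values. The low/high elevation contrast (boundary 2700 masl)
uses a pooled-variance t when Levene accepts homogeneity and Welch's t
otherwise. Polynomial fits are OLS on the raw basis (degree 1 or 2) with
the overall F test; degree-2 fits are labeled concave/convex by the sign of
the quadratic coefficient. The individual-vs-cumulative comparison runs
Kruskal–Wallis across per-unit, altitude-pooled and month-pooled metric
tables. No multiple-testing correction is applied across indices; each row
is a marginal test.

## Synthetic mosaic generator

Defaults emulate the study system the pipeline is built for: 8 altitudes
(2200–2900 masl, 100 m steps) × 8 months; bimodal precipitation (two rainy
blocks > 280 mm flanking four dry months < 200 mm); pools of 42 plants and
75 visitors; contiguous phenology windows with shifted-geometric spans of
mean 1.88 months (plants) and 2.41 (visitors); contiguous altitude bands
(mean 3 levels); ~2% of visitors form a permanent core present everywhere
(plants never do); per-cell richness targets (4.5 plants, 9 visitors at the
average month) modulated by a concave quadratic response to standardized
precipitation; specialist fractions following linear laws in altitude
(plants −0.44 + 0.0003·masl, visitors 0.15 + 0.0002·masl, clipped to
[0, 1]); visitor availability attenuated by 45% above the 2700 m divide;
and a 20% extra empty-cell rate on top of cells that are empty because no
plant and visitor co-occur. Empty cells are absent units, never zero
matrices. Everything derives from a single seed, bit-for-bit reproducibly.

Within a unit, link assignment is **plant-side primary**, because the
plant-side specialist gradient is the quantity the recovery analyses target:
plants are marked specialist by stratified randomized rounding of
f·P (rounding a fractional expectation rather than flipping independent
coins per species — same expectation, far less within-unit variance),
specialists get degree 1 and generalists a geometric tail matched to a mean
plant degree of 2.32. The resulting link total fixes I. Visitor degrees
(specialists 1, generalists ≥ 2 capped at 4) are then reconciled to I by
widening generalists first, converting visitors to specialists next, and
only as a last resort dropping surplus visitors. Pairing gives every
specialist plant exactly one partner before generalist quotas are filled,
so the plant gradient is enforced faithfully; the visitor side absorbs the
reconciliation noise, which is why its realized mean degree (~1.3) sits
slightly above the configured 1.17 target and its realized gradient is
noisier than the plants'. An `exact` mode replaces all sampling with
deterministic expectation-level choices for noise-free tests.

What the generator does *not* emulate: detection failure (all absence is
true absence), species abundances (only occurrences and link counts),
within-month phenology, and non-contiguous ranges. Passing recovery tests
therefore show the pipeline recovers structure *of this kind*; they are not
evidence about observational biases real campaigns add.

`null_effect_config` is the no-effect variant used for type-I audits:
single-cell windows and bands (units share no species, hence are
independent), enlarged pools to keep per-cell availability comparable, and
flattened richness/attenuation/specialist gradients. Independence matters:
with the default multi-cell ranges, units within a factor level share
species, which violates the iid assumptions of any one-way test regardless
of implementation.

## Numerical choices

- Assumption α for routing: 0.05 (Shapiro–Wilk, Levene both sides).
- H2 enumeration budget: 300k nodes; beyond it the greedy+transfer
  heuristic answers. Hill-climb sweeps capped at 60.
- NODF ties (equal degrees / equal marginal totals) score 0, per the strict
  decreasing-fill rule; the denominator counts all pairs.
- Degenerate inputs: constant metrics are flagged, not tested; single-month
  grids skip the time factor with a logged reason; H2 with degenerate
  bounds returns 0 with a logged note.
- All stage seeds derive from the run seed via SHA-256, so stages are
  independently reproducible; seeded runs are bit-identical (checksummed in
  the run manifest).
- Desk-scale defaults: pipeline null ensembles use 250 replicates per unit
  (the standalone `NullEnsembleSpec` default is 1000); calibration audits
  in the test suite use 200 trials and 30-replicate mosaic batches.

## Known limitations

- H2′ heuristic bounds above the enumeration regime are not certified
  extrema; they are clamped by the observed entropy and agree with
  exhaustive enumeration to < 0.05 nats on all tiny cases tested.
- The visitor-side specialist gradient is enforced only loosely (see link
  assignment); analyses of visitor specialization against altitude on
  generated data recover the sign unreliably at default sizes.
- The t contrast in `compare_to_null` inherits the classic anti-conservatism
  of comparing one observation to an ensemble mean; use `empirical_p` when
  a calibrated test is needed.
- Binary-mode weighted indices are degenerate where noted (WNODF = 0,
  H2′ = 0); run the generator in counts mode for meaningful weighted
  comparisons.
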