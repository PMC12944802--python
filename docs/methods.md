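# Methods

## The question and the statistic

The analysis asks whether a disease population is distributed across
small census-style areas in proportion to the background population. A
univariate cluster statistic (e.g. Moran's I on case counts) cannot answer
this: cases cluster wherever people do. Lee's L is a bivariate statistic
that couples the Pearson-type association between the two count variables
with the spatial autocorrelation of each, by correlating their spatially
smoothed (neighbourhood-averaged) values.

With areas `i = 1..n`, weights `w_ij`, centred variables
`x̃_i = x_i − x̄`, lags `ℓx̃_i = Σ_j w_ij x̃_j` and
`S = Σ_i (Σ_j w_ij)²`:

```
L   = (n / S) · Σ_i ℓx̃_i ℓỹ_i / ( ‖x̃‖ · ‖ỹ‖ )
L_i = (n² / S) · ℓx̃_i ℓỹ_i / ( ‖x̃‖ · ‖ỹ‖ )
```

so `mean_i(L_i) = L` identically. Two diagnostics separate genuine
bivariate association from autocorrelation artefacts: the spatial
smoothing scalar `SSS_x = L(x, x) ≥ 0` of each variable, and the Pearson
correlation `r_lag` of the two lag vectors. On lattices whose lag operator
is doubly stochastic (torus wrap), `L = √(SSS_x · SSS_y) · r_lag` exactly;
the test suite verifies this identity to 1e-10, alongside equivalence with
a literal double-loop transcription of the formulas and the reduction to
Pearson's r under include-self identity weights.

The analysed variables are **counts** (area population and case count),
not rates: the statistic directly compares the two distributions'
geography, which is the study question.

## Weights

Neighbourhoods are polygon-contiguity based: queen (any shared boundary
point, the default — "contiguous boundary" read inclusively) or rook
(shared positive-length segment), computed from the geometry via an
STR-tree and boundary-intersection dimension. Weights are row-standardised
binary contiguity, `w_ij = 1/|N(i)|`: the lag is the plain neighbourhood
average, matching a design in which each neighbour receives equal weight.
The self is never its own neighbour; an explicit include-self identity
matrix exists purely as the degenerate test fixture under which the lag is
the identity map.

Areas with no neighbour ("islands") keep empty weight rows. Their lag is
undefined, so they are excluded from all Lee statistics — `n` counts
non-island areas, and islands are reported, never silently imputed.
Because contiguity is symmetric, an island is nobody's neighbour and the
restriction to the non-island subgraph is exact. Torus lattices wrap
combinatorially; they exist for the algebraic identities above.

## Inference

Significance is by Monte Carlo permutation with the plus-one estimator
`p = (1 + #extreme) / (R + 1)`, default `R = 10,000`, two-sided
extremeness `|L*| ≥ |L_obs|` (one-sided options available).

The global null permutes the observed `(x_i, y_i)` **pairs jointly**
across areas. This destroys the spatial arrangement while preserving the
within-area pairing of population and cases — the correct null for "is
the arrangement special?", and the one under which the null scenario below
calibrates at its nominal level. Permuting one variable alone would also
destroy the x–y pairing, which is strong by construction (cases scale
with population), and would reject almost always.

The local null is the standard conditional permutation: for area `i`,
hold `(x_i, y_i)` fixed and permute the other `n − 1` pairs, which reduces
to drawing `|N(i)|` pairs without replacement from the others. One bank of
`R` permutations is shared across areas (each area's marginal p-value is
exact; only cross-area dependence is introduced, as in standard LISA
implementations). Global means and norms are held at their observed
values, which are permutation-invariant.

Extremeness is counted with a relative tolerance of order 1e-9: permuted
statistics are accumulated in a different summation order than the
observed one, and structural ties — permutations that leave the statistic
mathematically unchanged, common at small n — must count as "at least as
extreme". The suite checks Monte Carlo agreement with exhaustive
enumeration (all 4! global rearrangements at n = 4; all conditional
rearrangements at n = 5) to within 0.02.

Local p-values are **not** multiplicity-adjusted by default — the
classification mirrors per-area testing at α = 0.05, with the usual
caution about repeated local tests; a Benjamini–Hochberg option exists.

## Classification

Each non-island area gets one of five labels: `not_significant` if its
local pseudo-p exceeds α (default 0.05), otherwise High/Low for each
variable by the **sign of its lagged centred value**. Using the lags (not
the raw values) keeps the call consistent with the sign of `L_i`, which is
a product of the two lags: High/High and Low/Low imply `L_i > 0`, the two
discordant categories `L_i < 0` (a property test asserts this). A zero
lag is called Low — an arbitrary, deterministic tie-break, logged when it
fires. Report percentages round halves away from zero to integers.

## Accessibility description

Remoteness: each area carries five nonnegative population shares (Major
Cities … Very Remote); the area's label is the argmax share, ties broken
toward the less remote label in the fixed order. Hospitals fall in three
overlapping service categories: has an emergency department; **≥ 200
beds** (the inclusive reading of the bed-count cutoff, adopted because the
source material states the boundary both ways); and a case-insensitive
substring match of "large"/"major"/"medium" in the free-text description.
Per area and category, the access flag is true iff the minimum travel time
over that category's hospitals is **≤ 60 minutes**. The report tables give
each population group's share per remoteness label and per flag, and the
cross-tabulation of classification categories against both groupings;
marginal conservation is asserted on every randomised fixture.

## Synthetic geography

The generator emulates the study's inputs at design scale:

- **Areas**: an `nx × ny` lattice of square cells (row-major ids).
  Real-polygon input (GeoJSON) is supported by every downstream stage;
  the lattice is the testbed.
- **Populations**: i.i.d. log-normal with arithmetic mean 10,000 (the
  census design target) and σ(log) = 0.35, giving the right skew of real
  area sizes; rounded, floored at 1.
- **Risk surface**: baseline relative risk 1.0 everywhere; optional
  disjoint contiguous clusters (seed cell plus rook-graph ball of a given
  radius) at elevated RR.
- **Cases**: per-area `Binomial(population, prevalence × RR)`; default
  prevalence 0.009, a configurable stand-in in the reported 8–10 per
  1,000 birth-prevalence band (no population-prevalence figure for living
  CHD exists to copy). Each case is a person record placed uniformly
  inside its area's polygon with severity/sex/birth-decade drawn from the
  registry cohort's marginal shares (severity 31/38/17/13% mild/moderate/
  severe/unknown). Two 5% contamination fractions add non-structural and
  deceased records so the cohort filters have work to do; alive structural
  records reproduce the binomial counts exactly (a conservation test).
- **Hospitals**: at uniformly chosen cell centroids; Bernoulli(0.6)
  emergency department; beds from a fixed discrete distribution spanning
  the 200-bed cutoff; descriptions from a word list that both contains and
  lacks the size keywords.
- **Travel times**: straight-line centroid-to-hospital distance divided by
  a speed (length units/hour) × 60 — a Euclidean proxy for drive time.
- **Remoteness shares**: the distance from the area centroid to the
  nearest city centre selects one of five bands (four increasing radii);
  that band gets 1 − bleed of the share and adjacent bands split the rest
  (bleed 0.2 < 0.5, so the argmax stays at the centroid's band while the
  argmax rule is exercised on non-degenerate vectors).

Everything is seeded; one run seed expands into fixed per-stage
substreams, so changing the permutation count never perturbs the
synthetic data. Two presets fix the scenarios used throughout tests and
docs: **null** (20×20, no clusters — counts exchangeable across areas) and
**clustered** (one radius-2 cluster at RR 3).

What the generator does **not** emulate: spatially autocorrelated
population surfaces (areas are i.i.d.), real road networks, real ASGS
polygon shapes, multi-level SA1→SA2 aggregation, and registry
ascertainment artefacts. Consequences for interpretation: passing
calibration/recovery tests show the statistics behave correctly under
exchangeable-by-construction nulls and planted contiguous clusters; they
do not certify behaviour on real geographies, where population
autocorrelation raises SSS_x and global power. In particular, on the
clustered preset the **global** test has little power (a disease-only
cluster on an i.i.d. population surface leaves the pair-permutation null
nearly unchanged — the planted signal lives in SSS_y, not in the cross
term); detection there is carried by the **local** statistics, which flag
cluster areas at a median rate of ~0.5–0.6 against a ~0.04 false-positive
share outside.

## Cohort pipeline

Filters apply in a fixed order — structural-disease inclusion first, then
vital status — with a per-criterion exclusion tally; filtering is
idempotent. Point-in-polygon location is boundary-inclusive; a point on a
shared edge goes to the first containing area in id order (deterministic
tie-break), and points outside every polygon are tallied as geocoding
failures, never dropped silently. "Complex" disease is the moderate ∪
severe severity subset; unknown severity counts toward the total only.

## Numerical and I/O conventions

Zero-variance inputs (or zero-variance lags) raise a typed degenerate-
input error rather than returning NaN. Geometry is planar Cartesian
throughout; projected real-world coordinates are treated as planar. All
tables are RFC 4180 CSV with header rows (floats written at %.17g and
parsed round-trip where identity matters); geometry is RFC 7946 GeoJSON;
configs are YAML echoed verbatim into the output directory, and a rerun
with the same config and seed is byte-identical.

## Problem sizes used in validation

The suite validates formulas by brute-force oracle on random lattices up
to n = 100; exhaustive permutation agreement at n = 4 (global) and n = 5
(local); type-I calibration with 1,000 null replicates at R = 199 on the
20×20 lattice; and recovery with 100 clustered replicates at R = 999.
These replicate counts are the package's chosen validation scale for the
count-level generator path; the person-level path (points, filters,
aggregation) runs end-to-end in the pipeline tests.
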