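# Methods

## Model and assumptions

The package implements fuzzy DEMATEL for a panel of p experts rating the
pairwise influence among n criteria on an ordered linguistic scale. Each
term maps to a triangular fuzzy number (TFN) (l, m, u) on [0, 1]; a TFN is
a possibility distribution over the "true" influence score, peaked at m.
The method assumes:

- influence judgments are meaningfully aggregated by componentwise
  arithmetic averaging across experts (all experts weighted equally);
- total influence is the superposition of all directed walk contributions,
  so the total-relation matrix is the geometric series
  T_C = C(I − C)⁻¹ applied independently to the L, M and U components;
- a TFN is adequately summarized by its centroid (BNP defuzzification)
  once the series has been computed.

Pipeline order is: per-expert linguistic → TFN mapping with a forced crisp
zero diagonal; per-expert normalization by r = maxᵢ Σⱼ uᵢⱼ (each expert's
own factor); componentwise panel average; series inversion; defuzzification;
row/column sums. Some fuzzy-DEMATEL variants average before normalizing;
this package normalizes first, matching the procedure the embedded case
study follows.

## Parameters

| parameter | default | meaning |
|---|---|---|
| linguistic scale | 5 levels of the table in the README | term → TFN map; custom scales loadable from a `term,l,m,u` file, must satisfy 0 ≤ l ≤ m ≤ u ≤ 1 and be ordered weakest→strongest |
| retest threshold | 0.8 | minimum per-expert fraction of identical off-diagonal answers for a test–retest pair of panels to count as stable |
| display precision | full precision; 3 decimals typical | rounding (half-even) applied only when writing report tables |
| condition limit | 1e12 | 1-norm condition estimate of (I − C) above which the inversion is refused |
| zero tolerance | 1e-12 | |D − R| below this is treated as exactly zero (boundary between cause and effect, flagged) |

All quantities are dimensionless influence scores.

## Numerical choices

- **Defuzzification form.** BNP is computed as l + ((u−l) + (m−l))/3,
  algebraically (l+m+u)/3 but exact in floating point for crisp cells
  (l = m = u), so a crisp run defuzzifies to the identity.
- **Series inversion.** T = C(I−C)⁻¹ is evaluated with a linear solve
  rather than an explicit inverse. Before solving, the spectral radius of
  each component is computed; ρ ≥ 1 raises an explicit non-convergence
  error naming the component, and a condition estimate above 1e12 raises a
  singularity error instead of returning garbage.
- **Cause/effect boundary.** A criterion is "cause" iff D − R > 1e-12;
  values within ±1e-12 of zero are classified effect and flagged as
  boundary cases. The tolerance absorbs the ~1e-16 round-off of row/column
  sums so that an exactly symmetric system (zero relation by construction)
  does not produce spurious cause labels.
- **Ranking ties.** Criteria are ranked by prominence descending; ties are
  broken by input label order and the tied criteria are flagged.
  `ranking_by_prominence(..., decimals=k)` additionally rounds to k
  decimals before sorting, reproducing a ranking read off a printed
  k-decimal table.
- **Degenerate panels.** An all-zero matrix cannot be normalized (error).
  A *uniform* consensus (every off-diagonal cell the same term) normalizes
  to an upper-bound component whose row sums are all exactly 1, hence
  spectral radius exactly 1: the influence series diverges and the run is
  rejected with the non-convergence error. This is a real property of the
  method, not an implementation limit; convergence is guaranteed only for
  hollow, non-uniform matrices. Tests of the symmetry-null property
  (symmetric input ⇒ all relations zero) therefore use symmetric
  non-uniform consensus matrices.

## The embedded case study and its reproduction

The package embeds the published 14-criterion social-marketing case: the
aggregated normalized fuzzy direct-relation matrix (the pipeline's input
after the averaging stage; per-expert raw responses were not published),
the published defuzzified total-relation matrix, and the published
D / R / D+R / D−R table. Three cells of the input matrix carry obvious
typesetting defects (braces for parentheses; a missing comma; a misplaced
parenthesis); the repaired values are embedded and every repair is recorded
in the fixture's `repair_log`. Repairs were chosen so each triple satisfies
l ≤ m ≤ u and matches its column's magnitude pattern.

The published input is printed at 3 decimals. The series inversion
amplifies that rounding by roughly 1/(1 − ρ(U)) ≈ 8–9, which sets the
comparison tolerances used by `fdematel reproduce` and the acceptance
tests: ±0.01 per total-relation cell, ±0.05 on prominence, ±0.03 on
relation, exact match for the cause/effect partition. Several criteria are
near-tied in prominence (gaps < 0.001, below the input rounding noise), so
the full-precision end-to-end ranking can permute those neighbours. The
published ranking is reproduced exactly by ranking the row/column sums of
the published total-relation matrix at its own 3-decimal display precision
with label-order tie-breaking — i.e., by reading the ranking the way the
printed report presents it; that is the route the reproduction check uses.
A separately noted curiosity of the source: its prose assigns two criteria
to groups opposite to the signs in its own index table; the package follows
the table, which is internally consistent with the matrix sums.

## Synthetic panels

The generator emulates the study conditions: by default 14 criteria, 12
experts, and a per-cell perturbation probability of 0.2 around a shared
consensus matrix of scale levels. Noise moves a cell one ordinal level up
or down (equiprobable, clipped at the scale ends) because expert
disagreement on linguistic scales is local and ordinal; uniform resampling
over the whole scale is available as an option. Each expert draws from an
independent substream spawned from the root seed, so expert k's matrix is
invariant to the panel size. `plant_driver` installs a ground-truth cause
criterion (strongest outgoing, weakest incoming influence); with the
default conditions a planted driver is recovered in the cause group in
well over 95% of seeds, which the test suite verifies over 200 seeds.

What the generator does **not** model: correlated experts, systematic
leniency/severity biases, incomplete questionnaires, or the response
distribution of the real panel (unpublished). Passing synthetic-recovery
tests therefore demonstrates the pipeline's correctness and statistical
power under idealized ordinal-noise conditions, not robustness to real
panel pathologies.

## Problem sizes in the test suite

The suite exercises matrices up to 14×14 (the case-study size), 100 random
matrices against a 200-term truncated-series oracle (spectral radius drawn
in (0.1, 0.85) so the truncation itself is converged past the 1e-9
comparison tolerance), and 200 seeded recovery simulations at n = 14,
p = 12, noise 0.2. The whole suite runs in a few seconds.

## Known limitations

- Only triangular fuzzy numbers and BNP defuzzification are supported (no
  trapezoidal numbers, alpha-cut or centroid-variant defuzzifiers).
- No expert weighting, no threshold-based pruning of the total-relation
  matrix, no hybrid AHP/ANP coupling.
- The cause–effect diagram export is coordinates plus a minimal optional
  scatter; publication-quality styling is out of scope.
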