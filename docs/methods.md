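# Methods

## The model

`fahp` implements a fuzzy variant of the analytic hierarchy process built
on *complementary* three-scale judgment matrices rather than Saaty's 1–9
reciprocal scale. An evaluation system is a balanced tree: a goal node, one
or more criterion layers, and leaf indicators compared only among siblings.

For one internal node with n children, each of k experts scores every
unordered child pair (i, j) on {0, 0.5, 1}: 0 if i is at a disadvantage to
j, 0.5 for equal importance, 1 if i prevails. The pipeline is:

1. **Aggregation.** The score chosen by the most experts becomes f_ij
   (plurality); f_ji = 1 − f_ij and f_ii = 0.5 give the fuzzy judgment
   matrix F.
2. **Consistency transform.** With row sums r_i = Σ_j f_ij,

       r_ij = (r_i − r_j) / (2n) + 0.5

   yields the fuzzy consistent matrix R. The additive identity
   r_ij = r_ik − r_jk + 0.5 holds for every triple *by construction*, which
   is why this calculus needs no analogue of the classical consistency-ratio
   check — and none is performed.
3. **Direct priority vectors.** Either row normalization,
   w_i = Σ_j r_ij / Σ_ij r_ij, or the square-root (row geometric mean)
   method, w_i ∝ (Π_j r_ij)^{1/n}.
4. **Eigenvector refinement.** E = (r_ij / r_ji) is a positive reciprocal
   matrix; power iteration V ← E·(V / ‖V‖_∞), seeded with the normalizing
   vector, converges to its principal eigenvector in a handful of
   iterations. The returned weights are the final iterate normalized to
   sum 1; λ_max is reported as ‖V_final‖_∞.
5. **Synthesis.** A leaf's composite weight λ is the product of local
   weights along its root-to-leaf path (composite weights sum to 1), and an
   alternative's comprehensive score is

       P = Σ_i x_i λ_i + c

   over standardized leaf values x_i ∈ [0, 1], with correction c = 0 by
   default (interference effects assumed to offset).

Standardization is min-max across alternatives for *positive* leaves,
min-max after negation for *reverse* (cost) leaves, and pass-through for
*graded* leaves, whose values are five-grade expert scores already on
[0, 1] (excellent 0.80–1.0 down to very poor 0.00–0.19). Percentages are
converted to fractions by division by 100.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `tol` (power iteration) | 1e-4 | ∞-norm gap between successive normalized iterates at which iteration stops |
| `max_iter` | 100 | iteration cap; exceeding it raises `ConvergenceError` |
| `c` (correction) | 0 | additive term for disturbance factors outside the hierarchy |
| aggregation tie-break | 0.5 | any non-unique plurality resolves to equal importance |

The tie-break is the only symmetric, order-independent choice: aggregating
a panel with all scores complemented must produce the complementary matrix,
which pins ties to 0.5 (a property test asserts this).

The power-iteration seed is the full-precision normalizing vector, not a
3-decimal truncation of it; display rounding never feeds back into
arithmetic anywhere in the package. Reports round to 4 d.p.; internal state
is never rounded.

## Numerical notes

- **λ_max as an estimate.** Reporting λ_max = ‖V_final‖_∞ mirrors the
  iterative scheme itself. For a positive reciprocal matrix the true
  Perron root satisfies λ ≥ n, but the ∞-norm estimate at stopping
  tolerance `tol` can undershoot by O(n·tol); tests assert the bound with
  that slack. Tightening `tol` recovers the bound (the dense-eigendecomposition
  cross-check runs at 1e-10 and matches to 1e-6 element-wise).
- **Degenerate entries.** The geometric-mean method is undefined if any
  r_ij = 0 and the reciprocal transform if any r_ij ∈ {0, 1}. Notably, the
  row-sum transform can never produce such entries from a three-scale
  panel: row sums lie in [0.5, n − 0.5], so every r_ij stays within
  (n − 1)/(2n) of 0.5, strictly inside (0, 1). The error paths exist for
  directly constructed matrices and are exercised with a synthetic fixture
  (`extreme_consistent_matrix`) that no panel can generate.
- **Degenerate standardization.** If all alternatives share one raw value,
  min-max has no range; the package returns the indifference value 0.5 for
  every alternative and warns, keeping the leaf neutral rather than
  arbitrary.
- **Tie-breaks in ranking.** `compare` sorts by P descending with a stable
  input-order tie-break.

## The bundled case study

The package ships a worked comparison of two timber-extraction systems in
Shaowu city, Fujian — light cableway skidding versus road-cutting
skidding — over a three-benefit hierarchy (ecological, economic, social)
with 3 second-level, 9 third-level and 39 leaf indicators. Two comparison
matrices were published in full (the goal node and the natural-ecology
criterion) and are stored as aggregated panels; local weights for the
remaining nodes, the standardized leaf columns, the per-leaf integrated
values and the field cost measurements are stored verbatim. Re-running the
pipeline on the two panels reproduces the published weights to ≤ 0.002 per
component, and the path-product synthesis reproduces 77 of the 78 published
integrated cells exactly at 4 d.p. (all within 6e-4; the published figures
were printed from 3–4 d.p. intermediates, so exact-decimal equality
everywhere is not attainable from full-precision arithmetic, nor desirable).

Two bundled values deserve a note. The savings-rate leaf stores 0.29 — the
unit-cost savings fraction 1 − 104.65/148.44 = 0.2950 truncated at two
decimals — verbatim rather than re-derived. And the two qualitative leaves
named in the source (scientific-level improvement, labor-intensity
reduction) carry the `graded` flag; the remaining leaves are `positive`
except the two cost leaves marked `reverse`.

## The synthetic generator

`generate_fixture` emulates the assumed data-collection setup: balanced
hierarchies of configurable depth (default 3) with 3–9 children per node,
panels of 7 experts (the size used in the case study) scoring uniformly
over {0, 0.5, 1} (configurable skew for consensus panels), two or more
alternatives, and raw leaf values drawn uniformly — on [0, 1] for graded
leaves, an arbitrary [0, 100] scale otherwise. Identical seed and
configuration give identical output.

What the generator does *not* emulate: correlated expert opinion, systematic
disagreement between experts and field measurements, non-uniform indicator
scales or measurement error, and any temporal dynamics (production effects
of harvesting lag by years; the model here is a static snapshot). Passing
tests on generated data therefore demonstrate the calculus's structural
invariants — complementarity, additive consistency, order preservation,
eigenvector agreement — not predictive validity on real forest data.

## Ecological indicator calculators

The `indicators` module computes raw values for the quantitative ecological
leaves: Simpson diversity N(N−1)/Σ n_i(n_i−1), Shannon entropy −Σ r_i ln
r_i, landscape integrity V·O·R, plantation productivity (sum of seven
annual production terms), restoration force M_s/F_t, and the monetary
valuations for water conservation (flood storage + water supply), soil and
water conservation (K·P_r/2), air purification (M·L·d·P_y·(1+Z)·K_l), soil
improvement (G·S_1·Σ P_1i P_2i P_3i) and willingness-to-pay for future
generations. Because the source formulas reuse one-letter symbols across
indicators with different meanings, every calculator namespaces its
parameters with descriptive keyword names; docstrings give the mapping.
Two interpretive choices: the willingness-to-pay divisor is taken to be
the total respondent count (the only reading that keeps grade fractions
summing to ≤ 1), and the three soil-improvement component factors enter
only as a product since their individual meanings are not specified at the
source. These calculators are optional front-ends — the evaluation pipeline
accepts leaf values from any origin, as in the bundled case where most
leaves come from expert assessment and survey statistics.

## Known limitations

- Only the three-scale complementary calculus is supported; no Saaty 1–9
  input, no consistency ratios, no fuzzy-number (triangular/interval)
  extensions.
- Hierarchies must be balanced (equal leaf depth); composite path products
  across unequal depths would not be comparable without a normalization
  the model does not define.
- The comprehensive score is linear in the leaves; interactions between
  indicators are not modeled beyond what the hierarchy encodes.
- No sensitivity analysis over terrain, cutting area or skidding distance
  is included.
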