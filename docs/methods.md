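# Methods

## Scope and model

`infodecomp` operates on fully specified joint probability mass functions
over N named variables with finite alphabets, N ≤ 4 for lattice work. It does
not estimate distributions from samples; the pmf *is* the input. All
quantities are in bits (base-2 logarithms). Internally probabilities are
IEEE-754 doubles; an exact-rational mode was considered and rejected because
every supported decomposition is a short composition of sums, minima and
logarithms whose error is far below the 1e-9 conservation tolerances used
throughout.

## The redundancy lattice

Atoms are antichains of nonempty variable subsets ("sources") under the
partial order α ⪯ β iff every source of β contains some source of α. The
all-singletons atom (full redundancy) is the unique bottom, the single
full-set source (full synergy) the unique top. Enumeration proceeds by
depth-first extension: sources are visited in a fixed (cardinality, index)
order and a source joins the current antichain only if it is
inclusion-incomparable with everything already chosen, so each antichain is
produced exactly once. The atom count follows the Dedekind numbers minus two
(1, 4, 18, 166 for N = 1…4); N = 5 would already have 7579 atoms, which is
why `enumerate_antichains` refuses N > 4 rather than degrading slowly.

Atoms carry a canonical label — sources sorted by (cardinality, index
order), indices ascending, rendered `{X1}{X2,X3}` — used for table keys,
TSV output and lookup. The topological order used everywhere (file rows,
Möbius processing) sorts atoms by (strict-down-set size, canonical label),
which is deterministic and respects ⪯ because the down-set of a strictly
lower atom is strictly smaller.

Möbius inversion is computed as iterative subtraction in that topological
order with cached strict down-sets: partial(α) = cumulative(α) − Σ_{β≺α}
partial(β). Each atom is resolved exactly once; the inclusive down-set sum of
the output reproduces the input table to float precision, which the tests
assert on randomized tables.

## Redundancy functions

The decomposition is parameterized by a redundancy function
h∩(x, α, ℙ): the entropy shared by all sources of α at the outcome x. The
shipped default is h_min — the minimum local surprisal across the sources —
which is localizable (defined per outcome) and yields non-negative local
partial atoms. Ties in the minimum need no tie-breaking since only the value
is used. Alternative functions (e.g. differentiable shared-exclusion
variants) can be registered by name through
`register_redundancy_function`; none is shipped because h_min is the only
closed form this package commits to. Functions based on local co-information
are deliberately excluded: they can produce negative *local entropy* atoms,
which destroys the surprisal-difference reading of the divergence atoms.

## PED, GID and their relatives

- **Local PED**: Möbius inversion of {h∩(x, α)}; atoms sum to −log₂ ℙ(x).
- **Expected PED**: the probability-weighted average of local tables
  (decompose locally, then average — not the decomposition of averaged
  cumulative values). Atoms sum to H(ℙ).
- **GID**: atomwise E_ℙ[h∂^ℚ − h∂^ℙ] over supp(ℙ). Atoms sum to D(ℙ‖ℚ).
  Expectation weights come exclusively from the posterior; prior-only states
  contribute nothing. Individual atoms may be negative — the observer
  holding the posterior is *more* surprised by that combination of sources —
  and the copy-gate decomposition in the tests exhibits this.
- **Cross-entropy decomposition**: the prior's local tables averaged under
  the posterior's weights; equals GID + expected PED of the posterior,
  atomwise.

### Support policies

D(ℙ‖ℚ) is undefined when ℙ puts mass where ℚ has none. The default policy is
**strict** (raise), because both escape hatches bias the result:
**pseudocount** adds ε (default 1e-6, renormalizing afterwards) to every
state of ℚ's full alphabet product, which makes formerly impossible states
enormously surprising under the prior and lets them dominate the
expectation; **restrict** drops the offending posterior states and
renormalizes, discarding posterior information. The ε default and the
add-then-renormalize order are conventions of this package; callers who care
should pass their own ε. Alphabets and variable lists of prior and posterior
must match exactly; alignment is by state tuple, never row order.

## Derived measures

- **Total correlation** TC = D(ℙ‖∏ᵢℙ(Xᵢ)). The product-of-marginals prior
  always covers supp(ℙ), so no support policy is needed.
- **Negentropy**: GID against the uniform prior on the declared alphabet
  product.
- **O-information** Ω = (2−N)·TC(**X**) + Σᵢ TC(**X**₋ᵢ), N ≥ 3; and, at
  N = 3, a fixed linear combination of the 18 partial-TC atoms. The
  coefficient of an atom is (#covering subsystems − 1), where a subsystem
  "covers" an atom when some source fits inside it — which is why bivariate
  single-source atoms get coefficient 0 (the O-information is blind to
  pairwise structure) and only the top atom counts negatively (toward
  synergy).
- **TSE complexity** TSE = Σᵢ [(i/N)·TC(**X**) − ⟨TC⟩ᵢ], where ⟨TC⟩ᵢ averages
  over all size-i subsets and the total correlation of a single variable is
  taken to be 0 (a one-variable system cannot deviate from independence).
  At N = 3 the package also evaluates the ±1, ±2/3, ±1/3 atom-coefficient
  expansion, in which atoms low on the lattice are penalized and high atoms
  rewarded.
- **Identity status**: both N = 3 expansions are *exact* for partial-TC
  atoms, for any redundancy function whose single-source cumulative value is
  the source surprisal. The key fact is that the inclusive down-set sum at a
  single-source atom {**S**} telescopes (by the Möbius construction) to
  E_ℙ[h^ℚ(x_S) − h^ℙ(x_S)], and with ℚ = ∏ᵢℙ(Xᵢ) this is exactly TC(X_S).
  Expanding each subsystem TC this way and collecting terms yields the
  stored coefficient vectors. The coefficients are stored as data for N = 3
  only; the same derivation would generalize but is not exposed.
- **Single-target decomposition**: I(inputs;T) = E_T[D(ℙ(inputs|t) ‖
  ℙ(inputs))]; each conditional divergence is decomposed on the *input*
  lattice and averaged under ℙ(T). Atoms sum to the mutual information and
  the single-input down-set sums reproduce I(Xᵢ;T) exactly (same telescoping
  argument). With h_min this matches the pointwise
  informative/misinformative decomposition — notably, for a copied input the
  result is (redundancy 1, unique₁ 0, unique₂ −1, synergy 1), not the
  (0, 1, 0, 0) a Shannon-intuition reader might expect; the tests pin this
  against a brute-force oracle. The alternative joint formulation
  I = D(ℙ(inputs,T) ‖ ℙ(inputs)×ℙ(T)) is decomposed on the full lattice
  (18 atoms for 2 inputs); no linear bridge between the two atom sets is
  asserted, since none is known.

## Fixtures and what they do (not) show

The generator module provides the logic gates (XOR, AND, OR, COPY) on
equiprobable binary inputs, uniform and giant-bit distributions, and
symmetric-Dirichlet random pmfs (concentration 1.0 by default — a flat prior
over the simplex; seeds are mandatory arguments, no hidden global state).
These are exact, fully specified distributions: passing tests demonstrate
the algebraic correctness of the decompositions (conservation,
down-set/marginal constraints, the atom-combination identities, agreement
with brute-force oracles) on desk-scale systems. They do not exercise
estimation error, sampling noise, or large-alphabet/large-N behaviour, and
say nothing about the statistical problems of applying these measures to
empirical data.

Randomized panels in the tests and the acceptance script use 50 seeded
Dirichlet distributions at N ∈ {2,3}; the whole suite runs in a few seconds
because every object is at most 166 atoms by 16 states.

## Numerical conventions

- Probabilities ≤ 1e-15 in absolute value are treated as zero and dropped
  from supports at construction.
- Construction requires unit mass within 1e-12; file ingestion tolerates
  1e-6 and renormalizes with a logged warning.
- Conservation identities are asserted at 1e-9, the atom-combination
  identities at 1e-8 (they chain more floating-point sums).
- Sums use `math.fsum` where totals feed tolerance checks.
- Atom-table TSVs render values with 10 significant digits, rows in lattice
  topological order, so identical inputs give byte-identical outputs.

## Known limitations

- N ≤ 4 for full-lattice work, by design; the combinatorics, not the code,
  are the obstacle beyond that.
- Only h_min ships; the plugin contract is the extension point.
- No continuous variables, no estimators, no temporal/dynamic
  decompositions.
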