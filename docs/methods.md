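# Methods

## Model and state encoding

A synchronous Boolean network on nodes x₁..xₙ updates every node at each
discrete step through a logical function of the full current state.
Logical values are embedded as basis vectors — true ↦ e₂¹ = (1,0)ᵀ,
false ↦ e₂² = (0,1)ᵀ — and the integrated state is the semi-tensor product
(STP) x = x₁ ⋉ … ⋉ xₙ, a basis vector of dimension 2ⁿ whose index is

    j = 2ⁿ − Σᵢ bitᵢ · 2^{n−i}            (all-ones ↦ 1, all-zeros ↦ 2ⁿ).

All indexing in the package is 1-based to match this convention, and truth
tables are ordered by integrated-state index (all-ones assignment first),
*not* the more common all-zeros-first order. This single convention fixes
the column order of structure matrices, transition matrices and truth
tables consistently.

Matrices whose columns are all basis vectors ("logical matrices") are
stored as a column→row index list. The STP of two logical matrices is again
logical and is computed purely by index composition; dense arrays (any
dtype, including symbolic object arrays) appear only when a general operand
is involved. This keeps the algebraic transition-matrix construction
O(n·2ⁿ) in practice instead of forming 2²ⁿ-sized dense intermediates.

## Transition matrix: two routes, one answer

The normative definition of L is enumerative: column j encodes the
synchronous update of the state decoded from j. The algebraic route builds
each node's 2×2ⁿ structure matrix Mᵢ and evaluates

    Lₙ = M₁ ⋉ ∏ᵢ₌₂ⁿ [(I_{2ⁿ} ⊗ Mᵢ) ⋉ Φₙ]

left to right. The power-reducing matrix Φₙ (2²ⁿ×2ⁿ, column j carrying its
1 at row (j−1)·2ⁿ + j) collapses the duplicated state factor: x ⋉ x = Φₙ ⋉ x
for every basis state. Only Φ₂ has a conventional printed form; the general
row formula is adopted here with the x ⋉ x contract as the normative
definition, verified exhaustively for n ≤ 4 in the tests. Because the
associativity/lift bookkeeping of the product formula is easy to get wrong,
the package treats enumeration as ground truth and asserts the algebraic
result against it (exhaustively in tests for the bundled examples and
random networks up to n = 6; the CLI cross-checks on every invocation).

## Reachability semantics

The transition diagram is the functional graph of the successor map: out-
degree exactly one, so it decomposes into attractor cycles plus transient
trees. "Reachable in finite time" is read as ≥ 1 step, so an attractor
state is reachable from itself around the loop, and:

* a unique attractor ⇒ reachable states = that cycle's states;
* two or more attractors ⇒ no state is reachable from *every* initial
  state, so the reachable set is empty. The source examples only exhibit
  single-attractor systems; the empty-set consequence for the
  multi-attractor case follows from the definition and is made explicit
  here.
* the network is reachable ⇔ the map is a single 2ⁿ-cycle permutation,
  equivalent to the conjunction of the three matrix properties
  (permutation, zero diagonal, no 2-cycles for n ≥ 2) plus a single orbit.
  The 2-cycle exclusion is waived for n = 1, whose unique reachable network
  necessarily swaps its two states.

A trajectory decomposes into transient prefix plus periodic cycle at the
first state revisit; the transient ends at the *first* state that lies on
the attractor (a trajectory entering the cycle mid-way has that entry state
counted in the cycle, not the transient). Default simulation length is
2·2ⁿ + 1 steps, which guarantees the revisit for any deterministic map.

## Two-level minimization

"Simplest form" of a Boolean function is not formally defined in the
literature this package follows; the package commits to exact two-level
minimization: Quine–McCluskey prime implicants followed by an exact minimum
cover (essential primes first — they belong to every cover — then
exhaustive search over the remainder by increasing cover size). Ties are
broken by fewer total literals, then by lexicographically smallest
serialized form, making the output deterministic. Product terms are emitted
with literals in declared-variable order and sorted lexicographically. This
reproduces the canonical minimized dynamics of the six 2-node forms and the
worked feedback law. Exact covering is exponential in principle; intended
use is k ≲ 6 variables, which covers every network size the dense 2ⁿ
representations target. sympy's `SOPform` is used in the test suite as an
independent oracle, never as the implementation.

## Enumeration of reachable 2-node networks

Each node's update is one of the 16 two-variable connectives' truth tables,
so all 2⁴·2⁴ = 256 structure-matrix combinations are swept; column j of the
induced L encodes the pair of table entries. Filtering by the single-cycle
test and deduplicating at the transition-matrix level leaves the six
single 4-cycle permutations, reported in the conventional order L1..L6
(keyed by successor tuple, a stable citable ordering). Swapping x₁ ↔ x₂
induces a state permutation; conjugating each L by it maps the six forms
onto each other in three pairs. For general n the reachable matrices are
the (2ⁿ−1)! single-cycle permutations; full enumeration is allowed for
n ≤ 3 and refused (count only) beyond.

## Control synthesis by block doubling

A lower-triangle template has its first n nodes independent of the last,
which carries the input u. Given a reachable n-node base, each nonzero cell
(i, j) of Lₙ doubles into a 2×2 identity block (2j−1 → 2i−1, 2j → 2i) or
skew block (2j−1 → 2i, 2j → 2i−1) of L_{n+1}; collapsing blocks always
recovers Lₙ. Around the base cycle the blocks compose, and the two sheets
of the doubling exchange iff the number of skew blocks is odd — so the
extension is a single 2^{n+1}-cycle exactly for odd skew counts. (The prose
statement of this parity rule in the source literature is ambiguous between
identity and skew counts; the skew-count reading is the one consistent with
the sheet-exchange argument and is verified exhaustively in the tests for
the 2-node base and by sampling for 3-node bases.)

The feedback law is read off the extension: node n+1's truth table is bit
n+1 of the decoded successors, exact-minimized into u. Substituting u for
the input closes the loop with transition matrix equal to the target
extension by construction (asserted bit-exactly). The default assignment is
a single skew block on the base cell with the largest column index —
deterministic, and it reproduces the worked 3-node example; any assignment
can be supplied explicitly as per-column block types or (cell, type) pairs.
Structure matrices of base nodes lift to the extended space by M* = E ⋉ M
with the dummy operator E = (1 1 0 0 / 0 0 1 1), which appends an ignored
variable.

## Synthetic fixtures

`stpbn.fixtures` generates seeded random closed networks (depth-limited
random expression trees over the grammar connectives), random successor
maps, and random single-cycle permutation matrices. These emulate arbitrary
small Boolean dynamics for property tests (construction equivalence,
relabeling invariance, parity rule); they do not emulate biologically
structured networks — sparse in-degree, canalyzing functions, realistic
attractor statistics — so passing property tests certifies the algebra and
graph analysis, not biological plausibility of any particular random
instance. Problem sizes used in the tests (n ≤ 6 for construction
equivalence, exhaustive sweeps at n = 2, sampling at n = 3) were chosen
because the properties are dimension-generic: index arithmetic does not
change character with n, while exhaustive checks at small n give complete
coverage of the case analysis.

## Numerical and degenerate-input choices

* No floating point anywhere in the core: basis-vector indices and integer
  dense arrays only, so all comparisons are exact.
* `semi_tensor_product` accepts any matrix dimensions (α = lcm makes it
  total); logical inputs produce logical outputs.
* Degenerate networks: n = 1 is fully supported (including the waived
  2-cycle property); constant update functions are legal and produce
  non-permutation transition matrices, classified normally.
* Networks with declared inputs refuse transition-matrix construction
  until the inputs are bound (substitution closes the loop), keeping L
  square; appending inputs as extra state nodes is expressible by declaring
  them as nodes instead.
* Enumeration order of full-cycle matrices follows the lexicographic order
  of the cycle's visiting sequence after state 1 — deterministic across
  runs.

## Known limitations

* Dense-by-states representations bound practical use to n ≲ 20; no sparse
  or symbolic state-space back end.
* Synchronous deterministic semantics only: no asynchronous or
  probabilistic updates.
* Exact SOP minimization targets small k; no multi-level synthesis or
  don't-care handling, and no optimality claim about literal counts beyond
  two-level form.
* Control synthesis covers lower-triangle extensions of reachable bases;
  output feedback and non-reachable bases are out of scope.
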