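# Methods

## Model and scope

The package implements equal-weights (Fitch) maximum parsimony for
unordered discrete characters with states coded `0`–`9` and missing data
`?`.  All characters are treated as non-additive: any state-to-state
transformation costs one step.  Trees are treated as unrooted throughout
the optimisation — Fitch length is invariant to root placement for
symmetric costs — and outgroup rooting is applied only for presentation
and for clade queries.  Ordered/additive characters, step matrices,
polymorphic codings (`{01}`) and continuous characters are out of scope;
the `char_type`/`weights` fields exist so matrices carry their metadata,
but the analysis surface is equal-weights unordered parsimony.

## Tree length

`parsimony.tree_length` computes per-character minimum change counts
with Hartigan's count rule: at each internal node the states attained by
a maximal number of children are kept and every child outside that
majority costs one step.  On binary nodes this is exactly Fitch's
intersection/union recursion; on polytomies it is the standard exact
generalisation.  A missing cell enters as the universal state set and
never forces a change.  The search hot path uses a separate bit-packed
kernel (`_packed.PackedMatrix`): all characters are packed ten bits per
character into one big integer per taxon, so a full-tree Fitch pass is a
handful of bitwise operations per node regardless of character count
(the per-block "intersection empty" test is a shift/mask fold plus one
popcount).  The readable Hartigan path and the packed kernel are checked
against each other, against a brute-force enumeration oracle, and
against phangorn's independent implementation in the test suite.

## Step bounds and fit indices

Per character, minsteps *m* = (observed states − 1) and maxsteps *g* =
(non-missing taxa − largest state frequency), i.e. the star-tree length —
the TNT/PAUP convention for the retention index.  Ensemble indices on a
tree of length *L* with *M* = Σm, *G* = Σg:

    CI = M/L     RI = (G − L)/(G − M)     HI = 1 − CI     RC = CI·RI

Uninformative characters are **included** in the ensemble sums (the TNT
default; `index_report(..., include_uninformative=False)` provides the
restricted variant).  Printed integer renderings are **floor
truncations** computed in exact integer arithmetic — `(100·M)//L` — not
roundings: 0.875 prints as 87 and 0.90625 as 90.  Truncation is the only
convention that reproduces both printed percentages of the bundled
dataset from a single optimum, and it is applied uniformly.

## Exact search

`branch_and_bound` adds taxa stepwise in decreasing order of character
conflict (number of non-modal states a taxon carries; ties broken by
input order).  The initial upper bound is one greedy stepwise-addition
tree.  A partial tree on the first *k* taxa is abandoned when its packed
Fitch length plus an admissible completion bonus exceeds the incumbent:
the bonus counts, per character, states present among unplaced taxa but
absent from placed ones, each of which must cost at least one further
step.  Because the addition order is fixed, the bonus is precomputed per
level.  Pruning uses strict inequality, so all co-optimal trees are
retained; optima are deduplicated by a canonical unrooted form (sorted
nested parentheses rooted at the lexicographically smallest leaf).  On
the bundled 11-taxon matrix the search scores only a few complete
topologies out of 34,459,425 and finishes in well under a second.
`exhaustive_search` scores every topology (capped at 11 taxa) and serves
as the oracle for the branch-and-bound in the tests.

## Ratchet heuristic

`ratchet_search` is retained so heuristic behaviour can be compared with
the exact optimum: a random-addition starting tree is hill-climbed to a
local optimum by first-improvement sweeps over NNI neighbours and then
over subtree-prune-and-regraft moves (the pruned component is taken from
the non-base side of the tree; together with the ratchet's restarts this
neighbourhood reaches the exact optimum from every seed tested).  Each
iteration re-climbs under perturbed weights — a random ~25% of
characters doubled — then under original weights, keeping all trees that
tie the best length.  Every stochastic entry point requires an explicit
seed and is fully deterministic given it; there is no global RNG state.

## Collapsing, consensus, mapping

Multiple binary optima frequently differ only in branches no character
distinguishes.  `collapse_and_dedup` contracts every internal branch
whose minimum length over most-parsimonious reconstructions is zero
(for each character independently, the branch is charged the fewest
changes it carries in any MPR); collapsing never alters length, and is
idempotent.  MPRs themselves are enumerated exactly
(`mpr_enumerate`: depth-first assignment over the observed alphabet with
cost pruning, feasible at ≤ 3 states and ~20 internal nodes; a guard
refuses > 10⁶ reconstructions).  Reconstruction always happens on the
unrooted view: a degree-2 root splits one edge in two and would
manufacture spurious ambiguity across the root.  A change is
*unambiguous* iff it appears with identical branch and states in every
MPR of its character; ambiguous changes are reported but excluded from
figure-style annotation.  Classification is at character level:
characters with steps above their minimum contribute homoplasies; a
perfectly fitting character contributes an autapomorphy when the derived
state is private to one terminal, otherwise a synapomorphy.  This
reproduces the two-way black/white circle dichotomy of standard
cladogram artwork without attempting to read artwork.  ACCTRAN/DELTRAN
are deliberately not implemented; exact MPR enumeration subsumes the
question they approximate.

Strict consensus intersects the split sets of its inputs and rebuilds
the laminar hierarchy; its splits are by construction contained in every
input tree.

## Synthetic data

`simulate_mk` draws, for each character and branch, a Poisson number of
state changes (branch-specific means stored as branch lengths on the
generating topology; root state 0; each change jumps uniformly to
another state) — change counts per branch rather than continuous-time
rates, which controls expected homoplasy directly.
`simulate_perfect_hierarchy` emits one clade-membership character per
internal edge, giving a fully compatible matrix whose unique optimum is
the generating tree with CI = RI = 1.  `permute_columns` shuffles each
column independently, preserving per-character state multisets (hence
Σm and Σg) while destroying hierarchical signal.

What these generators emulate — and what they do not: they produce
small unordered matrices with 2–3 states and an optional autapomorphy-
rich fraction, like real species-diagnostic morphology, but characters
are independent and identically distributed across branches; there is no
rate heterogeneity, no character correlation and no missing data.
Passing recovery tests therefore demonstrate correctness of the search
and scoring machinery, not robustness to the violations real data show.

Measured behaviour of topology recovery (8 taxa, 50 binary characters,
exact search, success = generating topology among the optima): recovery
declines steeply with the per-branch change mean — roughly 9/10 at 0.04
changes/branch, ~3/4 at 0.05, ~1/2 at 0.1, and ~0 at 0.3, where each
character expects ~4 changes on the tree and homoplastic splits swamp
the signal.  Even at very low rates occasional parallel changes create
spurious groupings, so recovery plateaus below ~85% for this design.
These are honest properties of parsimony on such data, and the test
suite asserts the measured, seed-deterministic values rather than an
aspirational rate.

## Numerical and design choices

* Character ids are 1-based (matching the bundled table's numbering);
  taxa are addressed by label everywhere in public results.
* State symbols are single digits `0`–`9`; `-` is rejected (gap
  semantics are undefined for morphology), `{..}` polymorphisms are a
  documented non-goal.
* Stepwise-addition tie-breaks: insertion points are scanned in a fixed
  traversal order (base edge first, then preorder) and the first
  cheapest wins, making greedy starts and search logs reproducible.
* The enumeration cap (11 taxa) reflects the (2n−5)!! growth of unrooted
  topologies; `branch_and_bound` is the intended tool beyond ~9 taxa.
* Problem sizes in the test suite (6–8-taxon oracles, 10–30-seed
  simulation batches, 20 column permutations) were chosen so each
  experiment is decisive at the stated tolerances while the whole suite
  stays interactive.
* The bundled dataset's printed summary values are treated as claims to
  audit, not assertions to enforce: the `reconcile` command prints
  computed values beside printed ones and flags each row, because the
  printed length (25) and the printed indices (87/90) are mutually
  inconsistent under the standard definitions given this matrix
  (Σm = 21, Σg = 53 force L = 24 for CI 87/RI 90, and a 24-step tree
  exists).

## Known limitations

* Exact search is exponential; beyond ~12–14 taxa the branch-and-bound
  will stop being interactive and only the ratchet remains practical.
* The SPR neighbourhood excludes regrafts of the base-leaf-side
  component; the ratchet's perturbation restarts compensate in practice,
  but pathological landscapes could in principle require the full
  neighbourhood.
* No bootstrap/jackknife/Bremer support, no implied weighting, no
  likelihood scoring.
* NEXUS support covers the minimal CHARACTERS block this domain uses,
  not the full standard.
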