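# Methods

## Model and semantics

The package decides satisfaction of basic temporal formulas over finite runs
of a labeled system model. A system model is a directed graph with one
initial state and a truth assignment over atomic propositions at every state;
a *path* is a state sequence from the initial state; a *run* refines a path
by choosing, at every state, one codebook letter whose Boolean condition
holds there (a state satisfying neither `p` nor `q` admits, say, both
`s = ¬q` and `u = ¬p∧¬q`, so a path can carry several runs). A run satisfies
a formula iff the formula's finite-word automaton accepts its letter word.

Two quantifier conventions are composed:

* **existential over runs** — a path is satisfied iff *some* admissible run
  is accepted (each run is evaluated in its own tube, so one successful
  molecule suffices);
* **universal over paths** — the model satisfies the formula iff *every*
  enumerated path is satisfied. Existential CTL formulas are obtained by
  negating the verdict of their universal dual exactly once
  (`EpUq → ¬phi1`, `EFp → ¬G¬p`, `EGp → ¬F¬p`, `EXp → ¬X¬p`).

Finite-word semantics is used throughout because the tube readout is finite:
a run "holds forever" only up to the end of its strand. Consequently `Gp`
accepts `p^n` for every n ≥ 0 (a single looping accepting state), `Xp`
requires at least two letters (runs shorter than two states fail it), and
the empty word is accepted iff the initial state is accepting.

## Path enumeration and bounds

Exploration is bounded by `|V|·2^(|V|−1) + |E|` paths; for the interval-chop
formula the bound is the sum of that expression over the model's annotated
prefix and suffix intervals (`(2,2)` and `(2,1)` for the fixture `M2`,
giving 11). When the initial state lies on a cycle, path *k* repeats the
lexicographically smallest simple cycle through the initial state *k* times
and then follows the shortest route to a terminal state — exactly the
`(0,1)^k, 2` families of the bench run tables, which makes per-path reports
diffable against them. Models whose initial state is acyclic fall back to
exhaustive bounded enumeration, deduplicated and sorted for determinism.
Checking stops at the first unsatisfied path (one counterexample settles a
universal verdict); runs within a path are tried in letter-sorted order and
stop at the first complete tiling.

## Encoding and tiling

Strands are stored 5′→3′ with a written-orientation flag; the 3′→5′ table
convention for stickers is a display concern, and comparisons against
printed tables ignore grouping whitespace. The Watson–Crick complement is
base-wise with no reversal, so a sticker's text stays aligned under the
segment it pairs with.

Hybridization is idealized as perfect-complement, zero-mismatch pairing
(reported pairing specificity in the bench experiments exceeds 99%), which
turns annealing into an exact string-partition problem: a left-to-right
dynamic program over strand positions decides whether the strand can be cut
into segments each complementary to a provided sticker, with the first
segment forced to an initial-type sticker and the last to an acceptance-type
sticker in full-strand mode. The DP is exhaustive, so a tiling is found iff
one exists; for incomplete strands the reported witness maximizes the
covered prefix, with ties broken by sticker order, and uncovered positions
are listed (the electrophoresis "various lengths" signal). Coordinates are
1-based closed intervals on the 5′→3′ strand.

A codebook is validated before use: codewords pairwise distinct and of
uniform length, spacers of uniform length, no codeword equal to a spacer,
a codeword for every automaton letter, and enough spacers to address every
state index with one spare trailing spacer (the acceptance sticker for state
`j` covers `X_{j+1}…Xm I2` and needs `j < m`). The published codebooks use
m = 3 for 3-state automata and m = 7 for the 5-state one; no general rule
for choosing m is enforced beyond sufficiency.

## Fixture reconstruction

The bench models `M1`–`M3` are shipped with labelings reconstructed from the
published run tables: `M1` = `{p}·{}·{q}` over the cycle `0↔1` with exit
`1→2`; `M2` = `{p1,p3}·{p1,q1}·{p2}·{q2}` over `0↔1, 1→2→3` (state 0 carries
`p3` so the compound letter `m1 = p1∧p3` is admissible there, and only
there); `M3` = `{p}·{q}` over the two-cycle. `M1`'s terminal state has `p`
false — the choice is unconstrained by any published verdict and is recorded
here. These labelings reproduce every published verdict: the eight basic CTL
results on `M1`, the 15/15, 11/11 and 6/6 satisfied path tables, and the
projection-formula failure on `M2` (all four admissible runs of path 1 are
rejected).

## Kinetics

Competitive hybridization is simulated with the Gillespie direct method —
statistically identical to next-reaction-style algorithms and simpler to
verify. The annealing network for one tube has the input strand, each
sticker, and one complex per subset of the sticker placements found by the
exact tiling; reactions are stepwise, irreversible sticker additions in any
order, with mass-action propensities on molecule counts. Default conditions
are the bench tube: 60000 copies of each strand in 1e-15 L. Rate constants
are user-supplied (equal by default) because none are published; therefore
only structural properties are claimed quantitatively — per-strand mass
conservation at every sample, a complete-duplex count never exceeding the
smallest reactant count, and convergence of the duplex fraction to 1 when
the complete duplex is the only sink. Published time-to-completion figures
are not reproduced. Nonspecific (mismatched) binding is not modeled.

## What the tests do and do not show

Random-instance properties use well-separated synthetic codebooks (letter
codewords over {A,C}, spacers over {G,T}) so that tiling ambiguity cannot
arise from accidental sequence coincidences; with such codebooks, complete
annealing is verified to coincide with NFA acceptance on hundreds of random
(automaton, word) instances, and the DNA route agrees with a pure-logic
evaluation of the automaton on all bounded runs of random small models.
Passing these tests shows the simulation is faithful to the idealized
perfect-pairing model; it says nothing about thermodynamic behaviour of real
sequences (ensemble defect, free-energy landscapes, melt curves), which are
out of scope.

## Numerical and degenerate-input choices

* Tiling tie-breaks and path ordering are deterministic as described above,
  so reports are byte-reproducible.
* An empty sticker set is trivially incomplete, not an error; a zero-length
  core is vacuously covered.
* A state that admits no letter of the full codebook raises a mismatch
  error; a state that merely admits no letter of one automaton's alphabet
  yields a path with zero runs, which fails the existential readout (this is
  how a model with a `¬p∧¬q` state correctly falsifies `ApUq`).
* The SSA is exact and seeded; trajectories are sampled on an even grid and
  are piecewise constant between events.

## Problem sizes

All bench checks run at their published sizes (bounds 15, 11, 6; group
experiments of 10 and 70 subsets; 60000-molecule trajectories). Random
property tests use automata of at most 5 states and 3 letters with words up
to length 8, and system models of at most 3 states with exploration bounds
capped at 5 — sizes at which the independent brute-force oracles remain
exhaustive.
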