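# stickermc

Temporal-logic model checking with simulated DNA **sticker automata**.

Model checking asks whether every behaviour of a finite-state system
satisfies a temporal property. `stickermc` implements a molecular-computing
route to that question: the property is compiled to a finite automaton, each
bounded run of the system is encoded as a single DNA strand, and the
automaton's transitions become short single-stranded "stickers" that are
Watson–Crick complementary to contiguous segments of the run strand. In the
tube, a run is accepted exactly when the stickers anneal into a *complete*
double strand from initiator to terminator; here the annealing step is
simulated exactly, so the package doubles as a design and verification tool
for sticker-automaton experiments.

It is aimed at DNA-computing and molecular-programming researchers who want
to design codebooks, generate the strand libraries for an experiment, predict
the tube readout, and cross-check it against ordinary automaton semantics.

## The method

A property automaton is an NFA `(Σ, Q, T, q0, F)` over *codebook letters*:
atomic propositions (`p`, `q`, …) and compound letters with Boolean
conditions (`r = ¬p`, `s = ¬q`, `u = ¬p∧¬q`, `m1 = p1∧p3`, …). A word
`a1…an` is encoded 5′→3′ as

```
I1 · X0…Xm · C(a1) · X0…Xm · C(a2) · … · C(an) · X0…Xm · I2
```

with letter codewords `C(a)`, spacers `X0…Xm`, initiator `I1` and terminator
`I2`. Automaton components become stickers (written 3′→5′, aligned under the
input strand):

* transition `(si, a, sj)` → complement of `X_{i+1}…Xm C(a) X0…Xj`
* initial state `si` → complement of `I1 X0…Xi`
* acceptance state `sj` → complement of `X_{j+1}…Xm I2`

How far a sticker reaches into the flanking spacer blocks encodes the state
indices, so the stickers tile the whole strand without gaps or overlaps iff
the NFA accepts the word.

Model checking iterates this over a labeled system model: paths are
enumerated up to the exploration bound `|V|·2^(|V|−1) + |E|` (summed over
prefix/suffix intervals for the interval-chop formula), each path is refined
into its admissible runs, and the model satisfies the formula iff every path
has some run whose strand anneals completely.

Supported formulas: the eight basic CTL formulas (`ApUq, AFp, AGp, AXp` are
checked directly; `EpUq, EFp, EGp, EXp` via negation of their universal
dual), the two basic interval formulas `phi2 = (p1Uq1);(p2Uq2)` and
`phi3 = (pUq)*`, and the basic projection formula
`phi4 = ((p1Uq1),(p2Uq2)) prj (p3∧Xq3)`. The three bench system models
(`M1`, `M2`, `M3`) and the three published codebooks ship as fixtures. A
Gillespie stochastic-simulation module models the competitive hybridization
kinetics of a sticker group.

## Worked example

Does model `M1` (a `p`-state and a blank state cycling, with an exit to a
`q`-state) satisfy `EFp` — "some path eventually reaches `p`"?

```sh
$ stickermc check --model M1 --formula EFp
M1 |= EFp: satisfied
$ echo $?
0
```

The JSON report (add `--report out.json`) shows *why*: the existential
formula was reduced to its universal dual `G¬p` ("every path stays off `p`
forever"), whose check fails immediately — path 1 = states `0,1,2` emits the
letter word `p·r·r`, the `G¬p` automaton has no transition on `p`, no sticker
covers that segment, and the strand stays partially single-stranded:

```json
"verdict": true,
"paths": [ { "k": 1, "path": [0, 1, 2], "satisfied": false, "n_runs": 1 } ],
"decision_basis": { "core": "G!p", "core_verdict": false, "negated": true }
```

`M1` does **not** satisfy `G¬p`, so it **does** satisfy `EFp` (exit code 0;
unsatisfied formulas exit 1).

The same check from Python, for the dual-of-until formula `phi1`:

```python
>>> import stickermc as smc
>>> m1 = smc.fixture("M1")
>>> res = smc.check(m1, "phi1")
>>> res.verdict, res.bound, res.n_satisfied, res.rows[0]["witness"]
(True, 15, 15, ('s', 'u', 'q'))
```

All 15 bounded paths are satisfied — path 1's witness run `s,u,q` encodes to
a 65-nt strand whose trimmed 51-nt core is tiled by stickers `t0s0`, `t0u1`,
`t1q2` at positions 1–15, 16–33 and 34–51.

Other entry points: `stickermc encode` emits sticker sets or run strands as
FASTA, `stickermc tile` anneals a strand against a sticker FASTA (with
`--group-size k` for exhaustive subset experiments), `stickermc kinetics`
simulates a reaction network, and `stickermc fixtures --dump codebook-phi1`
prints a codebook as YAML.

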