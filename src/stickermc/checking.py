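"""The DNA model-checking loop and the per-logic checking algorithms.

The core loop plays the role of the tube protocol: enumerate the system's
paths up to the exploration bound; for each path, refine it into admissible
runs (one codebook letter per state, restricted to the formula automaton's
alphabet); encode each run as an input strand; anneal it against the formula's
sticker set; and read the verdict off the tiling.  A path is satisfied iff
some admissible run forms a complete double strand (each run gets its own
tube); the model satisfies the formula iff every path is satisfied.

Universal CTL formulas map directly onto the linear-time automata; the
existential ones are checked by negating their universal dual.  The interval
chop formula uses the sequential-composition bound over the model's
prefix/suffix intervals when that annotation is available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from .automata import (FSA, StickerError, SystemModel, admissible_letters,
                       composite_bound, enumerate_paths, run_length_bound)
from .encoding import Codebook, build_sticker_set, encode_input_run
from .formulas import (automaton_for, default_codebook_for, dual_reduction,
                       formula_spec)
from .tiling import readout, tile

__all__ = [
    "MCResult",
    "tl_mc_dna",
    "check_universal_ctl",
    "check_existential_ctl",
    "check_ctl",
    "check_itl",
    "check_ptl",
    "check",
]


@dataclass
class MCResult:
    """Model-checking verdict with the per-path table behind it.

    ``rows`` holds one entry per evaluated path: ``{"k", "path", "satisfied",
    "witness", "n_runs"}``.  Evaluation stops at the first unsatisfied path
    (one counterexample settles a universal check), so the verdict equals the
    conjunction of the recorded flags.  For existential formulas
    ``decision_basis`` records the universal core that was actually checked
    and the fact that its verdict was negated (exactly once).
    """

    verdict: bool
    formula: str
    model: str
    bound: int
    rows: list = field(default_factory=list)
    decision_basis: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "formula": self.formula,
            "model": self.model,
            "bound": self.bound,
            "paths": [dict(r, path=list(r["path"]),
                           witness=list(r["witness"]) if r["witness"] else None)
                      for r in self.rows],
            "decision_basis": self.decision_basis,
        }

    @property
    def n_satisfied(self) -> int:
        return sum(r["satisfied"] for r in self.rows)


def tl_mc_dna(model: SystemModel, formula_fsa: FSA, codebook: Codebook,
              bound: Optional[int] = None, formula_name: str = "") -> MCResult:
    """Check a model against one formula automaton via the DNA route.

    ``bound`` defaults to the run-length bound on the model's node and edge
    counts.  Runs of a path are enumerated in deterministic (letter-sorted)
    order and evaluation of a path stops at its first complete tiling.
    """
    if bound is None:
        bound = run_length_bound(model.n_states, model.n_edges)
    stickers = build_sticker_set(formula_fsa, codebook)
    paths = enumerate_paths(model, bound)
    rows = []
    verdict = True
    for k, path in enumerate(paths, 1):
        choices = [sorted(admissible_letters(q, model, codebook,
                                             restrict_to=formula_fsa.alphabet))
                   for q in path]
        if any(not c for c in choices):
            run_results = []  # some state supports no run of this automaton
        else:
            run_results = _run_iter(path, choices, codebook, stickers)
        verdict_row = readout(ReadoutView(run_results))
        rows.append({"k": k, "path": path,
                     "satisfied": verdict_row["satisfied"],
                     "witness": verdict_row["witness"],
                     "n_runs": verdict_row["n_runs"]})
        if not verdict_row["satisfied"]:
            verdict = False
            break  # one failing path settles the universal check
    return MCResult(verdict=verdict,
                    formula=formula_name or formula_fsa.name,
                    model=model.name, bound=bound, rows=rows)


class ReadoutView:
    """Lazy (label, tiling) sequence so readout can stop at the first
    complete run without materializing the whole run family."""

    def __init__(self, iterable):
        self._it = iter(iterable)
        self._n = 0

    def __iter__(self):
        for item in self._it:
            self._n += 1
            yield item

    def __len__(self):
        return self._n


def _run_iter(path, choices, codebook, stickers):
    for letters in itertools.product(*choices):
        strand = encode_input_run(letters, codebook)
        yield letters, tile(strand, stickers.strands, mode="full-strand")


def check_universal_ctl(model: SystemModel, name: str,
                        codebook: Optional[Codebook] = None) -> MCResult:
    """A-quantified basic CTL: same finite-run semantics as the matching
    linear-time formula, checked directly."""
    cores = {"ApUq": "pUq", "AFp": "Fp", "AGp": "Gp", "AXp": "Xp"}
    if name not in cores:
        raise StickerError(f"{name!r} is not a universal basic CTL formula")
    core = cores[name]
    cb = codebook or default_codebook_for(core)
    res = tl_mc_dna(model, automaton_for(core), cb, formula_name=name)
    res.decision_basis = {"core": core, "core_verdict": res.verdict,
                          "negated": False}
    return res


def check_existential_ctl(model: SystemModel, name: str,
                          codebook: Optional[Codebook] = None) -> MCResult:
    """E-quantified basic CTL via duality: check the universal core, then
    negate the verdict exactly once."""
    core, negate = dual_reduction(name)
    cb = codebook or default_codebook_for(core)
    inner = tl_mc_dna(model, automaton_for(core), cb, formula_name=name)
    inner.decision_basis = {"core": core, "core_verdict": inner.verdict,
                           "negated": negate}
    if negate:
        inner.verdict = not inner.verdict
    return inner


def check_ctl(model: SystemModel, name: str,
              codebook: Optional[Codebook] = None) -> MCResult:
    """Dispatch a basic CTL formula to the universal or existential check."""
    if name in ("ApUq", "AFp", "AGp", "AXp"):
        return check_universal_ctl(model, name, codebook)
    if name in ("EpUq", "EFp", "EGp", "EXp"):
        return check_existential_ctl(model, name, codebook)
    raise StickerError(f"{name!r} is not a basic CTL formula")


def check_itl(model: SystemModel, name: str,
              codebook: Optional[Codebook] = None) -> MCResult:
    """Basic interval formulas: the chop (phi2) uses the sequential-
    composition bound when the model carries a prefix/suffix annotation."""
    if name not in ("phi2", "phi3"):
        raise StickerError(f"{name!r} is not a basic ITL formula")
    cb = codebook or default_codebook_for(name)
    bound = None
    if name == "phi2" and model.interval_split is not None:
        bound = composite_bound(*model.interval_split)
    return tl_mc_dna(model, automaton_for(name), cb, bound=bound,
                     formula_name=name)


def check_ptl(model: SystemModel, name: str = "phi4",
              codebook: Optional[Codebook] = None) -> MCResult:
    """The basic projection formula (phi4)."""
    if name != "phi4":
        raise StickerError(f"{name!r} is not the basic PTL formula")
    cb = codebook or default_codebook_for(name)
    return tl_mc_dna(model, automaton_for(name), cb, formula_name=name)


def check(model: SystemModel, formula_name: str,
          codebook: Optional[Codebook] = None,
          bound: Optional[int] = None) -> MCResult:
    """Check any supported basic formula by name (the CLI entry point)."""
    spec = formula_spec(formula_name)
    if bound is not None:
        cb = codebook or default_codebook_for(formula_name)
        if spec.family in ("CTL-universal", "CTL-existential") \
                and formula_name[0] in "AE":
            raise StickerError("explicit bounds apply to direct automaton "
                               "checks; CTL names choose their own core")
        return tl_mc_dna(model, automaton_for(formula_name), cb, bound=bound,
                         formula_name=formula_name)
    if formula_name in ("ApUq", "AFp", "AGp", "AXp", "EpUq", "EFp", "EGp", "EXp"):
        return check_ctl(model, formula_name, codebook)
    if formula_name in ("phi2", "phi3"):
        return check_itl(model, formula_name, codebook)
    if formula_name == "phi4":
        return check_ptl(model, formula_name, codebook)
    cb = codebook or default_codebook_for(formula_name)
    return tl_mc_dna(model, automaton_for(formula_name), cb,
                     formula_name=formula_name)
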