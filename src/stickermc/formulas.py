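"""Built-in formula automata, CTL duality reductions, and packaged fixtures.

Supported basic formulas and their automata:

* ``pUq``, ``Fp``, ``Gp``, ``Xp`` — the basic linear-time formulas over a
  proposition ``p`` (and ``q`` for until); their negated-proposition variants
  ``F!p``/``G!p``/``X!p`` arise as duality cores and use the fresh letter
  ``r`` = not-p.
* ``phi1`` = !p U-dual !q, the universal dual of E p U q, automaton A1.
* ``phi2`` = (p1 U q1); (p2 U q2), the interval chop, automaton A2.
* ``phi3`` = (p U q)*, the interval star, automaton A3.
* ``phi4`` = ((p1 U q1), (p2 U q2)) prj (p3 and X q3), the projection
  formula, automaton A4 over compound letters m1..m4 (m1 = p1&p3 etc.).

Existential CTL formulas are checked by negating a universal core:
EpUq -> not phi1, EFp -> not G!p, EGp -> not F!p, EXp -> not X!p.

The three example system models M1, M2, M3 and the three codebooks used in
the bench experiments ship as fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

from .automata import FSA, StickerError, SystemModel
from .encoding import Codebook

__all__ = [
    "FormulaSpec",
    "FORMULA_NAMES",
    "automaton_for",
    "dual_reduction",
    "fixture",
    "FIXTURE_NAMES",
    "default_codebook_for",
]


@dataclass(frozen=True)
class FormulaSpec:
    """A supported basic formula: family, canonical name, atoms used."""

    family: str  # LTL-basic | CTL-universal | CTL-existential | ITL-chop | ITL-star | PTL-prj
    name: str
    atoms: tuple


_UNIVERSAL_CTL = ("ApUq", "AFp", "AGp", "AXp")
_EXISTENTIAL_CTL = ("EpUq", "EFp", "EGp", "EXp")
_LTL = ("pUq", "Fp", "Gp", "Xp", "F!p", "G!p", "X!p")

#: Formula names accepted at the command line.
FORMULA_NAMES = (_UNIVERSAL_CTL + _EXISTENTIAL_CTL
                 + ("phi1", "phi2", "phi3", "phi4", "pUq", "Fp", "Gp", "Xp"))


def formula_spec(name: str) -> FormulaSpec:
    if name in _UNIVERSAL_CTL:
        return FormulaSpec("CTL-universal", name, ("p", "q") if name == "ApUq" else ("p",))
    if name in _EXISTENTIAL_CTL:
        return FormulaSpec("CTL-existential", name, ("p", "q") if name == "EpUq" else ("p",))
    if name in _LTL:
        return FormulaSpec("LTL-basic", name, ("p", "q") if name == "pUq" else ("p",))
    if name == "phi1":
        return FormulaSpec("CTL-universal", name, ("p", "q"))
    if name == "phi2":
        return FormulaSpec("ITL-chop", name, ("p1", "q1", "p2", "q2"))
    if name == "phi3":
        return FormulaSpec("ITL-star", name, ("p", "q"))
    if name == "phi4":
        return FormulaSpec("PTL-prj", name, ("p1", "q1", "p2", "q2", "p3", "q3"))
    raise StickerError(f"unsupported formula {name!r}")


def _ltl_automaton(kind: str, target: str, other: str, name: str) -> FSA:
    """Finite-word automata for F/G/X over a letter and its complement."""
    letters = (target, other)
    if kind == "F":
        trans = {(0, l, 0) for l in letters} | {(0, target, 1)} | {(1, l, 1) for l in letters}
        return FSA.build(letters, 2, trans, 0, {1}, name)
    if kind == "G":
        return FSA.build(letters, 1, {(0, target, 0)}, 0, {0}, name)
    if kind == "X":
        trans = ({(0, l, 1) for l in letters} | {(1, target, 2)}
                 | {(2, l, 2) for l in letters})
        return FSA.build(letters, 3, trans, 0, {2}, name)
    raise StickerError(f"unknown temporal operator {kind!r}")


def automaton_for(formula) -> FSA:
    """The finite-word automaton recognizing a basic formula's run language."""
    name = formula.name if isinstance(formula, FormulaSpec) else str(formula)
    if name == "phi1":
        # A1: r = not-p, s = not-q, u = not-p & not-q
        return FSA.build(
            {"s", "u", "q"}, 3,
            {(0, "s", 0), (0, "u", 1), (0, "s", 2), (1, "s", 1), (1, "q", 2)},
            0, {2}, "A1")
    if name == "phi2":
        return FSA.build(
            {"p1", "q1", "p2", "q2"}, 3,
            {(0, "p1", 0), (0, "q1", 1), (1, "p2", 1), (1, "q2", 2)},
            0, {2}, "A2")
    if name == "phi3":
        # A3 uses states {0, 2} of the merged interval automaton; state 1 is
        # retained (unreachable) so the sticker state indices match the bench
        # encoding.
        return FSA.build(
            {"p", "q"}, 3,
            {(0, "p", 0), (0, "q", 2), (2, "p", 0), (2, "q", 2)},
            0, {2}, "A3")
    if name == "phi4":
        return FSA.build(
            {"m1", "m2", "p1", "q1", "m3", "m4", "p2", "q2"}, 5,
            {(0, "m1", 1), (0, "m2", 2), (1, "p1", 1), (1, "q1", 2),
             (2, "m3", 3), (2, "m4", 4), (3, "p2", 3), (3, "q2", 4)},
            0, {4}, "A4")
    if name == "A5":
        # merged interval automaton (A2 and A3 share states and a codebook)
        a2, a3 = automaton_for("phi2"), automaton_for("phi3")
        return FSA.build(a2.alphabet | a3.alphabet, 3,
                         a2.transitions | a3.transitions, 0, {2}, "A5")
    if name == "pUq":
        return FSA.build({"p", "q"}, 2, {(0, "p", 0), (0, "q", 1)}, 0, {1}, "A(pUq)")
    if name in ("Fp", "Gp", "Xp"):
        return _ltl_automaton(name[0], "p", "r", f"A({name})")
    if name in ("F!p", "G!p", "X!p"):
        return _ltl_automaton(name[0], "r", "p", f"A({name})")
    raise StickerError(f"no automaton for formula {name!r}")


def dual_reduction(existential_name: str) -> Tuple[str, bool]:
    """Reduce an existential CTL formula to a universal core plus negation.

    Returns ``(core formula name, negate flag)``; the model satisfies the
    existential formula iff it does NOT satisfy the core.
    """
    table = {"EpUq": "phi1", "EFp": "G!p", "EGp": "F!p", "EXp": "X!p"}
    if existential_name not in table:
        raise StickerError(
            f"{existential_name!r} is not an existential basic CTL formula")
    return table[existential_name], True


# ---------------------------------------------------------------------------
# fixtures: bench codebooks and example system models
# ---------------------------------------------------------------------------

def _codebook_phi1() -> Codebook:
    return Codebook(
        letters={"p": "CGA", "q": "CCC", "r": "CGC", "s": "AGC", "u": "GCG"},
        spacers=["GAA", "TTG", "CAA", "GGC"],
        i1="GCCA", i2="CGTC",
        conditions={
            "p": {"p": True}, "q": {"q": True},
            "r": {"p": False}, "s": {"q": False},
            "u": {"p": False, "q": False},
        },
        name="codebook-phi1")


def _codebook_itl() -> Codebook:
    return Codebook(
        letters={"p1": "GAT", "p2": "GAA", "q1": "ATA", "q2": "TTC",
                 "p": "TAT", "q": "TGA"},
        spacers=["CGA", "ATC", "GGA", "ATG"],
        i1="CGCT", i2="CGGC",
        name="codebook-ITL")


def _codebook_phi4() -> Codebook:
    return Codebook(
        letters={"p1": "CCGC", "q1": "ATCC", "p2": "CAAA", "q2": "GGGA",
                 "p3": "TTAC", "q3": "ATAT",
                 "m1": "GTGA", "m2": "GACC", "m3": "AACG", "m4": "GACG"},
        spacers=["TCGG", "CGCA", "TCAT", "GTGG", "TCTT", "TGCA", "TGGA", "CGTA"],
        i1="GCAG", i2="AACC",
        conditions={
            "m1": {"p1": True, "p3": True}, "m2": {"q1": True, "p3": True},
            "m3": {"p2": True, "q3": True}, "m4": {"q2": True, "q3": True},
        },
        name="codebook-phi4")


def _model_m1() -> SystemModel:
    # Two-state cycle feeding a terminal q-state; state 2's p-value is false
    # (unconstrained by any bench verdict).
    return SystemModel(
        n_states=3, edges={(0, 1), (1, 0), (1, 2)}, initial=0,
        labels={0: {"p": True, "q": False},
                1: {"p": False, "q": False},
                2: {"p": False, "q": True}},
        name="M1")


def _model_m2() -> SystemModel:
    return SystemModel(
        n_states=4, edges={(0, 1), (1, 0), (1, 2), (2, 3)}, initial=0,
        labels={
            0: {"p1": True, "q1": False, "p2": False, "q2": False,
                "p3": True, "q3": False},
            1: {"p1": True, "q1": True, "p2": False, "q2": False,
                "p3": False, "q3": False},
            2: {"p1": False, "q1": False, "p2": True, "q2": False,
                "p3": False, "q3": False},
            3: {"p1": False, "q1": False, "p2": False, "q2": True,
                "p3": False, "q3": False},
        },
        name="M2",
        interval_split=(2, 2, 2, 1))


def _model_m3() -> SystemModel:
    return SystemModel(
        n_states=2, edges={(0, 1), (1, 0)}, initial=0,
        labels={0: {"p": True, "q": False}, 1: {"p": False, "q": True}},
        name="M3")


_FIXTURES = {
    "M1": _model_m1,
    "M2": _model_m2,
    "M3": _model_m3,
    "codebook-phi1": _codebook_phi1,
    "codebook-ITL": _codebook_itl,
    "codebook-phi4": _codebook_phi4,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture(name: str):
    """A packaged system model or codebook by name (case-insensitive)."""
    canonical = {k.lower(): k for k in _FIXTURES}
    key = canonical.get(str(name).lower())
    if key is None:
        raise StickerError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    return _FIXTURES[key]()


def default_codebook_for(formula_name: str) -> Codebook:
    """The bench codebook conventionally paired with a formula."""
    if formula_name in ("phi2", "phi3"):
        return fixture("codebook-ITL")
    if formula_name == "phi4":
        return fixture("codebook-phi4")
    return fixture("codebook-phi1")
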