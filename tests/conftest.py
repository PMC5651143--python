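"""Shared fixtures, random-instance generators, and independent oracles.

The oracles here deliberately avoid the code paths they check: word
acceptance is re-derived by exhaustive enumeration of transition paths, and
model-checking verdicts are re-derived by pure-logic evaluation of the
formula automaton on all bounded runs (no DNA encoding or tiling).
"""

import itertools
import random

import pytest

from stickermc import (Codebook, FSA, SystemModel, admissible_letters,
                       automaton_for, build_sticker_set, enumerate_paths,
                       fixture)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def m1():
    return fixture("M1")


@pytest.fixture(scope="session")
def m2():
    return fixture("M2")


@pytest.fixture(scope="session")
def m3():
    return fixture("M3")


@pytest.fixture(scope="session")
def cb_phi1():
    return fixture("codebook-phi1")


@pytest.fixture(scope="session")
def cb_itl():
    return fixture("codebook-ITL")


@pytest.fixture(scope="session")
def cb_phi4():
    return fixture("codebook-phi4")


@pytest.fixture(scope="session")
def stickers_a1(cb_phi1):
    return build_sticker_set(automaton_for("phi1"), cb_phi1)


@pytest.fixture(scope="session")
def stickers_a4(cb_phi4):
    return build_sticker_set(automaton_for("phi4"), cb_phi4)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def accepts_bruteforce(fsa: FSA, word) -> bool:
    """NFA acceptance by exhaustive enumeration of all transition paths."""
    frontier = [fsa.initial]
    for letter in word:
        frontier = [t for q in frontier for (s, a, t) in fsa.transitions
                    if s == q and a == letter]
        if not frontier:
            return False
    return any(q in fsa.accepting for q in frontier)


def logic_verdict(model: SystemModel, fsa: FSA, codebook: Codebook,
                  bound: int) -> bool:
    """Pure-logic model-check: no strands, no tiling.

    Every bounded path must have SOME admissible run whose letter word the
    formula automaton accepts (brute-force acceptance).
    """
    for path in enumerate_paths(model, bound):
        choices = [sorted(admissible_letters(q, model, codebook,
                                             restrict_to=fsa.alphabet))
                   for q in path]
        if any(not c for c in choices):
            return False
        if not any(accepts_bruteforce(fsa, word)
                   for word in itertools.product(*choices)):
            return False
    return True


# ---------------------------------------------------------------------------
# random-instance generators (plain seeded random, deterministic)
# ---------------------------------------------------------------------------

def random_fsa(rng: random.Random, max_states: int = 5, max_letters: int = 3) -> FSA:
    n = rng.randint(1, max_states)
    letters = ["a", "b", "c"][:rng.randint(1, max_letters)]
    transitions = set()
    for _ in range(rng.randint(0, 2 * n * len(letters))):
        transitions.add((rng.randrange(n), rng.choice(letters), rng.randrange(n)))
    accepting = {q for q in range(n) if rng.random() < 0.5} or {rng.randrange(n)}
    return FSA.build(letters, n, transitions, 0, accepting)


def random_word(rng: random.Random, fsa: FSA, max_len: int = 8):
    letters = sorted(fsa.alphabet)
    # half the time follow real transitions, so accepted words appear often
    if rng.random() < 0.5:
        word, state = [], fsa.initial
        for _ in range(rng.randint(0, max_len)):
            succ = [(a, t) for (s, a, t) in fsa.transitions if s == state]
            if not succ:
                break
            a, state = rng.choice(sorted(succ))
            word.append(a)
        return tuple(word)
    return tuple(rng.choice(letters) for _ in range(rng.randint(0, max_len)))


def codebook_for_fsa(fsa: FSA) -> Codebook:
    """A well-separated codebook: letter codewords over {A,C}, spacers over
    {G,T}, so letter and spacer alphabets never collide."""
    lpool = ["".join(t) for t in itertools.product("AC", repeat=3)]
    spool = ["".join(t) for t in itertools.product("GT", repeat=3)]
    letters = {a: lpool[i] for i, a in enumerate(sorted(fsa.alphabet))}
    return Codebook(letters=letters, spacers=spool[:fsa.n_states + 1],
                    i1="GCCA", i2="CGTC", name="random")


def random_labeled_model(rng: random.Random, atoms=("p", "q"),
                         max_states: int = 3) -> SystemModel:
    n = rng.randint(1, max_states)
    edges = set()
    for u in range(n):
        for _ in range(rng.randint(0, 2)):
            edges.add((u, rng.randrange(n)))
    labels = {q: {a: rng.random() < 0.5 for a in atoms} for q in range(n)}
    return SystemModel(n_states=n, edges=edges, initial=0, labels=labels,
                       name=f"rand{n}")
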