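"""Finite-state automata, labeled system models, and bounded path enumeration.

A formula is represented by a nondeterministic finite automaton (NFA) over an
alphabet of *codebook letters*; a system is a labeled transition graph whose
states carry truth assignments over atomic propositions.  A *path* is a state
sequence of the system starting at its initial state; a *run* refines a path
with one admissible letter per state (a state may admit several letters, e.g.
both ``s`` = not-q and ``u`` = not-p-and-not-q).  Satisfaction is decided on
finite words only: a run satisfies a formula iff the formula automaton accepts
its letter word.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = [
    "StickerError",
    "AlphabetError",
    "CodebookMismatchError",
    "FSA",
    "SystemModel",
    "Run",
    "accepts",
    "run_length_bound",
    "composite_bound",
    "enumerate_paths",
    "admissible_letters",
]


class StickerError(Exception):
    """Base class for all errors raised by this package."""


class AlphabetError(StickerError):
    """A word contains a letter outside the automaton's alphabet."""


class CodebookMismatchError(StickerError):
    """A reachable system state admits no letter of the codebook."""


@dataclass(frozen=True)
class FSA:
    """Nondeterministic finite automaton (Sigma, Q, T, q0, F).

    States are dense integer indices ``0..n_states-1`` (the sticker encoding
    addresses states by index).  Transitions are ``(source, letter, target)``
    triples; multiple targets per (state, letter) are allowed.
    """

    alphabet: frozenset
    n_states: int
    transitions: frozenset
    initial: int
    accepting: frozenset
    name: str = ""

    def __post_init__(self):
        if self.n_states < 1:
            raise ValueError("an automaton needs at least one state")
        if not (0 <= self.initial < self.n_states):
            raise ValueError(f"initial state {self.initial} out of range")
        for q in self.accepting:
            if not (0 <= q < self.n_states):
                raise ValueError(f"accepting state {q} out of range")
        for (src, letter, dst) in self.transitions:
            if not (0 <= src < self.n_states and 0 <= dst < self.n_states):
                raise ValueError(f"transition ({src},{letter},{dst}) references missing state")
            if letter not in self.alphabet:
                raise ValueError(f"transition letter {letter!r} not in alphabet")

    @classmethod
    def build(cls, alphabet: Iterable, n_states: int, transitions: Iterable,
              initial: int, accepting: Iterable, name: str = "") -> "FSA":
        return cls(frozenset(alphabet), n_states,
                   frozenset((s, a, t) for (s, a, t) in transitions),
                   initial, frozenset(accepting), name)

    def successors(self, state: int, letter) -> frozenset:
        return frozenset(t for (s, a, t) in self.transitions
                         if s == state and a == letter)

    def to_dict(self) -> dict:
        return {
            "alphabet": sorted(self.alphabet),
            "states": self.n_states,
            "transitions": sorted([s, a, t] for (s, a, t) in self.transitions),
            "initial": self.initial,
            "accepting": sorted(self.accepting),
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FSA":
        return cls.build(d["alphabet"], d["states"],
                         [tuple(t) for t in d["transitions"]],
                         d["initial"], d["accepting"], d.get("name", ""))


@dataclass
class SystemModel:
    """Labeled system model: a transition graph with per-state truth values.

    ``labels[state]`` maps atomic-proposition names to booleans.  States with
    no outgoing edge are terminal.  ``interval_split`` optionally annotates a
    prefix/suffix interval decomposition ``(V1, E1, V2, E2)`` used by the
    sequential-composition exploration bound.
    """

    n_states: int
    edges: set
    initial: int
    labels: dict
    name: str = ""
    interval_split: Optional[tuple] = None

    def __post_init__(self):
        self.edges = {(int(u), int(v)) for (u, v) in self.edges}
        if not (0 <= self.initial < self.n_states):
            raise ValueError("initial state out of range")
        for (u, v) in self.edges:
            if not (0 <= u < self.n_states and 0 <= v < self.n_states):
                raise ValueError(f"edge ({u},{v}) references missing state")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def terminal_states(self) -> frozenset:
        with_out = {u for (u, _) in self.edges}
        return frozenset(q for q in range(self.n_states) if q not in with_out)

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_states))
        g.add_edges_from(self.edges)
        return g

    def to_dict(self) -> dict:
        return {
            "states": self.n_states,
            "edges": sorted([u, v] for (u, v) in self.edges),
            "initial": self.initial,
            "labels": {str(q): dict(sorted(props.items()))
                       for q, props in sorted(self.labels.items())},
            "name": self.name,
            "interval_split": list(self.interval_split) if self.interval_split else None,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SystemModel":
        split = d.get("interval_split")
        return cls(
            n_states=d["states"],
            edges={tuple(e) for e in d["edges"]},
            initial=d["initial"],
            labels={int(q): dict(props) for q, props in d["labels"].items()},
            name=d.get("name", ""),
            interval_split=tuple(split) if split else None,
        )


@dataclass(frozen=True)
class Run:
    """A system path refined with one admissible letter per state."""

    path: tuple
    letters: tuple

    def __post_init__(self):
        if len(self.path) != len(self.letters):
            raise ValueError("a run carries exactly one letter per state")


def accepts(fsa: FSA, word: Sequence) -> bool:
    """Standard NFA acceptance of a finite word.

    True iff some transition path consumes the whole word from the initial
    state to an accepting state; the empty word is accepted iff the initial
    state is accepting.
    """
    for letter in word:
        if letter not in fsa.alphabet:
            raise AlphabetError(f"letter {letter!r} not in alphabet {sorted(fsa.alphabet)}")
    current = {fsa.initial}
    for letter in word:
        current = {t for q in current for t in fsa.successors(q, letter)}
        if not current:
            return False
    return bool(current & fsa.accepting)


def run_length_bound(n_nodes: int, n_edges: int) -> int:
    """Exploration bound |V| * 2^(|V|-1) + |E| on the number of path families
    that must be checked for a pUq-like formula."""
    if n_nodes < 1:
        raise ValueError("a model has at least one node")
    if n_edges < 0:
        raise ValueError("edge count cannot be negative")
    return n_nodes * 2 ** (n_nodes - 1) + n_edges


def composite_bound(prefix_nodes: int, prefix_edges: int,
                    suffix_nodes: int, suffix_edges: int) -> int:
    """Sequential-composition bound: the run-length bound summed over the
    prefix and suffix intervals of the model."""
    return (run_length_bound(prefix_nodes, prefix_edges)
            + run_length_bound(suffix_nodes, suffix_edges))


def _k_family(model: SystemModel):
    """Detect the (cycle)^k + tail family of paths through the initial state.

    Returns (cycle, tail) where ``cycle`` is the lexicographically smallest
    simple cycle through the initial state (as a node list starting there) and
    ``tail`` is the shortest path from the cycle's last node to a terminal
    state (excluding that node; empty when no terminal is reachable), or None
    when the initial state lies on no cycle.
    """
    g = model.graph()
    cycles = []
    for cyc in nx.simple_cycles(g):
        if model.initial in cyc:
            i = cyc.index(model.initial)
            cycles.append(tuple(cyc[i:] + cyc[:i]))
    if not cycles:
        return None
    cycle = min(cycles, key=lambda c: (len(c), c))
    last = cycle[-1]
    terminals = model.terminal_states
    best_tail = None
    for term in sorted(terminals):
        try:
            sp = nx.shortest_path(g, last, term)
        except nx.NetworkXNoPath:
            continue
        tail = tuple(sp[1:])
        if best_tail is None or (len(tail), tail) < (len(best_tail), best_tail):
            best_tail = tail
    return cycle, (best_tail or ())


def _bounded_paths(model: SystemModel, max_len: int):
    """All paths from the initial state, each extended until it reaches a
    terminal state or the length cap; deduplicated and sorted."""
    out = set()
    succ = {}
    for (u, v) in model.edges:
        succ.setdefault(u, set()).add(v)
    stack = [(model.initial,)]
    while stack:
        path = stack.pop()
        nxt = succ.get(path[-1], ())
        if not nxt or len(path) >= max_len:
            out.add(path)
            continue
        for v in sorted(nxt):
            stack.append(path + (v,))
    return sorted(out)


def enumerate_paths(model: SystemModel, k_max: int):
    """The family of paths indexed k = 1..k_max.

    When the initial state lies on a cycle, path k repeats the cycle block k
    times and then proceeds to a terminal state (the shape printed in the run
    tables, e.g. ``(0,1)^k, 2``).  Otherwise all bounded simple-extension
    paths are returned, deduplicated and sorted, capped at ``k_max`` entries.
    Order is deterministic across runs.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    fam = _k_family(model)
    if fam is not None:
        cycle, tail = fam
        return [tuple(cycle) * k + tail for k in range(1, k_max + 1)]
    cap = run_length_bound(model.n_states, model.n_edges)
    paths = _bounded_paths(model, cap)
    if not paths:
        return []
    return paths[:k_max]


def admissible_letters(state: int, model: SystemModel, codebook,
                       restrict_to: Optional[Iterable] = None) -> frozenset:
    """Letters of the codebook whose Boolean condition holds at ``state``.

    Raises :class:`CodebookMismatchError` when the state admits no letter of
    the full codebook (a labeling/codebook mismatch).  When ``restrict_to`` is
    given (e.g. an automaton's alphabet) the result is intersected with it and
    may legitimately be empty — such a state simply supports no run of that
    automaton.
    """
    assignment = model.labels.get(state)
    if assignment is None:
        raise CodebookMismatchError(f"state {state} carries no truth assignment")
    full = frozenset(
        letter for letter in codebook.letters
        if all(assignment.get(atom, False) == value
               for atom, value in codebook.conditions[letter].items())
    )
    if not full:
        raise CodebookMismatchError(
            f"state {state} (labels {assignment}) admits no codebook letter")
    if restrict_to is not None:
        return full & frozenset(restrict_to)
    return full
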