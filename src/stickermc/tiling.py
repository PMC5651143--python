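"""In-silico annealing: exact tiling of an input strand by sticker complements.

Biochemically, the input strand and the stickers are annealed in one tube; a
complete double strand forms iff the stickers can cover the input strand from
initiator to terminator with no gaps or overlaps.  Here hybridization is
idealized as perfect-complement, zero-mismatch pairing (the reported pairing
specificity exceeds 99%), so the question becomes an exact string-partition
problem solved by left-to-right dynamic programming over strand positions: a
tiling is found iff one exists.

Coordinates in results are 1-based closed intervals along the input strand
5'->3', matching the "1st to the 15th sites" style of the tube readouts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .encoding import Strand

__all__ = ["TilingResult", "GroupResult", "tile", "group_experiments", "readout"]


@dataclass
class TilingResult:
    """Witness tiling of one input strand by one sticker subset.

    ``placements`` are ``(sticker name, (start, end))`` with 1-based closed
    intervals, contiguous from position 1.  When the tiling is incomplete the
    witness maximizes the covered prefix and ``uncovered`` lists the remaining
    positions (the "various lengths" electrophoresis signal).
    """

    complete: bool
    placements: list
    uncovered: list
    length: int

    @property
    def covered_prefix(self) -> int:
        return self.placements[-1][1][1] if self.placements else 0


@dataclass
class GroupResult:
    """Completeness verdicts for every sticker subset of one group size."""

    groups: list  # (tuple of sticker names, TilingResult)
    n_complete: int

    @property
    def complete_groups(self) -> list:
        return [names for names, res in self.groups if res.complete]


def _segments(stickers: Sequence[Strand]):
    return [(s, s.meta.get("segment") or s.pairing_segment) for s in stickers]


def _core_dp(seq: str, items) -> dict:
    """Left-to-right partition DP.

    Returns ``parent``: for every reachable cut position, the ``(prev, name)``
    of its first discovery (positions ascending, stickers in given order), so
    witness reconstruction is deterministic and ties favour earlier stickers.
    """
    n = len(seq)
    parent: dict = {0: None}
    for pos in range(n):
        if pos not in parent:
            continue
        for s, seg in items:
            end = pos + len(seg)
            if end <= n and end not in parent and seq.startswith(seg, pos):
                parent[end] = (pos, s.name)
    return parent


def _walk(parent: dict, end: int, offset: int = 0) -> list:
    placements = []
    pos = end
    while pos and parent.get(pos):
        prev, name = parent[pos]
        placements.append((name, (offset + prev + 1, offset + pos)))
        pos = prev
    placements.reverse()
    return placements


def tile(input_strand: Strand, stickers: Sequence[Strand], mode: str = "core") -> TilingResult:
    """Decide whether ``stickers`` tile ``input_strand`` exactly.

    mode="core": the strand must be partitioned, left to right, into segments
    each equal to the complement of some provided sticker.  mode="full-strand"
    (alias "full"): in addition the first segment must come from an
    initial-type sticker and the last from an acceptance-type sticker, with
    transition stickers in between.

    Search is exhaustive via dynamic programming over positions, so a tiling
    is found iff one exists.  On incomplete input the reported witness
    maximizes the covered prefix, ties broken by sticker order, and
    ``uncovered`` lists the unpaired positions.
    """
    if mode in ("full", "full-strand"):
        return _tile_full(input_strand, stickers)
    if mode != "core":
        raise ValueError(f"unknown tiling mode {mode!r}")
    seq = input_strand.seq
    n = len(seq)
    parent = _core_dp(seq, _segments(stickers))
    furthest = max(parent)
    complete = furthest == n
    return TilingResult(complete=complete, placements=_walk(parent, furthest),
                        uncovered=list(range(furthest + 1, n + 1)), length=n)


def _tile_full(input_strand: Strand, stickers: Sequence[Strand]) -> TilingResult:
    seq = input_strand.seq
    n = len(seq)
    first = [(s, seg) for s, seg in _segments(stickers) if s.role == "initial"]
    middle = [(s, seg) for s, seg in _segments(stickers) if s.role == "transition"]
    last = [(s, seg) for s, seg in _segments(stickers) if s.role == "acceptance"]

    best = TilingResult(complete=False, placements=[],
                        uncovered=list(range(1, n + 1)), length=n)
    for s0, p in first:
        if not seq.startswith(p) or len(p) > n:
            continue
        for s1, a in last:
            if len(p) + len(a) > n or not seq.endswith(a):
                continue
            mid = seq[len(p):n - len(a)]
            parent = _core_dp(mid, middle)
            if len(mid) in parent:
                placements = ([(s0.name, (1, len(p)))]
                              + _walk(parent, len(mid), offset=len(p))
                              + [(s1.name, (n - len(a) + 1, n))])
                return TilingResult(complete=True, placements=placements,
                                    uncovered=[], length=n)
        # incomplete witness: longest covered prefix through this initial
        mid_parent = _core_dp(seq[len(p):], middle)
        covered = len(p) + max(mid_parent)
        if covered > best.covered_prefix or (best.covered_prefix == 0 and not best.placements):
            placements = ([(s0.name, (1, len(p)))]
                          + _walk(mid_parent, max(mid_parent), offset=len(p)))
            cand = TilingResult(complete=False, placements=placements,
                                uncovered=list(range(covered + 1, n + 1)), length=n)
            if cand.covered_prefix > best.covered_prefix:
                best = cand
    return best


def group_experiments(input_strand: Strand, species: Sequence[Strand],
                      group_size: int, mode: str = "core") -> GroupResult:
    """Tile the strand against every C(n, k) subset of sticker species.

    Subsets are enumerated in deterministic combination order over the given
    species order, mirroring the exhaustive group experiments run in the tube.
    """
    if group_size > len(species):
        raise ValueError("group size exceeds the number of sticker species")
    groups = []
    n_complete = 0
    for combo in itertools.combinations(species, group_size):
        res = tile(input_strand, combo, mode=mode)
        groups.append((tuple(s.name for s in combo), res))
        n_complete += res.complete
    return GroupResult(groups=groups, n_complete=n_complete)


def readout(run_results: Sequence) -> dict:
    """Path verdict from per-run tilings: satisfied iff SOME admissible run
    formed a complete double strand (each run is evaluated in its own tube).

    ``run_results`` is a sequence of ``(run label, TilingResult)`` pairs; zero
    runs fail vacuously.
    """
    for label, res in run_results:
        if res.complete:
            return {"satisfied": True, "witness": label, "n_runs": len(run_results)}
    return {"satisfied": False, "witness": None, "n_runs": len(run_results)}
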