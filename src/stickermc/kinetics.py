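"""Stochastic kinetics of competitive hybridization (Gillespie direct method).

The annealing step is modelled as a well-mixed reaction network: the input
strand and each sticker are species, and stickers add stepwise to partial
assemblies until the complete duplex forms.  Trajectories are exact samples
of the chemical master equation via the direct stochastic simulation
algorithm; rate constants are user-supplied (equal, irreversible by default —
the bench rates are not published, so only structural properties such as mass
conservation and the reactant-count ceiling are quantitative claims here).

Counts are molecule numbers in a fixed volume (default 1e-15 L with 60000
copies of each reactant, the bench tube conditions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .encoding import Strand
from .tiling import tile

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "simulate_ssa",
    "build_annealing_network",
    "COMPLETE_DUPLEX",
]

#: Conventional name of the fully-assembled duplex species.
COMPLETE_DUPLEX = "complete-duplex"


@dataclass(frozen=True)
class Reaction:
    """Elementary reaction: reactant multiset -> product multiset at a rate."""

    reactants: tuple
    products: tuple
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate constants must be positive")
        if len(self.reactants) > 2:
            raise ValueError("at most bimolecular reactions are supported")


@dataclass
class ReactionNetwork:
    """Species, reactions, initial counts and the composition bookkeeping.

    ``composition[species]`` counts the elementary strands inside each
    (possibly complex) species, so conservation of every strand type can be
    checked on any trajectory.
    """

    species: list
    reactions: list
    counts: dict
    volume: float = 1e-15
    composition: dict = field(default_factory=dict)

    def __post_init__(self):
        for sp in self.species:
            self.counts.setdefault(sp, 0)
            self.composition.setdefault(sp, Counter({sp: 1}))
        for r in self.reactions:
            for sp in r.reactants + r.products:
                if sp not in self.counts:
                    raise ValueError(f"reaction references unknown species {sp!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("initial counts must be nonnegative")

    def strand_totals(self, counts: Optional[dict] = None) -> Counter:
        """Total copies of each elementary strand across all complexes."""
        counts = counts if counts is not None else self.counts
        total: Counter = Counter()
        for sp, n in counts.items():
            for strand, mult in self.composition[sp].items():
                total[strand] += mult * n
        return total


@dataclass
class Trajectory:
    """Sampled species counts over time."""

    times: np.ndarray
    counts: np.ndarray  # shape (n_samples, n_species)
    species: list

    def of(self, species_name: str) -> np.ndarray:
        return self.counts[:, self.species.index(species_name)]

    def final(self) -> dict:
        return dict(zip(self.species, self.counts[-1].tolist()))


def _propensity(reaction: Reaction, counts: dict) -> float:
    r = reaction.reactants
    if len(r) == 0:
        return reaction.rate
    if len(r) == 1:
        return reaction.rate * counts[r[0]]
    a, b = r
    if a == b:
        n = counts[a]
        return reaction.rate * n * (n - 1) / 2.0
    return reaction.rate * counts[a] * counts[b]


def simulate_ssa(network: ReactionNetwork, t_end: float, seed: int = 0,
                 n_samples: int = 200) -> Trajectory:
    """Exact stochastic simulation (direct method), deterministic per seed.

    The trajectory is sampled at ``n_samples`` evenly spaced times in
    ``[0, t_end]`` (the state between events is piecewise constant).
    """
    if not network.species:
        raise ValueError("empty network")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    rng = np.random.default_rng(seed)
    counts = dict(network.counts)
    sample_times = np.linspace(0.0, t_end, n_samples + 1)
    out = np.empty((len(sample_times), len(network.species)), dtype=np.int64)
    order = network.species
    t = 0.0
    next_sample = 0

    def record_before(time_limit):
        # record samples falling strictly before the next event
        nonlocal next_sample
        while next_sample < len(sample_times) and sample_times[next_sample] < time_limit:
            out[next_sample] = [counts[sp] for sp in order]
            next_sample += 1

    while True:
        props = [_propensity(rx, counts) for rx in network.reactions]
        total = sum(props)
        if total <= 0.0:
            break
        t_next = t + rng.exponential(1.0 / total)
        if t_next > t_end:
            break
        record_before(t_next)
        pick = rng.uniform(0.0, total)
        acc = 0.0
        chosen = network.reactions[-1]
        for rx, a in zip(network.reactions, props):
            acc += a
            if pick <= acc:
                chosen = rx
                break
        for sp in chosen.reactants:
            counts[sp] -= 1
        for sp in chosen.products:
            counts[sp] += 1
        t = t_next
    while next_sample < len(sample_times):
        out[next_sample] = [counts[sp] for sp in order]
        next_sample += 1
    return Trajectory(times=sample_times, counts=out, species=list(order))


def _complex_name(bound: frozenset) -> str:
    return "d·{" + "+".join(sorted(bound)) + "}"


def build_annealing_network(input_strand: Strand, stickers: Sequence[Strand],
                            rate: float = 1e-4, counts: int = 60000,
                            volume: float = 1e-15) -> ReactionNetwork:
    """Reaction network for annealing one input strand with a sticker group.

    Only stickers that actually place on the strand (per the exact tiling
    witness) acquire binding reactions; binding is stepwise and irreversible,
    in any order, so the assemblies are exactly the subsets of the witness
    placements.  When the witness covers the whole strand the full assembly is
    the single terminal complex and is named :data:`COMPLETE_DUPLEX`.
    """
    result = tile(input_strand, stickers, mode="core")
    placed = [name for name, _ in result.placements]
    species = ["d"] + [s.name for s in stickers]
    comp = {sp: Counter({sp: 1}) for sp in species}
    init = {sp: counts for sp in species}

    def name_of(subset: frozenset) -> str:
        if result.complete and len(subset) == len(placed):
            return COMPLETE_DUPLEX
        return _complex_name(subset)

    reactions = []
    subsets = [frozenset()]
    seen = {frozenset()}
    while subsets:
        sub = subsets.pop()
        src = "d" if not sub else name_of(sub)
        for sticker in placed:
            if sticker in sub:
                continue
            new = sub | {sticker}
            dst = name_of(new)
            if dst not in comp:
                species.append(dst)
                comp[dst] = Counter({"d": 1, **{s: 1 for s in new}})
                init[dst] = 0
            reactions.append(Reaction((src, sticker), (dst,), rate))
            if new not in seen:
                seen.add(new)
                subsets.append(new)
    return ReactionNetwork(species=species, reactions=reactions, counts=init,
                           volume=volume, composition=comp)
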