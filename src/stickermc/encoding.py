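"""DNA sticker encoding of automata: codebooks, strands, FASTA export.

An input word ``a1..an`` becomes the single strand
``5' I1 X0..Xm C(a1) X0..Xm ... C(an) X0..Xm I2 3'`` where ``I1``/``I2`` are
initiator/terminator sequences and ``X0..Xm`` is a spacer block separating
letter codewords.  Automaton components become short "sticker" strands, each
the Watson-Crick complement of a contiguous input-strand segment:

* transition (si, a, sj) -> complement of ``X_{i+1}..Xm C(a) X0..Xj``
* initial state si        -> complement of ``I1 X0..Xi``
* acceptance state sj     -> complement of ``X_{j+1}..Xm I2``

How far a sticker reaches into the neighbouring spacer blocks encodes the
source and target state indices, so a complete non-overlapping tiling of the
input strand exists iff the automaton accepts the word.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .automata import FSA, StickerError

__all__ = [
    "CodebookError",
    "EncodingError",
    "Codebook",
    "Strand",
    "StickerSet",
    "wc_complement",
    "encode_input_run",
    "trim_to_core",
    "encode_transition",
    "encode_initial",
    "encode_acceptance",
    "build_sticker_set",
    "validate_codebook",
    "export_fasta",
    "read_fasta",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class CodebookError(StickerError):
    """A codebook cannot encode the requested object."""


class EncodingError(StickerError):
    """A strand is inconsistent with the encoding scheme."""


def wc_complement(seq: str) -> str:
    """Base-wise Watson-Crick complement, preserving left-to-right order.

    The orientation of the written text flips (5'->3' becomes 3'->5'); no
    reversal is applied, so the result stays aligned position-for-position
    with its template.
    """
    bad = set(seq) - set("ACGT")
    if bad:
        raise EncodingError(f"non-ACGT characters {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)


@dataclass
class Codebook:
    """Letter codewords plus initiator, terminator and spacer sequences.

    ``conditions[letter]`` is the letter's Boolean condition over atomic
    propositions as a mapping ``{atom: required truth value}``; a letter with
    no explicit condition stands for the single atom of the same name.
    """

    letters: dict
    spacers: list
    i1: str
    i2: str
    conditions: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        for letter in self.letters:
            self.conditions.setdefault(letter, {letter: True})

    @property
    def m(self) -> int:
        """Maximum spacer index."""
        return len(self.spacers) - 1

    @property
    def spacer_block(self) -> str:
        return "".join(self.spacers)

    def codeword(self, letter) -> str:
        try:
            return self.letters[letter]
        except KeyError:
            raise CodebookError(f"no codeword for letter {letter!r}") from None

    def spacer_run(self, lo: int, hi: int) -> str:
        """Concatenation X_lo .. X_hi (empty when lo > hi)."""
        if lo < 0 or hi > self.m:
            raise CodebookError(f"spacer range X{lo}..X{hi} outside X0..X{self.m}")
        return "".join(self.spacers[lo:hi + 1])

    def to_dict(self) -> dict:
        return {
            "letters": dict(sorted(self.letters.items())),
            "spacers": list(self.spacers),
            "I1": self.i1,
            "I2": self.i2,
            "conditions": {k: dict(sorted(v.items()))
                           for k, v in sorted(self.conditions.items())},
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Codebook":
        return cls(letters=dict(d["letters"]), spacers=list(d["spacers"]),
                   i1=d["I1"], i2=d["I2"],
                   conditions={k: dict(v) for k, v in d.get("conditions", {}).items()},
                   name=d.get("name", ""))


@dataclass
class Strand:
    """A DNA strand with the orientation it is conventionally written in.

    ``seq`` is always stored 5'->3'.  Stickers are conventionally written
    3'->5' so that their text aligns base-for-base under the input strand;
    :attr:`written` recovers that left-to-right table text.
    """

    seq: str
    written_orientation: str = "5'->3'"  # or "3'->5'"
    role: str = "input-run"
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.written_orientation not in ("5'->3'", "3'->5'"):
            raise ValueError("orientation must be \"5'->3'\" or \"3'->5'\"")
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise EncodingError(f"non-ACGT characters {sorted(bad)} in strand")

    @property
    def written(self) -> str:
        """The strand text left-to-right in its conventional orientation."""
        return self.seq if self.written_orientation == "5'->3'" else self.seq[::-1]

    @property
    def pairing_segment(self) -> str:
        """The 5'->3' input-strand segment this sticker hybridizes to."""
        return wc_complement(self.written)

    def display(self) -> str:
        if self.written_orientation == "5'->3'":
            return f"5' {self.written} 3'"
        return f"3' {self.written} 5'"

    def __len__(self) -> int:
        return len(self.seq)


def _sticker(segment: str, role: str, name: str, meta: dict) -> Strand:
    text = wc_complement(segment)  # 3'->5' left-to-right
    return Strand(seq=text[::-1], written_orientation="3'->5'", role=role,
                  name=name, meta=dict(meta, segment=segment))


def encode_input_run(letters: Sequence, codebook: Codebook) -> Strand:
    """Encode a word as the full input strand I1 (block C(ai))* block I2."""
    parts = [codebook.i1]
    for letter in letters:
        parts.append(codebook.spacer_block)
        parts.append(codebook.codeword(letter))
    parts.append(codebook.spacer_block)
    parts.append(codebook.i2)
    return Strand(seq="".join(parts), role="input-run", name="run-" + "".join(map(str, letters)),
                  meta={"letters": tuple(letters)})


def trim_to_core(run_strand: Strand, codebook: Codebook,
                 initial_index: int, accepting_index: int) -> Strand:
    """Strip the segments covered by the initial and acceptance stickers.

    The initial sticker covers ``I1 X0..Xi`` and the acceptance sticker covers
    ``X_{j+1}..Xm I2``; the remaining core is what the transition stickers
    must tile.
    """
    prefix = codebook.i1 + codebook.spacer_run(0, initial_index)
    suffix = codebook.spacer_run(accepting_index + 1, codebook.m) + codebook.i2
    seq = run_strand.seq
    if not seq.startswith(prefix) or not seq.endswith(suffix):
        raise EncodingError(
            "run strand does not carry the expected initiator/terminator context")
    core = seq[len(prefix):len(seq) - len(suffix)]
    return Strand(seq=core, role="input-core",
                  name=run_strand.name + "-core",
                  meta=dict(run_strand.meta, trimmed=(initial_index, accepting_index)))


def encode_transition(i: int, letter, j: int, codebook: Codebook) -> Strand:
    """Sticker for transition (si, letter, sj):
    complement of X_{i+1}..Xm C(letter) X0..Xj, written 3'->5'."""
    if not (0 <= i <= codebook.m and 0 <= j <= codebook.m):
        raise CodebookError(f"state index out of spacer range 0..{codebook.m}")
    segment = (codebook.spacer_run(i + 1, codebook.m)
               + codebook.codeword(letter)
               + codebook.spacer_run(0, j))
    return _sticker(segment, "transition", f"t{i}{letter}{j}",
                    {"src": i, "letter": letter, "dst": j})


def encode_initial(i: int, codebook: Codebook) -> Strand:
    """Sticker for initial state si: complement of I1 X0..Xi."""
    if not (0 <= i <= codebook.m):
        raise CodebookError(f"initial state index {i} out of range 0..{codebook.m}")
    return _sticker(codebook.i1 + codebook.spacer_run(0, i),
                    "initial", f"s{i}-initial", {"state": i})


def encode_acceptance(j: int, codebook: Codebook) -> Strand:
    """Sticker for acceptance state sj: complement of X_{j+1}..Xm I2.

    Requires j <= m-1 so that at least one trailing spacer remains.
    """
    if not (0 <= j <= codebook.m - 1):
        raise CodebookError(
            f"acceptance state index {j} needs a spare spacer (0..{codebook.m - 1})")
    return _sticker(codebook.spacer_run(j + 1, codebook.m) + codebook.i2,
                    "acceptance", f"s{j}-acceptance", {"state": j})


@dataclass
class StickerSet:
    """All stickers realizing one automaton under one codebook."""

    initial: Strand
    acceptance: list
    transitions: list
    fsa: Optional[FSA] = None
    codebook: Optional[Codebook] = None

    @property
    def strands(self) -> list:
        return [self.initial, *self.acceptance, *self.transitions]

    def transition_by_name(self, name: str) -> Strand:
        for s in self.transitions:
            if s.name == name:
                return s
        raise KeyError(name)


def build_sticker_set(fsa: FSA, codebook: Codebook) -> StickerSet:
    """One sticker per transition, plus initial and acceptance stickers."""
    report = validate_codebook(codebook, fsa)
    if not report["valid"]:
        raise CodebookError("codebook cannot encode automaton: "
                            + "; ".join(report["violations"]))
    transitions = [encode_transition(s, a, t, codebook)
                   for (s, a, t) in sorted(fsa.transitions,
                                           key=lambda x: (x[0], str(x[1]), x[2]))]
    return StickerSet(
        initial=encode_initial(fsa.initial, codebook),
        acceptance=[encode_acceptance(j, codebook) for j in sorted(fsa.accepting)],
        transitions=transitions,
        fsa=fsa,
        codebook=codebook,
    )


def validate_codebook(codebook: Codebook, fsa: Optional[FSA] = None) -> dict:
    """Report-style validation of a codebook, optionally against an automaton.

    Checks: uniform codeword length; pairwise-distinct codewords; uniform
    spacer length; no codeword equal to a spacer; and, when an automaton is
    given, a codeword for every alphabet letter and enough spacers for its
    state indices (acceptance needs one spare spacer).
    """
    violations = []
    lengths = {len(c) for c in codebook.letters.values()}
    if len(lengths) > 1:
        violations.append(f"letter codewords have mixed lengths {sorted(lengths)}")
    if len(set(codebook.letters.values())) != len(codebook.letters):
        dupes = sorted({c for c in codebook.letters.values()
                        if list(codebook.letters.values()).count(c) > 1})
        violations.append(f"duplicate codewords {dupes}")
    if len({len(x) for x in codebook.spacers}) > 1:
        violations.append("spacers have mixed lengths")
    clash = set(codebook.letters.values()) & set(codebook.spacers)
    if clash:
        violations.append(f"codewords equal to spacers: {sorted(clash)}")
    if fsa is not None:
        missing = sorted(a for a in fsa.alphabet if a not in codebook.letters)
        if missing:
            violations.append(f"letters without codewords: {missing}")
        if fsa.n_states - 1 > codebook.m - 1:
            violations.append(
                f"{len(codebook.spacers)} spacers cannot address "
                f"{fsa.n_states} states with a spare trailing spacer")
    return {"valid": not violations, "violations": violations}


def export_fasta(strands: Iterable[Strand], handle_or_path, allow_empty: bool = False) -> int:
    """Write strands to FASTA (sequences 5'->3'); returns the record count."""
    strands = list(strands)
    if not strands and not allow_empty:
        raise ValueError("refusing to write an empty FASTA (pass allow_empty=True)")
    records = [
        SeqRecord(Seq(s.seq), id=s.name or f"strand{i}",
                  description=f"role={s.role} written={s.written_orientation}")
        for i, s in enumerate(strands)
    ]
    if isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__"):
        with open(handle_or_path, "w") as fh:
            return SeqIO.write(records, fh, "fasta")
    return SeqIO.write(records, handle_or_path, "fasta")


def read_fasta(handle_or_path) -> list:
    """Read strands back from FASTA written by :func:`export_fasta`."""
    out = []
    for rec in SeqIO.parse(handle_or_path, "fasta"):
        fields = dict(part.split("=", 1) for part in rec.description.split()
                      if "=" in part)
        out.append(Strand(seq=str(rec.seq),
                          written_orientation=fields.get("written", "5'->3'"),
                          role=fields.get("role", "input-run"),
                          name=rec.id))
    return out
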