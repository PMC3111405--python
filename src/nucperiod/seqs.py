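"""Symbolic DNA fragments, k-mer indicator sequences and FASTA I/O.

The starting point for all period estimation in this package is the binary
indicator representation of a symbolic sequence: given a set of k-mers of
interest (by default the nucleosome positioning dinucleotides {AA, TT, TA}),
a DNA fragment ``s[n]`` of length ``N`` maps to ``x[n] in {0, 1}`` with
``x[n] = 1`` exactly when a member k-mer starts at position ``n``.  A
perfectly p-periodic fragment is one whose indicator is an impulse train
``x[n] = 1 iff n == n0 (mod p)``.

Coordinates are 0-based half-open throughout (BED convention).  The trailing
``k - 1`` indicator positions of a fragment are always 0 (no k-mer can start
there); the indicator keeps the full fragment length ``N`` so the estimator
formulas all share one ``N``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
from Bio import SeqIO

__all__ = [
    "SymbolicFragment",
    "SymbolSet",
    "IndicatorSequence",
    "FastaFormatError",
    "read_fasta",
    "windows",
    "indicator",
    "perfect_periodic",
    "indicator_to_fragment",
    "NPS_DINUCLEOTIDES",
]

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class FastaFormatError(ValueError):
    """Raised when an input file is not parseable as FASTA."""


@dataclass(frozen=True)
class SymbolicFragment:
    """A (windowed) symbolic sequence with genome coordinates.

    ``start``/``end`` are 0-based half-open; ``end - start`` always equals
    the number of symbols.
    """

    seq_id: str
    symbols: str
    start: int = 0
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.end is None:
            object.__setattr__(self, "end", self.start + len(self.symbols))
        if self.end - self.start != len(self.symbols):
            raise ValueError(
                f"coordinate span {self.start}:{self.end} does not match "
                f"symbol count {len(self.symbols)} for {self.seq_id!r}"
            )

    @property
    def N(self) -> int:
        return len(self.symbols)

    def ambiguity_fraction(self) -> float:
        """Fraction of symbols outside the unambiguous {A, C, G, T} alphabet."""
        if not self.symbols:
            return 0.0
        n_bad = sum(1 for c in self.symbols if c not in _DNA)
        return n_bad / len(self.symbols)


@dataclass(frozen=True)
class SymbolSet:
    """A non-empty set of equal-length k-mers of interest."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(sorted({m.upper() for m in self.members}))
        if not members:
            raise ValueError("SymbolSet needs at least one member")
        lengths = {len(m) for m in members}
        if len(lengths) != 1:
            raise ValueError(f"members must share one k-mer length, got {lengths}")
        object.__setattr__(self, "members", members)

    @property
    def k(self) -> int:
        return len(self.members[0])

    def reverse_complement(self) -> "SymbolSet":
        return SymbolSet(tuple(m.translate(_COMPLEMENT)[::-1] for m in self.members))

    def is_reverse_complement_closed(self) -> bool:
        return set(self.members) == set(self.reverse_complement().members)

    def with_reverse_complement(self) -> "SymbolSet":
        """Union with the reverse-complement set, for scanning one strand only."""
        return SymbolSet(self.members + self.reverse_complement().members)


#: The nucleosome positioning dinucleotides.  Reverse-complement closed, so a
#: forward-strand scan covers both strands.
NPS_DINUCLEOTIDES = SymbolSet(("AA", "TT", "TA"))


@dataclass
class IndicatorSequence:
    """Binary 0/1 occurrence sequence x[n] for a symbol set on a fragment."""

    values: np.ndarray
    seq_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.uint8)
        if values.ndim != 1:
            raise ValueError("indicator values must be one-dimensional")
        if np.any(values > 1):
            raise ValueError("indicator values must be 0/1")
        self.values = values

    @property
    def N(self) -> int:
        return int(self.values.size)

    @property
    def n0(self) -> Optional[int]:
        """Position of the first occurrence, or None if there are none."""
        nz = np.flatnonzero(self.values)
        return int(nz[0]) if nz.size else None

    def count(self) -> int:
        return int(self.values.sum())


def _open_text(path) -> Iterator:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path) -> Iterator[SymbolicFragment]:
    """Stream fragments from a (possibly gzipped) multi-record FASTA file.

    Records are yielded in file order with coordinates ``[0, len)``; symbols
    are uppercased.  A file whose first non-blank character is not ``>`` is
    rejected with :class:`FastaFormatError`.
    """
    with _open_text(path) as handle:
        first = handle.read(1)
        while first.isspace():
            first = handle.read(1)
        if first == "":
            return
        if first != ">":
            raise FastaFormatError(f"{path}: not FASTA (first record does not start with '>')")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            if not record.id:
                raise FastaFormatError(f"{path}: record with empty identifier")
            yield SymbolicFragment(seq_id=record.id, symbols=str(record.seq).upper())


def windows(fragment: SymbolicFragment, width: int, step: int = 1) -> Iterator[SymbolicFragment]:
    """Yield every ``[i, i + width)`` window at stride ``step``.

    Window coordinates are offset by the parent fragment's ``start``.  A
    fragment shorter than ``width`` yields nothing.
    """
    if width < 2:
        raise ValueError(f"width must be >= 2, got {width}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    for i in range(0, fragment.N - width + 1, step):
        yield SymbolicFragment(
            seq_id=fragment.seq_id,
            symbols=fragment.symbols[i : i + width],
            start=fragment.start + i,
        )


def _match_positions(symbols: str, symbol_set: SymbolSet) -> np.ndarray:
    """Boolean array over start positions 0..N-k of member k-mer matches."""
    k = symbol_set.k
    N = len(symbols)
    if N < k:
        return np.zeros(0, dtype=bool)
    arr = np.frombuffer(symbols.encode("ascii"), dtype="S1")
    n_starts = N - k + 1
    hit = np.zeros(n_starts, dtype=bool)
    for member in symbol_set.members:
        m = np.ones(n_starts, dtype=bool)
        for j, ch in enumerate(member):
            m &= arr[j : j + n_starts] == ch.encode("ascii")
        hit |= m
    return hit


def indicator(fragment: SymbolicFragment, symbol_set: SymbolSet = NPS_DINUCLEOTIDES) -> IndicatorSequence:
    """Binary indicator x[n] = 1 iff a member k-mer starts at position n.

    Overlapping occurrences each count (``AAA`` has AA at positions 0 and 1);
    ambiguity symbols never match; the trailing ``k - 1`` positions are 0.
    """
    values = np.zeros(fragment.N, dtype=np.uint8)
    hit = _match_positions(fragment.symbols, symbol_set)
    values[: hit.size] = hit
    return IndicatorSequence(values=values, seq_id=fragment.seq_id)


def perfect_periodic(N: int, p: int, n0: int = 0) -> IndicatorSequence:
    """The perfectly p-periodic indicator: x[n] = 1 iff n == n0 (mod p)."""
    if not (0 <= n0 < p <= N):
        raise ValueError(f"need 0 <= n0 < p <= N, got n0={n0}, p={p}, N={N}")
    values = np.zeros(N, dtype=np.uint8)
    values[n0::p] = 1
    return IndicatorSequence(values=values, seq_id=f"perfect_p{p}_n0{n0}")


def indicator_to_fragment(x: IndicatorSequence, seq_id: Optional[str] = None) -> SymbolicFragment:
    """Back-convert an indicator to a concrete DNA fragment.

    Produces a sequence of length ``N + 1`` over {T, A, C} in which the
    dinucleotide starting at position ``n`` is a member of {AA, TT, TA} exactly
    when ``x[n] = 1``: each occurrence is written as TA, which degrades to TT
    under overlap (both members), while every non-occurrence position reads
    AC, AT, CA, CC or CT (non-members).  Useful for symbol-level pipelines
    (e.g. the blockwise bootstrap) applied to synthesized numeric data.
    """
    chars = np.full(x.N + 1, b"C", dtype="S1")
    ones = np.flatnonzero(x.values)
    chars[ones + 1] = b"A"
    chars[ones] = b"T"
    return SymbolicFragment(
        seq_id=seq_id if seq_id is not None else (x.seq_id or "indicator"),
        symbols=chars.tobytes().decode("ascii"),
    )
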