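"""Genotype sequences, Hamming geometry and combinatorial volumes.

Sequence space is the set of all ``A**L`` strings of length ``L`` over an
``A``-letter alphabet (default the DNA alphabet ``ACGT``), with edges between
strings that differ at exactly one position.  Everything downstream — the
one-dimensional projection, the hitting-time analysis, the Monte-Carlo
walkers — builds on the primitives here.

Space sizes and ball volumes are computed with exact integer arithmetic:
``A**L`` overflows 64-bit types already for L around 31, and the theory is
about precisely those regimes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, List, Sequence as TypingSequence

import numpy as np

DNA_ALPHABET = "ACGT"

__all__ = [
    "DNA_ALPHABET",
    "SequenceSpace",
    "hamming_distance",
    "ball_volume",
    "shell_volume",
    "read_fasta_centers",
]


def hamming_distance(a: str, b: str) -> int:
    """Number of positions at which two equal-length sequences differ."""
    if len(a) != len(b):
        raise ValueError(
            f"sequences must have equal length (got {len(a)} and {len(b)})"
        )
    return sum(x != y for x, y in zip(a, b))


def shell_volume(L: int, d: int, A: int = 4) -> int:
    """Exact number of sequences at Hamming distance exactly ``d`` from a center.

    C(L, d) * (A-1)**d, as an arbitrary-precision integer.
    """
    if not 0 <= d <= L:
        raise ValueError(f"shell distance d={d} outside [0, L={L}]")
    return math.comb(L, d) * (A - 1) ** d


def ball_volume(L: int, w: int, A: int = 4) -> int:
    """Exact number of sequences within Hamming distance ``w`` of a center.

    Sum_{i=0..w} C(L, i) * (A-1)**i, evaluated in exact integer arithmetic.
    This is the size of a broad-peak target set with radius ``w``.
    """
    if not 0 <= w <= L:
        raise ValueError(f"ball radius w={w} outside [0, L={L}]")
    return sum(math.comb(L, i) * (A - 1) ** i for i in range(w + 1))


@dataclass(frozen=True)
class SequenceSpace:
    """The space of all length-``L`` strings over a fixed ordered alphabet.

    Parameters
    ----------
    L
        Sequence length (number of positions), at least 1.
    alphabet
        Ordered string of distinct characters; its length is the alphabet
        size ``A`` (at least 2).  Default is the DNA alphabet ``ACGT``.
    """

    L: int
    alphabet: str = DNA_ALPHABET

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"sequence length L must be >= 1, got {self.L}")
        if len(self.alphabet) < 2:
            raise ValueError("alphabet must contain at least 2 characters")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet characters must be distinct")

    @property
    def A(self) -> int:
        """Alphabet size."""
        return len(self.alphabet)

    @property
    def size(self) -> int:
        """Total number of sequences, A**L, as an exact integer."""
        return self.A**self.L

    @property
    def n_neighbors(self) -> int:
        """Number of point-mutation neighbors of any sequence: L*(A-1)."""
        return self.L * (self.A - 1)

    # ------------------------------------------------------------------ #
    # validation and codecs
    # ------------------------------------------------------------------ #

    def validate(self, s: str) -> str:
        """Check that ``s`` belongs to this space; return it unchanged."""
        if len(s) != self.L:
            raise ValueError(f"sequence length {len(s)} != L={self.L}")
        bad = set(s) - set(self.alphabet)
        if bad:
            raise ValueError(f"characters {sorted(bad)} not in alphabet {self.alphabet!r}")
        return s

    def encode(self, s: str) -> np.ndarray:
        """Sequence string -> int8 array of alphabet indices."""
        self.validate(s)
        lut = {c: i for i, c in enumerate(self.alphabet)}
        return np.fromiter((lut[c] for c in s), dtype=np.int8, count=self.L)

    def decode(self, arr: TypingSequence[int]) -> str:
        """Array of alphabet indices -> sequence string."""
        return "".join(self.alphabet[int(i)] for i in arr)

    # ------------------------------------------------------------------ #
    # geometry
    # ------------------------------------------------------------------ #

    def hamming(self, a: str, b: str) -> int:
        self.validate(a)
        self.validate(b)
        return hamming_distance(a, b)

    def neighbors(self, s: str) -> List[str]:
        """All L*(A-1) sequences at Hamming distance one from ``s``.

        Deterministic order: by position, then by alphabet order of the
        substituted character (the current character is skipped).  Downstream
        tie-breaking (greedy ascent) relies on this ordering.
        """
        self.validate(s)
        out: List[str] = []
        for i, c in enumerate(s):
            for x in self.alphabet:
                if x != c:
                    out.append(s[:i] + x + s[i + 1 :])
        return out

    def iter_sequences(self) -> Iterator[str]:
        """Iterate over all A**L sequences (guarded: A**L <= 10**6)."""
        if self.size > 10**6:
            raise ValueError(
                f"space of size {self.size} too large to enumerate (limit 10**6)"
            )
        import itertools

        for tup in itertools.product(self.alphabet, repeat=self.L):
            yield "".join(tup)

    # ------------------------------------------------------------------ #
    # randomness
    # ------------------------------------------------------------------ #

    def random_sequence(self, rng: np.random.Generator) -> str:
        """A sequence with i.i.d. uniform characters at every position."""
        idx = rng.integers(0, self.A, size=self.L)
        return self.decode(idx)

    def propose_mutation(self, s: str, rng: np.random.Generator) -> str:
        """One point mutant of ``s``, uniform among its L*(A-1) neighbors."""
        self.validate(s)
        pos = int(rng.integers(0, self.L))
        shift = int(rng.integers(1, self.A))
        lut = {c: i for i, c in enumerate(self.alphabet)}
        new = self.alphabet[(lut[s[pos]] + shift) % self.A]
        return s[:pos] + new + s[pos + 1 :]

    def random_at_distance(self, center: str, d: int, rng: np.random.Generator) -> str:
        """A uniform random sequence at Hamming distance exactly ``d`` from center."""
        self.validate(center)
        if not 0 <= d <= self.L:
            raise ValueError(f"distance d={d} outside [0, L={self.L}]")
        positions = rng.choice(self.L, size=d, replace=False)
        lut = {c: i for i, c in enumerate(self.alphabet)}
        chars = list(center)
        for p in positions:
            shift = int(rng.integers(1, self.A))
            chars[int(p)] = self.alphabet[(lut[center[int(p)]] + shift) % self.A]
        return "".join(chars)

    def ball_volume(self, w: int) -> int:
        return ball_volume(self.L, w, self.A)


def read_fasta_centers(path, space: SequenceSpace) -> List[str]:
    """Read target-center sequences from a FASTA file.

    Records are uppercased and validated against ``space``; any character
    outside the alphabet is an error.
    """
    from Bio import SeqIO

    centers = []
    for rec in SeqIO.parse(str(path), "fasta"):
        centers.append(space.validate(str(rec.seq).upper()))
    if not centers:
        raise ValueError(f"no FASTA records found in {path}")
    return centers
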