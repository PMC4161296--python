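"""Fitness landscapes over sequence space.

Four landscape families:

* :class:`BroadPeakLandscape` — a single target ball of Hamming radius ``w``
  around a center sequence, embedded in an otherwise flat landscape.
* :class:`MultiPeakLandscape` — a union of ``m`` such balls.
* :class:`MultiplicativeLandscape` — fitness ``(1 + sigma)**(L - d)`` growing
  multiplicatively toward the center, with an embedded target ball.
* :class:`TabulatedLandscape` — an explicit fitness table over a fully
  enumerated small space (guard ``A**L <= 10**6``), used for rugged landscapes.

Plus the two operators that reduce a rugged tabulated landscape to a
"targets + neutral background" caricature for discovery-time analysis:
:func:`threshold_binarize` (step function at a fitness threshold ``f_star``)
and :func:`plateau_approximate` (whole greedy-ascent basins whose local peak
clears ``f_star`` become targets; the rest of the landscape is flattened at
the highest sub-threshold local maximum ``f_max``).  The plateau variant is
the more lenient of the two: its target set always contains the threshold
target set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np

from .sequences import SequenceSpace, hamming_distance

ENUMERATION_LIMIT = 10**6

__all__ = [
    "BroadPeakLandscape",
    "MultiPeakLandscape",
    "MultiplicativeLandscape",
    "TabulatedLandscape",
    "EmptyTargetError",
    "generate_rugged",
    "find_local_maxima",
    "greedy_basin",
    "threshold_binarize",
    "plateau_approximate",
]


class EmptyTargetError(ValueError):
    """Raised when an approximation produces an empty target set."""


@dataclass(frozen=True)
class BroadPeakLandscape:
    """Single broad peak: target = ball of radius ``w`` around ``center``.

    Fitness is 1 outside the target and ``target_advantage`` (default 1,
    i.e. neutral discovery) inside.
    """

    space: SequenceSpace
    center: str
    w: int
    target_advantage: float = 1.0

    def __post_init__(self) -> None:
        self.space.validate(self.center)
        if not 0 <= self.w <= self.space.L:
            raise ValueError(f"width w={self.w} outside [0, L={self.space.L}]")
        if self.target_advantage <= 0:
            raise ValueError("target_advantage must be positive")

    @classmethod
    def from_fraction(
        cls, space: SequenceSpace, center: str, c: float, target_advantage: float = 1.0
    ) -> "BroadPeakLandscape":
        """Build with radius w = floor(c * L) from a width fraction c in [0, 1]."""
        if not 0 <= c <= 1:
            raise ValueError(f"width fraction c={c} outside [0, 1]")
        return cls(space, center, int(np.floor(c * space.L)), target_advantage)

    @property
    def centers(self) -> List[str]:
        return [self.center]

    def distance(self, s: str) -> int:
        return hamming_distance(s, self.center)

    def in_target(self, s: str) -> bool:
        return self.distance(s) <= self.w

    def fitness(self, s: str) -> float:
        return self.target_advantage if self.in_target(s) else 1.0

    def target_size(self) -> int:
        return self.space.ball_volume(self.w)


@dataclass(frozen=True)
class MultiPeakLandscape:
    """Union of ``m`` broad peaks of common radius ``w``."""

    space: SequenceSpace
    centers: Tuple[str, ...]
    w: int
    target_advantage: float = 1.0

    def __post_init__(self) -> None:
        if len(self.centers) < 1:
            raise ValueError("at least one target center required")
        for c in self.centers:
            self.space.validate(c)
        if not 0 <= self.w <= self.space.L:
            raise ValueError(f"width w={self.w} outside [0, L={self.space.L}]")
        object.__setattr__(self, "centers", tuple(self.centers))

    @property
    def m(self) -> int:
        return len(self.centers)

    def distance(self, s: str) -> int:
        """Hamming distance to the nearest target center."""
        return min(hamming_distance(s, c) for c in self.centers)

    def in_target(self, s: str) -> bool:
        return self.distance(s) <= self.w

    def fitness(self, s: str) -> float:
        return self.target_advantage if self.in_target(s) else 1.0

    @classmethod
    def random(
        cls,
        space: SequenceSpace,
        m: int,
        w: int,
        rng: np.random.Generator,
        target_advantage: float = 1.0,
    ) -> "MultiPeakLandscape":
        """``m`` target centers drawn uniformly at random from the space."""
        centers = tuple(space.random_sequence(rng) for _ in range(m))
        return cls(space, centers, w, target_advantage)


@dataclass(frozen=True)
class MultiplicativeLandscape:
    """Multiplicative gradient toward a center with an embedded target ball.

    fitness(s) = (1 + sigma)**(L - d(s, center)); sigma = 0 reduces to a flat
    landscape.  The target set is the ball of radius ``w`` around the center.
    """

    space: SequenceSpace
    center: str
    sigma: float
    w: int

    def __post_init__(self) -> None:
        self.space.validate(self.center)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.w <= self.space.L:
            raise ValueError(f"width w={self.w} outside [0, L={self.space.L}]")

    @property
    def centers(self) -> List[str]:
        return [self.center]

    def distance(self, s: str) -> int:
        return hamming_distance(s, self.center)

    def in_target(self, s: str) -> bool:
        return self.distance(s) <= self.w

    def fitness(self, s: str) -> float:
        return (1.0 + self.sigma) ** (self.space.L - self.distance(s))

    def fitness_by_distance(self, k: int) -> float:
        return (1.0 + self.sigma) ** (self.space.L - k)


class TabulatedLandscape:
    """Explicit fitness table over every sequence of a small space.

    Optionally carries a target set (a set of sequences), as produced by the
    approximation operators.
    """

    def __init__(
        self,
        space: SequenceSpace,
        fitness: Dict[str, float],
        target: Set[str] | None = None,
    ) -> None:
        if space.size > ENUMERATION_LIMIT:
            raise ValueError(
                f"space of size {space.size} exceeds enumeration limit {ENUMERATION_LIMIT}"
            )
        if len(fitness) != space.size:
            raise ValueError(
                f"fitness table has {len(fitness)} entries; expected {space.size}"
            )
        for s, f in fitness.items():
            space.validate(s)
            if f < 0:
                raise ValueError(f"negative fitness {f} for {s}")
        self.space = space
        self._fitness = dict(fitness)
        self.target: Set[str] = set(target) if target is not None else set()

    def fitness(self, s: str) -> float:
        return self._fitness[s]

    def in_target(self, s: str) -> bool:
        return s in self.target

    def items(self):
        return self._fitness.items()

    def max_fitness(self) -> float:
        return max(self._fitness.values())

    def min_fitness(self) -> float:
        return min(self._fitness.values())

    # ------------------------------------------------------------------ #
    # plain-text round trip: header line "#L=<L> alphabet=<alphabet>",
    # then one "<sequence> <fitness>" pair per line.
    # ------------------------------------------------------------------ #

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#L={self.space.L} alphabet={self.space.alphabet}\n")
            for s in sorted(self._fitness):
                line = f"{s}\t{self._fitness[s]!r}"
                if s in self.target:
                    line += "\t*"
                fh.write(line + "\n")

    @classmethod
    def from_file(cls, path) -> "TabulatedLandscape":
        with open(path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#L="):
                raise ValueError(f"malformed landscape header: {header!r}")
            fields = dict(kv.split("=", 1) for kv in header[1:].split())
            space = SequenceSpace(int(fields["L"]), fields["alphabet"])
            fitness: Dict[str, float] = {}
            target: Set[str] = set()
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                fitness[parts[0]] = float(parts[1])
                if len(parts) > 2 and parts[2] == "*":
                    target.add(parts[0])
        return cls(space, fitness, target)


def generate_rugged(
    space: SequenceSpace,
    anchor: str,
    slope: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> TabulatedLandscape:
    """Rough-Mount-Fuji landscape on a fully enumerated small space.

    f(s) = base - slope * d(s, anchor) + eps_s with eps_s i.i.d.
    Normal(0, noise_sd**2), shifted so the minimum fitness is >= 0.
    slope > 0 with zero noise gives a smooth cone peaked at the anchor;
    slope = 0 with noise gives a maximally epistatic random field.
    """
    space.validate(anchor)
    seqs = list(space.iter_sequences())
    d = np.array([hamming_distance(s, anchor) for s in seqs], dtype=float)
    eps = rng.normal(0.0, noise_sd, size=len(seqs)) if noise_sd > 0 else np.zeros(len(seqs))
    f = slope * space.L - slope * d + eps
    f -= min(f.min(), 0.0)  # shift into the non-negative range
    return TabulatedLandscape(space, dict(zip(seqs, f.tolist())))


def find_local_maxima(land: TabulatedLandscape) -> List[str]:
    """All sequences with fitness strictly above every point-mutation neighbor.

    Strict comparison: a flat landscape has no local maxima, and plateaus are
    never maxima.  Returned in the space's lexicographic enumeration order.
    """
    out = []
    for s in land.space.iter_sequences():
        fs = land.fitness(s)
        if all(land.fitness(r) < fs for r in land.space.neighbors(s)):
            out.append(s)
    return out


def greedy_basin(land: TabulatedLandscape, s: str) -> str:
    """The local maximum reached from ``s`` by steepest ascent.

    At each step move to the strictly best improving neighbor; ties are broken
    by the deterministic neighbor order (position, then alphabet).  Returns
    ``s`` itself when no neighbor improves.
    """
    land.space.validate(s)
    cur = s
    while True:
        f_cur = land.fitness(cur)
        best, f_best = None, f_cur
        for r in land.space.neighbors(cur):
            fr = land.fitness(r)
            if fr > f_best:  # strict improvement; first hit wins ties at equal fr
                best, f_best = r, fr
        if best is None:
            return cur
        cur = best


def threshold_binarize(
    land: TabulatedLandscape, f_star: float, target_fitness: float = 2.0
) -> TabulatedLandscape:
    """Step-function approximation of a rugged landscape.

    Sequences with fitness >= ``f_star`` form the target set (assigned the
    common fitness ``target_fitness`` > 1); everything else becomes neutral
    background with fitness 1.
    """
    if target_fitness <= 1:
        raise ValueError("target_fitness must exceed the neutral background 1")
    target = {s for s, f in land.items() if f >= f_star}
    if not target:
        raise EmptyTargetError(
            f"no sequence reaches f_star={f_star} (max fitness {land.max_fitness()})"
        )
    fit = {s: (target_fitness if s in target else 1.0) for s, _ in land.items()}
    return TabulatedLandscape(land.space, fit, target)


def plateau_approximate(land: TabulatedLandscape, f_star: float) -> TabulatedLandscape:
    """Basin-level approximation of a rugged landscape.

    A sequence is a target when its greedy-ascent basin terminates at a local
    peak of fitness >= ``f_star`` (the target thus starts at the upslope of a
    sufficiently high mountain range).  Every non-target sequence is assigned
    the common fitness ``f_max`` = the highest basin-peak fitness below
    ``f_star``, so the complement of the target set is exactly flat.  Target
    fitness values are left untouched.
    """
    peak_of: Dict[str, str] = {}
    for s in land.space.iter_sequences():
        peak_of[s] = greedy_basin(land, s)
    target = {s for s, p in peak_of.items() if land.fitness(p) >= f_star}
    if not target:
        raise EmptyTargetError(
            f"no basin peak reaches f_star={f_star} (max fitness {land.max_fitness()})"
        )
    sub_peaks = {land.fitness(p) for s, p in peak_of.items() if s not in target}
    f_max = max(sub_peaks) if sub_peaks else float("nan")
    fit = {
        s: (land.fitness(s) if s in target else f_max) for s, _ in land.items()
    }
    return TabulatedLandscape(land.space, fit, target)
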