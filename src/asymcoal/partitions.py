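"""Set partitions of [n], mass partitions, coagulation, and paint-box sampling.

The ancestral process of a discrete-generation population is a sequence of
partitions of the sample {1, ..., n}: individuals in the same block share a
common ancestor.  One generation back, lineages merge according to a
*coagulation* increment; exchangeable increments are exactly the ones that can
be produced by the paint-box construction from a mass partition
(rho_1 >= rho_2 >= ... >= 0, sum <= 1, deficit = "dust").
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Partition",
    "MassPartition",
    "coagulate",
    "restrict",
    "paintbox_sample",
    "paintbox_partition_probability",
    "all_partitions",
    "singleton_partition",
]

MASS_TOL = 1e-12


def _canonical_blocks(blocks: Sequence[Sequence[int]]) -> tuple[tuple[int, ...], ...]:
    sorted_blocks = [tuple(sorted(b)) for b in blocks if len(b) > 0]
    sorted_blocks.sort(key=lambda b: b[0])
    return tuple(sorted_blocks)


@dataclass(frozen=True)
class Partition:
    """A set partition of {1, ..., n} in canonical (least-element) order.

    Blocks are stored as sorted tuples, ordered by their least element, so two
    partitions are equal iff their canonical block lists are equal, and
    instances are hashable (usable as keys of transition-probability maps).
    """

    n: int
    blocks: tuple[tuple[int, ...], ...]

    def __init__(self, n: int, blocks: Sequence[Sequence[int]]):
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "blocks", _canonical_blocks(blocks))
        self._validate()

    def _validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"partition ground set size must be >= 1, got {self.n}")
        seen: set[int] = set()
        for b in self.blocks:
            for x in b:
                if not (1 <= x <= self.n):
                    raise ValueError(f"element {x} outside ground set [1, {self.n}]")
                if x in seen:
                    raise ValueError(f"element {x} appears in more than one block")
                seen.add(x)
        if len(seen) != self.n:
            missing = set(range(1, self.n + 1)) - seen
            raise ValueError(f"blocks do not cover the ground set; missing {sorted(missing)}")

    # -- basic queries ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.blocks)

    def block_sizes(self) -> tuple[int, ...]:
        """Sizes of the blocks in least-element order."""
        return tuple(len(b) for b in self.blocks)

    def profile(self) -> tuple[int, ...]:
        """Block sizes in non-increasing order (the relabeling invariant)."""
        return tuple(sorted((len(b) for b in self.blocks), reverse=True))

    def is_singletons(self) -> bool:
        return len(self.blocks) == self.n

    def block_of(self, x: int) -> int:
        """Index (0-based) of the block containing element x."""
        for i, b in enumerate(self.blocks):
            if x in b:
                return i
        raise ValueError(f"element {x} not in ground set")

    # -- serialization ----------------------------------------------------
    def to_string(self) -> str:
        """Compact string form, e.g. ``"1,3|2"`` for {{1,3},{2}}."""
        return "|".join(",".join(str(x) for x in b) for b in self.blocks)

    @classmethod
    def from_string(cls, s: str, n: int | None = None) -> "Partition":
        blocks = [[int(x) for x in part.split(",")] for part in s.split("|")]
        size = n if n is not None else max(x for b in blocks for x in b)
        return cls(size, blocks)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Partition({self.n}, {self.to_string()!r})"


def singleton_partition(n: int) -> Partition:
    """The partition of [n] into n singletons (the identity for coagulation)."""
    return Partition(n, [(i,) for i in range(1, n + 1)])


def coagulate(pi: Partition, pi_prime: Partition) -> Partition:
    """Merge the blocks of ``pi`` according to the blocks of ``pi_prime``.

    The k-th block of the result is the union of pi's blocks whose indices
    (1-based, least-element order) lie in the k-th block of ``pi_prime``.
    The pair is admissible when ``len(pi) <= pi_prime.n``; indices of
    ``pi_prime`` beyond ``len(pi)`` refer to empty blocks and are dropped.
    """
    if len(pi) > pi_prime.n:
        raise ValueError(
            f"inadmissible pair: pi has {len(pi)} blocks but pi_prime partitions "
            f"[{pi_prime.n}]"
        )
    new_blocks = []
    for idx_block in pi_prime.blocks:
        merged: list[int] = []
        for j in idx_block:
            if j <= len(pi):
                merged.extend(pi.blocks[j - 1])
        if merged:
            new_blocks.append(merged)
    return Partition(pi.n, new_blocks)


def restrict(pi: Partition, m: int) -> Partition:
    """Restriction of a partition of [n] to [m]: intersect blocks, drop empties."""
    if m > pi.n:
        raise ValueError(f"cannot restrict a partition of [{pi.n}] to [{m}]")
    if m < 1:
        raise ValueError("restriction size must be >= 1")
    blocks = [[x for x in b if x <= m] for b in pi.blocks]
    return Partition(m, [b for b in blocks if b])


@dataclass(frozen=True)
class MassPartition:
    """Non-increasing masses in (0,1] with an explicit dust component.

    ``parts`` are the interval lengths of the paint-box; ``dust`` is the
    leftover mass rho_0 = 1 - sum(parts), whose uniforms become singletons.
    Inputs violating sum(parts) + dust == 1 by more than 1e-12 are rejected
    (silent renormalization would hide model bugs).
    """

    parts: tuple[float, ...]
    dust: float = field(default=0.0)

    def __init__(self, parts: Sequence[float], dust: float | None = None):
        parts = tuple(float(p) for p in parts if p != 0.0)
        if any(p < 0 for p in parts):
            raise ValueError("mass partition parts must be non-negative")
        if any(parts[i] < parts[i + 1] - MASS_TOL for i in range(len(parts) - 1)):
            raise ValueError("mass partition parts must be non-increasing")
        total = math.fsum(parts)
        if dust is None:
            dust = 1.0 - total
            if -MASS_TOL < dust < 0.0:
                dust = 0.0
        if dust < -MASS_TOL or abs(total + dust - 1.0) > MASS_TOL:
            raise ValueError(
                f"sum(parts) + dust = {total + dust} violates the unit constraint "
                f"by more than {MASS_TOL}"
            )
        object.__setattr__(self, "parts", parts)
        object.__setattr__(self, "dust", float(dust))

    @property
    def sum_of_squares(self) -> float:
        """sum rho_i^2 — the pair-merge probability of the paint-box."""
        return math.fsum(p * p for p in self.parts)

    def __len__(self) -> int:
        return len(self.parts)


def paintbox_sample(rho: MassPartition, n: int, rng: np.random.Generator) -> Partition:
    """Sample an exchangeable partition of [n] from the paint-box on ``rho``.

    n i.i.d. uniforms are assigned to consecutive half-open intervals
    [sum_{j<k} rho_j, sum_{j<=k} rho_j); uniforms in the terminal dust
    interval [1-rho_0, 1) become singletons.
    """
    if n < 1:
        raise ValueError("sample size must be >= 1")
    u = rng.random(n)
    edges = np.cumsum(rho.parts)
    cells = np.searchsorted(edges, u, side="right")  # == len(parts) -> dust
    k = len(rho.parts)
    groups: dict[int, list[int]] = {}
    blocks: list[list[int]] = []
    for i, c in enumerate(cells, start=1):
        if c >= k:
            blocks.append([i])
        else:
            groups.setdefault(int(c), []).append(i)
    blocks.extend(groups.values())
    return Partition(n, blocks)


def paintbox_partition_probability(rho: MassPartition, pi: Partition) -> float:
    """Exact probability that the paint-box on ``rho`` produces ``pi``.

    Non-singleton blocks must land in distinct paint intervals; each singleton
    block lands either in a fresh distinct interval or in the dust.  Computed
    by exhaustive enumeration of injections (intended for small n / few parts).
    """
    parts = rho.parts
    k = len(parts)
    sizes = pi.block_sizes()
    heavy = [b for b in sizes if b >= 2]
    s = sum(1 for b in sizes if b == 1)
    total = 0.0
    # l singletons take distinct intervals, s - l fall in dust
    for l in range(0, s + 1):
        r = len(heavy) + l
        if r > k:
            break
        dust_factor = rho.dust ** (s - l) * math.comb(s, l)
        if dust_factor == 0.0:
            continue
        exps = heavy + [1] * l
        acc = 0.0
        for assign in itertools.permutations(range(k), r):
            prod = 1.0
            for e, idx in zip(exps, assign):
                prod *= parts[idx] ** e
            acc += prod
        # permutations() distinguishes the order of equal-size blocks; the
        # exponent list enumerates labeled blocks, so ordering is correct, but
        # the l chosen singletons are unlabeled here -> comb(s, l) above picks
        # which singletons, and permutations assigns their intervals in order.
        total += dust_factor * acc
    return total


def all_partitions(n: int) -> Iterator[Partition]:
    """Iterate over all set partitions of [n] (restricted-growth strings)."""
    if n < 1:
        return
    a = [0] * n
    b = [1] * n  # b[i] = 1 + max(a[:i])

    while True:
        blocks: dict[int, list[int]] = {}
        for i, c in enumerate(a, start=1):
            blocks.setdefault(c, []).append(i)
        yield Partition(n, list(blocks.values()))
        # next restricted growth string
        i = n - 1
        while i > 0 and a[i] == b[i]:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = b[i] + (1 if a[i] == b[i] else 0)
        # recompute b from scratch for safety
        for j in range(1, n):
            b[j] = max(b[j - 1], a[j - 1] + 1)
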