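"""Exact coagulation rates of Lambda- and Xi-coalescents, plus a reference
continuous-time Lambda-coalescent simulator.

A Lambda-coalescent merges a single group of b out of n blocks at rate
``lambda_{n,b} = int_0^1 p^(b-2) (1-p)^(n-b) Lambda(dp)``.  A Xi-coalescent
allows simultaneous mergers: at rate Xi(d rho)/sum(rho_i^2) a paint-box on the
mass partition rho coagulates the blocks.  Here Xi is represented by a finite
list of mass-partition atoms plus an optional Kingman mass (an atom at the
zero mass partition producing pairwise merges).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import integrate, special

from .partitions import (
    MassPartition,
    Partition,
    all_partitions,
    coagulate,
    paintbox_partition_probability,
    singleton_partition,
)

__all__ = [
    "LambdaMeasure",
    "XiMeasure",
    "RateMatrix",
    "lambda_rate",
    "lambda_rate_table",
    "xi_rate_matrix",
    "simulate_lambda_coalescent",
    "KINGMAN",
    "BOLTHAUSEN_SZNITMAN",
]


@dataclass(frozen=True)
class LambdaMeasure:
    """A finite measure on [0,1] driving a Lambda-coalescent.

    kind:
      * ``point_mass`` — total_mass at location ``p`` (p=0 is Kingman's
        coalescent, p=1 the star coalescent);
      * ``beta`` — total_mass times the Beta(a, b) distribution (Beta(1,1)
        is the Bolthausen–Sznitman coalescent);
      * ``truncated_density`` — total_mass is ignored; an unnormalized density
        on (cutoff, 1] integrated by adaptive quadrature.
    """

    kind: Literal["point_mass", "beta", "truncated_density"]
    p: float = 0.0
    a: float = 1.0
    b: float = 1.0
    total_mass: float = 1.0
    density: Callable[[float], float] | None = field(default=None, compare=False)
    cutoff: float = 0.0

    @classmethod
    def point_mass(cls, p: float, total_mass: float = 1.0) -> "LambdaMeasure":
        if not 0.0 <= p <= 1.0:
            raise ValueError("point mass location must lie in [0, 1]")
        return cls(kind="point_mass", p=p, total_mass=total_mass)

    @classmethod
    def beta(cls, a: float, b: float, total_mass: float = 1.0) -> "LambdaMeasure":
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")
        return cls(kind="beta", a=a, b=b, total_mass=total_mass)

    @classmethod
    def truncated_density(
        cls, density: Callable[[float], float], cutoff: float = 0.0
    ) -> "LambdaMeasure":
        return cls(kind="truncated_density", density=density, cutoff=cutoff)

    def mass(self) -> float:
        """Total mass Lambda([0,1]) (= lambda_{2,2})."""
        return lambda_rate(2, 2, self)


KINGMAN = LambdaMeasure.point_mass(0.0)
BOLTHAUSEN_SZNITMAN = LambdaMeasure.beta(1.0, 1.0)


def lambda_rate(n: int, b: int, Lambda: LambdaMeasure) -> float:
    """Collision rate lambda_{n,b} = int p^(b-2)(1-p)^(n-b) Lambda(dp).

    Closed forms for point masses (0^0 := 1) and Beta measures; adaptive
    Gauss–Kronrod quadrature for truncated densities (abs tol 1e-10).
    """
    if b < 2 or b > n:
        raise ValueError(f"need 2 <= b <= n, got b={b}, n={n}")
    if Lambda.kind == "point_mass":
        p = Lambda.p
        val = (p ** (b - 2) if (p > 0 or b == 2) else 0.0) * (1.0 - p) ** (n - b)
        return Lambda.total_mass * val
    if Lambda.kind == "beta":
        a, c = Lambda.a, Lambda.b
        # int p^(b-2)(1-p)^(n-b) Beta(a,c)(dp) = B(a+b-2, c+n-b) / B(a, c)
        log_ratio = (
            special.betaln(a + b - 2, c + n - b) - special.betaln(a, c)
        )
        return Lambda.total_mass * math.exp(log_ratio)
    assert Lambda.density is not None
    val, _ = integrate.quad(
        lambda p: p ** (b - 2) * (1.0 - p) ** (n - b) * Lambda.density(p),
        Lambda.cutoff,
        1.0,
        epsabs=1e-10,
        limit=200,
    )
    return val


def lambda_rate_table(n_max: int, Lambda: LambdaMeasure) -> dict[tuple[int, int], float]:
    """All lambda_{n,b} for 2 <= b <= n <= n_max."""
    return {
        (n, b): lambda_rate(n, b, Lambda)
        for n in range(2, n_max + 1)
        for b in range(2, n + 1)
    }


@dataclass(frozen=True)
class XiMeasure:
    """Finite-support coagulation measure: mass-partition atoms + Kingman mass.

    Each atom (rho, w) contributes paint-box mergers from rho at rate
    w / sum(rho_i^2); ``kingman_mass`` adds pairwise merges at that rate.
    An atom with sum(rho_i^2) == 0 and positive weight is rejected.
    """

    atoms: tuple[tuple[MassPartition, float], ...]
    kingman_mass: float = 0.0

    def __init__(
        self,
        atoms: list[tuple[MassPartition, float]] | tuple = (),
        kingman_mass: float = 0.0,
    ):
        atoms = tuple((rho, float(w)) for rho, w in atoms)
        for rho, w in atoms:
            if w < 0:
                raise ValueError("atom weights must be non-negative")
            if w > 0 and rho.sum_of_squares == 0.0:
                raise ValueError(
                    "Xi atom with sum(rho_i^2) == 0 and positive weight is "
                    "not integrable (use kingman_mass for the zero atom)"
                )
        if kingman_mass < 0:
            raise ValueError("kingman_mass must be non-negative")
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "kingman_mass", float(kingman_mass))

    @classmethod
    def from_lambda_atoms(cls, pairs: list[tuple[float, float]]) -> "XiMeasure":
        """Lambda-type measure from (p, weight) pairs: atoms (p; dust 1-p)."""
        return cls([(MassPartition([p], 1.0 - p), w) for p, w in pairs])


@dataclass
class RateMatrix:
    """Coagulation rates Q^(n)(pi~) := Q^(n)(0_n, pi~) for non-trivial pi~.

    Rates depend on pi~ only through its block-size profile; the mapping is
    stored per labeled partition for direct use against transition maps.
    """

    n: int
    rates: dict[Partition, float]

    def rate(self, pi: Partition) -> float:
        return self.rates.get(pi, 0.0)

    def total_rate(self) -> float:
        return math.fsum(self.rates.values())

    def pair_rate(self) -> float:
        """Rate of the merger of one specific pair (= lambda_{n,2} analog)."""
        pi = Partition(self.n, [[1, 2]] + [[i] for i in range(3, self.n + 1)])
        return self.rate(pi)

    def by_profile(self) -> dict[tuple[int, ...], tuple[float, int]]:
        """Map profile -> (per-partition rate, number of labeled partitions)."""
        out: dict[tuple[int, ...], list] = {}
        for pi, r in self.rates.items():
            prof = pi.profile()
            if prof in out:
                out[prof][1] += 1
                out[prof][0] = max(out[prof][0], r)
            else:
                out[prof] = [r, 1]
        return {k: (v[0], v[1]) for k, v in out.items()}

    def to_tsv(self) -> str:
        buf = io.StringIO()
        buf.write("block_size_profile\trate\n")
        for prof, (r, _count) in sorted(self.by_profile().items(), reverse=True):
            buf.write(f"{','.join(map(str, prof))}\t{r:.12g}\n")
        return buf.getvalue()


def xi_rate_matrix(n: int, Xi: XiMeasure) -> RateMatrix:
    """Exact Q^(n) of the Xi-coalescent on partitions of [n].

    For each non-trivial partition pi~, the rate is
    kingman_mass * 1{pi~ is a single pair merge}
    + sum over atoms of weight / sum(rho_i^2) * P(paint-box(rho) = pi~).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rates: dict[Partition, float] = {}
    for pi in all_partitions(n):
        if pi.is_singletons():
            continue
        r = 0.0
        if Xi.kingman_mass > 0 and pi.profile() == (2,) + (1,) * (n - 2):
            r += Xi.kingman_mass
        for rho, w in Xi.atoms:
            if w == 0:
                continue
            r += w / rho.sum_of_squares * paintbox_partition_probability(rho, pi)
        if r > 0:
            rates[pi] = r
    return RateMatrix(n=n, rates=rates)


@dataclass
class ContinuousTrace:
    """Jump-chain record of a continuous-time coalescent started at 0_n."""

    n: int
    times: list[float]
    partitions: list[Partition]

    def block_counts(self) -> list[int]:
        return [len(p) for p in self.partitions]

    def to_newick(self) -> str:
        from .population import trace_to_newick

        return trace_to_newick(self.times, self.partitions)


def simulate_lambda_coalescent(
    n: int, Lambda: LambdaMeasure, rng: np.random.Generator, t_max: float = math.inf
) -> ContinuousTrace:
    """Simulate the Lambda-coalescent on [n] until absorption (or t_max).

    With m blocks present, each specific group of b blocks merges at rate
    lambda_{m,b}; total jump rate sum_b C(m,b) lambda_{m,b}.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if Lambda.mass() <= 0:
        raise ValueError("Lambda has zero total mass: no mergers ever occur")
    state = singleton_partition(n)
    t = 0.0
    times = [0.0]
    partitions = [state]
    while len(state) > 1 and t < t_max:
        m = len(state)
        group_rates = np.array(
            [math.comb(m, b) * lambda_rate(m, b, Lambda) for b in range(2, m + 1)]
        )
        total = group_rates.sum()
        t += rng.exponential(1.0 / total)
        if t >= t_max:
            break
        b = 2 + rng.choice(m - 1, p=group_rates / total)
        merging = rng.choice(m, size=b, replace=False) + 1  # block indices, 1-based
        inc_blocks = [sorted(merging.tolist())] + [
            [j] for j in range(1, m + 1) if j not in set(merging.tolist())
        ]
        state = coagulate(state, Partition(m, inc_blocks))
        times.append(t)
        partitions.append(state)
    return ContinuousTrace(n=n, times=times, partitions=partitions)
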