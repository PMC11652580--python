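"""Forward one-generation population dynamics and genealogy transition matrices.

Two model classes are supported, both neutral in the sense that reproductive
success is not heritable:

* Asymmetric Wright–Fisher (AWF): each generation an independent random
  probability vector eta over the N parents is drawn and the n sampled
  children choose parents i.i.d. from eta (sampling *with* replacement).
* Asymmetric Cannings (AC): each generation an integer offspring vector xi
  with total Sigma_N >= N is drawn, and children are sampled *without*
  replacement from the Sigma_N child slots.

Grouping sampled children by parent gives the coagulation increment of the
ancestral process; its distribution over partitions of [n] is

    AWF:  P(pi~)  = E[ sum_{distinct i_1..i_j} prod_k eta_{i_k}^{b_k} ]
    AC :  P~(pi~) = E[ sum_{distinct i_1..i_j} prod_k (xi_{i_k})_{b_k} ] / (Sigma_N)_n

with b_k the block sizes of pi~ and (x)_b the falling factorial.  The
distinct-index sums are evaluated exactly per draw via an inclusion–exclusion
over set partitions of the exponent list (products of power sums), which makes
the Monte-Carlo estimators conditionally exact given the drawn eta / xi.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Literal, Sequence

import numpy as np

from .partitions import Partition, all_partitions, coagulate, singleton_partition

__all__ = [
    "FrequencyModel",
    "OffspringModel",
    "DeterministicFrequency",
    "DiscreteFrequency",
    "UniformFrequency",
    "DiscreteOffspring",
    "MultinomialOffspring",
    "GenealogyTrace",
    "TransitionEstimate",
    "awf_increment",
    "ac_increment",
    "awf_transition_matrix",
    "ac_transition_matrix",
    "awf_transition_given_eta",
    "ac_transition_given_xi",
    "pair_coalescence_probability",
    "simulate_genealogy",
    "ac_awf_discrepancy",
    "distinct_power_sum_batch",
    "generation_rng",
    "trace_to_newick",
]

PROB_TOL = 1e-12


# ---------------------------------------------------------------------------
# model interfaces
# ---------------------------------------------------------------------------


class FrequencyModel:
    """One-generation law of the family-frequency vector eta^(N).

    Subclasses implement ``sample`` (and, for speed, ``sample_batch``); finite
    models may expose ``outcomes()`` for exact enumeration and an analytic
    pair-coalescence probability via ``exact_pair_probability()``.
    """

    N: int

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def sample_batch(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.stack([self.sample(rng) for _ in range(size)])

    def outcomes(self) -> list[tuple[np.ndarray, float]] | None:
        return None

    def exact_pair_probability(self) -> float | None:
        out = self.outcomes()
        if out is None:
            return None
        return math.fsum(p * float(np.sum(eta**2)) for eta, p in out)


class OffspringModel:
    """One-generation law of the offspring-size vector xi^(N), Sigma xi >= N."""

    N: int

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def sample_batch(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.stack([self.sample(rng) for _ in range(size)])

    def outcomes(self) -> list[tuple[np.ndarray, float]] | None:
        return None

    def exact_pair_probability(self) -> float | None:
        out = self.outcomes()
        if out is None:
            return None
        total = 0.0
        for xi, p in out:
            s = int(xi.sum())
            total += p * float(np.sum(xi * (xi - 1))) / (s * (s - 1))
        return total


def _check_probability_vector(eta: np.ndarray) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < -PROB_TOL) or abs(eta.sum() - 1.0) > 1e-9:
        raise ValueError(f"not a probability vector (sum={eta.sum()})")
    return np.clip(eta, 0.0, None)


class DeterministicFrequency(FrequencyModel):
    """A fixed frequency vector every generation (e.g. the classical
    Wright-Fisher model with eta = (1/N, ..., 1/N))."""

    def __init__(self, eta: Sequence[float]):
        self.eta = _check_probability_vector(np.asarray(eta, dtype=float))
        self.N = len(self.eta)

    def sample(self, rng):
        return self.eta

    def sample_batch(self, rng, size):
        return np.broadcast_to(self.eta, (size, self.N)).copy()

    def outcomes(self):
        return [(self.eta, 1.0)]


class DiscreteFrequency(FrequencyModel):
    """A finite mixture of frequency vectors (exactly enumerable)."""

    def __init__(self, outcomes: Iterable[tuple[Sequence[float], float]]):
        self._outcomes = [
            (_check_probability_vector(np.asarray(v, dtype=float)), float(p))
            for v, p in outcomes
        ]
        if abs(math.fsum(p for _, p in self._outcomes) - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")
        self.N = len(self._outcomes[0][0])
        self._probs = np.array([p for _, p in self._outcomes])

    def sample(self, rng):
        k = rng.choice(len(self._outcomes), p=self._probs)
        return self._outcomes[k][0]

    def outcomes(self):
        return list(self._outcomes)


class UniformFrequency(DeterministicFrequency):
    """Classical Wright–Fisher: every parent equally likely, c_N = 1/N."""

    def __init__(self, N: int):
        super().__init__(np.full(N, 1.0 / N))

    def exact_pair_probability(self):
        return 1.0 / self.N


class DiscreteOffspring(OffspringModel):
    """A finite mixture of offspring vectors (exactly enumerable)."""

    def __init__(self, outcomes: Iterable[tuple[Sequence[int], float]]):
        self._outcomes = []
        for v, p in outcomes:
            xi = np.asarray(v, dtype=np.int64)
            if np.any(xi < 0):
                raise ValueError("offspring sizes must be non-negative")
            self._outcomes.append((xi, float(p)))
        if abs(math.fsum(p for _, p in self._outcomes) - 1.0) > 1e-9:
            raise ValueError("outcome probabilities must sum to 1")
        self.N = len(self._outcomes[0][0])
        self._probs = np.array([p for _, p in self._outcomes])

    def sample(self, rng):
        k = rng.choice(len(self._outcomes), p=self._probs)
        return self._outcomes[k][0]

    def outcomes(self):
        return list(self._outcomes)


class MultinomialOffspring(OffspringModel):
    """Cannings offspring: xi ~ Multinomial(N, p) for a fixed weight vector."""

    def __init__(self, N: int, p: Sequence[float] | None = None):
        self.N = N
        self.p = (
            np.full(N, 1.0 / N) if p is None else _check_probability_vector(np.asarray(p))
        )

    def sample(self, rng):
        return rng.multinomial(self.N, self.p)

    def sample_batch(self, rng, size):
        return rng.multinomial(self.N, self.p, size=size)


# ---------------------------------------------------------------------------
# distinct-index sums (inclusion-exclusion over set partitions of exponents)
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _index_partitions(j: int) -> tuple[tuple[tuple[int, ...], ...], ...]:
    return tuple(p.blocks for p in all_partitions(j)) if j >= 1 else ((),)


def _partition_coefficient(blocks: tuple[tuple[int, ...], ...]) -> int:
    coef = 1
    for b in blocks:
        coef *= (-1) ** (len(b) - 1) * math.factorial(len(b) - 1)
    return coef


def distinct_power_sum_batch(columns: Sequence[np.ndarray]) -> np.ndarray:
    """sum over distinct indices i_1..i_j of prod_k f_k(i_k), per draw.

    ``columns`` is a list of arrays of shape (draws, N), one per factor.  The
    sum is computed by inclusion-exclusion over the set partitions of the
    factor list: grouping factors multiplies them at a common index, so

        sum_distinct = sum_sigma prod_B (-1)^{|B|-1}(|B|-1)! * sum_i prod_{k in B} f_k(i).
    """
    j = len(columns)
    draws = columns[0].shape[0]
    out = np.zeros(draws)
    for blocks in _index_partitions(j):
        term = np.ones(draws)
        for b in blocks:
            prod = columns[b[0] - 1]
            for k in b[1:]:
                prod = prod * columns[k - 1]
            term = term * prod.sum(axis=1)
        out += _partition_coefficient(blocks) * term
    return out


def awf_transition_given_eta(eta_batch: np.ndarray, sizes: Sequence[int]) -> np.ndarray:
    """Conditional P(increment = pi~ | eta) for one labeled pi~ of block sizes
    ``sizes``; shape (draws,)."""
    cols = [eta_batch**b for b in sizes]
    return distinct_power_sum_batch(cols)


def _falling_factorial(x: np.ndarray, b: int) -> np.ndarray:
    out = np.ones_like(x, dtype=float)
    for r in range(b):
        out = out * (x - r)
    return out


def ac_transition_given_xi(xi_batch: np.ndarray, sizes: Sequence[int], n: int) -> np.ndarray:
    """Conditional P~(increment = pi~ | xi) for one labeled pi~; shape (draws,)."""
    xi = np.asarray(xi_batch, dtype=float)
    sigma = xi.sum(axis=1)
    if np.any(sigma < n):
        raise ValueError("total offspring Sigma_N smaller than the sample size n")
    cols = [_falling_factorial(xi, b) for b in sizes]
    denom = _falling_factorial(sigma, n)
    return distinct_power_sum_batch(cols) / denom


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


@dataclass
class TransitionEstimate:
    """Transition-probability map on partitions of [n], with standard errors.

    ``probs[pi]`` estimates P(increment = pi); ``se`` is zero for exact
    (enumerated) models.  Probabilities depend on pi only through its
    block-size profile.
    """

    n: int
    probs: dict[Partition, float]
    se: dict[Partition, float]
    method: str
    reps: int = 0

    def row_sum(self) -> float:
        return math.fsum(self.probs.values())

    def prob_of_profile(self, profile: tuple[int, ...]) -> float:
        for pi, p in self.probs.items():
            if pi.profile() == tuple(profile):
                return p
        return 0.0

    def nontrivial(self) -> dict[Partition, float]:
        return {pi: p for pi, p in self.probs.items() if not pi.is_singletons()}


def _profiles_and_partitions(n: int) -> dict[tuple[int, ...], list[Partition]]:
    grouped: dict[tuple[int, ...], list[Partition]] = {}
    for pi in all_partitions(n):
        grouped.setdefault(pi.profile(), []).append(pi)
    return grouped


def _matrix_from_profile_values(
    n: int, values: dict[tuple[int, ...], float], ses: dict[tuple[int, ...], float],
    method: str, reps: int,
) -> TransitionEstimate:
    probs: dict[Partition, float] = {}
    se: dict[Partition, float] = {}
    for prof, pis in _profiles_and_partitions(n).items():
        for pi in pis:
            probs[pi] = values[prof]
            se[pi] = ses.get(prof, 0.0)
    return TransitionEstimate(n=n, probs=probs, se=se, method=method, reps=reps)


def _transition_matrix(
    batch_fn: Callable[[np.ndarray, tuple[int, ...]], np.ndarray],
    sample_batch: Callable[[np.random.Generator, int], np.ndarray],
    outcomes: list[tuple[np.ndarray, float]] | None,
    n: int,
    method: str | tuple[str, int],
    rng: np.random.Generator | None,
) -> TransitionEstimate:
    profiles = _profiles_and_partitions(n)
    if method == "enumerate":
        if outcomes is None:
            raise ValueError("enumeration requested for a model without finite outcomes")
        values, ses = {}, {}
        for prof in profiles:
            v = 0.0
            for vec, p in outcomes:
                v += p * float(batch_fn(vec[None, :], prof)[0])
            values[prof] = v
            ses[prof] = 0.0
        return _matrix_from_profile_values(n, values, ses, "enumerate", 0)
    if isinstance(method, tuple) and method[0] == "monte_carlo":
        reps = int(method[1])
        if rng is None:
            raise ValueError("monte_carlo method requires an rng")
        sums = {prof: 0.0 for prof in profiles}
        sqsums = {prof: 0.0 for prof in profiles}
        done = 0
        while done < reps:
            k = min(reps - done, _batch_size_hint())
            batch = sample_batch(rng, k)
            for prof in profiles:
                vals = batch_fn(batch, prof)
                sums[prof] += float(vals.sum())
                sqsums[prof] += float((vals**2).sum())
            done += k
        values = {prof: sums[prof] / reps for prof in profiles}
        ses = {
            prof: math.sqrt(
                max(sqsums[prof] / reps - values[prof] ** 2, 0.0) / reps
            )
            for prof in profiles
        }
        return _matrix_from_profile_values(n, values, ses, "monte_carlo", reps)
    raise ValueError(f"unknown method {method!r}")


_BATCH_ELEMENTS = 2_000_000


def _batch_size_hint(N: int = 1000) -> int:
    return max(1, _BATCH_ELEMENTS // max(N, 1))


def awf_transition_matrix(
    model: FrequencyModel,
    n: int,
    method: str | tuple[str, int] = "enumerate",
    rng: np.random.Generator | None = None,
) -> TransitionEstimate:
    """Transition-probability map of the AWF coagulation increment on [n]."""
    return _transition_matrix(
        lambda batch, prof: awf_transition_given_eta(batch, prof),
        model.sample_batch,
        model.outcomes(),
        n,
        method,
        rng,
    )


def ac_transition_matrix(
    model: OffspringModel,
    n: int,
    method: str | tuple[str, int] = "enumerate",
    rng: np.random.Generator | None = None,
) -> TransitionEstimate:
    """Transition-probability map of the AC coagulation increment on [n]."""
    return _transition_matrix(
        lambda batch, prof: ac_transition_given_xi(batch, prof, n),
        model.sample_batch,
        model.outcomes(),
        n,
        method,
        rng,
    )


def pair_coalescence_probability(
    model: FrequencyModel | OffspringModel,
    reps: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Estimate of c_N (probability two random children share a parent).

    Returns (estimate, standard_error); the SE is 0 for exactly enumerable
    models.  AWF: E[sum eta_i^2]; AC: E[sum xi_i(xi_i-1)/(Sigma(Sigma-1))].
    """
    exact = model.exact_pair_probability()
    if exact is not None:
        return float(exact), 0.0
    if reps < 1 or rng is None:
        raise ValueError("Monte-Carlo c_N needs reps >= 1 and an rng")
    is_offspring = isinstance(model, OffspringModel)
    vals = np.empty(reps)
    done = 0
    while done < reps:
        k = min(reps - done, _batch_size_hint(model.N))
        batch = model.sample_batch(rng, k)
        if is_offspring:
            b = np.asarray(batch, dtype=float)
            s = b.sum(axis=1)
            vals[done : done + k] = (b * (b - 1)).sum(axis=1) / (s * (s - 1))
        else:
            vals[done : done + k] = (batch**2).sum(axis=1)
        done += k
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(reps))


# ---------------------------------------------------------------------------
# increments and genealogy simulation
# ---------------------------------------------------------------------------


def _partition_from_labels(labels: np.ndarray) -> Partition:
    groups: dict[int, list[int]] = {}
    for child, lab in enumerate(labels, start=1):
        groups.setdefault(int(lab), []).append(child)
    return Partition(len(labels), list(groups.values()))


def awf_increment(eta: np.ndarray, n: int, rng: np.random.Generator) -> Partition:
    """Group n children by their i.i.d. eta-distributed parent choices."""
    eta = _check_probability_vector(eta)
    parents = rng.choice(len(eta), size=n, p=eta / eta.sum())
    return _partition_from_labels(parents)


def ac_increment(xi: np.ndarray, n: int, rng: np.random.Generator) -> Partition:
    """Group n children sampled without replacement from the xi child slots.

    Uses a multivariate-hypergeometric draw over parent labels rather than an
    explicit slot list, so Sigma_N may be large.
    """
    xi = np.asarray(xi, dtype=np.int64)
    if int(xi.sum()) < n:
        raise ValueError(f"total offspring {int(xi.sum())} < sample size {n}")
    counts = rng.multivariate_hypergeometric(xi, n)
    labels = np.repeat(np.arange(len(xi)), counts)
    rng.shuffle(labels)  # exchangeable assignment of children to parents
    return _partition_from_labels(labels)


def generation_rng(root_seed: int, replicate: int, t: int) -> np.random.Generator:
    """Counter-based per-generation stream: reproducible and parallelizable."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(root_seed), spawn_key=(replicate, t))
    )


@dataclass
class GenealogyTrace:
    """Time-indexed ancestral partitions of a sample of size n.

    ``partitions[t] = coagulate(partitions[t-1], increments[t-1])`` where each
    increment is a partition of the current number of blocks; times are in
    generations or rescaled by c_N.
    """

    n: int
    times: list[float] = field(default_factory=list)
    partitions: list[Partition] = field(default_factory=list)
    increments: list[Partition | None] = field(default_factory=list)
    time_scale: str = "generations"
    mrca_reached: bool = False

    def block_counts(self) -> list[int]:
        return [len(p) for p in self.partitions]

    def replay(self) -> list[Partition]:
        """Re-apply the increments from 0_n (consistency check)."""
        out = [self.partitions[0]]
        for inc in self.increments:
            out.append(out[-1] if inc is None else coagulate(out[-1], inc))
        return out

    def to_jsonl(self) -> str:
        lines = []
        for t, pi, inc in zip(self.times, self.partitions, [None] + list(self.increments)):
            lines.append(
                json.dumps(
                    {
                        "time": t,
                        "partition": pi.to_string(),
                        "increment": None if inc is None else inc.to_string(),
                    }
                )
            )
        return "\n".join(lines) + "\n"

    def to_newick(self) -> str:
        return trace_to_newick(self.times, self.partitions)


def trace_to_newick(times: Sequence[float], partitions: Sequence[Partition]) -> str:
    """Render a coalescent trace as a Newick tree with branch lengths.

    Branch lengths are differences of coalescence times in the trace's time
    scale.  If the MRCA was not reached, remaining lineages are joined at the
    final time (a zero-length-root comb), so output is always a single tree.
    """
    n = partitions[0].n
    node: dict[tuple[int, ...], tuple[str, float]] = {
        (i,): (str(i), 0.0) for i in range(1, n + 1)
    }
    for t, pi in zip(times[1:], partitions[1:]):
        for block in pi.blocks:
            if block in node:
                continue
            children = [b for b in node if set(b) <= set(block)]
            if len(children) == 1:
                node[block] = node.pop(children[0])
                continue
            parts = []
            for ch in sorted(children):
                label, h = node.pop(ch)
                parts.append(f"{label}:{t - h:.10g}")
            node[block] = ("(" + ",".join(parts) + ")", t)
    remaining = sorted(node)
    if len(remaining) == 1:
        label, _ = node[remaining[0]]
        return label + ";"
    t_end = times[-1]
    parts = []
    for b in remaining:
        label, h = node[b]
        parts.append(f"{label}:{t_end - h:.10g}")
    return "(" + ",".join(parts) + ");"


def simulate_genealogy(
    model: FrequencyModel | OffspringModel,
    n: int,
    horizon: int | Literal["until_mrca"] = "until_mrca",
    rng: np.random.Generator | None = None,
    *,
    seed: int | None = None,
    replicate: int = 0,
    time_scale: Literal["generations", "rescaled"] = "generations",
    c_N: float | None = None,
    max_generations: int = 10_000_000,
) -> GenealogyTrace:
    """Simulate the discrete-time genealogy of a sample of n individuals.

    Each generation draws a fresh, independent eta / xi (static environment)
    and an increment among the current lineages.  With ``seed`` given, each
    generation uses a counter-based stream so traces are reproducible; with
    ``rng`` given, draws come sequentially from that generator.

    ``time_scale='rescaled'`` divides the generation index by c_N (a plug-in
    estimate must be supplied unless the model has an analytic value).
    """
    if isinstance(horizon, int) and horizon <= 0:
        raise ValueError("horizon must be a positive number of generations")
    if n > model.N:
        raise ValueError(f"sample size n={n} exceeds population size N={model.N}")
    if rng is None and seed is None:
        raise ValueError("provide either rng or seed")
    if time_scale == "rescaled":
        if c_N is None:
            c_N = model.exact_pair_probability()
        if c_N is None:
            raise ValueError("rescaled time needs c_N (no analytic value available)")
    is_offspring = isinstance(model, OffspringModel)
    state = singleton_partition(n)
    trace = GenealogyTrace(
        n=n, times=[0.0], partitions=[state], increments=[], time_scale=time_scale
    )
    t = 0
    limit = horizon if isinstance(horizon, int) else max_generations
    while t < limit and len(state) > 1:
        t += 1
        gen_rng = rng if rng is not None else generation_rng(seed, replicate, t)
        vec = model.sample(gen_rng)
        m = len(state)
        inc = (
            ac_increment(vec, m, gen_rng)
            if is_offspring
            else awf_increment(vec, m, gen_rng)
        )
        state = coagulate(state, inc)
        trace.increments.append(inc)
        trace.partitions.append(state)
        trace.times.append(t * c_N if time_scale == "rescaled" else float(t))
    trace.mrca_reached = len(state) == 1
    return trace


# ---------------------------------------------------------------------------
# sampling with vs. without replacement (AC vs AWF)
# ---------------------------------------------------------------------------


@dataclass
class DiscrepancyReport:
    """Distance between AC and induced-AWF transition maps for one N."""

    N: int
    n: int
    norm: float  # max over 2 <= m <= n of sum_{pi~} |P~ - P| (max abs row sum)
    norm_se: float
    c_N: float
    c_tilde_N: float
    mean_inv_sigma: float
    same_limit_flag: bool  # c_N / E[1/Sigma_N] large => shared limit genealogy

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "n": self.n,
            "norm": self.norm,
            "norm_se": self.norm_se,
            "c_N": self.c_N,
            "c_tilde_N": self.c_tilde_N,
            "mean_inv_sigma": self.mean_inv_sigma,
            "same_limit_flag": self.same_limit_flag,
        }


def ac_awf_discrepancy(
    model: OffspringModel,
    n: int,
    reps: int,
    rng: np.random.Generator,
    flag_threshold: float = 100.0,
) -> DiscrepancyReport:
    """Compare the AC transition map with its induced AWF map (eta = xi/Sigma).

    Both maps are estimated on the *same* offspring draws (common random
    numbers), each conditionally exactly, so the per-draw difference is exact
    given xi.  The norm is the maximum absolute row-sum over partitions of [m]
    for 2 <= m <= n; when Monte-Carlo estimated it is a noisy lower bound of
    the true operator-norm distance.
    """
    per_m_profiles = {m: _profiles_and_partitions(m) for m in range(2, n + 1)}
    # accumulate per-draw signed differences per (m, profile)
    diff_sums = {m: {prof: 0.0 for prof in per_m_profiles[m]} for m in per_m_profiles}
    diff_sqs = {m: {prof: 0.0 for prof in per_m_profiles[m]} for m in per_m_profiles}
    c_vals = np.empty(reps)
    ct_vals = np.empty(reps)
    inv_sigma = np.empty(reps)
    done = 0
    while done < reps:
        k = min(reps - done, _batch_size_hint(model.N))
        xi = np.asarray(model.sample_batch(rng, k), dtype=float)
        sigma = xi.sum(axis=1)
        eta = xi / sigma[:, None]
        inv_sigma[done : done + k] = 1.0 / sigma
        c_vals[done : done + k] = (eta**2).sum(axis=1)
        ct_vals[done : done + k] = (xi * (xi - 1)).sum(axis=1) / (sigma * (sigma - 1))
        for m, profiles in per_m_profiles.items():
            for prof in profiles:
                d = ac_transition_given_xi(xi, prof, m) - awf_transition_given_eta(
                    eta, prof
                )
                diff_sums[m][prof] += float(d.sum())
                diff_sqs[m][prof] += float((d**2).sum())
        done += k
    norm = 0.0
    norm_se = 0.0
    for m, profiles in per_m_profiles.items():
        row = 0.0
        row_se2 = 0.0
        for prof, pis in profiles.items():
            mean = diff_sums[m][prof] / reps
            var = max(diff_sqs[m][prof] / reps - mean**2, 0.0) / reps
            row += abs(mean) * len(pis)
            row_se2 += var * len(pis) ** 2
        if row > norm:
            norm = row
            norm_se = math.sqrt(row_se2)
    c_N = float(c_vals.mean())
    mean_inv = float(inv_sigma.mean())
    return DiscrepancyReport(
        N=model.N,
        n=n,
        norm=norm,
        norm_se=norm_se,
        c_N=c_N,
        c_tilde_N=float(ct_vals.mean()),
        mean_inv_sigma=mean_inv,
        same_limit_flag=bool(c_N / mean_inv > flag_threshold),
    )
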