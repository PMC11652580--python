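"""Concrete population models with known multiple-merger coalescent limits.

* Generalized Eldon–Wakeley: one random individual replaces a fraction Y of
  the population per generation; with Y drawn from the normalized law
  y^{-2} Lambda(dy) above a vanishing cutoff, the genealogy converges to the
  Lambda-coalescent on the timescale c_N ~ E[Y^2].
* Recurrent bottlenecks: with small probability the next generation descends
  from only k individuals; depending on how bottleneck frequency compares to
  the background coalescence rate the limit is the paint-box coalescent of the
  bottleneck law, the background limit, or their superposition.
* Poisson–Dirichlet power frequencies: eta_i ∝ V_i^gamma for a size-biased
  PD(alpha, theta) sequence V; for theta in (-alpha, alpha) the limit is the
  Beta(1-theta/alpha, 1+theta/alpha)-coalescent, for theta >= alpha Kingman's.
* The (N, beta, kappa)-exponential model: branching-selection particles on the
  line whose family-frequency law reduces exactly to PD-power frequencies with
  (alpha, theta, gamma) = (1/beta, 0, kappa/beta); its genealogy is always
  Bolthausen–Sznitman, on the timescale c_N ~ 1 / (ell * sum_{i<=N} i^-kappa).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, special
from scipy.special import logsumexp

from .partitions import MassPartition, Partition, all_partitions, paintbox_partition_probability
from .population import FrequencyModel, OffspringModel, UniformFrequency
from .rates import LambdaMeasure, RateMatrix

__all__ = [
    "EldonWakeleyParams",
    "EldonWakeleyOffspring",
    "EldonWakeleyFrequency",
    "eldon_wakeley_offspring",
    "BottleneckParams",
    "SymmetricBottleneckLaw",
    "NormalizedWeightsBottleneckLaw",
    "BottleneckFrequency",
    "bottleneck_frequencies",
    "bottleneck_limit_rates",
    "PDPowerParams",
    "PDPowerFrequency",
    "pd_stick_breaking",
    "pd_constants",
    "PDConstants",
    "zeta_limit_check",
    "ExpModelParams",
    "exp_model_step",
    "exp_model_frequencies",
    "ExpModelFrequency",
    "exp_model_reduction",
    "exp_model_timescale_constants",
    "MODEL_REGISTRY",
    "make_model",
]


# ---------------------------------------------------------------------------
# Eldon–Wakeley
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EldonWakeleyParams:
    """Sweep-fraction law for the generalized Eldon–Wakeley model.

    The sweep fraction Y is drawn from y^{-2} Lambda(dy) restricted to
    (N^{(epsilon-1)/2}, 1] and normalized; epsilon in (0,1) controls how fast
    the cutoff vanishes.
    """

    Lambda: LambdaMeasure
    epsilon: float
    N: int

    def __post_init__(self):
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.N < 2:
            raise ValueError("N must be >= 2")

    @property
    def cutoff(self) -> float:
        return self.N ** ((self.epsilon - 1.0) / 2.0)


class _TruncatedYSampler:
    """Sampler and moment oracle for Y ~ y^{-2} Lambda(dy) on (cutoff, 1]."""

    def __init__(self, Lambda: LambdaMeasure, cutoff: float, grid_size: int = 4096):
        self.Lambda = Lambda
        self.cutoff = cutoff
        if Lambda.kind == "point_mass":
            if Lambda.p <= cutoff:
                raise ValueError(
                    f"Lambda has zero mass above the cutoff {cutoff:.3g}"
                )
            self._point = Lambda.p
            return
        self._point = None
        lo = max(cutoff, Lambda.cutoff if Lambda.kind == "truncated_density" else 0.0)
        if lo >= 1.0:
            raise ValueError("cutoff >= 1: empty support")
        # inverse-CDF on a log-spaced grid; density ∝ y^{-2} * lambda(y)
        grid = np.exp(np.linspace(math.log(lo + 1e-300), 0.0, grid_size))
        grid[0], grid[-1] = lo, 1.0
        dens = grid**-2.0 * self._lambda_density(grid)
        cdf = np.concatenate(
            [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))]
        )
        if cdf[-1] <= 0:
            raise ValueError("Lambda has zero mass above the cutoff")
        self._grid = grid
        self._cdf = cdf / cdf[-1]

    def _lambda_density(self, y: np.ndarray) -> np.ndarray:
        L = self.Lambda
        if L.kind == "beta":
            return L.total_mass * np.exp(
                (L.a - 1) * np.log(y) + (L.b - 1) * np.log1p(-np.minimum(y, 1 - 1e-16))
                - special.betaln(L.a, L.b)
            )
        assert L.density is not None
        return np.vectorize(L.density)(y)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self._point is not None:
            return np.full(size, self._point)
        u = rng.random(size)
        return np.interp(u, self._cdf, self._grid)

    def moment(self, b: int) -> float:
        """E[Y^b] by quadrature (exact for point masses)."""
        if self._point is not None:
            return self._point**b
        num, _ = integrate.quad(
            lambda y: y ** (b - 2) * float(self._lambda_density(np.array([y]))[0]),
            self.cutoff, 1.0, epsabs=1e-12, limit=200,
        )
        den, _ = integrate.quad(
            lambda y: y**-2 * float(self._lambda_density(np.array([y]))[0]),
            self.cutoff, 1.0, epsabs=1e-12, limit=200,
        )
        return num / den


def eldon_wakeley_offspring(
    params: EldonWakeleyParams, rng: np.random.Generator
) -> np.ndarray:
    """One offspring vector: xi_K = floor(Y N), N - floor(Y N) scattered ones.

    floor(Y N) <= 1 degenerates to the all-ones vector (every individual has
    exactly one child: the all-singletons generation); floor(Y N) = N is a
    deterministic full merge.  The total is always Sigma = N.
    """
    N = params.N
    sampler = _TruncatedYSampler(params.Lambda, params.cutoff)
    y = float(sampler.sample(rng, 1)[0])
    m = max(int(math.floor(y * N)), 1)
    xi = np.zeros(N, dtype=np.int64)
    k = int(rng.integers(N))
    xi[k] = m
    others = np.delete(np.arange(N), k)
    ones = rng.choice(others, size=N - m, replace=False)
    xi[ones] = 1
    return xi


class EldonWakeleyOffspring(OffspringModel):
    """Offspring-vector model; Sigma_N = N every generation."""

    def __init__(self, params: EldonWakeleyParams):
        self.params = params
        self.N = params.N
        self._sampler = _TruncatedYSampler(params.Lambda, params.cutoff)

    def sample(self, rng):
        return eldon_wakeley_offspring(self.params, rng)

    def sample_batch(self, rng, size):
        # the coagulation law only depends on the multiset of offspring sizes,
        # so the sweeping parent is placed at index 0 (WLOG by non-heritability)
        N = self.N
        m = np.maximum(np.floor(self._sampler.sample(rng, size) * N).astype(np.int64), 1)
        cols = np.arange(N)[None, :]
        xi = ((cols >= 1) & (cols <= (N - m)[:, None])).astype(np.int64)
        xi[:, 0] = m
        return xi

    def y_moment(self, b: int) -> float:
        """Oracle E[Y^b] of the truncated sweep-fraction law (quadrature)."""
        return self._sampler.moment(b)

    def sample_sweep_fractions(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draws of the sweep fraction Y (for moment-ratio diagnostics)."""
        return self._sampler.sample(rng, size)

    def exact_pair_probability(self):
        if self.params.Lambda.kind == "point_mass":
            m = max(int(math.floor(self.params.Lambda.p * self.N)), 1)
            return m * (m - 1) / (self.N * (self.N - 1))
        return None


class EldonWakeleyFrequency(FrequencyModel):
    """AWF version: eta = xi / N with the sweeping parent at index 1."""

    def __init__(self, params: EldonWakeleyParams):
        self.params = params
        self.N = params.N
        self._offspring = EldonWakeleyOffspring(params)

    def sample(self, rng):
        return self.sample_batch(rng, 1)[0]

    def sample_batch(self, rng, size):
        return self._offspring.sample_batch(rng, size) / self.N


# ---------------------------------------------------------------------------
# recurrent bottlenecks
# ---------------------------------------------------------------------------


class SymmetricBottleneckLaw:
    """nu_bar_k = point mass at (1/k, ..., 1/k): Wright–Fisher bottleneck."""

    def sample(self, k: int, rng: np.random.Generator) -> np.ndarray:
        return np.full(k, 1.0 / k)

    def mass_partition_atoms(
        self, k: int, rng: np.random.Generator | None = None, mc_atoms: int = 0
    ) -> list[tuple[MassPartition, float]]:
        return [(MassPartition([1.0 / k] * k), 1.0)]

    def pair_merge_probability(self, k: int) -> float:
        return 1.0 / k


class NormalizedWeightsBottleneckLaw:
    """nu_bar_k = (W_1/S_k, ..., W_k/S_k) for i.i.d. finite-variance weights
    (Dirichlet-type bottleneck; exponential weights give Dirichlet(1,...,1))."""

    def __init__(self, weight_sampler: Callable[[int, np.random.Generator], np.ndarray] | None = None):
        self._w = weight_sampler or (lambda k, rng: rng.exponential(size=k))

    def sample(self, k: int, rng: np.random.Generator) -> np.ndarray:
        w = np.asarray(self._w(k, rng), dtype=float)
        return w / w.sum()

    def mass_partition_atoms(
        self, k: int, rng: np.random.Generator | None = None, mc_atoms: int = 256
    ) -> list[tuple[MassPartition, float]]:
        if rng is None:
            raise ValueError("Monte-Carlo atoms need an rng")
        atoms = []
        for _ in range(mc_atoms):
            v = np.sort(self.sample(k, rng))[::-1]
            atoms.append((MassPartition(v, 0.0), 1.0 / mc_atoms))
        return atoms

    def pair_merge_probability(self, k: int, rng: np.random.Generator | None = None,
                               reps: int = 4096) -> float:
        if rng is None:
            rng = np.random.default_rng(0)
        return float(
            np.mean([np.sum(self.sample(k, rng) ** 2) for _ in range(reps)])
        )


@dataclass
class BottleneckParams:
    """Wright–Fisher-type population with rare one-generation collapses.

    With probability sum_{k<=b_N} F(k) / a_N the next generation descends from
    k ~ F|[b_N] individuals with conditional frequency law nu_bar_k; otherwise
    frequencies come from ``hat_factory(N)``.  a_N and b_N are diverging
    sequences with sum_{k<=b_N} F(k) = o(a_N) and b_N = o(N).
    """

    F: dict[int, float]
    a_N: Callable[[int], float]
    b_N: Callable[[int], int]
    nu_bar: SymmetricBottleneckLaw | NormalizedWeightsBottleneckLaw
    hat_factory: Callable[[int], FrequencyModel] = UniformFrequency

    def bottleneck_probability(self, N: int) -> float:
        bn = self.b_N(N)
        p = sum(w for k, w in self.F.items() if k <= bn) / self.a_N(N)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"bottleneck probability {p} outside [0, 1] at N={N}")
        return p

    def conditional_size_law(self, N: int) -> tuple[np.ndarray, np.ndarray]:
        bn = self.b_N(N)
        ks = np.array([k for k in sorted(self.F) if k <= bn])
        ws = np.array([self.F[k] for k in ks], dtype=float)
        if ws.sum() <= 0:
            return ks, ws
        return ks, ws / ws.sum()


def bottleneck_frequencies(
    params: BottleneckParams, N: int, rng: np.random.Generator
) -> np.ndarray:
    """One draw of the frequency vector eta^(N) of the bottleneck model."""
    p = params.bottleneck_probability(N)
    if p > 0 and rng.random() < p:
        ks, ws = params.conditional_size_law(N)
        k = int(rng.choice(ks, p=ws))
        eta = np.zeros(N)
        eta[:k] = params.nu_bar.sample(k, rng)
        # bottleneck survivors are exchangeable; scatter them
        rng.shuffle(eta)
        return eta
    return params.hat_factory(N).sample(rng)


class BottleneckFrequency(FrequencyModel):
    def __init__(self, params: BottleneckParams, N: int):
        self.params = params
        self.N = N
        self._hat = params.hat_factory(N)

    def sample(self, rng):
        return bottleneck_frequencies(self.params, self.N, rng)

    def sample_batch(self, rng, size):
        p = self.params.bottleneck_probability(self.N)
        out = self._hat.sample_batch(rng, size)
        hits = np.nonzero(rng.random(size) < p)[0]
        ks, ws = self.params.conditional_size_law(self.N)
        for i in hits:
            k = int(rng.choice(ks, p=ws))
            row = np.zeros(self.N)
            row[:k] = self.params.nu_bar.sample(k, rng)
            out[i] = row  # power sums are permutation-invariant; no shuffle
        return out


def bottleneck_limit_rates(
    params: BottleneckParams,
    n: int,
    rng: np.random.Generator | None = None,
    mc_atoms: int = 256,
    N_grid: Sequence[int] = (10_000, 40_000, 160_000),
    truncation: int | None = None,
) -> tuple[RateMatrix, dict]:
    """Limit coagulation matrix Q_bar and the time-scale regime report.

    Q_bar(pi~) = sum_k F(k) * E_{nu_bar_k}[ P(paint-box(rho) = pi~) ].  F must
    be finitely supported or truncated (the report carries the neglected tail
    mass, an upper bound on the missing pair-merge rate).  The regime is
    classified from the trend of hat_c_N * a_N over the N grid:
    -> 0: bottleneck mergers dominate (rate matrix Q_bar, time unit a_N);
    -> inf: background dominates; -> ell in (0, inf): superposition
    Q_bar + ell * Q_hat.
    """
    ks = sorted(params.F)
    tail_mass = 0.0
    if truncation is not None:
        tail_mass = sum(params.F[k] for k in ks if k > truncation)
        ks = [k for k in ks if k <= truncation]
    rates: dict[Partition, float] = {}
    for pi in all_partitions(n):
        if pi.is_singletons():
            continue
        r = 0.0
        for k in ks:
            atoms = params.nu_bar.mass_partition_atoms(k, rng=rng, mc_atoms=mc_atoms)
            r += params.F[k] * math.fsum(
                w * paintbox_partition_probability(rho, pi) for rho, w in atoms
            )
        if r > 0:
            rates[pi] = r
    products = []
    for N in N_grid:
        hat = params.hat_factory(N)
        c_hat = hat.exact_pair_probability()
        if c_hat is None:
            raise ValueError("regime classification needs an enumerable hat model")
        products.append(c_hat * params.a_N(N))
    if products[-1] < 0.5 * products[0] or products[-1] < 1e-3:
        regime = "bottleneck-dominated"
    elif products[-1] > 2.0 * products[0] or products[-1] > 1e3:
        regime = "background-dominated"
    else:
        regime = "superposition"
    report = {
        "regime": regime,
        "c_hat_times_a_N": dict(zip(N_grid, products)),
        "ell_estimate": products[-1],
        "neglected_tail_mass": tail_mass,
    }
    return RateMatrix(n=n, rates=rates), report


# ---------------------------------------------------------------------------
# Poisson–Dirichlet power frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PDPowerParams:
    """eta_i ∝ V_i^gamma for a size-biased PD(alpha, theta) sequence V."""

    alpha: float
    theta: float
    gamma: float
    N: int

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.theta <= -self.alpha:
            raise ValueError("theta must exceed -alpha")
        if self.gamma != 0.0 and not (self.alpha / 2 < self.gamma <= self.alpha):
            warnings.warn(
                "gamma outside (alpha/2, alpha]: the Beta-coalescent timescale "
                "asymptotics are not guaranteed in this regime",
                stacklevel=2,
            )


def pd_stick_breaking(
    alpha: float, theta: float, N: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Size-biased PD(alpha, theta) prefix by stick breaking.

    Y_i ~ Beta(1-alpha, theta+i*alpha) independent; V_1 = Y_1 and
    V_i = Y_i * prod_{j<i}(1-Y_j).  Returns (V, Y).
    """
    if not (0.0 < alpha < 1.0) or theta <= -alpha:
        raise ValueError("need 0 < alpha < 1 and theta > -alpha")
    i = np.arange(1, N + 1)
    Y = rng.beta(1.0 - alpha, theta + alpha * i)
    sticks = np.cumprod(1.0 - Y)
    V = Y * np.concatenate([[1.0], sticks[:-1]])
    return V, Y


class PDPowerFrequency(FrequencyModel):
    """Family frequencies eta_i = V_i^gamma / sum_j V_j^gamma."""

    def __init__(self, params: PDPowerParams):
        self.params = params
        self.N = params.N

    def sample(self, rng):
        return self.sample_batch(rng, 1)[0]

    def sample_batch(self, rng, size):
        p = self.params
        if p.gamma == 0.0:
            return np.full((size, self.N), 1.0 / self.N)
        i = np.arange(1, self.N + 1)
        Y = rng.beta(1.0 - p.alpha, p.theta + p.alpha * i, size=(size, self.N))
        sticks = np.cumprod(1.0 - Y, axis=1)
        V = Y * np.concatenate([np.ones((size, 1)), sticks[:, :-1]], axis=1)
        W = V**p.gamma
        return W / W.sum(axis=1, keepdims=True)

    def limit_measure(self) -> LambdaMeasure:
        """The limiting Lambda for theta in (-alpha, alpha)."""
        p = self.params
        if not -p.alpha < p.theta < p.alpha:
            raise ValueError("Beta-coalescent limit requires theta in (-alpha, alpha)")
        return LambdaMeasure.beta(1.0 - p.theta / p.alpha, 1.0 + p.theta / p.alpha)


@dataclass
class PDConstants:
    """Asymptotic timescale constants of the PD-power model."""

    alpha: float
    theta: float
    gamma: float
    N: int
    u_N: float            # sum_{i<=N} i^(-gamma/alpha)
    mu_N: float           # centering of the log-stick martingale
    upsilon: float        # Upsilon_{theta/alpha} = -psi(theta/alpha + 1)
    K_alpha_theta: float  # exp{psi(theta+1) - Upsilon_{theta/alpha}/alpha}
    ell: float            # timescale constant of the Beta-coalescent limit
    L_N: float            # ell * u_N^(1 + theta/alpha)
    c_N_predicted: float | None  # (1 - theta/alpha)/L_N for theta in (-alpha, alpha)

    def to_dict(self) -> dict:
        return {
            "u_N": self.u_N, "mu_N": self.mu_N, "K": self.K_alpha_theta,
            "ell": self.ell, "L_N": self.L_N, "c_N_predicted": self.c_N_predicted,
        }


def upsilon_constant(a: float) -> float:
    """Upsilon_a = lim_N [sum_{i<=N} (a+i)^{-1} - log N] = -psi(a+1)."""
    return -float(special.digamma(a + 1.0))


def stick_breaking_K(alpha: float, theta: float) -> float:
    """The constant K with e^{mu_N} ~ K N^{(1-alpha)/alpha} / alpha.

    The centering mu_N = -sum E[log(1-Y_i)] of the log-stick martingale
    satisfies mu_N = psi(theta+1) - log N - log alpha + log(N)/alpha
    + Upsilon_{theta/alpha}/alpha + o(1), hence
    K = exp{psi(theta+1) + Upsilon_{theta/alpha}/alpha}.  (Note the plus sign:
    it is forced by Upsilon_a = lim[sum_{i<=N}(a+i)^{-1} - log N] and is
    verified numerically against the digamma partial sums in the test suite.)
    """
    return math.exp(
        float(special.digamma(theta + 1.0)) + upsilon_constant(theta / alpha) / alpha
    )


def pd_timescale_ell(alpha: float, theta: float, gamma: float) -> float:
    """The constant ell_{alpha,theta,gamma} of the Beta-coalescent timescale."""
    g_over_a = gamma / alpha
    inv = (
        (alpha / gamma)
        * math.gamma(1.0 - alpha) ** (theta / alpha)
        / math.gamma(1.0 + gamma - alpha) ** (1.0 + theta / alpha)
        * math.gamma((alpha + theta) / alpha * (1.0 - g_over_a) + 1.0)
        / math.gamma((alpha + theta) * (1.0 - g_over_a) + 1.0)
        * math.gamma(1.0 + theta)
        * math.gamma(1.0 - theta / alpha)
        / math.exp(special.betaln(1.0 - theta / alpha, 1.0 + theta / alpha))
    )
    return 1.0 / inv


def pd_constants(alpha: float, theta: float, gamma: float, N: int) -> PDConstants:
    """All timescale constants at a given N (see PDConstants fields).

    Emits a warning outside the regime alpha/2 < gamma <= alpha in which the
    u_N-asymptotics hold.
    """
    if not (0.0 < alpha < 1.0) or theta <= -alpha:
        raise ValueError("need 0 < alpha < 1 and theta > -alpha")
    if not (alpha / 2 < gamma <= alpha):
        warnings.warn("gamma outside (alpha/2, alpha]: asymptotics unreliable", stacklevel=2)
    i = np.arange(1, N + 1)
    u_N = float(np.sum(i ** (-gamma / alpha)))
    mu_N = float(
        np.sum(special.digamma(theta + (i - 1) * alpha + 1.0)
               - special.digamma(theta + i * alpha))
    )
    ups = upsilon_constant(theta / alpha)
    K = stick_breaking_K(alpha, theta)
    ell = pd_timescale_ell(alpha, theta, gamma)
    L_N = ell * u_N ** (1.0 + theta / alpha)
    c_pred = (1.0 - theta / alpha) / L_N if -alpha < theta < alpha else None
    return PDConstants(alpha, theta, gamma, N, u_N, mu_N, ups, K, ell, L_N, c_pred)


def zeta_limit_check(
    alpha: float,
    theta: float,
    gamma: float,
    N_grid: Sequence[int],
    rng: np.random.Generator,
    paths: int = 5,
) -> dict:
    """Pathwise check of zeta_{N,gamma} ~ u_N e^{gamma S_N} * constant.

    On each stick-breaking path computes r_N = zeta_{N,gamma}/(u_N e^{gamma S_N})
    with S_N = mu_N + sum log(1 - Y_i), and compares r at the largest N to the
    almost-sure limit Gamma(1+gamma-alpha)/Gamma(1-alpha) * K^{-gamma}.
    """
    if not (alpha / 2 < gamma <= alpha):
        raise ValueError("pathwise zeta asymptotics need alpha/2 < gamma <= alpha")
    N_grid = sorted(int(N) for N in N_grid)
    N_max = N_grid[-1]
    i = np.arange(1, N_max + 1)
    mu_cum = np.cumsum(
        special.digamma(theta + (i - 1) * alpha + 1.0)
        - special.digamma(theta + i * alpha)
    )
    u_cum = np.cumsum(i ** (-gamma / alpha))
    K = stick_breaking_K(alpha, theta)
    target = math.gamma(1.0 + gamma - alpha) / math.gamma(1.0 - alpha) * K**-gamma
    idx = np.array(N_grid) - 1
    ratios = np.empty((paths, len(N_grid)))
    for p in range(paths):
        V, Y = pd_stick_breaking(alpha, theta, N_max, rng)
        zeta = np.cumsum(V**gamma)
        S = mu_cum + np.cumsum(np.log1p(-Y))
        r = zeta / (u_cum * np.exp(gamma * S))
        ratios[p] = r[idx]
    rel_dev = np.abs(ratios[:, -1] / target - 1.0)
    return {
        "target": target,
        "N_grid": list(N_grid),
        "ratios": ratios.tolist(),
        "relative_deviation_at_N_max": rel_dev.tolist(),
        "max_relative_deviation": float(rel_dev.max()),
    }


# ---------------------------------------------------------------------------
# the (N, beta, kappa)-exponential model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpModelParams:
    """Branching-selection particle system on the line.

    A parent at position x spawns a Poisson point process of children with
    intensity e^{-(s - kappa x)} ds; N children survive selection, sampled
    without replacement with weights proportional to e^{beta x}.  beta > 1 is
    required for the selection weights to be summable.
    """

    N: int
    beta: float
    kappa: float
    K_atoms: int | None = None

    def __post_init__(self):
        if self.beta <= 1.0:
            raise ValueError("beta must exceed 1 (summable selection weights)")
        if self.kappa <= 0.0:
            raise ValueError("kappa must be positive")

    def resolved_K(self) -> int:
        """PPP truncation: enough atoms that the typical tail weight share
        e^{beta z_K}/sum ~ K^{-beta} stays around 3e-8, leaving a wide margin
        below the 1e-6 abort threshold (the share scales with the top atom's
        exponential gap, whose tail is e^{-t})."""
        if self.K_atoms is not None:
            if self.K_atoms < self.N:
                raise ValueError("K_atoms must be at least N")
            return self.K_atoms
        return int(
            min(
                max(4 * self.N, self.N + math.ceil(50 * self.beta),
                    math.ceil(10 ** (7.5 / self.beta))),
                5_000_000,
            )
        )


def _ppp_atoms(K: int, rng: np.random.Generator) -> np.ndarray:
    """Decreasing atoms z_i = -log(E_1 + ... + E_i) of a unit-intensity PPP."""
    return -np.log(np.cumsum(rng.exponential(size=K)))


def exp_model_step(
    params: ExpModelParams, positions: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One generation of the exponential model.

    Returns (new_positions, parents): the N selected children's positions
    X_eq + Z_i, and each child's parent index (chosen independently with
    probability proportional to e^{kappa X_i}).  All position arithmetic is in
    log space (log-sum-exp, Gumbel-top-N selection) to avoid overflow.
    """
    positions = np.asarray(positions, dtype=float)
    K = params.resolved_K()
    x_eq = float(logsumexp(params.kappa * positions))
    z = _ppp_atoms(K, rng)
    log_w = params.beta * z
    tail_share = math.exp(log_w[-1] - logsumexp(log_w))
    if tail_share > 1e-6:
        raise RuntimeError(
            f"PPP truncation too aggressive: last-atom selection-weight share "
            f"{tail_share:.2e} > 1e-6; increase K_atoms (currently {K})"
        )
    keys = log_w + rng.gumbel(size=K)
    selected = np.argpartition(keys, -params.N)[-params.N :]
    Z = z[selected]
    new_positions = x_eq + Z
    parent_logits = params.kappa * positions
    parent_probs = np.exp(parent_logits - logsumexp(parent_logits))
    parents = rng.choice(params.N, size=params.N, p=parent_probs)
    return new_positions, parents


def exp_model_frequencies(kappa: float, positions: np.ndarray) -> np.ndarray:
    """Family frequencies e^{kappa X_i} / sum_j e^{kappa X_j} of a generation."""
    logits = kappa * np.asarray(positions, dtype=float)
    return np.exp(logits - logsumexp(logits))


class ExpModelFrequency(FrequencyModel):
    """Frequency model of the exponential model, sampled from the explicit
    particle construction (one branching-selection step per draw).

    The frequency vectors of successive generations are i.i.d. — they depend
    only on the selected PPP atoms, not on the previous positions — so drawing
    a fresh step per sample matches the genealogy's one-generation law.
    """

    def __init__(self, params: ExpModelParams):
        self.params = params
        self.N = params.N

    def sample(self, rng):
        positions, _ = exp_model_step(self.params, np.zeros(self.N), rng)
        return exp_model_frequencies(self.params.kappa, positions)


def exp_model_reduction(params: ExpModelParams) -> PDPowerFrequency:
    """Exact-in-distribution shortcut: PD-power frequencies with
    (alpha, theta, gamma) = (1/beta, 0, kappa/beta)."""
    return PDPowerFrequency(
        PDPowerParams(
            alpha=1.0 / params.beta, theta=0.0, gamma=params.kappa / params.beta,
            N=params.N,
        )
    )


def exp_model_timescale_constants(beta: float, kappa: float) -> dict[str, float]:
    """Two candidate values of lim c_N * sum_{i<=N} i^{-kappa}.

    ``direct`` substitutes (alpha, theta, gamma) = (1/beta, 0, kappa/beta) into
    the PD-power timescale prediction c_N ~ 1/(ell u_N), giving
    lim c_N u_N = 1/ell = Gamma(2-kappa) /
    (kappa Gamma(1-(1-kappa)/beta) Gamma(1+(1-kappa)/beta)); ``printed`` is the
    variant with Gamma(1+(1+kappa)/beta) in the denominator.  The two coincide
    at kappa = 1; a Monte-Carlo estimate of c_N u_N adjudicates elsewhere.
    """
    direct = 1.0 / pd_timescale_ell(1.0 / beta, 0.0, kappa / beta)
    printed = math.gamma(2.0 - kappa) / (
        kappa
        * math.gamma(1.0 - (1.0 - kappa) / beta)
        * math.gamma(1.0 + (1.0 + kappa) / beta)
    )
    return {"direct": direct, "printed": printed}


# ---------------------------------------------------------------------------
# registry for the CLI / config layer
# ---------------------------------------------------------------------------


def _make_wright_fisher(N: int, **kw) -> FrequencyModel:
    return UniformFrequency(N)


def _make_eldon_wakeley(N: int, *, a: float = 1.0, b: float = 1.0,
                        epsilon: float = 0.5, point: float | None = None,
                        representation: str = "offspring", **kw):
    Lambda = (
        LambdaMeasure.point_mass(point) if point is not None else LambdaMeasure.beta(a, b)
    )
    params = EldonWakeleyParams(Lambda=Lambda, epsilon=epsilon, N=N)
    if representation == "frequency":
        return EldonWakeleyFrequency(params)
    return EldonWakeleyOffspring(params)


def _make_bottleneck(N: int, *, law: str, F: dict | None = None,
                     a_exponent: float = 0.5, **kw) -> FrequencyModel:
    F = {int(k): float(v) for k, v in (F or {2: 1.0}).items()}
    nu = SymmetricBottleneckLaw() if law == "symmetric" else NormalizedWeightsBottleneckLaw()
    params = BottleneckParams(
        F=F,
        a_N=lambda n: float(n) ** a_exponent,
        b_N=lambda n: max(int(round(n ** 0.25)), max(F)),
        nu_bar=nu,
    )
    return BottleneckFrequency(params, N)


def _make_pd_power(N: int, *, alpha: float, theta: float = 0.0,
                   gamma: float | None = None, **kw) -> FrequencyModel:
    return PDPowerFrequency(
        PDPowerParams(alpha=alpha, theta=theta,
                      gamma=alpha if gamma is None else gamma, N=N)
    )


def _make_exp_model(N: int, *, beta: float, kappa: float,
                    K_atoms: int | None = None, reduced: bool = True, **kw):
    params = ExpModelParams(N=N, beta=beta, kappa=kappa, K_atoms=K_atoms)
    return exp_model_reduction(params) if reduced else ExpModelFrequency(params)


MODEL_REGISTRY: dict[str, Callable[..., FrequencyModel | OffspringModel]] = {
    "wright-fisher": _make_wright_fisher,
    "eldon-wakeley": _make_eldon_wakeley,
    "bottleneck-symmetric": lambda N, **kw: _make_bottleneck(N, law="symmetric", **kw),
    "bottleneck-dirichlet": lambda N, **kw: _make_bottleneck(N, law="dirichlet", **kw),
    "pd-power": _make_pd_power,
    "exp-model": _make_exp_model,
}


def make_model(key: str, N: int, **params) -> FrequencyModel | OffspringModel:
    if key not in MODEL_REGISTRY:
        raise KeyError(
            f"unknown model key {key!r}; available: {sorted(MODEL_REGISTRY)}"
        )
    return MODEL_REGISTRY[key](N, **params)
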