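"""Convergence diagnostics for AWF genealogies.

These estimators probe, at finite N, the moment conditions under which the
rescaled genealogy of an asymmetric Wright-Fisher population converges to a
multiple-merger coalescent:

* ``phi_estimate`` — the normalized size-biased moment functionals
  phi_j(b_1,...,b_j) = lim E[prod s_i^{b_i-1} prod (1-S_i)] / c_N whose
  existence for all b_i >= 2 characterizes a Xi-coalescent limit;
* ``lambda_criterion`` — checks E[eta_i^b]/c_N against the collision-rate
  ratios lambda_{b,b}/lambda_{2,2} of a target Lambda-coalescent;
* ``kingman_criterion`` — checks that third-moment and single-frequency tail
  ratios vanish along an N-grid (Kingman domain of attraction);
* ``eq4_harness`` — the direct empirical check that the one-generation
  transition probabilities satisfy P(pi~) = c_N Q(pi~) + o(c_N).

Finite-N estimates can only certify *consistency* with a limit statement,
never existence of the limit; reports carry standard errors and trend slopes
rather than verdicts.

All ratios use common random numbers: c_N is estimated on the same frequency
draws as the numerator, and the size-biased moments are Rao-Blackwellized by
evaluating their conditional expectation given eta exactly (distinct-index
power sums), which in particular forces phi(2) = 1 identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .partitions import Partition
from .population import (
    FrequencyModel,
    _batch_size_hint,
    _profiles_and_partitions,
    awf_transition_given_eta,
)
from .rates import LambdaMeasure, RateMatrix, lambda_rate

__all__ = [
    "SizeBiasedSequence",
    "PhiEstimate",
    "size_biased_reorder",
    "phi_estimate",
    "lambda_criterion",
    "kingman_criterion",
    "eq4_harness",
    "CriterionReport",
]


@dataclass
class SizeBiasedSequence:
    """A size-biased reordering of the non-zero entries of a frequency vector.

    values[j] = 0 for j >= K where K counts the non-zero source entries;
    partial sums S_i are non-decreasing and bounded by 1.
    """

    values: np.ndarray
    K: int

    @property
    def partial_sums(self) -> np.ndarray:
        return np.cumsum(self.values)


def size_biased_reorder(eta: np.ndarray, rng: np.random.Generator) -> SizeBiasedSequence:
    """Sequential draws without replacement with P(next = eta_i) ∝ eta_i.

    Implemented by the exponential-race equivalence: sorting the non-zero
    entries by E_i / eta_i (E_i i.i.d. standard exponentials) in increasing
    order realizes successive size-biased sampling.
    """
    eta = np.asarray(eta, dtype=float)
    nz = eta[eta > 0]
    keys = rng.exponential(size=nz.shape) / nz
    ordered = nz[np.argsort(keys)]
    out = np.zeros_like(eta)
    out[: len(ordered)] = ordered
    return SizeBiasedSequence(values=out, K=len(ordered))


@dataclass
class PhiEstimate:
    """Monte-Carlo estimate of phi_j(b_1, ..., b_j)."""

    block_sizes: tuple[int, ...]
    value: float
    std_error: float
    c_N_used: float
    reps: int

    def to_dict(self) -> dict:
        return {
            "block_sizes": list(self.block_sizes),
            "value": self.value,
            "std_error": self.std_error,
            "c_N_used": self.c_N_used,
            "reps": self.reps,
        }


def _ratio_and_se(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Delta-method SE of mean(x)/mean(y) with common random numbers."""
    n = len(x)
    mx, my = float(x.mean()), float(y.mean())
    r = mx / my
    vx = float(x.var(ddof=1)) if n > 1 else 0.0
    vy = float(y.var(ddof=1)) if n > 1 else 0.0
    cxy = float(np.cov(x, y, ddof=1)[0, 1]) if n > 1 else 0.0
    var_r = (vx - 2 * r * cxy + r * r * vy) / (n * my * my) if n > 1 else 0.0
    return r, math.sqrt(max(var_r, 0.0)), my


def _batched_draws(
    model: FrequencyModel,
    reps: int,
    rng: np.random.Generator,
    stats: Callable[[np.ndarray], dict[str, np.ndarray]],
) -> dict[str, np.ndarray]:
    """Accumulate per-draw statistics of eta over batches of reps draws."""
    acc: dict[str, list[np.ndarray]] = {}
    done = 0
    while done < reps:
        k = min(reps - done, _batch_size_hint(model.N))
        batch = np.asarray(model.sample_batch(rng, k), dtype=float)
        for name, vals in stats(batch).items():
            acc.setdefault(name, []).append(vals)
        done += k
    return {name: np.concatenate(chunks) for name, chunks in acc.items()}


def phi_estimate(
    model: FrequencyModel,
    block_sizes: Sequence[int],
    reps: int,
    rng: np.random.Generator,
) -> PhiEstimate:
    """Estimate phi(b_1,...,b_j) = E[prod s_i^{b_i-1} prod_{i<j}(1-S_i)] / c_N.

    The inner expectation over the size-biased reordering is computed exactly
    per eta draw (it equals the distinct-index sum of prod eta^{b_i}); c_N is
    estimated on the same draws, so the ratio SE comes from the delta method.
    Block sizes b_i >= 1 are accepted (b=1 terms arise in the recursion
    phi(b_1,...,b_j,1) + sum_k phi(..., b_k+1, ...) = phi(b_1,...,b_j)).
    """
    sizes = tuple(int(b) for b in block_sizes)
    if any(b < 1 for b in sizes):
        raise ValueError("block sizes must be >= 1")
    if reps < 100:
        raise ValueError("reps < 100 gives meaningless standard errors")
    data = _batched_draws(
        model,
        reps,
        rng,
        lambda batch: {
            "num": awf_transition_given_eta(batch, sizes),
            "c": (batch**2).sum(axis=1),
        },
    )
    value, se, c_hat = _ratio_and_se(data["num"], data["c"])
    return PhiEstimate(
        block_sizes=sizes, value=value, std_error=se, c_N_used=c_hat, reps=reps
    )


@dataclass
class CriterionReport:
    """Tabular diagnostic report (serializes to TSV and JSON)."""

    name: str
    rows: list[dict] = field(default_factory=list)
    passed: bool | None = None
    notes: str = ""

    def add(self, **kwargs) -> None:
        self.rows.append(kwargs)

    def to_tsv(self) -> str:
        if not self.rows:
            return ""
        cols = list(self.rows[0].keys())
        lines = ["\t".join(cols)]
        for row in self.rows:
            lines.append("\t".join(_fmt(row.get(c)) for c in cols))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "passed": self.passed, "notes": self.notes, "rows": self.rows},
            indent=2,
            default=float,
        )


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.8g}"
    return str(v)


def _loglog_slope(x: Sequence[float], y: Sequence[float]) -> float:
    lx, ly = np.log(np.asarray(x, float)), np.log(np.asarray(y, float))
    return float(np.polyfit(lx, ly, 1)[0])


def _zscore(estimate: float, target: float, se: float) -> float:
    # SEs at floating-noise level mean the model is deterministic: compare exactly
    if se > 1e-12:
        return (estimate - target) / se
    return 0.0 if math.isclose(estimate, target, rel_tol=1e-9, abs_tol=1e-9) else math.inf


def lambda_criterion(
    model: FrequencyModel,
    Lambda: LambdaMeasure,
    b_max: int,
    reps: int,
    rng: np.random.Generator,
    index: int = 1,
    model_factory: Callable[[int], FrequencyModel] | None = None,
    N_grid: Sequence[int] | None = None,
) -> CriterionReport:
    """Check E[(eta_i)^b]/c_N against lambda_{b,b}/lambda_{2,2} for b <= b_max.

    The sufficient condition for a Lambda-coalescent limit is that a single
    designated frequency (default index 1 — it need not be the largest entry)
    carries all surviving coagulations.  Optionally also checks the residual
    condition E[sum_{k != i} eta_k^2] = o(c_N) as a monotone trend across an
    N-grid (requires ``model_factory``).
    """
    if b_max < 2:
        raise ValueError("b_max must be >= 2")
    idx = index - 1
    exps = list(range(2, b_max + 1))
    data = _batched_draws(
        model,
        reps,
        rng,
        lambda batch: {
            **{f"m{b}": batch[:, idx] ** b for b in exps},
            "c": (batch**2).sum(axis=1),
            "resid": (batch**2).sum(axis=1) - batch[:, idx] ** 2,
        },
    )
    lam22 = lambda_rate(2, 2, Lambda)
    report = CriterionReport(name="lambda_criterion")
    ok = True
    for b in exps:
        r, se, _ = _ratio_and_se(data[f"m{b}"], data["c"])
        target = lambda_rate(b, b, Lambda) / lam22
        z = _zscore(r, target, se)
        report.add(statistic=f"r_{b}", estimate=r, se=se, target=target, z=z)
        # b = 2 is excluded from the verdict: r_2 -> 1 is equivalent to the
        # residual condition (tested as a trend below), and its z-score is
        # degenerate because numerator and denominator share the leading term.
        if b >= 3 and se > 0 and abs(z) > 3:
            ok = False
    # residual condition across an N-grid (trend, not a finite-N threshold)
    if model_factory is not None and N_grid is not None:
        ratios = []
        for N in N_grid:
            m = model_factory(N)
            d = _batched_draws(
                m,
                reps,
                rng,
                lambda batch: {
                    "resid": (batch**2).sum(axis=1) - batch[:, idx] ** 2,
                    "c": (batch**2).sum(axis=1),
                },
            )
            r, se, _ = _ratio_and_se(d["resid"], d["c"])
            ratios.append(r)
            report.add(statistic=f"residual_ratio_N{N}", estimate=r, se=se,
                       target=0.0, z=float("nan"))
        slope = _loglog_slope(N_grid, np.maximum(ratios, 1e-300))
        report.add(statistic="residual_loglog_slope", estimate=slope, se=0.0,
                   target=0.0, z=float("nan"))
        if slope >= 0:
            ok = False
    report.passed = ok
    return report


def kingman_criterion(
    model_factory: Callable[[int], FrequencyModel],
    beta_exponent: float,
    N_grid: Sequence[int],
    reps: int,
    rng: np.random.Generator,
) -> CriterionReport:
    """Trend test for the Kingman domain of attraction.

    Estimates E[sum_{i>=2} eta_i^3]/c_N and E[eta_1^beta]/c_N across the
    N-grid and reports whether both decay (negative log-log slope) while
    c_N -> 0.  ``beta_exponent`` must exceed 2.
    """
    if beta_exponent <= 2:
        raise ValueError("beta_exponent must exceed 2")
    report = CriterionReport(name="kingman_criterion")
    third, tail, cs = [], [], []
    for N in N_grid:
        model = model_factory(N)
        d = _batched_draws(
            model,
            reps,
            rng,
            lambda batch: {
                "third": (batch**3).sum(axis=1) - batch[:, 0] ** 3,
                "tail": batch[:, 0] ** beta_exponent,
                "c": (batch**2).sum(axis=1),
            },
        )
        r3, se3, c_hat = _ratio_and_se(d["third"], d["c"])
        rb, seb, _ = _ratio_and_se(d["tail"], d["c"])
        third.append(max(r3, 1e-300))
        tail.append(max(rb, 1e-300))
        cs.append(c_hat)
        report.add(statistic=f"third_moment_ratio_N{N}", estimate=r3, se=se3,
                   target=0.0, z=float("nan"))
        report.add(statistic=f"eta1_beta_ratio_N{N}", estimate=rb, se=seb,
                   target=0.0, z=float("nan"))
        report.add(statistic=f"c_N_N{N}", estimate=c_hat, se=0.0,
                   target=0.0, z=float("nan"))
    s3 = _loglog_slope(N_grid, third)
    sb = _loglog_slope(N_grid, tail)
    sc = _loglog_slope(N_grid, cs)
    report.add(statistic="third_moment_slope", estimate=s3, se=0.0, target=0.0, z=float("nan"))
    report.add(statistic="eta1_beta_slope", estimate=sb, se=0.0, target=0.0, z=float("nan"))
    report.add(statistic="c_N_slope", estimate=sc, se=0.0, target=0.0, z=float("nan"))
    report.passed = bool(s3 < 0 and sb < 0 and sc < 0)
    return report


def eq4_harness(
    model: FrequencyModel,
    n: int,
    Q: RateMatrix,
    reps: int,
    rng: np.random.Generator,
    q_pair_normalizer: float = 1.0,
) -> CriterionReport:
    """Empirical check of the convergence condition P(pi~) = c_N Q(pi~) + o(c_N).

    For each non-trivial block-size profile the one-generation probability
    P(pi~) is estimated (conditionally exactly given eta) and the ratio
    P(pi~)/c_N is compared, with a z-score, to Q(pi~)/q_pair_normalizer, where
    ``q_pair_normalizer`` is the pair-merge rate of the same coagulation
    measure on a sample of two (the theorem's normalization makes it 1 when Q
    comes from a measure with lambda_{2,2} = 1).
    """
    profiles = [p for p in _profiles_and_partitions(n) if p != (1,) * n]
    data = _batched_draws(
        model,
        reps,
        rng,
        lambda batch: {
            **{str(prof): awf_transition_given_eta(batch, prof) for prof in profiles},
            "c": (batch**2).sum(axis=1),
        },
    )
    report = CriterionReport(name="eq4_harness")
    ok = True
    grouped = _profiles_and_partitions(n)
    for prof in profiles:
        rep_partition = grouped[prof][0]
        target = Q.rate(rep_partition) / q_pair_normalizer
        r, se, _ = _ratio_and_se(data[str(prof)], data["c"])
        z = _zscore(r, target, se)
        report.add(statistic="profile_" + ",".join(map(str, prof)),
                   estimate=r, se=se, target=target, z=z)
        if se > 0 and abs(z) > 3:
            ok = False
    report.passed = ok
    return report
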