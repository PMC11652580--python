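"""End-to-end study computations at their reference sizes.

Each function runs one of the package's headline checks from scratch —
generating the model inputs, executing the method, and measuring the result —
and returns a flat dict of numbers.  They are consumed by the acceptance
script and the acceptance test suite, and double as worked examples of the
API.  Problem sizes follow the package's reference study conditions (stated in
docs/methods.md); every function takes a seed so reruns are reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .criteria import _batched_draws, _ratio_and_se, kingman_criterion, phi_estimate
from .io_cli import generate_fixtures
from .models import (
    BottleneckParams,
    EldonWakeleyOffspring,
    EldonWakeleyParams,
    ExpModelFrequency,
    ExpModelParams,
    PDPowerFrequency,
    PDPowerParams,
    SymmetricBottleneckLaw,
    bottleneck_limit_rates,
    exp_model_reduction,
    exp_model_timescale_constants,
    pd_constants,
    zeta_limit_check,
)
from .partitions import Partition
from .population import (
    UniformFrequency,
    ac_awf_discrepancy,
    ac_transition_matrix,
    awf_increment,
    awf_transition_matrix,
)
from .rates import BOLTHAUSEN_SZNITMAN, LambdaMeasure, lambda_rate, lambda_rate_table
from .models import BottleneckFrequency

__all__ = [
    "oracle_equivalence",
    "rate_identities",
    "phi_diagnostics",
    "eldon_wakeley_limit",
    "ac_awf_equivalence",
    "exp_model_reduction_ks",
    "pd_power_shape",
    "exp_model_timescale",
    "zeta_pathwise_limit",
    "bottleneck_forward_rates",
]


def _rng(seed: int, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(salt,)))


def oracle_equivalence() -> dict:
    """Exact transition formulas vs brute-force enumeration on tiny models."""
    max_err = 0.0
    max_row_err = 0.0
    for fx in generate_fixtures().values():
        for n, table in fx.tables.items():
            est = (
                awf_transition_matrix(fx.model, n, method="enumerate")
                if fx.kind == "frequency"
                else ac_transition_matrix(fx.model, n, method="enumerate")
            )
            max_err = max(
                max_err, max(abs(est.probs[pi] - p) for pi, p in table.items())
            )
            max_row_err = max(max_row_err, abs(est.row_sum() - 1.0))
    return {"max_abs_error": max_err, "max_row_sum_error": max_row_err}


def rate_identities() -> dict:
    """Collision-rate recursion and Bolthausen-Sznitman closed forms."""
    measures = [
        LambdaMeasure.beta(a, b)
        for a in (0.5, 1.0, 2.0)
        for b in (0.5, 1.0, 3.0)
    ] + [LambdaMeasure.point_mass(p) for p in (0.0, 0.25, 0.75, 1.0)]
    rec_err = 0.0
    for m in measures:
        table = lambda_rate_table(11, m)
        for n in range(2, 11):
            for b in range(2, n + 1):
                rec_err = max(
                    rec_err,
                    abs(table[(n, b)] - table[(n + 1, b)] - table[(n + 1, b + 1)]),
                )
    quad = LambdaMeasure.truncated_density(lambda p: 1.0)
    bs_err = max(
        abs(lambda_rate(b, b, BOLTHAUSEN_SZNITMAN) - 1.0 / (b - 1))
        for b in range(2, 11)
    )
    bs_quad_err = max(
        abs(lambda_rate(b, b, BOLTHAUSEN_SZNITMAN) - lambda_rate(b, b, quad))
        for b in range(2, 11)
    )
    return {
        "max_recursion_error": rec_err,
        "max_bs_closed_form_error": bs_err,
        "max_bs_quadrature_error": bs_quad_err,
    }


def phi_diagnostics(seed: int, reps: int = 10_000) -> dict:
    """phi(2) = 1 and the moment recursion, on the PD-power model."""
    model = PDPowerFrequency(PDPowerParams(0.7, 0.0, 0.7, 500))
    phi2 = phi_estimate(model, [2], reps, _rng(seed, 1))
    # recursion phi(2,2,1) + phi(3,2) + phi(2,3) = phi(2,2) on shared draws
    parts = {}
    for sizes in [(2, 2), (2, 2, 1), (3, 2), (2, 3)]:
        parts[sizes] = phi_estimate(model, sizes, reps, _rng(seed, 2)).value
    lhs = parts[(2, 2, 1)] + parts[(3, 2)] + parts[(2, 3)]
    rhs = parts[(2, 2)]
    return {
        "phi2_deviation": abs(phi2.value - 1.0),
        "recursion_relative_error": abs(lhs - rhs) / rhs,
        "phi22": rhs,
    }


def eldon_wakeley_limit(seed: int, reps: int = 10_000) -> dict:
    """Sweep-fraction moment ratio vs quadrature oracle, and its N-trend."""
    N = 10_000
    off = EldonWakeleyOffspring(EldonWakeleyParams(BOLTHAUSEN_SZNITMAN, 0.5, N))
    y = off.sample_sweep_fractions(_rng(seed, 3), reps)
    num, den = y**3, y**2
    ratio, se, _ = _ratio_and_se(num, den)
    oracle = off.y_moment(3) / off.y_moment(2)
    trend = []
    for N_k in (100, 1000, 10_000):
        off_k = EldonWakeleyOffspring(EldonWakeleyParams(BOLTHAUSEN_SZNITMAN, 0.5, N_k))
        trend.append(off_k.y_moment(3) / off_k.y_moment(2))
    return {
        "moment_ratio": ratio,
        "moment_ratio_se": se,
        "oracle_ratio": oracle,
        "z_vs_oracle": (ratio - oracle) / se,
        "trend_ratios": trend,
        "trend_monotone_toward_half": bool(
            trend[0] > trend[1] > trend[2] > 0.5
        ),
    }


def ac_awf_equivalence(seed: int, reps: int = 4000) -> dict:
    """Sampling with vs without replacement: norm decay across N."""
    grid = (50, 200, 800)
    norms = []
    for N in grid:
        off = EldonWakeleyOffspring(EldonWakeleyParams(BOLTHAUSEN_SZNITMAN, 0.5, N))
        rep = ac_awf_discrepancy(off, 3, reps, _rng(seed, 4))
        norms.append(rep.norm)
    slope = float(np.polyfit(np.log(grid), np.log(norms), 1)[0])
    return {"N_grid": list(grid), "norms": norms, "loglog_slope": slope}


def exp_model_reduction_ks(
    seed: int, N: int = 100, reps: int = 2000, retries: int = 3
) -> dict:
    """Explicit particle construction vs PD-power law: KS on the top family
    frequency, with the multiple-testing retry rule (pass if any seed's p > 0.01)."""
    params = ExpModelParams(N=N, beta=2.0, kappa=1.0)
    em = ExpModelFrequency(params)
    red = exp_model_reduction(params)
    pvalues = []
    for attempt in range(retries):
        rng = _rng(seed, 5 + attempt)
        mx_em = np.array([em.sample(rng).max() for _ in range(reps)])
        mx_rd = red.sample_batch(rng, reps).max(axis=1)
        pvalues.append(float(stats.ks_2samp(mx_em, mx_rd).pvalue))
        if pvalues[-1] > 0.01:
            break
    return {"ks_pvalues": pvalues, "passed": any(p > 0.01 for p in pvalues)}


def pd_power_shape(seed: int, N: int = 5000, reps: int = 10_000) -> dict:
    """Shape diagnostics of the PD-power model at (0.7, 0, 0.7).

    Reports both the single-index ratio E[eta_1^3]/c_N (the sufficient-
    condition statistic, which approaches the Bolthausen-Sznitman value 1/2
    only logarithmically in N) and the triple-merge ratio E[sum_i eta_i^3]/c_N
    (the genealogical shape statistic, already converged at this N); plus the
    Kingman-criterion trend for theta = 2 alpha.
    """
    model = PDPowerFrequency(PDPowerParams(0.7, 0.0, 0.7, N))
    d = _batched_draws(
        model,
        reps,
        _rng(seed, 8),
        lambda b: {
            "eta1_cubed": b[:, 0] ** 3,
            "sum_cubed": (b**3).sum(axis=1),
            "c": (b**2).sum(axis=1),
        },
    )
    r1, se1, _ = _ratio_and_se(d["eta1_cubed"], d["c"])
    rs, ses, _ = _ratio_and_se(d["sum_cubed"], d["c"])
    king = kingman_criterion(
        lambda N_k: PDPowerFrequency(PDPowerParams(0.6, 1.2, 0.6, N_k)),
        3.0,
        (200, 800, 3200),
        4000,
        _rng(seed, 9),
    )
    return {
        "eta1_ratio": r1,
        "eta1_ratio_se": se1,
        "triple_merge_ratio": rs,
        "triple_merge_ratio_se": ses,
        "target": 0.5,
        "kingman_trend_passed": bool(king.passed),
    }


def exp_model_timescale(seed: int, N: int = 5000, reps: int = 10_000) -> dict:
    """c_N * u_N of the exponential model vs the two candidate constants."""
    out = {}
    for kappa in (1.0, 0.75):
        model = exp_model_reduction(ExpModelParams(N=N, beta=2.0, kappa=kappa))
        d = _batched_draws(
            model, reps, _rng(seed, 10), lambda b: {"c": (b**2).sum(axis=1)}
        )
        c = d["c"]
        u_N = pd_constants(0.5, 0.0, kappa / 2.0, N).u_N
        est = float(c.mean()) * u_N
        se = float(c.std(ddof=1) / math.sqrt(reps)) * u_N
        cands = exp_model_timescale_constants(2.0, kappa)
        matches = {
            name: bool(abs(est - val) < 3 * se) for name, val in cands.items()
        }
        out[kappa] = {
            "c_N_u_N": est,
            "se": se,
            "candidates": cands,
            "matches": matches,
            "closer_candidate": min(cands, key=lambda k: abs(est - cands[k])),
        }
    return out


def zeta_pathwise_limit(seed: int, N_max: int = 100_000, paths: int = 5) -> dict:
    """Pathwise normalizing-sum asymptotics at (alpha,theta,gamma) = (0.7,0.2,0.6)."""
    rep = zeta_limit_check(0.7, 0.2, 0.6, [N_max // 10, N_max], _rng(seed, 11), paths)
    return {
        "target": rep["target"],
        "relative_deviations": rep["relative_deviation_at_N_max"],
        "max_relative_deviation": rep["max_relative_deviation"],
    }


def bottleneck_forward_rates(
    seed: int, N: int = 10_000, merge_draws: int = 20_000, eq4_reps: int = 10_000
) -> dict:
    """Forward bottleneck model vs its limit coagulation rates.

    F = delta_2, symmetric bottleneck law, a_N = sqrt(N), uniform background
    (regime where bottleneck mergers dominate).  Checks the per-generation
    pair-merge probability against (F(2)/a_N)/2 + (1/N)(1 - F(2)/a_N), and the
    n = 3 transition ratios against the limit rates plus the exactly known
    finite-N background contribution.
    """
    params = BottleneckParams(
        F={2: 1.0},
        a_N=lambda n: n**0.5,
        b_N=lambda n: max(2, int(round(n**0.25))),
        nu_bar=SymmetricBottleneckLaw(),
    )
    model = BottleneckFrequency(params, N)
    rng = _rng(seed, 12)
    merged = sum(
        len(awf_increment(model.sample(rng), 2, rng)) == 1 for _ in range(merge_draws)
    )
    a_N = N**0.5
    pair_target = 0.5 / a_N + (1 - 1 / a_N) / N
    pair_est = merged / merge_draws
    pair_se = math.sqrt(pair_target * (1 - pair_target) / merge_draws)

    # n = 3 ratios: P(pi~)/c_N vs (bottleneck + background) finite-N targets
    from .criteria import eq4_harness

    Qbar, regime = bottleneck_limit_rates(params, 3)
    q2 = bottleneck_limit_rates(params, 2)[0].total_rate()
    rep = eq4_harness(model, 3, Qbar, eq4_reps, _rng(seed, 13), q_pair_normalizer=q2)
    # exact finite-N transition probabilities of the mixture model
    p_b = params.bottleneck_probability(N)
    uniform = awf_transition_matrix(UniformFrequency(N), 3, method="enumerate")
    c_exact = p_b * 0.5 + (1 - p_b) / N
    finite_targets = {}
    for prof, Q_part in (((2, 1), Partition(3, [[1, 2], [3]])), ((3,), Partition(3, [[1, 2, 3]]))):
        p_exact = p_b * Qbar.rate(Q_part) + (1 - p_b) * uniform.probs[Q_part]
        finite_targets[prof] = p_exact / c_exact
    rows = {}
    max_z = 0.0
    for row in rep.rows:
        prof = tuple(int(x) for x in row["statistic"].split("_")[1].split(","))
        z = (row["estimate"] - finite_targets[prof]) / row["se"]
        rows[str(prof)] = {
            "estimate": row["estimate"],
            "se": row["se"],
            "limit_target": row["target"],
            "finite_N_target": finite_targets[prof],
            "z_vs_finite_N": z,
        }
        max_z = max(max_z, abs(z))
    return {
        "pair_merge_probability": pair_est,
        "pair_merge_target": pair_target,
        "pair_merge_z": (pair_est - pair_target) / pair_se,
        "regime": regime["regime"],
        "eq4_rows": rows,
        "eq4_max_abs_z": max_z,
    }
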