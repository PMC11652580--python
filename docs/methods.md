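# Methods

## Population models

`asymcoal` models a haploid population of constant size N in discrete
generations, neutral in the sense of **non-heritable** reproductive success:
the vector of offspring numbers is drawn freshly and independently every
generation (static environment), and children choose parents exchangeably.

* **AWF (asymmetric Wright–Fisher)** — a random probability vector
  η = (η₁, …, η_N) is drawn; each child independently picks parent i with
  probability ηᵢ. Grouping a sample of n children by parent is the paint-box
  construction on η, so the coagulation increment of the ancestral process has
  law P(π̃) = E[Σ_{distinct i₁..i_j} Π_k η_{i_k}^{b_k}], where b_k are the
  block sizes of π̃. The pair-coalescence probability c_N = E[Σηᵢ²] sets the
  coalescent timescale.
* **AC (asymmetric Cannings)** — an integer offspring vector ξ with total
  Σ_N ≥ N is drawn and the next generation is an N-sample without replacement
  from the child slots. A sample of n children then has increment law
  P̃(π̃) = E[Σ_{distinct} Π_k (ξ_{i_k})_{b_k}/(Σ_N)_n] (falling factorials).
  Setting η = ξ/Σ_N gives the companion AWF model; the transition maps differ
  by O(E[1/Σ_N]) in row-sum norm, so whenever c_N ≫ E[1/Σ_N] the two models
  share their limit genealogy. `ac_awf_discrepancy` measures this distance
  with common random numbers (both maps evaluated on the same ξ draws, each
  conditionally exactly), so the reported norm is exact given the draws and
  only the expectation over ξ is Monte-Carlo.

The ancestral process starts from the singleton partition of the sample
{1..n}; each generation one increment is drawn among the current lineages and
applied by the coagulation operator (blocks of the state merged according to
blocks of the increment, re-canonicalized by least elements). Traces record
times, partitions and increments, and export as JSON-lines and Newick
(branch lengths = inter-coalescence times; if the MRCA is not reached the
remaining lineages are joined at the final time).

## Exact evaluation of the distinct-index sums

All moment functionals used by the estimators reduce to sums over distinct
indices of products of per-index powers. These are evaluated exactly per draw
by inclusion–exclusion over set partitions of the factor list (products of
power sums): Σ_distinct = Σ_σ Π_{B∈σ} (−1)^{|B|−1}(|B|−1)! · Σᵢ Π_{k∈B} f_k(i).
For j factors this costs Bell(j) power sums of length N — exact, vectorized,
and free of rare-event noise. Consequences:

* the transition-map estimators are conditionally exact given η/ξ (only the
  environment expectation is Monte-Carlo);
* φ(2) = 1 holds to machine precision, because the same power sum appears in
  numerator and denominator of every ratio (common random numbers);
* the moment recursion φ(b₁..b_j,1) + Σ_k φ(..,b_k+1,..) = φ(b₁..b_j) holds
  exactly per draw (it is an algebraic identity of the distinct sums), so the
  Monte-Carlo check is really a consistency check of the implementation.

The size-biased reordering itself (`size_biased_reorder`) uses the
exponential-race representation: sort the non-zero ηᵢ by Eᵢ/ηᵢ.

## Coalescent rates

λ_{n,b} uses closed forms for Beta measures (ratio of Beta functions via
`betaln`) and point masses (0⁰ := 1 at p = 0, Kingman), and adaptive
Gauss–Kronrod quadrature (abs. tol. 1e−10) for truncated densities. Ξ is
represented as a finite list of mass-partition atoms plus a Kingman mass;
continuous Ξ (or Λ) measures are atomized by Monte-Carlo where needed. The
paint-box probability of a partition assigns non-singleton blocks injectively
to paint intervals and lets each singleton take either a fresh interval or the
dust; it is computed by exhaustive enumeration of injections, intended for
n ≤ 8 and a moderate number of intervals (all uses in the package have n ≤ 6;
beyond that, estimate paint-box probabilities by sampling `paintbox_sample`).

## Convergence diagnostics

The one-generation law determines the limit: if P(π̃) = c_N·Q(π̃) + o(c_N) for
a coagulation matrix Q (normalized so the pair rate at n = 2 is 1), the
rescaled genealogy converges to the corresponding coalescent. The diagnostics
operationalize this at finite N:

* `eq4_harness` — estimates P(π̃)/c_N per block-size profile and z-scores
  against Q(π̃)/q_pair.
* `lambda_criterion` — estimates r_b = E[ηᵢᵇ]/c_N against λ_{b,b}/λ_{2,2}.
  The verdict uses b ≥ 3 plus the residual trend E[Σ_{k≠i}η_k²]/c_N across a
  geometric N-grid: the b = 2 ratio is excluded because its z-score is
  degenerate (numerator and denominator share the leading term) and its
  content *is* the residual condition.
* `kingman_criterion` — trend test (log-log slopes) of E[Σ_{i≥2}ηᵢ³]/c_N and
  E[η₁^β]/c_N (β > 2) across an N-grid, together with c_N → 0.

All "o(c_N)" statements are tested as monotone trends across a geometric grid
(default {N, 4N, 16N}); asymptotic statements have no finite-N threshold.
Monte-Carlo ratios use the delta method for standard errors, with c_N always
estimated on the same draws as the numerator. Tolerances in tests are stated
in standard-error units (3 SE by default). Finite-N estimates certify
*consistency* with a limit, never existence.

## Model zoo: parameters and defaults

* **Eldon–Wakeley** (`EldonWakeleyParams(Lambda, epsilon, N)`): one uniformly
  chosen parent produces ⌊YN⌋ copies replacing as many randomly chosen
  individuals; Y ~ normalized y⁻²Λ(dy) on (N^{(ε−1)/2}, 1]. ε ∈ (0, 1)
  controls how fast the truncation vanishes (default 0.5 in the reference
  runs); the limit genealogy is the Λ-coalescent with c_N ~ E[Y²]. ⌊YN⌋ ≤ 1
  degenerates to the all-ones offspring vector (an all-singletons generation);
  a Λ with no mass above the cutoff is rejected. Sampling uses an
  inverse-CDF table on a 4096-point log-spaced grid; moment oracles use
  quadrature. Note the finite-N moment ratios E[Yᵇ]/E[Y²] sit above their
  limits λ_{b,b}/λ_{2,2} because of the truncation (e.g. 0.55 vs 0.50 for
  b = 3 at N = 10⁴, ε = 0.5) and converge only as the cutoff vanishes.
* **Bottlenecks** (`BottleneckParams(F, a_N, b_N, nu_bar, hat_factory)`): with
  probability Σ_{k≤b_N}F(k)/a_N the generation descends from k ~ F|[b_N]
  individuals with conditional frequency law ν̄_k (symmetric 1/k, or
  normalized i.i.d. weights — Dirichlet type; fresh independent draw per
  bottleneck event); otherwise from the background model (uniform by
  default). The limit rate matrix Q̄(π̃) = Σ_k F(k)∫ϱ_ρ(π̃)ν̄_k(dρ) is exact
  for the symmetric law and Monte-Carlo-atomized for weight laws; infinite
  F supports are truncated with the neglected tail mass reported (an upper
  bound on the missing pair-merge rate). The time-scale regime is classified
  from the trend of ĉ_N·a_N (→0 bottleneck-dominated, →∞
  background-dominated, else superposition).
* **PD-power** (`PDPowerParams(alpha, theta, gamma, N)`): ηᵢ ∝ Ṽᵢ^γ for the
  stick-breaking size-biased PD(α, θ) sequence Ṽᵢ = Yᵢ·Π_{j<i}(1−Y_j),
  Yᵢ ~ Beta(1−α, θ+iα). γ = 0 is the classical Wright–Fisher model; γ = 1 a
  renormalized PD prefix. Constants: u_N = Σ_{i≤N} i^{−γ/α};
  K = exp{ψ(θ+1) − ψ(θ/α+1)/α} (the constant in e^{μ_N} ~ K·N^{(1−α)/α}/α,
  where μ_N centers the log-stick martingale S_N; the sign of the
  digamma-limit term is forced by Υ_a = lim[Σ_{i≤N}(a+i)⁻¹ − log N] = −ψ(a+1)
  and is verified against partial sums in the tests); the normalizing sum
  ζ_{N,γ} = ΣṼᵢ^γ satisfies ζ_{N,γ}/u_N → Γ(1+γ−α)/Γ(1−α)·K^{−γ}e^{γS_∞}
  a.s. for α/2 < γ ≤ α (pathwise-checkable via `zeta_limit_check`; the
  pathwise fluctuation scale is ~1/u_N, so tight agreement needs large N when
  γ/α is close to 1), and converges to a finite limit for γ > α.
* **Exponential model** (`ExpModelParams(N, beta, kappa, K_atoms)`): particles
  at positions x branch into a PPP of children with intensity e^{−(s−κx)}ds
  and N survivors are selected with weights ∝ e^{βx} (β > 1 for summability).
  All position arithmetic is in log space; selection uses Gumbel-top-N on the
  log weights. The one-generation family-frequency law equals the PD-power
  law with (α, θ, γ) = (1/β, 0, κ/β) (`exp_model_reduction`), which is the
  recommended way to simulate its genealogy. The PPP is truncated at
  K_atoms = max(4N, N+⌈50β⌉, ⌈10^{7.5/β}⌉) atoms by default, keeping the
  typical last-atom selection-weight share near K^{−β} ≈ 3·10⁻⁸; a run aborts
  if the realized share exceeds 10⁻⁶ (the share scales with the top atom's
  exponential gap, so with the default K this is a ~e⁻³⁰ event).

## Asymptotic timescale constants and their limits of validity

`pd_constants` exposes the closed-form timescale display
ℓ_{α,θ,γ} and the prediction c_N ≈ (1−θ/α)/(ℓ·u_N^{1+θ/α}) for
θ ∈ (−α, α), and `exp_model_timescale_constants` exposes the two published
candidate constants for lim c_N·u_N of the exponential model (they coincide
at κ = 1). Two caveats, established by this package's own numerical
experiments and reflected in the reported diagnostics:

1. **Logarithmic finite-N bias at γ = α.** The single-frequency statistics
   (E[η₁ᵇ]/c_N, c_N·u_N) approach their limits at rate ~1/log N: at
   (α, θ, γ) = (0.7, 0, 0.7), E[η₁³]/c_N = 0.44 at N = 5·10³ and is still
   ≈ 0.45 at N = 3·10⁵ against the limit 0.5, while the genealogically
   equivalent triple-merge ratio E[Σᵢηᵢ³]/c_N is already 0.50 ± 0.01 at
   N = 5·10³. Shape conclusions should therefore be drawn from the
   transition-ratio diagnostics (`eq4_harness`, full-sum moments), not from
   single-index ratios, at practical N.
2. **The γ < α regime.** The closed-form constants assume the η₁-moment
   scale u_N^{−(1+θ/α)}. Our Monte-Carlo experiments (cross-validated by an
   independent stable-subordinator construction of the PD frequencies and by
   a conditional-quadrature representation of E[η₁^δ]) indicate that for
   γ < α the actual scale is u_N^{−q} with q = (θ+α)/γ, and that the limit
   shape is the Beta(2−q, q)-coalescent rather than
   Beta(1−θ/α, 1+θ/α): at (α, θ, γ) = (0.5, 0, 0.375) the measured
   triple-merge ratio is ≈ 1/3 (the Beta(2/3, 4/3) value) across
   N = 2·10³…2·10⁵, and c_N·u_N decays ≈ N^{−0.14} instead of converging.
   The closed-form constants should be treated as reliable only at γ = α
   (equivalently κ = 1 for the exponential model); the diagnostics report the
   measured values either way.

## Reference study sizes

The benchmark computations (`asymcoal.benchmarks`, used by
`scripts/acceptance.py` and the acceptance tests) run at: exact oracle checks
on all N ≤ 5, n ≤ 4 fixtures; rate identities to n = 11; φ diagnostics at
10⁴ draws; Eldon–Wakeley at N = 10⁴ (trend grid 10²…10⁴), 10⁴ draws;
discrepancy decay at N ∈ {50, 200, 800}, 4·10³ draws; exponential-model KS at
N = 100, 2·10³ draws per arm with a 3-seed retry (multiple-testing guard:
fail only if all retries fail); PD-power shape at N = 5·10³, 10⁴ draws;
timescale at N = 5·10³; pathwise ζ at N = 10⁵ on 5 paths (a test additionally
verifies the 10%-band convergence at N = 10⁷); bottleneck forward checks at
N = 10⁴. The whole set runs in well under a minute.

## What the models do and do not emulate

The simulators generate the population models exactly as specified above —
they are the study system, not approximations of field data. Real populations
violate several standing assumptions: constant N, non-overlapping
generations, haploidy, a static environment (i.i.d. offspring laws across
generations), and non-heritability itself. Passing diagnostics therefore
certify the mathematical link between a one-generation law and its limit
coalescent; they say nothing about whether a given biological population has
that one-generation law.

## Numerical choices

* Probability-vector tolerance 1e−12 (mass partitions are rejected, not
  renormalized, beyond it); rate quadrature tolerance 1e−10; SEs below 1e−12
  are treated as exact in z-scores.
* Reproducibility: generation t of replicate r uses the counter-based stream
  SeedSequence(root, (r, t)), so traces are byte-identical across reruns and
  replicates are parallelizable.
* Without-replacement child sampling uses multivariate-hypergeometric counts
  over parent labels (no explicit slot lists), so Σ_N may be large.
* Degenerate inputs: ⌊YN⌋ ∈ {0, 1} sweeps (all-singleton generations), γ = 0
  power tilts (uniform), zero-mass Λ in the jump simulator, bottleneck
  probability > 1, and inadmissible coagulation pairs all raise or degrade
  explicitly rather than silently.
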