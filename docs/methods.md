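# Methods

## Model

A closed population of N individuals is partitioned into k groups, group i
holding the fraction f_i.  Infection follows separable mixing: a group-i
infective contacts each member of group j at rate β λ_i μ_j / N, so λ
measures relative infectivity and μ relative susceptibility.  Infectious
periods are exponential with mean 1/γ, or Erlang with s stages of rate sγ
(the method of stages; s → ∞ is the constant period 1/γ).  The state
(I_1, …, I_k) — stage-resolved, (I_{jv}) — is a continuous-time Markov
chain with infection rate (β/N)(Σ_m λ_m I_m) μ_j (N_j − I_j) into group j,
stage-advance rate sγ I_{j,v−1}, and recovery rate sγ I_{js}.

Scaling convention: Σ f_i = 1 and Σ f_i λ_i = Σ f_i μ_i = 1, with the
overall scale carried by β.  `validate_model` enforces this to 1e-10;
re-scaling is opt-in (`normalise=True`) and absorbs the factors into β so
all transition rates are unchanged — silent rescaling would mask typos in
published parameter sets.  The basic reproduction number is
R₀ = (β/γ) Σ f_i λ_i μ_i; every persistence computation requires R₀ > 1
and raises a dedicated error otherwise (the endemic state does not exist
subcritically, so returning 0 would be misleading).

## Equilibria

For R₀ > 1 the mean-field ODE dy_i/dt = β(Σ λ_j y_j) μ_i (f_i − y_i) − γ y_i
has the unique endemic equilibrium y*_i = μ_i f_i D/(1 + μ_i D), with
D = D(λ, μ) the unique positive root of (β/γ) Σ μ_j f_j λ_j /(1 + μ_j D) = 1.
The left side is strictly decreasing from R₀, so the root is bracketed by
growing the upper end geometrically from 1 and then polished with Brent's
method to machine precision (xtol 1e-14); bracketing was preferred to
Newton for robustness near R₀ ≈ 1 where the root approaches 0.  The
momentum fixed point of the extinction path is
θ*_i = −ln(1 + λ_i D(μ, λ)) with the role-swapped root.  The staged root
D_s(μ, λ) solves (β/(sγ)) Σ μ_j f_j λ_j Σ_{v=1}^s (1+λ_j D_s)^{−v} = 1 and
the staged momenta are θ*_{iv} = −(s+1−v) ln(1+λ_i D_s); stage occupancy at
the endemic point is uniform, y*_{iv} = y*_i / s.

Homogeneous closed forms used as oracles throughout the tests:
D = R₀ − 1, y* = 1 − 1/R₀, θ* = −ln R₀.

## Action formulas

The mean time τ to extinction from quasi-stationarity satisfies
lim (ln τ)/N = A.  With one heterogeneity only (μ ≡ 1 or λ ≡ 1, tested to
1e-10), A = Σ f_i ln(1 + c_i D(1, c)) − (γ/β) D(1, c) with c the
heterogeneous vector; the two cases coincide by network duality (the chain's
decay parameter is invariant under transposing the infection-rate matrix).
The homogeneous reduction is A₀ = 1/R₀ − 1 + ln R₀ with prefactor
C = R₀ √(2π)/(R₀ − 1)² in τ ~ (C/√N) e^{AN} (time scaled to unit mean
infectious period); no prefactor is available for heterogeneous models and
none is computed.

With both heterogeneities, the straight-line (near-threshold) estimate is
Ã = (D(λ,μ)/2) Σ μ_i f_i ln(1 + λ_i D(μ,λ)) / (1 + μ_i D(λ,μ)).  Ã is not
symmetric under λ ↔ μ although the true action is; `action_tilde` therefore
also reports the swapped value and their difference, plus a warning flag
once R₀ > 1.2, the regime where the straight-line geometry degrades.

For λ ≡ 1 the Hamilton–Jacobi equation admits closed-form potentials
V(y) (entropy-like, with the explicit 0·ln 0 = 0 branch at the boundary of
the box [0, f]) and U(θ) via the internal root Q(μ, θ) of
(β/γ) Σ μ_j f_j/(e^{−θ_j} + μ_j Q) = 1, and the action is the potential
drop V(0) − V(y*) = U(0) − U(θ*).  The stage-resolved generalisations give
the same drop for every s — Erlang periods do not change the leading-order
persistence time in the susceptibility-heterogeneous case.  One caveat
found while testing: the closed-form U differs from the strict Legendre
transform of V by the additive constant −Σ f_i ln f_i.  Constants are
immaterial (only differences of potentials enter any observable), and the
test suite pins the offset as θ-independent rather than asserting equality.

## Heteroclinic boundary-value solver

With both heterogeneities no closed form exists and the action is computed
as the integral A = ∫ θ·dy/dt dt = −∫ y·dθ/dt dt along the heteroclinic
orbit of Hamilton's equations connecting (y*, 0) to (0, θ*) on the
zero-energy manifold H = 0.

Formulation.  The orbit reaches the fixed points only at infinite time, so
it is posed on a truncated interval rescaled to x ∈ [0, 1] with length T:
dz/dx = T F(z), 2k equations.  Boundary conditions are projections built
from the linearisation at each fixed point (central finite differences,
step 1e-7; both Jacobians have exactly k stable and k unstable directions,
asserted at run time): the departure z(0) − (y*, 0) must lie in the
unstable right subspace, the arrival z(1) − (0, θ*) in the stable one —
k conditions each, 2k in total.  Keeping T fixed during each solve pins
the phase; freeing T as an unknown parameter (tried first) let the Newton
iteration wander into negative or overflowing interval lengths.

Interval selection.  T starts at 6/r_e + 6/r_x + 10/γ, where r_e, r_x are
the slowest linear rates at the two fixed points, and is grown by factors
of 1.7 — warm-starting each solve from the previous profile — until both
endpoint deviations fall below `endpoint_tol` (default 1e-4 relative to the
fixed-point separation).  The initial profile is a smooth cosine ramp
between the endpoints, which is exactly the straight-line geometry that
becomes the true orbit as R₀ → 1⁺.  If the direct solve fails or lands on
a spurious branch (detected by max |H| on a 501-point probe), a homotopy in
(λ, μ) from the homogeneous model supplies a usable profile, with adaptive
step bisection.

Action evaluation.  The integral is accumulated by trapezoidal quadrature
on a 2001-point dense output of the collocation spline, plus analytic
corrections for the truncated tails: near the extinction point θ is already
≈ θ* while y ≠ 0, so the missing tail contributes −θ*·y(T) at first order
(and θ(0)·(y(0) − y*) at the endemic end, second order but kept for
symmetry).  With these corrections the truncation error is O(endpoint_tol²)
and the computed action agrees with the explicit formula to ~1e-6 absolute
on the single-heterogeneity test models.  The alternative quadrature form
−∫ y·dθ (with its own boundary corrections) is reported in the diagnostics
and must agree to 1e-6; `action_from_trajectory` refuses trajectories whose
max |H| exceeds 1e-6.

The staged Hamiltonian is provided for evaluation and fixed-point
verification only; no staged boundary-value solve is attempted.

## Exact eigenvalue route

The transient class C (at least one infective) of the finite chain supports
a unique quasi-stationary distribution q with q Q_C = −(1/τ) q, Σq = 1,
where −(1/τ) is the eigenvalue of largest real part and τ is the exact mean
persistence time (the extinction time from q is exactly exponential).
States are enumerated mixed-radix: per-group (stage-resolved) local states,
all-susceptible first, composed little-endian; the absorbing state is index
0 of the product space and transient state i is product-state i+1.  The
generator is assembled vectorised per transition type.  Below 2000 states a
dense eigendecomposition is used; above, ARPACK shift-invert at σ = 0 on
Q_Cᵀ (the sought eigenvalue is the one closest to zero, separated from the
rest of the spectrum by orders of magnitude, so shift-invert converges in a
few iterations — the Fig.-1-scale solve with ~9·10⁴ states takes about one
second).  The residual ‖qQ_C − λq‖∞ is reported and must be below 1e-8.

The two-point finite-size estimate
(ln(τ₂√N₂) − ln(τ₁√N₁))/(N₂ − N₁) assumes the conjectured form
τ ~ (C/√N)e^{AN} and recovers A exactly on synthetic τ of that form.

## Stochastic simulation and the censored-window MLE

Exponential and Erlang runs are exact Gillespie simulations of the group
(and stage) rates.  Constant periods use a chronological event queue of
scheduled recoveries; between events the total infection rate is constant,
so the next infection is sampled exactly from an exponential with that rate
(no thinning).  Runs start from the largest-remainder rounding of N y*
(stage occupancy round-robin); initial infectives under constant periods
carry full periods 1/γ, so a no-transmission run with one infective goes
extinct at exactly 1/γ.

The estimator fixes a burn-in t₀ (default 10/γ, enough for the process to
relax to near-quasi-stationarity at the fixture sizes used) and a window
end t_max (default: doubled from 20/γ until ≥ 30% of 30 pilot runs go
extinct inside the window).  Runs extinct before t₀ are discarded; with r
extinctions at T_1..T_r in (t₀, t_max] and m survivors,
τ̂ = (m(t_max − t₀) + Σ(T_i − t₀))/r — the MLE for an exponential tail under
censoring — with standard error τ̂/√r attached.  Reproducibility: one root
seed spawns independent child streams per run (pilot and main runs use
separate spawns), so r, m and τ̂ are bit-for-bit reproducible.

## Network interpretation

A joint (d_in, d_out) degree distribution with per-link rate κ maps onto
the group model by β = κ E[d_out], f_j = p(pair j), μ_j = d_in(j)/E[d_in],
λ_j = d_out(j)/E[d_out]; stub-matching requires E[d_in] = E[d_out] (checked
to 1e-10).  Groups are ordered lexicographically in (d_in, d_out) so group
indices are stable across calls.  Partially directed networks collapse by
(d_in, d_out, d_un) → (d_in + d_un, d_out + d_un), aggregating coinciding
pairs.  For constant in-degree (resp. out-degree) the degree-space action
A_out (resp. A_in) is evaluated directly on the degree marginal and agrees
with the group-model explicit action to machine precision — the group-model
statement is exact, the network reading approximate (annealed); no attempt
is made to quantify the annealing error, and no quenched (stub-paired)
network is simulated.

## Heterogeneity orderings

p-majorization follows the shared-permutation definition: x⁽¹⁾ ≺_p x⁽²⁾
iff some permutation σ sorts both vectors non-increasingly, the p-weighted
means agree, and every p-weighted partial sum of x⁽¹⁾ along σ is dominated.
The sorting candidate is unique up to joint ties; permutations are
enumerated only within joint-tied blocks (where reordering permutes the
weights), capped at 2·10⁴ candidates.  "Incomparable" is a first-class
verdict.  One consequence surfaced by testing: a mean-preserving
(Robin-Hood) transfer whose donor drops strictly below a third entry lying
between its old and new values destroys the shared permutation — the pair
is then incomparable even though all convex-sum inequalities hold.
`robin_hood_pair` rejects such crossing transfers and `max_safe_amount`
returns the largest comparable transfer; the property suites draw below
that cap.

The convex order on finite integer-supported distributions is checked by
the cumulative characterisation Σ_{i≤j} P(X⁽¹⁾≤i) ≤ Σ_{i≤j} P(X⁽²⁾≤i);
unequal means give "incomparable".

## Synthetic fixtures

`random_model` draws f from a Dirichlet(5·1) (moderately balanced groups),
heterogeneous vectors as log-normal with σ = 0.5 rescaled to unit
f-weighted mean, and sets β to hit the requested R₀ exactly — mirroring the
convention of fixing R₀ and letting the overall infection rate float.
These fixtures emulate moderate, unimodal heterogeneity; they do not probe
extreme superspreading tails, degenerate near-zero group fractions, or
correlated (λ, μ) structure beyond what the "both" mode induces, so passing
property suites on them does not certify behaviour at such extremes (the
captioned model with λ ∝ (50, 1) covers one strongly heterogeneous case
explicitly).

## Problem sizes and numerical defaults

The test suite exercises exact eigensolves up to N = 600 (≈ 9·10⁴ states),
boundary-value solves for k ≤ 3, and simulation fixtures at N = 60–80 with
250–300 runs — sizes at which each check completes in seconds while leaving
the asymptotic regime visible (e.g. (ln τ)/N at N = 600 sits within 0.01 of
the explicit action).  Root-finding tolerances are 1e-14 (absolute, Brent);
collocation tolerance 1e-8 with at most 3·10⁴ mesh nodes; eigen-residual
bound 1e-8; zero-energy bound 1e-6.  The state-space cap for exact solves
defaults to 2·10⁶ states.

## Known limitations

- No prefactor C, hence no absolute τ prediction, for heterogeneous models;
  only the exponent A and exact finite-N τ.
- No staged heteroclinic solve; the staged Hamiltonian is evaluation-only,
  and no explicit staged-infectivity potential is known.
- The annealed network mapping is used as-is; its error relative to a
  quenched network is not quantified.
- Exact eigensolves beyond the state-space cap are refused rather than
  approximated.
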