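# Methods

## Model and assumptions

The PLSQR model describes smoking uptake and cessation in a closed,
well-mixed population normalized to a unit total.  Five compartments —
potential smokers P, occasional smokers L, heavy smokers S, temporary
quitters Q, permanent quitters R — exchange mass through bilinear contact
terms and linear transition terms.  A single rate a acts both as natural
death in every compartment and as renewal into P, which is what closes the
population: the componentwise sum of the vector field is a(1 − T), so
T(0) = 1 implies T(t) = 1 along the exact integer-order flow.  All rates are
plain per-unit-time quantities; no time unit is assumed.

### Incidence variants

Printed statements of this model disagree about the occasional-smoker
inflow: some give bPS, others bPL.  The package implements both behind an
explicit `ModelVariant` flag and defaults to **PS**, for two reasons that
are checked by tests rather than taken on faith:

* only the PS form conserves the total population (under PL the sum of the
  field is a(1 − T) + bP(L − S), and the built-in scenario drifts by more
  than 1e-3 over t ∈ [0, 30]);
* the model's Jacobian, equilibrium system and eigenvalue analysis are
  internally consistent only with PS (the Jacobian rows bS, −a − cS, bP − cL
  are derivatives of bPS, not bPL).

The Jacobian function therefore uses PS unconditionally; the PL variant is
retained for fidelity and for demonstrating the conservation failure.

## Equilibria, R0 and stability

The smoking-free equilibrium E0 = (1, 0, 0, 0, 0) is parameter-free.  The
reproductive number is implemented exactly as the closed formula
R0 = df(1 − e)/((a + d)(a + f)).  Note a structural property of this
formula, asserted as a test over 1000 random parameter draws: it is
strictly below 1 for every positive parameter set, since
df(1 − e) < (a + d)(a + f) identically.  Under this formula the smoking-free
state is always sub-threshold, so the operational check for an endemic state
is the numeric root scan, not an R0 > 1 comparison.  (The next-generation
factorization J = F − V behind R0 is not re-derived symbolically; only the
final formula is exposed.)

Endemic equilibria are parametrized by the heavy-smoker level S*:
P* = a/(a + bS*), L* = abS*/((a + bS*)(a + cS*)), Q* = d(1 − e)S*/(a + f),
R* = edS*/a, with S* a positive root of the scalar residual
g(S*) = −(a + d) + cL*(S*) + fd(1 − e)/(a + f).  The L* expression carries an
extra factor S* relative to one printed form of it; the form used here is
the only one consistent with L* = bP*S*/(a + cS*) and the only one that
zeroes the vector field, which every returned root must do to residual
< 1e-10.  Roots are bracketed by a uniform sign scan (default 10^4 intervals
over (0, s_max], s_max = 1, the population scale) and refined by Brent's
method to xtol 1e-12.  All sign-change roots are returned; the scan can and
does find two crossings for strongly super-critical contact rates.  An exact
zero sitting on a grid node without a sign change would be missed; for
floating-point inputs this is measure-zero and deliberately not special-cased.

Local stability at E0 is reported two ways and cross-checked: the three
closed-form eigenvalues λ1 = −a, λ2,3 = ½(−2a − d − f ∓ √(d² + 2df − 4def + f²)),
and the full numeric spectrum of the 5×5 Jacobian (numpy eigensolver).  The
closed-form values must each match a numeric eigenvalue to 1e-8, the two
remaining numeric eigenvalues equal −a, and λ2·λ3 = (a + d)(a + f) − df(1 − e)
is asserted as an algebraic identity at tolerance 1e-12.  A negative
discriminant yields a complex pair, not an error.  The verdict
(`locally_stable` / `not_stable`) is decided by the numeric spectrum's real
parts.

### Lyapunov diagnostics

The Volterra function M = Σ (x − x* − x* log(x/x*)) and its derivative along
the PS flow, dM/dt = Σ ((x − x*)/x)·ẋ, are evaluated directly by the chain
rule; no expanded algebraic decomposition of dM/dt is exposed.  The state
must be strictly positive (logarithm and division); reference-equilibrium
components may be zero, using the standard convention x* log(x*/x) → 0, so
diagnostics relative to E0 are well defined.

A caution established during development and encoded in a test: local
asymptotic stability does **not** make dM/dt negative in every direction.
At E0 + ε·(1,1,1,1,1) the leading term is dM/dt = ε(b − 4a) + O(ε²), which
is positive for the built-in rates.  What stability guarantees — and what
the tests assert — is decay of M along the flow: M(traj(t)) relative to E0
is decreasing at late times and dM/dt < 0 at the late-time state.

## The fractional solver

The ABC operator of order σ ∈ (0, 1] has Mittag-Leffler kernel and
normalization AB(σ) = 1 − σ + σ/Γ(σ) (equal to 1 at σ = 1).  A solution of
D^ABC y = f(t, y) satisfies the Volterra identity with a local term
(1 − σ)/AB(σ)·f(t, y(t)) plus a power-law-weighted memory integral.

### Atangana–Toufik stepping

The memory integral is discretized on a uniform grid (t0 = 0; the scheme
assumes equal spacing) with a piecewise-linear two-point Lagrange
interpolant of f, giving per-summand weight pairs indexed by the lag
k = n − j:

    current(k) = (k+1)^σ (k+2+σ) − k^σ (k+2+2σ)
    lagged(k)  = (k+1)^(σ+1) − k^σ (k+1+σ)

applied with the common factor h^σ/Γ(σ+2).  Numerical conventions:

* the step index appearing in the weight formulas is the current step n
  (the only reading for which the j = n summand is well defined and the
  σ = 1 limit is classical);
* the j = 0 summand references f at step −1; the bootstrap f₋₁ := f₀ is
  used, the standard initialization of two-step schemes — it affects only
  the first-step contribution;
* full memory is kept (no short-memory truncation); each f is evaluated
  once and cached, so cost is quadratic in the number of steps;
* iterates are not clamped to the positive orthant: a non-finite state
  aborts with the step index, and negative transients are left visible so
  convergence checks are not corrupted.

At σ = 1 both weights are constant ((3, 1), i.e. (3/2, 1/2)·h after the
h/Γ(3) factor) and the memory sum telescopes: the iterates coincide with
two-step Adams–Bashforth to accumulation roundoff (asserted at ≤ 1e-10 over
1000 steps).  Both weights are nonnegative for all lags and σ ∈ (0, 1]
(property-tested over n ≤ 200).

### Oracles

Three independent references validate the scheme:

* **RK4** (classical fixed-step) on the identical integer-order system: at
  σ = 1 the ATM trajectory matches within 1e-3 at h = 0.01 over t ∈ [0, 10]
  and improves under step halving;
* the **scalar linear closed form**: for D^ABC y = λy,
  y(t) = AB·y0/(AB − λ(1 − σ)) · E_{σ,1}(σλt^σ/(AB − λ(1 − σ))); ATM errors
  at t = 1 decrease strictly through h ∈ {0.02, 0.01, 0.005} for
  σ ∈ {0.7, 0.8, 0.9, 1.0};
* **equilibrium fixedness**: started exactly at E0, every iterate stays E0
  to machine precision for any σ (f ≡ 0 kills every term).

For σ < 1 the ABC formulation has an inherent jump at t = 0+: the closed
form satisfies the Volterra identity with y(0+) ≠ y0, while the stepping
scheme pins y(0) = y0.  Oracle comparisons are therefore made away from the
origin (t ≥ 0.5).

### Mittag-Leffler evaluation

E_{σ,σ1}(z) = Σ z^k/Γ(σk + σ1) is summed by the power series with
consecutive-term ratios computed via log-gamma, stopping when a term's
relative magnitude falls below 1e-14 (hard cap 10 000 terms, non-convergence
raises).  The evaluator is validated for |z| ≤ 50 — ample for every solver
oracle here, whose arguments are negative and of magnitude a few units —
and refuses larger arguments rather than silently losing precision to
cancellation.

## Scenarios, defaults and determinism

The built-in scenario carries the rates a=0.04, b=0.23, c=0.3, d=0.2, e=0.4,
f=0.25 and initial fractions (0.60301, 0.24, 0.10628, 0.0326, 0.01811),
which sum to exactly 1.  Defaults chosen where the source material states
none, fixed once and recorded in every sweep manifest:

* horizon t_end = 30 and step h = 0.01 — long enough to show the full
  transient and the approach to the smoking-free state, short enough that
  the quadratic-memory solver stays comfortably in the sub-second range;
* sweep orders {1.0, 0.95, 0.90, 0.85, 0.80}.

Config files are flat key–value YAML; missing keys fall back to the built-in
scenario (each fallback logged), unknown keys and invariant violations fail
with single-line named diagnostics.  The pipeline contains no randomness:
repeated sweeps are byte-identical, and CSV values use the shortest
round-trip decimal representation so re-reading reproduces the doubles
bit-for-bit (read with pandas `float_precision="round_trip"` for exact
equality with the manifest).

### Fractional-order ordering of compartments

Lowering σ lowers P and R and raises L, S and Q during the transient.  This
ordering needs an evaluation time: it holds on roughly t ∈ (0, 25] for the
built-in scenario but degrades near t = 30 as all orders converge to the
same steady state (R at σ = 0.85 crosses R at σ = 1).  The documented
reference time is **t = 10**, a mid-transient point well inside the window;
the property test evaluates there.

### Random fixtures

`random_fixture(seed)` draws the five rates log-uniformly on [1e-3, 1]
(three decades around the built-in magnitudes), e uniformly on [0, 1], and a
positive initial state rescaled to sum exactly to 1.  These fixtures probe
algebraic identities (conservation, eigenvalue relations, the sub-threshold
property of R0) — they emulate parameter uncertainty, not data: no
measurement noise, no demographic structure, no fitting.  Passing tests
certify the mathematics of the model and scheme, not agreement with observed
smoking prevalence.

## Known limitations

* R0, as implemented from its closed formula, cannot exceed 1; threshold
  behavior in the classical sense is not reachable under it, and endemic
  existence is decided by the root scan instead.
* Uniform grids only; no adaptive stepping, no short-memory acceleration,
  so cost grows quadratically with step count.
* The Mittag-Leffler evaluator is a validated-range series, not a
  global-argument algorithm.
* No parameter estimation from data, no demographic extensions (births ≠
  deaths, age structure), no stochastic formulation.
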