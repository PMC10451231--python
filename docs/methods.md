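# Methods

## Model and assumptions

The plant is a linear three-compartment model of oral drug transport:
absorption from the GI tract (`ka`), elimination from the absorption and
tissue compartments (`ke1`, `ke3`) and transfer into the sampled tissue
compartment (`k23`), all first-order with rates in 1/h.  The bundled
nominal parameter set (`ka = 0.0370`, `ke1 = 0.1214`, `k23 = 1.2725`,
`ke3 = 0.2171`) describes sulfathiazole suspension kinetics in the rat.
The model assumes linear (non-saturable) kinetics, a drug-free initial
state, instantaneous dosing at the sampling instants and no measurement
noise in the feedback path.  States are carried in the units the dose is
given in (mg); the observation is labelled mg/mL but no volume of
distribution is applied — unit bookkeeping is pass-through, because the
control laws only ever use ratios of output to input.

The characteristic polynomial factors as
`(s + ka + ke1)(s + k23)(s + ke3)`, so the continuous model is stable for
any positive rates; `continuous_char_roots` returns these factored roots
(ascending, for deterministic assertions) rather than calling an
eigensolver, and the test suite checks the two agree to 1e−10.

## Discretization and uncertainty

`zoh_discretize` computes `F = exp(A·T)` via `scipy.linalg.expm` and
`g = A⁻¹(F−I)b` by a linear solve; a singular `A` (only reachable through
the permissive model constructor) falls back to the augmented-matrix
exponential, and the object records which path was taken.  The default
dosing period is `T = 6` h.

Uncertainty is applied element-wise to the *discrete* pair: `F_lo/hi =
(1∓Δ)F`, `g_lo/hi = (1∓Δ)g`, default `Δ = 0.1`.  A secondary mode
(`make_interval_continuous`) perturbs the continuous rates first and
discretizes both corners; the two parameterizations do not coincide
(discretization is nonlinear in the rates) and the discrete-domain scaling
is the package default.  `Δ ≥ 1` is rejected outright: it would allow
negative rates.

Robust stability of the interval family is certified through monotonicity:
for non-negative matrices the spectral radius is monotone in the entries,
so the family is Schur iff the upper corner is.  The certificate string
records `ρ(F_hi)`, the argument, and an explicit check of all four
`(F, g)` corners.  If the lower corner has negative entries (possible after
deliberate destabilization) the code falls back to exhaustive per-entry
vertex enumeration, capped at 4096 vertices.  "Stable" means
`ρ < 1 − 1e−9`.

## Dosing laws

*Sampling convention.* Sample-then-dose at every `kT` with `x(0) = 0`; the
first concentration affected by `u(0)` is `y(1) = cᵀg·u(0)`.  This is the
unique convention consistent with the package's reference dosing table.

*Integral controller.* `u(0) = ki·r`, then
`u(k) = u(k−1) + ki·(r − y(k))` using the **most recent** sample.  (The
alternative `y(k−1)` indexing fails to reproduce the reference table by
several mg per step and is not used.)  The closed-loop characteristic
polynomial under this convention is `p(z) = (z−1)·det(zI−F) + ki·z·num(z)`,
degree 4, where `num` is the strictly-proper plant numerator; its
coefficients match the reference loop transfer function exactly, which is
the strongest available confirmation of the convention.  Loading-dose runs
override `u(0)` only; mis-dosing runs administer `scale·u(k)` for the first
`n` steps while the loop observes the concentrations the scaled doses
actually produced.  Whether the integrator continues from the administered
or the computed dose is configurable; administered is the default (feedback
should see reality).  Negative computed doses are simulated as-is and
flagged — they are a diagnostic for infeasible protocols, not an error.

*Open loop.* `u = r / gain` with `gain = cᵀ(I−F)⁻¹g` by linear solve
(raises when `ρ(F) ≥ 1`: no finite steady state exists).

*AUC.* Trapezoidal rule on the `T`-spaced samples over the simulated
horizon; the reference experiments use 24 intervals of 6 h (25 samples,
144 h).  `T`-spaced sampling suffices to reproduce the reference AUC
values, so no intra-interval (continuous) curve is computed.

*Therapeutic range.* No canonical numeric band exists for the bundled
scenario, so the default is `r·(1 ± 0.1)` — the same relative width as the
design uncertainty — and is always user-overridable.

## Robust state-feedback synthesis

To study unstable plants the lower interval corner is destabilized by
adding 0.7 to `F_lo[0,0]`, pushing its largest eigenvalue to ≈1.048.  The
synthesis problem is: find a row `K` such that `F + gK` is non-negative
and Schur for every `F` in the element-wise hull of
`{F_lo(destabilized), F_hi}` and `g ∈ [g_lo, g_hi]`.

Split `K = K⁺ + K⁻` with `K⁺ ≥ 0`, `K⁻ ≤ 0`.  Every closed-loop member is
then bracketed by

    F_min + g_lo K⁺ + g_hi K⁻  ≤  F + gK  ≤  F_max + g_hi K⁺ + g_lo K⁻,

so it suffices to (a) make the upper bracket Schur — imposed linearly
through a chosen positive left Lyapunov vector `v`:
`vᵀM ≤ vᵀ/α − ε⁺`, with margin `ε⁺ > 0` and tightening `α > 1` — and
(b) keep the lower bracket element-wise non-negative.  Both constraints
are linear in `(K⁺, K⁻)`, giving a small LP solved with `scipy`'s HiGHS
(deterministic; no seeds).  The objective minimizes `Σ K⁺ − Σ K⁻` (total
gain magnitude), so a stable family yields `K = 0`.  Defaults:
`ε⁺ = 1e−3`, `ε⁻ = −1e−3` (strict-negativity margin bookkeeping on the
negative part), `v = (1,1,1)ᵀ`, `α = 1.01`, gain entries capped at ±10.

Because LP vertex solutions are solver-dependent, numeric equality with
any particular published gain vector is *not* part of the contract; the
contract is the a-posteriori verification that all four corner closed
loops are Schur and non-negative.  The returned `FeedbackGain` carries the
corner spectra and, on failure, explicit diagnostics — a bad gain is never
returned silently.  The `v`-normalized multipliers `σ± = K±·(g_loᵀv)` are
recorded as metadata.

*Cascade loop.* `u(k) = v(k) + K x(k)` with the outer integrator
`v(0) = ki·r`, `v(k) = v(k−1) + ki·(r − y(k))`.  With `K = 0` this is
bit-identical to the plain integral controller (asserted in tests).

*A structural caveat.* The destabilized corner matrix has **negative DC
gain** (`cᵀ(I−F')⁻¹g ≈ −6.9` with the nominal `g`), so any controller that
holds a positive concentration target on that particular matrix must
settle at a negative dose; positive dosing at the target is mathematically
impossible there.  The meaningful robustness statement — and the one the
tests assert — is that the cascade tracks the target with non-negative
doses on every *stable* member of the uncertainty family the gain was
synthesized against (all four interval corners and the nominal plant),
while `detect_infeasible_dosing` flags the destabilized-matrix run.

## Identification

`PKIdentification` fits the four rates to sampled concentrations by
unweighted nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective, every rate bounded below by 1e−6), treating the
dose as an impulse into the absorption compartment and observing
compartment 3 by default.  The fit is deterministic (no random restarts);
a running-minimum SSE path is recorded for monotonicity checks.  On
noise-free synthetic data the rates are recovered to well under 1%
relative error across random positive parameter sets.

The response surface is, however, *sloppy*: the tissue-compartment output
has near-collinear sensitivities to the rates, so additive noise of 5% of
the peak concentration already produces median relative errors of tens of
percent (about 6% at 1% noise).  The test suite therefore asserts the
noise-free recovery bound and the monotone degradation with noise level,
not a tight bound at high noise.  The bundled seven-point in-vivo series
is a smoke-test input only: its dose normalization is not recorded
precisely enough to pin the printed nominal rates, and no such agreement
is asserted.

## What the synthetic experiments do and do not show

The simulations exercise exactly the modelled conditions: linear kinetics,
exact samples, perfectly periodic dosing, uncertainty entering as a static
element-wise interval.  Passing tests show the algebra and the robustness
arguments are implemented correctly under those conditions.  They do not
show robustness to nonlinear kinetics, sampling jitter, missed doses,
measurement noise in the feedback path, or time-varying parameters — none
of which are modelled.  Full state feedback additionally presumes a state
observer in any real application; only the output compartment is
measurable.

## Problem sizes and numerics

All reference computations are desk-scale: 3×3 matrices, horizons of 24 to
300 dosing intervals, an LP with 6 variables and 12 constraints.  The full
test suite runs in well under a minute on one CPU.  Property tests use
fixed seeds / derandomized hypothesis profiles; noisy-identification
checks use 10 replicates per noise level and random-rate recovery checks 8
draws, sizes chosen to keep the suite fast while leaving the conclusions
unambiguous.  Trajectory serialization writes floats at 17 significant
digits so CSV/JSON round trips are bit-exact (`pandas` is read back in
round-trip precision mode).
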