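# Methods

## Kinetic model

The package models folding as a linear two- or three-state scheme with
first-order microscopic rates. Each rate constant obeys the kinetic
linear free-energy relationship k_xy(D) = k_xy(0)·exp(∓m_xy·D/RT);
kinetic m-values are stored as non-negative magnitudes with an explicit
folding/unfolding direction flag, which removes the commonest source of
sign errors (folding rates decay, unfolding rates grow with denaturant).
Temperature defaults to 283.15 K and R to 0.0083145 kJ mol⁻¹ K⁻¹
(RT ≈ 2.354 kJ mol⁻¹); both are overridable through
`ExperimentConditions`.

For the three-state on-pathway scheme U ⇌ I ⇌ N the observable slow
phase is taken to be the exact smaller non-zero eigenvalue of the rate
matrix, λ₋ = (s − √(s²−4p))/2, evaluated as 2p/(s + √(s²−4p)) to avoid
cancellation when the phases are well separated. The pre-equilibrium
approximation k_IN·K_UI/(1+K_UI) + k_NI is provided alongside for
comparison but is never the default: the exact eigenvalue remains valid
when k_NI becomes comparable to the U ⇌ I rates, as happens for
destabilised variants with unfolding rates of tens per second. The
discriminant is clamped at zero (with a warning) if round-off drives it
negative; for positive rates it cannot be negative analytically.

Equilibrium populations come from detailed balance
(1 : K_UI : K_UI·k_IN/k_NI) evaluated as a log-space softmax, so extreme
stabilities cannot overflow. Thermodynamic identities —
ΔG°_UN = ΔG°_UI + ΔG°_IN, M_UN = M_UI + m_IN + m_NI — hold exactly by
construction. Sign convention: stable (more folded) states have negative
ΔG, so destabilising mutations give positive ΔΔG.

## Chevron fitting

`ThreeStateChevronFitter` minimises joint residuals of {ln k_obs,
initial fluorescence, final fluorescence}. Rate residuals are formed on
ln k_obs (chevrons span three decades and are analysed in log space; the
noise model is multiplicative), amplitude residuals on the linear
normalised scale. When per-point rate sigmas are supplied they weight
the log-rate block; otherwise the two blocks are balanced by one
reweighting pass using each block's residual RMS from an initial
unit-weight fit. This choice is configurable (`weighting="unit"`, a
fixed tuple, or the default `"auto"`) because no single weighting is
canonical for simultaneous rate/amplitude fits.

Free parameters are k_IU(0), m_IU, k_IN(0), m_IN, k_NI(0), m_NI plus a
linear fluorescence baseline (intercept, slope) per species; k_UI and
m_UI default to being fixed at the continuous-flow wild-type values
(1574 s⁻¹, 1.23 kJ mol⁻¹ M⁻¹), so the intermediate's stability is
carried by k_IU. Rates are optimised as logarithms (positivity),
m-values linearly with a lower bound at zero. The optimiser is
trust-region-reflective least squares (scipy `least_squares`, numerical
Jacobian) started from a data-driven guess (branch slopes/intercepts of
the chevron, edge fits of the amplitude data) plus a seeded
Latin-hypercube multistart (±1.5 natural-log units on rates, ×0.5–1.5 on
m-values; 8 starts by default).

The burst phase is modelled as a completed U ⇌ I pre-equilibration: the
initial refolding signal is the population-weighted U/I baseline with N
excluded, which assumes the fast phase finishes within the instrument
dead time at all denaturant concentrations — consistent with fixing
k_UI at 1574 s⁻¹ (1/e time < 1 ms). The unfolding initial signal is the
native baseline. Two-state fits have no burst phase; the initial
refolding signal is the unfolded baseline.

Parameter covariance is the Gauss–Newton estimate s²(JᵀJ)⁻¹ at the
optimum (s² = residual variance), computed via SVD; directions in the
numerical null space and log-rate sigmas above 5 natural-log units mark
parameters as unidentifiable (e.g. the unfolding branch of a
single-branch dataset). Parameters at a bound are flagged separately.
A total-m-value constraint (M_UN range from equilibrium experiments,
used when a chevron alone does not pin the overall denaturant
dependence) is implemented as a heavy soft penalty (weight 10³ per
kJ mol⁻¹ M⁻¹ of violation), so fitted values may exceed the band by
~10⁻³ at most; a hard reparameterisation was rejected as it would
distort the covariance of the remaining parameters.

Exponential trace fits use the same least-squares machinery with
multistart over rate decades spanned by the time grid; double-exponential
fits whose two rates collapse (ratio < 1.5) fall back to a single phase
with a warning, and rates are reported sorted descending so the slow
phase always maps onto the chevron observable.

## Equilibrium fits

Equilibrium curves are fitted to the two-state linear extrapolation
model, S(D) = f_N·(a + bD) + (1−f_N)·(c + dD) with
f_N = 1/(1 + exp((ΔG°_UN + M_UN·D)/RT)), evaluated through a logistic
(`expit`) for stability. The implementation exposes named
intercept/slope baselines rather than the bare (a..d) symbols, whose
roles are notoriously easy to transpose. Fluorescence and CD curves
share one code path; the probe is metadata. A fit is flagged
non-identifiable when the fitted midpoint −ΔG°_UN/M_UN falls outside the
data range or the data do not bracket the transition (model f_N range
narrower than [0.2, 0.8] over the data). The fraction-native transform
f_N = (S − B_D)/(B_N − B_D) is the exact analytical inverse of the
signal model and is not clipped to [0, 1] for noisy data.

## Φ-value analysis

Φ_I = ΔΔG°_UI/ΔΔG°_UN and Φ_TS2 = [ΔΔG°_UI − RT ln(k_IN^mut/k_IN^ref)]/
ΔΔG°_UN, the bracketed numerator being ΔΔG°_U-TS2. Errors are propagated
to first order treating each protein's (K_UI), (k_IN) and (k_NI) blocks
as independent measurements while keeping the algebraic dependence
between numerator and denominator — the two share the ΔΔG°_UI term, so
naive quadrature on the ratio would overestimate σ_Φ roughly threefold.
Variant and reference errors are independent (separate experiments). A
Monte-Carlo resampling check (10⁵ draws) agrees with the delta-method
sigmas to within 10%.

Φ-values are reported only when |ΔΔG°_UN| ≥ 2.5 kJ mol⁻¹; below that
the result is an explicit ND (NaN value, `determinable=False`), with a
`force` flag for exploratory use. Classification bins are low (Φ ≤ 0.4),
mid (0.4 < Φ ≤ 0.7) and high (Φ > 0.7); the boundary assignment to the
lower bin is an arbitrary documented convention. Negative Φ-values are
reported as computed. The total-m-value quality check passes a variant
when |M_UN − M_ref|/M_ref < 0.10 strictly (reference 5.4 kJ mol⁻¹ M⁻¹
gives the open pass band 4.86–5.94). Pseudo-wild-type referencing
(e.g. I54V as the reference for IV54T) is a per-variant mapping that
defaults to wild type.

## Synthetic data

Generators are pure functions of (parameters, grid, seed). Chevrons use
the experimental design — refolding 0.75–8.0 M (16 points), unfolding
3.0–8.0 M (11 points) — or an arbitrary grid whose branch labels are
assigned by the chevron minimum. Rate noise is multiplicative lognormal
(default 3% relative, appropriate for rates spanning decades); amplitude
noise is additive Gaussian (default 0.01 in normalised units, about 1%
of a typical signal span). Traces are propagated through the exact
eigendecomposition of the rate matrix from all-U (refolding) or all-N
(unfolding) initial conditions, with an optional dead-time offset.

The packaged scenario library transcribes the published best-fit
parameters for wild-type Im7 and its solvation and overpacking variants
(rates 0.1–1600 s⁻¹, m-values 0.03–4.5 kJ mol⁻¹ M⁻¹, ΔG −9 to −27
kJ mol⁻¹ at 283.15 K), which serve as generating truth. Fluorescence
baseline coefficients are not published; one synthetic canonical set is
used for every scenario (intermediate more fluorescent than U and N,
unfolded baseline normalised to 1 at 7.75 M urea), chosen to reproduce
the qualitative burst-phase fluorescence overshoot of refolding
experiments. The generator does not model photobleaching, mixing
artefacts or dead-time truncation of the slow phase, so passing recovery
tests demonstrate correctness of the estimators under the assumed noise
model, not robustness to instrument systematics.

## Test problem sizes and numerical choices

Round-trip tests refit noise-free 27-point chevrons to 10⁻⁶ relative;
the stochastic recovery suite uses 200 seeded replicates with 2
optimiser starts per fit (a data-driven start plus one perturbation),
which recovers the generating ln-rates with ~95% 2σ coverage and a mean
k_IN bias below 1%. Equilibrium recovery uses 41-point curves (0–8 M,
0.2 M steps) at the default 0.01 amplitude noise, at which the fitted
ΔG°_UN standard error (~0.55 kJ mol⁻¹) matches the published ±0.59 for
the intermediate-trapped variant curve. Eigenvalue fidelity is checked
against `numpy.linalg.eigvals` over 1000 random schemes spanning six
rate decades at 10⁻⁹ relative tolerance.

## Known limitations

- Schemes with more than three states, off-pathway or triangular
  topologies are out of scope.
- Global fitting across multiple variants simultaneously is not
  implemented; each dataset is fitted independently.
- The published Φ columns of the overpacked-variant series are
  reproduced from the printed rate constants for all variants except
  L37F, whose published fit used a directly measured k_UI rather than
  the fixed wild-type value; its printed Φ_I cannot be regenerated from
  the tabulated parameters alone and is excluded from regression tests,
  as is F84Y, whose printed Φ_I (0.90) reflects unrounded fit values
  (recomputation from the rounded table gives ≈ 0.85).
- Φ_TS2 for a two-state variant (no k_IN exists) is undefined here; the
  analysis reports its ΔΔG°_UN only.
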