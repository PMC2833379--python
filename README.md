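# foldkin

Kinetic and thermodynamic analysis of protein folding from stopped-flow
and equilibrium denaturation data: chevron-plot global fitting to
two-state (U ⇌ N) and three-state on-pathway (U ⇌ I ⇌ N) schemes,
linear-extrapolation equilibrium fits, and Φ-value analysis with
propagated errors. The package ships a seeded synthetic-data generator
that emulates the stopped-flow observables, so the whole pipeline runs
and is tested without any external data.

It is written for experimentalists analysing urea- or GdmCl-dilution
kinetics of small globular proteins — the worked parameter sets describe
the four-helix bacterial immunity protein Im7, which folds through a
compact on-pathway intermediate at 10 °C.

## The model

Every microscopic rate constant depends exponentially on denaturant
concentration *D*:

    k_xy(D) = k_xy(0) · exp(∓ m_xy · D / RT)

(− for folding steps, + for unfolding steps; kinetic m-values in
kJ mol⁻¹ M⁻¹). For the three-state scheme the observable slow relaxation
rate is the smaller non-zero eigenvalue of the rate matrix; with
s = k_UI + k_IU + k_IN + k_NI and p = k_UI·k_IN + k_UI·k_NI + k_IU·k_NI,

    λ± = (s ± √(s² − 4p)) / 2 .

Free energies follow ΔG°_UI = −RT ln(k_UI/k_IU), ΔG°_UN = ΔG°_UI +
ΔG°_IN (negative for stable states), total m-values are sums of kinetic
m-values, and Tanford betas are β_I = M_UI/M_UN,
β_TS2 = (M_UI + m_IN)/M_UN. Variant-vs-reference comparisons give

    Φ_I   = ΔΔG°_UI / ΔΔG°_UN
    Φ_TS2 = [ΔΔG°_UI − RT ln(k_IN^mut / k_IN^ref)] / ΔΔG°_UN

with first-order error propagation over the independent measurement
blocks (K_UI, k_IN, k_NI) of each protein, and an ND flag whenever
|ΔΔG°_UN| < 2.5 kJ mol⁻¹. Equilibrium curves are fitted to the standard
two-state sigmoid with linear baselines,
S(D) = f_N·B_N(D) + (1−f_N)·B_D(D), f_N = 1/(1+exp((ΔG°_UN + M_UN·D)/RT)).

The fitters are scikit-learn-style estimators
(`ThreeStateChevronFitter`, `TwoStateChevronFitter`,
`EquilibriumCurveFitter`, `ExponentialTraceFitter`) with `fit`/`predict`,
`get_params`/`set_params` and trailing-underscore fitted attributes;
module-level functions (`fit_chevron_three_state`, ...) wrap them.

## Worked example

```sh
$ foldkin simulate --scenario WT --seed 1 -o wt_chevron.csv
simulate: scenario=WT kind=chevron seed=1 -> wt_chevron.csv
$ foldkin fit-chevron wt_chevron.csv --n-starts 4 --seed 1 -o wt_fit.json
WT: success=True dG_UN=-24.91 kJ/mol M_UN=5.322 kJ/mol/M seed=1
$ foldkin phi --variant F15Y --reference WT
F15Y vs WT: ddG_UN = 10.51 +/- 0.85 kJ/mol; phi_I = 0.6206 +/- 0.034; phi_TS2 = 0.6525 +/- 0.031 (mid)
```

The first command writes a wild-type chevron (refolding 0.75–8.0 M,
unfolding 3.0–8.0 M urea) with 3% lognormal rate noise. The global fit
recovers the generating parameters — e.g. k_IN = 257.7 s⁻¹ against a
true 253.9 s⁻¹, and ΔG°_UN = −24.91 ± 0.35 against −25.21 kJ mol⁻¹ —
with β_I = 0.778 and β_TS2 = 0.918, i.e. the intermediate buries ~78%
and the rate-limiting transition state ~92% of the native surface. The
`phi` command compares the helix-I variant F15Y with wild type: a
Φ_I ≈ 0.62 means that position has gained most of its native
desolvation/packing free energy already in the intermediate.

The same operations are available as a library:

```python
from foldkin import load_scenario_library, compute_phi

lib = load_scenario_library()
res = compute_phi(lib["F15Y"].to_record(), lib["WT"].to_record())
print(res.phi_I, res.phi_I_sigma)   # 0.6206 0.0341
```

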