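# Methods

## Model

The membrane potential of a cell permeable to the monovalent ions K⁺, Na⁺
and Cl⁻ is modelled with the Goldman-Hodgkin-Katz (GHK) voltage equation,
with the anion's internal/external concentrations swapped relative to the
cations. Divalent ions (Ca²⁺, Mg²⁺) are excluded: the analysis fits only the
three monovalent permeabilities, and the assay conditions (2 mM external
Ca²⁺) keep the Ca²⁺-permeable pathways silent for monovalents. The GHK
voltage is invariant under uniform scaling of (P_K, P_Na, P_Cl), so all
permeabilities are dimensionless ratios normalized to the residual K⁺
permeability of SLO3-mutant non-capacitated sperm at pH 7.4 (P_K ≡ 1.0).
The thermal voltage RT/F is evaluated from the bath temperature (a field,
not a constant); at the assay's 37 °C it is 26.73 mV.

## Ion concentrations

External concentrations follow the HS-based recording medium: 151 mM Na⁺
(135 NaCl + 1 Na-pyruvate + 15 NaHCO₃), 143 mM Cl⁻, with K⁺ swept over
5/10/20/30 mM. Internal K⁺ is 120 mM (a standard literature value for mouse
sperm). Internal Na⁺ (14 mM) and Cl⁻ (40 mM) are not directly measured by
the assay; they are configuration defaults chosen so the forward model
reproduces the measured resting potentials (≈ −39 mV mutant, ≈ −45 mV
wild-type at 5 mM K⁺) and are overridable everywhere a `BathComposition` is
accepted. Nominal 0 mM substitutions (e.g. 1 mM Na⁺ media made with
impermeant NMDG⁺) are floored at 10⁻³ mM to keep the logarithms defined.

## Passive chloride redistribution

Sperm lack primary active Cl⁻ transport, so under a sustained
hyperpolarization internal Cl⁻ drains until its equilibrium potential
matches the membrane potential. At that fixed point Cl⁻ carries no net
flux, the chloride terms cancel out of the GHK expression, and the solution
is closed-form: Em from the cation terms alone, then
Cl_in = Cl_out·exp(Em·F/RT). The solver is exact (no iteration); the
residual |E_Cl(Cl_in) − Em| is zero to floating-point precision, checked to
10⁻⁶ mV in the tests. With the capacitated wild-type permeabilities
(P_K = 4.38, P_Na = 0.13) the fixed point is Em ≈ −68 mV, Cl_in ≈ 11 mM.

## Dye calibration

Each fluorescence recording is calibrated against itself: after valinomycin
clamps the membrane at E_K, sequential KCl additions (7.2, 11.7, 20.7,
38.7 mM final) step the potential through a Nernst ladder. The plateau
fluorescence after each addition — the median over a fixed 30 s window
ending just before the next event (the recordings reach steady state within
1–3 min but no plateau detector is specified, so a fixed window is used) —
is paired with the step's Nernst voltage; membrane potential is read off by
piecewise-linear interpolation between anchors, with terminal-segment
extrapolation beyond the anchor range (capacitated potentials can pass the
most hyperpolarized anchor). A single least-squares line through the anchors
is available as an alternative mode for robustness comparisons; which mode
produced a given report is recorded in it. Because every conversion is
anchored per trace, any monotone affine gain/offset in the fluorescence
channel cancels exactly. The dye physics implies fluorescence falls upon
hyperpolarization (dF/dEm > 0); calibrations violating that sign, or with
non-monotone plateaus, are flagged rather than rejected.

Anchor voltages reuse the same Nernst code path as the forward models, so
they agree bit-for-bit. Note the correctly computed ladder at 37 °C is
−84.9/−75.2/−62.2/−47.0/−30.2 mV; published roundings of the middle anchors
sometimes differ by up to 0.2 mV, which is beyond what any single
temperature can reconcile and is treated as rounding error, not signal.

## Fitting

Permeabilities are estimated by weighted nonlinear least squares: minimize
Σₖ wₖ·(Em_obs(k) − Em_GHK(k))² over the free parameters with bounds ≥ 0,
weights wₖ = 1/SEMₖ² (unit weights when SEMs are absent). Because only
ratios are identifiable, every fit carries a constraint set with at least
one parameter fixed; an all-free request is rejected as under-determined.
The optimizer is `scipy.optimize.least_squares` (trust-region reflective)
with 5 starts — one at unity plus four drawn log-uniformly from
[0.01, 20] — because the objective can be shallow in P_Na; the best cost
wins. Tolerances are set to 10⁻¹²; fixed parameters are returned unchanged
to machine precision.

The staged procedure assumes wild-type and mutant non-capacitated sperm
share all permeabilities except the SLO3 contribution to P_K:

1. mutant baseline: P_K fixed at 1.0, fit P_Na and P_Cl;
2. wild-type baseline: P_Na/P_Cl fixed at stage-1 values, fit P_K;
3. each remaining condition, with constraints by condition type:
   capacitated/pH-8 fits hold P_Na and P_Cl at stage-1 values and free P_K
   (the hyperpolarization is a K⁺-permeability effect); amiloride fits hold
   the genotype's baseline P_K, free P_Na, and drop the chloride term;
   low-Na and low-Cl media drop the chloride term and free P_K. An optional
   all-free cross-check records the SSE of a fit with every permeability
   floating, to confirm the constrained fits are not materially worse.

Chloride handling in hyperpolarized fits is genuinely ambiguous — either
P_Cl falls or internal Cl⁻ redistributes; both modes are implemented. Stage
fits default to a fixed Cl_in of 40 mM (so the preset fit values are
recovered as printed); the `redistribute_cl` flag instead sets Cl_in to its
passive equilibrium per candidate parameter vector, in which case P_Cl
drops out of the voltage and is not identifiable. Neither mode is asserted
as the "true" mechanism.

Two statistics accompany the fits. Curves are compared with
χ² = Σₖ (Em_a − Em_b)²/(SEM_a² + SEM_b²), one degree of freedom per shared
K⁺ point. Per-permeability p-values come from a nested-fit comparison:
refit with that permeability pinned to zero and refer the SSE increase to
χ²(1) — a likelihood-ratio test under the Gaussian error model with known
per-point SEMs (the published analyses do not state their method; this is
the package's convention). When dropping a parameter would leave no fixed
parameter (scale degeneracy), the first remaining free one is fixed at its
full-fit estimate.

## Synthetic data

The generator emulates the assay's statistical structure, not its
biophysics: per condition, a ground-truth permeability preset feeds the GHK
forward model on the 5/10/20/30 mM K⁺ grid; n = 11 replicate experiments
(n = 4 for the blocker/pH/media conditions, matching the corresponding
experiment counts) receive i.i.d. Gaussian noise of σ = 2 mV — the few-mV
SEM scale of population recordings — and are summarized as mean/SEM/n.
Conditions analysed without a chloride term (amiloride, low-Na, low-Cl
media) are simulated with internal Cl⁻ at its passive equilibrium per K⁺
level; others keep Cl_in fixed. Heterogeneous populations (only a fraction
of cells capacitate) can be emulated as a voltage-space population-weighted
mean of two subpopulation offsets; the capacitated wild-type preset
(P_K = 4.38) already represents such a population average, so mixtures are
off by default. Fluorescence traces use an affine dye model (gain
+2 AU/mV, offset 400 AU, noise 3 AU ≈ 1.5 mV) with the calibration ladder
appended.

What passing tests therefore show: the estimation machinery recovers known
ground truth under Gaussian noise on a GHK-generated world. What they do
not show: robustness to dye kinetics, photobleaching, mitochondrial
partitioning, non-Gaussian or correlated replicate error, or real ion
redistribution dynamics — none of which the generator models.

Preset P_Na values are deliberately inconsistent across pH labels (0.13 at
pH 7.4, 0.15 at pH 7, 0.12 for the mutant at pH 8): both printed
conventions from the source analyses are kept, keyed by pH, rather than
silently reconciled. The mutant capacitated P_K preset (1.2) quantifies a
"slight increase" by analogy with the quantified pH-8 mutant value.

## Verification design

Parameter-recovery checks use medians over replicate synthetic suites
rather than single draws: from a 4-point K⁺ grid at σ = 2 mV, n = 11, the
Fisher information gives a sampling SD for P_Cl of ≈ 0.11 (its two bath
terms nearly cancel, leaving only the curvature of the Em-K relation to
pin it), so a single-suite check against a ±0.1 band would measure luck,
not correctness. Medians over 7 suites reduce the Monte-Carlo error to
≈ 0.04 while testing the same recovery claim. P_Na and the wild-type P_K
are far better determined (SD ≈ 0.005 and 0.09) and are held to a 10%
median-error bound outright; P_Cl is held to 1.25× its information-bound
median. All test randomness flows from one fixed seed committed in
`tests/conftest.py`.

## Known limitations

- Internal Na⁺/Cl⁻ defaults are calibrated to resting potentials, not
  measured; conclusions sensitive to them should sweep `BathComposition`.
- The GHK framework assumes independent ion movement and a constant field;
  rectifying channels or electrogenic transport would violate it.
- P_Cl estimates from 4-point curves are intrinsically low-precision (see
  above); treat single-fit P_Cl values as ±0.1–0.15.
- The chi-square curve comparison treats per-point means as independent
  Gaussians with known SEMs; with n ≤ 4 experiments this is approximate.
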