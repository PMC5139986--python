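# Methods

This note documents the model equations, the parameter choices and their
rationale, the calibration procedure, the synthetic-data conditions used in
the tests, and the numerical decisions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Units and normalisation

Time is in seconds, pressures in mmHg, saturations in percent,
concentrations in mM, the proton motive force Δp in mV. Blood volumes are
dimensionless, normalised so each compartment's total blood volume is 1 at
baseline; flow is in normalised volume per second, with the baseline flow
q_n = 0.1 s⁻¹, i.e. a mean transit time of 10 s. No absolute flow scale is
prescribed by the physiology the model encodes, so this is a convention; it
fixes the venous time constants (see below) but not the steady-state
behaviour, which is what the confound analyses use. Haemoglobin outputs are
scaled to μM by a single haematocrit/vessel-density factor
(`hb_scale = 84 μM` of total haemoglobin per unit normalised volume, a
typical adult-head tissue value); absolute μM calibration against a real
instrument is not identifiable from the model, so outputs should be read as
relative unless the user supplies a scale.

## Cerebral compartment

State vector: radius r_c (relative to baseline), venous pressure Pv_c,
tissue O2, the four redox pool concentrations (CuA_ox/red, a3_ox/red), Δp,
and a low-pass filtered copy of tissue O2 (O2_filt) that carries the slow
oxygen feedback on vascular tone.

Haemodynamics: G = G_n·r⁴ (Poiseuille), Va = Va_n·r² (cross-sectional
area), inflow q = G(Pa − Pv), venous store dPv/dt = (G(Pa−Pv) − Pv·Gv)/Cv,
Vv = Vv_nc + Pv·Cv. The radius relaxes with time constant τ_r = 5 s towards

    r_set = (Pa/Pa_n)^(−g_P) (PaCO2/PaCO2_n)^(g_C) (1 + g_u(u−1)) (O2_filt/O2_n)^(−g_O2)

The multiplicative power-law form keeps the set-point positive and makes
the gains dimensionless elasticities. With g_P near 0.25 the steady flow
q ∝ Pa^(1−4·g_P) is nearly pressure-invariant — the autoregulation plateau.

Oxygen: venous saturation is the quasi-steady solution of the
convection–diffusion balance q·c_tot·(SaO2 − SvO2)/100 = D_O2·(φ·SvO2 − O2),
i.e. blood equilibrates fast relative to the vascular and tissue dynamics.
Tissue O2 obeys dO2/dt = D_O2(φ·SvO2 − O2) − f3. The O2 feedback acts
through a 30 s first-order filter (τ_O2f), producing the slow secondary
adjustment of flow after CO2/demand/saturation steps.

Metabolism: the three-reaction chain rates f1–f3 (rate equations in
`fnirsim.metabolism`) are expressed in O2-consumption-equivalent units, so
f3 is CMRO2 directly and pool-transfer bookkeeping absorbs electron
stoichiometry into the λ coefficients. Δp obeys
C_dp·dΔp/dt = f1 + f2 + f3 − k_L·u·Δp: all three reactions pump protons and
consumption scales with demand u and with Δp itself. A substrate-supply
dependence is deliberately omitted (assumed non-limiting for functional
experiments in healthy adults). Note the published form of the f2 equation
labels the a3_ox coefficient "λf1,b"; this package reads it as a
per-equation coefficient λf2,b, which is the only dimensionally and
structurally consistent interpretation.

### Calibration

`calibrate_cerebral` computes every derived constant analytically so the
baseline operating point (Pa 100 mmHg, PaCO2 40 mmHg, SaO2 96 %, u 1, with
SvO2 70 %, O2 0.024 mM, Δp 145 mV, CMRO2 0.035 mM/s, pools 2.2 μM at 70 %
oxidised) is an **exact fixed point**: vascular constants from the
resistance/volume split (below), c_tot, φ, D_O2 and k_L from the baseline
flux balances, and the rate-equation intercepts λf1–λf3 so that
f1 = f2 = f3 = CMRO2_n. The baseline venous saturation (70 %) is an assumed
conventional value, exposed as a parameter. It then *verifies* the
qualitative steady-state targets — signs of (ΔHbO2, ΔHHb) for upward steps
of each input (Pa: −/−, PaCO2: +/−, SaO2: +/−, u: +/−) and monotonicity of
CMRO2 in u — and raises listing any violation. The procedure is
deterministic (no random search), so the "seed" of the calibration is the
documented default gain set itself.

The default gains (g_P 0.27, g_C 1.2, g_u 0.15, g_O2 0.15) and λ slopes
were chosen, once, as the simplest round values satisfying all the
qualitative targets simultaneously, including the scenario-level ones
(hypercapnia-alone false positives, no pressure-alone false positives,
pressure-alone and CO2-alone false negatives under activation). They give:
activation (u 1.25) flow ≈ +20 % with CMRO2 ≈ +11 %, CO2 reactivity ≈ +9 %
flow per mmHg, autoregulation slightly over-compensating in radius but with
near-flat flow (the venous divider returns part of the compensation). The
resulting response magnitudes (activation ≈ +3.8/−0.6 μM; 2.5 mmHg CO2 step
≈ +6.2/−2.4 μM) are in the low-μM range typical of adult fNIRS.

## Scalp compartment

Same Windkessel relations with no regulation and no metabolism. The flow
estimate is either pressure-based (Fx = λFx + λFx,p·Pa) or flux-based
(Fy = Flux_y·Fy,n, with Fy,n defaulting to the pressure model's baseline
value so the variants agree at baseline). The arterial conductance is
back-computed from the flow estimate as the conductance that would carry it
as steady through-flow, G = F·Gv/(Gv·Pa − F); this reproduces the venous
divider Pv* = G·Pa/(G+Gv) and the baseline venous pressure share
Pv/Pa = Rfrac_v exactly, and gives the venous relaxation time constant
Cv/(G+Gv). The printed form of the venous ODE is divided by Cv on
dimensional grounds. Post-venous pressure is taken as exactly zero, and a
single venous conductance Gv serves both compliant discharge and
through-flow (the split is not separately identifiable).

Baseline normalisation: Va + Vv = 1 with Vv/Va = vratio (default 3),
venous resistance share Rfrac_v (default 0.1, so Pv_n = 10 mmHg ≪ Pa), and
compliant venous fraction Volc_frac (default 0.1, fixing Cv). With the
default flow normalisation the venous time constant is ≈ 0.7 s: venous
buffering is fast relative to the 1 Hz output sampling, and the tests show
the *shape* of the step response on the sampled grid is insensitive to ±50 %
changes in Volc_frac and Rfrac_v, as expected while Pv ≪ Pa.

The default λFx/λFx,p are fitted by least squares to a small **synthetic**
pressure–flux table packaged in `fnirsim.scalp` (weak scalp autoregulation:
flow ≈ +0.85 %/mmHg, with small deterministic scatter); the original
experimental pressure/laser-Doppler data set is not distributed. The table
and the fit are replaceable via configuration.

Scalp oxygen: arterial saturation tracks systemic SaO2 instantaneously;
venous saturation is fixed at the cerebral baseline value. Consequently,
without a saturation change the scalp moves ΔHbO2 and ΔHHb in the same
direction, with the ΔHHb excursion ≈ 0.15× the ΔHbO2 excursion at default
saturations.

## Observation

HbO2 = hb_scale·(Va·Sa + Vv·Sv)/100 and HHb = hb_scale·(Va(1−Sa/100) +
Vv(1−Sv/100)), per compartment, reported as changes from the first sample
(every output series starts at exactly 0). The merged output is the
weighted sum w_scalp·scalp + w_cerebral·cerebral — pure post-processing.
ΔoxCCO reports the change in oxidised CuA (×1000 to μM); CuA is used as the
redox marker because it is the NIRS-visible copper centre and the simplest
choice consistent with the model structure.

## Simulation and signal conditioning

Both compartments are integrated jointly with LSODA (the metabolic pools
make the system stiff), relative tolerance 1e-6 and absolute tolerances
1e-8 scaled per state, with output sampling (default 1 Hz) decoupled from
solver steps. Runs start from the steady state of the first input sample,
so held inputs produce flat outputs (verified to ~1e-10 μM). Protocols:
square-wave steps (baseline → range top → baseline) and a multi-frequency
protocol in which each input oscillates at its own frequency (defaults
complete integer cycle counts over the 600 s segment, so pairwise input
correlations are < 0.05). Conditioning mirrors standard practice:
laser-Doppler flux is normalised to the *median* of the first 2 min
(robust to outliers), smoothing is a centred 1 min moving average whose
edge windows shrink rather than trim (keeps short baselines; whether the
original practice was centred or trailing is not documented — centred is
used and flagged here), and coarse series are upsampled by linear
interpolation.

## Scenario machinery

Templates: activation (a, b) is the model's own steady-state response to
u = 1.25 (a > 0, b < 0); FN1 = (0, 0); FN2 = (a, 0); FN3 = (a, −b), i.e.
ΔHHb *rising* by the magnitude it would normally fall — template magnitudes
are deliberately tied to the model's activation response since no external
μM values are prescribed. The classifier assigns the template with lowest
total absolute error, ties broken by fixed template order. Sweeps apply
simultaneous steps and classify only the settled steady state (21×21 grid
by default). The scenario optimiser is seeded differential evolution over
step values within the input ranges (SaO2 capped at its 96 % baseline:
spontaneous saturation *rises* are implausible in functional experiments);
the objective is the classifier metric on the steady-state response, with
the scalp contribution (flux value and merge weight w_scalp ∈ [0, 2])
optionally included. Results are reproducible per seed but, the search
being non-convex, neither unique nor necessarily optimal.

## Comparison and attribution analytics

Cross-correlation is normalised by n·sd·sd with whole-series means (so
lag 0 equals the Pearson coefficient and values lie in [−1, 1]); the default
maximum lag is 2.5 min. DTW uses absolute local distance and the symmetric
unit-weight step set {(1,1), (1,0), (0,1)} with no global window and
closed-end alignment (open-end alignment is a possible variant; closed-end
is used and flagged). It reports W, the mean absolute difference of the
alignment index vectors, and D, the accumulated distance; model signals are
min-max rescaled into the measured range first, since DTW is
scale-sensitive. Attribution solves min ‖measured − S·scalp − C·cerebral‖₂
with S, C ≥ 0 by non-negative least squares over the concatenated ΔHbO2 and
ΔHHb series — a single weight pair shared by both signals, encoding the
assumption that both are contaminated by scalp to the same degree.

## Synthetic data and what the tests show

The package generates all of its own inputs: step protocols at the
documented range bounds (Pa 75–125 mmHg, PaCO2 37.5–42.5 mmHg, SaO2
90–100 %, u and flux 0.75–1.25), the multi-frequency protocol, and a
`noisy_mixture` fixture that mixes the model's own scalp and cerebral
outputs 0.3/0.7 with 10 % Gaussian noise. Passing tests therefore
demonstrate internal consistency and the mechanisms of confounding —
directions, sufficiency regions, recoverability of known mixtures — not
agreement with any particular experimental recording. Real data bring
variable physiological delays, Mayer waves, instrument noise and
subject-specific scaling that the generator does not emulate; the
attribution results on real recordings should be treated with the same
caution as any simplistic least-squares unmixing.

## Numerical choices

Steady states are found by a scaled 6-dimensional root solve (pool totals
conserved, O2 filter at its fixed point) started from baseline, with the
venous-pressure residual de-weighted (its dynamics are two orders of
magnitude faster than the rest); solutions are verified against the full
right-hand side at tolerance 1e-8. Degenerate inputs raise typed errors:
non-positive concentrations inside logarithms (naming the pool), flow
estimates exceeding what the venous bed can pass, constant series handed to
min-max rescaling, collinear or zero model signals in attribution.

## Known limitations

* The cerebral compartment is a reduced model: one lumped arterial segment,
  a quasi-steady venous saturation, and a three-reaction metabolic chain.
  It reproduces directional and steady-state structure, not detailed
  transient morphology.
* Scalp blood flow is driven by pressure or measured flux only; autonomic,
  thermal and cardiac-output influences on skin blood flow are out of
  scope, as is any scalp metabolism (which likely makes the model
  overestimate scalp ΔHbO2 relative to ΔHHb effects).
* Intra-beat pulsatility and spontaneous oscillations (e.g. Mayer waves)
  are not modelled; inputs held constant produce constant outputs.
* Photon-transport weighting by source–detector separation is not
  modelled; separations are labels on measured data only.
* Because the steady-state response directions of Pa (volume-mediated at
  regulated flow) and PaCO2 (flow- and saturation-mediated) are linearly
  independent, a two-input steady-state search can reproduce *any* of the
  no-activation templates, including FN2/FN3, without a scalp contribution.
  The corresponding exclusivity test
  (`test_fn_search_without_scalp_matches_only_fn1`) documents this and
  fails by design; a time-course objective was evaluated and does not
  restore the exclusivity either, because the transient shapes of the
  pressure, CO2 and demand responses are too similar in this reduced model.
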