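# Methods

This note records the models mesokit implements, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic-data
generators do and do not emulate. Units follow one package-wide convention:
assimilation A in µmol m⁻² s⁻¹, partial pressures in µbar, conductances and
A–Ci slopes in mol m⁻² s⁻¹ bar⁻¹ (numerically equal to µmol m⁻² s⁻¹ µbar⁻¹),
isotope deltas in ‰ at the API surface and exact ratio fractions internally.

## Enzyme-limited C4 model (`c4model`)

The C4 pathway is modelled in its enzyme-limited form with a CO₂-saturated
bundle sheath:

    Vp(Cm) = min(Cm·Vpmax/(Cm + Kp), Vpr)
    A(Cm)  = min(Vp + gbs·Cm − Rm,  Vcmax − Rd)

Oxygen and photorespiration terms are omitted: the bundle-sheath CO₂ pump
keeps Rubisco near saturation, and the isotope measurements this package
accompanies are made at 2% O₂. The linearisation of Vp at small Cm, in
series with the mesophyll conductance, yields the closed-form initial slope
dA/dCi = gm·Vpmax/(gm·Kp + Vpmax); the bundle-sheath leak term gbs·Cm adds
< 0.2% to the slope at the default gbs and is neglected in the closed form.

Parameter defaults (every run records its parameter set):

| parameter | default | units | provenance |
| --- | --- | --- | --- |
| Vpmax | 250 | µmol m⁻² s⁻¹ | slope-relation value used throughout |
| Kp | 82 | µbar | slope-relation value used throughout |
| Vpr | 80 | µmol m⁻² s⁻¹ | standard C4-model literature value |
| Vcmax | 42 | µmol m⁻² s⁻¹ | chosen so A_max ≈ 41, the magnitude of young *Setaria* leaves |
| gbs | 0.003 | mol m⁻² s⁻¹ bar⁻¹ | standard C4-model literature value |
| Rd, Rm | 1.0, 0.5 | µmol m⁻² s⁻¹ | typical day respiration; Rm = Rd/2 |

`solve_A_from_Ci` finds the fixed point gm·(Ci − Cm) = A(Cm) by bracketed
Brent root-finding on Cm ∈ [0, Ci + (Rd+1)/gm + 1] (xtol 1e-13) and verifies
the residual to 1e-9 µmol m⁻² s⁻¹, relaxed proportionally only when machine
precision of Cm limits the attainable residual at extreme gm. Limitation
regimes are resolved by taking the minimum rate. Because the printed slope
relation has no mesophyll-respiration term, Rm defaults to 0 in slope
comparisons (the model exposes it).

Below the CO₂ compensation point A is negative and a larger gm speeds
respiratory efflux, so monotonicity of A in gm holds only where A ≥ 0; tests
assert it there.

## Initial-slope fitting (`aci`)

Ordinary (unweighted) least squares of A on Ci over records with
Ci ≤ ci_max. The default window ci_max = 60 µbar keeps PEPC well inside its
quasi-linear regime (Kp = 82 µbar): on noiseless synthetic curves the
curvature bias at this window is ~1–2%, and it shrinks monotonically as the
window tightens. A_max is the mean A over records whose Ca exceeds a
plateau fraction (default 0.9) of the largest setpoint. Mole fractions
(ppm) convert to partial pressures via Patm; a missing Patm column means
exactly 1 bar and is logged.

The record validator allows Ci to exceed Ca by 5% plus 15 µbar: near-zero
Ca the respiratory efflux legitimately makes Ci > Ca.

## ¹⁸O discrimination and g_m (`isoflux`)

Observed discrimination uses the open-chamber mass balance with
ξ = Ce/(Ce − Co):

    Δ_obs = ξ(δ_o − δ_e) / (1 + δ_o − ξ(δ_o − δ_e))

The ternary (transpiration) correction, on by default, converts the
wet-basis outlet CO₂ to the dry-air basis of the inlet,
Co_dry = Co·(1 + E·s/u), before forming ξ; the full ternary algebra of the
underlying gas-exchange theory is not reproduced.

The CO₂ at the exchange site is located by inverting

    Δ_obs = ā + (Cm/(Ca − Cm))·Δ_ea

where ā = 8.8‰ is the diffusional fractionation of C¹⁸O¹⁶O in air
(boundary-layer weighting neglected at chamber flow rates) and Δ_ea is the
exact-ratio enrichment of CO₂ equilibrated with evaporating-site water over
chamber CO₂. Leaf water is taken from measured chamber vapor assuming
liquid–vapor equilibrium at Tleaf (Majoube-type fractionation, 9.3‰ at
25 °C); a Craig–Gordon evaporative-enrichment option is deliberately not
modelled — with it off the evaporating-site enrichment is understated,
which is conservative for the retro-diffusion signal. The CO₂–water ¹⁸O
equilibrium fractionation is the rational form ε_w(T) = 17604/T − 17.93‰
(41.1‰ at 25 °C); coefficients are configurable. VSMOW and VPDB-CO₂ scales
interconvert through a single configurable ratio factor 1.04143. All delta
arithmetic is exact ratio products; the additive approximation would err by
~0.1–0.4‰ at these enrichments and is never used.

Finally g_m = A/(Ci − Cm). In `ca_limited` mode the full-equilibrium
estimate is corrected for finite CA as a series resistance,

    1/g_m = 1/g_m,eq − 3/k_CA

(the factor 3 from the three oxygen positions exchanged per hydration
cycle). This is an approximation to a full finite-equilibration treatment
and the results' metadata always names the variant used. It diverges as
g_m,eq → k_CA/3 (the equilibrium assumption has then absorbed the entire CA
resistance), which is reported as an error. At the leaf value
k_CA = 6.5 mol m⁻² s⁻¹ bar⁻¹ the correction inflates the four genotype-level
estimates {0.42, 0.46, 0.55, 0.59} by 1.24–1.37-fold (mean ≈ 1.31) without
reordering them.

Averaging: each reading is inverted separately and the per-reading g_m
values are averaged (mean ± SE); inverting the mean record is available by
flag and is less exposed to the convexity of 1/(Ci − Cm) under noise.

## Stopped-flow permeability (`permeability`)

CO₂ entry into a spherical cell with excess intracellular CA and buffering
produces a surface-limited single-exponential fluorescence quench,
F(t) = baseline + amplitude·e^(−kt), fitted by nonlinear least squares
(log-linear initialisation, amplitude bounded positive) after a 5 ms
dead-time. The rate constant converts to permeability via the
surface-to-volume ratio of the spherical-equivalent cell,

    P_CO2 = k·d/6,

with an absolute-calibration scale factor (buffering capacity, gradient
normalisation) exposed in config and defaulting to 1; generator and
estimator share it, so recovery tests are scale-consistent by construction.
Fits are rejected as signal-free when the amplitude is under 5 residual
standard deviations or when less than one e-fold of decay lies inside the
acquisition window (k, amplitude and baseline are then degenerate). At the
study operating point (P = 1.5×10⁻⁴ m s⁻¹, d = 4.63 µm) k = 194.4 s⁻¹, so a
0.2 s acquisition spans ~39 e-folds and the tail pins the baseline.

## Freeze–thaw survival (`growth`)

Growth curves are log-transformed with a positive floor (default 0.001 OD)
guarding blank wells, anchored by subtracting the t = 0 log-OD so the
integral measures cumulative growth (identical curves then give exactly
100%), and trapezoid-integrated from time zero to the untreated control's
stationary onset. Onset is the first time at or after the rolling-slope
maximum where the slope of the log curve falls below slope_eps
(default 0.01 h⁻¹ over a 2 h window); a curve that never grew returns the
first window end, a curve that never plateaus is an error. %AUC =
100·AUC(treated)/AUC(untreated); values above 100% are preserved. Raw-OD
integration is available by flag. Treated/untreated pairing is always
explicit (a pair_id column or a well mapping), never positional.

## Synthetic data (`simulate`)

One integer seed drives every generator through deterministic per-channel
substreams; fixed seed means byte-identical CSVs. Environmental defaults
reproduce the measurement conditions: 380 µmol mol⁻¹ reference CO₂, 25 °C,
2% O₂, 1500 µmol m⁻² s⁻¹, 55% RH, 10 isotope readings per leaf, 0.2 s
stopped-flow windows, 10-min plate sampling over 30 h.

* **A–Ci curves** step Ca over 0–1600 ppm (19 setpoints) under a constant
  stomatal conductance (gsw = 0.3 mol m⁻² s⁻¹; stomata did not differ
  between the genotypes this emulates), solve the coupled model at each
  step, and add Gaussian noise σ_A (default 0.2 µmol m⁻² s⁻¹).
* **Isotope batches** place the leaf at the ambient operating point, locate
  the isotopic exchange site at the true Cm (full equilibrium) or at the
  apparent Cm of the effective conductance 1/(1/gm + 3/k_CA) (finite CA) —
  making the generator the exact inverse of the corresponding estimator —
  and solve the outlet δ self-consistently with the chamber mass balance
  (transpiration dilutes the outlet; the estimator's ternary toggle undoes
  it). Design values where the study is silent: chamber flow 150 µmol s⁻¹
  over 6 cm² of leaf (drawdown ≈ 160 ppm, ξ ≈ 3.4, as coupled-TDL
  protocols use to tame noise amplification by ξ), inlet CO₂ δ¹⁸O = −30‰
  VPDB-CO₂ (depleted cylinder gas; its depletion relative to
  leaf-equilibrated CO₂ drives the retro-diffusion signal), chamber vapor
  −8‰ VSMOW (transpired source water at isotopic steady state). Per-reading
  noise: 0.3‰ on the outlet CO₂ δ (the inlet is a calibrated reference),
  0.1‰ on vapor δ, 0.2 µmol m⁻² s⁻¹ on A. Under these conditions the
  recovered-g_m SEs (~0.015–0.03 over 10 readings) sit at the low end of
  leaf-level SEs reported for this kind of measurement, and the convexity
  bias of per-reading inversion is well under one SE.
* **Stopped-flow traces** are exponential quenches with multiplicative
  Gaussian noise (σ_F = 1%).
* **Growth pairs**: the untreated well grows logistically (r = 0.45 h⁻¹,
  K = 1.2 OD, od₀ = 0.02); freeze–thaw kills all but a survival fraction of
  the inoculum, and because dead cells still scatter light the treated well
  starts at the same OD with only the viable fraction growing — a longer
  effective lag. Additive OD noise, readings clipped at zero.

What the generators do **not** emulate: instrument drift and TDL
calibration cycles, chamber leaks, boundary-layer heterogeneity, leaf-water
isotopic gradients (Péclet effects), cell-size dispersion in the stopped
flow, and death or clumping during plate growth. Passing recovery tests
therefore demonstrates correctness of the inference chain under its own
stated noise model, not robustness to every artefact of real instruments.

## Numerical choices

Brent bracketed root-finding everywhere a scalar balance is solved
(mesophyll fixed point, stomatal operating point), xtol 1e-12 to 1e-13;
outlet-δ fixed-point iteration to 1e-16 (converges in a handful of steps);
OLS through statsmodels; exponential fits through scipy curve_fit with
analytic initialisation. Ties between limitation regimes take the minimum
rate. Degenerate inputs (flat traces, absent plateaus, discrimination below
the diffusional floor, Cm outside (0, Ca)) raise named errors or flag the
record rather than returning numbers; batch estimators count and report
exclusions.

Problem sizes used in the validation suite — 10-reading isotope batches,
100-trace stopped-flow ensembles, 100–200-replicate slope simulations —
match the corresponding measurement protocols (10 readings per leaf, ~75
injections per line) and give sub-minute runtimes.

## Known limitations

* The CA-limited correction is a series-resistance stand-in, not a full
  finite-equilibration model; its mean inflation (≈1.31 over the four
  genotype values) is slightly above the ≈1.25 a full treatment reports.
* Evaporating-site water is taken at vapor–liquid equilibrium; ignoring
  evaporative enrichment understates Δ_ea and correspondingly inflates the
  noise sensitivity of the inversion.
* Absolute permeabilities depend on the configured calibration scale; only
  relative comparisons across lines are calibration-free.
* The C4 model's light-limited branch and temperature responses of kinetic
  constants are out of scope; all parameters are 25 °C values.
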