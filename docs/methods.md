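# Methods

`cardiorenal` simulates an integrated heart–kidney system: beat-resolved
ventricular mechanics and a lumped systemic/pulmonary circulation, coupled
to renal sodium/water homeostasis and neurohormonal feedback, with
stress-driven growth of the left-ventricular myocytes. This note documents
the model, its assumptions, the calibration, and the limits of what the
package's tests demonstrate.

## Ventricular mechanics (fast timescale)

Each ventricle is a thick-walled sphere of contractile tissue carried by a
single representative myofiber. Chamber pressure follows from fiber stress
σ_f and the radial matrix stress σ_m,r through

    P = (1/3) (σ_f − 2 σ_m,r) ln(1 + V_w / V_cav),

with wall volume V_w and instantaneous cavity volume V_cav. σ_m,r is taken
proportional to chamber pressure, σ_m,r = −w_r·P with a small calibrated
weight (w_r = 0.045): a compressive radial stress that slightly amplifies
the pressure generated at a given fiber stress. Fiber natural strain is
ε_f = (1/3)·ln((V_cav + V_w/3)/(V_cav0 + V_w/3)) and sarcomere length
l_s = l_ref·exp(ε_f) with l_ref = 2.0 μm at the unloaded cavity volume.

Active stress is σ_a0 · f_len(l_s) · f_time(t) · f_vel(dl_s/dt):

* f_len — piecewise linear from a zero-force length of 1.55 μm (actin
  overlap bound; fixed, not fitted) to saturation at 2.33 μm;
* f_time — a sine-squared rise/decay twitch whose duration scales with the
  square root of cycle length; the peak sits late in systole
  (t_peak_frac ≈ 0.93), which is what lets the pressure maximum occur at
  mid-ejection cavity volumes and reconciles peak fiber stress with peak
  chamber pressure at the baseline operating point;
* f_vel — linear force–velocity factor with v_max ≈ 15 μm/s, evaluated on a
  10 ms low-pass-filtered shortening velocity to keep the beat ODE explicit.

The product is passed through a graded contractile-reserve saturation:
linear up to a knee of 50 kPa, then tanh-saturating toward a maximal active
tension of 58 kPa. Baseline peak active stress is 48.7 kPa, so the ceiling
never acts at baseline; under overload it is what makes stroke volume fall,
which in turn drives the renal retention that raises filling pressures.
Both ceiling parameters are calibrated so severe pressure overload produces
the clinically observed phenotype (elevated end-diastolic and peak systolic
pressures with reduced but preserved ejection).

Passive stress is exponential in sarcomere extension beyond the unloaded
length, σ_p = c_p (e^{k_p (l_s − 2.0)} − 1), zero at and below it.

## Circulation

Seven compartments in a closed loop — LV, systemic arterial, peripheral,
venous, RV, pulmonary arterial, pulmonary venous — each passive bed with a
linear pressure–volume relation P = (V − V0)/C (negative pressures
permitted; no collapse law). Flows are Ohmic, with inertance on the two
arterial outflows (dQ/dt = (ΔP − RQ)/I). Valves are ideal diodes switched
algebraically; the mitral valve may carry back-leak when the reverse
pressure difference exceeds a threshold ΔP_leak, which is how mitral
regurgitation is imposed (the threshold is ramped down over a scenario).
Aortic stenosis is a multiplier on the lumped valve/large-artery resistance
R_art upstream of the arterial compartment; because the pulsatile ejection
flow is several times the mean flow, baseline R_art ≈ 0.95 mmHg·min/L
already yields a ~22 mmHg peak valve gradient (LV peak pressure 134 vs
systolic arterial pressure 113).

The beat state (7 volumes, 2 inertial flows, 2 velocity filters) is
integrated by a fixed-step RK4 kernel (default 1 ms), compiled with numba;
a simulated year integrates on the order of 10^5 beats. Beats are strictly
periodic at 60/HR s; end diastole is sampled at activation onset (no atria
exist, and passive filling has ceased by then).

## Kidney and body fluids (hours–days)

The renal vasculature is a series network (preafferent, afferent, efferent,
peritubular/venous) perfused by MAP against the systemic venous pressure.
At the baseline operating point (MAP 81.3 mmHg) the segment resistances
give RBF 1 L/min, glomerular pressure 60 mmHg and peritubular pressure
~16 mmHg; the filtration coefficient is derived so GFR = K_f(P_gc − P_bow −
π_gc) = 100 mL/min there. All derived constants are computed from the
parameter set, so the baseline closes exactly: with every signal at 1,
excretion equals intake by construction.

The nephron is three lumped segments: proximal tubule (70% Na reabsorption,
isotonic water), loop+distal (80% of the remainder, macula densa at its
exit), and connecting/collecting (fraction derived to balance intake).
Effect multipliers are bounded normalized sigmoids, 1 at setpoint: AT1-bound
AngII stimulates proximal reabsorption and constricts the renal arterioles
(efferent most strongly); mineralocorticoid-receptor occupancy and the
pressure-natriuresis signal act on the collecting segment, ANP opposes it;
vasopressin scales collecting-duct water reabsorption.

The pressure-natriuresis driver is the renal interstitial hydrostatic
pressure, modeled as linear in the peritubular capillary pressure computed
at the arterial-side operating point (reference venous pressure) plus a
distal-flow term. Taking the pressure input on the arterial side is a
deliberate structural choice: it keeps long-term arterial pressure
kidney-determined, so a pure heart-rate reduction is compensated by fluid
retention that restores MAP (raising filling volume and ED stress), while
venous congestion still acts retentively through reduced RBF/GFR. With a
venous-referenced driver, congestion becomes directly natriuretic and the
heart-rate arm settles several mmHg low instead.

Whole-body balances: d(Na)/dt = intake − excretion, d(ECF)/dt = intake −
urine; blood volume follows a linear monotone compliance partition,
V_b = 4.95 L + 0.25·ΔECF (a quarter of retained extracellular fluid stays
intravascular), interstitial volume takes the rest. Plasma Na is body Na
over ECF volume.

## Neurohormones

All hormone levels are dimensionless, normalized to baseline = 1; only
relative changes are meaningful. Renin secretion falls with macula densa Na
flow and is strongly disinhibited as AT1-bound AngII falls
(exp(4.5·(1−AT1)), capped at 20×); this makes the closed-loop map from
secretion inhibition to plasma renin activity strongly compensating — a 90%
secretion block yields roughly a 35–40% PRA reduction. The
angiotensin chain is a unity-gain linear cascade; AT1 binding scales with
the unblocked receptor fraction, so AT1 blockade lowers bound AngII even as
renin rises several-fold. Aldosterone rises with AT1-bound AngII and drives
a saturating mineralocorticoid-receptor occupancy. ANP is driven by LV EDP
(the model has no atria to provide an atrial stretch signal) and acts only
on tubular sodium reabsorption. Vasopressin is a steep sigmoid of plasma
Na. Hormones are held at their quasi-steady values at each macro-step —
their half-lives (minutes) are far below the macro step — with the explicit
first-order kinetics available for sub-macro-step work. Whole-body flow
autoregulation is a finite-gain proportional controller on peripheral
resistance, multiplier (CO/CO_set)^1.5 with a 12 h relaxation.

## Multi-rate engine

Each macro-step (default 90 min; year-long experiments in the tests and the
reproduction script use 2–4 h, which the halving check shows is converged
to <1%): (1) simulate beats to beat-to-beat periodicity at the current slow
state; (2) freeze the per-beat summary (MAP, venous pressure, EDP, CO, peak
and ED fiber stress); (3) solve the renal/hormonal operating point and
advance the slow states (body Na, ECF, autoregulation multiplier, myocyte
increments ΔD and ΔL) in sub-steps; (4) re-derive the beat parameters (LV
wall volume and unloaded cavity volume from the myocyte geometry, blood
volume target, scheduled interventions). The renal blood volume feeds back
into the circulation through the venous compartment, which relaxes at
1/min toward V_ven,target = V_b − Σ(other compartments).

Breakdown (EF collapse, non-physical volumes, loss of renal perfusion
pressure) terminates a run with a flagged status; these "physiologically
untenable" endpoints are legitimate, reportable outcomes of the overload
experiments.

## Remodeling (months)

Myocytes are cylinders; LV wall volume is myocyte volume plus fixed
interstitium (26.4 mL) and fibrosis (4.8 mL). Baseline diameter is derived
from wall volume, count and length (17.26 μm — the printed 23.3 μm is
inconsistent with the other published geometry values and is available as
an override). Peak systolic fiber stress above its 49.2 kPa setpoint grows
diameter at K_d0 = 43.8 μm/yr (shrinkage below setpoint at full rate, with
a configurable floor at −50% of baseline); ED fiber stress above 4.5 kPa
grows length at K_l0 = 17.5 μm/yr (one-way ratchet). Both rates taper
linearly to zero as the increments approach their caps (25 and 115 μm).
Lengthening dilates the unloaded cavity volume by the cube of relative
myocyte length. LV mass is wall volume × 1.05 g/mL; LVMI uses a 1.8 m²
body surface area. The right ventricle does not remodel.

Because the growth law has no dead band, baseline stationarity requires the
calibrated baseline peak stress to equal the setpoint almost exactly; the
calibration pins it to 49.200 kPa at ~1e-6 relative, giving <0.01% LV-mass
drift per simulated year.

## Calibration

Supplementary-level constants are recalibrated, not copied. Stage 1 is a
weighted least squares over the 13 free beat-level parameters against the
normal operating point (113/71 arterial, LV 140/8.3, EDV/ESV 103/32, mean
PA 12.7, MAP ≈ 84, peak/ED fiber stress 49.2/4.3 kPa) —
`scripts/calibrate_baseline.py`. Stage 2 is a Newton polish of
(σ_a0, c_p, V0_ven, t_sys) onto (σ_peak, EDP, EDV, ESV) exactly, with
secant trims of the pulmonary resistance (mean PA) and R_art (PSP). The
shipped defaults land every Table-level quantity within its band: 112.6/69.0
arterial, PSP 134.3, EDP 8.35, EF 69.1%, CO 5.0, mean PA 12.70, TPR 16.3,
σ_peak 49.2000, σ_ED 4.232 kPa; GFR 100, RBF 1000, blood volume 4.95 L and
ISF 12 L close by construction. PSP is the one compromised quantity (−4%):
with σ_peak pinned at 49.2 kPa, the pressure law bounds the achievable peak
pressure through the cavity volume at the stress peak.

Renal/hormonal gains were calibrated on a panel of stated behaviors:
doubling Na intake raises MAP < 5 mmHg; 90% renin-secretion inhibition
reduces PRA ≈ 35–40%; AT1 blockade and (heart-rate + renin-inhibition)
produce matched chronic MAP reductions; heart-rate reduction alone is
volume-compensated back to baseline MAP.

## What the experiments show (and don't)

The packaged experiments reproduce the qualitative physiology: severe
stenosis without remodeling retains sodium monotonically into an untenable
high-EDP state; diameter-only growth renormalizes peak stress and restores
sodium balance (at its own convergence horizon, ~2.5 years for the 3×
ramp); length-only growth is maladaptive under pressure overload and enters
a runaway (thinning wall, falling stroke volume, venous congestion) under
regurgitation; combined growth preserves ejection fraction relative to
length-only. On the hypertensive LVH patient, AT1 blockade and the
beta-blocker surrogate produce matched MAP reductions but strictly larger
mass regression for AT1 blockade, because heart-rate lowering is
volume-compensated and raises filling volume and both fiber stresses.

The one-year overload magnitudes are smaller than the reference values the
reproduction script is compared against (diameter ~30% vs 75%; length ~2%
vs 25% and 70%): integrating the growth laws at their published rate
constants over a single year cannot produce those magnitudes unless the
stress ratios sit far above setpoint for the entire year, which the ramped
scenarios (and the reference hemodynamic endpoints themselves) do not
support; the quantities are reported as computed.

The model is a single representative virtual patient. It contains no
fibrosis-driven stiffening, no atria, no sympathetic dynamics beyond the
heart-rate/renin effects, no potassium/urea/acid-base, and spherical LV
geometry (internal diameters are overestimated at matched volumes). Growth
is purely stress-driven with constant tissue properties, so regression
under therapy is symmetric with growth, which likely overstates how fast
mass regresses. Numerical choices: beat RK4 at 1 ms with hard diode
switching; renal operating point by damped fixed-point iteration (tol
1e-11); RAAS fixed point by bracketed root finding; slow states by
sub-stepped explicit updates with fluxes frozen per macro-step (halving the
macro-step changes year-end remodeling outputs by <0.5%).
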