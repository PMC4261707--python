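# Methods

## Model structure and assumptions

The kidney's proximal tubules are represented as a single lumped chain of
nine well-mixed compartments: six equal proximal convoluted sub-segments
(PCT1–6, total volume VCTX·VPTC·VPCTC = 0.216 × 0.3 × 0.7 L ≈ 45 mL)
followed by three equal proximal straight sub-segments (PST1–3, the
remaining 30% of proximal-tubule volume), a fixed-volume urinary bladder
(0.2 L) and a cumulative urine collector. Plasma glucose and plasma
inhibitor concentration are *forcings*: reabsorbed glucose goes to
accumulator compartments, never back to plasma, so there is no
glucose–insulin feedback. This is the right regime for clamped-glucose
experiments and for fasting normoglycemia, and it is what makes the
transporter arithmetic clean; it is wrong for scenarios where glucosuria
itself moves glycemia.

Water handling is prescribed, not simulated: every sub-segment reabsorbs
the same fraction of filtered water, giving outflows Q_i = (1 − 0.074·i)·GFR.
The registry's flow scheme quotes both "0.333·GFR" for the last segment
and per-segment decrements of 0.074; these disagree by 0.001·GFR
(1 − 9·0.074 = 0.334). We use the self-consistent decrement form
everywhere; the discrepancy is ~0.3% on the final flow and far below
other uncertainties. Luminal solute transport is advective only
(flux = flow × upstream concentration); axial diffusion is neglected.

Reabsorption kinetics are Michaelis–Menten per sub-segment, with each
transporter's whole-kidney capacity split uniformly across its host
segments (V_max2/6 per PCT, V_max1/3 per PST). Competitive inhibition
scales the apparent K_m by (1 + C_drug/K_i) using the *luminal* drug
concentration of the same sub-segment. The inhibitor is filtered in its
unbound fraction (f_up·GFR·C_plasma) and is not reabsorbed, so at steady
state it simply concentrates ~3× along the tubule as water is removed —
which is why luminal exposure at the SGLT2 site exceeds f_up·C_plasma
even though the drug is highly bound.

The bladder has a volumetric imbalance by construction (inflow ≈
0.334·GFR ≈ 2.2 L/h versus urine outflow KX ≈ 0.6 L/h): the unmodeled
distal nephron reclaims that water. The bladder is therefore treated as a
fixed-volume, well-mixed solute buffer: d(amount)/dt = Q9·C9 − KX·C_UB.
Its solute time constant (V_X/KX ≈ 20 min) is what delays urine
collection relative to tubular outflow in stepped protocols.

## Solvers

*ODE path.* The 26-state mass-balance system (9 glucose + 9 drug segment
amounts, bladder, cumulative urine/reabsorbed/filtered accumulators) is
integrated with LSODA, rtol 1e−8, atol 1e−10 mmol. Negative-state
clipping is deliberately absent — tolerances are chosen so trajectories
stay non-negative, and the simulator raises if a state dips below −1e−7.
Integration restarts at forcing discontinuities (clamp step edges).
Glucose and drug mass balance (filtered = Δcontent + urine + reabsorbed)
is verified on every run to 1e−6 relative error.

*Analytic steady state.* Under constant forcing the chain solves
sequentially: each sub-segment's concentration is the positive root of
Q·C² + (Q·K_app + V_max,seg − L_in)·C − L_in·K_app = 0, evaluated in the
numerically stable form 2·L_in·K_app/(b + √(b² + 4·Q·L_in·K_app)) when
b ≥ 0 so that C → 0 cleanly as the load vanishes. This solver is an
independent oracle for the ODE path: the test suite checks agreement to
0.1% per segment across a glucose (50–600 mg/dL) × drug (0–10⁴ nM) grid,
and it also provides initial conditions for simulations ("start at the
steady state of the forcing at t0"), which removes burn-in transients.

## Parameters

Defaults live in `src/sgltsim/data/parameters.json`:

| parameter | value | note |
|---|---|---|
| V_max1 | 20 mmol/h | SGLT1 capacity, shared healthy/T2DM |
| V_max2 | 93.5 / 110 mmol/h | SGLT2 capacity, healthy / T2DM (disease upregulation) |
| K_m1, K_m2 | 0.5, 4.0 mM | glucose affinity, SGLT1 / SGLT2 |
| GFR | protocol-specific | healthy clamp arms span 5.66–7.38 L/h; midpoints used by default |
| KX | 0.6 L/h | bladder outflow for clamp emulations |
| dapagliflozin | MW 409, f_up 0.07, K_i1 400 nM, K_i2 0.3 nM | |
| canagliflozin | MW 454, f_up 0.01, K_i1 200 nM, K_i2 0.6 nM | |

Unit conventions: mg/dL at interfaces, mM internally (glucose MW 180.16
g/mol); ng/mL ↔ nM for drugs via each compound's MW; clamp steps default
to 40 min (a 100→350 mg/dL escalation in six steps over 4 h).

## Drug forcing

Two interchangeable sources feed the plasma-inhibitor forcing: a
closed-form two-compartment model with first-order oral absorption
(ka default 1.0 h⁻¹ — an assumption, as only the fitting procedure, not
the disposition estimates, is reproducible from public sources) and
multiple-dose superposition; or a piecewise-linear empirical profile with
flat edge extrapolation. The shipped dapagliflozin day-7 profile is a
clearly labelled **synthetic stand-in** (the trial's mean PK is not
publicly tabulated); it is used for qualitative drug-arm demonstrations
only and never for quantitative targets.

## Synthetic daily glucose profile

The loss-of-function experiments need a normoglycemic 24-h input. The
generator places three post-meal raised-cosine excursions (default meals
at 07:30, 12:30, 18:30, 4-h width, seeded jitter of ±30 min and 15% in
relative amplitude) on a nocturnal floor, then fixes the floor and gain
so the time-weighted mean is exactly 90 mg/dL with the range inside
80–125 mg/dL. It emulates the *constraints* of a healthy mean profile,
not any measured trace — real profiles have dawn phenomena, asymmetric
meal responses and day-to-day variability. Daily-UGE results that depend
on the profile's shape (most strongly the 50%-SGLT2-loss case, which
sits on the splay of the titration curve) are therefore approximate by
construction; complete-loss cases are insensitive to the shape because
the relevant transporter is either absent or saturated.

## Calibration

`calibrate()` estimates (V_max1, V_max2,T2DM, the healthy-to-diabetic
V_max2 proportion, K_m1, K_m2, K_i2) from step-wise clamp UGE tables by
bounded least squares (SciPy trf) from literature starting points
(V_max1 14, V_max2 126 mmol/h, proportion 1.0, K_m1 1.8 mM, K_m2 4.9 mM,
K_i2 6 nM), with optional seeded multi-start. Records whose actual
glucose deviates ≥25% from the group mean are excluded up front, and the
fit is restricted to 100–400 mg/dL.

Design choices worth flagging:

* **Quasi-steady forward model.** Per-step UGE is predicted as the
  analytic steady-state excretion rate at the step's actual glucose ×
  step duration, accounted at bladder inflow. Tubule transit (~1 min) is
  negligible against 40-min steps; the synthetic-data generator uses the
  same accounting, so generator and estimator see the same model and the
  recovery study measures estimation error, not discretisation error.
  The cost drops from an ODE solve to nine quadratics per record.
* **Relative weighting by default.** The assumed observation noise is
  multiplicative lognormal (UGE is positive and right-skewed), for which
  residuals scaled by the observation are the matched choice. Unit
  weights on grams are available by flag but let the high-glucose steps
  (tens of grams) drown the threshold-region steps that carry all the
  K_m information; in recovery simulations at 5% noise they degrade K_m1
  recovery by roughly a factor of seven.
* **Structural identifiability guard.** Without any inhibited arm, K_i2
  does not enter the model: it is dropped from the free set and flagged,
  along with a warning that V_max1/V_max2 separation degrades (the two
  capacities are separable only because the data include arms with and
  without SGLT2 perturbation).

Recovery on noise-free 4-arm synthetic data is exact (all parameters
within 2%, typically to machine precision). At 5% multiplicative noise
(20-seed study), medians are ~6%/3%/0.4%/11%/11% for V_max1 / V_max2 /
proportion / K_m1 / K_m2 — but K_i2 recovers only to ~50% median. That is
a property of the experiment, not the estimator: at clinically realistic
inhibitor exposure the luminal drug level (tens of nM) is two orders of
magnitude above K_i2 (0.3 nM), so the data constrain the inhibition
*strength* K_m2·C_drug/K_i2 through a residual-SGLT2 term worth only a
few percent of UGE. A Fisher-information (Cramér–Rao) analysis at the
truth gives a lower bound of ~62% CV for K_i2 under these conditions —
no estimator can do materially better, and the corresponding acceptance
test documents this by failing. Point-estimate K_i2 from a single such
study should be treated as order-of-magnitude.

## Numerical and reporting conventions

* SGLT2 occupancy is C_drug/(C_drug + K_i2) averaged over the PCT
  sub-segments using luminal concentration (the site of competition); a
  plasma-based convention is available by flag.
* Transporter shares and efficiencies are window integrals of the exact
  cumulative accumulators, not trapezoid sums of sampled rates.
* Zero total reabsorption makes shares undefined; the report flags the
  window rather than inventing a number.
* Daily simulations use a 6-min output grid over 24 h and start from the
  analytic steady state of the profile at midnight (the nocturnal floor,
  effectively the periodic state); clamp simulations restart the
  integrator at step edges.
* Loss-of-function scans reuse the intact run as the f = 0 reference;
  "reduction" is 1 − reabsorbed/reabsorbed_intact over the same window.

## Known limitations

* No glucose–insulin feedback, no distal-nephron transport, and no
  hydrodynamic response of urine flow to luminal glucose — predictions
  above ~400 mg/dL plasma glucose underestimate excretion in inhibited
  states for this reason.
* The nine-segment discretisation is a modeling grain, not anatomy;
  per-segment concentrations are averages over substantial tubule
  populations.
* Transporter kinetics are assumed identical across nephrons and
  constant in time; disease and drug effects enter only through V_max2.
* The bladder's fixed-volume treatment distorts sub-20-minute dynamics
  of urine appearance; per-step UGE at 40-min resolution is insensitive
  to it.
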