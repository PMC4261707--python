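# sgltsim

A systems pharmacology model of renal glucose reabsorption in humans,
focused on the two sodium–glucose cotransporters of the proximal tubule:
SGLT2 (low affinity, high capacity, early convoluted segments) and SGLT1
(high affinity, low capacity, late straight segments), with competitive
inhibition by SGLT2 inhibitors such as dapagliflozin and canagliflozin.

The package is aimed at quantitative pharmacologists and renal
physiologists who want to ask mechanistic "what-if" questions that static
threshold/splay formulas cannot answer: how the reabsorption burden splits
between the two transporters as glycemia rises, how much glucosuria a
partial or complete loss of transporter function produces, why potent
SGLT2 inhibitors only suppress 30–50% of reabsorption clinically (SGLT1
compensation plus residual SGLT2 activity), and whether a dual SGLT1/2
inhibitor would do better.

## Model

Glomerular filtrate enters a chain of nine well-mixed sub-segments — six
equal proximal convoluted (PCT1–6) and three equal proximal straight
(PST1–3) — then a urinary bladder compartment and a urine collector.
Water reabsorption is uniform along the tubule, so the luminal flow
leaving sub-segment *i* is

    Q_i = (1 − 0.074 · i) · GFR ,  i = 1 … 9,

falling from 0.926·GFR to about one third of GFR (two thirds of filtered
water reclaimed by the end of the proximal tubule). In each sub-segment
glucose is reabsorbed by a Michaelis–Menten process,

    R_j = V_max,j · C_glu,j / (K_m + C_glu,j),

with V_max2 split uniformly over the PCT sub-segments and V_max1 over the
PST sub-segments. A filtered inhibitor (only the unbound fraction f_up
passes the glomerulus) travels the lumen without being reabsorbed and
competes with glucose:

    R*_j = V_max,j · C_glu,j / (K_m · (1 + C_drug,j / K_i) + C_glu,j).

Reabsorbed mass is routed to accumulator compartments rather than back to
plasma, which is appropriate for clamped-glucose experiments. Default
parameters ship in a JSON registry: V_max1 = 20 mmol/h, V_max2 = 93.5
(healthy) / 110 (T2DM) mmol/h, K_m1 = 0.5 mM, K_m2 = 4 mM; dapagliflozin
MW 409, f_up 0.07, K_i1 400 nM, K_i2 0.3 nM; canagliflozin MW 454, f_up
0.01, K_i1 200 nM, K_i2 0.6 nM.

Two solvers cross-check each other: a stiff ODE integrator for arbitrary
time-varying forcing, and an analytic steady-state solver for clamped
conditions that walks the tubule solving one quadratic per sub-segment.
The library also provides clamp/daily-profile protocol builders, a
two-compartment PK model plus empirical-profile interpolation for the
inhibitor forcing, transporter contribution/efficiency/occupancy reports,
loss-of-function and sensitivity scans, and a calibration module that
estimates the kinetic parameters from step-wise urinary glucose excretion
(UGE) tables, validated by parameter recovery on synthetic data.

## Worked example

Steady state in a healthy subject clamped at 100 mg/dL plasma glucose,
GFR 6.5 L/h:

```sh
sgltsim steady-state --subject healthy --glucose 100 --gfr 6.5 --out out/
```

```json
{
  "plasma_glucose_mgdl": 100.0,
  "gfr_L_per_h": 6.5,
  "filtered_mmol_per_h": 36.08,
  "sglt1_mmol_per_h": 2.67,
  "sglt2_mmol_per_h": 33.39,
  "uge_mmol_per_h": 0.017,
  "sglt1_share": 0.074,
  "sglt2_share": 0.926,
  "sglt1_efficiency": 0.134,
  "sglt2_efficiency": 0.357
}
```

(Values abridged/rounded.) Of 36 mmol/h of filtered glucose essentially
all is reclaimed — urinary loss is 0.017 mmol/h — with SGLT2 carrying
~93% of the work while running at only ~36% of its capacity and SGLT1
mopping up the remainder at ~13% of its capacity. The same library call
is `steady_state_profile()`; the equivalent loss-of-function experiment
from Python:

```python
import sgltsim as s

profile = s.synth_daily_glucose_profile(90, 80, 125, seed=1)  # mg/dL
phys = s.physiology_defaults(gfr=7.4)
healthy = s.transporter_params("healthy")
scan = s.loss_of_function_scan("sglt2", [0, 0.5, 1.0], profile, phys, healthy)
print(scan)
#    fraction_lost  uge_g_per_day  reabsorbed_mmol_per_day  reabsorption_reduction_pct
# 0            0.0           0.18                    886.2                        0.00
# 1            0.5           4.01                    831.2                        6.21
# 2            1.0          78.70                    450.4                       49.18
```

A normoglycemic subject spills essentially no glucose; losing half of
SGLT2 capacity produces ~4 g/day of glucosuria, and a complete loss —
the familial-renal-glucosuria limit, and the theoretical ceiling for an
SGLT2 inhibitor — produces ~79 g/day while total reabsorption falls by
only ~49%, because SGLT1 compensates downstream.

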