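# Reference human parameterization of the granulopoiesis model.
#
# Provenance: physiological constants (transition times, half-lives,
# steady-state counts, filgrastim kinetics, endogenous G-CSF level) are
# documented plausible human values from standard haematology/PK
# literature ranges; chemotherapy toxicity constants are model-scale
# values chosen once so that a CHOP-like regimen without G-CSF produces a
# leukocyte nadir of ~1-2 x10^3/µL around day 10-12 with recovery within
# the cycle.  Units are stated per field; see granulosim.params.
cell:
  T_S: 2.5            # stem-cell turnover time [d]
  T_CG: 3.0           # committed progenitor transit time [d]
  T_PGB: 3.5          # proliferating precursor transit time [d]
  T_MGB: 6.0          # postmitotic maturation time [d] (~metamyelocyte->band)
  T_GRA_hours: 7.0    # circulating granulocyte half-life [h]
  mgb_survival: 0.8   # fraction surviving postmitotic apoptosis
  self_renewal_slope: 0.8   # stem-cell self-renewal feedback slope
  p_min: 0.05
  p_max: 0.95
  GRA_ss: 4.4         # steady-state granulocytes [10^3/µL]
  LY_ss: 2.6          # steady-state lymphocytes [10^3/µL] -> WBC_ss = 7.0
  T_LY_rec: 25.0      # lymphocyte recovery time constant [d]

# Regulation curves: factor bounds, steepness; anchored to exactly 1 at
# the baseline signal (endogenous G-CSF serum level, or GRA_ss for the
# production curve).  The half-effect point is derived from the exact-1
# normalization (see RegulationCurve.half_effect).
regulation:
  A_PGB:            {fmin: 0.55, fmax: 2.6, hill: 0.8, increasing: true}
  T_PGB:            {fmin: 0.80, fmax: 1.6, hill: 0.8, increasing: true}
  T_MGB:            {fmin: 0.15, fmax: 1.3, hill: 1.0, increasing: false}
  MGB_survival:     {fmin: 0.70, fmax: 1.20, hill: 1.0, increasing: true}
  endog_production: {fmin: 0.05, fmax: 20.0, hill: 1.3, increasing: false}

gcsf_base_conc: 0.025   # endogenous serum G-CSF [µg/L] (~25 pg/mL)
body_weight_kg: 75.0
prednisone_halflife_multiplier: 1.6

# PK constants per derivative; endogenous G-CSF uses the filgrastim set.
gcsf:
  filgrastim:
    k_sc12: 2.5     # depot sub1 -> sub2 [1/d]
    k_sc2c: 2.5     # sub2 -> central [1/d]
    V_bio: 600.0    # MM bioavailability-loss capacity [µg/d]
    K_bio: 150.0    # MM bioavailability-loss constant [µg]
    V_d: 12.0       # central volume [L]
    k_cp: 0.4       # central -> peripheral (reversible binding) [1/d]
    k_pc: 1.2       # peripheral -> central [1/d]
    k_ren: 2.0      # renal first-order elimination [1/d]
    V_spec: 1.38    # granulocyte-mediated elimination capacity [µg/L/d per 10^3 cells/µL]
    K_spec: 2.0     # granulocyte-mediated MM constant [µg/L]
    potency: 1.0
  pegfilgrastim:    # slower absorption, marginal renal clearance
    k_sc12: 1.0
    k_sc2c: 1.0
    V_bio: 300.0
    K_bio: 300.0
    V_d: 12.0
    k_cp: 0.4
    k_pc: 1.2
    k_ren: 0.15     # pegylation suppresses renal elimination
    V_spec: 1.38
    K_spec: 2.0
    potency: 1.0

# Stage-specific kill intensities s_X [1/d at reference dose, unit chain
# scale], transit chain (n, k_tox), first-application excess, and the
# two-parameter lymphocyte pulse.
drugs:
  cyclophosphamide:
    {s_S: 0.08, s_CG: 0.45, s_PGB: 0.90, s_MGB: 0.06,
     n_transit: 3, k_tox: 0.40, f_first: 1.15, ref_dose: 750.0,
     dose_exponent: 1.0, ly_intensity: 0.08, ly_decay: 0.18}
  doxorubicin:
    {s_S: 0.05, s_CG: 0.30, s_PGB: 0.55, s_MGB: 0.04,
     n_transit: 3, k_tox: 0.40, f_first: 1.15, ref_dose: 50.0,
     dose_exponent: 1.0, ly_intensity: 0.05, ly_decay: 0.18}
  vincristine:
    {s_S: 0.015, s_CG: 0.10, s_PGB: 0.22, s_MGB: 0.01,
     n_transit: 3, k_tox: 0.45, f_first: 1.10, ref_dose: 1.4,
     dose_exponent: 1.0, ly_intensity: 0.03, ly_decay: 0.20}
  etoposide:
    {s_S: 0.05, s_CG: 0.25, s_PGB: 0.45, s_MGB: 0.03,
     n_transit: 3, k_tox: 0.40, f_first: 1.15, ref_dose: 200.0,
     dose_exponent: 1.0, ly_intensity: 0.04, ly_decay: 0.18}
  procarbazine:
    {s_S: 0.03, s_CG: 0.15, s_PGB: 0.28, s_MGB: 0.02,
     n_transit: 3, k_tox: 0.35, f_first: 1.10, ref_dose: 700.0,
     dose_exponent: 1.0, ly_intensity: 0.05, ly_decay: 0.15}
  epirubicin:
    {s_S: 0.06, s_CG: 0.33, s_PGB: 0.62, s_MGB: 0.04,
     n_transit: 3, k_tox: 0.40, f_first: 1.15, ref_dose: 150.0,
     dose_exponent: 1.0, ly_intensity: 0.05, ly_decay: 0.18}
  paclitaxel:
    {s_S: 0.015, s_CG: 0.10, s_PGB: 0.25, s_MGB: 0.02,
     n_transit: 3, k_tox: 0.50, f_first: 1.10, ref_dose: 225.0,
     dose_exponent: 1.0, ly_intensity: 0.02, ly_decay: 0.22}

# Risk-group toxicity multipliers (applied to all s_X and ly_intensity):
# leukopenic-risk tertiles differ in chemotherapy sensitivity only.
risk_multipliers:
  low: 0.55
  medium: 1.0
  high: 1.6
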