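# Methods

## Model structure

The simulator couples three sub-models through a single ODE system.

**Cell kinetics.**  Granulopoiesis is a chain of compartments — stem
cells (S), committed progenitors (CG), proliferating precursors (PGB),
postmitotic maturing precursors (MGB), circulating granulocytes (GRA) —
plus circulating lymphocytes (LY).  Every marrow stage obeys a balance
equation of amplified influx, transition-time efflux and chemotherapy
loss, `dC/dt = C_in·A − C/T − Ψ·C`.  Marrow compartments are
dimensionless (1 at the untreated steady state): the baseline
amplifications are absorbed into fixed flux-normalization gains computed
from the transition times, which makes the unit steady state exact by
construction rather than the result of a numerical fixed-point search.
Blood counts are in 10³ cells/µL with defaults GRA_ss = 4.4 and
LY_ss = 2.6 (WBC_ss = 7.0, comfortably above the 4.0 leukopenia
threshold).  Stem cells divide with a self-renewal probability that
declines linearly in S with p(1) = 1/2 (slope 0.8, clipped to
[0.05, 0.95]); the committed fraction 2(1−p)S/T_S feeds CG, so a
depleted stem pool both regrows and transiently prioritizes
self-renewal over commitment.

**G-CSF pharmacodynamics.**  Four properties are regulated by the
effective G-CSF serum concentration (endogenous + filgrastim +
pegfilgrastim central concentrations, potency-weighted): PGB
amplification (up), PGB transition time (up — longer proliferation),
MGB transition time (down — faster release of the marrow reserve) and
the postmitotic survival fraction (up, capped at 1).  Endogenous
production is regulated downward by GRA.  Each curve is a Hill-type
sigmoid with bounds [fmin, fmax] and steepness h, *normalized to equal
exactly 1 at the baseline signal*.  That exact-1 anchoring
over-determines the usual 4-parameter Hill family: once the bounds and
steepness are fixed, the half-effect concentration is implied by the
normalization constant A = (1−fmin)/(fmax−1) and is exposed as a
derived property rather than a free parameter.  The curve interface is
a single class, so alternative forms can be swapped.

**G-CSF pharmacokinetics.**  Per derivative: a two-stage subcutaneous
depot (transition and absorption rates ≈ 2.5/d filgrastim, 1.0/d
pegfilgrastim) delays absorption by several hours; a Michaelis–Menten
loss from the first depot stage competes with the transition, making
bioavailability dose-dependent (≈ 0.54 at 300 µg, ≈ 0.63 at 600 µg for
filgrastim — relative loss shrinks as the loss route saturates);
first-order reversible central↔peripheral binding; first-order renal
elimination (2.0/d filgrastim, 0.15/d pegfilgrastim — pegylation
suppresses renal clearance, which is what makes pegfilgrastim persist
until counts recover); and granulocyte-mediated elimination
V_spec·GRA·C/(K_spec+C), linear in GRA and saturable in concentration.
Endogenous G-CSF shares the filgrastim constants; its baseline
production rate is derived from the configured baseline serum level
(0.025 µg/L ≈ 25 pg/mL) so the endogenous equilibrium closes exactly.
Each block carries cumulative per-route elimination integrals, so mass
balance is auditable to integrator precision.  Doses are absolute µg;
per-kg doses are converted with a body-weight field (default 75 kg).

**Chemotherapy.**  Each administration starts a transit chain of n
concatenated first-order stages (default n = 3, rate k_tox ≈ 0.4/d);
the terminal stage follows an Erlang density peaking (n−1)/k_tox days
after the bolus — the delayed damage maximum.  The impulse injected
into the chain is (dose/reference dose)^exponent, times a
first-application excess f_first ≈ 1.1–1.15 for the first exposure to a
drug.  One chain per administration drives all four marrow stages via
stage-specific kill intensities s_X; simultaneous drugs contribute
additive chains.  GRA receives no direct kill (chemotherapy targets
proliferating/marrow cells); MGB receives a small intensity.
Lymphocyte depletion is a two-parameter exponential kill-rate pulse
applied directly at administration, with first-order recovery toward
LY_ss (time constant 25 d — slow, so lymphopenia accumulates over
cycles, as observed clinically).  Prednisone multiplies the granulocyte
half-life (×1.6) inside its administration window; overlapping windows
take the maximum.  All effects are reversible: after the last
administration every compartment returns to baseline.

## Reference parameterization

`granulosim/data/reference_params.yaml` is the single source of truth;
no default is hard-coded.  Physiological constants sit at textbook
values (postmitotic maturation 6 d, granulocyte blood half-life 7 h,
filgrastim serum half-life ≈ 3.5 h at normal counts, endogenous G-CSF
rising ≈ 10-fold at GRA = 1).  Stem/progenitor turnover (T_S = 2.5 d,
T_CG = 3 d, T_PGB = 3.5 d) and the toxicity intensities were chosen
once so that a CHOP-14-like course without G-CSF shows the clinically
expected pattern: nadir ≈ day 10–13 of each cycle, WBC ≈ 2.8–3.5
×10³/µL at nadir, near-stationary cycles after cycle 2.  The regulation
curve bounds (A_PGB ≤ 2.6, T_MGB ≥ 0.15 of baseline, survival gain
≤ 1.2) balance two opposing mechanisms: amplification rewards sustained
stimulation, while accelerated MGB release empties the marrow reserve.
With this balance the model reproduces the family's headline behaviour:
on the full 14×14 schedule grid the optimal filgrastim schedule starts
around day 7 and runs to the cycle end, and day-1/2 starts are strictly
worse *even with more injections* — early injections are also cleared
fastest because granulocyte-mediated elimination scales with the
still-high counts.  Risk tertiles are represented as documented
multipliers (0.55 / 1.0 / 1.6) on all kill intensities and lymphotoxic
amplitudes only; cell kinetics and G-CSF PK/PD are shared across risk
groups by assumption.

## Numerics

The flat state vector stacks the 6 cell compartments, three 7-component
PK blocks and one transit chain per administration (pre-allocated from
the event timeline; a chain before its activation is identically zero).
Integration uses VODE in Adams (non-stiff, variable step/order,
functional iteration) mode — the closest scipy analogue of the classic
Adams–Bashforth–Moulton family — with rtol 1e-8 / atol 1e-10, restarted
at every event so bolus discontinuities are exact: chemotherapy boluses
increment a chain's first stage, G-CSF injections the subcutaneous
depot, and prednisone window edges force restarts because the RHS is
discontinuous there.  Dense output is reported on a fixed 0.1-day grid.
Day convention: "day 1" is the first day of cycle 1; events fire at the
start of their day (t = day − 1); same-day chemotherapy precedes G-CSF.
Halving the tolerances moves WBCAOC by < 1e-6 relative.  State
components are clamped at zero inside the RHS when computing fluxes, so
integrator under-shoot cannot propagate negative counts.

Outcome metrics treat the reported trajectory as exactly piecewise
linear: WBCAOC integrates the clipped deficit analytically per segment
(threshold crossings located in closed form), DoL sums crossing-bounded
sub-intervals, and MLC refines the grid minimum with a local parabola
through three points when the vertex stays inside the bracket.  The
default evaluation window is day 0 to the end of the last cycle,
excluding the 28-day follow-up tail.

Schedule optimization is exhaustive: one simulation per feasible grid
cell (consecutive daily injections fitting inside the cycle), pure
per-cell computation, NaN for infeasible cells, and a no-G-CSF baseline.
Selection minimizes the objective (maximizes MLC) with ties within 1 %
of the optimum broken toward fewest injections, then latest start.
Sequential regimens declared in cycle blocks are optimized by a greedy
forward pass with later blocks unsupported during the search
(conservative), then frozen.  The pegfilgrastim search is a full
day × dose factorial reporting the smallest dose whose best outcome is
within max(5 % relative, 0.1 absolute) of the full-dose optimum.

## Calibration

The residual is the sum of squared log-WBC differences at the exact
observation days (dense-output interpolation, no binning); the log
scale keeps nadirs from being drowned out by recovery peaks.  A failed
simulation maps to a large finite penalty.  The search is a
(µ, λ) evolution strategy — defaults µ = 5, λ = 35, intermediate
recombination of two parents, per-coordinate log-normal self-adaptive
step sizes with the standard learning rates 1/√(2n) and 1/√(2√n),
reflection into bounds, comma selection, best-ever tracked separately —
chosen over CMA-style methods to stay close to the classic scheme this
model family uses.  Fits run at rtol 1e-6 (the objective is far above
solver noise); reproducibility is exact given the seed.  Only toxicity
fields may be freed; PK/PD and cell kinetics are fixed by assumption.

## Synthetic data

The generator emulates trial-style median WBC curves: simulate a known
ground truth, sample at observation days, apply multiplicative
log-normal noise per pseudo-patient (counts are positive and
right-skewed) and report the per-day median of 25 pseudo-patients at
σ = 0.1 by default.  It does not emulate dropout, per-patient
covariates, G-CSF non-compliance, assay detection limits, or
within-patient correlation of repeated measures — so passing recovery
tests demonstrate identifiability under idealized median-level noise,
not performance on real cohorts.  The parameter-recovery experiments
use a three-cycle cyclophosphamide course (1500 mg/m², deep nadirs) with
30 observation days spanning all cycles, which makes all four freed
toxicity parameters (kill intensity, transit rate, first-application
excess, lymphotoxic amplitude) individually informative; the
lymphotoxic amplitude remains the weakest-identified because
lymphopenia enters WBC additively and separates from granulotoxicity
mainly through its slow cumulative drift.

## Problem sizes

The test suite and the acceptance script use the toy regimens as
shipped: six cycles for the CHOP-like grids (105 feasible schedule
cells, one simulation each), two-to-three-cycle single-drug courses for
calibration studies, evolution-strategy budgets of a few hundred
evaluations per fit, and 10 seeds for the noisy-recovery medians.

## Known limitations

Median-level modelling only — no inter-patient variability or
individual trajectories; no infection-risk translation of the leukocyte
endpoints; other haematopoietic lineages neglected; the transit chain
is a phenomenological stand-in for cytotoxic drug PK; toxicity
additivity ignores drug–drug interactions; non-consecutive filgrastim
patterns are out of scope.  The bundled parameterization is a
documented plausible reference set, not a fit to clinical data: the
package reproduces the qualitative structure of optimized G-CSF
scheduling (risk ordering, late-start optima, pegfilgrastim dose
headroom), while absolute outcome values depend on the toxicity
constants used.
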