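# Methods

## The measurement problem

Forearm VPPG is recorded at 4 Hz for 60 s: 2 s at rest with the arms down
(the zero-volume reference, after at least 30 s of complete filling),
abduction ("Ca") until second 30, prayer ("Pra") until second 45, then arm
lowering. Signal increases denote emptying. Because the probe gain is
arbitrary, only the *normalized* end-of-abduction value

%PPGmax = 100 · End-Ca-PPG / PPGmax

is comparable across limbs; PPGmax — the maximum over the Ca-Pra window —
is interpretable as complete emptying precisely because the Pra phase
releases any positional compression.

## The compartment model

The simulator treats the forearm venous pool as one well-mixed compartment
of volume V with arterial inflow q and first-order venous outflow:

- rest: V = V_full (complete filling, arms down);
- Ca: dV/dt = q·(1−a) − k0·(1−c)·(V − V_empty), with c ∈ [0,1] the
  fractional outflow block and a ∈ [0,1] the fractional arterial inflow
  block imposed by the position;
- Pra: dV/dt = q_h(t) − k0·(V − V_e(t)), with a reactive-hyperaemia inflow
  surge q_h(t) = q·(1 + surge_gain·a·e^(−Δt/τ_s)) and a gradually developing
  post-ischemic venodilation V_e(t) = V_empty·(1 + d·a·(1 − e^(−Δt/τ_d)));
- after second 45: V relaxes back to V_full (arm lowering; flagged and
  excluded from analysis).

The PPG readout is G·(V_full − V) plus Gaussian sensor noise, re-zeroed to
the resting-window mean. Integration is explicit Euler on the 0.25 s sample
grid, which is stable for k0 ≤ 2 s⁻¹ (defaults keep k0·dt ≤ 0.2) and
trivially reproducible.

Two refinements matter for morphology. First, the outflow block engages
over a short onset ramp (`block_onset_s`): the costo-clavicular angle
closes as the arm travels, so a limb with a near-total block still shows a
brief initial emptying peak before refilling — without the ramp the refill
morphology has no early local maximum. Second, venodilation develops
gradually during Pra. A first-order compartment cannot overshoot a
monotonically relaxing equilibrium, so an instantaneous venodilated empty
volume could never produce the observed "rise then late decline" in Pra;
with τ_d ≈ 6 s the equilibrium first falls (surge decays) and then rises
(dilation grows), and the trace follows.

Default scales: V_full − V_empty = 9 volume units with G = 1, so a
noise-free normal response has ≈9 AU amplitude, matching the order of
magnitude of typical recordings; q/k0 = 0.2 keeps the patent steady state
within ~2% of complete emptying.

### Response-pattern presets

Six parameter sets reproduce the canonical noise-free morphologies:
A/B complete emptying (c ≤ 0.3), C incomplete (c = 0.88), D refill with
negative values (c = 1 with 3 s onset ramp and high inflow), E severely
slowed but complete outflow with Pra filling (c = 0.78, a = 0.95, d = 1.5),
F venodilation filling on a patent limb (c = 0, a = 0.85, d = 2). Each
classifies to its intended label (a round-trip property in the tests).

## Feature extraction

PPGmax is the maximum over [rest_end, pra_end]; samples after pra_end are
discarded because arm lowering is not standardized. End-Ca-PPG is the
median of the last 1 s (4 samples) of the Ca phase — a median rather than
the single second-30 sample for noise robustness; the window length is a
parameter. %PPGmax is structurally ≤ 100 (the End-Ca samples lie inside the
max window) and unbounded below. A limb with PPGmax ≤ 0 never showed
detectable emptying; %PPGmax is then undefined and the limb is flagged
invalid and excluded from ROC input rather than dividing by a non-positive
maximum. %PPGmax is exactly invariant to positive rescaling of the trace —
the whole point of the normalization — which holds to rounding error in the
tests.

## Pattern classification

All thresholds are fractions of PPGmax, so classification is gain-invariant.
Decision order: (1) a Pra rise above δ_rise·PPGmax ⇒ incomplete emptying,
subtyped refill when an early Ca peak exceeds End-Ca by the same margin;
(2) otherwise a Pra decline above δ_fall·PPGmax ⇒ venodilation filling;
(3) otherwise complete. A complete (or venodilation) emptier that took
longer than t_slow to reach 90% of its End-Ca value is re-labelled
slowed-but-complete; applying the slow-outflow override to the venodilation
branch as well keeps the "slow outflow, max at Ca end, Pra filling"
morphology a distinct label instead of merging it with the fast
venodilation one. Incomplete evidence outranks venodilation when both fire
because the degree of emptying is the primary clinical question.

Defaults δ_rise = 0.13, δ_fall = 0.10, t_slow = 20 s. δ_rise coheres with
an 87% emptying criterion: a Pra rise of more than 13 points of PPGmax is
exactly the complement of 87% emptying at the end of Ca.

## ROC analysis

Orientation is fixed: low %PPGmax ⇒ test positive. Cutoff semantics are
strict less-than at observed scores (plus the two trivial endpoints), the
convention of the common clinical-statistics packages, and consistent with
counting "values < 87" as test-positive. Sensitivity and specificity are
computed by direct counting; the AUC is the trapezoidal area of that
staircase, which equals the tie-corrected Mann–Whitney statistic (asserted
to 1e−12 against pair enumeration in the tests, and cross-checked against
scikit-learn). The standard error uses the Hanley–McNeil closed form with
Q1 = A/(2−A), Q2 = 2A²/(1+A); an exact DeLong estimate is available via
`se_method="delong"`. For A = 0.589 with 207/641 limbs the closed form
gives 0.0233 — published software variants that handle ties differently
may print 0.024; nothing downstream depends on the SE. The optimal cutoff
minimizes √((1−sens)² + (1−spec)²) on the unit square (equal cost of false
positives and negatives); ties break toward higher sensitivity, then lower
cutoff. Limbs are analysed independently; no within-patient clustering
correction is applied, matching limb-by-limb clinical reporting.

## Confusion-table reconstruction

Given class sizes and a sensitivity/specificity printed to one decimal, the
reconstruction enumerates all tp ∈ [0, n_pos] and tn ∈ [0, n_neg] whose
exact percentages round (half-up, matching reporting style) to the printed
values. At 207/641 with 60.9/47.6 the windows admit exactly one pair
(tp = 126, tn = 305), so PPV 27.3%, NPV 79.0% and accuracy 50.8% follow
exactly. Non-unique reconstructions return every candidate; silently
picking one is never done.

## The synthetic cohort

No per-limb recordings are publicly deposited, so the cohort generator
emulates the study conditions: 424 patients (848 limbs), compression on the
right only / left only / both sides / neither in 41 / 44 / 61 / 278
patients (hence 102 right-positive and 105 left-positive limbs), 4 Hz / 60 s
traces, log-normal per-limb gain spread (σ = 0.8) around a 9 AU median
amplitude, and 0.12 AU sensor noise.

Each ultrasound class draws limb physiology from a severity distribution
with three phenotypes:

- *patent* (c uniform on [0, c_patent_max]): emptying complete or nearly so;
- *moderate* block (c = c_mod_lo + (c_mod_hi−c_mod_lo)·Beta(mod_a, mod_b)):
  partial emptying;
- *severe* block (c uniform on [c_sev_lo, 1]) with log-normally boosted
  arterial inflow: the refill phenotype, reaching zero or negative %PPGmax.

A fraction p_inflow of limbs additionally carries an arterial inflow block
with venodilation (the Pra-filling morphologies). Phenotype counts within
each class are allocated by exact quota and shuffled, rather than drawn
per-limb: the class composition is the condition the samplers are
calibrated to, and quota allocation makes it hold at every seed instead of
only in expectation (a per-limb Bernoulli draw would wobble the 207-limb
positive class by ±3–4 sensitivity points between seeds).

The default constants were calibrated so the full pipeline on the
848-limb cohort reproduces the clinical operating point: sensitivity/
specificity at the 87 %PPGmax threshold within ±5 points of 60.9/47.6, the
below-87 fraction within ±5 points of 52.7, and the closest-to-corner
cutoff within ±3 of 87. Two distributional features do the work: the
negative class has a density gap just below 87 (its moderate blocks start
at c = 0.78) with its patent pile beginning just above 87, while the
positive class has a density bump ending at the 87 edge (moderate blocks
from c = 0.70, weighted toward the low end) — together these pin the
population distance-minimum near 87 and give the positive class the deeper
score distribution that produces an AUC near 0.57–0.59. These constants are
calibration values of the generator, not claims about physiology.

What the generator does **not** emulate: movement artifacts, probe
slippage, respiratory oscillations, device rounding (the empirical
distribution has a discrete spike at exactly 100 %PPGmax that noise smears
here), the deepest observed outliers (%PPGmax near −575 requires extreme
capacity/inflow ratios that the default jitter rarely produces), or any
correlation between a patient's two limbs. Passing tests therefore show
that the *analysis machinery* recovers the operating characteristics of
data with the study's marginal structure — not that the compartment model
is a validated forward model of individual patients.

## Problem sizes and determinism

The test suite and the acceptance script both run the full 424-patient
cohort; one cohort simulates in about two seconds, and the whole suite runs
in a few seconds. Every stochastic component hangs off one master seed via
spawned substreams (statuses and phenotype shuffles, per-limb parameters,
per-limb sensor noise), so cohorts, reports and the acceptance JSON are
bit-reproducible for a given seed.

## Known limitations

- The Euler grid matches the device sample rate; rate constants well above
  2 s⁻¹ would need a finer integration step.
- The patent steady state leaves a ~0.2% asymptotic residual, so noise-free
  "complete emptying" yields %PPGmax ≈ 99.97 rather than exactly 100;
  tests use a 0.1-point tolerance there.
- DeLong and Hanley–McNeil standard errors can differ noticeably for small
  or heavily tied samples; the default reports Hanley–McNeil.
- The slowed-outflow label depends on t_slow, which has no published
  reference value; 20 s was chosen as two-thirds of the Ca phase.
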