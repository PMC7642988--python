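# Methods

## The myocyte model

The cellular substrate is the O'Hara–Rudy (2011) human ventricular
cardiomyocyte model in its epicardial parameterization: 41 states —
membrane potential; Hodgkin–Huxley-type gates for I_Na (fast and late),
I_to, I_CaL (with the Ca²⁺-dependent and CaMKII-phosphorylated gating
modes), I_Kr, I_Ks and I_K1; intracellular and subspace Na⁺, K⁺ and Ca²⁺
with SR uptake/release; and the CaMKII trapping variable. Units are ms, mV,
mM and µA/µF throughout. The equations are implemented directly from the
published formulation; the epicardial scalings (I_NaL ×0.6, I_to ×4,
I_CaL ×1.2, I_Kr ×1.3, I_Ks ×1.4, I_K1 ×1.2, NCX ×1.1, NaK ×0.9, I_Kb ×0.6,
SERCA ×1.3, calmodulin buffer ×1.3) are baked into the right-hand side.

Validation is behavioral rather than against an external code: (a) the
unperturbed model paced at 1 Hz for 1,000 beats settles at APD₉₀ =
230.9 ms, consistent to within ~1 % with the baseline implied by the
reference drug responses used for calibration (a +43 % prolongation of
100 ms and a +76 % prolongation of 177 ms both imply ≈ 232–233 ms); (b) single beats integrated by the production
kernel and by scipy's stiff LSODA on the same right-hand side agree to
< 0.1 ms in APD₉₀ (asserted at 0.5 ms in the suite); (c) gating, charge-
balance and concentration-positivity invariants are property-tested.

### Perturbation hooks

`ModelParameters` exposes exactly the knobs the analysis varies:

* per-current conductance multipliers (defaults 1.0) for the nine varied
  currents plus I_Kb and the background/pump currents;
* extracellular [K⁺], [Na⁺], [Ca²⁺] (defaults 5.4 / 140 / 1.8 mM);
* signed voltage shifts `dv_act_mV` / `dv_inact_mV` applied only to the
  I_CaL steady-state activation/inactivation curves (activation is
  evaluated at V − dv_act); time constants are untouched. A −3/+3 mV pair
  enlarges the window-current overlap integral about three-fold;
* the stimulus (−80 µA/µF, 1 ms). The 1 ms default (rather than the 0.5 ms
  of the original model code) keeps the stimulus suprathreshold from the
  ≈ −114 mV resting potential reached at [K⁺]ₒ = 2 mM, where a 0.5 ms pulse
  no longer elicits an action potential; at normal [K⁺]ₒ the longer pulse
  changes baseline APD₉₀ by < 0.5 ms.

## Numerics

The integrator is an adaptive-step hybrid: gates (and the relaxation-form
SR-release fluxes and the I_CaL mode fraction) advance by exact exponential
(Rush–Larsen) updates, voltage and concentrations by forward Euler. The
step is chosen so the voltage change per step stays below 0.05 mV, capped
at 0.1 ms during the action potential, 0.05 ms in the first 20 ms of a
beat, and 1 ms in diastole; steps never straddle the stimulus edge.
These settings were fixed by matching LSODA (rtol 1e-8) single beats and
are exposed in `SolverSettings`. The scheme is deterministic: identical
inputs give bit-identical trajectories, which the suite asserts.
Recorded beats are resampled onto a uniform 0.25 ms output grid by linear
interpolation for biomarker extraction.

Degenerate cases: the GHK flux expressions are guarded at |V| < 1 µV; a
non-finite state aborts the run with a solver error carrying the condition
label and beat index.

## Pharmacology

Drug block is concentration-dependent pore block: fractional inhibition
b(c) = cʰ/(IC₅₀ʰ + cʰ) per current, applied as a conductance multiplier
(1 − b). Multiple drugs combine assuming independent binding sites — per
current, unblocked fractions multiply. There is no state- or
use-dependence: block is identical at all pacing rates.

The shipped drug table (`data/drug_blocks.json`) covers the seven screened
currents (I_Na, I_NaL, I_CaL, I_to, I_Kr, I_Ks, I_K1). The underlying
patch-clamp screen is published only graphically, so the table is
calibrated: the channel pattern (CQ blocking mainly I_Kr and I_K1; AZM
mainly I_Kr and I_to, with minor effects elsewhere) and the minor-channel
IC₅₀ magnitudes follow the heterologous-expression literature, while the
two dominant I_Kr IC₅₀ values were fitted once — by a secant search on the
default model at the reference protocol — so that 5 µM CQ prolongs APD₉₀ by
+43 % and 20 µM AZM by +29 %. The combined-treatment prolongation
(+175 ms, +76 %) and everything downstream (rate dependence, ISO
interactions, population statistics, hypokalemia, window-shift EADs) are
predictions, not fitted. Evaluated block fractions at the clinical
concentrations: CQ — I_Kr 45 %, I_K1 30 %, I_Na/I_NaL 10 %, I_Ks 8 %,
I_CaL 7 %, I_to 5 %; AZM — I_Kr 36 %, I_to 18 %, I_NaL 8 %, I_Na/I_CaL/I_Ks
5 %, I_K1 2 %. Users can override the table with their own JSON.

## β-adrenergic (ISO) modulation

The β-adrenergic cascade is represented phenomenologically as the maximal
(1 µM isoproterenol) endpoint of PKA phosphorylation, shipped in
`data/iso_effects.json`:

| target | transformation | provenance |
|---|---|---|
| I_Ks | ×9.14 | calibrated (see below) |
| I_CaL | ×2.2, activation −10 mV, inactivation −6 mV | experimental PKA magnitudes |
| I_NaK | ×1.3 | experimental pump stimulation |

`iso_fraction` interpolates linearly between identity and this endpoint
(multipliers as 1 + f·(m−1), shifts as f·shift). This interpolation is a
convenience for intermediate sympathetic tone, not a receptor-occupancy
model, and is flagged as an extrapolation.

The I_Ks factor is the one calibrated number: it is fitted so that 2 Hz
pacing plus maximal ISO shortens the drug-free APD₉₀ by 21 % relative to
1 Hz. With it fixed, the model reproduces the drugged-group responses
(CQ −33 %, AZM −32 %, CQ+AZM −40 % at 2 Hz + ISO vs 1 Hz) and the
phosphorylation-knockout result — disabling the I_Ks and I_CaL components
returns the CQ+AZM + ISO action potential to within 1 ms of the plain 2 Hz
one — without further adjustment. The hyperpolarizing I_CaL activation
shift is what makes ISO exacerbate, rather than suppress, EADs once the
window current is enlarged: it moves the augmented current into the
plateau voltage range.

## Biomarkers and event detection

Per beat (beats are stimulus-aligned): APD at level L measured from the
maximum-dV/dt instant to the first downward crossing of
V_peak − L/100·(V_peak − V_diastolic), linearly interpolated; RMP as the
last pre-stimulus sample; peak potential; Ca²⁺-transient amplitude and
diastolic level.

Published EAD/RF incidence figures rarely state their operational
definitions, so the detectors here are explicit and configurable
(`BiomarkerConfig`), with defaults chosen so the qualitative outcomes
(no events in normokalemic human runs; events after the window shift) are
reproduced:

* **EAD** — after the initial spike (first 50 ms) and before repolarization
  to the APD₉₀ level, a local minimum followed by a rise ≥ 2 mV. The search
  starts 100 ms into the beat so the epicardial phase-1 notch/dome, a
  legitimate early rise, is not misclassified.
* **RF** — the potential never falls below −60 mV between 50 ms
  post-upstroke and the next stimulus. An RF beat has no defined APD₉₀; it
  is reported as the cycle length and flagged. Incidence statistics count
  the EAD/RF union.
* **Alternans** — successive APD differences > 5 ms with strictly
  alternating sign over ≥ 4 recorded beats.

All three are validated on 1,000 seeded parametric traces with labels exact
by construction (sensitivity = specificity = 1 for amplitudes ≥ 2× the
thresholds). Incidence numbers under EAD-prone conditions are necessarily
threshold-sensitive; the defaults above are part of the reported method.

## Protocols and the experiment grid

Every run prepaces from a carried-over state and then records 2 beats.
The full-fidelity protocol (used for all single-model results) prepaces
1,000 beats at the target rate, starting from the shipped 1,000-beat 1 Hz
control steady state (`data/ord_epi_steady_1hz.json`, regenerated by this
package's own kernel). Conditions compose drugs, ISO, [K⁺]ₒ and window
shifts onto the base model; a condition's control is the drug-free run at
the same rate/ISO/[K⁺]ₒ/shift.

## Population of models

Variants scale the nine varied conductances by independent 𝒩(1.0, 0.2)
draws; negative draws are resampled (not truncated) to preserve the
distribution shape. Calibration excludes variants whose drug-free 1 Hz
baseline APD₉₀ or RMP leaves the physiological windows
(`data/calibration_ranges.json`: 120–450 ms, −98…−75 mV, representing
mean ± 3 SD of experimental reference ranges). The windows are wide
relative to the sampled variability, so an unperturbed population is
retained essentially in full (inclusion ≈ 100 %). Per-variant drug effects are differences
against that variant's own matched control; summaries report medians, IQRs
and EAD/RF incidence as a percentage of included variants. Runs are
embarrassingly parallel and worker-count invariant.

Population runs use a desk-scale protocol: each run warm-starts from the
shipped control steady state (variant controls) or the variant's own
matched control (drug runs) and prepaces up to 300 beats with an early stop
once |ΔAPD₉₀| < 0.05 ms/beat for 10 consecutive beats (minimum 100). At
n = 100 variants this reproduces the full-protocol medians to within
~4–5 % (the residual bias comes from slow Na⁺ accumulation under K⁺-current
block); the package defaults document this as the intended scale, with the
1,000-beat protocol available for full-fidelity runs.

## Synthetic data

`cardiopop.synthetic` generates the three inputs the analysis layer
assumes, with exact ground truth: Hill-curve datasets with Gaussian
measurement noise (clipped to [0, 1]); piecewise linear/exponential
AP-like waveforms with injectable EAD bumps, repolarization failure and
APD alternans; and population biomarker tables drawn from normal/Bernoulli
distributions. The waveforms are deliberately non-physiological — a square
upstroke, a linearly sagging plateau, a linear repolarization ramp — which
is sufficient to specify the detector contracts while staying independent
of the ODE core. Passing detector tests on this corpus therefore
demonstrates the detectors' logic, not their behavior on every real AP
morphology; the acceptance suite covers the latter on simulated beats.

## Known limitations

* The drug table and ISO set are calibrated representations of graphically
  published data; absolute incidence numbers inherit that uncertainty and
  the detector thresholds.
* Pore block is state-independent; use-dependent or trapped block (relevant
  for some hERG blockers) is out of scope.
* The β-adrenergic model has no receptor→cAMP→PKA dynamics; `iso_fraction`
  interpolation between endpoints is phenomenological.
* Epicardial cell type only; no endo/mid-myocardial variants, no tissue
  coupling, no pharmacokinetics.
* At pacing rates where the APD approaches the cycle length the RMP rises
  through incomplete repolarization; APD comparisons there are reported but
  carry the RF-flag caveat above.
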