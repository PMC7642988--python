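# cardiopop

In-silico analysis of drug-induced cellular proarrhythmia in the human
ventricle: a paced O'Hara–Rudy (2011) epicardial cardiomyocyte model with
multichannel Hill-equation drug block, phenomenological β-adrenergic (ISO)
modulation, hypokalemia and I<sub>Ca,L</sub> window-current perturbations,
proarrhythmia biomarker detection, and calibrated population-of-models
studies.

The package is aimed at cardiac safety-pharmacology and computational
electrophysiology work: it reproduces, at the cellular level, how
chloroquine (CQ, 5 µM) and azithromycin (AZM, 20 µM) — individually and in
combination — prolong the action potential, how sympathetic activation
(faster pacing plus isoproterenol) counteracts that prolongation, and under
which conditions (reduced repolarization reserve, enlarged
I<sub>Ca,L</sub> window) early afterdepolarizations (EADs) and
repolarization failure (RF) emerge.

## The model

The cell is the ORd human ventricular epicardial myocyte: 41 ODE states
(membrane potential, Hodgkin–Huxley-style gates, intracellular/subspace
Na⁺, K⁺ and Ca²⁺, CaMKII trapping), paced with a −80 µA/µF, 1 ms stimulus.
Drug action is pure pore block: for each targeted current *X* the maximal
conductance is multiplied by 1 − *b*, with

> *b*(c) = c^h / (IC₅₀^h + c^h)

per drug and channel, and multiple drugs combining as independent binding
sites (unblocked fractions multiply). β-adrenergic stimulation is a
phenomenological parameter transformation (dominant I<sub>Ks</sub> and
I<sub>Ca,L</sub> up-scaling plus gating shifts and Na⁺/K⁺-pump
stimulation), linearly interpolated by an `iso_fraction` between no effect
and the maximal 1 µM ISO effect.

Inter-individual variability is a population of models: the conductances of
nine major currents (I<sub>Na</sub>, I<sub>NaL</sub>, I<sub>Ca,L</sub>,
I<sub>Kr</sub>, I<sub>Ks</sub>, I<sub>K1</sub>, I<sub>to</sub>,
I<sub>NCX</sub>, I<sub>NaK</sub>) are scaled by independent
𝒩(1.0, 0.2) factors; variants with non-physiological baseline APD₉₀ or RMP
are excluded before analysis. Per-variant drug effects are always measured
against that variant's own drug-free control at the same pacing/ISO/[K⁺]ₒ
setting.

See `docs/methods.md` for the full model account, parameter provenance and
numerical choices.

## Worked example

```python
from cardiopop import study

effects = study.single_model_effects(keys=["ctl_1hz", "cq_1hz", "comb_1hz"])
a0 = effects["ctl_1hz"].apd90_ms
for key, label in [("ctl_1hz", "control"), ("cq_1hz", "CQ 5 uM"), ("comb_1hz", "CQ + AZM")]:
    bm = effects[key]
    print(f"{label:9s} APD90 = {bm.apd90_ms:6.1f} ms "
          f"({100 * (bm.apd90_ms - a0) / a0:+5.1f}%)  EAD={bm.ead}  RF={bm.rf}")
```

prints

```
control   APD90 =  230.9 ms ( +0.0%)  EAD=False  RF=False
CQ 5 uM   APD90 =  330.2 ms (+43.0%)  EAD=False  RF=False
CQ + AZM  APD90 =  406.3 ms (+75.9%)  EAD=False  RF=False
```

i.e. after 1,000 conditioning beats at 1 Hz the baseline epicardial APD₉₀
is ≈231 ms; 5 µM chloroquine prolongs it by 43%, and the CQ+AZM combination
by 76% (+175 ms) — more than the sum of the individual effects, because the
two drugs' IKr block multiplies. No EAD or RF occurs in these normokalemic
single-cell conditions.

Lower-level entry points: `cardiopop.model` (ODE core),
`cardiopop.pharmacology` (Hill fitting, block tables, ISO),
`cardiopop.protocols` (pacing and the condition grid),
`cardiopop.biomarkers` (APD/RMP/CaT metrics, EAD/RF/alternans detectors),
`cardiopop.population` (sampling, calibration, batched runs),
`cardiopop.synthetic` (ground-truth generators for testing). A thin CLI is
included:

```bash
cardiopop simulate --config figure11 --out results/fig11
cardiopop report --results results/fig11
cardiopop fit-hill --input inhibition.csv
```

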