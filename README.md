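# purkinje-trials

In silico drug trials on populations of human cardiac Purkinje cell
models: population-of-models construction, IC50 pore-block pharmacology,
multi-rate pacing, action-potential biomarker and EAD quantification, and
torsade-de-pointes (TdP) risk classification — with a synthetic
rabbit-Purkinje-fiber data generator standing in for animal experiments.

## Who this is for

Safety pharmacologists and computational electrophysiologists who want to
screen compounds for proarrhythmic risk from ion-channel IC50 data alone,
and to compare those predictions against the classic in vitro
Purkinje-fiber assay and against clinical TdP classes (CredibleMeds:
1 = known risk, 2 = conditional risk, NC = not classified).

## The model and the method

**Cell model.** A reduced Hodgkin–Huxley human Purkinje action-potential
model with the 12 ionic currents that shape the Purkinje AP: fast and
late Na⁺ (I_Na, I_NaL), L- and T-type Ca²⁺ (I_CaL, I_CaT), transient and
sustained outward K⁺ (I_to, I_sus), rapid and slow delayed rectifiers
(I_Kr, I_Ks), funny current (I_f), inward rectifier (I_K1), Na⁺/Ca²⁺
exchanger (I_NCX) and the Na⁺/K⁺ pump (I_NaK). Its control biomarkers at
0.25, 1 and 3 Hz lie inside healthy human Purkinje calibration windows,
with the physiological rate ordering APD90(slow) > APD90(1 Hz) >
APD90(3 Hz), and it reproduces the canonical pharmacology: hERG (I_Kr)
block prolongs APD90 monotonically, Na⁺ block slows the upstroke, and
sufficiently strong hERG block produces early afterdepolarizations (EADs)
in variants with strong depolarizing and weak repolarizing currents.

**Population of models.** Cell-to-cell variability is modeled by scaling
the 12 maximal conductances with factors Latin-hypercube-sampled in
[50, 200]% of baseline. Each candidate is paced to steady state at 1 Hz;
only candidates whose nine control biomarkers (APD10/25/50/75/90,
dV/dtMax, APA, TOP, EOP) fall inside experimental calibration ranges and
that show no control EADs/DADs at any pacing rate are retained. All drug
trials run on one frozen, hash-identified population.

**Drug model.** Simple pore block: at concentration C a channel with
half-maximal inhibitory concentration IC50 keeps the residual conductance
fraction

    r = 1 / (1 + (C / IC50)^h),   h = 1 by default.

The bundled library carries 14 reference compounds with per-channel
IC50s (I_Na, I_CaL, I_to, I_Kr), the concentrations and pacing rates of
the corresponding fiber assay, and their clinical TdP class.

**Risk metrics.** A compound is called *risky* by the abnormality metric
if at least one population member shows an EAD/DAD at slow pacing
(0.2–0.25 Hz) at any tested concentration, and by the APD90 metric if the
mean APD90 prolongation at 1 Hz exceeds +10%. Calls are scored against
the clinical classes as a confusion matrix; paired in silico / in vitro
percent changes are rated strong / qualitative / disagreement with a
15-point tolerance.

**Synthetic in vitro assay.** Per-fiber control biomarkers are drawn from
truncated normals around published rabbit Purkinje control statistics;
dose effects are configurable Emax curves with fiber-level noise and
Bernoulli EAD flags, so the whole downstream pipeline is testable with no
animal data.

## Worked example

```python
from purkinje_trials import (ReducedPurkinjeModel, PacingProtocol, ScalingVector,
                             BlockSet, CurrentId, analyze_beat, get_drug,
                             block_set, DoseRequest)

model = ReducedPurkinjeModel()
state = model.prepace_to_steady_state(n_beats=50, frequency_hz=1.0)
_, trace = model.pace(state, PacingProtocol(frequency_hz=1.0, n_beats=1))
control = analyze_beat(trace)

dofetilide = get_drug("dofetilide")
blk = block_set(DoseRequest(dofetilide, 0.01))        # top assay dose, in uM
_, dosed_trace = model.pace(state, PacingProtocol(1.0, 30), block=blk)
dosed = analyze_beat(dosed_trace)

sus = ScalingVector.from_dict({CurrentId.ICaL: 2.0, CurrentId.INaL: 2.0,
                               CurrentId.IK1: 0.5, CurrentId.INaK: 0.5})
sus_state = model.prepace_to_steady_state(sus, n_beats=50, frequency_hz=1.0)
_, sus_trace = model.pace(sus_state, PacingProtocol(0.25, 10), sus,
                          BlockSet.from_dict({CurrentId.IKr: 0.1}))
```

prints (via the obvious `print` statements):

```
control 1 Hz: APD90 = 229 ms, dV/dtMax = 379 V/s, APA = 113 mV, TOP = -85.5 mV
dofetilide 0.01 uM: residual IKr = 0.825, residual INa = 0.9999
dofetilide 0.01 uM at 1 Hz: APD90 = 242 ms (+5.7% vs control)
susceptible variant, 90% IKr block, 0.25 Hz: EAD
```

Reading: at its highest assay concentration dofetilide blocks ~17% of
I_Kr and essentially nothing else, which prolongs the baseline cell's
APD90 by ~6% at 1 Hz; the same degree-of-block logic applied at 90% I_Kr
block at slow pacing triggers an EAD — the cellular arrhythmia precursor
— in a variant with high Ca²⁺/late-Na⁺ and low repolarization-reserve
conductances.

A command-line layer mirrors the pipeline stages
(`purkinje-trials build-population | run-trial | simulate-invitro |
classify | compare`).

## Layout

```
src/purkinje_trials/
  cell_model.py         # 12-current reduced Purkinje model + pacing API
  _engine.py            # Rush-Larsen integrator (numba)
  biomarkers.py         # nine AP biomarkers, EAD/DAD detection
  population.py         # LHS sampling + calibration
  drug_block.py         # pore-block model + bundled drug library
  trials.py             # drug-trial orchestration and aggregation
  risk_metrics.py       # classification, confusion matrix, consistency
  synthetic_invitro.py  # synthetic rabbit-fiber assay + fixtures
  cli.py                # thin command-line layer
  data/                 # drug library, control statistics, outcome flags
docs/methods.md         # modeling and numerical choices, in detail
scripts/acceptance.py   # recompute headline quantities -> JSON
tests/                  # pytest suite (reduced simulation profile)
```
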