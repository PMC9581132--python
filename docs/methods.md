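# Methods

This note documents the modeling, numerical and design choices behind
`purkinje-trials`, in the order the pipeline uses them. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. The bundled reduced Purkinje cell model

### Scope and intent

The cell model is a reduced Hodgkin–Huxley formulation written for this
package. It is *not* a transcription of any published detailed Purkinje
model: it carries the 12 ionic currents that population sampling and
pore-block pharmacology act on (I_Na, I_NaL, I_CaL, I_CaT, I_to, I_sus,
I_Kr, I_Ks, I_f, I_K1, I_NCX, I_NaK), and it is tuned to a behavioral
contract rather than to a voltage-clamp dataset:

1. control biomarkers at 0.25, 1 and 3 Hz inside healthy human Purkinje
   calibration windows (mean ± 2 SD of the published control statistics
   bundled in `data/biomarker_reference.yaml`);
2. rate ordering APD90(0.25 Hz) > APD90(1 Hz) > APD90(3 Hz);
3. APD90 non-decreasing in I_Kr block; dV/dtMax non-increasing in I_Na
   block;
4. at slow pacing, ≥ 90% I_Kr block produces an EAD in a variant with
   high I_CaL/I_NaL and low I_K1/I_NaK;
5. quiescent (non-pacemaking) at baseline with no stimulus.

All five are asserted by the test suite on every run.

### Formulation

Voltages in mV, time in ms, currents in A/F with membrane capacitance
normalized to 1, so dV/dt = −(ΣI_ion − I_stim). Intracellular ion
concentrations are held fixed; reversal potentials are constants
(E_K = −87.8, E_Na = +54.8, E_Ks = −80, effective E_CaL = +55,
E_f = −22 mV). E_Na uses an effective intracellular Na⁺ of 18 mM — higher
than a physiological bulk value — which caps the spike overshoot at the
modest Purkinje level (~+27 mV) while the fast kinetics keep the upstroke
velocity in the hundreds of V/s. With concentrations fixed, I_NCX and
I_NaK reduce to instantaneous voltage-dependent currents whose magnitudes
the population scaling factors multiply.

Gates (12 state variables plus voltage): m, h, j for I_Na (conventional
human-ventricular kinetics, with the onset of inactivation above −40 mV
sped up 2.5× so the Na⁺ current is a brief, large pulse); hL for I_NaL
(activation instantaneous); d, f for I_CaL; fT for I_CaT (activation
instantaneous); r, s for I_to; xr for I_Kr (with an instantaneous
rectification factor); xs for I_Ks; y for I_f. I_K1 and I_sus are
instantaneous functions of voltage.

Three kinetic choices produce the physiology the contract asks for:

* **Rate adaptation.** I_Ks deactivates slowly (τ ≈ 0.6 s at diastolic
  potentials), so the gate accumulates beat-to-beat at 1 and 3 Hz but not
  at 0.2–0.25 Hz; I_NaL availability (hL) recovers with τ ≈ 0.5 s at
  rest, so late Na⁺ current is fully restored only at slow pacing. Both
  act in the same direction: longer APs at slower rates.
* **Diastolic depolarization.** I_f activates below ≈ −75 mV with
  τ ≈ 1.5 s. During the long diastole of slow pacing it depolarizes the
  membrane by a few mV, reproducing the rate dependence of the take-off
  potential (more depolarized TOP at slower rates); I_K1 keeps the
  baseline cell quiescent.
* **EAD mechanism.** The I_CaL inactivation gate f has a non-zero
  pedestal (12%) and a bell-shaped time constant peaking near the plateau
  (~500 ms around −27 mV). When repolarization is slowed by strong I_Kr
  block, the window current around −25 mV can reactivate regeneratively
  and produce the positive late voltage deflection detected as an EAD.
  This happens only when depolarizing conductances are high and
  repolarization reserve is low, matching the variant profile in the
  contract.

### Stimulus

Rectangular current pulse, default duration 0.5 ms, amplitude twice the
diastolic threshold; the threshold is found once per model by bisection
(12 iterations between 1 and 128 A/F on a 200 ms test window) and cached.
A 0.5 ms pulse (rather than a longer one) keeps the regenerative upstroke
mostly clear of the stimulus window; because a suprathreshold pulse can
still overlap the upstroke, the biomarker layer subtracts the known pulse
amplitude (an A/F pulse adds exactly that many V/s) from slopes measured
inside the stimulus window instead of discarding those samples.

### Numerics

Integration uses the Rush–Larsen scheme: forward Euler for the voltage,
exact exponential update against the voltage-frozen steady state for
every gate. Time stepping is block-adaptive: the beat is divided into
0.1 ms blocks (equal to the trace sampling interval, so recorded samples
always fall on block boundaries); a block is integrated in 0.02 ms
sub-steps whenever the predicted voltage excursion exceeds 0.2 mV or
within the first 20 ms of the beat (stimulus, upstroke, notch), and in a
single 0.1 ms step otherwise. The step-size choice is a deterministic
function of the state, so repeated runs are bitwise identical; there is
no randomness anywhere in the solver. Switching the plateau/diastole
blocks from fine to coarse stepping moves APD90 by under 0.2 ms —
far below the biomarker tolerances used anywhere in the pipeline — and
makes slow-pacing beats (4–5 s cycles, mostly diastole) several times
cheaper. Non-finite or runaway states (|V| > 300 mV) abort the run with a
flagged `SolverFailure`; NaNs never propagate silently.

A tolerance-controlled stiff ODE solver was considered and rejected:
Rush–Larsen with these step sizes is the standard scheme for cardiac
ionic models, is converged at the tolerances that matter here, and is an
order of magnitude faster and exactly reproducible.

### Beat windowing and traces

A beat spans [stimulus onset, next stimulus onset); traces are recorded
for the last beat of a pacing run at 0.1 ms, in local time. The state
cache keys pre-pacing results by (scalings, frequency, beat count,
stimulus), so drug trials restart from each member's control steady
state without re-pacing.

## 2. Biomarkers and abnormality detection

Nine biomarkers per beat: TOP (voltage at stimulus onset), APA (peak −
TOP), dV/dtMax (maximal forward-difference slope before the peak, with
the stimulus-window correction above; the reference instant is the
*earliest* sample attaining the maximum, with ties resolved within float
jitter), APD10/25/50/75/90 (time from the dV/dtMax instant to the first
later downward crossing of peak − x%·APA, linearly interpolated between
samples), and EOP (voltage at the last sample of the beat window — the
quantity has no standard published definition, so this operational one is
recorded here and in every trial manifest).

Abnormality screening precedes biomarker computation and biomarkers are
never reported for abnormal beats. A beat is flagged when dV/dt exceeds
+0.01 V/s after 150 ms from stimulus onset: an EAD if the membrane is
still above −70 mV, a DAD if the deflection occurs after repolarization
below −70 mV. All three constants are configurable and written to trial
manifests. The slope threshold sits well above the diastolic
depolarization rate that I_f produces at slow pacing (~0.001 V/s) and
well below genuine afterdepolarization upstrokes. Two additional rules:
a beat that *starts* or *ends* above −70 mV reflects repolarization
failure spilling across the beat window and is counted as an EAD-type
abnormality; a trace whose peak rises less than 10 mV above TOP is "no AP
elicited".

The 150 ms window start is a deliberate reading of an ambiguous
upstream convention (a per-beat abnormality criterion cannot start at
150 s when beats last 0.33–5 s); it is configurable for users who want a
different convention.

## 3. Population construction and calibration

Latin hypercube sampling (scipy's implementation) draws n conductance
factor vectors in [0.5, 2.0]¹²; each dimension's n equal-width bins
receive exactly one sample, the pairing across dimensions is random but
seeded. Candidates are paced individually to 1 Hz steady state; the full
protocol uses 1,000 pre-pacing beats, but because the model holds ion
concentrations fixed its slowest time scales are gate kinetics (~1.5 s),
and the limit cycle is reached within a few tens of beats — the reduced
profiles below exploit this.

Calibration retains candidates whose nine 1 Hz control biomarkers fall
inside the configured ranges and that remain free of EADs/DADs in
control at 1 Hz plus the extra rates (default 0.25 and 3 Hz, 150 control
beats each at full scale). Default ranges: published healthy human
Purkinje mean ± 2 SD for APD50, APD90, dV/dtMax, APA and TOP; for the
biomarkers without a published range, baseline ± 50% for APD75 and EOP.
APD10 and APD25 get a deliberately wide window ([0.5 × baseline value,
1.5 × baseline APD50]) because early-repolarization durations are
bimodal across conductance variants — the phase-1 notch either dips below
the 10/25% repolarization level (duration ~2 ms) or stays above it
(duration rides with the plateau, ~200 ms) — and a narrow band around
either mode would reject the other for a shape artifact rather than a
physiological one. Ranges are a configuration object, never hard-coded
downstream. Calibration is a pure filter (retained ⊆ candidates, order
preserved, idempotent); integration failures are recorded as exclusions
with reasons, not raised. Under the default windows roughly a third of
candidates survive; the retained count is seed-dependent by design and no
particular population size is a target.

The calibrated population is frozen: a content hash over the model
parameters and the scaling matrix identifies it, and aggregation refuses
to mix results from different populations.

## 4. Drug trials

Pore block scales each targeted channel's maximal conductance by
1/(1 + (C/IC50)^h), h = 1 unless configured otherwise; channels without
a measured IC50 keep residual 1.0 (a missing value means "no measurable
effect in the tested range", not a large finite IC50). Population scaling
and drug block compose by per-channel multiplication, so their order is
irrelevant. Concentrations beyond a drug's assay list are allowed (the
in-silico assay has no solubility limit) but logged as extrapolation.

For each member × concentration × frequency, the member is paced from
its cached control steady state at that frequency with the block applied
(150 beats at full scale; reduced profiles below), the last beat is
screened for abnormalities, and biomarkers are computed only if normal.
Screening the last beat only is the default; an "any of the last k
beats" mode (k = 3) exists for alternans-prone regimes and is off by
default. Summaries report, per cell, the mean percent change of each
biomarker over members normal in both the dosed and control cell
(percent change per member against its own control, then averaged) and
the EAD/DAD incidence as a percentage of the population. Every trial
writes a manifest with the design, population hash and all detector
thresholds.

## 5. Risk metrics

The abnormality metric calls a compound risky if any tested
concentration yields non-zero incidence at the compound's slow rate
(one member suffices). The APD90 metric calls it risky if the maximum
over concentrations of the mean APD90 change at 1 Hz strictly exceeds
+10%. Truth: TdP classes 1 and 2 are risky, NC safe. Accuracy is rounded
half-up to integer percent. Consistency of paired percent changes:
same trend and |difference| ≤ 15 points → strong; same trend, larger
difference → qualitative; opposite trend → disagreement. A value of
exactly 0 is treated as agreeing in trend with either sign (the rule
must be total, and a zero change carries no trend information).

The bundled categorical outcome fixtures
(`data/reference_outcomes.yaml`) encode, per compound and assay arm,
whether EADs were observed at slow pacing and whether APD90 prolongation
exceeded +10% at 1 Hz in the published reference characterization. They
make the classification layer testable at desk scale, independently of
any simulation.

## 6. Synthetic in vitro generator

The generator emulates the *output schema and statistical structure* of
a rabbit Purkinje-fiber assay — it never estimates a real dose–response.
Control cohorts draw each biomarker per fiber from a truncated normal
around the published rabbit control mean ± SD at each rate (truncation:
durations and amplitudes positive, TOP and EOP in [−100, −60] mV). The
published control table covers APD50, APD90, dV/dtMax, APA and TOP; the
remaining four biomarkers use synthetic defaults chosen to sit
consistently inside that envelope and are flagged as such here.
Biomarkers are drawn independently across columns (the within-fiber
correlation structure of real assays is not reproduced, and no test
should be read as validating it); draws are seeded and byte-identical
across runs. Fiber counts default to the 4–7 per compound typical of the
emulated assay.

Dose effects are Emax curves per biomarker (max percent change, EC50,
Hill), applied multiplicatively with fiber-level Gaussian noise (default
SD 5% of the effect factor), plus Bernoulli EAD flags per concentration
at the slow rate only — mirroring that EAD screening in the emulated
assay happens at slow pacing. Sequential-dosing carry-over is not
modeled; each concentration is an independent equilibrium. With 200
fibers and 5% noise the pipeline recovers a configured Emax effect to
well within 2 percentage points, which is what the recovery test and the
acceptance script check.

`synthesize_trace` builds stylized AP waveforms for testing the
biomarker extractors: a linear upstroke at the target dV/dtMax, a
monotone cubic (PCHIP) repolarization through the exact (time, voltage)
anchor of every requested APD level, and an optional Gaussian positive
deflection for EAD/DAD detector tests. Anchors are hit exactly by
construction, so round-trip errors come only from sampling and are far
below 1%.

## 7. Reduced profiles, and what the tests do and do not show

Full-scale protocol: 1,000 LHS candidates, 1,000 pre-pacing beats, 150
control and drug beats, populations of hundreds. The test suite and the
acceptance script run reduced profiles — 30–60 pre-pacing beats, 15–30
drug beats, populations built from 120–200 candidates or from a handful
of constructed variants — which this model reaches the same limit cycle
on (fixed concentrations, see §3). These profiles demonstrate the
pipeline's *behavioral* properties: calibration windows, rate ordering,
block monotonicity, EAD susceptibility, dose-monotone prolongation,
non-zero EAD incidence under strong hERG block in a population
containing susceptible variants. They do not — and are not meant to —
reproduce any published population size or drug-specific percent
prolongation: those depend on the original detailed cell model, on
unpublished experimental calibration ranges, and on the original
sampling stream. EAD incidence in a few-dozen-member population is a
rare-event statistic and can legitimately be zero for some seeds; the
capability itself is always verified on the constructed susceptible
variant.

## 8. Known limitations

* No intracellular ion dynamics: no Ca²⁺ transients, no Na⁺ loading, no
  long-term (minutes-scale) rate memory; APD accommodation beyond gate
  kinetics is absent.
* I_NCX and I_NaK are instantaneous voltage functions at fixed
  concentrations; their scalings act as simple current multipliers.
* The effective E_Na (+54.8 mV) is a shape parameter, not a statement
  about intracellular sodium.
* Pore block is conductance scaling only — no state- or rate-dependent
  binding, so compounds whose risk profile depends on binding kinetics
  are outside the model's reach.
* The synthetic in vitro generator draws biomarkers independently and
  models no carry-over, washout, or compound adsorption effects.
* Single-cell only: no fiber/tissue electrotonic coupling, which in real
  preparations damps EAD expression.
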