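# Methods

## The biological problem

Atrial myocytes of the rabbit largely lack transverse tubules. Calcium
entering through L-type channels at the cell surface triggers
calcium-induced calcium release only at the peripheral calcium release
units (CRUs); activation of the cell interior relies on a regenerative
"fire-diffuse-fire" wave in which calcium released by one CRU diffuses to
its neighbour and triggers it in turn, producing a centripetal wave.
Chronic rapid pacing remodels the currents and calcium-handling proteins
of these cells and can abolish the inward propagation entirely — "calcium
silencing" — or destabilize it into beat-to-beat alternans. `atriawave`
implements a spatially discretized rabbit atrial myocyte model, a
calibrated population-of-models workflow, eight remodeling scenarios
expressed as multiplicative parameter scalings, and a five-category
calcium-wave phenotype classifier, so the contribution of each remodeling
mechanism can be dissected in silico.

## Cell model

**Geometry.** One transverse slice of the cell is divided into 18 serially
coupled domains with no-flux ends. Domains 1 and 18 carry the sarcolemma
(half of the whole-cell membrane each); every domain contains bulk cytosol
(6.67e-13 L), a network-SR store and a junctional-SR (release) store
(together 6% of the cytosolic volume, 22% of which is junctional), and a
small sub-SR space (SRS, 1%) where CRUs sense and deposit calcium.
Membrane domains add a sub-sarcolemmal space (2%) and a junctional cleft
(0.1%) in which the L-type current accumulates before reaching the CRUs.

**Membrane electrophysiology.** Hodgkin–Huxley formulations are used for
INa (m³hj), Ito1, IKr, IKs, IK1 and ICaT; the L-type current carries
voltage-dependent activation/inactivation gates plus instantaneous
calcium-dependent inactivation sensed in the junctional cleft (half
inactivation at 25 µM cleft calcium). The Na/Ca exchanger uses an
allosteric-saturation formulation (γ = 0.35, saturation factor 0.1)
sensing sub-sarcolemmal calcium; the Na/K pump has Na and K
half-saturations (10 mM, 1.5 mM) and the standard voltage factor; a
plasmalemmal calcium pump and three background currents complete the
sarcolemma. Intracellular potassium is held fixed; intracellular sodium is
a dynamic balance of INa, INab, 3INCX and 3INaK.

**Sodium dynamics.** The physiological sodium turnover time is many
minutes, far beyond any practical pre-pacing protocol, so the sodium pool
is given a reduced effective distribution volume (acceleration factor 14).
This moves the slow Na/NaK/NCX balance to a time scale of tens of beats
while leaving its steady state unchanged; it is a deliberate model
reduction, stated here because it affects how quickly the Na/K-pump
scenario expresses its phenotype.

**Calcium release.** Each domain carries one mean-field CRU with
closed/open/inactivated states. Opening is steeply sigmoidal in SRS
calcium (half-activation 40 µM, Hill 4) and gated by the junctional-SR
load (half-activation 0.40 mM, Hill 8); closing accelerates as the local
store empties, so release terminates by junctional-SR depletion; the
junctional SR refills from the network SR with a 150 ms time constant,
giving post-release refractoriness. A calcium-dependent closed-to-
inactivated pathway (half-activation 0.32 µM SRS calcium, Hill 6) builds
*standing* refractoriness when diastolic calcium is chronically elevated —
this is the substrate by which calcium-overloaded remodeled cells can lose
propagation. The diastolic SR leak scales with the resting open
probability (RyR_P[0] × RyR_P[5]) and RyR density (RyR_P[11] × NRyRs), so
remodeling of those parameters shifts the load balance.

**Remodeling-parameter semantics.** `RyR_P[0]` and `RyR_P[1]` scale the
CRU opening and (inversely) closing rates, `RyR_P[5]` the single-channel
open-probability scale — in the low-calcium linear regime the steady-state
open fraction is proportional to each of them. `RyR_P[11]` and `NRyRs`
enter only through their product with the baseline-normalized release
magnitude. `Jmaxup` (0.0053 mM/ms) is the SERCA maximum flux in a Hill-2
forward/reverse pump with low cytosolic affinity (Kmf 2 µM) and a weak
reverse term. `Buff_factor` multiplies the dissociation constants of the
cytosolic-type buffers (troponin 70 µM/Kd 0.5 µM, calmodulin 50 µM/Kd
2.38 µM, and the membrane-space buffer), so **values below 1 mean stronger
buffering**: 0.15 binds calcium ~6.7× more tightly. Calsequestrin (10 mM,
Kd 0.8 mM) buffers both SR compartments and is not affected by
Buff_factor. Buffering uses the rapid-buffering (instantaneous
equilibrium) approximation throughout.

**Wave propagation pathway.** Release enters the SRS, drains to the bulk
cytosol (3/ms) and spreads to neighbouring domains along two routes: bulk
cytosolic diffusion (0.85/ms per interface) and a sub-SR pathway (0.3/ms)
that represents diffusion at the z-line/release-site level. The SRS route
carries the trigger: it lets the local trigger signal reach tens of µM —
and hence a safely high CRU activation threshold — while bulk free-calcium
transients stay in the ~0.3 µM range observed experimentally. The
network-SR compartments of neighbouring domains are also weakly coupled
(0.1/ms), representing SR lumenal continuity, which equalizes store load
along the cell.

**Baseline parameterization.** The conductances were fitted so the
baseline cell at 1 Hz shows a rabbit-atrial control phenotype: APD90
≈ 95 ms, RMP ≈ −78 mV, membrane CaT amplitude ≈ 0.33 µM, CD50 ≈ 90 ms,
full centripetal propagation (CaT ratio ≈ 0.96) with membrane-to-centre
activation spreading over ~30 ms, diastolic calcium ≈ 0.13 µM, SR content
≈ 0.72 mM, diastolic Na ≈ 9.3 mM. The membrane ignition margin is
deliberately tight: triggering fails when the L-type conductance falls
below roughly 0.85× its baseline-equivalent trigger strength. This is a
design choice, not an accident — it reproduces the experimental
observation that a 60% ICaL reduction silences every member of a
heterogeneous calibrated population, because calibration (which demands
full propagation) retains only models whose net trigger strength is above
the ignition threshold, and scaling any such model's GCaL by 0.4 puts it
below.

## Numerics

The production integrator is an operator-split fixed-step scheme:
Rush–Larsen exponential updates for the 11 Hodgkin–Huxley gates (evaluated
at the pre-step voltage) and a Heun (second-order predictor–corrector)
step for the voltage, ion and CRU states. The default step is 0.05 ms;
population screening uses 0.1 ms. Both satisfy the refinement criterion
(halving the step changes APD90 by < 1 ms and CaT amplitude by < 2%). An
adaptive LSODA mode over the same right-hand side (rtol 1e-6, atol 1e-9)
is available for verification runs. Integration is deterministic: equal
inputs give bit-identical outputs. A non-finite state aborts the run and
the result is flagged failed (the classifier maps it to category
"other"). With all sarcolemmal calcium fluxes disabled the scheme
conserves total (free + buffered, volume-weighted) cell calcium to ~1e-7
relative over 1 s.

The packaged initial condition is the end-diastolic state of the baseline
cell after 150 pre-pacing beats at 1 Hz; study runs prepend 50 further
pre-pacing beats (configurable) so each remodeled parameter set
re-equilibrates before the 10 recorded beats. Remodeling scenarios with
slow secondary dynamics (sodium accumulation, store unloading) are only
partially equilibrated at that depth; the recorded window reflects the
state after 50 s of remodeled pacing, which is the declared study
condition.

## Population and calibration

Candidates share the baseline calcium-handling block and vary eight
maximum conductances (GCaL, GNa, Gto1, GKr, GKs, GK1, ImaxNCX, ImaxNaK)
by independent log-uniform multipliers in [0.5, 2] (Latin-hypercube
sampling optional). Calibration simulates each candidate (50 pre-beats +
10 recorded at 1 Hz) and accepts it iff: mean APD90 ∈ [70, 122] ms, RMP
∈ [−82, −74] mV, membrane CaT amplitude ∈ [0.19, 0.47] µM, mean CaT ratio
≥ 0.5 (full propagation), no alternans, and no afterdepolarization
(re-rise of V more than 5 mV above the running diastolic envelope). The
default control population takes the first 16 passers (8 in the
scaled-down acceptance configuration) from a 300-candidate pool; the
acceptance yield is a few percent — severe attrition is the norm when
multi-criterion physiological windows screen wide conductance ranges.
Calibration is a pure
deterministic filter, so every accepted model re-simulated passes again.

## Classification

Per model, the last 10 recorded beats give a membrane amplitude sequence
(mean of the two membrane domains) and a per-beat central-to-membrane
amplitude ratio (centermost two domains). Alternans: some consecutive
amplitude pair differs by more than 5% of the larger of the two (pairs
with both amplitudes zero are ignored). Silencing: the ratio is ≤ 0.10 on
*every* beat (boundary inclusive). Validity screens run first:
repolarization failure (diastolic V never returns within 15 mV of the
cell's resting potential), irregular dynamics (the amplitude sequence is
neither period-1 nor period-2 within 5% between consecutive same-phase
beats — comparing consecutive beats makes a slow convergence drift
acceptable while genuine aperiodicity is not), or integrator failure; any
flag yields "other". Otherwise silencing ∧ alternans →
alternans-and-silencing, else silencing, else alternans, else normal.

## Synthetic line scans

The generator writes domains × time matrices with a
difference-of-exponentials beat waveform (rise 5 ms, decay 60 ms),
per-domain centripetal delay, center-ward attenuation, even-beat
alternation scaling, seeded Gaussian noise, and an accompanying analytic
AP train whose APD90 is known in closed form (with an optional
repolarization-failure variant). These traces exercise the biomarker and
classifier code paths end to end without the ODE model; they share the
simulator's container and text format. What they do *not* emulate:
stochastic spark noise, motion artefacts, indicator dynamics, or any
coupling between voltage and calcium — so classifier tests on synthetic
data validate the decision rules, not the physiology.

## Design choices where the ground was open

- Mean-field deterministic CRU gating (one effective unit per domain):
  the target phenotypes are deterministic wave categories, so stochastic
  per-channel gating would add cost without changing the classification.
- NRyRs is treated as a dimensionless release-magnitude scale normalized
  to its baseline 198000; only its ratio to baseline enters the model.
- Whether Buff_factor scales buffer concentration or affinity is not
  observable at the level of the studied phenotypes; affinity scaling was
  chosen and the direction (0.15 → stronger buffering) is fixed by the
  remodeling table's pairing.
- Pacing rate: remodeled populations are represented purely by parameter
  scalings and paced at 1 Hz; rapid-pacing is not itself simulated.
- CD50 is measured relative to the per-beat pre-stimulus diastolic level,
  threshold at diastolic + 50% of amplitude, with linear interpolation.
- RMP is the diastolic minimum over the final 50 ms before each stimulus
  (a plateau-mean option exists).

## Problem sizes

The default study uses a 300-candidate pool, 16 accepted models, 50
pre-pacing beats + 10 recorded per run, and a 0.05 ms step. The
acceptance script runs the scaled-down configuration: 8 accepted models,
0.1 ms screening step, scenarios control/1/7/8. Both configurations were
chosen as the package's standard small-study sizes; all are configurable.

## Known limitations

- The equation set is an original behavioral formulation; agreement with
  experimentally reported rapid-pacing phenomenology is at the level of
  calibration windows and wave phenotypes, and intermediate category
  percentages under the mixed-response scenarios (NCX up, NaK down, RyR
  open probability up) depend on formulation details.
- One transverse slice; no longitudinal propagation, no mitochondria, no
  temperature or β-adrenergic effects, no contraction.
- The accelerated sodium pool compresses the time axis of Na-dependent
  remodeling; only its quasi-steady expression is meaningful.
- Scenario 6 (RyR density 0.25×) reduces the release magnitude ~16-fold;
  the model responds with uniform silencing rather than the zoo of
  unphysiological patterns seen in the reference behavior.
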