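# Methods

`bgreach` simulates two-dimensional arm reaching under closed-loop control
by a cortico-basal-ganglia circuit whose dopamine supply comes from a
simulated population of substantia nigra pars compacta (SNc) neurons.
This note documents the model, its assumptions, the calibration
procedure, and the design choices made where the underlying science left
the design open.

## Model overview

Three nested loops run at three timescales (50 ms behavioural step; the
products below are validated at configuration load):

| loop | timestep | iterations per behavioural step |
|---|---|---|
| STN–GPe lattice | 0.02 ms | 2500 |
| SNc–striatum | 0.025 ms | 2000 |
| cortico-BG (behaviour) | 50 ms | 100 per 5-s trial |

**Outer (sensory-motor) loop.** A kinematic two-link arm (shoulder +
elbow, each joint driven by an agonist/antagonist muscle pair) maps
motor-neuron activations to joint angles, muscle lengths and the planar
hand position.  The proprioceptive cortex (PC) is a Kohonen
self-organising map (SOM) over muscle-length vectors; the prefrontal
cortex (PFC) is a SOM over reachable positions; the motor cortex (MC)
combines a SOM feature layer with a continuous attractor network (CANN)
that integrates proprioceptive, prefrontal and basal-ganglia input.  A
linear readout (four motor neurons) converts the MC output into muscle
activations.

**Inner (cortico-basal-ganglia) loop.**  The striatum evaluates the hand
position with a Gaussian value function of the hand-target distance
(V = exp(−‖X_targ − X_arm‖²/σ_V²), σ_V = 0.8 m) and its temporal
difference δ_V.  The dopamine-derived value difference gates the
cortical drive into direct (D1) and indirect (D2) pathways with
complementary sigmoids (gains a_D1 = −a_D2).  The D2 pathway drives an
excitatory-inhibitory STN–GPe lattice (8×8, Gaussian lateral coupling);
GPi combines the direct-pathway signal with the STN output, and a
thalamic relay feeds the result back into MC.

**Central (nigrostriatal) loop.**  64 SNc neurons, each a reduced
single-compartment soma (a fast inward current, a delayed-rectifier
potassium current with the passive leak folded in, an L-type calcium
current, a PMCA pump and an NCX exchanger in Morris–Lecar form) coupled
to a biochemical terminal (levodopa synthesis from tyrosine with
autoreceptor inhibition, AADC conversion to cytosolic dopamine, VMAT
packing into a vesicular pool that sets the readily releasable pool,
calcium-dependent release, DAT reuptake and enzymatic clearance).
Striatal GABA feedback inhibits the soma as a decreasing sigmoid of δ_V;
pooled extracellular dopamine (sum over living terminals divided by the
configured population size) is read back out as the SNc-derived value
difference δV^SNc through a calibrated affine map.

**Parkinsonian conditions.**  A lesion kills a seeded fraction of SNc
neurons by clamping their membrane potential at −80 mV, silencing their
terminals; the pool shrinks proportionally.  Two routings are
distinguished: PD1 (striatum only; the STN lateral coupling ε_s follows
the *computed* δ_V) and PD2 (striatum + STN; ε_s follows the collapsed
δV^SNc).

**Medication.**  Oral levodopa enters a gut depot, is absorbed
first-order into a two-compartment plasma model (advanced with the exact
matrix exponential, so mass balance and superposition hold to machine
precision), crosses into the terminals through the competitive aromatic
amino-acid transporter, and feeds the terminal levodopa pool.  A
medication session samples the plasma curve, equilibrates the slow
terminal pools to each sampled level, and runs reaching trials.

## How the closed loop produces movement and its disorders

The PFC recall drive is trained to evoke, for any target position, a
narrow "goal spike" in MC at the site whose posture puts the hand on the
target.  The motor-neuron stage decodes the MC output as a population
vector (the output grid is normalised by its total activity before the
linear readout), so the command interpolates between the current-posture
representation and the goal.  A second-order low-pass at the muscle
stage (excitation then activation, per-stage constant `mn_beta`) turns
the command into a smooth reach of ~0.5 s.

Dopamine enters through the indirect pathway.  While dopamine signals
improvement (δV^SNc above the gating threshold), λ_D2 is small and the
STN–GPe lattice idles at its noise floor.  When the dopamine signal is
tonically collapsed (cell loss), λ_D2 stays high, the D2-gated cortical
drive excites the lattice, and the thalamic relay injects its envelope
back into MC; this mass competes with the goal spike for the population
decode and progressively stalls the reach.  In PD2, ε_s additionally
rises with the collapsed δV^SNc: past the lattice's locking transition
the population synchronises, the relay becomes a large spatially uniform
mass, and the arm freezes (rigidity with near-zero velocity and
synchrony >0.9).  Levodopa refills the terminal pools, raises the pooled
dopamine back over the gating/coupling anchors, and releases the arm;
as plasma falls the deficit returns (wearing-off).

A known limitation: at 25 % cell loss the dopamine signal during a
successful reach stays close to control's, so the simulated 25 % deficit
is much milder than the reference behaviour; 50 % and 75 % loss and all
PD2 phenotypes are reproduced.

## Calibration

`calibrate()` re-fits three couplings from scratch, in this order:

1. **Dopamine read-out.**  A scan holds δ_V at eleven values, lets the
   population settle, and records the pooled dopamine response.  An
   unanchored least-squares affine fit δ ≈ gain·(DA − crossing) defines
   δV^SNc.  The response saturates near ~300 nM on the positive side and
   floors near ~20 nM, which places the zero crossing (~130 nM) well
   above the resting level (~50 nM): any substantial cell loss then reads
   out as a persistently negative value difference, while the healthy
   population crosses into "Go" as soon as movement raises release.
2. **STN coupling map.**  A synchrony-versus-coupling scan of the
   unforced lattice finds the largest coupling with synchrony ≤ 0.1
   (ε_lo) and the smallest with ≥ 0.9, multiplied by a 1.5× robustness
   margin because a striatally driven lattice needs more coupling to
   lock (ε_hi).  The map's value-difference anchors are expressed as
   fractions (0.55 and 0.95) of the span between the healthy resting
   read-out and a 25 %-survival population's resting read-out, which
   keeps the healthy operating point a fixed safety margin below the
   coupling onset across calibrations.
3. The MSN gating threshold is a fixture constant (θ = 0.08 on the
   δV^SNc scale) chosen between the dopamine levels reached during
   healthy and lesioned movement.

## Training

Motor babbling draws desired activations on the complementary manifold
(agonist + antagonist = 1 per joint — the posture map is otherwise not
invertible), drives the arm, and trains the PC/PFC/MC SOMs with a
standard Kohonen schedule (rate 0.5 → 0.01, radius N/2 → 1, exponential
decay).  The PFC→MC projection learns, by a normalised delta rule, to
recall a sharpened peak-normalised copy of the feature pattern of the
posture that reaches each position; two closed-loop aim-correction
rounds then re-aim each recall at the inverse-kinematics posture that
cancels the residual equilibrium bias of the posture/recall mixture.  The motor readout is supervised on
the steady MC outputs under *both* proprioceptive and recall drive, so
both families of cortical patterns decode to the correct activations.
Loop consistency (activations → arm → cortex → activations) reaches a
mean absolute error of ~0.02 on held-out activations (tolerance 0.1).
Because training is stochastic, each realisation is validated (the
closed-loop equilibrium must land within 0.07 m of the configured target,
the loop error under 0.1, and two probe reaching trials must succeed);
a failing realisation restarts with a derived seed, as in
multi-initialised clustering.

## Numerical choices

- Explicit Euler throughout; the CANNs integrate at the 50-ms
  behavioural step, the lattices and neurons at their fine steps.  The
  slow terminal chemistry sub-steps every 10th soma step.
- CANN convolutions are circular (torus); the STN/GPe lateral operators
  exclude the autapse (centre) term.
- The STN output oscillates at tens of hertz, so the thalamus receives
  the per-window RMS *envelope* of each unit rather than an
  instantaneous sample (which would alias to zero across a 50-ms step).
- The STN/GPe units carry a small seeded band-limited noise current
  (amplitude 0.15, redrawn every 25 internal steps) and ±5 % time-constant
  heterogeneity; this keeps the weak-coupling regime irregular and
  desynchronised.  All noise flows from the trial seed.
- Striatal outputs are rectified (firing rates); an optional smooth rate
  ceiling is configurable and inactive at the fixture's signal scales.
- Non-finite states raise immediately (blow-up guards) rather than
  propagating.
- The two fine-timestep inner loops have numba-compiled kernels that
  mirror the numpy reference implementations to ~1e-14; tests assert the
  agreement, and the numpy path is used automatically when numba is
  unavailable.

## Units and nondimensionalisation

Soma: mV, ms, µM calcium; the flux-to-voltage conversion F·vol_cyt is
normalised to 1 so fluxes are numerically equal to currents, and the
lumped membrane constant C_snc·AR_pmu appears as C_m = 20.  Terminal:
µM for levodopa and the cytosolic/vesicular pools, nM for extracellular
dopamine (release flux in nM/ms; the vesicular drain carries the
1/1000 µM↔nM factor).  PK: mg, L, 1/h.  Supplement-only functional
forms are closed as follows and each sits behind its own function so
alternatives can be swapped: Hill-4 release probability plus a
calcium-independent spontaneous component (which keeps a healthy
population's release floor well above a deeply lesioned pool's),
Michaelis–Menten DAT reuptake, first-order enzymatic clearance,
Michaelis–Menten AADC conversion, saturable VMAT packing with
first-order vesicular turnover.

## What the defaults emulate — and what they do not

The shipped fixture uses anthropomorphic arm geometry (links 0.30 m and
0.35 m, 5-cm muscle levers), a fixed target at (0.30, 0.35) m about
0.66 m from the start posture, 20×20 cortical and thalamic grids, an
8×8 STN/GPe lattice, and 64 SNc neurons — sizes chosen so a full 5-s
trial runs in a few seconds on one CPU.  With them the control condition
reaches in ~0.5 s at ~1.9 m/s peak velocity with a dopamine transient
peaking near 300 nM; cell-loss sweeps reproduce slowed and failed
reaches, the tremor-to-rigidity transition of the dual (striatum + STN)
lesion, and levodopa's restore-then-wear-off time course.  The generator
produces a single fixed reaching task with seeded stochasticity only in
the network dynamics; it does not emulate trial-to-trial target
variation, sensory noise, muscle fatigue, or progressive degeneration
within a session, so passing tests demonstrate the mechanisms' internal
consistency rather than quantitative fidelity to any particular
experimental subject.  Velocity peaks earlier in the simulated reach
(~0.1 s) than in human data (~0.2 s): the command is quasi-ballistic and
the bell shape comes from the muscle filter alone.

## Known limitations

- The 25 %-cell-loss deficit is under-expressed (see above).
- The hyperdirect pathway, SNr, cholinergic interneurons, force-based
  arm dynamics, and progressive degeneration are out of scope.
- The synchrony measure (variance of the mean field over the mean unit
  variance, computed in 200-ms blocks) is a standard bounded stand-in;
  other definitions would shift absolute values.
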