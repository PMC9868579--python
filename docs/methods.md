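# Model and methods

## Scope and state vector

`purinesim` integrates a single well-mixed cell with LSODA
(`scipy.integrate.solve_ivp`, rtol 1e-6 / atol 1e-9, storage every 1 s)
over a 23-component state vector:

| block | states | units |
|---|---|---|
| extracellular pool | ATP, ADP, AMP, UTP | µM |
| P2X gating | P2X4 open/desensitized, P2X7 open | fractions |
| Gq branch | active Gαq, PLCβ, IP₃, DAG, PKC | a.u. / nM |
| calcium | cytosolic Ca²⁺, ER Ca²⁺, CaM·Ca | nM / µM / nM |
| migration | PI3K recruitment, pAkt, distance | – / a.u. / µm |
| cytokine | NFAT active + nuclear, TNFα mRNA/protein/exported | fractions / a.u. |

Spatially resolved Ca²⁺, membrane potential/K⁺ currents, store-operated
entry, CD73/adenosine, and stochastic single-channel gating are outside the
model by design.

## Nucleotide pool (CD39)

Two Michaelis–Menten steps, ATP→ADP→AMP, with a shared enzyme-density
multiplier (1 = wild type, 0 = knockout). Defaults put the chain in its
effectively first-order regime (Km = 10 mM ≫ doses): k₁ = 0.0155 s⁻¹ for
the ATPase step and k₂ = 4.2×10⁻⁴ s⁻¹ for the ADPase step. These are
phenomenological rates chosen jointly so that (a) ATP falls below 5% of the
bolus within ~3 minutes, (b) the ADP intermediate peaks at t ≈ 4 min — the
timing that makes pAkt maximal near 4 min — and (c) ADP persists long
enough (τ ≈ 40 min) to sustain the hour-scale migration integral. In the
first-order limit ADP(t) follows the closed bi-exponential
k₁a₀(e^(−k₁t) − e^(−k₂t))/(k₂−k₁), which the tests use as the analytic
oracle. UTP is not a CD39 substrate; AMP is a terminal sink.

## P2X4 / P2X7 gating

Minimal mass-conserving Markov schemes with Hill-shaped agonist occupancy.
P2X4 (C↔O→D→C) has EC50 = 10 µM (n = 1.5), opens within seconds and
desensitizes (0.05 s⁻¹) with slow recovery, giving the sharp, brief
micromolar transient. P2X7 (C↔O) has EC50 = 700 µM (n = 1.35) and no
desensitization, giving the millimolar plateau. Open fractions convert to
cytosolic Ca²⁺ influx linearly in the expression multiplier ρ (g_X4 = 80,
g_X7 = 300 nM/s at ρ = 1); the conductances absorb the cell-volume/Faraday
factor of the well-mixed compartment. EGTA zeroes only the Ca²⁺ driving
term; gating continues to evolve.

## Gq/IP₃/DAG/PKC oscillator

The Cuthbertson–Chay-lineage loop: agonist-occupied P2Y2 activates Gαq
(capacity 100 a.u.), Gαq activates PLCβ, PLCβ produces IP₃ and DAG, and
PKC — activated cooperatively by DAG (Hill 4) and promoted by cytosolic
Ca²⁺ — both inhibits PLCβ and accelerates Gαq deactivation (quadratic in
PKC). Two numerical choices matter:

- PKC deactivates through a Michaelis (zero-order) term. This
  ultrasensitivity is what turns the loop into a genuine relaxation limit
  cycle; with plain first-order decay every parameterization we examined
  only rings transiently before settling.
- PKC feedback acts on both PLCβ and Gαq deactivation. Inhibition of PLCβ
  alone cannot deplete active Gαq, and the observed cycles climb to ~80 of
  the 100 a.u. Gαq capacity before collapsing, which requires the
  deactivation route.

At 1 mM ATP without hydrolysis the cycle is sustained (period ~70 s, Gαq
max ≈ 80 a.u.); 100 µM gives smaller cycles; with CD39 active the agonist
decays and the cycles shrink to a decaying transient. Reducing the
activation-rate input `k_g_cc` ~50-fold crosses a bifurcation to
single-peak behavior — below threshold the basal Gαq deactivation
(0.02 s⁻¹) dominates and DAG never reaches the PKC switch.

## Calcium handling

Cytosol and ER exchange through IP₃R release (open fraction cooperative in
IP₃ and in cytosolic Ca²⁺, i.e. deterministic CICR), SERCA uptake (Hill 2,
Vmax 200 nM/s, K 200 nM) and an ER leak; the plasma membrane carries P2X
influx, NCX extrusion (Vmax 150 nM/s, K 300 nM) and a constitutive influx.
CaM (5 µM total, Kd 1 µM) is an explicit fast buffer whose bound form
drives calcineurin and MLCK. The resting state is constructed, not tuned:
the ER load is derived from the leak/SERCA balance (≈400 µM at the default
leak 10⁻⁴ s⁻¹) and the constitutive influx from the NCX balance, so 100 nM
cytosolic Ca²⁺ is an exact fixed point for any choice of the other rates.
The IP₃R rate (3.13×10⁻⁴ s⁻¹ per nM gradient) is the single constant
calibrated to the 180 nM first peak of the P2X7-null 1 mM protocol. With
every membrane flux closed, total Ca²⁺ (cytosol + CaM-bound +
volume-weighted ER, volume ratio 0.18) is conserved to integrator
tolerance; this is asserted in the tests.

## PI3K / pAkt / migration

PI3K drive has two routes. The P2Y12/Gi route is a Hill function of ADP
(n ≈ 0.48, K ≈ 8 mM — over the micromolar range effectively a power law)
scaled by ρ_P2Y12. The Ca²⁺ route is modeled as slow membrane recruitment
of PI3K: a saturating Hill sensor of Ca²⁺ above baseline drives a
recruitment state m (on-rate 0.33 s⁻¹ at saturating Ca²⁺, reversal
5.7×10⁻⁴ s⁻¹, τ ≈ 30 min). Recruited PI3K multiplies the P2Y12 term
(1 + 7.56·m) and carries a small P2Y12-independent activity (0.071·m).
The slow reversal is a deliberate design choice: an instantaneous Ca²⁺
sensor cannot simultaneously give the knockout reductions of *peak* pAkt
(which occurs at ~4 min, after the Ca²⁺ transient) and the persistence of
P2Y12-null migration over an hour. pAkt relaxes toward the drive at
0.064 s⁻¹ and is reported normalized to the peak of the 50 µM wild-type
run (absolute reference 8.807, a frozen calibration constant).

At 50 µM/5 min the P2Y12-dependent and Ca-dependent contributions to peak
pAkt partition 90:10; P2X4 and P2X7 knockouts reduce the peak ≈40% and
≈12% through their shares of the recruiting Ca²⁺ signal; EGTA removes
≈75% of the Ca-conducted component, quantified against a run with the
Ca→PI3K inputs clamped at rest.

The migration rate is a Michaelis function of normalized pAkt
(half-saturation 0.30, 0.0211 µm/s at saturation) times a CaM/MLCK
efficiency that is neutral (1.0) at resting CaM·Ca; the calibrated default
gain of that efficiency is 0 (the term is in place for refitting). The
saturation — rather than strict proportionality — is what lets a 90% pAkt
knockdown appear as a ~75% distance reduction, and compresses the early
peak so that the 1-hour distance is ~11× the 5-minute distance (4.2 µm →
46 µm at 50 µM). Calibrated values land at 45.7 µm (1 h), 4.23 µm (5 min),
75.0% (P2Y12-null) and 69.6% (BV2 preset, mean over 50/100/500 µM); the
joint calibration could not pull the hour distance closer to 48 µm without
breaking the pAkt peak-time structure.

## NFAT / TNFα

CaM·Ca activates calcineurin (Hill 3, K 1.5 µM), which dephosphorylates
cytosolic NFAT; active NFAT imports into the nucleus at 0.005 s⁻¹ and
exports at 0.002 s⁻¹, so nuclear accumulation is minutes-slow — the
mechanism separating migration-permissive short waveforms from
transcription-inducing sustained ones. Transcription is linear in nuclear
NFAT above its basal fraction; mRNA, protein and exported protein are in
arbitrary units (an optional linear calibration to secreted pg-equivalents
can be layered on). NFAT fractions are conserved by construction.

## Expression presets and protocols

Receptor densities scale linearly with mRNA-derived multipliers:
primary = (1, 1, 1, 1), BV2 = (0.18, 0.65, 1.02, 0.030) for
(P2X4, P2X7, P2Y2, P2Y12). Protocols specify agonist (ATP or UTP; UTP
reaches only P2Y2), dose, onset, optional washout, CD39 multiplier, EGTA
flag and expression preset. Shipped presets cover the standard protocols
(resting control, 1 mM ± CD39, P2X7-null, the 50 µM dose/knockout panel,
the waveform-sensitivity scan, BV2 Ca²⁺ and migration, a UTP demo).

The waveform-sensitivity scan runs 200 µM for 5 min at CD39 multiplier 0.2
(so the oscillation survives the collection window) and measures realized
waveform features from the Ca²⁺ trace itself: the amplitude panel scans
`k_g_cc`, the frequency panel scans the PKC deactivation rate `d_pkc`
(which sets the refractory period; `k_g_cc` leaves the realized frequency
nearly unchanged in this parameterization). Both normalized migration and
TNFα increase monotonically along both axes, TNFα faster.

## Fitting

A genetic algorithm (tournament selection k = 3, BLX-0.4 crossover and
Gaussian mutation in log space, elitism 1) refines any dotted parameter of
`ModelParams` against waveform/endpoint features under a weighted
squared-relative-error objective; failed simulations receive a large
finite penalty. All randomness flows from one recorded seed; the best loss
is non-increasing across generations. At population 32 / 40 generations it
recovers the ER leak rate and P2X4 conductance from a self-generated
100 µM Ca²⁺ trace to well under 10% (about 1.5 min on one CPU).

## Imaging pipeline

Cell detection on a (T, M, N) 16-bit stack: time-sum → log transform →
min-max normalization → threshold (Otsu by default, manual override) →
connected-component labeling. Touching cells merge (no watershed); motion
and photobleaching correction are out of scope. Per-cell traces are mean
label-pixel intensities per frame, normalized to a pre-stimulus control
window by division (F/F₀, default) or subtraction; ensemble summaries use
a centered window-8 moving average with a running variance band.
Displacements convert pixel vectors to micrometers at 1.6 µm/px.

The synthetic generator places Gaussian-blob cells (σ = radius/2) on a
jittered grid, injects exponential-decay transients at a known onset, and
adds Poisson shot noise plus Gaussian read noise, all from one seed. It
emulates the intensity statistics of a widefield Fluo-4 recording but not
cell motion, morphology changes, bleaching, or overlapping somata — so
passing tests certify the extraction arithmetic and segmentation logic,
not robustness to those real-data effects. At SNR ≥ 5 the pipeline
recovers the cell count exactly, centroids within 2 px, traces at
correlation ≥ 0.95 and onsets within one frame.

## Problem sizes and numerical notes

Standard runs integrate 10 simulated minutes (migration panels: 1 hour)
with 1 s storage; each takes well under a second on one CPU, and the whole
calibration-target recomputation is a few seconds. Halving the integrator
tolerances changes stored Ca²⁺ by < 0.1 nM. An optional fine-step mode
caps the internal step at 0.1 ms for short regression runs. State clipping
at the RHS boundary (occupancy simplices, non-negative concentrations)
guards against tolerance-scale excursions by the stepper; a non-finite
state aborts the run naming the offending variable.

## Known limitations

- The knockout/dose calibration is an effective-parameter fit; individual
  constants (e.g. the ADP Hill constant, the CD39 rates) are
  phenomenological and should be re-estimated before quantitative use on
  new data (`purinesim fit`).
- P2X7-null pAkt reduction calibrates to ~12% against the ~15% reference,
  and the 1-h migration to ~46 µm against 48 µm; both sit inside the
  registry tolerance bands but are the weakest points of the joint fit.
- Early high-dose Ca²⁺ in this parameterization is carried mainly by
  P2X4/IP₃R rather than P2X7, so the BV2 preset reduces the 500 µM 20-s
  transient more strongly (~50%) than the mRNA-share argument (~15%)
  suggests.
- Deterministic equations describe ensemble averages; single-cell
  variability, stochastic IP₃R clusters, and spatial Ca²⁺ microdomains are
  not represented.
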