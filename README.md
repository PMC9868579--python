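# purinesim

A deterministic whole-cell model of ATP-stimulated microglia, plus the
fluorescence-imaging pipeline used to extract per-cell Ca²⁺ traces from
time-lapse stacks.

Microglia sense extracellular nucleotides through two receptor classes:
ionotropic P2X channels (P2X4 opens at micromolar ATP and desensitizes;
P2X7 needs near-millimolar ATP and stays open) and metabotropic P2Y
receptors (P2Y2 couples ATP/UTP to Gαq→PLCβ→IP₃/DAG and ER Ca²⁺ release;
P2Y12 couples ADP to Gi→PI3K→pAkt and migration). The surface
ectonucleotidase CD39 hydrolyzes ATP→ADP→AMP, so the agonist pool itself is
dynamic: CD39 simultaneously terminates P2X/P2Y2 signaling and *creates*
the P2Y12 agonist. The model couples these pathways to cytosol/ER Ca²⁺
handling (IP₃R, SERCA, NCX, leak, CaM buffering), a
CaM→calcineurin→NFAT→TNFα transcription branch, and a pAkt-driven
migration readout — one stiff ODE system (23 states, LSODA) driven by
declarative stimulus protocols.

The model reproduces, among others: a 100 nM resting Ca²⁺ baseline; a
180 nM first Ca²⁺ peak for 1 mM ATP with P2X7 silenced; IP₃/DAG relaxation
oscillations whose cycles shrink when CD39 is active; pAkt that peaks ~4 min
into a 50 µM ATP application (tracking the CD39-produced ADP transient) and
scales +50%/+300% at 100 µM/1 mM; knockout pAkt reductions
(P2Y12⁻/⁻ ≈ 90%, P2X4⁻/⁻ ≈ 40%, P2X7⁻/⁻ ≈ 15%, EGTA ≈ 75% of the
Ca-conducted component); and migration distances of ≈4 µm at 5 min and
≈46 µm at 1 h for 50 µM ATP, cut ~75% by P2Y12 knockout and ~70% by the
BV2-cell expression profile.

## Worked example

```python
from purinesim import ModelParams, Protocol, run

params = ModelParams()
traj = run(Protocol(dose_uM=50.0, horizon_s=300.0), params)   # 50 uM, 5 min
feats = traj.ca_features()
print(f"Ca peak   {feats['peak_value']:.1f} nM at t = {feats['time_to_peak']:.0f} s")
print(f"pAkt peak {traj.pakt_norm.max():.2f} at t = {traj.t[traj.pakt_norm.argmax()]:.0f} s")
print(f"distance  {traj.distance[-1]:.2f} um after 5 min")
```

prints

```
Ca peak   168.8 nM at t = 36 s
pAkt peak 1.00 at t = 248 s
distance  4.23 um after 5 min
```

i.e. a ~69 nM Ca²⁺ transient above the 100 nM baseline peaking 36 s after
ATP addition, normalized pAkt maximal (1.0 by definition of the reference
protocol) at ~4.1 min, and 4.2 µm of accumulated movement in 5 minutes.

Knockouts and phenotypes are expression multipliers:

```python
from purinesim import ReceptorExpression
p2x7_null = Protocol(dose_uM=1000.0, horizon_s=600.0,
                     expression=ReceptorExpression(1, 0, 1, 1))
print(run(p2x7_null, params).ca_features()["peak_value"])   # -> 179.9 (nM)
```

The command line mirrors the library: `purinesim simulate --config run.yaml
--out out/`, `purinesim preset fig4_p2x7ko`, `purinesim matrix --out
fig5d.csv`, `purinesim fit --spec fit.yaml --out params.json` (genetic-
algorithm refinement), and `purinesim traces --stack stack.tif --control
0:600 --out traces.csv` for the imaging pipeline.

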