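# fateswitch

Simulation and single-cell analytics for the epiblast-versus-primitive-endoderm
(Epi/PrE) fate decision, modelled as a bistable NANOG/GATA mutual-repression
circuit driven by a pulse of exogenous GATA and modulated by FGF/MAPK
signaling.

Embryonic stem cells pre-cultured with MAPK inhibited sit in a NANOG-high,
GATA-low state. A transient (6 h) pulse of exogenous GATA — heterogeneous in
strength from cell to cell — pushes a fraction of the population across the
separatrix into the GATA-high PrE-like state, where it stays after the pulse
decays: the circuit is an irreversible toggle switch. The package is for
quantitative/systems biologists who want to simulate this circuit, analyse
its phase-plane and quasi-potential structure, and run the measurement
analytics used on real time-lapse and flow-cytometry data (ROC fate
prediction, hierarchical trace clustering, histogram peak analysis) on
synthetic data with known ground truth.

## Model

Per cell, three ODEs for NANOG `N`, endogenous GATA `G` and exogenous GATA
`G_X` (concentrations in arbitrary units, time in hours):

```
dN/dt   = α_N f_N(s) / (1 + ((G + G_X)/K_GN)^h_N)  −  γ_N N
dG/dt   = α_G f_G(s) / (1 + (N/K_NG)^h_G)          −  γ_G G
dG_X/dt = D·u(t)  −  γ_X G_X
```

`u(t)` is 1 during the induction pulse `[t_start, t_end)` and 0 otherwise;
exogenous and endogenous GATA repress NANOG through their sum. The per-cell
maximum exogenous production rate `D` ("dose", drawn log-normally) is the
only source of cell-to-cell variability. Signaling level `s` enters either
as NANOG inhibition `f_N(s) = 1/(1+(s/K_s)^m)` (the default coupling) or as
GATA promotion `f_G(s) = s^m/(K_s^m+s^m)`.

At default parameters and saturated signaling, the autonomous (`G_X = 0`)
system has exactly three equilibria — a stable NANOG-high Epi state, a stable
GATA-high PrE state, and a saddle whose stable manifold is the separatrix.
Lowering `s` under the NANOG-inhibiting coupling strengthens NANOG, shrinks
the PrE basin of attraction and raises the critical dose `D*` needed to flip
a cell, which is how signaling sets the fate proportions of a population.

## Worked example

```python
import numpy as np
from fateswitch import (ModelParameters, PulseProtocol, DoseDistribution,
                        find_equilibria, critical_dose, generate_timelapse,
                        roc_timecourse)

params, protocol, dist = ModelParameters(), PulseProtocol(), DoseDistribution()

for eq in find_equilibria(params):
    print(f"{eq.stability:>6}  N={eq.N:.3f}  G={eq.G:.3f}")
print("critical dose D* =", round(critical_dose(params, protocol), 3))

data = generate_timelapse(params, protocol, dist, n=200, seed=1)
tc = roc_timecourse(data.channel_matrix("G_X"), data.label_vector(true=True),
                    times=data.times, n_boot=100, seed=2)
mask = (data.times >= 3) & (data.times <= 6)
print("plateau AUC =", round(tc.auc_t[mask].mean(), 3))
```

prints

```
stable  N=2.000  G=0.001
saddle  N=0.418  G=0.418
stable  N=0.001  G=2.000
critical dose D* = 0.35
plateau AUC = 0.981
```

— the bistable phase-plane structure (two mutually exclusive expression
states separated by a saddle), the dose above which the 6 h pulse commits a
cell to the PrE-like fate, and the plateau separability of the two fate
classes by the noisy exogenous reporter during the pulse.

A command-line interface mirrors the library: `fate-switch simulate`,
`phaseplane`, `potential`, `sweep`, `roc`, `cluster`, `peaks` and
`synth`, all driven by a YAML config (see `src/fateswitch/defaults.yaml`)
with `--seed`/`--out` flags and provenance records next to every output.

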