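# retinox

Hybrid simulation of retinal microvascular blood flow and tissue
oxygenation: a heterogeneous arteriolar tree with active flow regulation,
coupled to Green's-function oxygen transport in the arteriolar tissue and
Krogh-cylinder transport in lumped capillary/venule compartments.

## Who this is for

Researchers in ocular hemodynamics and computational physiology who want
to ask how the *geometry* of an arteriolar branch — its branching pattern,
pathway depths, capillary allocation — shapes tissue oxygenation, oxygen
extraction, and the response to changed oxygen demand, capillary density,
or impaired autoregulation. Because patient-specific network geometries
are rarely available, the package includes a seeded generator of
anatomically plausible arteriolar trees, so that geometric heterogeneity
itself becomes an experimental variable.

## The model

- **Hemodynamics.** Each vessel obeys Poiseuille's law,
  Q = ΔP·πD⁴/(128 µL); conservation of flow at nodes gives a linear
  system solved by successive over-relaxation, with fixed inlet
  (40 mmHg) and terminal-outlet (24 mmHg) pressures. Discharge
  hematocrit (inflow H_D = 0.4) propagates under red-cell flux
  conservation, and apparent viscosity follows an empirical µ(D, H_D)
  law; the schemes alternate to convergence.
- **Flow regulation.** Per arteriole, diameter and smooth-muscle
  activation follow wall-mechanics ODEs: Laplace tension
  T = (P − IOP)·D/2 balances passive + active wall tension
  T_total(D, A), and A tracks a sigmoid of the tone stimulus
  S_tone = C_myo·T − C_shear·τ_wall − C_meta·S_meta + C″_tone
  (myogenic, shear, and conducted metabolic responses; time constants
  τ_d = 1 s, τ_a = 20 s).
- **Oxygen transport.** Arterioles are discrete oxygen sources in a
  Michaelis–Menten-consuming tissue, solved by a Green's-function
  superposition with exact global source/sink balance; each capillary is
  a Krogh cylinder with a tissue sleeve whose width follows from the
  capillary density; blood oxygen follows
  f(P_b) = Q(H_D·C0·S(P_b) + α_b·P_b) with a Hill saturation curve
  (P50 = 26 mmHg, n = 2.7).
- **Metrics.** Oxygen extraction fraction
  OEF = Σ Q_i·(SaO2 − SvO2,i)/(Q_total·SaO2), hypoxic-tissue threshold
  curves, radial Krogh profiles, and capillary-count distributions for
  network comparison.

See `docs/methods.md` for equations, parameter provenance, numerical
methods, and limitations.

## Worked example

```python
import numpy as np
from retinox import GeneratorConfig
from retinox.pipeline import SimulationConfig, run_simulation

cfg = SimulationConfig(
    generator=GeneratorConfig(seed=11, n_terminals=24),
    m0=3.0,                  # oxygen demand, cm3 O2/100 cm3/min
    capillary_density=500.0, # 1/mm2
)
res = run_simulation(cfg)
r = res.report
print(f"Krogh sleeve width d = {res.tissue_width:.2f} um")
print(f"OEF = {r.oef:.3f}")
print(f"arteriolar tissue below 25 mmHg: "
      f"{100 * np.interp(25, r.thresholds, r.threshold_curve):.1f} %")
print(f"mean arteriolar tissue PO2 = {r.mean_tissue_po2:.1f} mmHg")
print(f"corr(capillary length, downstream PO2) = "
      f"{r.length_po2_correlation:.2f}")
```

prints

```
Krogh sleeve width d = 20.47 um
OEF = 0.542
arteriolar tissue below 25 mmHg: 14.9 %
mean arteriolar tissue PO2 = 37.1 mmHg
corr(capillary length, downstream PO2) = -0.98
```

Reading: at an oxygen demand of 3 cm³O2/100 cm³/min this seeded
24-terminal branch extracts 54% of delivered oxygen; about 15% of the
arteriolar tissue sits below 25 mmHg; and pathways with longer
capillaries end at systematically lower PO2 — the downstream signature of
branching heterogeneity. Comparing two seeds with identical inlet
saturation (0.92), pressure drop (16 mmHg), and order diameters isolates
the effect of geometry alone (`retinox.metrics.compare_networks`).

A command-line interface mirrors the pipeline
(`retinox generate | flow | regulate | oxygen | metrics | sweep |
compare`); run `retinox --help`.

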