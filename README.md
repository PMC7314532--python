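# ecsdiff

Analysis of diffusion in brain extracellular space (ECS), for
neurophysiologists working with real-time iontophoresis (RTI) and for
modellers of extrasynaptic (volume) transmission. The package covers two
linked computations:

1. **ECS geometry from tracer curves.** In the RTI paradigm an
   iontophoretic micropipette releases the inert cation TMA⁺ into the
   ECS and an ion-selective microelectrode ~100–150 μm away records the
   concentration transient. The transient is governed by the
   point-source diffusion equation with first-order uptake; fitting it
   yields the ECS **volume fraction** α (ECS volume / tissue volume),
   **tortuosity** λ (λ² = D/ADC, the hindrance factor relating free and
   apparent diffusion), and the nonspecific uptake rate k′ (s⁻¹). For a
   current step of duration *T*, the concentration increment at distance
   *r* is

   C(r,t) = Q/(8π D\*α r) · [e^{rβ} erfc(r/(2√(D\*t)) + √(k′t)) +
   e^{−rβ} erfc(r/(2√(D\*t)) − √(k′t))],  0 < t ≤ T,

   with D\* = D/λ², β = √(k′/D\*), Q = I·n_t/(zF), and the falling
   phase by superposition C(r,t) − C(r,t−T). The workflow mirrors the
   bench protocol: electrode calibration (log-linear, Nernstian), an
   agar reference fit (α=1, λ=1, k′=0 by definition) for the transport
   number n_t and free diffusion coefficient D, then bounded multi-start
   least squares for (α, λ, k′) per tissue curve, repeat averaging per
   depth, cortical-layer assignment, and a two-way group × layer ANOVA
   with a layer-pooling rule.

2. **Dopamine volume transmission under altered ECS geometry.** The
   spherically symmetric reaction–diffusion equation with
   Michaelis–Menten transporter uptake,

   ∂C/∂t = D\*(∂²C/∂r² + (2/r)∂C/∂r) − V_m·C/(K_m + C),

   is solved by conservative finite volumes with a stiff adaptive time
   integrator, with dopamine released as a flux through a 2-μm sphere
   (tonic 1-s current vs charge-matched 20-Hz/4-ms bursts). Comparing a
   control substrate (α=0.20, λ=1.54) against an alcohol-exposed one
   (α=0.19, λ=1.39) quantifies how a looser, less tortuous ECS extends
   the reach of extrasynaptically released dopamine.

Since raw in-vivo recordings are not available, a seeded synthetic-data
module generates every input with known ground truth — single curves,
full two-group cohorts (6 animals/group × 9 depths × 3 repeats, 2%
peak-proportional noise), calibration tables, and random neurite
skeletons for the microglia ramification index.

## Worked example

```python
import numpy as np
from ecsdiff import (ECSParameters, IontophoreticSource, generate_curve,
                     fit_agar, fit_tissue)
from ecsdiff.core import default_times
from ecsdiff.synth import make_curve

src = IontophoreticSource()          # 20 nA bias, +180 nA step, 24 s
free = ECSParameters(alpha=1.0, lam=1.0, kprime=0.0)

# agar reference: recover electrode transport number and free D
agar = fit_agar(generate_curve(src, free, 120.0, default_times(),
                               medium="agar"), src)
print(agar.transport_number, agar.free_D)
# 0.2999999999999999 1.239999999999999e-05

# noisy tissue curve with known truth, fitted for (alpha, lambda, k')
truth = ECSParameters(alpha=0.196, lam=1.503, kprime=0.004)
curve, _ = make_curve(truth, src, r=120.0, noise_fraction=0.02, seed=5)
fit = fit_tissue(curve, agar, source=src)
print(fit.params)
# ECSParameters(alpha=0.1969..., lam=1.5206..., kprime=0.00479...)
```

The fitted α ≈ 0.197 and λ ≈ 1.52 recover the generating truth to
within the scatter implied by 2% measurement noise on a single curve;
averaging 3 repeats × 9 depths per animal, the cohort pipeline
(`analysis/02_fit_cohort.py`) recovers group means to ±0.004 in α and
±0.005 in λ.

## Analysis pipeline

Numbered drivers under `analysis/` reproduce the full study flow and
write tables under `results/`:

| script | what it does |
| --- | --- |
| `01_simulate_cohort.py` | simulate the two-group cohort (324 curves), write truth table |
| `02_fit_cohort.py` | agar fit, per-curve tissue fits, per-depth means, group summary |
| `03_compare_groups.py` | group × layer ANOVA, pooling rule, pooled contrast |
| `04_dopamine_fields.py` | dopamine fields for control/EtOH × tonic/phasic, difference maps, integrals |
| `05_vm_scan.py` | EtOH-control contrast across ±30/60% transporter V_m |
| `06_morphometry.py` | ramification index on synthetic microglial skeletons |

Running `02` then `03` on the default cohort prints a decisive group
effect for both parameters (α: F(1,40)=61.5; λ: F(1,40)=88.7, both
p < 1e-8) with no layer effect, so layers are pooled. Running `04`-`05`
shows the EtOH substrate holds ~5.3% more space-integrated dopamine
during release, for both release modes and across the whole V_m scan.

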