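# Methods

## Point-source diffusion model (core)

The forward model is the classical RTI description of an inert tracer
released from an iontophoretic point source into an isotropic porous
medium: volume fraction α dilutes the source (1/α), tortuosity λ slows
it (D\* = D/λ²), and nonspecific first-order uptake k′ removes it. The
constant-current step response is the two-term erfc expression given in
the README; the post-pulse phase is the superposition of an equal and
opposite step delayed by the pulse duration, and the continuously
applied bias current contributes a steady baseline
C_b(r) = Q_b/(4π D\* α r)·e^{−r√(k′/D\*)}; measured curves are treated
as increments above that baseline.

Numerical care: products e^{x}·erfc(y) overflow for strong uptake or
large distances. With a = r/(2√(D\*t)) and b = √(k′t) the identity
r√(k′/D\*) = 2ab lets the whole bracket be written as
e^{−a²−b²}[erfcx(a+b) + erfcx(a−b)], where erfcx is the scaled
complementary error function; every factor is bounded for admissible
arguments.

Internal units are μm, s, μM; diffusion coefficients are accepted in
cm²/s and converted on entry (1 cm²/s = 10⁸ μm²/s). Key defaults, used
for synthesis only (in analysis both always come from the agar fit):
TMA⁺ free D = 1.24e-5 cm²/s and transport number 0.3, typical bench
values for TMA⁺ microelectrode arrays at body temperature; valence z=1.

## Inverse problem (rti)

* **Electrode calibration** — ordinary least squares of V against
  log₁₀C (Nernstian response); the inverse map 10^((V−offset)/slope)
  converts voltages to concentrations. Non-monotone voltage series are
  flagged, not rejected.
* **Agar fit** — (n_t, D) by bounded least squares with α=1, λ=1, k′=0
  fixed; D is optimised in log₁₀ space since it is a scale parameter.
  Nine starts on a coarse (n_t, D) grid.
* **Tissue fit** — (α, λ, k′) with (n_t, D) fixed; bounds α ∈ (0.01, 1],
  λ ∈ [0.9, 3], k′ ∈ [0, 0.1] s⁻¹. The λ lower bound sits below the
  physical limit 1 so that noise on near-free curves does not pin the
  estimate at the bound; fits ending on any bound carry an `at_bound`
  flag. Multi-start grid α ∈ {0.1, 0.2, 0.3} × λ ∈ {1.2, 1.5, 1.8} ×
  k′ ∈ {0, 0.005}; lowest SSR wins, ties broken by fewest function
  evaluations; a start that reproduces the curve to ~machine precision
  short-circuits the rest of the grid. Non-convergence returns the best
  point flagged `converged=False` so cohort pipelines degrade
  gracefully rather than raising.
* **Fit window** — rise (0–24 s) plus 48 s of decay at 5 Hz, both
  phases weighted equally.
* **Aggregation** — repeats averaged per depth (converged fits only),
  depths mapped to cortical layers (400/600 μm → III, 800 → IV,
  1000–1400 → V, 1600/1800 → VI, 2000 → white matter), and each
  animal × layer cell averaged for the ANOVA. White matter is excluded
  from the layer factor.
* **Group comparison** — two-way fixed-effects ANOVA (group, layer,
  interaction; type-II sums of squares via statsmodels OLS). If neither
  the layer effect nor the interaction reaches p < 0.05, layers are
  pooled; the pooled contrast is reported as a Welch two-sample test on
  per-animal means. This pooled test is an interpretation of the
  pooling step — the ANOVA group effect remains the primary statistic.
  Only α and λ are tested by default (k′ behind a flag), without
  multiplicity correction, matching the two-parameter reporting
  convention of the field.

## Dopamine reaction–diffusion solver (dopamine)

Spherically symmetric diffusion with Michaelis–Menten uptake, dopamine
entering through the surface of a source sphere of radius a:
−D\*∂C/∂r|_a = Q(t)/(4πa²α). The α division reflects that released
molecules occupy only the ECS share of tissue volume.

* **Discretisation** — conservative finite volumes on spherical shells:
  uniform 0.25-μm cells out to 10 μm, then widths growing geometrically
  (factor 1.05) to 2 μm, out to r_pad = 300 μm where C = 0 is imposed
  (≥ 3× the 100-μm reporting window; the release deposits no
  appreciable mass there within 3 s). Because inter-cell fluxes are
  antisymmetric, total ECS mass is conserved to the time-integrator
  tolerance when V_m = 0 — the conservation test measures time error
  only, by construction.
* **Time integration** — BDF (variable order, adaptive) with an
  analytic tridiagonal Jacobian; the integration restarts at every
  source-current discontinuity (2 segments tonic, 41 phasic) so the
  stiff stepper never straddles a jump. rtol 1e-6 / atol 1e-8 μM by
  default; the reported field changes by < 0.2% in max-norm when the
  grid is halved and tolerances tightened.
* **Release protocols** — tonic: 100 nA constant for 1 s. Phasic:
  4-ms bursts at 20 Hz (20 bursts in 1 s). "Normalised" phasic release
  is interpreted as equal delivered charge: burst amplitude
  100 nA × 1 s / 0.08 s = 1250 nA; a same-amplitude alternative is
  selectable. The dopamine transport number defaults to 1.0 (the stated
  source current is treated as fully converted flux), configurable.
* **Kinetics and geometry defaults** — V_m = 0.2 μM/s, K_m = 0.15 μM;
  control substrate α = 0.20, λ = 1.54; EtOH substrate α = 0.19,
  λ = 1.39; D_free = 6.9e-6 cm²/s.
* **Space integrals** — three weightings: `volume`
  (∫Cα4πr²dr, the moles present in the ECS), `spatial` (∫C4πr²dr), and
  `plain` (∫C dr). The moles integral is the conservation diagnostic,
  but it is nearly identical between two geometries holding the same
  released mass, so the EtOH-vs-control contrast is expressed with the
  `spatial` weighting: at equal ECS mass, the smaller EtOH volume
  fraction concentrates dopamine into less fluid, raising concentration
  everywhere by ~α_control/α_EtOH, on top of the redistribution caused
  by the lower tortuosity. This reading of the ambiguous "total
  concentration integrated across all the space" is a package decision;
  both other weightings remain available.
* **V_m scan** — multipliers {−60%, −30%, +30%, +60%} of baseline V_m.
  The printed range "−60 to 30, +30 and +60%" is read as the symmetric
  four-point set (the likelier intent); the set is configurable.

### Oracle comparisons

The solver is validated against the closed-form point-source solution
with uptake linearised (K_m → ∞ at fixed V_m/K_m = k′). The closed form
describes an ideal point source while the solver feeds flux through a
finite sphere, which shifts the diffusion front outward by roughly the
source radius; at leading-edge probes this shift dominates all other
error. The quantitative comparison therefore uses a 0.05-μm source
radius and a refined far grid (0.125-μm cells), achieving < 0.5% at all
nine probe points (r ∈ {20, 50, 80} μm × t ∈ {0.3, 1.0, 2.5} s);
production runs keep the physiological 2-μm radius. An independent
Crank–Nicolson oracle (u = rC substitution, uniform fine grid) checks
the closed form itself in the test suite — the two routes to the same
field never share code.

## Synthetic data (synth)

The generator emulates the RTI study design: two groups × 6 animals ×
9 depths (400–2000 μm) × 3 repeats, electrode spacing drawn once per
animal from U(100, 150) μm. Group truths are the printed cortical
estimates (control α = 0.196, λ = 1.503; EtOH α = 0.176, λ = 1.403);
k′ truth is 0.004 s⁻¹ for both groups, a typical cortical value, since
no group estimate is reported. Per-animal parameters are truncated
normal around the group truth with SDs 0.017 (α) and 0.037 (λ) — chosen
so the n = 6 group-mean SE matches the reported ±0.007 and ±0.015; this
is a calibration of the generator, not a reported quantity. Measurement
noise is additive Gaussian with SD = 2% of the noiseless curve peak (no
noise statistics are reported; this is a stated assumption,
configurable, including a voltage-domain variant applied before
calibration inversion). Seeding uses `numpy.random.SeedSequence`
spawning per group and animal, so any sub-cohort is reproducible from
the master seed alone.

What the generator does **not** emulate: electrode drift, depth-dependent
tissue heterogeneity, anesthesia effects, within-animal correlation
beyond the shared parameter draw, or non-Gaussian noise. Passing
recovery tests therefore demonstrate correctness of the inverse
machinery under the stated noise model, not robustness to every
real-recording artifact.

## Morphometry

The ramification index
(Σ terminal orders + n terminals) × (total length / n primary) operates
on pre-extracted skeleton summaries. Branch order is counted from 1 at
the primary process (the convention is not universal; order-0-based
counting would shift the first bracket by n_terminals). Image
segmentation and 3-D reconstruction are out of scope.

## Problem sizes

Default problem sizes were chosen as the smallest that exercise the
full study design: the cohort recovery runs all 324 curves (≈30 s),
the PDE oracle grid has ~2500 cells (≈1.5 s per solve), and production
dopamine grids ~200 cells (≈0.2 s per tonic solve). The type-I-error
simulation uses 200 replicates of the full 2 × 6 × 4 ANOVA layout.

## Known limitations

* The tissue fit assumes the agar-derived (n_t, D) transfer exactly to
  tissue; electrode aging between agar and tissue recordings would bias
  α (which trades off against n_t) more than λ.
* The ANOVA treats animal × layer cells as independent observations
  (no mixed-effects nesting), matching the field's standard analysis.
* The dopamine model is homogeneous and isotropic with spatially
  uniform uptake; transporter density gradients and anisotropy are not
  represented.
* Near the source the continuum ECS description itself is marginal at
  the 2-μm scale; absolute near-source concentrations should be read as
  model quantities, while the control-vs-EtOH contrast is robust.
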