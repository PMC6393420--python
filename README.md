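# dtekit — device thrombogenicity emulation toolkit

Implantable blood pumps (ventricular assist devices, VADs) impose
supraphysiologic shear on circulating platelets, and flow-induced platelet
activation drives the thromboembolic complications that still plague these
devices. *Device thrombogenicity emulation* scores a candidate pump design
by the stress history of a large Lagrangian platelet population flowing
through it: each platelet trajectory carries the local viscous stress
tensor, which is collapsed into a scalar dose, and the population's dose
distribution — the device's *thrombogenic footprint* — is compared between
designs and against bench measurements of platelet activation.

`dtekit` is the post-processing side of that workflow, for engineers and
researchers who already have (or want to emulate) Lagrangian trajectory
exports from a CFD discrete-phase run:

- **Scalar stress.** The six components of the viscous stress tensor are
  reduced to a von-Mises-type rotational invariant

  σ = √[(τ₁₁² + τ₂₂² + τ₃₃² − τ₁₁τ₂₂ − τ₁₁τ₃₃ − τ₂₂τ₃₃ + 3(τ₁₂² + τ₁₃² + τ₂₃²)) / 3]

- **Stress accumulation (SA).** The per-platelet thrombogenic dose is the
  exposure-time integral along the trajectory, evaluated as a
  left-rectangle sum over the recorded steps:

  SA = ∫ σ(t) dt ≈ Σᵢ σᵢ·Δtᵢ   [dyne·s/cm²]

- **Thrombogenic footprints.** An SA ensemble is collapsed into a
  Gaussian-kernel probability density (Silverman bandwidth, linear SA
  grid). Populations of unequal size are made comparable by bootstrap
  equalization: both are resampled with replacement to a common size and
  the density is the replicate mean. Footprints are compared by
  Kolmogorov–Smirnov distance, main-mode shift, and tail mass above a
  threshold (default 50 dyne·s/cm², the "risky" tail).
- **Region-of-interest analysis.** Labelled axial/radial regions (stator,
  bearing, blade, …) localize where the dose is accrued; per-region SA
  values sum exactly to the global SA.
- **Platelet activity statistics.** For bench recirculation-loop data, the
  platelet activity state (PAS, thrombin generation normalized to
  sonicated platelets) is fitted against time; the slope is the platelet
  activation rate (PAR, min⁻¹). Pooled and per-experiment estimators,
  SEM, Welch/Student two-sample comparison and fold change are provided.
- **Synthetic pump surrogate.** An analytic annular Couette–Poiseuille
  flow (rotating inner wall + axial throughflow) with passive-tracer RK4
  advection generates trajectory ensembles whose SA has the closed form
  σ(r)·L/u_z(r) — every pipeline stage is testable without CFD software.
  Operating-point arithmetic (rpm calibration on a quadratic head curve,
  impeller revolutions, inlet mass flow) is included.

## Worked example

The end-to-end demonstration simulates a matched pair of surrogate-pump
populations — a baseline ("MIN-like") design and a degraded ("MAX-like")
variant in which 20% of platelets recirculate with 5× residence time —
then runs the full footprint and PAS/PAR comparison:

```sh
dte demo --seed 7 --out-dir demo_out
```

prints (abridged):

```json
{
  "ks_statistic": 0.186,
  "main_mode_shift": 0.277,
  "tail_mass_a": 0.0,
  "tail_mass_b": 0.017,
  "threshold": 50.0
}
{
  "par_a": 7.9006e-05,
  "par_b": 4.1043e-04,
  "fold_change": 5.195,
  "p_value": 4.80e-15,
  "significant": true
}
```

Reading: the two SA distributions differ (KS distance 0.186) mostly in the
tail — 1.7% of MAX-like platelets exceed 50 dyne·s/cm² versus none in the
baseline, the recirculating subpopulation by construction — while the main
mode barely moves (+0.28 dyne·s/cm²). The synthetic bench comparison
recovers the programmed ~5-fold higher activation rate
(4.1×10⁻⁴ vs 7.9×10⁻⁵ min⁻¹) as strongly significant. `demo_out/`
contains the SA ensembles, footprint curves, per-region footprints, PAS
records and a manifest (config echo + stage seeds) that regenerates every
file bit-exactly.

Library use mirrors the CLI:

```python
import dtekit as dk

cfg = dk.AnnulusFlowConfig()                    # 3/6 mm annulus, 30 mm long
sc = dk.SeedConfig(n_particles=9800)
dur = dk.choose_duration(cfg, sc, exit_target=0.9)
ens = dk.advect(cfg, dk.seed_particles(cfg, sc),
                dk.SeedConfig(n_particles=9800, max_duration=dur))
sa = dk.sa_ensemble(ens, completed_only=True)   # dyne·s/cm² per platelet
fp = dk.build_footprint(sa)                     # the thrombogenic footprint
```

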