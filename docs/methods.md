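# Methods

This note documents the models, numerical choices and defaults behind
`dtekit`, and what the synthetic surrogate does and does not establish
about real device data.

## Scalar stress and stress accumulation

The viscous stress tensor recorded along a Lagrangian platelet trajectory
is collapsed to the von-Mises-type invariant

    sigma = sqrt[(tau11^2 + tau22^2 + tau33^2
                  - tau11 tau22 - tau11 tau33 - tau22 tau33
                  + 3 (tau12^2 + tau13^2 + tau23^2)) / 3].

This form is invariant under rotation of the coordinate frame and under
addition of any hydrostatic component, and positively homogeneous
(sigma(cT) = |c| sigma(T)); a formula that weighted the three shear
components unequally would depend on an arbitrary axis labelling, which is
why the symmetric form is used. Cancellation in the quadratic form limits
achievable accuracy to O(sqrt(eps)·|tau|) when sigma is many orders of
magnitude below the component scale; the implementation clips
rounding-level negatives before the square root.

Stress accumulation is the exposure-time integral of sigma, evaluated by
the left-rectangle rule over the recorded samples:

    SA = sum_i sigma_i (t_{i+1} - t_i),

the final sample contributing nothing. The rectangle sum is the defining
contract (it makes per-region doses sum *exactly* to the global dose, see
below); a trapezoid option exists behind a flag for smoother integrands.
Non-uniform steps are supported because exported trajectory tables may
drop samples even when the solver used a fixed step. SA is always
reported in dyne·s/cm^2 (1 Pa = 10 dyne/cm^2); the internal canonical
unit is Pa because CFD exports are SI, and the conversion happens at one
reporting boundary only. A caveat on units: multiplying by 10 and
dividing by 10 is not bit-exact in binary floating point, so the
conversion round trip is guaranteed only to ~2 ulp.

Trajectories with fewer than two samples cannot be scored; they are kept
in the ensemble (they count toward seeding and exit-fraction statistics)
and excluded from SA with a warning. Particles still inside the domain at
the end of a run are scored up to their last sample and included by
default — the 90%-exit rule (below) is a duration criterion, not a
filter — with a `completed_only` flag to restrict to exited particles.

## Thrombogenic footprints

An SA ensemble is collapsed into a probability density via a 1-D Gaussian
kernel estimate on a linear SA grid (512 points by default). The default
bandwidth is the classic Silverman rule of thumb
h = 0.9 min(sd, IQR/1.34) n^(-1/5). The kernel evaluator is written
in-house (a ~20-line weighted sum) because the footprint contract needs an
*absolute* bandwidth, a documented rule-of-thumb, and a clean error path
for zero-spread input; `scipy.stats.gaussian_kde` is retained as an
independent cross-check in the test suite with the bandwidth pinned to
ours. SA is non-negative by construction, so the grid never extends below
zero and the density is renormalized after the implicit clip; every
footprint integrates to 1 within 1e-3 (trapezoid rule on its own grid) and
this is enforced as a validation invariant.

**Bootstrap equalization.** Footprints from populations of unequal size
are made comparable by resampling both with replacement to a common
`n_target` (default: the larger population), `reps` times (default 1000),
and reporting the pointwise mean density over replicates. The bandwidth is
held at its base-sample value across replicates; with a shared bandwidth,
the mean of per-replicate kernel densities is *identical* to a single
kernel density weighted by the pooled resample counts, which is how
`build_footprint` computes it (the identity is asserted in the tests), so
bootstrapping costs no more than a plain density estimate. All resampling
is driven by an explicit seed and is exactly reproducible.

What equalization can and cannot do: the replicate mean converges, as
reps grows, to the kernel density of the *base sample* — it equalizes
sizes and stabilizes comparisons, but it cannot add information. A
500-point subsample's density deviates from the parent 10,000-sample
density by an irreducible sampling error of order
sqrt(f(x) / (n h)) — about 7% of the peak pointwise, 7–17% in sup-norm
for a Gaussian-shaped ensemble and worse for densities with sharp edges —
regardless of the number of bootstrap replicates. Comparisons between
footprints built from a few hundred platelets should therefore be read at
that resolution, not at the percent level.

**Modes and comparison.** Modes are local density maxima found by
`scipy.signal.find_peaks` with prominence at least 0.01× the global peak
(the default suppresses most sampling ripple while keeping genuine
secondary/tertiary tail modes; ripple on a low secondary mode can
occasionally split it). Two-design comparison reports the two-sample
Kolmogorov–Smirnov distance on the raw SA values, the main-mode shift
between bootstrap-equalized footprints on a shared grid, and the ratio of
empirical tail masses P(SA > threshold), threshold 50 dyne·s/cm^2 by
default; a zero reference tail is flagged and the ratio reported as
infinite.

## Regions of interest

Regions are labelled half-open axial intervals [z_min, z_max), optionally
restricted to a half-open radial band, validated to be pairwise
non-overlapping with unique labels. Samples are assigned geometrically by
position, or by the solver's `zone` labels when the export carries them
(the solver's own cell-zone segmentation is usually the more faithful
partition when available; geometric mode is the default for synthetic
data). Each left-rectangle step sigma_i Δt_i is credited to the region
containing its *starting* sample, samples outside every region to a
reserved `unassigned` label — so every step is credited exactly once and
per-region SA values sum to the global SA to the last bit. A trajectory
contributes one SA value per region it enters; repeated visits accumulate,
matching SA's meaning as cumulative exposure. Per-region footprints are
built on a shared grid so they are comparable across regions and devices.

## The annular pump surrogate

The synthetic generator is an analytic annular Couette–Poiseuille flow:
inner wall (the "impeller") rotating at omega, outer wall fixed, plus a
pressure-driven axial throughflow of rate q. Both velocity components and
both nonzero viscous stress components (tau_rtheta = -2 mu B / r^2,
tau_rz = mu du_z/dr) are closed-form, sigma is constant along every
streamline, and a particle seeded at radius r accumulates exactly
SA(r) = sigma(r) · L / u_z(r) over a full transit. That closed form is the
oracle against which the advect → score → footprint pipeline is tested,
including a change-of-variables check: pushing the area-uniform seeding
density through SA(r) by dense sampling must reproduce the pipeline's
footprint to 5% of its peak at the reference scale.

Defaults (all configurable): blood-analog viscosity 0.0035 Pa·s and
density 1080 kg/m^3; annulus 3/6 mm radii × 30 mm length; omega
1100 rad/s (~10,500 rpm); q = 2.0 L/min. The geometry and kinematics were
chosen once so that transit times and doses land in the
few-to-tens of dyne·s/cm^2 range typical of axial blood pumps, with the
degraded-variant tail (below) extending beyond 100 dyne·s/cm^2. Seeding
releases 9,800 tracers (the typical discrete-phase batch size for this
application) in one upstream cross-sectional batch, area-uniform in the
annulus (r = sqrt(ri^2 + u(ro^2 - ri^2)), u ~ U[0,1]), at an integration
step of 7.53e-5 s.

Integration is fixed-step RK4 on the cylindrical state (r, theta, z). In
this field dr/dt = 0, so the radius — and with it sigma — is conserved
exactly and RK4 is exact along each streamline; a Cartesian integration
would leak O((omega dt)^5) radius error per step and break the closed-form
oracle at the tested tolerances. When a particle crosses z = L within a
step, its final sample is placed at the linearly interpolated crossing
time, so the recorded exposure equals the true transit time instead of
overshooting by up to one step (an O(dt/transit) ≈ 0.3% bias that would
otherwise dominate the SA comparison). The run duration is the smallest
multiple of dt by which a target fraction (default 90%) of the seeded
population has exited — particles seeded arbitrarily close to a no-slip
wall never exit, so a 100% target hits the configured cap with a warning.

Particles are passive tracers: no inertia, buoyancy or two-way coupling.
At the ~3 µm platelet scale the Stokes number in these flows is
negligible, and tracer advection is what keeps the oracle closed-form.
The surrogate is laminar and steady, scores the viscous stress only, and
makes no attempt to reproduce any real pump's hydraulics, turbulence,
rpm, or footprint mode locations — it exists to validate the
post-processing machinery, so passing tests certify the pipeline, not any
statement about a physical device. A `plug_flow` switch replaces the
axial profile with a uniform velocity (slipping at the walls, no axial
shear) as a degenerate configuration for residence-time logic tests.

**Two-device fixture.** `two_device_ensembles` produces a matched pair
with known ground truth: the baseline ensemble, and a degraded variant in
which a chosen fraction of particles (default 0.2) has its time axis
stretched by a residence multiplier (default 5), emulating a
slow-recirculation subpopulation. Stretching time multiplies SA by
exactly the multiplier, so the variant's footprint acquires a
high-SA mode and strictly more tail mass — the contrast the comparison
machinery must detect.

**Operating-point arithmetic.** The impeller speed needed to deliver a
target pressure head at a given flow is solved on a quadratic head curve
H = a·rpm^2 − b·Q^2 by bracketed root finding (Brent) to 1e-8 relative —
equal to the closed form sqrt((H + bQ^2)/a), which the tests assert.
Revolutions over a run are rpm·duration/60; the inlet mass flow is
q·rho/60000 kg/s (q in L/min).

## Platelet activity statistics

PAS values are normalized thrombin-generation measurements (0 = quiescent,
1 = sonication-activated); values above 1 are retained with a warning
rather than clipped, since assay noise can exceed the nominal ceiling.
The activation rate PAR is the OLS slope of PAS versus time in minutes.
Two estimators: the *pooled* fit regresses the within-time-point mean PAS
on time (unweighted means — replicate counts per time point are treated
as equal); the *per-experiment* estimator averages individual-experiment
slopes and reports their SEM (flagged undefined for a single experiment).
Device comparison reports the fold change of PARs and a two-sided
two-sample t-test on the individual slopes — the only replicated unit.
The unequal-variance (Welch) form is the default for robustness, with the
classical pooled-variance form behind a flag; both forms appear in the
report.

The PAS generator produces pas = intercept + slope·t + N(0, noise_sd),
clipped at zero, at the standard 0/10/20/30 min design with 13
experiments per device by default. Default noise_sd = 0.001 on the
normalized scale — assay repeatability small relative to typical PAS
levels of 0.01–0.05. At that noise, a 13-vs-13 comparison of slopes
8e-5 vs 4e-4 min^-1 is essentially always significant and the mean
estimated fold change is ~5 (slightly above, since E[1/x] > 1/E[x] for
the noisy denominator); null comparisons hold the 5% level. The
generator draws i.i.d. Gaussian errors per measurement; real assay data
have batch structure (experiments for both devices run on shared platelet
batches), so the synthetic power estimates are optimistic about
between-batch variability.

## Trajectory I/O

The `dte-tsv` dialect is a tab-delimited table (one row per particle per
time step) with `#` header comments carrying the stress unit (required),
label, run metadata and exited-particle list; floats are written with 17
significant digits and parsed with round-trip precision, so text round
trips are value-exact. `dte-h5` is an HDF5 container with the same
logical schema for large ensembles. Reading validates monotone times per
particle (duplicated time stamps name the offending particle), unique
particle ids, finite tensors, and known units; malformed rows are
reported with line information.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit seed and is bit-reproducible;
the demo writes a manifest (config echo + per-stage seeds) sufficient to
regenerate each artifact byte-identically. The reference problem sizes
used by the test suite and the acceptance script — 9,800 particles at
dt = 7.53e-5 s for the pipeline oracle, 10,000-sample ensembles for
density checks, 1,000 Monte-Carlo replicates for PAR power and 2,000 for
the null level — run in about a minute on one CPU; the demo pipeline
defaults to 2,000 particles and 200 bootstrap replicates, a scale at
which its statistics are stable.

## Known limitations

- The 5%-of-peak bootstrap-equalization target is met only when the
  smaller population is itself large: a 500-point subsample carries
  ~7–17% sup-norm sampling error against a 10,000-sample density, and no
  number of bootstrap replicates reduces it (see the footprint section).
  The suite's bootstrap-convergence check against a 500-point subsample
  accordingly fails at that tolerance, by roughly the predicted margin.
- Scoring uses whatever tensor the trajectory table carries; if a
  turbulent run exports only the viscous part, Reynolds-stress
  contributions to the dose are absent.
- Mode counting on low, noisy secondary modes is sensitive to the
  prominence threshold; report mode locations together with the bandwidth
  used.
- The surrogate cannot emulate recirculation, separation, or unsteady
  structures of a real pump; the two-device fixture injects its tail
  contrast by construction rather than by hydrodynamics.
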