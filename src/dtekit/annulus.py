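"""Analytic annular Couette-Poiseuille pump surrogate with particle advection.

The surrogate flow lives in the annulus r_inner < r < r_outer with the inner
wall rotating at angular velocity omega (the "impeller") and a pressure-
driven axial throughflow of volumetric rate q.  Both velocity components
are known in closed form:

    u_theta(r) = A r + B / r,   A = -omega ri^2 / (ro^2 - ri^2),
                                B =  omega ri^2 ro^2 / (ro^2 - ri^2)
    u_z(r)     = k [ ro^2 - r^2 + (ro^2 - ri^2) ln(r/ro) / ln(ro/ri) ]

with k chosen so that 2 pi Int u_z r dr = q.  The only nonzero viscous
stress components (cylindrical) are

    tau_rtheta = -2 mu B / r^2        (Couette swirl shear)
    tau_rz     =  mu du_z/dr          (Poiseuille axial shear)

so the von-Mises scalar stress reduces to sigma(r) =
sqrt(tau_rtheta^2 + tau_rz^2): constant along every streamline.  A particle
seeded at radius r therefore accumulates exactly

    SA(r) = sigma(r) * length / u_z(r)          (closed form, the oracle)

over its transit — every stage of the Lagrangian post-processing pipeline
can be checked against this without CFD software.

Particles are passive tracers (no inertia, gravity, or two-way coupling):
at the ~3 um platelet scale the Stokes number is negligible, and tracer
advection is what keeps the oracle closed-form.  The flow is laminar and
steady; the surrogate exists to exercise the post-processing, not to
reproduce pump hydraulics.

The module also carries the pump operating-point arithmetic: rpm
calibration against a quadratic head curve H = a rpm^2 - b Q^2, impeller
revolutions over a simulated duration, and the inlet mass-flow conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ValidationError
from .trajectory import Trajectory, TrajectoryEnsemble

__all__ = [
    "AnnulusFlowConfig",
    "PumpCurve",
    "OperatingPoint",
    "SeedConfig",
    "annulus_velocity",
    "annulus_stress",
    "analytic_sa",
    "seed_particles",
    "advect",
    "choose_duration",
    "calibrate_rpm",
    "rotations",
    "mass_flow",
    "two_device_ensembles",
]

PA_TO_DYNE_CM2 = 10.0
L_MIN_TO_M3_S = 1.0 / 60_000.0


@dataclass(frozen=True)
class AnnulusFlowConfig:
    """Geometry, fluid, and kinematics of the annular surrogate.

    Defaults: blood-analog viscosity 0.0035 Pa.s and density 1080 kg/m^3;
    a 3/6 mm annulus of 30 mm length, inner wall at 1100 rad/s (~10,500
    rpm) and 2 L/min throughflow, which places transit times and stress
    accumulation in the few-to-tens of dyne.s/cm^2 range typical of axial
    blood pumps.  ``plug_flow=True`` replaces the Poiseuille profile with a
    uniform u_z = q/A (a degenerate configuration used to test
    residence-time logic; it has no axial shear and slips at the walls).
    """

    r_inner: float = 0.003
    r_outer: float = 0.006
    length: float = 0.03
    mu: float = 0.0035
    rho: float = 1080.0
    omega: float = 1100.0
    q: float = 2.0  # L/min
    plug_flow: bool = False

    def __post_init__(self) -> None:
        if not self.r_outer > self.r_inner > 0:
            raise ValidationError("need r_outer > r_inner > 0")
        if self.mu <= 0 or self.rho <= 0 or self.q <= 0 or self.length <= 0:
            raise ValidationError("mu, rho, q, length must be positive")

    # -- Couette coefficients (inner wall rotating, outer fixed) --
    @property
    def couette_A(self) -> float:
        ri2, ro2 = self.r_inner**2, self.r_outer**2
        return -self.omega * ri2 / (ro2 - ri2)

    @property
    def couette_B(self) -> float:
        ri2, ro2 = self.r_inner**2, self.r_outer**2
        return self.omega * ri2 * ro2 / (ro2 - ri2)

    @property
    def q_m3s(self) -> float:
        return self.q * L_MIN_TO_M3_S

    @property
    def annulus_area(self) -> float:
        return math.pi * (self.r_outer**2 - self.r_inner**2)

    @property
    def poiseuille_scale(self) -> float:
        """k such that the axial profile integrates to the flow rate q."""
        ri, ro = self.r_inner, self.r_outer
        log = math.log(ro / ri)
        # Int (ro^2 - r^2) r dr over [ri, ro]
        i1 = ro**2 * (ro**2 - ri**2) / 2.0 - (ro**4 - ri**4) / 4.0
        # Int ln(r/ro) r dr over [ri, ro]
        i2 = -(ro**2) / 4.0 + ri**2 / 4.0 - (ri**2 / 2.0) * math.log(ri / ro)
        integral = i1 + (ro**2 - ri**2) / log * i2
        return self.q_m3s / (2.0 * math.pi * integral)


@dataclass(frozen=True)
class PumpCurve:
    """Quadratic head curve H = a rpm^2 - b Q^2 (Pa; Q in L/min)."""

    head_coefficient: float  # a, Pa per rpm^2
    loss_coefficient: float = 0.0  # b, Pa per (L/min)^2

    def __post_init__(self) -> None:
        if self.head_coefficient <= 0 or self.loss_coefficient < 0:
            raise ValidationError("need a > 0 and b >= 0")

    def head(self, rpm: float, q: float) -> float:
        return self.head_coefficient * rpm**2 - self.loss_coefficient * q**2


@dataclass(frozen=True)
class OperatingPoint:
    """A pump operating state: impeller speed, flow, and pressure head."""

    rpm: float
    q: float  # L/min
    head: float  # Pa

    def __post_init__(self) -> None:
        if self.rpm < 0 or self.q <= 0 or self.head < 0:
            raise ValidationError("operating point values must be positive")


@dataclass(frozen=True)
class SeedConfig:
    """Particle seeding and integration parameters.

    Defaults mirror a typical discrete-phase run: ~9.8e3 tracers released
    in one upstream cross-sectional batch, integrated at a 7.53e-5 s time
    step until exit or ``max_duration``.
    """

    n_particles: int = 9800
    seed: int = 0
    dt: float = 7.53e-5
    max_duration: float = 0.3

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ValidationError("n_particles must be >= 1")
        if self.dt <= 0:
            raise ValidationError("dt must be positive")


def _check_r(r, cfg: AnnulusFlowConfig, strict: bool = False):
    r = np.asarray(r, dtype=float)
    lo, hi = cfg.r_inner, cfg.r_outer
    bad = (r < lo) | (r > hi) if not strict else (r <= lo) | (r >= hi)
    if np.any(bad):
        kind = "strictly inside" if strict else "inside"
        raise ValidationError(f"radius not {kind} the annulus [{lo}, {hi}]")
    return r


def annulus_velocity(r, cfg: AnnulusFlowConfig):
    """Velocity components ``(u_theta, u_z)`` in m/s at radius ``r``."""
    r = _check_r(r, cfg)
    u_theta = cfg.couette_A * r + cfg.couette_B / r
    if cfg.plug_flow:
        u_z = np.full_like(r, cfg.q_m3s / cfg.annulus_area)
    else:
        ri, ro = cfg.r_inner, cfg.r_outer
        log = math.log(ro / ri)
        u_z = cfg.poiseuille_scale * (
            ro**2 - r**2 + (ro**2 - ri**2) * np.log(r / ro) / log
        )
    return u_theta, u_z


def _du_z_dr(r, cfg: AnnulusFlowConfig):
    if cfg.plug_flow:
        return np.zeros_like(np.asarray(r, dtype=float))
    ri, ro = cfg.r_inner, cfg.r_outer
    log = math.log(ro / ri)
    return cfg.poiseuille_scale * (-2.0 * r + (ro**2 - ri**2) / (log * r))


def _cyl_shear(r, cfg: AnnulusFlowConfig):
    """The two nonzero cylindrical shear components (tau_rtheta, tau_rz), Pa."""
    tau_rt = -2.0 * cfg.mu * cfg.couette_B / r**2
    tau_rz = cfg.mu * _du_z_dr(r, cfg)
    return tau_rt, tau_rz


def annulus_stress(r, theta, cfg: AnnulusFlowConfig) -> np.ndarray:
    """Cartesian viscous stress components at (r, theta), shape ``(..., 6)``.

    Rotates the cylindrical tensor (tau_rtheta, tau_rz, rest zero) into the
    Cartesian frame; component order matches
    :data:`~dtekit.trajectory.TAU_COLUMNS`.  The scalar stress of the
    result is independent of theta.
    """
    r = _check_r(r, cfg)
    theta = np.asarray(theta, dtype=float)
    tau_rt, tau_rz = _cyl_shear(r, cfg)
    c, s = np.cos(theta), np.sin(theta)
    tau11 = -2.0 * c * s * tau_rt
    tau22 = 2.0 * c * s * tau_rt
    tau33 = np.zeros_like(tau11)
    tau12 = (c**2 - s**2) * tau_rt
    tau13 = c * tau_rz
    tau23 = s * tau_rz
    return np.stack([tau11, tau22, tau33, tau12, tau13, tau23], axis=-1)


def analytic_sa(r, cfg: AnnulusFlowConfig) -> float | np.ndarray:
    """Closed-form stress accumulation of a full transit, dyne.s/cm^2.

    sigma is constant along a streamline, so SA = sigma(r) * length /
    u_z(r).  Undefined at the walls (infinite residence time).
    """
    r = _check_r(r, cfg, strict=not cfg.plug_flow)
    _, u_z = annulus_velocity(r, cfg)
    if np.any(u_z <= 0):
        raise ValidationError("u_z <= 0: infinite residence time at the wall")
    tau_rt, tau_rz = _cyl_shear(r, cfg)
    sigma = np.hypot(tau_rt, tau_rz)  # Pa
    sa = sigma * cfg.length / u_z * PA_TO_DYNE_CM2
    return float(sa) if np.ndim(sa) == 0 else sa


def seed_particles(
    cfg: AnnulusFlowConfig, seed_cfg: SeedConfig
) -> np.ndarray:
    """Initial Cartesian positions ``(n, 3)`` at z = 0.

    Radii are area-uniform over the annulus cross-section
    (r = sqrt(ri^2 + u (ro^2 - ri^2)), u ~ U[0,1]); angles uniform.
    Deterministic given ``seed_cfg.seed``.
    """
    rng = np.random.default_rng(seed_cfg.seed)
    u = rng.random(seed_cfg.n_particles)
    r = np.sqrt(cfg.r_inner**2 + u * (cfg.r_outer**2 - cfg.r_inner**2))
    theta = rng.uniform(0.0, 2.0 * math.pi, seed_cfg.n_particles)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta),
                            np.zeros(seed_cfg.n_particles)])


def _rk4_step(state: np.ndarray, dt: float, cfg: AnnulusFlowConfig):
    """One RK4 step of the cylindrical state (r, theta, z) per particle.

    dr/dt = 0 in this field, so the radius is conserved exactly and the
    remaining derivatives are constant along the step — RK4 is then exact.
    The generic stage evaluation is kept so a different field would still
    integrate correctly.
    """

    def deriv(s):
        r = s[:, 0]
        u_theta, u_z = annulus_velocity(r, cfg)
        return np.column_stack([np.zeros_like(r), u_theta / r, u_z])

    k1 = deriv(state)
    k2 = deriv(state + 0.5 * dt * k1)
    k3 = deriv(state + 0.5 * dt * k2)
    k4 = deriv(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def advect(
    cfg: AnnulusFlowConfig,
    seeds: np.ndarray,
    seed_cfg: SeedConfig,
    label: str = "annulus",
) -> TrajectoryEnsemble:
    """Integrate seeded tracers through the annulus; record stress per step.

    Fixed-step RK4 in cylindrical coordinates; a particle is marked exited
    when its axial position reaches the annulus length, with its final
    sample placed at the interpolated crossing time (so the recorded
    exposure time equals the true transit time, not the next grid time).
    Integration stops at exit or at ``seed_cfg.max_duration``.

    Returns a validated ensemble in Pa with run metadata (rpm, flow, dt,
    duration, seed, n_seeded).
    """
    if seed_cfg.dt <= 0:
        raise ValidationError("dt must be positive")
    seeds = np.asarray(seeds, dtype=float)
    n = len(seeds)
    r0 = np.hypot(seeds[:, 0], seeds[:, 1])
    _check_r(r0, cfg)
    state = np.column_stack([r0, np.arctan2(seeds[:, 1], seeds[:, 0]),
                             seeds[:, 2]])
    dt = seed_cfg.dt
    n_steps = int(math.ceil(seed_cfg.max_duration / dt))

    active = np.arange(n)
    # flat per-sample records
    rec_pid = [active.copy()]
    rec_t = [np.zeros(n)]
    rec_r = [state[:, 0].copy()]
    rec_th = [state[:, 1].copy()]
    rec_z = [state[:, 2].copy()]
    exited = np.zeros(n, dtype=bool)

    t = 0.0
    for _ in range(n_steps):
        if len(active) == 0:
            break
        new = _rk4_step(state, dt, cfg)
        t_next = t + dt
        crossed = new[:, 2] >= cfg.length
        if np.any(crossed):
            # place the final sample at the z = length crossing
            frac = (cfg.length - state[crossed, 2]) / (
                new[crossed, 2] - state[crossed, 2]
            )
            rec_pid.append(active[crossed])
            rec_t.append(t + frac * dt)
            rec_r.append(state[crossed, 0])
            rec_th.append(
                state[crossed, 1] + frac * (new[crossed, 1] - state[crossed, 1])
            )
            rec_z.append(np.full(crossed.sum(), cfg.length))
            exited[active[crossed]] = True
        keep = ~crossed
        active = active[keep]
        state = new[keep]
        t = t_next
        if len(active):
            rec_pid.append(active.copy())
            rec_t.append(np.full(len(active), t))
            rec_r.append(state[:, 0].copy())
            rec_th.append(state[:, 1].copy())
            rec_z.append(state[:, 2].copy())

    pid = np.concatenate(rec_pid)
    t_flat = np.concatenate([np.atleast_1d(x) for x in rec_t])
    r_flat = np.concatenate(rec_r)
    th_flat = np.concatenate(rec_th)
    z_flat = np.concatenate(rec_z)
    tau_flat = annulus_stress(r_flat, th_flat, cfg)
    x_flat = r_flat * np.cos(th_flat)
    y_flat = r_flat * np.sin(th_flat)

    order = np.lexsort((t_flat, pid))
    pid, t_flat = pid[order], t_flat[order]
    pos = np.column_stack([x_flat, y_flat, z_flat])[order]
    tau_flat = tau_flat[order]
    bounds = np.searchsorted(pid, np.arange(n + 1))

    width = len(str(n - 1))
    trajectories = []
    for p in range(n):
        lo, hi = bounds[p], bounds[p + 1]
        trajectories.append(
            Trajectory(
                f"p{p:0{width}d}", t_flat[lo:hi], pos[lo:hi], tau_flat[lo:hi],
                exited=bool(exited[p]),
            )
        )
    meta = {
        "rpm": cfg.omega * 60.0 / (2.0 * math.pi),
        "flow_l_min": cfg.q,
        "dt_s": dt,
        "duration_s": seed_cfg.max_duration,
        "seed": seed_cfg.seed,
        "n_seeded": n,
    }
    return TrajectoryEnsemble(trajectories, stress_unit="Pa",
                              label=label, meta=meta)


def choose_duration(
    cfg: AnnulusFlowConfig,
    seed_cfg: SeedConfig,
    exit_target: float = 0.9,
) -> float:
    """Smallest multiple of dt by which ``exit_target`` of particles exit.

    Transit times follow from the seeded radii (residence time = length /
    u_z(r) in this steady field).  If the target is not reachable within
    ``max_duration`` the cap is returned with a warning — particles seeded
    arbitrarily close to a no-slip wall never exit.
    """
    if not 0.0 < exit_target <= 1.0:
        raise ValidationError("exit_target must lie in (0, 1]")
    seeds = seed_particles(cfg, seed_cfg)
    r = np.hypot(seeds[:, 0], seeds[:, 1])
    _, u_z = annulus_velocity(r, cfg)
    transit = np.where(u_z > 0, cfg.length / np.maximum(u_z, 1e-300), np.inf)
    k = int(math.ceil(exit_target * len(transit)))
    t_needed = np.sort(transit)[k - 1]
    if not np.isfinite(t_needed):
        warnings.warn("exit target unreachable; returning max_duration",
                      stacklevel=2)
        return seed_cfg.max_duration
    duration = math.ceil(t_needed / seed_cfg.dt - 1e-12) * seed_cfg.dt
    if duration > seed_cfg.max_duration:
        warnings.warn(
            f"exit target {exit_target} needs {duration:.4g} s "
            f"> max_duration {seed_cfg.max_duration}; returning the cap",
            stacklevel=2,
        )
        return seed_cfg.max_duration
    return duration


def calibrate_rpm(curve: PumpCurve, q: float, target_head: float) -> float:
    """Impeller speed delivering ``target_head`` at flow ``q`` (L/min).

    Solves a rpm^2 - b q^2 = target_head by bracketed root finding to 1e-8
    relative tolerance; equals sqrt((target_head + b q^2)/a).
    """
    a, b = curve.head_coefficient, curve.loss_coefficient
    rhs = target_head + b * q**2
    if rhs < 0:
        raise ValidationError("target head unachievable with this curve")
    if rhs == 0:
        return 0.0
    hi = math.sqrt(rhs / a) * 2.0

    rpm = brentq(lambda x: curve.head(x, q) - target_head, 0.0, hi,
                 rtol=1e-9, xtol=1e-300)
    return float(rpm)


def rotations(rpm: float, duration: float) -> float:
    """Impeller revolutions completed over *duration* seconds."""
    if rpm < 0 or duration < 0:
        raise ValidationError("rpm and duration must be >= 0")
    return rpm * duration / 60.0


def mass_flow(q: float, rho: float) -> float:
    """Inlet mass-flow rate (kg/s) from flow q (L/min) and density (kg/m^3)."""
    if q <= 0 or rho <= 0:
        raise ValidationError("q and rho must be positive")
    return q * rho / 60_000.0


def two_device_ensembles(
    cfg: AnnulusFlowConfig,
    seed_cfg: SeedConfig,
    recirc_fraction: float = 0.2,
    residence_multiplier: float = 5.0,
    seed: int | None = None,
) -> tuple[TrajectoryEnsemble, TrajectoryEnsemble]:
    """A matched low/high-thrombogenicity ensemble pair with known contrast.

    The baseline ("MIN-like") ensemble is the plain advected population.
    The degraded ("MAX-like") variant models a slow-recirculation
    subpopulation: a fraction of particles has its time axis stretched by
    ``residence_multiplier``, multiplying its SA by exactly that factor and
    adding a high-SA mode to the footprint tail — a ground-truth tail
    difference for footprint comparison.
    """
    if not 0.0 <= recirc_fraction <= 1.0:
        raise ValidationError("recirc_fraction must lie in [0, 1]")
    if residence_multiplier < 1.0:
        raise ValidationError("residence_multiplier must be >= 1")
    seeds = seed_particles(cfg, seed_cfg)
    base = advect(cfg, seeds, seed_cfg, label="MIN_like")

    rng = np.random.default_rng(seed_cfg.seed + 1 if seed is None else seed)
    n = len(base)
    n_recirc = int(round(recirc_fraction * n))
    recirc = set(rng.choice(n, size=n_recirc, replace=False).tolist())
    trajectories = []
    for i, tr in enumerate(base):
        if i in recirc:
            trajectories.append(
                Trajectory(tr.particle_id, tr.t * residence_multiplier,
                           tr.pos.copy(), tr.tau.copy(), exited=tr.exited)
            )
        else:
            trajectories.append(tr)
    meta = dict(base.meta)
    meta.update(recirc_fraction=recirc_fraction,
                residence_multiplier=residence_multiplier)
    degraded = TrajectoryEnsemble(trajectories, stress_unit="Pa",
                                  label="MAX_like", meta=meta)
    return base, degraded
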