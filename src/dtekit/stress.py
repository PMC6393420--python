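"""Scalar stress and stress accumulation (SA) along platelet trajectories.

The six-component viscous stress tensor recorded along a Lagrangian platelet
trajectory is collapsed into a von-Mises-type rotational invariant

    sigma = sqrt( (tau11^2 + tau22^2 + tau33^2
                   - tau11*tau22 - tau11*tau33 - tau22*tau33
                   + 3*(tau12^2 + tau13^2 + tau23^2)) / 3 )

and integrated over exposure time to give the per-platelet thrombogenic
dose, the stress accumulation

    SA = sum_i sigma_i * dt_i        [dyne.s/cm^2]

using the left-rectangle rule (the final sample contributes nothing); a
trapezoid option is available behind a flag.  sigma is invariant under
addition of a hydrostatic component and under rotation of the coordinate
frame, and positively homogeneous: sigma(c*T) = |c|*sigma(T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .trajectory import (
    STRESS_UNITS,
    StressTensorSample,
    Trajectory,
    TrajectoryEnsemble,
)

__all__ = [
    "SAEnsemble",
    "scalar_stress",
    "stress_accumulation",
    "sa_ensemble",
    "exit_fraction",
    "top_sa_trajectories",
]


def scalar_stress(sample) -> float | np.ndarray:
    """Von-Mises-type scalar stress of a stress tensor.

    Parameters
    ----------
    sample
        A :class:`~dtekit.trajectory.StressTensorSample`, or an array of
        shape ``(..., 6)`` with components in
        :data:`~dtekit.trajectory.TAU_COLUMNS` order.

    Returns
    -------
    Scalar stress in the same unit as the input components; shape ``(...)``
    for array input.
    """
    if isinstance(sample, StressTensorSample):
        tau = sample.tau()
        scalar = True
    else:
        tau = np.asarray(sample, dtype=float)
        scalar = tau.ndim == 1
    if tau.shape[-1] != 6:
        raise ValidationError("stress tensor must have 6 components")
    if not np.all(np.isfinite(tau)):
        raise ValidationError("non-finite stress tensor component")
    t11, t22, t33, t12, t13, t23 = np.moveaxis(tau, -1, 0)
    quad = (
        t11**2 + t22**2 + t33**2
        - t11 * t22 - t11 * t33 - t22 * t33
        + 3.0 * (t12**2 + t13**2 + t23**2)
    )
    # The quadratic form is PSD; clip rounding-level negatives.
    sigma = np.sqrt(np.maximum(quad, 0.0) / 3.0)
    return float(sigma) if scalar else sigma


def stress_accumulation(
    trajectory: Trajectory,
    stress_unit: str = "Pa",
    method: str = "rectangle",
) -> float:
    """Stress accumulation of one trajectory, in dyne.s/cm^2.

    ``method="rectangle"`` (default, the defining contract) uses the
    left-rectangle sum ``sum_i sigma_i * (t_{i+1} - t_i)``;
    ``method="trapezoid"`` integrates sigma(t) with the trapezoid rule.
    Non-uniform time steps are supported.
    """
    if trajectory.n_samples < 2:
        raise ValidationError(
            f"particle {trajectory.particle_id}: need >= 2 samples for SA"
        )
    dt = np.diff(trajectory.t)
    if np.any(dt <= 0):
        raise ValidationError(
            f"particle {trajectory.particle_id}: non-monotone sample times"
        )
    sigma = scalar_stress(trajectory.tau)
    if method == "rectangle":
        sa = float(np.sum(sigma[:-1] * dt))
    elif method == "trapezoid":
        sa = float(np.trapezoid(sigma, trajectory.t))
    else:
        raise ValueError(f"unknown quadrature method {method!r}")
    # Report in dyne.s/cm^2 regardless of the stored unit.
    return sa * (STRESS_UNITS["dyne/cm2"] / STRESS_UNITS[stress_unit])


@dataclass
class SAEnsemble:
    """One SA value per scoreable platelet trajectory (global or per-ROI).

    ``n_seeded`` preserves the seeding count of the source ensemble so that
    exit-fraction bookkeeping survives SA extraction; ``roi`` is ``None``
    for a whole-device ensemble.
    """

    values: np.ndarray
    particle_ids: list[str] = field(default_factory=list)
    n_seeded: int = 0
    label: str = ""
    roi: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError("SA values must be non-negative")
        if self.n_seeded == 0:
            self.n_seeded = len(self.values)
        if len(self.values) > self.n_seeded:
            raise ValidationError("n_scored exceeds n_seeded")
        if self.particle_ids and len(self.particle_ids) != len(self.values):
            raise ValidationError("particle_ids length mismatch")

    @property
    def n_scored(self) -> int:
        return len(self.values)

    def to_csv(self, path) -> None:
        """Serialize as CSV ``particle_id, sa_dyn_s_cm2`` with # metadata."""
        ids = self.particle_ids or [str(i) for i in range(self.n_scored)]
        with open(path, "wt") as fh:
            fh.write(f"# label={self.label}\n")
            fh.write(f"# roi={self.roi if self.roi is not None else ''}\n")
            fh.write(f"# n_seeded={self.n_seeded}\n")
            fh.write("particle_id,sa_dyn_s_cm2\n")
            for pid, v in zip(ids, self.values):
                fh.write(f"{pid},{v:.17g}\n")

    @classmethod
    def from_csv(cls, path) -> "SAEnsemble":
        header = {}
        with open(path, "rt") as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line[1:].strip().partition("=")
                header[key.strip()] = value.strip()
        df = pd.read_csv(path, comment="#", dtype={"particle_id": str})
        return cls(
            df["sa_dyn_s_cm2"].to_numpy(),
            particle_ids=df["particle_id"].tolist(),
            n_seeded=int(header.get("n_seeded", len(df))),
            label=header.get("label", ""),
            roi=header.get("roi") or None,
        )


def sa_ensemble(
    ensemble: TrajectoryEnsemble,
    completed_only: bool = False,
    method: str = "rectangle",
) -> SAEnsemble:
    """Score every trajectory of *ensemble* into an :class:`SAEnsemble`.

    Trajectories with fewer than 2 samples are excluded with a warning
    (they remain in the trajectory ensemble for exit-fraction statistics).
    With ``completed_only`` only trajectories flagged as exited contribute.
    """
    if len(ensemble) == 0:
        raise ValidationError("cannot score an empty ensemble")
    values, ids = [], []
    n_short = 0
    for tr in ensemble:
        if completed_only and not tr.exited:
            continue
        if tr.n_samples < 2:
            n_short += 1
            continue
        values.append(
            stress_accumulation(tr, ensemble.stress_unit, method=method)
        )
        ids.append(tr.particle_id)
    if n_short:
        warnings.warn(
            f"{n_short} trajectories with <2 samples excluded from SA",
            stacklevel=2,
        )
    if not values:
        raise ValidationError(
            "no scoreable trajectories"
            + (" (completed_only=True and none exited)" if completed_only else "")
        )
    return SAEnsemble(
        np.array(values), particle_ids=ids,
        n_seeded=ensemble.n_seeded, label=ensemble.label,
    )


def exit_fraction(ensemble: TrajectoryEnsemble) -> float:
    """Fraction of the seeded population that left the flow domain."""
    if ensemble.n_seeded == 0:
        raise ValidationError("exit fraction undefined for zero seeded particles")
    n_exited = sum(tr.exited for tr in ensemble)
    return n_exited / ensemble.n_seeded


def top_sa_trajectories(
    ensemble: TrajectoryEnsemble, k: int
) -> list[tuple[str, float]]:
    """The *k* highest-SA trajectories as ``(particle_id, SA)``, descending.

    Ties are broken by ascending particle_id.  If *k* exceeds the number of
    scoreable trajectories, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sa = sa_ensemble(ensemble)
    pairs = sorted(
        zip(sa.particle_ids, sa.values), key=lambda p: (-p[1], p[0])
    )
    if k > len(pairs):
        warnings.warn(
            f"k={k} exceeds {len(pairs)} scored trajectories; returning all",
            stacklevel=2,
        )
        k = len(pairs)
    return [(pid, float(v)) for pid, v in pairs[:k]]
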