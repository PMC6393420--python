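"""Region-of-interest analysis: localize thrombogenic potential.

Pump regions (stator, bearing, impeller-shroud gap, blade, lower impeller,
...) are modelled as labelled, non-overlapping half-open axial intervals
[z_min, z_max), optionally restricted in cylindrical radius.  Each
trajectory sample is assigned to at most one region — by position
(geometric mode, default) or by the solver ``zone`` label carried in the
trajectory table (label mode) — and the left-rectangle SA steps whose
starting sample lies in a region accumulate into that region's SA.

By construction the per-region SA values, together with the reserved
``"unassigned"`` label, sum exactly to the global stress accumulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import yaml

from .errors import ValidationError
from .footprint import Footprint, build_footprint
from .stress import SAEnsemble, scalar_stress
from .trajectory import STRESS_UNITS, Trajectory, TrajectoryEnsemble

__all__ = [
    "UNASSIGNED",
    "ROIDefinition",
    "ROISet",
    "assign_segments",
    "roi_sa",
    "roi_footprints",
]

#: Reserved label for samples outside every region.
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ROIDefinition:
    """One labelled region: half-open in z, optionally half-open in r (m)."""

    label: str
    z_min: float
    z_max: float
    r_min: float | None = None
    r_max: float | None = None

    def __post_init__(self) -> None:
        if self.label == UNASSIGNED:
            raise ValidationError(f"label {UNASSIGNED!r} is reserved")
        if not self.z_max > self.z_min:
            raise ValidationError(f"ROI {self.label}: z_max must exceed z_min")
        if (self.r_min is None) != (self.r_max is None):
            raise ValidationError(
                f"ROI {self.label}: r_min and r_max must be given together"
            )
        if self.r_min is not None and not self.r_max > self.r_min:
            raise ValidationError(f"ROI {self.label}: r_max must exceed r_min")

    def contains(self, z: np.ndarray, r: np.ndarray) -> np.ndarray:
        inside = (z >= self.z_min) & (z < self.z_max)
        if self.r_min is not None:
            inside &= (r >= self.r_min) & (r < self.r_max)
        return inside

    def _r_interval(self) -> tuple[float, float]:
        if self.r_min is None:
            return (-np.inf, np.inf)
        return (self.r_min, self.r_max)


@dataclass
class ROISet:
    """An ordered set of pairwise non-overlapping regions."""

    regions: list[ROIDefinition]

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValidationError("ROI labels must be unique")
        for i, a in enumerate(self.regions):
            for b in self.regions[i + 1:]:
                if self._overlap(a, b):
                    raise ValidationError(
                        f"ROIs {a.label!r} and {b.label!r} overlap"
                    )

    @staticmethod
    def _overlap(a: ROIDefinition, b: ROIDefinition) -> bool:
        z_overlap = a.z_min < b.z_max and b.z_min < a.z_max
        ar, br = a._r_interval(), b._r_interval()
        r_overlap = ar[0] < br[1] and br[0] < ar[1]
        return z_overlap and r_overlap

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.regions]

    @classmethod
    def from_yaml(cls, path) -> "ROISet":
        """Read regions from a YAML list of {label, z_min, z_max[, r_min, r_max]}."""
        with open(path, "rt") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, list):
            raise ValidationError(f"{path}: expected a YAML list of regions")
        return cls([ROIDefinition(**entry) for entry in raw])

    def to_yaml(self, path) -> None:
        entries = []
        for r in self.regions:
            e = {"label": r.label, "z_min": r.z_min, "z_max": r.z_max}
            if r.r_min is not None:
                e.update(r_min=r.r_min, r_max=r.r_max)
            entries.append(e)
        with open(path, "wt") as fh:
            yaml.safe_dump(entries, fh, sort_keys=False)


def _sample_labels(traj: Trajectory, rois: ROISet, mode: str) -> np.ndarray:
    """Per-sample ROI label (object array); UNASSIGNED outside every region."""
    labels = np.full(traj.n_samples, UNASSIGNED, dtype=object)
    if mode == "geometric":
        z = traj.pos[:, 2]
        r = traj.radius()
        for roi in rois:
            free = labels == UNASSIGNED
            labels[free & roi.contains(z, r)] = roi.label
    elif mode == "zone":
        if traj.zone is None:
            raise ValidationError(
                f"particle {traj.particle_id}: no zone labels in trajectory; "
                "use geometric assignment"
            )
        known = set(rois.labels)
        for i, zlab in enumerate(traj.zone):
            if zlab in known:
                labels[i] = zlab
    else:
        raise ValueError(f"unknown assignment mode {mode!r}")
    return labels


def assign_segments(
    traj: Trajectory, rois: ROISet, mode: str = "geometric"
) -> dict[str, list[tuple[int, int]]]:
    """Assign samples to regions; contiguous runs as half-open index intervals.

    Returns a map from ROI label (plus :data:`UNASSIGNED`) to a list of
    ``(start, stop)`` sample-index intervals, ``stop`` exclusive.  Every
    sample belongs to exactly one label.
    """
    labels = _sample_labels(traj, rois, mode)
    segments: dict[str, list[tuple[int, int]]] = {}
    start = 0
    for i in range(1, traj.n_samples + 1):
        if i == traj.n_samples or labels[i] != labels[start]:
            segments.setdefault(labels[start], []).append((start, i))
            start = i
    return segments


def roi_sa(
    traj: Trajectory,
    rois: ROISet,
    stress_unit: str = "Pa",
    mode: str = "geometric",
) -> dict[str, float]:
    """Per-region stress accumulation of one trajectory (dyne.s/cm^2).

    Each left-rectangle step ``sigma_i * dt_i`` is credited to the region
    containing sample ``i``; repeated visits accumulate.  All ROI labels are
    present in the result (0.0 when never entered) plus
    :data:`UNASSIGNED`; the values sum exactly to the global SA.
    """
    if traj.n_samples < 2:
        raise ValidationError(
            f"particle {traj.particle_id}: need >= 2 samples for SA"
        )
    dt = np.diff(traj.t)
    if np.any(dt <= 0):
        raise ValidationError(
            f"particle {traj.particle_id}: non-monotone sample times"
        )
    sigma = scalar_stress(traj.tau)
    steps = sigma[:-1] * dt
    labels = _sample_labels(traj, rois, mode)[:-1]
    to_cgs = STRESS_UNITS["dyne/cm2"] / STRESS_UNITS[stress_unit]
    out = {lab: 0.0 for lab in rois.labels}
    out[UNASSIGNED] = 0.0
    for lab in np.unique(labels):
        out[lab] = float(np.sum(steps[labels == lab])) * to_cgs
    return out


def roi_footprints(
    ensemble: TrajectoryEnsemble,
    rois: ROISet,
    mode: str = "geometric",
    include_unassigned: bool = False,
    grid_spec: tuple[float, float, int] | None = None,
    **footprint_options,
) -> dict[str, Footprint]:
    """Per-region footprints over a shared grid, comparable across regions.

    A trajectory contributes one SA value to each region it enters.  A grid
    is derived from the pooled per-region SA values when not supplied, so
    every returned footprint shares the same evaluation grid.  Regions
    entered by no trajectory are omitted with a warning.
    """
    if len(ensemble) == 0:
        raise ValidationError("cannot analyse an empty ensemble")
    labels = rois.labels + ([UNASSIGNED] if include_unassigned else [])
    values: dict[str, list[float]] = {lab: [] for lab in labels}
    ids: dict[str, list[str]] = {lab: [] for lab in labels}
    for tr in ensemble:
        if tr.n_samples < 2:
            continue
        segments = assign_segments(tr, rois, mode)
        per_roi = roi_sa(tr, rois, ensemble.stress_unit, mode)
        for lab in labels:
            if lab in segments:  # trajectory entered this region
                values[lab].append(per_roi[lab])
                ids[lab].append(tr.particle_id)

    if grid_spec is None:
        pooled = [v for vs in values.values() for v in vs]
        if not pooled:
            raise ValidationError("no trajectory entered any region")
        grid_spec = (0.0, 1.05 * max(pooled) + 1e-12, 512)

    footprints = {}
    for lab in labels:
        if not values[lab]:
            warnings.warn(f"ROI {lab!r} entered by zero trajectories; omitted",
                          stacklevel=2)
            continue
        sa = SAEnsemble(
            np.array(values[lab]), particle_ids=ids[lab],
            n_seeded=ensemble.n_seeded, label=ensemble.label, roi=lab,
        )
        footprints[lab] = build_footprint(
            sa, grid_spec=grid_spec, label=f"{ensemble.label}:{lab}",
            **footprint_options,
        )
    return footprints
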