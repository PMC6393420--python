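"""Lagrangian platelet trajectory ensembles: data model, validation, units, I/O.

A trajectory is a per-particle time series of position and the six
independent components of the viscous stress tensor, as exported from a
Lagrangian (discrete-phase) CFD run.  The canonical internal stress unit is
Pa; reporting operations convert to dyne/cm^2 (CGS) at the boundary, the
unit in which stress accumulation is conventionally plotted
(1 Pa = 10 dyne/cm^2).

Two on-disk dialects are supported:

``dte-tsv``
    Tab-delimited text with header
    ``particle_id  t  x  y  z  tau11  tau22  tau33  tau12  tau13  tau23  zone``,
    one row per (particle, time step).  Comment lines start with ``#``; a
    ``# stress_unit=<unit>`` comment is required.  ``zone`` may be empty.

``dte-h5``
    An HDF5 container with the same logical schema, for large ensembles.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, UnitError, ValidationError

#: Canonical ordering of the six independent viscous stress components.
TAU_COLUMNS = ("tau11", "tau22", "tau33", "tau12", "tau13", "tau23")

#: Supported stress units and the factor converting *from Pa* into them.
STRESS_UNITS = {"Pa": 1.0, "dyne/cm2": 10.0}

_TSV_COLUMNS = ("particle_id", "t", "x", "y", "z") + TAU_COLUMNS + ("zone",)

DIALECTS = ("dte-tsv", "dte-h5")


def _check_unit(unit: str) -> str:
    if unit not in STRESS_UNITS:
        raise UnitError(
            f"unknown stress unit {unit!r}; supported: {sorted(STRESS_UNITS)}"
        )
    return unit


@dataclass
class StressTensorSample:
    """One recorded point of a platelet trajectory.

    Times are in seconds, positions in metres.  Stress components are in the
    unit declared by the enclosing ensemble (internally Pa).
    """

    t: float
    x: float
    y: float
    z: float
    tau11: float
    tau22: float
    tau33: float
    tau12: float
    tau13: float
    tau23: float
    zone: str | None = None

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"sample time must be >= 0, got {self.t}")
        if not np.all(np.isfinite(self.tau())):
            raise ValidationError("stress tensor components must be finite")

    def tau(self) -> np.ndarray:
        """The six components in canonical order (tau11..tau23)."""
        return np.array(
            [self.tau11, self.tau22, self.tau33,
             self.tau12, self.tau13, self.tau23]
        )


@dataclass
class Trajectory:
    """Time-ordered samples of one particle.

    Parameters
    ----------
    particle_id
        Identifier, unique within an ensemble.
    t : (n,) array
        Sample times (s), strictly increasing.
    pos : (n, 3) array
        Cartesian positions (m); z is the axial coordinate.
    tau : (n, 6) array
        Stress components in :data:`TAU_COLUMNS` order.
    zone : (n,) object array, optional
        Per-sample cell-zone / ROI labels from the exporting solver.
    exited
        Whether the particle left the flow domain before simulation end.
    """

    particle_id: str
    t: np.ndarray
    pos: np.ndarray
    tau: np.ndarray
    zone: np.ndarray | None = None
    exited: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float).reshape(len(self.t), 3)
        self.tau = np.asarray(self.tau, dtype=float).reshape(len(self.t), 6)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        if np.any(self.t < 0):
            raise ValidationError(
                f"particle {self.particle_id}: negative sample time"
            )
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            raise ValidationError(
                f"particle {self.particle_id}: sample times not strictly increasing"
            )
        if not np.all(np.isfinite(self.tau)):
            raise ValidationError(
                f"particle {self.particle_id}: non-finite stress component"
            )

    def sample(self, i: int) -> StressTensorSample:
        """Materialize sample ``i`` as a :class:`StressTensorSample`."""
        zone = None if self.zone is None else (self.zone[i] or None)
        return StressTensorSample(
            self.t[i], *self.pos[i], *self.tau[i], zone=zone
        )

    def radius(self) -> np.ndarray:
        """Cylindrical radius sqrt(x^2+y^2) per sample (z is the pump axis)."""
        return np.hypot(self.pos[:, 0], self.pos[:, 1])


@dataclass
class TrajectoryEnsemble:
    """A seeded platelet population with its run metadata.

    ``meta`` carries run provenance (rpm, flow rate L/min, time step s,
    duration s, seed, n_seeded).  ``n_seeded`` falls back to the number of
    stored trajectories when the metadata does not say otherwise.
    """

    trajectories: list[Trajectory]
    stress_unit: str = "Pa"
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unit(self.stress_unit)
        ids = [tr.particle_id for tr in self.trajectories]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate particle_id in ensemble: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def n_seeded(self) -> int:
        return int(self.meta.get("n_seeded", len(self.trajectories)))

    def get(self, particle_id: str) -> Trajectory:
        for tr in self.trajectories:
            if tr.particle_id == particle_id:
                return tr
        raise KeyError(particle_id)


def convert_stress_units(
    ensemble: TrajectoryEnsemble, target: str
) -> TrajectoryEnsemble:
    """Return a copy of *ensemble* with stresses expressed in *target* unit.

    Pa -> dyne/cm2 multiplies every tensor component by exactly 10; the
    inverse divides by 10.  Converting to the current unit is the identity
    (same object returned).
    """
    _check_unit(target)
    if target == ensemble.stress_unit:
        return ensemble
    factor = STRESS_UNITS[target] / STRESS_UNITS[ensemble.stress_unit]
    out = []
    for tr in ensemble.trajectories:
        tau = tr.tau * factor if factor >= 1 else tr.tau / (1.0 / factor)
        out.append(
            Trajectory(
                tr.particle_id, tr.t.copy(), tr.pos.copy(), tau,
                zone=None if tr.zone is None else tr.zone.copy(),
                exited=tr.exited,
            )
        )
    return TrajectoryEnsemble(out, stress_unit=target,
                              label=ensemble.label, meta=dict(ensemble.meta))


# ---------------------------------------------------------------------------
# dte-tsv dialect
# ---------------------------------------------------------------------------

def _parse_header_comments(path) -> dict:
    meta = {}
    with open(path, "rt") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def _read_tsv(path) -> TrajectoryEnsemble:
    header = _parse_header_comments(path)
    if "stress_unit" not in header:
        raise FormatError(f"{path}: missing required '# stress_unit=' comment")
    unit = _check_unit(header["stress_unit"])
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#",
            dtype={"particle_id": str, "zone": str},
            float_precision="round_trip",  # 17-digit text must round-trip
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"{path}: malformed trajectory table: {exc}") from exc
    missing = [c for c in _TSV_COLUMNS if c not in df.columns and c != "zone"]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    numeric = ["t", "x", "y", "z", *TAU_COLUMNS]
    for col in numeric:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            lines = (df.index[bad] + 2).tolist()[:5]
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} near line(s) {lines}"
            ) from exc
    meta = {k[5:]: _maybe_number(v) for k, v in header.items()
            if k.startswith("meta.")}
    exited_ids = set(json.loads(header.get("exited", "[]")))
    label = header.get("label", "")
    return _ensemble_from_frame(df, unit, label, meta, exited_ids)


def _maybe_number(v: str):
    try:
        f = float(v)
    except ValueError:
        return v
    return int(f) if f.is_integer() and "." not in v and "e" not in v.lower() else f


def _ensemble_from_frame(df, unit, label, meta, exited_ids) -> TrajectoryEnsemble:
    has_zone = "zone" in df.columns and df["zone"].notna().any()
    trajectories = []
    for pid, grp in df.groupby("particle_id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        t = grp["t"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"particle {pid}: duplicate or non-increasing sample times"
            )
        zone = None
        if has_zone:
            zone = grp["zone"].fillna("").to_numpy(dtype=object)
        trajectories.append(
            Trajectory(
                str(pid), t, grp[["x", "y", "z"]].to_numpy(),
                grp[list(TAU_COLUMNS)].to_numpy(),
                zone=zone, exited=str(pid) in exited_ids,
            )
        )
    return TrajectoryEnsemble(trajectories, stress_unit=unit,
                              label=label, meta=meta)


def _write_tsv(ensemble: TrajectoryEnsemble, path) -> None:
    buf = io.StringIO()
    buf.write("# dialect=dte-tsv\n")
    buf.write(f"# stress_unit={ensemble.stress_unit}\n")
    if ensemble.label:
        buf.write(f"# label={ensemble.label}\n")
    for key in sorted(ensemble.meta):
        buf.write(f"# meta.{key}={ensemble.meta[key]}\n")
    exited = [tr.particle_id for tr in ensemble if tr.exited]
    buf.write(f"# exited={json.dumps(exited)}\n")
    buf.write("\t".join(_TSV_COLUMNS) + "\n")
    for tr in ensemble:
        zone = tr.zone if tr.zone is not None else [""] * tr.n_samples
        for i in range(tr.n_samples):
            nums = "\t".join(
                format(v, ".17g")
                for v in (tr.t[i], *tr.pos[i], *tr.tau[i])
            )
            buf.write(f"{tr.particle_id}\t{nums}\t{zone[i]}\n")
    with open(path, "wt") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# dte-h5 dialect
# ---------------------------------------------------------------------------

def _write_h5(ensemble: TrajectoryEnsemble, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["dialect"] = "dte-h5"
        f.attrs["stress_unit"] = ensemble.stress_unit
        f.attrs["label"] = ensemble.label
        f.attrs["meta"] = json.dumps(ensemble.meta)
        str_dt = h5py.string_dtype()
        ids = np.array([tr.particle_id for tr in ensemble], dtype=object)
        f.create_dataset("particle_id", data=ids, dtype=str_dt)
        f.create_dataset(
            "exited", data=np.array([tr.exited for tr in ensemble], dtype=bool)
        )
        counts = np.array([tr.n_samples for tr in ensemble], dtype=np.int64)
        f.create_dataset("n_samples", data=counts)
        if len(ensemble) == 0:
            return
        f.create_dataset("t", data=np.concatenate([tr.t for tr in ensemble]))
        f.create_dataset("pos", data=np.concatenate([tr.pos for tr in ensemble]))
        f.create_dataset("tau", data=np.concatenate([tr.tau for tr in ensemble]))
        if any(tr.zone is not None for tr in ensemble):
            zones = np.concatenate([
                tr.zone if tr.zone is not None
                else np.full(tr.n_samples, "", dtype=object)
                for tr in ensemble
            ])
            f.create_dataset("zone", data=zones.astype(object), dtype=str_dt)


def _read_h5(path) -> TrajectoryEnsemble:
    with h5py.File(path, "r") as f:
        if f.attrs.get("dialect") != "dte-h5":
            raise FormatError(f"{path}: not a dte-h5 container")
        unit = _check_unit(str(f.attrs["stress_unit"]))
        label = str(f.attrs.get("label", ""))
        meta = json.loads(f.attrs.get("meta", "{}"))
        ids = [s.decode() if isinstance(s, bytes) else str(s)
               for s in f["particle_id"][:]]
        exited = f["exited"][:]
        counts = f["n_samples"][:]
        trajectories = []
        if counts.sum() > 0:
            t = f["t"][:]
            pos = f["pos"][:]
            tau = f["tau"][:]
            zone = None
            if "zone" in f:
                zone = np.array(
                    [s.decode() if isinstance(s, bytes) else str(s)
                     for s in f["zone"][:]], dtype=object,
                )
            offsets = np.concatenate([[0], np.cumsum(counts)])
            for k, pid in enumerate(ids):
                lo, hi = offsets[k], offsets[k + 1]
                trajectories.append(
                    Trajectory(
                        pid, t[lo:hi], pos[lo:hi], tau[lo:hi],
                        zone=None if zone is None else zone[lo:hi],
                        exited=bool(exited[k]),
                    )
                )
    return TrajectoryEnsemble(trajectories, stress_unit=unit,
                              label=label, meta=meta)


# ---------------------------------------------------------------------------
# Public I/O API
# ---------------------------------------------------------------------------

def read_trajectories(path, dialect: str = "dte-tsv") -> TrajectoryEnsemble:
    """Read and validate a trajectory ensemble.

    Rows are grouped by ``particle_id`` and sorted by time; duplicated
    (particle, time) pairs raise :class:`~dtekit.errors.ValidationError`
    naming the particle, and malformed rows raise
    :class:`~dtekit.errors.FormatError` with line information.
    """
    if dialect == "dte-tsv":
        return _read_tsv(path)
    if dialect == "dte-h5":
        return _read_h5(path)
    raise FormatError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")


def write_trajectories(
    ensemble: TrajectoryEnsemble, path, dialect: str = "dte-tsv"
) -> None:
    """Write *ensemble* so that :func:`read_trajectories` reproduces it.

    The text dialect stores floats at 17 significant digits, i.e. the
    round trip is value-exact for IEEE doubles.
    """
    if dialect == "dte-tsv":
        _write_tsv(ensemble, path)
    elif dialect == "dte-h5":
        _write_h5(ensemble, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}; supported: {DIALECTS}")
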