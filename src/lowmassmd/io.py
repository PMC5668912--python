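"""File formats: PDB (read), XYZ trajectories, CSV records, JSON configs.

The PDB reader is a strict minimal fixed-width parser covering only
ATOM/HETATM/MODEL/ENDMDL records — enough to load toy topologies and
multi-model reference structures — and it reports the offending line
number on malformed records.  XYZ trajectory blocks carry the step index
and effective time on the comment line (``step=<n> t_smt=<fs>``) so a
round trip preserves the time axis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError
from .kinetics import FoldingRecord, PopulationSeries
from .metrics import StructureModel
from .toysim import ConstraintSet, ForceField, ToySystem, Trajectory


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path) -> list[StructureModel]:
    """Parse a PDB file into one StructureModel per MODEL.

    Files without MODEL records yield a single model.  Residue ids are
    taken 1-based as written; chain ids are ignored (pairing downstream
    is by residue id and atom name).  A malformed fixed-width record
    raises :class:`FormatError` carrying the 1-based line number.
    """
    models: list[StructureModel] = []
    names: list[str] = []
    resids: list[int] = []
    coords: list[list[float]] = []

    def flush(lineno):
        nonlocal names, resids, coords
        if names:
            models.append(
                StructureModel(names, np.array(resids), np.array(coords))
            )
            names, resids, coords = [], [], []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                flush(lineno)
            elif rec == "ENDMDL":
                flush(lineno)
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError("truncated ATOM record", line=lineno)
                try:
                    name = line[12:16].strip()
                    resid = int(line[22:26])
                    xyz = [
                        float(line[30:38]),
                        float(line[38:46]),
                        float(line[46:54]),
                    ]
                except ValueError as err:
                    raise FormatError(
                        f"malformed fixed-width field ({err})", line=lineno
                    ) from None
                names.append(name)
                resids.append(resid)
                coords.append(xyz)
    flush(None)
    if not models:
        raise FormatError(f"no ATOM records found in {path}")
    return models


def write_pdb(structure_or_traj, labels, residue_ids, path) -> None:
    """Write a structure or trajectory as (multi-model) PDB."""
    if isinstance(structure_or_traj, Trajectory):
        frames = structure_or_traj.frames
    else:
        frames = np.asarray(structure_or_traj, dtype=float)[None, :, :]
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            if len(frames) > 1:
                fh.write(f"MODEL     {m:4d}\n")
            for i, (x, y, z) in enumerate(frame):
                fh.write(
                    f"ATOM  {i + 1:5d} {labels[i]:<4s} TOY A{residue_ids[i]:4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
                )
            if len(frames) > 1:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ trajectories
# ---------------------------------------------------------------------------

def write_xyz_trajectory(traj: Trajectory, labels, path) -> None:
    """One XYZ block per frame; comment line ``step=<n> t_smt=<fs>``."""
    n = traj.frames.shape[1] if traj.n_frames else len(labels)
    if len(labels) != n and traj.n_frames:
        raise FormatError("labels length does not match particle count")
    with open(path, "w") as fh:
        for frame, step in zip(traj.frames, traj.step_indices):
            fh.write(f"{len(labels)}\n")
            fh.write(f"step={step} t_smt={step * traj.effective_dt:.6f}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz_trajectory(path) -> tuple[Trajectory, list[str]]:
    """Inverse of :func:`write_xyz_trajectory`.

    Coordinates round-trip to the printed precision (6 decimals); step
    indices exactly.  Returns the trajectory and the atom labels.
    """
    frames, steps, labels = [], [], []
    times = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i])
        except ValueError:
            raise FormatError("expected atom count", line=i + 1) from None
        comment = lines[i + 1].strip()
        fields = dict(
            kv.split("=", 1) for kv in comment.split() if "=" in kv
        )
        try:
            steps.append(int(fields["step"]))
            times.append(float(fields.get("t_smt", "nan")))
        except (KeyError, ValueError):
            raise FormatError("comment line must carry step=<n>", line=i + 2) from None
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError("frame truncated", line=len(lines))
        frame = np.empty((n, 3))
        labs = []
        for a, ln in enumerate(block):
            parts = ln.split()
            if len(parts) != 4:
                raise FormatError("expected 'label x y z'", line=i + 3 + a)
            labs.append(parts[0])
            frame[a] = [float(p) for p in parts[1:]]
        if labels and labs != labels:
            raise FormatError("atom labels differ between frames", line=i + 3)
        labels = labs
        frames.append(frame)
        i += 2 + n
    if not frames:
        return Trajectory(np.empty((0, 0, 3)), np.empty(0, dtype=int), dt=1.0), []
    steps_arr = np.array(steps, dtype=np.int64)
    eff_dt = 1.0
    if len(steps) and steps[0] > 0 and np.isfinite(times[0]):
        eff_dt = times[0] / steps[0]
    return (
        Trajectory(np.array(frames), steps_arr, dt=eff_dt, effective_dt=eff_dt),
        labels,
    )


# ---------------------------------------------------------------------------
# CSV records and series
# ---------------------------------------------------------------------------

def write_folding_records(records, path) -> None:
    """Columns: sim_id, time_ns, event (1 = folded, 0 = censored)."""
    pd.DataFrame(
        {
            "sim_id": np.arange(1, len(records) + 1),
            "time_ns": [r.time for r in records],
            "event": [int(r.event) for r in records],
        }
    ).to_csv(path, index=False)


def read_folding_records(path) -> list[FoldingRecord]:
    df = pd.read_csv(path)
    for col in ("time_ns", "event"):
        if col not in df.columns:
            raise FormatError(f"records CSV missing column {col!r}")
    return [
        FoldingRecord(time=float(t), event=bool(e))
        for t, e in zip(df["time_ns"], df["event"])
    ]


def write_population_series(series: PopulationSeries, path) -> None:
    """Table-style CSV with percentages rounded to the nearest integer
    (matching printed-table style); full precision stays in memory."""
    df = series.to_frame()
    out = df.copy()
    for col in ("mean_pct", "sd_pct", "se_pct"):
        out[col] = np.rint(df[col]).astype(int)
    out.to_csv(path, index=False)


def write_rmsd_series(steps, rmsd, path) -> None:
    pd.DataFrame({"step": steps, "rmsd_A": rmsd}).to_csv(path, index=False)


def read_rmsd_series(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise FormatError("RMSD CSV needs (step, rmsd) columns")
    return df[cols[0]].to_numpy(), df[cols[1]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# JSON system configuration
# ---------------------------------------------------------------------------

def system_to_json(
    system: ToySystem,
    ff: ForceField,
    constraints: ConstraintSet | None,
    path,
) -> None:
    doc = {
        "particles": {
            "masses": system.masses.tolist(),
            "positions": system.positions.tolist(),
            "velocities": system.velocities.tolist(),
            "labels": list(system.labels),
            "residue_ids": system.residue_ids.tolist(),
        },
        "forcefield": {
            "bonds": [list(t) for t in ff.bonds],
            "angles": [list(t) for t in ff.angles],
            "torsions": [list(t) for t in ff.torsions],
            "lj_pairs": [list(t) for t in ff.lj_pairs],
        },
    }
    if constraints is not None:
        doc["constraints"] = {
            "pairs": [list(t) for t in constraints.pairs],
            "tolerance": constraints.tolerance,
            "max_iterations": constraints.max_iterations,
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def system_from_json(path) -> tuple[ToySystem, ForceField, ConstraintSet | None]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise FormatError(f"invalid JSON system config: {err}") from None
    try:
        p = doc["particles"]
        system = ToySystem(
            masses=np.array(p["masses"], dtype=float),
            positions=np.array(p["positions"], dtype=float),
            velocities=np.array(p["velocities"], dtype=float),
            labels=list(p.get("labels", [])),
            residue_ids=(
                np.array(p["residue_ids"]) if "residue_ids" in p else None
            ),
        )
        f = doc.get("forcefield", {})
        ff = ForceField(
            bonds=[tuple(t) for t in f.get("bonds", [])],
            angles=[tuple(t) for t in f.get("angles", [])],
            torsions=[tuple(t) for t in f.get("torsions", [])],
            lj_pairs=[tuple(t) for t in f.get("lj_pairs", [])],
        )
    except (KeyError, TypeError) as err:
        raise FormatError(f"system config missing field: {err}") from None
    constraints = None
    if "constraints" in doc:
        c = doc["constraints"]
        constraints = ConstraintSet(
            pairs=[tuple(t) for t in c["pairs"]],
            tolerance=float(c.get("tolerance", 1e-8)),
            max_iterations=int(c.get("max_iterations", 500)),
        )
    ff.validate(system.n_particles)
    return system, ff, constraints
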