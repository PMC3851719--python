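"""PLUMED-dialect COLVAR time-series files.

One file per replica: a ``#! FIELDS time position lambda work nhb`` header
followed by whitespace-separated numeric rows.  Columns are mapped by name,
so field order is irrelevant; ``work`` and ``nhb`` are optional on input
(work is recomputed downstream from position and lambda when absent).
Values are written with 9 significant digits so a write/read roundtrip
preserves them to well under 1e-6 relative.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .simulate import WorkTrajectory

__all__ = ["read_colvar", "write_colvar", "write_ensemble", "read_ensemble_dir"]

_REQUIRED = ("time", "position", "lambda")


def write_colvar(trajectory: WorkTrajectory, path) -> None:
    """Write one trajectory as a COLVAR file (PLUMED dialect)."""
    path = Path(path)
    fields = ["time", "position", "lambda"]
    cols = [trajectory.time, trajectory.position, trajectory.lam]
    if trajectory.work is not None:
        fields.append("work")
        cols.append(trajectory.work)
    if trajectory.nhb is not None:
        fields.append("nhb")
        cols.append(np.asarray(trajectory.nhb, dtype=float))
    with path.open("w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        if trajectory.seed is not None:
            fh.write(f"#! SET seed {trajectory.seed}\n")
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")


def read_colvar(path) -> WorkTrajectory:
    """Read one trajectory from a COLVAR file, mapping columns by name."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.readlines()
    if not lines or not lines[0].startswith("#! FIELDS"):
        raise FormatError(f"{path}:1: missing '#! FIELDS' header")
    fields = lines[0].split()[2:]
    missing = [f for f in _REQUIRED if f not in fields]
    if missing:
        raise FormatError(f"{path}:1: header lacks required fields {missing}")
    seed = None
    rows = []
    for ln_no, line in enumerate(lines[1:], start=2):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            parts = s.split()
            if parts[:2] == ["#!", "SET"] and len(parts) == 4 and parts[2] == "seed":
                seed = int(parts[3])
            continue
        vals = s.split()
        if len(vals) != len(fields):
            raise FormatError(
                f"{path}:{ln_no}: row has {len(vals)} values, expected {len(fields)}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError:
            raise FormatError(f"{path}:{ln_no}: non-numeric value") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.asarray(rows)
    col = {f: data[:, i] for i, f in enumerate(fields)}
    work = col.get("work")
    if work is not None and len(work) and work[0] != 0.0:
        work = work - work[0]
    nhb = col.get("nhb")
    return WorkTrajectory(
        time=col["time"],
        position=col["position"],
        lam=col["lambda"],
        work=work,
        nhb=None if nhb is None else nhb.astype(int),
        seed=seed,
    )


def write_ensemble(ensemble, directory, prefix: str = "colvar") -> list[Path]:
    """Write every replica as ``<prefix>_rep####.dat`` in ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tr in enumerate(ensemble.trajectories):
        p = directory / f"{prefix}_rep{i:04d}.dat"
        write_colvar(tr, p)
        paths.append(p)
    return paths


def read_ensemble_dir(directory, prefix: str = "colvar"):
    """Read all ``<prefix>_rep*.dat`` files in a directory into an ensemble."""
    from .simulate import WorkEnsemble

    directory = Path(directory)
    paths = sorted(directory.glob(f"{prefix}_rep*.dat"))
    if not paths:
        raise FormatError(f"no {prefix}_rep*.dat files in {directory}")
    return WorkEnsemble(trajectories=tuple(read_colvar(p) for p in paths))
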