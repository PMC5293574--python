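"""On-disk formats: XYZ trajectories, HDF5 sample containers, YAML
configuration blocks and tidy CSV observable tables.

XYZ is the interchange trajectory format (one frame per sample, element
tag "C", comment line carrying the MCS index, replica id and wall energy);
the HDF5 container holds the authoritative data (positions, energy
components, metadata, restart log).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .engine import RunSchedule, SampleSet
from .model import Conformation, ModelParams

__all__ = [
    "write_xyz", "read_xyz",
    "save_samples", "load_samples",
    "save_params", "load_params",
    "save_schedule", "load_schedule",
    "correlation_to_frame", "histogram_to_frame",
]


class TrajectoryFormatError(ValueError):
    """Malformed XYZ input; message names the offending frame/line."""


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

def write_xyz(path, confs, comments: Sequence[str] | None = None,
              element: str = "C") -> None:
    """Write conformations (or a SampleSet) as a multi-frame XYZ file.

    For a SampleSet the comment line of each frame records
    ``mcs=<index> replica=<id> u_surf=<wall energy>``.
    """
    if isinstance(confs, SampleSet):
        comments = [
            f"mcs={int(m)} replica={int(r)} u_surf={u:.17g}"
            for m, r, u in zip(confs.mcs_index, confs.replica_id,
                               confs.u_surf)]
        confs = confs.conformations()
    elif isinstance(confs, Conformation):
        confs = [confs]
    else:
        confs = list(confs)
    if comments is None:
        comments = [""] * len(confs)
    with open(path, "w") as fh:
        for conf, comment in zip(confs, comments):
            fh.write(f"{conf.n_beads}\n{comment}\n")
            for x, y, z in conf.positions:
                fh.write(f"{element} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path):
    """Read a multi-frame XYZ file -> (list of Conformation, list of
    comment strings).  Truncated frames or frames whose bead count differs
    from the first are rejected with the frame number."""
    confs: list[Conformation] = []
    comments: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    frame = 0
    n_expected = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame += 1
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"frame {frame}: bad atom-count line {lines[i]!r}") from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryFormatError(
                f"frame {frame}: bead count {n} differs from frame 1 "
                f"({n_expected})")
        if len(lines) < i + 2 + n:
            raise TrajectoryFormatError(
                f"frame {frame}: truncated (expected {n} coordinate lines)")
        comments.append(lines[i + 1])
        pos = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"frame {frame}: bad coordinate line "
                    f"{lines[i + 2 + k]!r}")
            pos[k] = [float(p) for p in parts[1:4]]
        confs.append(Conformation(pos, copy=False))
        i += 2 + n
    return confs, comments


# ---------------------------------------------------------------------------
# HDF5 sample container
# ---------------------------------------------------------------------------

def save_samples(path, samples: SampleSet) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("positions", data=samples.positions)
        fh.create_dataset("energies", data=samples.energies)
        fh.create_dataset("mcs_index", data=samples.mcs_index)
        fh.create_dataset("replica_id", data=samples.replica_id)
        meta = fh.create_group("meta")
        meta.attrs["params"] = json.dumps(samples.params.to_dict())
        meta.attrs["schedule"] = json.dumps(samples.schedule.to_dict())
        meta.attrs["restarts"] = json.dumps(samples.restarts)
        meta.attrs["failed_replicas"] = json.dumps(samples.failed_replicas)


def load_samples(path) -> SampleSet:
    with h5py.File(path, "r") as fh:
        for name in ("positions", "energies", "mcs_index", "replica_id"):
            if name not in fh:
                raise ValueError(f"{path}: missing dataset {name!r}")
        if "meta" not in fh:
            raise ValueError(f"{path}: missing metadata group")
        meta = fh["meta"]
        return SampleSet(
            params=ModelParams.from_dict(json.loads(meta.attrs["params"])),
            schedule=RunSchedule.from_dict(
                json.loads(meta.attrs["schedule"])),
            positions=fh["positions"][()],
            energies=fh["energies"][()],
            mcs_index=fh["mcs_index"][()],
            replica_id=fh["replica_id"][()],
            restarts=json.loads(meta.attrs["restarts"]),
            failed_replicas=json.loads(meta.attrs["failed_replicas"]),
        )


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def save_params(path, params: ModelParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def load_params(path) -> ModelParams:
    with open(path) as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))


def save_schedule(path, schedule: RunSchedule) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule.to_dict(), fh, sort_keys=False)


def load_schedule(path) -> RunSchedule:
    with open(path) as fh:
        return RunSchedule.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# tidy observable tables
# ---------------------------------------------------------------------------

def correlation_to_frame(curve, **metadata) -> pd.DataFrame:
    """CorrelationCurve -> tidy DataFrame (lag, value, n, [normalized]) with
    constant metadata columns (b, eps_a, replica, ...) appended."""
    data = {"lag": curve.lag, "value": curve.value, "n": curve.n_pairs}
    if curve.normalized is not None:
        data["normalized"] = curve.normalized
    df = pd.DataFrame(data)
    for key, val in metadata.items():
        df[key] = val
    return df


def histogram_to_frame(hist, **metadata) -> pd.DataFrame:
    """HeightHistogram -> tidy DataFrame (bin, count, proportion)."""
    df = pd.DataFrame({"bin": hist.bin_centers, "count": hist.counts,
                       "proportion": hist.proportions})
    for key, val in metadata.items():
        df[key] = val
    return df
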