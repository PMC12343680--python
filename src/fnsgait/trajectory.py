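"""Discretized trajectories and the tab-delimited motion-table formats.

A :class:`Trajectory` holds a strictly increasing time grid with states
(coordinates, speeds, activations, optionally normalized tendon forces) and
controls (muscle excitations in [0.01, 1], actuator controls in [-1, 1]).

STO/MOT-style tables (header, then tab-delimited columns with time first) are
the interchange format for trajectories and force/angle time series; TRC is
the marker-trajectory format.  Both are plain text and round-trip losslessly
at full double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "write_sto",
    "read_sto",
    "write_trc",
    "read_trc",
]

EXCITATION_LO = 0.01
EXCITATION_HI = 1.0


@dataclass
class Trajectory:
    """States and controls on a time grid.

    Column order of ``states`` is [q (n_q), u (n_q), a (n_mus)] and of
    ``controls`` is [excitations (n_mus), actuator controls (n_act)];
    the name lists make the layout explicit and file-portable.
    """

    time: np.ndarray  # (n,)
    coord_names: list
    muscle_names: list
    actuator_names: list
    q: np.ndarray  # (n, n_q) rad or m
    u: np.ndarray  # (n, n_q) rad/s or m/s
    a: np.ndarray  # (n, n_mus) activations
    excitation: np.ndarray  # (n, n_mus) in [0.01, 1]
    actuator: np.ndarray  # (n, n_act) dimensionless in [-1, 1]
    tendon_force: np.ndarray | None = None  # (n, n_mus) normalized, optional
    model: object = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        for name in ("q", "u", "a", "excitation", "actuator"):
            setattr(self, name, np.atleast_2d(np.asarray(getattr(self, name), dtype=float)))
        n = self.time.size
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")
        for name, arr, width in (
            ("q", self.q, len(self.coord_names)),
            ("u", self.u, len(self.coord_names)),
            ("a", self.a, len(self.muscle_names)),
            ("excitation", self.excitation, len(self.muscle_names)),
            ("actuator", self.actuator, len(self.actuator_names)),
        ):
            if arr.shape != (n, width):
                raise ValueError(
                    f"trajectory field {name!r}: shape {arr.shape} != ({n}, {width})"
                )
        if np.any(self.excitation < EXCITATION_LO - 1e-9) or np.any(
            self.excitation > EXCITATION_HI + 1e-9
        ):
            raise ValueError("muscle excitations must lie within [0.01, 1]")

    # ------------------------------------------------------------------ util
    @property
    def t_i(self):
        return float(self.time[0])

    @property
    def t_f(self):
        return float(self.time[-1])

    @property
    def duration(self):
        return self.t_f - self.t_i

    def interpolate(self, new_time):
        """Linear resampling onto a new (strictly increasing) grid."""
        new_time = np.asarray(new_time, dtype=float)

        def col(arr):
            return np.column_stack(
                [np.interp(new_time, self.time, arr[:, j]) for j in range(arr.shape[1])]
            ) if arr.shape[1] else np.zeros((new_time.size, 0))

        return Trajectory(
            new_time, self.coord_names, self.muscle_names, self.actuator_names,
            col(self.q), col(self.u), col(self.a), col(self.excitation),
            col(self.actuator),
            tendon_force=None if self.tendon_force is None else col(self.tendon_force),
            model=self.model, meta=dict(self.meta),
        )

    def to_frame(self):
        data = {"time": self.time}
        for names, arr, prefix in (
            (self.coord_names, self.q, "q"),
            (self.coord_names, self.u, "u"),
            (self.muscle_names, self.a, "a"),
            (self.muscle_names, self.excitation, "e"),
            (self.actuator_names, self.actuator, "r"),
        ):
            for j, nm in enumerate(names):
                data[f"{prefix}/{nm}"] = arr[:, j]
        if self.tendon_force is not None:
            for j, nm in enumerate(self.muscle_names):
                data[f"ftilde/{nm}"] = self.tendon_force[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df, model=None):
        def block(prefix):
            cols = [c for c in df.columns if c.startswith(prefix + "/")]
            names = [c.split("/", 1)[1] for c in cols]
            return names, df[cols].to_numpy(dtype=float)

        cn, q = block("q")
        _, u = block("u")
        mn, a = block("a")
        _, e = block("e")
        an, r = block("r")
        ftn = [c for c in df.columns if c.startswith("ftilde/")]
        ft = df[ftn].to_numpy(dtype=float) if ftn else None
        return cls(df["time"].to_numpy(dtype=float), cn, mn, an, q, u, a, e, r,
                   tendon_force=ft, model=model)

    def save_sto(self, path, name="trajectory"):
        write_sto(self.to_frame(), path, name=name)

    @classmethod
    def load_sto(cls, path, model=None):
        return cls.from_frame(read_sto(path), model=model)


# -------------------------------------------------------------- STO / MOT ---
def write_sto(df, path, name="data", in_degrees=False):
    """Write a DataFrame (first column must be 'time') as an STO/MOT table."""
    if df.columns[0] != "time":
        raise ValueError("first column must be 'time'")
    with open(path, "w") as fh:
        fh.write(f"{name}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(df)}\n")
        fh.write(f"nColumns={len(df.columns)}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(df.columns) + "\n")
        np.savetxt(fh, df.to_numpy(dtype=float), fmt="%.17g", delimiter="\t")


def read_sto(path):
    """Read an STO/MOT table into a DataFrame (time first column)."""
    with open(path) as fh:
        lines = fh.readlines()
    try:
        header_end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise ValueError(f"{path}: no 'endheader' line; not an STO/MOT table") from None
    columns = lines[header_end + 1].rstrip("\n").split("\t")
    data = np.loadtxt(lines[header_end + 2:], delimiter="\t", ndmin=2)
    return pd.DataFrame(data, columns=columns)


# --------------------------------------------------------------------- TRC ---
def write_trc(path, time, marker_names, xyz, data_rate=100.0, units="m"):
    """Write marker trajectories as a TRC file.

    xyz: (n_frames, n_markers, 3) in the stated units.
    """
    time = np.asarray(time, dtype=float)
    xyz = np.asarray(xyz, dtype=float)
    n, nm, _ = xyz.shape
    with open(path, "w") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{data_rate:g}\t{data_rate:g}\t{n}\t{nm}\t{units}\t{data_rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(marker_names) + "\t\t\t\n")
        sub = ["", ""]
        for j in range(nm):
            sub += [f"X{j+1}", f"Y{j+1}", f"Z{j+1}"]
        fh.write("\t".join(sub) + "\n")
        flat = xyz.reshape(n, nm * 3)
        for i in range(n):
            row = [str(i + 1), f"{time[i]:.17g}"] + [f"{v:.17g}" for v in flat[i]]
            fh.write("\t".join(row) + "\n")


def read_trc(path):
    """Read a TRC file.  Returns (time (n,), marker_names, xyz (n, nm, 3))."""
    with open(path) as fh:
        lines = fh.readlines()
    meta = lines[2].split("\t")
    n, nm = int(meta[2]), int(meta[3])
    names_row = lines[3].rstrip("\n").split("\t")
    marker_names = [c for c in names_row[2:] if c]
    if len(marker_names) != nm:
        raise ValueError(f"{path}: expected {nm} marker names, found {len(marker_names)}")
    data = np.loadtxt(lines[5:5 + n], delimiter="\t", ndmin=2)
    time = data[:, 1]
    xyz = data[:, 2:2 + nm * 3].reshape(len(time), nm, 3)
    return time, marker_names, xyz
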