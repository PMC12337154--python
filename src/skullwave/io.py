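"""HDF5 persistence and CSV export helpers.

Acoustic maps and channel data carry their own ``save``/``load`` (HDF5
with datasets per property grid and attributes for spacing and seeds);
this module adds run-level containers: saving a full case set and
writing tidy metric tables.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .solver import ChannelData


def save_caseset(path, caseset) -> None:
    """Write a four-case decomposition result to one HDF5 file."""
    with h5py.File(path, "w") as f:
        g = f.create_group("grid")
        g.create_dataset("z", data=caseset.grid.z)
        g.create_dataset("x", data=caseset.grid.x)
        if caseset.reference is not None:
            f.attrs["reference"] = caseset.reference
        for case, cd in caseset.channel.items():
            grp = f.create_group(f"channel/{case}")
            grp.create_dataset("traces", data=cd.traces)
            grp.attrs["dt"] = cd.dt
            grp.attrs["t0"] = cd.t0
            if cd.element_x is not None:
                grp.create_dataset("element_x", data=cd.element_x)
            if cd.focus is not None:
                grp.attrs["focus"] = cd.focus
                grp.attrs["t_focal"] = cd.t_focal
            if cd.f0 is not None:
                grp.attrs["f0"] = cd.f0
                grp.attrs["t_pulse_center"] = cd.t_pulse_center
        for case, rf in caseset.rf.items():
            f.create_dataset(f"rf/{case}", data=rf.data)


def load_channel_group(path, case: str) -> ChannelData:
    """Read one case's channel data back from a case-set file."""
    with h5py.File(path, "r") as f:
        grp = f[f"channel/{case}"]
        return ChannelData(
            grp["traces"][...],
            dt=float(grp.attrs["dt"]),
            t0=float(grp.attrs["t0"]),
            element_x=grp["element_x"][...] if "element_x" in grp else None,
            f0=float(grp.attrs["f0"]) if "f0" in grp.attrs else None,
            t_pulse_center=float(grp.attrs["t_pulse_center"])
            if "t_pulse_center" in grp.attrs else None,
            focus=tuple(grp.attrs["focus"]) if "focus" in grp.attrs else None,
            t_focal=float(grp.attrs["t_focal"]) if "t_focal" in grp.attrs else None,
        )


def export_bmode_csv(path, bmode) -> None:
    """Dump a B-mode dB grid plus axes as plain CSV (depth rows)."""
    path = Path(path)
    header = "depth_m," + ",".join(f"{x:.6e}" for x in bmode.grid.x)
    rows = np.column_stack([bmode.grid.z, bmode.db])
    np.savetxt(path, rows, delimiter=",", header=header, comments="")


def write_metrics_csv(path, table) -> None:
    """Write a tidy metric table (pandas DataFrame) to CSV."""
    table.to_csv(path, index=False)
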