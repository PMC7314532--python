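"""Plain-text I/O for curves, calibration tables and simulated fields.

Diffusion-curve CSVs carry their metadata (distance, depth, medium,
animal, group) as ``# key: value`` header lines above the column header,
so a curve file is self-describing and round-trips losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import CalibrationTable, DiffusionCurve
from .dopamine import ConcentrationField

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_calibration_csv",
    "read_calibration_csv",
    "field_to_frame",
]


def write_curve_csv(curve: DiffusionCurve, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "distance_um": curve.distance,
        "depth_um": curve.depth,
        "medium": curve.medium,
        "animal_id": curve.animal_id,
        "group": curve.group,
    }
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("time_s,conc_uM\n")
        for t, c in zip(curve.times, curve.concentration):
            fh.write(f"{t:.10g},{c:.10g}\n")


def read_curve_csv(path: str | Path) -> DiffusionCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=n_header)
    depth = float(meta.get("depth_um", "nan"))
    return DiffusionCurve(
        distance=float(meta["distance_um"]),
        times=df["time_s"].to_numpy(),
        concentration=df["conc_uM"].to_numpy(),
        medium=meta.get("medium", "tissue"),  # type: ignore[arg-type]
        depth=depth,
        animal_id=meta.get("animal_id", ""),
        group=meta.get("group", ""),
    )


def write_calibration_csv(table: CalibrationTable, path: str | Path) -> None:
    pd.DataFrame(
        {"conc_mM": table.concentrations, "voltage_mV": table.voltages}
    ).to_csv(path, index=False)


def read_calibration_csv(path: str | Path) -> CalibrationTable:
    df = pd.read_csv(path)
    return CalibrationTable(
        concentrations=df["conc_mM"].to_numpy(), voltages=df["voltage_mV"].to_numpy()
    )


def field_to_frame(field: ConcentrationField) -> pd.DataFrame:
    """Long-format (r, t, C) frame for a simulated concentration field."""
    rr, tt = np.meshgrid(field.r, field.t)
    return pd.DataFrame(
        {"t_s": tt.ravel(), "r_um": rr.ravel(), "conc_uM": field.C.ravel()}
    )
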