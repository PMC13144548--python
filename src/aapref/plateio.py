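"""Plate-reader table IO: long/wide OD tables, plate maps, condition tables.

All formats are plain delimited text (tab- or comma-separated, detected
from the header), UTF-8, '.' decimal point. Lines starting with '#' are
provenance/comments and are ignored on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .growth import GrowthCurve


def _read_table(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = None
        for line in fh:
            if not line.startswith("#") and line.strip():
                header = line
                break
    if header is None:
        raise ValueError(f"{path}: no data rows")
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, comment="#")


def read_plate(path: str | Path,
               plate_map: dict[str, str] | None = None) -> list[GrowthCurve]:
    """Read OD600 curves from a wide (time_h + one column per well) or long
    (time_h, well_id, od[, condition_id]) table; the dialect is detected
    from the header. ``plate_map`` optionally maps well_id -> condition_id.
    """
    df = _read_table(path)
    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "time_h" not in cols:
        raise ValueError(f"{path}: missing required column 'time_h'")
    curves: list[GrowthCurve] = []
    if {"well_id", "od"}.issubset(cols):  # long dialect
        for well, grp in df.groupby("well_id", sort=True):
            grp = grp.sort_values("time_h")
            cond = ""
            if "condition_id" in cols:
                cond = str(grp["condition_id"].iloc[0])
            if plate_map is not None:
                cond = plate_map.get(str(well), cond)
            curves.append(_make_curve(path, grp["time_h"].to_numpy(),
                                      grp["od"].to_numpy(), str(well), cond))
    else:  # wide dialect
        t = df["time_h"].to_numpy(dtype=float)
        for col in cols:
            if col == "time_h":
                continue
            cond = plate_map.get(col, "") if plate_map else ""
            curves.append(_make_curve(path, t, df[col].to_numpy(dtype=float),
                                      col, cond))
    return curves


def _make_curve(path, t, od, well, cond) -> GrowthCurve:
    if np.any(~np.isfinite(np.asarray(od, float))):
        raise ValueError(f"{path}: non-finite OD values in well {well}")
    try:
        return GrowthCurve(time_h=np.asarray(t, float),
                           od=np.asarray(od, float),
                           well_id=well, condition_id=cond)
    except ValueError as exc:
        raise ValueError(f"{path}: well {well}: {exc}") from exc


def write_plate(curves: Iterable[GrowthCurve], path: str | Path,
                layout: str = "long", header_lines: Iterable[str] = ()) -> None:
    """Write curves as a delimited text table (lossless round-trip)."""
    curves = list(curves)
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        if layout == "long":
            fh.write("condition_id\twell_id\ttime_h\tod\n")
            for c in curves:
                for t, od in zip(c.time_h, c.od):
                    fh.write(f"{c.condition_id}\t{c.well_id}\t{t:g}\t{od:.6g}\n")
        elif layout == "wide":
            t0 = curves[0].time_h
            for c in curves[1:]:
                if not np.array_equal(c.time_h, t0):
                    raise ValueError("wide layout needs a shared time grid")
            fh.write("time_h\t" + "\t".join(c.well_id for c in curves) + "\n")
            for i, t in enumerate(t0):
                fh.write(f"{t:g}\t" + "\t".join(f"{c.od[i]:.6g}" for c in curves)
                         + "\n")
        else:
            raise ValueError(f"unknown layout: {layout!r}")


def read_plate_map(path: str | Path) -> dict[str, str]:
    """Read a well_id -> condition_id map (columns well_id, condition_id)."""
    df = _read_table(path)
    if not {"well_id", "condition_id"}.issubset(df.columns):
        raise ValueError(f"{path}: plate map needs well_id and condition_id")
    return dict(zip(df["well_id"].astype(str), df["condition_id"].astype(str)))


def write_table(df: pd.DataFrame, path: str | Path,
                header_lines: Iterable[str] = ()) -> None:
    """Write a DataFrame as TSV with '#' provenance header lines."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
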