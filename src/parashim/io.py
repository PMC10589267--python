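"""Spectrum export/import: minimal JCAMP-DX (XYPOINTS) and CSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fields import FieldMap, SampleGrid
from .spectrometer import Spectrum

__all__ = [
    "spectrum_to_jcamp",
    "spectrum_from_jcamp",
    "spectrum_to_csv",
    "spectrum_from_csv",
    "fieldmaps_to_csv",
]


def spectrum_to_jcamp(spec: Spectrum, path: str | Path, title: str = "parashim spectrum") -> None:
    """Write a single spectrum as JCAMP-DX 4.24 with an (XY..XY) table."""
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=HZ",
        "##YUNITS=ARBITRARY UNITS",
        f"##NPOINTS={spec.intensities.size}",
        f"##FIRSTX={spec.axis_hz[0]:.10g}",
        f"##LASTX={spec.axis_hz[-1]:.10g}",
        "##XYPOINTS=(XY..XY)",
    ]
    for x, y in zip(spec.axis_hz, spec.intensities):
        lines.append(f"{x:.10g}, {y:.10g}")
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def spectrum_from_jcamp(path: str | Path) -> Spectrum:
    text = Path(path).read_text().splitlines()
    xs, ys = [], []
    in_table = False
    meta: dict = {}
    for line in text:
        line = line.strip()
        if line.startswith("##"):
            if line.startswith("##XYPOINTS"):
                in_table = True
            elif line.startswith("##END"):
                in_table = False
            elif "=" in line:
                key, val = line[2:].split("=", 1)
                meta[key.strip()] = val.strip()
            continue
        if in_table and line:
            sx, sy = line.split(",")
            xs.append(float(sx))
            ys.append(float(sy))
    if not xs:
        raise ValueError(f"no XYPOINTS table found in {path}")
    return Spectrum(np.array(ys), np.array(xs), {"jcamp": meta})


def spectrum_to_csv(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"axis_hz": spec.axis_hz, "intensity": spec.intensities}).to_csv(
        path, index=False
    )


def spectrum_from_csv(path: str | Path) -> Spectrum:
    df = pd.read_csv(path)
    return Spectrum(df["intensity"].to_numpy(), df["axis_hz"].to_numpy())


def fieldmaps_to_csv(grid: SampleGrid, fields: list[FieldMap], path: str | Path) -> None:
    """Export field maps as rows of (x_mm, y_mm, z_mm, offset_hz, channel)."""
    frames = []
    for fm in fields:
        frames.append(
            pd.DataFrame(
                {
                    "x_mm": grid.points[:, 0],
                    "y_mm": grid.points[:, 1],
                    "z_mm": grid.points[:, 2],
                    "offset_hz": fm.offsets,
                    "channel": fm.channel_id,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
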