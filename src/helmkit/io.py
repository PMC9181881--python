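"""Readers and writers for the tabular text formats.

Decays are TSV with ``#key: value`` header comments and columns
``time_ns`` / ``counts``; spectra and melting curves are two-column CSV.
Write-then-read and read-then-write are identities (counts bit-exact,
metadata preserved).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .grids import TimeGrid
from .models import DecayCurve, MeltingCurve, ResponseCurve, SteadyStateSpectrum

__all__ = [
    "write_decay",
    "read_decay",
    "write_spectrum",
    "read_spectrum",
    "write_melting_curve",
    "read_melting_curve",
    "write_json_record",
]


def write_decay(path, decay: DecayCurve) -> None:
    path = Path(path)
    lines = [
        f"#excitation_nm: {decay.excitation_wavelength:g}",
        f"#emission_nm: {decay.emission_wavelength:g}",
        f"#polarization: {decay.polarization}",
        f"#seed: {decay.seed if decay.seed is not None else ''}",
        "time_ns\tcounts",
    ]
    for t, c in zip(decay.grid.centers(), decay.counts):
        lines.append(f"{t:.6f}\t{int(round(c))}")
    path.write_text("\n".join(lines) + "\n")


def read_decay(path) -> DecayCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    counts: list[int] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise ParseError("malformed header comment", lineno)
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
                continue
            if line.startswith("time_ns"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"expected 2 columns, got {len(parts)}", lineno)
            try:
                t = float(parts[0])
            except ValueError:
                raise ParseError(f"bad time value {parts[0]!r}", lineno) from None
            try:
                c = int(parts[1])
            except ValueError:
                raise ParseError(
                    f"counts must be integers, got {parts[1]!r}", lineno
                ) from None
            if c < 0:
                raise ParseError(f"negative count {c}", lineno)
            times.append(t)
            counts.append(c)
    if len(times) < 2:
        raise ParseError("fewer than 2 data rows")
    t = np.array(times)
    diffs = np.diff(t)
    bw = float(np.median(diffs))
    if np.any(np.abs(diffs - bw) > 1e-6):
        raise ParseError(
            f"non-uniform time grid (bin widths {diffs.min():.6g}.."
            f"{diffs.max():.6g})"
        )
    grid = TimeGrid(
        start=round(float(t[0]) - bw / 2.0, 9),
        stop=round(float(t[-1]) + bw / 2.0, 9),
        bin_width=round(bw, 9),
    )
    for key in ("excitation_nm", "emission_nm", "polarization"):
        if key not in meta:
            raise ParseError(f"missing required header #{key}")
    seed = meta.get("seed", "")
    return DecayCurve(
        grid=grid,
        counts=np.array(counts, dtype=float),
        emission_wavelength=float(meta["emission_nm"]),
        excitation_wavelength=float(meta["excitation_nm"]),
        polarization=meta["polarization"],
        seed=int(seed) if seed else None,
    )


def write_spectrum(path, spectrum: SteadyStateSpectrum | ResponseCurve) -> None:
    if isinstance(spectrum, ResponseCurve):
        df = pd.DataFrame(
            {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.sensitivity}
        )
    else:
        df = pd.DataFrame(
            {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
        )
    df.to_csv(path, index=False)


def read_spectrum(path) -> SteadyStateSpectrum:
    df = pd.read_csv(path)
    if list(df.columns) != ["wavelength_nm", "intensity"]:
        raise ParseError(f"unexpected spectrum columns {list(df.columns)}")
    return SteadyStateSpectrum(
        wavelengths=df["wavelength_nm"].to_numpy(),
        intensities=df["intensity"].to_numpy(),
    )


def write_melting_curve(path, curve: MeltingCurve) -> None:
    pd.DataFrame(
        {"temperature_C": curve.temperatures, "absorbance_260": curve.absorbance}
    ).to_csv(path, index=False)


def read_melting_curve(path) -> MeltingCurve:
    df = pd.read_csv(path)
    if list(df.columns) != ["temperature_C", "absorbance_260"]:
        raise ParseError(f"unexpected melting columns {list(df.columns)}")
    return MeltingCurve(
        temperatures=df["temperature_C"].to_numpy(),
        absorbance=df["absorbance_260"].to_numpy(),
    )


def write_json_record(path, record: dict) -> None:
    """Serialise an analysis result (fit, R statistic, ...) as stable JSON."""
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
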