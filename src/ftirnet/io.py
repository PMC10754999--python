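"""Reading and writing spectral datasets.

Three formats are supported:

``csv_wide``
    Header row: ``sample_id, replicate_id, class_label, <w1>, <w2>, ...``
    where the remaining column names are the wavenumbers; one row per
    spectrum.
``csv_long``
    Tidy table with columns ``sample_id, replicate_id, class_label,
    wavenumber, absorbance``.
``jcampdx``
    A minimal single-spectrum JCAMP-DX dialect: ``##XUNITS``, ``##XFACTOR``,
    ``##YFACTOR``, ``##NPOINTS``, ``##FIRSTX``, ``##LASTX`` and an
    ``##XYDATA=(X++(Y..Y))`` table of space-separated values.  Anything
    fancier (compressed ASDF forms, multiple blocks) raises an
    unsupported-record error.  A path pointing at a directory is read as one
    spectrum per ``*.jdx``/``*.dx`` file.

All formats round-trip absorbance to <= 1e-9 relative error and labels
exactly.  Axes stored descending in a file are reversed to the internal
ascending convention on read.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import AxisMismatchError, DataError, SpectrumParseError
from .spectra import DEFAULT_CLASSES, SpectralDataset, Spectrum, WavenumberGrid

FORMATS = ("csv_wide", "csv_long", "jcampdx")

_META_COLS = ["sample_id", "replicate_id", "class_label"]


def read_spectra(path, format: str = "csv_wide", class_names=None) -> SpectralDataset:
    """Read a :class:`SpectralDataset`; the grid is inferred from the file axis."""
    path = Path(path)
    if format not in FORMATS:
        raise DataError(f"unknown format {format!r}; choose from {FORMATS}")
    if not path.exists():
        raise DataError(f"no such file or directory: {path}")
    if format == "csv_wide":
        return _read_csv_wide(path, class_names)
    if format == "csv_long":
        return _read_csv_long(path, class_names)
    return _read_jcampdx(path, class_names)


def write_spectra(ds: SpectralDataset, path, format: str = "csv_wide") -> None:
    """Write a dataset; inverse of :func:`read_spectra` for every format."""
    path = Path(path)
    if format not in FORMATS:
        raise DataError(f"unknown format {format!r}; choose from {FORMATS}")
    if path.parent and not path.parent.exists():
        raise DataError(f"directory does not exist: {path.parent}")
    if format == "csv_wide":
        _write_csv_wide(ds, path)
    elif format == "csv_long":
        _write_csv_long(ds, path)
    else:
        _write_jcampdx(ds, path)


# ---------------------------------------------------------------------------
# csv_wide


def _read_csv_wide(path: Path, class_names) -> SpectralDataset:
    df = pd.read_csv(path, dtype={"sample_id": str})
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise SpectrumParseError(f"{path}: missing metadata columns {missing}")
    wn_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        axis = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise SpectrumParseError(f"{path}: non-numeric wavenumber column: {exc}") from exc
    grid = WavenumberGrid.from_axis(axis) if len(axis) >= 2 else WavenumberGrid()
    values = df[wn_cols].to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        for i, row in enumerate(values):
            try:
                np.asarray(row, dtype=float)
            except (TypeError, ValueError):
                raise SpectrumParseError(f"{path}: non-numeric absorbance in data row {i}") from None
        values = values.astype(float)
    if len(axis) >= 2 and axis[0] > axis[-1]:
        values = values[:, ::-1]
    meta = df[_META_COLS].copy()
    meta["replicate_id"] = meta["replicate_id"].astype(int)
    if class_names is None:
        class_names = tuple(dict.fromkeys(meta["class_label"])) or None
    return SpectralDataset(
        grid=grid,
        absorbance=values.astype(float).reshape(len(df), -1) if len(df) else np.empty((0, grid.n_points)),
        meta=meta,
        class_names=class_names if class_names else DEFAULT_CLASSES,
    )


def _write_csv_wide(ds: SpectralDataset, path: Path) -> None:
    wn = [f"{w:g}" for w in ds.grid.wavenumbers]
    df = ds.meta[_META_COLS].copy()
    body = pd.DataFrame(ds.absorbance, columns=wn)
    pd.concat([df, body], axis=1).to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# csv_long


def _read_csv_long(path: Path, class_names) -> SpectralDataset:
    df = pd.read_csv(path, dtype={"sample_id": str})
    need = _META_COLS + ["wavenumber", "absorbance"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SpectrumParseError(f"{path}: missing columns {missing}")
    if not np.issubdtype(df["absorbance"].dtype, np.number):
        bad = df[pd.to_numeric(df["absorbance"], errors="coerce").isna()].index
        raise SpectrumParseError(f"{path}: non-numeric absorbance at row {int(bad[0])}")
    spectra: list[Spectrum] = []
    axis_ref = None
    for (sid, rid, lab), grp in df.groupby(_META_COLS, sort=False):
        grp = grp.sort_values("wavenumber")
        axis = grp["wavenumber"].to_numpy(dtype=float)
        if axis_ref is None:
            axis_ref = axis
        elif len(axis) != len(axis_ref) or not np.allclose(axis, axis_ref):
            raise AxisMismatchError(
                f"{path}: spectrum ({sid}, {rid}) axis differs from the first spectrum"
            )
        spectra.append(Spectrum(str(sid), int(rid), str(lab), grp["absorbance"].to_numpy(dtype=float)))
    if axis_ref is None:
        return SpectralDataset.from_spectra(WavenumberGrid(), [], class_names)
    grid = WavenumberGrid.from_axis(axis_ref)
    return SpectralDataset.from_spectra(grid, spectra, class_names)


def _write_csv_long(ds: SpectralDataset, path: Path) -> None:
    wn = ds.grid.wavenumbers
    frames = []
    for i in range(len(ds)):
        row = ds.meta.iloc[i]
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": row["sample_id"],
                    "replicate_id": int(row["replicate_id"]),
                    "class_label": row["class_label"],
                    "wavenumber": wn,
                    "absorbance": ds.absorbance[i],
                }
            )
        )
    cols = _META_COLS + ["wavenumber", "absorbance"]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
    out.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# jcampdx


def _read_jcampdx(path: Path, class_names) -> SpectralDataset:
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".jdx", ".dx"})
        if not files:
            raise DataError(f"{path}: no .jdx/.dx files found")
        spectra = [_parse_jcamp_file(p) for p in files]
        grids = {s[0] for s in spectra}
        if len(grids) > 1:
            raise AxisMismatchError(f"{path}: spectra use different wavenumber grids")
        grid = spectra[0][0]
        return SpectralDataset.from_spectra(grid, [s[1] for s in spectra], class_names)
    grid, spec = _parse_jcamp_file(path)
    return SpectralDataset.from_spectra(grid, [spec], class_names)


def _parse_jcamp_file(path: Path):
    header: dict[str, str] = {}
    ydata: list[float] = []
    in_table = False
    x_from_table: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                if value.replace(" ", "") != "(X++(Y..Y))":
                    raise SpectrumParseError(f"{path}:{lineno}: unsupported XYDATA form {value!r}")
                in_table = True
                continue
            if key == "END":
                in_table = False
                continue
            header[key] = value
            continue
        if in_table:
            parts = line.split()
            try:
                nums = [float(p) for p in parts]
            except ValueError:
                raise SpectrumParseError(f"{path}:{lineno}: non-numeric table entry") from None
            if not nums:
                continue
            x_from_table.append(nums[0])
            ydata.extend(nums[1:])
    if not ydata:
        raise SpectrumParseError(f"{path}: no XYDATA table found")
    try:
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
        npoints = int(float(header["NPOINTS"]))
    except KeyError as exc:
        raise SpectrumParseError(f"{path}: missing required record ##{exc.args[0]}") from None
    xfactor = float(header.get("XFACTOR", 1.0))
    yfactor = float(header.get("YFACTOR", 1.0))
    if len(ydata) != npoints:
        raise AxisMismatchError(f"{path}: NPOINTS={npoints} but table has {len(ydata)} ordinates")
    axis = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    values = np.asarray(ydata, dtype=float) * yfactor
    if axis[0] > axis[-1]:
        axis = axis[::-1]
        values = values[::-1]
    grid = WavenumberGrid.from_axis(axis)
    title = header.get("TITLE", path.stem)
    sid, _, rest = title.partition("|")
    rid, _, lab = rest.partition("|")
    spec = Spectrum(
        sample_id=sid.strip() or path.stem,
        replicate_id=int(rid) if rid.strip().isdigit() else 0,
        class_label=lab.strip() or "unknown",
        absorbance=values,
    )
    return grid, spec


def _write_jcampdx(ds: SpectralDataset, path: Path) -> None:
    if len(ds) == 1:
        _write_one_jcamp(ds, 0, path)
        return
    os.makedirs(path, exist_ok=True)
    for i in range(len(ds)):
        row = ds.meta.iloc[i]
        fname = Path(path) / f"{row['sample_id']}_r{int(row['replicate_id'])}.jdx"
        _write_one_jcamp(ds, i, fname)


def _write_one_jcamp(ds: SpectralDataset, i: int, path: Path) -> None:
    row = ds.meta.iloc[i]
    y = ds.absorbance[i]
    ymax = np.max(np.abs(y)) if len(y) else 1.0
    yfactor = ymax / 32767.0 if ymax > 0 else 1.0
    wn = ds.grid.wavenumbers
    lines = [
        f"##TITLE={row['sample_id']}|{int(row['replicate_id'])}|{row['class_label']}",
        "##JCAMP-DX=4.24",
        "##DATATYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1.0",
        f"##YFACTOR={yfactor:.12g}",
        f"##FIRSTX={wn[0]:.12g}",
        f"##LASTX={wn[-1]:.12g}",
        f"##NPOINTS={ds.grid.n_points}",
        "##XYDATA=(X++(Y..Y))",
    ]
    scaled = y / yfactor
    per_line = 6
    for start in range(0, len(y), per_line):
        chunk = scaled[start : start + per_line]
        lines.append(f"{wn[start]:.12g} " + " ".join(f"{v:.12g}" for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")
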