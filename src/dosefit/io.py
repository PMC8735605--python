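"""File formats and the packaged reference dataset.

Scan and scatter-factor files are plain CSV.  Lines starting with ``#``
before the header carry ``key: value`` metadata (energy, field size,
SSD, source, machine); the data section is comma-separated with a
header row.  Comparison reports are TSV with a footer carrying the
summary statistics.

The package ships a reference beam-commissioning dataset for a set of
flattened beams (4, 6, 10 and 18 MV), organised in four tables:

* ``table1`` — measured and modeled central-axis depth-dose columns per
  energy (46 depths, 0.1-23 cm), plus the reported percent-error column;
* ``table2`` — the fitted buildup-tail parameters (n, mu) per energy;
* ``table3`` — square-field collimator scatter factors for 6 and 10 MV
  (19 field sizes, 4-40 cm), measured and modeled columns;
* ``table4`` — an 8 x 8 collimator scatter matrix versus upper/lower
  jaw setting for a 6 MV beam.

``load_fixture`` returns these as ready-made domain objects.
"""

from __future__ import annotations

import io as _io
import json
from importlib import resources
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .fitting import ComparisonTable, round_half_away, summarize_errors
from .model import BeamModelParams, DepthDoseCurve
from .scatter import JawScMatrix, ScTable

__all__ = [
    "ParseError",
    "read_scan",
    "write_scan",
    "read_sc_table",
    "write_sc_table",
    "read_jaw_matrix",
    "write_jaw_matrix",
    "write_report",
    "write_json",
    "load_fixture",
    "fixture_names",
]

SCHEMA_VERSION = 1

_ENERGIES = ("4MV", "6MV", "10MV", "18MV")
_SC_ENERGIES = ("6MV", "10MV")


class ParseError(ValueError):
    """A scan/table file violated the dialect; the message names the line."""


def _split_metadata(text: str) -> Tuple[dict, str, int]:
    """Strip leading '# key: value' lines; return (meta, rest, header_lineno)."""
    meta = {}
    lines = text.splitlines()
    i = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
        elif line.strip():
            break
    else:
        i += 1
    return meta, "\n".join(lines[i:]), i + 1


def _meta_float(meta: dict, key: str):
    try:
        return float(meta[key])
    except (KeyError, ValueError):
        return None


def read_scan(path: Union[str, Path]) -> DepthDoseCurve:
    """Read a depth-dose scan CSV (columns ``depth_cm``, ``pdd_percent``)."""
    text = Path(path).read_text()
    meta, body, offset = _split_metadata(text)
    if not body.strip():
        raise ParseError(f"{path}: empty data section")
    try:
        df = pd.read_csv(_io.StringIO(body))
    except Exception as exc:  # noqa: BLE001 - surface as dialect error
        raise ParseError(f"{path}: cannot parse data section: {exc}") from exc
    for col in ("depth_cm", "pdd_percent"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ParseError(f"{path}: empty data section")
    depth = pd.to_numeric(df["depth_cm"], errors="coerce")
    value = pd.to_numeric(df["pdd_percent"], errors="coerce")
    for colname, col in (("depth_cm", depth), ("pdd_percent", value)):
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            raise ParseError(
                f"{path}: non-numeric {colname} at line {offset + 1 + bad[0]}"
            )
    d = depth.to_numpy(float)
    v = value.to_numpy(float)
    steps = np.diff(d)
    if np.any(steps == 0):
        line = offset + 2 + int(np.nonzero(steps == 0)[0][0])
        raise ParseError(f"{path}: duplicate depth at line {line}")
    if np.any(steps < 0):
        line = offset + 2 + int(np.nonzero(steps < 0)[0][0])
        raise ParseError(f"{path}: decreasing depth at line {line}")
    nonpos = np.nonzero((v <= 0) & (d > 0))[0]
    if nonpos.size:
        raise ParseError(
            f"{path}: non-positive dose at line {offset + 1 + int(nonpos[0])}"
        )
    return DepthDoseCurve(
        depths=d,
        values=v,
        energy=meta.get("energy", ""),
        field_size_cm=_meta_float(meta, "field_size_cm"),
        ssd_cm=_meta_float(meta, "ssd_cm") or 100.0,
        source=meta.get("source", "measured"),
        meta=meta,
    )


def _write_meta(fh, meta: dict) -> None:
    for key, val in meta.items():
        if val not in (None, ""):
            fh.write(f"# {key}: {val}\n")


def write_scan(curve: DepthDoseCurve, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        _write_meta(
            fh,
            {
                "energy": curve.energy,
                "field_size_cm": curve.field_size_cm,
                "ssd_cm": curve.ssd_cm,
                "source": curve.source,
            },
        )
        fh.write("depth_cm,pdd_percent\n")
        for d, v in zip(curve.depths, curve.values):
            fh.write(f"{d:.10g},{v:.12g}\n")


def read_sc_table(path: Union[str, Path]) -> ScTable:
    """Read a long-form S_c table CSV (columns ``field_size_cm``, ``sc``)."""
    text = Path(path).read_text()
    meta, body, _ = _split_metadata(text)
    if not body.strip():
        raise ParseError(f"{path}: empty data section")
    df = pd.read_csv(_io.StringIO(body))
    for col in ("field_size_cm", "sc"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return ScTable(
        field_sizes=df["field_size_cm"].to_numpy(float),
        sc=df["sc"].to_numpy(float),
        energy=meta.get("energy", ""),
        machine=meta.get("machine", ""),
    )


def write_sc_table(table: ScTable, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, {"energy": table.energy, "machine": table.machine})
        fh.write("field_size_cm,sc\n")
        for fs, sc in zip(table.field_sizes, table.sc):
            fh.write(f"{fs:.10g},{sc:.12g}\n")


def read_jaw_matrix(path: Union[str, Path]) -> JawScMatrix:
    """Read a jaw S_c matrix CSV.

    First header cell is ``upper_cm``; the remaining header cells are
    the lower-jaw sizes; each data row starts with the upper-jaw size.
    """
    text = Path(path).read_text()
    meta, body, _ = _split_metadata(text)
    if not body.strip():
        raise ParseError(f"{path}: empty data section")
    df = pd.read_csv(_io.StringIO(body), index_col=0)
    return JawScMatrix(
        upper_sizes=df.index.to_numpy(float),
        lower_sizes=np.array([float(c) for c in df.columns]),
        values=df.to_numpy(float),
        energy=meta.get("energy", ""),
        machine=meta.get("machine", ""),
    )


def write_jaw_matrix(matrix: JawScMatrix, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        _write_meta(fh, {"energy": matrix.energy, "machine": matrix.machine})
        fh.write("upper_cm," + ",".join(f"{l:.10g}" for l in matrix.lower_sizes) + "\n")
        for u, row in zip(matrix.upper_sizes, matrix.values):
            fh.write(f"{u:.10g}," + ",".join(f"{v:.12g}" for v in row) + "\n")


def write_report(table: ComparisonTable, path: Union[str, Path]) -> None:
    """Write a comparison report TSV with a max-error/RMSE footer."""
    max_abs, rmse = summarize_errors(table)
    with open(path, "w") as fh:
        fh.write("depth_cm\tmeasured\tmodeled\terror_pct\n")
        for d, m, mod, e in zip(
            table.depths, table.measured, table.modeled, table.pct_error
        ):
            fh.write(f"{d:.10g}\t{m:.10g}\t{mod:.10g}\t{round_half_away(e, 2):.2f}\n")
        fh.write(f"# max_abs_error_pct: {max_abs:.2f}\trmse_pct: {rmse:.4f}\n")


def write_json(obj, path: Union[str, Path]) -> None:
    """Serialise a fit result (or any object with ``to_dict``) to JSON."""
    payload = obj.to_dict() if hasattr(obj, "to_dict") else dict(obj)
    payload.setdefault("schema_version", SCHEMA_VERSION)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# --------------------------------------------------------------- fixtures


def _data_text(filename: str) -> str:
    return (resources.files("dosefit") / "data" / filename).read_text()


def _depth_dose_frame() -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(_data_text("depth_dose_reference.csv")), comment="#")


def _sc_square_frame() -> pd.DataFrame:
    return pd.read_csv(_io.StringIO(_data_text("sc_square_reference.csv")), comment="#")


def _energy_label(tag: str) -> str:
    return tag.replace("MV", " MV")


def fixture_names() -> Tuple[str, ...]:
    names = ["table2", "table4"]
    for e in _ENERGIES:
        names += [
            f"table1_{e}_measured",
            f"table1_{e}_modeled",
            f"table1_{e}_comparison",
        ]
    for e in _SC_ENERGIES:
        names += [f"table3_{e}", f"table3_{e}_modeled"]
    return tuple(sorted(names))


def load_fixture(name: str):
    """Return one member of the packaged reference dataset.

    Recognised names (see :func:`fixture_names`):

    * ``table1_<energy>_<measured|modeled>`` — a DepthDoseCurve;
    * ``table1_<energy>_comparison`` — a ComparisonTable whose
      ``pct_error`` column holds the dataset's reported error cells;
    * ``table2`` — dict of energy label -> BeamModelParams;
    * ``table3_<energy>`` (measured) / ``table3_<energy>_modeled`` — ScTable;
    * ``table4`` — the 6 MV JawScMatrix.
    """
    if name == "table2":
        df = pd.read_csv(_io.StringIO(_data_text("beam_params_reference.csv")), comment="#")
        return {
            row.energy: BeamModelParams(n=row.n, mu=row.mu)
            for row in df.itertuples()
        }
    if name == "table4":
        df = pd.read_csv(
            _io.StringIO(_data_text("sc_jaw_reference.csv")), comment="#", index_col=0
        )
        return JawScMatrix(
            upper_sizes=df.index.to_numpy(float),
            lower_sizes=np.array([float(c) for c in df.columns]),
            values=df.to_numpy(float),
            energy="6 MV",
            machine="Elekta Infinity",
        )
    parts = name.split("_")
    if parts[0] == "table1" and len(parts) == 3 and parts[1] in _ENERGIES:
        df = _depth_dose_frame()
        energy, kind = parts[1], parts[2]
        if kind in ("measured", "modeled"):
            return DepthDoseCurve(
                depths=df["depth_cm"].to_numpy(float),
                values=df[f"{energy}_{kind}"].to_numpy(float),
                energy=_energy_label(energy),
                field_size_cm=10.0,
                source=kind,
            )
        if kind == "comparison":
            return ComparisonTable(
                depths=df["depth_cm"].to_numpy(float),
                measured=df[f"{energy}_measured"].to_numpy(float),
                modeled=df[f"{energy}_modeled"].to_numpy(float),
                pct_error=df[f"{energy}_error"].to_numpy(float),
            )
    if parts[0] == "table3" and parts[1] in _SC_ENERGIES:
        df = _sc_square_frame()
        kind = "modeled" if name.endswith("_modeled") else "measured"
        return ScTable(
            field_sizes=df["field_size_cm"].to_numpy(float),
            sc=df[f"{parts[1]}_{kind}"].to_numpy(float),
            energy=_energy_label(parts[1]),
            machine="Varian TrueBeam",
        )
    raise KeyError(
        f"unknown fixture {name!r}; valid names: {', '.join(fixture_names())}"
    )
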