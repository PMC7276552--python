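"""Readers and writers for the package's delimited-text artefacts.

All formats are TSV with ``#``-prefixed ``key: value`` metadata lines, so
every artefact is diffable and round-trips losslessly up to float
formatting.  Missing values (e.g. the goniometer blind region) are written
as ``NA``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .types import AngleResolvedMap, FormatError, ParticleEnsemble, SpecularTrace

__all__ = [
    "read_angle_map",
    "write_angle_map",
    "read_particles",
    "write_particles",
    "read_specular_trace",
    "write_specular_trace",
    "write_spectrum",
    "read_spectrum",
    "write_report",
    "read_report",
    "config_hash",
    "load_config",
    "dump_config",
]

_NA = "NA"


def _read_meta_and_body(path: str | Path) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
        else:
            body.append(line)
    return meta, body


def _fmt(x: float) -> str:
    if np.isnan(x):
        return _NA
    return format(float(x), ".10g")


def read_angle_map(path: str | Path) -> AngleResolvedMap:
    """Read an angle-resolved map.

    Layout: metadata lines (``# theta_in: ...``, ``# blind_halfwidth: ...``),
    a header row of wavelengths (nm), then one row per theta_out with the
    angle in the first column.  Cells are reals or ``NA``.
    """
    meta, body = _read_meta_and_body(path)
    if "theta_in" not in meta:
        raise FormatError(f"{path}: missing '# theta_in:' metadata line")
    if not body:
        raise FormatError(f"{path}: no data rows")
    header = body[0].split("\t")
    try:
        wavelength = np.array([float(w) for w in header[1:]])
    except ValueError as exc:
        raise FormatError(f"{path}: wavelength header is not numeric") from exc
    theta_out = []
    rows = []
    for line in body[1:]:
        cells = line.split("\t")
        if len(cells) != wavelength.size + 1:
            raise FormatError(f"{path}: row has {len(cells) - 1} cells, expected {wavelength.size}")
        theta_out.append(float(cells[0]))
        rows.append([np.nan if c == _NA else float(c) for c in cells[1:]])
    return AngleResolvedMap(
        theta_in=float(meta["theta_in"]),
        theta_out=np.array(theta_out),
        wavelength=wavelength,
        intensity=np.array(rows),
        blind_halfwidth=float(meta.get("blind_halfwidth", 5.0)),
    )


def write_angle_map(amap: AngleResolvedMap, path: str | Path, extra_meta: dict | None = None) -> None:
    lines = [f"# theta_in: {_fmt(amap.theta_in)}", f"# blind_halfwidth: {_fmt(amap.blind_halfwidth)}"]
    for k, v in (extra_meta or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("theta_out\\lambda\t" + "\t".join(_fmt(w) for w in amap.wavelength))
    for th, row in zip(amap.theta_out, amap.intensity):
        lines.append(_fmt(th) + "\t" + "\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_particles(path: str | Path) -> ParticleEnsemble:
    """Read a hard-disk ensemble (columns x_nm, y_nm; radius/box metadata)."""
    meta, body = _read_meta_and_body(path)
    for key in ("radius_nm", "box_nm"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}:' metadata line")
    box = tuple(float(v) for v in meta["box_nm"].split())
    if len(box) != 2:
        raise FormatError(f"{path}: box_nm must hold two values")
    if body and body[0].startswith("x_nm"):
        body = body[1:]
    pos = np.array([[float(c) for c in line.split("\t")] for line in body]) if body else np.empty((0, 2))
    return ParticleEnsemble(
        positions=pos,
        radius=float(meta["radius_nm"]),
        box=box,  # type: ignore[arg-type]
        periodic_y=meta.get("periodic_y", "false").lower() in ("true", "1", "yes"),
    )


def write_particles(ens: ParticleEnsemble, path: str | Path, extra_meta: dict | None = None) -> None:
    lines = [
        f"# radius_nm: {_fmt(ens.radius)}",
        f"# box_nm: {_fmt(ens.box[0])} {_fmt(ens.box[1])}",
        f"# periodic_y: {str(ens.periodic_y).lower()}",
    ]
    for k, v in (extra_meta or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append("x_nm\ty_nm")
    for x, y in ens.positions:
        lines.append(f"{_fmt(x)}\t{_fmt(y)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_specular_trace(path: str | Path) -> SpecularTrace:
    meta, body = _read_meta_and_body(path)
    if body and body[0].startswith("theta_in"):
        body = body[1:]
    data = np.array([[float(c) if c != _NA else np.nan for c in line.split("\t")] for line in body])
    inten = data[:, 2] if data.shape[1] > 2 else None
    return SpecularTrace(theta_in=data[:, 0], lambda_s=data[:, 1], intensity=inten)


def write_specular_trace(trace: SpecularTrace, path: str | Path) -> None:
    lines = ["theta_in\tlambda_s\tintensity"]
    for th, lam, inten in zip(trace.theta_in, trace.lambda_s, trace.intensity):
        lines.append(f"{_fmt(th)}\t{_fmt(lam)}\t{_fmt(inten)}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_spectrum(path: str | Path, wavelength: np.ndarray, columns: dict[str, np.ndarray],
                   meta: dict | None = None) -> None:
    """Write a wavelength-indexed spectrum table (R, T, ... columns)."""
    lines = [f"# {k}: {v}" for k, v in (meta or {}).items()]
    names = list(columns)
    lines.append("wavelength_nm\t" + "\t".join(names))
    for i, w in enumerate(wavelength):
        lines.append(_fmt(w) + "\t" + "\t".join(_fmt(columns[n][i]) for n in names))
    Path(path).write_text("\n".join(lines) + "\n")


def read_spectrum(path: str | Path) -> dict[str, np.ndarray]:
    meta, body = _read_meta_and_body(path)
    names = body[0].split("\t")
    data = np.array([[float(c) if c != _NA else np.nan for c in line.split("\t")] for line in body[1:]])
    out = {n: data[:, i] for i, n in enumerate(names)}
    out["_meta"] = meta  # type: ignore[assignment]
    return out


def write_report(obj: dict[str, Any], path: str | Path) -> None:
    """JSON report with numpy scalars/arrays coerced to plain Python."""

    def default(o: Any) -> Any:
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def read_report(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def config_hash(config: dict) -> str:
    """Stable short hash of a config mapping, embedded in every output."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def dump_config(config: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
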