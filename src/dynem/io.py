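"""Plain-text I/O: TSV matrices and run manifests.

All on-disk formats are tab-separated with '.' decimals and LF line
endings.  Floats are written with 12 significant digits so that
write-then-read round trips are exact to well below 1e-12 and two runs
with identical seeds produce byte-identical files.

Formats
-------
network:        rows = metabolites, columns = reactions, final row
                ``#reversible`` of 0/1 flags.
modes:          rows = reactions (first column ``reaction_id``),
                one column per elementary mode, header = mode ids.
flux:           first column ``time_s``, one column per reaction.
concentration:  first column ``time_s``, one column per metabolite.
labels:         ``experiment_id`` and ``class`` columns.
coefficients:   long format ``em  time_s  reaction  alpha``.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynema import DynEMACoefficients, FluxTimeSeries
from .fluxestim import ConcentrationTimeSeries
from .network import ElementaryModeMatrix, MetabolicNetwork

_FMT = "%.12g"


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _fmt(x: float) -> str:
    return _FMT % x


def _read_tsv_lines(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text()
    return [line.split("\t") for line in text.splitlines() if line.strip() != ""]


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def write_network(net: MetabolicNetwork, path: str | Path) -> None:
    lines = ["\t".join(("",) + net.reaction_ids)]
    for m, mid in enumerate(net.metabolite_ids):
        lines.append("\t".join([mid] + [_fmt(v) for v in net.stoich[m]]))
    lines.append("\t".join(["#reversible"] + [str(int(r)) for r in net.reversible]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_network(path: str | Path) -> MetabolicNetwork:
    """Read a network TSV; raises :class:`ParseError` on ragged rows."""
    path = Path(path)
    rows = _read_tsv_lines(path)
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one metabolite row")
    header = rows[0]
    reaction_ids = tuple(h.strip() for h in header[1:])
    width = len(header)
    met_ids: list[str] = []
    stoich: list[list[float]] = []
    reversible = np.zeros(len(reaction_ids), dtype=bool)
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(f"{path}: line {i} has {len(row)} fields, expected {width}")
        if row[0].strip() == "#reversible":
            try:
                reversible = np.array([bool(int(v)) for v in row[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {i}: bad reversibility flag ({exc})") from exc
            continue
        met_ids.append(row[0].strip())
        try:
            stoich.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-numeric coefficient ({exc})") from exc
    return MetabolicNetwork(np.array(stoich), reaction_ids, tuple(met_ids), reversible)


# ---------------------------------------------------------------------------
# elementary modes
# ---------------------------------------------------------------------------

def write_modes(
    ems: ElementaryModeMatrix, path: str | Path, reaction_ids: tuple[str, ...] | None = None
) -> None:
    rids = reaction_ids or tuple(f"r{k + 1}" for k in range(ems.n_reactions))
    lines = ["\t".join(("reaction_id",) + ems.em_ids)]
    for k, rid in enumerate(rids):
        lines.append("\t".join([rid] + [_fmt(v) for v in ems.modes[k]]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_modes(path: str | Path) -> ElementaryModeMatrix:
    path = Path(path)
    rows = _read_tsv_lines(path)
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one reaction row")
    em_ids = tuple(h.strip() for h in rows[0][1:])
    width = len(rows[0])
    vals: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(f"{path}: line {i} has {len(row)} fields, expected {width}")
        try:
            vals.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-numeric mode entry ({exc})") from exc
    return ElementaryModeMatrix(np.array(vals), em_ids)


# ---------------------------------------------------------------------------
# time series
# ---------------------------------------------------------------------------

def _write_timeseries(values: np.ndarray, time_s: np.ndarray, cols: tuple[str, ...], path: Path) -> None:
    lines = ["\t".join(("time_s",) + cols)]
    for j in range(values.shape[0]):
        lines.append("\t".join([_fmt(time_s[j])] + [_fmt(v) for v in values[j]]))
    path.write_text("\n".join(lines) + "\n")


def _read_timeseries(path: Path) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    rows = _read_tsv_lines(path)
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one data row")
    cols = tuple(h.strip() for h in rows[0][1:])
    width = len(rows[0])
    times: list[float] = []
    vals: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise ParseError(f"{path}: line {i} has {len(row)} fields, expected {width}")
        try:
            times.append(float(row[0]))
            vals.append([float(v) for v in row[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-numeric value ({exc})") from exc
    return np.array(vals), np.array(times), cols


def write_fluxes(fts: FluxTimeSeries, path: str | Path, reaction_ids: tuple[str, ...] | None = None) -> None:
    rids = reaction_ids or tuple(f"r{k + 1}" for k in range(fts.n_reactions))
    _write_timeseries(fts.fluxes, fts.time_s, rids, Path(path))


def load_fluxes(path: str | Path) -> FluxTimeSeries:
    path = Path(path)
    vals, times, _ = _read_timeseries(path)
    return FluxTimeSeries(vals, times, path.stem)


def write_concentrations(
    cts: ConcentrationTimeSeries, path: str | Path, metabolite_ids: tuple[str, ...] | None = None
) -> None:
    mids = metabolite_ids or tuple(f"m{k + 1}" for k in range(cts.n_metabolites))
    _write_timeseries(cts.conc, cts.time_s, mids, Path(path))


def load_concentrations(path: str | Path) -> ConcentrationTimeSeries:
    path = Path(path)
    vals, times, _ = _read_timeseries(path)
    return ConcentrationTimeSeries(vals, times, path.stem)


# ---------------------------------------------------------------------------
# labels and coefficients
# ---------------------------------------------------------------------------

def write_labels(ids: tuple[str, ...], y: np.ndarray, path: str | Path) -> None:
    lines = ["experiment_id\tclass"]
    for eid, cls in zip(ids, np.asarray(y).ravel()):
        lines.append(f"{eid}\t{int(cls)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_labels(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    path = Path(path)
    rows = _read_tsv_lines(path)
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header row and at least one label row")
    ids: list[str] = []
    ys: list[int] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != 2:
            raise ParseError(f"{path}: line {i} has {len(row)} fields, expected 2")
        ids.append(row[0].strip())
        try:
            ys.append(int(row[1]))
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-integer class ({exc})") from exc
    return tuple(ids), np.array(ys)


def write_coefficients(
    coeffs: DynEMACoefficients,
    time_s: np.ndarray,
    path: str | Path,
    em_ids: tuple[str, ...] | None = None,
    reaction_ids: tuple[str, ...] | None = None,
) -> None:
    """Long-format coefficient table: em, time_s, reaction, alpha."""
    E, J, K = coeffs.alpha.shape
    eids = em_ids or tuple(f"EM{e + 1}" for e in range(E))
    rids = reaction_ids or tuple(f"r{k + 1}" for k in range(K))
    lines = ["em\ttime_s\treaction\talpha"]
    for e in range(E):
        for j in range(J):
            for k in range(K):
                lines.append(
                    f"{eids[e]}\t{_fmt(time_s[j])}\t{rids[k]}\t{_fmt(coeffs.alpha[e, j, k])}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def load_coefficients(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    params: dict,
    seed: int | None,
    inputs: dict[str, str | Path],
) -> Path:
    """Record command, parameter snapshot, seed and input hashes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "params": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
        "seed": seed,
        "inputs": {name: file_sha256(p) for name, p in inputs.items()},
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
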