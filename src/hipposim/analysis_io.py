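"""Population statistics, growth-curve/arrest analyses, and file I/O.

Per-step summaries record the population size, the max/mean/min of nuclear
(X2) and phosphorylated (X3) YAP/TAZ over cells, and the per-colour counts.
Snapshots and time series are written as plain delimiter-separated tables
with a versioned schema header (diff-able, viewer-friendly); snapshots can
additionally be exported as extended-XYZ for standard 3D structure viewers.
All statistics functions are pure: populations are never mutated.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .model_core import COLOR_NAMES, Population

SNAPSHOT_SCHEMA = "hipposim-snapshot v1"
TIMESERIES_SCHEMA = "hipposim-timeseries v1"

_SNAPSHOT_COLUMNS = (
    "id", "t", "x", "y", "z", "vx", "vy", "vz",
    "sigma", "radius", "age", "color", "X1", "X2", "X3", "rho",
)


class SchemaError(ValueError):
    """File header does not carry the expected schema version."""


@dataclass(frozen=True)
class TrajectoryRecord:
    """Per-step population summary."""

    t: float  # simulated time (s)
    N: int  # cell count
    X2_max: float
    X2_mean: float
    X2_min: float
    X3_max: float
    X3_mean: float
    X3_min: float
    counts_by_color: tuple[int, int, int, int]  # cyan, orange, blue, red


def concentration_stats(pop: Population, l: int) -> tuple[float, float, float]:
    """(max, mean, min) of species ``l`` (1, 2 or 3) over all cells."""
    if pop.N == 0:
        raise ValueError("population is empty")
    if l not in (1, 2, 3):
        raise ValueError("species index l must be 1, 2 or 3")
    col = pop.X[:, l - 1]
    return float(col.max()), float(col.mean()), float(col.min())


def color_counts(pop: Population) -> tuple[int, int, int, int]:
    counts = np.bincount(pop.color, minlength=4)
    return tuple(int(c) for c in counts[:4])


def make_record(pop: Population) -> TrajectoryRecord:
    """Summarise a population into a :class:`TrajectoryRecord`."""
    x2 = concentration_stats(pop, 2)
    x3 = concentration_stats(pop, 3)
    return TrajectoryRecord(
        t=pop.t, N=pop.N,
        X2_max=x2[0], X2_mean=x2[1], X2_min=x2[2],
        X3_max=x3[0], X3_mean=x3[1], X3_min=x3[2],
        counts_by_color=color_counts(pop),
    )


def arrest_fraction(pop: Population) -> float:
    """Fraction of cells in the arrest colours (cyan or blue)."""
    c = color_counts(pop)
    return (c[0] + c[2]) / pop.N if pop.N else 0.0


def first_crossing_time(
    series: Sequence[tuple[float, float]],
    threshold: float,
    direction: str,
) -> Optional[float]:
    """Earliest time at which the series is strictly below/above ``threshold``.

    ``series`` is an iterable of (t, value) sorted by t; returns ``None``
    if the threshold is never crossed in the stated direction.
    """
    pts = list(series)
    if not pts:
        raise ValueError("empty series")
    if direction not in ("below", "above"):
        raise ValueError("direction must be 'below' or 'above'")
    for t, value in pts:
        if (direction == "below" and value < threshold) or (
            direction == "above" and value > threshold
        ):
            return t
    return None


def _series(records: Sequence[TrajectoryRecord], attr: str):
    t = np.array([rec.t for rec in records])
    y = np.array([getattr(rec, attr) for rec in records], dtype=np.float64)
    return t, y


def cn_ratio(
    normal: Sequence[TrajectoryRecord],
    cancer: Sequence[TrajectoryRecord],
) -> list[tuple[float, float]]:
    """Cancer/normal ratio of mean nuclear YAP/TAZ over time.

    With the preset initial concentrations the ratio starts at exactly 2 and
    its persistence quantifies how faithfully the twofold YAP/TAZ excess is
    maintained as both tissues grow.  Series on different time grids are
    linearly interpolated onto the union grid of their overlap; points with
    a zero denominator are excluded with a warning.
    """
    tn, yn = _series(normal, "X2_mean")
    tc, yc = _series(cancer, "X2_mean")
    if len(tn) == len(tc) and np.array_equal(tn, tc):
        grid = tn
    else:
        lo, hi = max(tn.min(), tc.min()), min(tn.max(), tc.max())
        grid = np.union1d(tn, tc)
        grid = grid[(grid >= lo) & (grid <= hi)]
        yn = np.interp(grid, tn, yn)
        yc = np.interp(grid, tc, yc)
    out: list[tuple[float, float]] = []
    for t, num, den in zip(grid, yc, yn):
        if den == 0.0:
            warnings.warn(f"cn_ratio: zero normal-tissue mean X2 at t={t}; point excluded")
            continue
        out.append((float(t), float(num / den)))
    return out


def growth_curve(records: Sequence[TrajectoryRecord]) -> list[tuple[float, int]]:
    """(t, N) extracted from a record list."""
    return [(rec.t, rec.N) for rec in records]


def reference_curve(t, T_CC: float):
    """Uncoupled doubling law ``N(t) = 2^(1 + floor(t/T_CC))`` from two cells.

    Matches a density-uncoupled run at every snapshot and serves as the
    exponential reference against which suppressed growth is judged.
    """
    t = np.asarray(t, dtype=np.float64)
    n = 2.0 ** (1.0 + np.floor(t / T_CC))
    return n if n.ndim else float(n)


# -- snapshot I/O ---------------------------------------------------------


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def write_snapshot(pop: Population, path) -> None:
    """Write a per-cell table (one row per cell) with a versioned header.

    Values are serialised round-trip safe; ``read_snapshot`` restores the
    population field-for-field.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# {SNAPSHOT_SCHEMA} t={_fmt(pop.t)} k={pop.k} zeta={_fmt(pop.zeta)} "
                 f"next_id={pop._next_id}\n")
        w = csv.writer(fh)
        w.writerow(_SNAPSHOT_COLUMNS)
        radius = pop.radius
        for i in range(pop.N):
            w.writerow(
                [int(pop.ids[i]), _fmt(pop.t)]
                + [_fmt(v) for v in pop.r[i]]
                + [_fmt(v) for v in pop.v[i]]
                + [_fmt(pop.sigma[i]), _fmt(radius[i]), _fmt(pop.age[i])]
                + [int(pop.color[i])]
                + [_fmt(v) for v in pop.X[i]]
                + [_fmt(pop.rho[i])]
            )


def _check_schema(line: str, expected: str, path) -> dict:
    if not line.startswith("# ") or expected not in line:
        found = line.strip()
        raise SchemaError(
            f"{path}: expected schema header '# {expected} ...', found {found!r}"
        )
    meta = {}
    for token in line[2:].split():
        if "=" in token:
            key, val = token.split("=", 1)
            meta[key] = val
    return meta


def read_snapshot(path) -> Population:
    """Read a snapshot table back into a :class:`Population`."""
    path = Path(path)
    with path.open() as fh:
        meta = _check_schema(fh.readline(), SNAPSHOT_SCHEMA, path)
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != _SNAPSHOT_COLUMNS:
            raise SchemaError(f"{path}: unexpected column header {header}")
        rows = []
        for lineno, row in enumerate(reader, start=3):
            if not row:
                continue
            if len(row) != len(_SNAPSHOT_COLUMNS):
                raise SchemaError(f"{path}:{lineno}: expected "
                                  f"{len(_SNAPSHOT_COLUMNS)} fields, got {len(row)}")
            try:
                rows.append([float(x) for x in row])
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    pop = Population(zeta=float(meta["zeta"]))
    pop.t = float(meta["t"])
    pop.k = int(meta["k"])
    if rows:
        arr = np.array(rows)
        pop.ids = arr[:, 0].astype(np.int64)
        pop.r = arr[:, 2:5].copy()
        pop.v = arr[:, 5:8].copy()
        pop.sigma = arr[:, 8].copy()
        pop.age = arr[:, 10].copy()
        pop.color = arr[:, 11].astype(np.int64)
        pop.X = arr[:, 12:15].copy()
        pop.rho = arr[:, 15].copy()
    pop._next_id = int(meta.get("next_id", (pop.ids.max() + 1) if len(rows) else 0))
    return pop


def write_extxyz(pop: Population, path) -> None:
    """Extended-XYZ export for 3D viewers.

    First line: cell count.  Species column carries the phase/arrest colour
    name; auxiliary per-cell columns are the radius and nuclear YAP/TAZ.
    """
    path = Path(path)
    radius = pop.radius
    with path.open("w") as fh:
        fh.write(f"{pop.N}\n")
        fh.write(
            'Properties=species:S:1:pos:R:3:radius:R:1:x2:R:1 '
            f'Time={_fmt(pop.t)}\n'
        )
        for i in range(pop.N):
            name = COLOR_NAMES[int(pop.color[i])]
            x, y, z = pop.r[i]
            fh.write(f"{name} {_fmt(x)} {_fmt(y)} {_fmt(z)} "
                     f"{_fmt(radius[i])} {_fmt(pop.X[i, 1])}\n")


# -- time-series I/O ------------------------------------------------------

_TS_COLUMNS = ("t", "N", "X2_max", "X2_mean", "X2_min",
               "X3_max", "X3_mean", "X3_min",
               "n_cyan", "n_orange", "n_blue", "n_red")


def write_timeseries(records: Iterable[TrajectoryRecord], path) -> None:
    """Write per-step summaries as a versioned delimiter-separated table."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# {TIMESERIES_SCHEMA}\n")
        w = csv.writer(fh)
        w.writerow(_TS_COLUMNS)
        for rec in records:
            w.writerow(
                [_fmt(rec.t), rec.N]
                + [_fmt(getattr(rec, f.name)) for f in fields(TrajectoryRecord)
                   if f.name.startswith("X")]
                + list(rec.counts_by_color)
            )


def read_timeseries(path) -> list[TrajectoryRecord]:
    """Read a time-series table written by :func:`write_timeseries`."""
    path = Path(path)
    out: list[TrajectoryRecord] = []
    with path.open() as fh:
        _check_schema(fh.readline(), TIMESERIES_SCHEMA, path)
        reader = csv.reader(fh)
        header = next(reader)
        if tuple(header) != _TS_COLUMNS:
            raise SchemaError(f"{path}: unexpected column header {header}")
        for lineno, row in enumerate(reader, start=3):
            if not row:
                continue
            try:
                out.append(TrajectoryRecord(
                    t=float(row[0]), N=int(row[1]),
                    X2_max=float(row[2]), X2_mean=float(row[3]), X2_min=float(row[4]),
                    X3_max=float(row[5]), X3_mean=float(row[6]), X3_min=float(row[7]),
                    counts_by_color=tuple(int(x) for x in row[8:12]),
                ))
            except (ValueError, IndexError) as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    return out
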