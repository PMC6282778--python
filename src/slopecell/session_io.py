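"""Session data model and plain-text on-disk format.

A session directory holds:

* ``positions.tsv`` — columns ``t_s, x_cm, y_cm`` (uniform camera rate),
* ``spikes.tsv``    — columns ``unit_id, t_s`` (sorted within unit),
* ``lfp.tsv``       — columns ``t_s, uv`` (optional, uniform rate),
* ``session.yaml``  — geometry, sampling rates, and the schedule of
  condition blocks (tilt, elevated end, start/end time).

Everything is delimited text so sessions can be inspected and produced
from any language.  Numeric fields round-trip to better than 1e-9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .geometry import NORTH, SOUTH, TrackGeometry

__all__ = [
    "ConditionBlock",
    "Session",
    "SessionFormatError",
    "SessionValidationError",
    "load_session",
    "write_session",
    "write_report",
]

_FLOAT_FMT = "%.9f"


class SessionFormatError(Exception):
    """A mandatory file is missing or malformed."""


class SessionValidationError(Exception):
    """Session content violates an invariant (names the offending series)."""


@dataclass(frozen=True)
class ConditionBlock:
    """One contiguous run of a single tilt condition.

    ``elevated_end`` is recorded for 0-degree blocks too: it carries the
    session's direction convention so "uphill"/"downhill" labels on the
    flat copy the tilted blocks of the same session.
    """

    block_id: int
    tilt: int
    elevated_end: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.elevated_end not in (NORTH, SOUTH):
            raise ValueError(f"elevated_end must be north/south, got {self.elevated_end!r}")
        if not self.t_end > self.t_start:
            raise ValueError(f"block {self.block_id}: t_end must exceed t_start")


@dataclass
class Lfp:
    t: np.ndarray
    uv: np.ndarray
    fs_hz: float


@dataclass
class Session:
    """In-memory session: positions, spike trains, LFP, and schedule."""

    positions_t: np.ndarray
    positions_x: np.ndarray
    positions_y: np.ndarray
    spike_trains: dict[str, np.ndarray]
    schedule: list[ConditionBlock]
    geometry: TrackGeometry = field(default_factory=TrackGeometry)
    lfp: Lfp | None = None
    position_fs_hz: float = 50.0

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.positions_t[0]), float(self.positions_t[-1])

    def validate(self) -> None:
        _check_monotone(self.positions_t, "positions")
        x, y = self.positions_x, self.positions_y
        g = self.geometry
        bad = np.flatnonzero((x < 0) | (x > g.long_axis_cm) | (y < 0) | (y > g.short_axis_cm))
        if bad.size:
            raise SessionValidationError(
                f"positions: coordinates outside the {g.long_axis_cm} x "
                f"{g.short_axis_cm} cm track at row {bad[0]}"
            )
        t0, t1 = self.t_span
        for unit, st in self.spike_trains.items():
            _check_monotone(st, f"spikes[{unit}]")
            if st.size and (st[0] < t0 - 1e-9 or st[-1] > t1 + 1e-9):
                raise SessionValidationError(
                    f"spikes[{unit}]: spike time outside the session span [{t0}, {t1}]"
                )
        if self.lfp is not None:
            _check_monotone(self.lfp.t, "lfp")
        blocks = sorted(self.schedule, key=lambda b: b.t_start)
        for a, b in zip(blocks, blocks[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise SessionValidationError(
                    f"schedule: blocks {a.block_id} and {b.block_id} overlap"
                )


def _check_monotone(t: np.ndarray, name: str) -> None:
    if t.size < 2:
        return
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise SessionValidationError(
            f"{name}: timestamps not strictly increasing at row {bad[0] + 1} "
            f"(t={t[bad[0] + 1]!r})"
        )


# ---------------------------------------------------------------------------
# on-disk format


def write_session(session: Session, path: str | Path) -> None:
    """Write a validated session to a directory of TSV files + session.yaml."""
    session.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "t_s": session.positions_t,
            "x_cm": session.positions_x,
            "y_cm": session.positions_y,
        }
    ).to_csv(path / "positions.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)

    rows = [
        (unit, t)
        for unit in sorted(session.spike_trains)
        for t in session.spike_trains[unit]
    ]
    pd.DataFrame(rows, columns=["unit_id", "t_s"]).to_csv(
        path / "spikes.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )

    if session.lfp is not None:
        pd.DataFrame({"t_s": session.lfp.t, "uv": session.lfp.uv}).to_csv(
            path / "lfp.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )

    g = session.geometry
    config = {
        "geometry": {
            "long_axis_cm": g.long_axis_cm,
            "short_axis_cm": g.short_axis_cm,
            "roi_long_cm": g.roi_long_cm,
            "endzone_south_cm": g.endzone_south_cm,
            "endzone_north_cm": g.endzone_north_cm,
            "bin_side_cm": g.bin_side_cm,
            "pivot_end": g.pivot_end,
        },
        "position_fs_hz": session.position_fs_hz,
        "lfp_fs_hz": None if session.lfp is None else session.lfp.fs_hz,
        "units": sorted(session.spike_trains),
        "schedule": [
            {
                "block_id": b.block_id,
                "tilt_deg": b.tilt,
                "elevated_end": b.elevated_end,
                "t_start_s": float(b.t_start),
                "t_end_s": float(b.t_end),
            }
            for b in session.schedule
        ],
    }
    (path / "session.yaml").write_text(yaml.safe_dump(config, sort_keys=False))


def load_session(path: str | Path) -> Session:
    """Load and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    cfg_path = path / "session.yaml"
    if not cfg_path.exists():
        raise SessionFormatError(f"missing session.yaml in {path}")
    config = yaml.safe_load(cfg_path.read_text())
    gcfg = config.get("geometry", {})
    geometry = TrackGeometry(
        long_axis_cm=gcfg.get("long_axis_cm", 120.0),
        short_axis_cm=gcfg.get("short_axis_cm", 24.0),
        roi_long_cm=gcfg.get("roi_long_cm", 103.0),
        endzone_south_cm=gcfg.get("endzone_south_cm", 8.5),
        endzone_north_cm=gcfg.get("endzone_north_cm", 8.5),
        bin_side_cm=gcfg.get("bin_side_cm", 2.5),
        pivot_end=gcfg.get("pivot_end", SOUTH),
    )

    for fname in ("positions.tsv", "spikes.tsv"):
        if not (path / fname).exists():
            raise SessionFormatError(f"missing mandatory file {fname} in {path}")

    pos = pd.read_csv(path / "positions.tsv", sep="\t")
    spikes = pd.read_csv(path / "spikes.tsv", sep="\t", dtype={"unit_id": str})
    spike_trains: dict[str, np.ndarray] = {
        unit: grp["t_s"].to_numpy(float) for unit, grp in spikes.groupby("unit_id")
    }
    # units listed in the config but silent in spikes.tsv get empty trains
    for unit in config.get("units", []) or []:
        spike_trains.setdefault(str(unit), np.empty(0))

    lfp = None
    if (path / "lfp.tsv").exists():
        lf = pd.read_csv(path / "lfp.tsv", sep="\t")
        lfp = Lfp(
            t=lf["t_s"].to_numpy(float),
            uv=lf["uv"].to_numpy(float),
            fs_hz=float(config.get("lfp_fs_hz") or 250.0),
        )

    schedule = [
        ConditionBlock(
            block_id=int(b["block_id"]),
            tilt=int(b["tilt_deg"]),
            elevated_end=str(b["elevated_end"]),
            t_start=float(b["t_start_s"]),
            t_end=float(b["t_end_s"]),
        )
        for b in config.get("schedule", [])
    ]

    session = Session(
        positions_t=pos["t_s"].to_numpy(float),
        positions_x=pos["x_cm"].to_numpy(float),
        positions_y=pos["y_cm"].to_numpy(float),
        spike_trains=spike_trains,
        schedule=schedule,
        geometry=geometry,
        lfp=lfp,
        position_fs_hz=float(config.get("position_fs_hz", 50.0)),
    )
    session.validate()
    return session


def write_report(
    tables: Mapping[str, pd.DataFrame],
    path: str | Path,
    summary: Mapping | None = None,
) -> None:
    """Write analysis tables as TSV plus a machine-readable summary.json.

    Reruns on identical inputs produce byte-identical files: floats are
    fixed-format and key order is preserved.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(path / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    if summary is not None:
        (path / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n"
        )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
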