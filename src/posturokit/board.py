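"""Balance-board recordings and center-of-pressure (CoP) extraction.

A four-corner strain-gauge board (Wii-Balance-Board class hardware) reports
one value per corner per sample: front-left (FL), front-right (FR),
posterior-left (PL) and posterior-right (PR), in uncalibrated board units.
The CoP displacement along each axis is a signed corner contrast:

    CPap = (FR + PR) - (FL + PL)
    CPml = (FL + FR) - (PL + PR)

Note these formulas, kept literal here, put the right-minus-left contrast
on the "ap" output and the front-minus-back contrast on "ml" — the reverse
of the anatomical convention.  ``axis_convention="anatomical"`` swaps the
two outputs for users who want front-back sway on the AP channel.

Consumer boards emit samples with inconsistent inter-sample intervals, so
raw channels are regularised by linear interpolation onto a uniform grid
anchored at the first timestamp before any parameter is computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDataError,
    ParameterError,
    ParseError,
    SchemaError,
    ValidationError,
)

AxisConvention = Literal["paper", "anatomical"]
Normalize = Literal["none", "total_load"]

BOARD_CSV_COLUMNS = ("t", "fl", "fr", "pl", "pr")

# Floating-point guard when counting grid points: a span that is a whole
# number of periods up to rounding must include its final grid point.
_GRID_EPS = 1e-9


@dataclass
class BoardRecording:
    """Raw per-sample board output: timestamps + four corner channels.

    Parameters
    ----------
    timestamps : array of float
        Sample times in seconds, strictly increasing, length >= 2.
    fl, fr, pl, pr : arrays of float
        Corner sensor values in board units, one per timestamp.
    board_id : str
        Free-text device identifier.
    nominal_rate : float
        The board's advertised rate in Hz (default 20); actual intervals
        may be irregular.
    """

    timestamps: np.ndarray
    fl: np.ndarray
    fr: np.ndarray
    pl: np.ndarray
    pr: np.ndarray
    board_id: str = ""
    nominal_rate: float = 20.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        for name in ("fl", "fr", "pl", "pr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.timestamps.shape:
                raise ValidationError(
                    f"channel {name!r} has length {arr.size}, "
                    f"expected {self.timestamps.size}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"channel {name!r} contains non-finite values")
        if self.timestamps.ndim != 1 or self.timestamps.size < 2:
            raise ValidationError("recording needs at least 2 samples")
        if not np.all(np.isfinite(self.timestamps)):
            raise ValidationError("timestamps contain non-finite values")
        if not np.all(np.diff(self.timestamps) > 0):
            bad = int(np.flatnonzero(np.diff(self.timestamps) <= 0)[0]) + 1
            raise ValidationError(
                f"timestamps must be strictly increasing (violation at sample {bad})"
            )

    @property
    def n(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass
class CoPTrajectory:
    """Regularly sampled CoP displacement series.

    ``cp_ap`` and ``cp_ml`` are in board units on a uniform grid at ``rate``
    Hz.  ``duration`` is ``n / rate`` seconds.
    """

    rate: float
    cp_ap: np.ndarray
    cp_ml: np.ndarray

    def __post_init__(self) -> None:
        self.cp_ap = np.asarray(self.cp_ap, dtype=float)
        self.cp_ml = np.asarray(self.cp_ml, dtype=float)
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if self.cp_ap.shape != self.cp_ml.shape or self.cp_ap.ndim != 1:
            raise ValidationError("cp_ap and cp_ml must be 1-D arrays of equal length")
        if self.cp_ap.size < 2:
            raise ValidationError("trajectory needs at least 2 samples")
        if not (np.all(np.isfinite(self.cp_ap)) and np.all(np.isfinite(self.cp_ml))):
            raise ValidationError("trajectory contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.cp_ap.size)

    @property
    def duration(self) -> float:
        return self.n / self.rate

    def times(self) -> np.ndarray:
        """Grid times in seconds, starting at 0."""
        return np.arange(self.n) / self.rate


def compute_cop(
    rec: BoardRecording, axis_convention: AxisConvention = "paper"
) -> tuple[np.ndarray, np.ndarray]:
    """Corner contrasts -> raw (cp_ap, cp_ml) aligned to ``rec.timestamps``.

    With the default ``"paper"`` convention the outputs follow the literal
    formulas above; ``"anatomical"`` swaps them so cp_ap carries the
    front-minus-back contrast.
    """
    cp_ap = (rec.fr + rec.pr) - (rec.fl + rec.pl)
    cp_ml = (rec.fl + rec.fr) - (rec.pl + rec.pr)
    if axis_convention == "anatomical":
        cp_ap, cp_ml = cp_ml, cp_ap
    elif axis_convention != "paper":
        raise ParameterError(f"unknown axis_convention {axis_convention!r}")
    return cp_ap, cp_ml


def resample_linear(
    values: np.ndarray, timestamps: np.ndarray, rate: float
) -> tuple[np.ndarray, float]:
    """Linearly interpolate an irregular series onto a uniform grid.

    The grid is ``t0 + k/rate`` for ``k = 0..K`` where ``t0`` is the first
    timestamp and ``K = floor((t_last - t0) * rate)``; no extrapolation
    beyond the recorded span.
    """
    if rate <= 0:
        raise ParameterError("rate must be positive")
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if timestamps.size < 2:
        raise InsufficientDataError("need at least 2 samples to resample")
    if not np.all(np.diff(timestamps) > 0):
        raise ValidationError("timestamps must be strictly increasing")
    t0 = timestamps[0]
    span = timestamps[-1] - t0
    k_max = int(np.floor(span * rate + _GRID_EPS))
    grid = t0 + np.arange(k_max + 1) / rate
    return np.interp(grid, timestamps, values), float(rate)


def build_trajectory(
    rec: BoardRecording,
    rate: float = 20.0,
    axis_convention: AxisConvention = "paper",
    normalize: Normalize = "none",
) -> CoPTrajectory:
    """Resample the four raw channels, then combine them into a CoP trajectory.

    Channels are regularised first and combined second; for linear
    operations the order is mathematically irrelevant, but resampling raw
    sensor streams mirrors how acquisition pipelines treat the hardware
    output.  ``normalize="total_load"`` divides both CoP axes by the
    per-sample sum of the four channels (dimensionless output).
    """
    if rec.duration < 2.0 / rate:
        raise InsufficientDataError(
            f"recording spans {rec.duration:.3f} s; need at least {2.0 / rate:.3f} s"
        )
    channels = {}
    for name in ("fl", "fr", "pl", "pr"):
        channels[name], _ = resample_linear(getattr(rec, name), rec.timestamps, rate)
    reg = BoardRecording(
        timestamps=rec.timestamps[0] + np.arange(channels["fl"].size) / rate,
        board_id=rec.board_id,
        nominal_rate=rate,
        **channels,
    )
    cp_ap, cp_ml = compute_cop(reg, axis_convention=axis_convention)
    if normalize == "total_load":
        total = reg.fl + reg.fr + reg.pl + reg.pr
        if np.any(total == 0):
            raise ValidationError("total load is zero at some sample; cannot normalize")
        cp_ap = cp_ap / total
        cp_ml = cp_ml / total
    elif normalize != "none":
        raise ParameterError(f"unknown normalize mode {normalize!r}")
    return CoPTrajectory(rate=float(rate), cp_ap=cp_ap, cp_ml=cp_ml)


# ---------------------------------------------------------------------------
# File I/O
#
# Board CSV: header `t,fl,fr,pl,pr`, optional `#` comment lines, UTF-8.
# Board JSON: {"board_id": ..., "nominal_rate": ..., "samples": [{t,fl,fr,pl,pr}]}.
# Trajectory CSV: header `t,cp_ap,cp_ml` on the regular grid.
# ---------------------------------------------------------------------------


def read_board_recording(
    path: str | Path, format: Literal["csv", "json"] | None = None
) -> BoardRecording:
    """Read a raw board recording from CSV or JSON.

    ``format`` defaults to the file extension.  Raises :class:`SchemaError`
    for missing columns, :class:`ParseError` for non-numeric cells (naming
    the row), and :class:`ValidationError` for non-monotone timestamps.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        return _read_board_csv(path)
    if format == "json":
        return _read_board_json(path)
    raise ParameterError(f"unknown format {format!r}")


def _read_board_csv(path: Path) -> BoardRecording:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed file
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in BOARD_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    cols = {}
    for c in BOARD_CSV_COLUMNS:
        numeric = pd.to_numeric(df[c], errors="coerce")
        bad = numeric.isna() & df[c].notna()
        if bad.any() or numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise ParseError(f"{path}: non-numeric value in column {c!r} at row {row}")
        cols[c] = numeric.to_numpy(dtype=float)
    return BoardRecording(
        timestamps=cols["t"],
        fl=cols["fl"],
        fr=cols["fr"],
        pl=cols["pl"],
        pr=cols["pr"],
        board_id=path.stem,
    )


def _read_board_json(path: Path) -> BoardRecording:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if "samples" not in payload:
        raise SchemaError(f"{path}: missing 'samples' key")
    samples = payload["samples"]
    rows = {k: [] for k in BOARD_CSV_COLUMNS}
    for i, s in enumerate(samples):
        for k in BOARD_CSV_COLUMNS:
            if k not in s:
                raise SchemaError(f"{path}: sample {i} missing field {k!r}")
            try:
                rows[k].append(float(s[k]))
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric field {k!r} in sample {i}"
                ) from exc
    return BoardRecording(
        timestamps=np.array(rows["t"]),
        fl=np.array(rows["fl"]),
        fr=np.array(rows["fr"]),
        pl=np.array(rows["pl"]),
        pr=np.array(rows["pr"]),
        board_id=str(payload.get("board_id", "")),
        nominal_rate=float(payload.get("nominal_rate", 20.0)),
    )


def write_board_recording(
    rec: BoardRecording, path: str | Path, format: Literal["csv", "json"] | None = None
) -> None:
    """Write a recording; inverse of :func:`read_board_recording`."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        df = pd.DataFrame(
            {
                "t": rec.timestamps,
                "fl": rec.fl,
                "fr": rec.fr,
                "pl": rec.pl,
                "pr": rec.pr,
            }
        )
        df.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "board_id": rec.board_id,
            "nominal_rate": rec.nominal_rate,
            "samples": [
                {
                    "t": float(t),
                    "fl": float(a),
                    "fr": float(b),
                    "pl": float(c),
                    "pr": float(d),
                }
                for t, a, b, c, d in zip(rec.timestamps, rec.fl, rec.fr, rec.pl, rec.pr)
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ParameterError(f"unknown format {format!r}")


def write_trajectory_csv(traj: CoPTrajectory, path: str | Path) -> None:
    """Export a trajectory as `t,cp_ap,cp_ml` CSV on its regular grid."""
    pd.DataFrame(
        {"t": traj.times(), "cp_ap": traj.cp_ap, "cp_ml": traj.cp_ml}
    ).to_csv(Path(path), index=False)


def read_trajectory_csv(path: str | Path, rate: float | None = None) -> CoPTrajectory:
    """Read a `t,cp_ap,cp_ml` CSV; the rate is inferred from the time column
    unless given explicitly."""
    df = pd.read_csv(Path(path), comment="#")
    missing = [c for c in ("t", "cp_ap", "cp_ml") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    t = df["t"].to_numpy(dtype=float)
    if rate is None:
        if t.size < 2:
            raise InsufficientDataError("cannot infer rate from fewer than 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValidationError(f"{path}: time column is not a regular grid")
        rate = 1.0 / float(dt[0])
    return CoPTrajectory(
        rate=float(rate),
        cp_ap=df["cp_ap"].to_numpy(dtype=float),
        cp_ml=df["cp_ml"].to_numpy(dtype=float),
    )
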