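"""Joint-angle kinematics from 3D landmark time series.

Upper-limb range-of-motion assessment from markerless pose landmarks
(webcam pose estimators emit up to ~182 named 3D landmarks per frame at
20 Hz).  Joints are measured as interior three-point angles: the angle at
a vertex landmark between the rays toward a proximal and a distal
landmark.  Full ISB joint coordinate systems (segment-embedded Euler
sequences) are not constructed — pose landmarks alone do not define the
segment frames those conventions require — and the metadata of every
series records the three-point convention used instead.

Angle series are smoothed with an exponential moving average (EMA), the
first-order recursive filter y_i = alpha*x_i + (1-alpha)*y_{i-1}, and
summarized as range of motion (max - min), peak/mean angular velocity and
peak acceleration from finite differences (central in the interior,
one-sided at the endpoints).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .board import resample_linear
from .errors import (
    GeometryError,
    InsufficientDataError,
    ParameterError,
    SchemaError,
    ValidationError,
)

DEFAULT_RATE = 20.0
DEFAULT_ALPHA = 0.9
ANGLE_CONVENTION = "interior 3-point angle (proximal-vertex-distal), degrees"


@dataclass
class LandmarkSeries:
    """Named 3D landmark trajectories sharing one frame clock.

    ``landmarks`` maps a name (e.g. ``shoulder_l``) to an (n_frames, 3)
    array of positions in a consistent length unit.
    """

    rate: float
    landmarks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValidationError("rate must be positive")
        if not self.landmarks:
            raise ValidationError("landmark set is empty")
        n = None
        for name, arr in list(self.landmarks.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"landmark {name!r} must be an (n, 3) array")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"landmark {name!r} has non-finite coordinates")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValidationError(
                    f"landmark {name!r} has {arr.shape[0]} frames, expected {n}"
                )
            self.landmarks[name] = arr

    @property
    def n_frames(self) -> int:
        return next(iter(self.landmarks.values())).shape[0]

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.landmarks[name]
        except KeyError:
            raise SchemaError(f"landmark {name!r} not present in series") from None

    def interpolate_gaps(self, timestamps: np.ndarray, rate: float | None = None
                         ) -> "LandmarkSeries":
        """Resample every coordinate onto a regular grid (for dropped frames).

        ``timestamps`` gives the true (possibly irregular) frame times.
        """
        rate = rate or self.rate
        out = {}
        for name, arr in self.landmarks.items():
            cols = [resample_linear(arr[:, j], timestamps, rate)[0] for j in range(3)]
            out[name] = np.column_stack(cols)
        return LandmarkSeries(rate=rate, landmarks=out)


@dataclass
class JointAngleSeries:
    """One joint's angle over time, in degrees."""

    joint: str
    angle: np.ndarray
    definition: tuple[str, str, str]  # (proximal, vertex, distal)
    rate: float
    smoothed: bool = False
    convention: str = ANGLE_CONVENTION

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=float)
        if self.angle.ndim != 1 or self.angle.size == 0:
            raise ValidationError("angle series must be a non-empty 1-D array")


@dataclass
class KinematicSummary:
    """Scalar kinematic descriptors of one joint-angle series."""

    rom: float                    # degrees
    peak_angular_velocity: float  # degrees/s
    peak_acceleration: float      # degrees/s^2
    mean_angular_velocity: float  # degrees/s

    def as_dict(self) -> dict:
        return asdict(self)


def joint_angle(p: Sequence[float], v: Sequence[float], d: Sequence[float]) -> float:
    """Interior angle (degrees) at vertex ``v`` between rays v->p and v->d.

    The cosine is clamped to [-1, 1] before the arc-cosine so collinear
    configurations survive round-off.
    """
    u1 = np.asarray(p, dtype=float) - np.asarray(v, dtype=float)
    u2 = np.asarray(d, dtype=float) - np.asarray(v, dtype=float)
    n1 = np.linalg.norm(u1)
    n2 = np.linalg.norm(u2)
    if n1 == 0 or n2 == 0:
        raise GeometryError("zero-length ray: a landmark coincides with the vertex")
    c = np.clip(np.dot(u1, u2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def joint_angle_series(
    series: LandmarkSeries, proximal: str, vertex: str, distal: str
) -> np.ndarray:
    """Frame-wise interior angles (degrees) for one landmark triple."""
    u1 = series[proximal] - series[vertex]
    u2 = series[distal] - series[vertex]
    n1 = np.linalg.norm(u1, axis=1)
    n2 = np.linalg.norm(u2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        frame = int(np.flatnonzero((n1 == 0) | (n2 == 0))[0])
        raise GeometryError(f"zero-length ray at frame {frame}")
    c = np.clip(np.einsum("ij,ij->i", u1, u2) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(c))


def ema_smooth(series: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential moving average: y_0 = x_0; y_i = a*x_i + (1-a)*y_{i-1}."""
    if not 0 < alpha <= 1:
        raise ParameterError(f"alpha must be in (0, 1], got {alpha}")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ParameterError("series must be a non-empty 1-D array")
    y = np.empty_like(x)
    y[0] = x[0]
    for i in range(1, x.size):  # short series at 20 Hz; loop is fine
        y[i] = alpha * x[i] + (1 - alpha) * y[i - 1]
    return y


def angular_kinematics(angles: JointAngleSeries) -> KinematicSummary:
    """Summarize a joint-angle series.

    Velocity uses first-order central differences (one-sided at the
    endpoints); acceleration differences the velocity the same way.
    """
    a = angles.angle
    if a.size < 3:
        raise InsufficientDataError("need at least 3 frames for kinematics")
    dt = 1.0 / angles.rate
    vel = np.gradient(a, dt)
    acc = np.gradient(vel, dt)
    return KinematicSummary(
        rom=float(np.max(a) - np.min(a)),
        peak_angular_velocity=float(np.max(np.abs(vel))),
        peak_acceleration=float(np.max(np.abs(acc))),
        mean_angular_velocity=float(np.mean(np.abs(vel))),
    )


def rom_assessment(
    series: LandmarkSeries,
    joint_defs: Mapping[str, tuple[str, str, str]],
    alpha: float = DEFAULT_ALPHA,
) -> list[tuple[JointAngleSeries, KinematicSummary]]:
    """Per-joint angle extraction, EMA smoothing, and kinematic summary.

    ``joint_defs`` maps a joint name to its (proximal, vertex, distal)
    landmark triple; every named landmark must exist in the series.
    """
    out = []
    for joint, (prox, vert, dist) in joint_defs.items():
        raw = joint_angle_series(series, prox, vert, dist)
        smoothed = ema_smooth(raw, alpha)
        jas = JointAngleSeries(
            joint=joint,
            angle=smoothed,
            definition=(prox, vert, dist),
            rate=series.rate,
            smoothed=True,
        )
        out.append((jas, angular_kinematics(jas)))
    return out


# ---------------------------------------------------------------------------
# Landmark file I/O: CSV `frame,landmark,x,y,z` (long form) and JSON.
# ---------------------------------------------------------------------------


def read_landmarks_csv(path: str | Path, rate: float = DEFAULT_RATE) -> LandmarkSeries:
    df = pd.read_csv(Path(path), comment="#")
    missing = [c for c in ("frame", "landmark", "x", "y", "z") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    n_frames = int(df["frame"].max()) + 1
    landmarks = {}
    for name, grp in df.groupby("landmark"):
        grp = grp.sort_values("frame")
        if len(grp) != n_frames or not np.array_equal(
            grp["frame"].to_numpy(), np.arange(n_frames)
        ):
            raise SchemaError(
                f"{path}: landmark {name!r} has missing or duplicated frames"
            )
        landmarks[str(name)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
    return LandmarkSeries(rate=rate, landmarks=landmarks)


def write_landmarks_csv(series: LandmarkSeries, path: str | Path) -> None:
    rows = []
    for name, arr in series.landmarks.items():
        for i, (x, y, z) in enumerate(arr):
            rows.append((i, name, x, y, z))
    pd.DataFrame(rows, columns=["frame", "landmark", "x", "y", "z"]).sort_values(
        ["frame", "landmark"]
    ).to_csv(Path(path), index=False)


def summary_json(results: Iterable[tuple[JointAngleSeries, KinematicSummary]]) -> str:
    payload = {
        jas.joint: {
            "definition": list(jas.definition),
            "convention": jas.convention,
            "smoothed": jas.smoothed,
            **summ.as_dict(),
        }
        for jas, summ in results
    }
    return json.dumps(payload, indent=1, sort_keys=True)
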