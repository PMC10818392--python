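"""The nine printed stabilometry parameters and the static balance protocol.

Given a regularly sampled CoP trajectory (cp_ap, cp_ml at rate f, N
samples), the static balance test reports:

==================  =========================================================
DOT                 sum_i sqrt(cp_ap_i^2 + cp_ml_i^2)   (radial-distance sum)
95% ellipse area    pi * 2.4478^2 * sqrt(lambda1 * lambda2), lambda_k the
                    eigenvalues of the sample covariance (divisor N-1)
AP / ML RoM         max - min per axis
AP / ML SD          sqrt(mean of squared deviations from the mean); divisor N
AP / ML velocity    (f/N) * sum |x_{i+1} - x_i|
TMV                 (f/N) * sum sqrt(d_ap^2 + d_ml^2) over increments
==================  =========================================================

Two deliberate fidelity choices, both switchable:

* The DOT formula sums radial distances from the origin, not increment
  lengths.  "Total displacement of sway" conventionally means path length,
  so :func:`path_length` is provided separately and both appear in reports.
* The printed SD formula omits mean subtraction although it is described
  as dispersion about the mean position.  ``center=True`` (default)
  subtracts the mean; ``center=False`` evaluates the literal formula.

The constant 2.4478 is sqrt of the 95% quantile of the chi-square
distribution with 2 degrees of freedom: under a bivariate Gaussian model
the returned ellipse is expected to contain 95% of CoP samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .board import CoPTrajectory
from .errors import InsufficientDataError, ParameterError, ProtocolError

Axis = Literal["ap", "ml"]

#: sqrt(chi2.ppf(0.95, df=2)), at the precision used throughout.
ELLIPSE_SCALE_95 = 2.4478

DEFAULT_TRIAL_DURATION = 10.0
DEFAULT_TRIAL_TOLERANCE = 0.25
PARAMETER_NAMES = (
    "dot_eq3",
    "path_length",
    "ellipse_area",
    "ap_rom",
    "ml_rom",
    "ap_sd",
    "ml_sd",
    "ap_velocity",
    "ml_velocity",
    "tmv",
)


def _axis_signal(traj: CoPTrajectory, axis: Axis) -> np.ndarray:
    if axis == "ap":
        return traj.cp_ap
    if axis == "ml":
        return traj.cp_ml
    raise ParameterError(f"axis must be 'ap' or 'ml', got {axis!r}")


def total_displacement(traj: CoPTrajectory) -> float:
    """Sum of per-sample radial distances from the origin (board units)."""
    if traj.n < 1:
        raise InsufficientDataError("empty trajectory")
    return float(np.sum(np.hypot(traj.cp_ap, traj.cp_ml)))


def path_length(traj: CoPTrajectory) -> float:
    """Total CoP path length: sum of increment lengths (board units).

    The conventional reading of "total displacement of sway"; reported
    alongside :func:`total_displacement` because the two differ.
    """
    if traj.n < 2:
        raise InsufficientDataError("need at least 2 samples for path length")
    return float(np.sum(np.hypot(np.diff(traj.cp_ap), np.diff(traj.cp_ml))))


def ellipse_area_95(traj: CoPTrajectory) -> float:
    """Area of the 95% prediction ellipse (board units squared).

    Computed as pi * 2.4478^2 * sqrt(product of covariance eigenvalues),
    with the unbiased (N-1) sample covariance.  Degenerate clouds
    (collinear or coincident points) give area 0; a single distinct point
    additionally emits a warning.
    """
    if traj.n < 3:
        raise InsufficientDataError("need at least 3 samples for the ellipse area")
    pts = np.column_stack([traj.cp_ap, traj.cp_ml])
    if np.all(pts == pts[0]):
        warnings.warn("all CoP samples coincide; ellipse area is degenerate (0)")
        return 0.0
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.clip(eigvals, 0.0, None)  # covariance is PSD up to round-off
    return float(np.pi * ELLIPSE_SCALE_95**2 * np.sqrt(np.prod(eigvals)))


@dataclass
class PredictionEllipse:
    """Center, covariance, and squared Mahalanobis radius of the 95% ellipse."""

    center: np.ndarray
    cov: np.ndarray
    radius_sq: float

    @property
    def area(self) -> float:
        eigvals = np.clip(np.linalg.eigvalsh(self.cov), 0.0, None)
        return float(np.pi * self.radius_sq * np.sqrt(np.prod(eigvals)))

    def contains(self, ap: np.ndarray, ml: np.ndarray) -> np.ndarray:
        """Boolean mask: which (ap, ml) points lie inside the ellipse."""
        pts = np.column_stack([np.ravel(ap), np.ravel(ml)]) - self.center
        inv = np.linalg.inv(self.cov)
        d2 = np.einsum("ij,jk,ik->i", pts, inv, pts)
        return d2 <= self.radius_sq


def prediction_ellipse_95(traj: CoPTrajectory) -> PredictionEllipse:
    """The fitted 95% prediction ellipse as a geometric object."""
    if traj.n < 3:
        raise InsufficientDataError("need at least 3 samples for the ellipse")
    pts = np.column_stack([traj.cp_ap, traj.cp_ml])
    return PredictionEllipse(
        center=pts.mean(axis=0),
        cov=np.cov(pts, rowvar=False, ddof=1),
        radius_sq=ELLIPSE_SCALE_95**2,
    )


def cop_range(traj: CoPTrajectory, axis: Axis) -> float:
    """Range of motion on one axis: max - min (board units)."""
    x = _axis_signal(traj, axis)
    if x.size < 1:
        raise InsufficientDataError("empty trajectory")
    return float(np.max(x) - np.min(x))


def cop_dispersion(traj: CoPTrajectory, axis: Axis, center: bool = True) -> float:
    """Dispersion of CoP displacement on one axis (board units).

    ``center=True`` (default): sqrt(mean((x - mean(x))^2)) — dispersion
    about the mean position.  ``center=False``: the literal
    sqrt(mean(x^2)) (root-mean-square about the origin).  Divisor N in
    both modes.
    """
    x = _axis_signal(traj, axis)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 samples for dispersion")
    if center:
        x = x - np.mean(x)
    return float(np.sqrt(np.mean(x**2)))


def mean_velocity(traj: CoPTrajectory, axis: Axis) -> float:
    """Mean axis velocity: (f/N) * sum of absolute increments (units/s).

    The divisor is N (the literal formula), not N-1; the two differ by a
    factor (N-1)/N.
    """
    x = _axis_signal(traj, axis)
    if x.size < 2:
        raise InsufficientDataError("need at least 2 samples for velocity")
    return float(traj.rate / traj.n * np.sum(np.abs(np.diff(x))))


def total_mean_velocity(traj: CoPTrajectory) -> float:
    """Total mean velocity: (f/N) * planar path length (units/s)."""
    if traj.n < 2:
        raise InsufficientDataError("need at least 2 samples for velocity")
    return float(traj.rate / traj.n * np.sum(
        np.hypot(np.diff(traj.cp_ap), np.diff(traj.cp_ml))
    ))


@dataclass
class StabilometryResult:
    """All stabilometry parameters for one trial (board units / seconds)."""

    dot_eq3: float
    path_length: float
    ellipse_area: float
    ap_rom: float
    ml_rom: float
    ap_sd: float
    ml_sd: float
    ap_velocity: float
    ml_velocity: float
    tmv: float
    n: int
    rate: float

    def as_dict(self) -> dict:
        return asdict(self)


def analyze_trajectory(
    traj: CoPTrajectory, center: bool = True, recenter: bool = False
) -> StabilometryResult:
    """Compute every stabilometry parameter for one trajectory.

    ``recenter`` subtracts the mean CoP from both axes before any
    computation (default off: values are used exactly as extracted).
    """
    if recenter:
        traj = CoPTrajectory(
            rate=traj.rate,
            cp_ap=traj.cp_ap - np.mean(traj.cp_ap),
            cp_ml=traj.cp_ml - np.mean(traj.cp_ml),
        )
    return StabilometryResult(
        dot_eq3=total_displacement(traj),
        path_length=path_length(traj),
        ellipse_area=ellipse_area_95(traj),
        ap_rom=cop_range(traj, "ap"),
        ml_rom=cop_range(traj, "ml"),
        ap_sd=cop_dispersion(traj, "ap", center=center),
        ml_sd=cop_dispersion(traj, "ml", center=center),
        ap_velocity=mean_velocity(traj, "ap"),
        ml_velocity=mean_velocity(traj, "ml"),
        tmv=total_mean_velocity(traj),
        n=traj.n,
        rate=traj.rate,
    )


@dataclass
class StaticBalanceReport:
    """Three ten-second trials plus their element-wise mean."""

    per_trial: list[StabilometryResult]
    mean_across_trials: StabilometryResult
    trial_duration: float
    settings: dict

    def as_dict(self) -> dict:
        return {
            "trials": [t.as_dict() for t in self.per_trial],
            "mean": self.mean_across_trials.as_dict(),
            "trial_duration": self.trial_duration,
            "settings": self.settings,
        }


def run_static_balance_test(
    trials: list[CoPTrajectory],
    center: bool = True,
    recenter: bool = False,
    trial_duration: float = DEFAULT_TRIAL_DURATION,
    duration_tolerance: float = DEFAULT_TRIAL_TOLERANCE,
) -> StaticBalanceReport:
    """Run the three-trial static balance protocol.

    Each trial must last ``trial_duration`` seconds within
    ``duration_tolerance``; the report carries per-trial parameters and
    their element-wise arithmetic mean.
    """
    if len(trials) != 3:
        raise ProtocolError(f"static balance test requires 3 trials, got {len(trials)}")
    for i, traj in enumerate(trials, start=1):
        if abs(traj.duration - trial_duration) > duration_tolerance:
            raise ProtocolError(
                f"trial {i} lasts {traj.duration:.3f} s; expected "
                f"{trial_duration:.1f} +/- {duration_tolerance:.2f} s"
            )
    results = [analyze_trajectory(t, center=center, recenter=recenter) for t in trials]
    mean = StabilometryResult(
        **{k: float(np.mean([getattr(r, k) for r in results])) for k in PARAMETER_NAMES},
        n=int(np.mean([r.n for r in results])),
        rate=float(np.mean([r.rate for r in results])),
    )
    return StaticBalanceReport(
        per_trial=results,
        mean_across_trials=mean,
        trial_duration=trial_duration,
        settings={"center": center, "recenter": recenter},
    )
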