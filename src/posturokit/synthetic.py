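"""Seeded synthetic generators for every pipeline stage.

Real recordings require a physical balance board and a pose camera, so
each analysis stage has a matching generator with analytically known
ground truth:

* :func:`simulate_sway` — CoP trajectories from an Ornstein-Uhlenbeck
  (OU) process (the standard stochastic stand-in for quiet-stance sway:
  mean-reverting with stationary SD ``sigma / sqrt(2*theta)``), a pure
  sinusoid, or their sum.
* :func:`simulate_board_recording` — inverts the CoP corner contrasts
  back to four non-negative channel streams under a constant total load,
  with optional Gaussian timestamp jitter emulating the inconsistent
  inter-sample intervals of consumer boards.
* :func:`simulate_dbt_trace` — a scripted mediolateral trace that holds
  each target zone for a chosen time, for exercising the DBT scorer.
* :func:`simulate_landmarks` — arm landmark triples whose elbow angle
  follows a known profile (static, linear flexion, or sinusoid).

All generators are pure functions of (config, seed): the same inputs give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .board import BoardRecording, CoPTrajectory
from .dbt import DBTConfig
from .errors import GenerationError, ParameterError
from .kinematics import LandmarkSeries

SwayModel = Literal["ou", "sinusoid", "mixed"]


@dataclass(frozen=True)
class SwaySimConfig:
    """Postural-sway simulation parameters.

    OU parameters: ``ou_theta`` (1/s mean reversion) and ``ou_sigma``
    (board units * s^-1/2 diffusion) give stationary SD
    ``ou_sigma / sqrt(2 * ou_theta)`` per axis.  ``timestamp_jitter_sd``
    (seconds) perturbs board timestamps, clipped to just under half the
    nominal interval so order is never violated.
    """

    seed: int = 0
    duration: float = 10.0
    rate: float = 20.0
    model: SwayModel = "ou"
    ou_theta: float = 1.0
    ou_sigma: float = math.sqrt(2.0)
    sine_amplitude: float = 1.0
    sine_freq: float = 0.5
    timestamp_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ParameterError("duration and rate must be positive")
        if self.model not in ("ou", "sinusoid", "mixed"):
            raise ParameterError(f"unknown sway model {self.model!r}")
        if self.ou_theta <= 0 or self.ou_sigma < 0:
            raise ParameterError("ou_theta must be > 0 and ou_sigma >= 0")
        if self.timestamp_jitter_sd < 0:
            raise ParameterError("timestamp_jitter_sd must be >= 0")

    @property
    def stationary_sd(self) -> float:
        return self.ou_sigma / math.sqrt(2.0 * self.ou_theta)


def _ou_path(times: np.ndarray, theta: float, sigma: float,
             rng: np.random.Generator) -> np.ndarray:
    """Exact-discretization OU path at arbitrary (increasing) times.

    x_{k+1} = x_k e^{-theta dt} + sqrt(sigma^2 (1 - e^{-2 theta dt}) /
    (2 theta)) * xi, started from the stationary distribution.
    """
    sd_inf = sigma / math.sqrt(2.0 * theta)
    x = np.empty(times.size)
    x[0] = rng.normal(0.0, sd_inf)
    dts = np.diff(times)
    decay = np.exp(-theta * dts)
    innov_sd = sd_inf * np.sqrt(1.0 - decay**2)
    noise = rng.normal(size=dts.size)
    for k in range(dts.size):
        x[k + 1] = x[k] * decay[k] + innov_sd[k] * noise[k]
    return x


def _sway_at(cfg: SwaySimConfig, times: np.ndarray,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the configured sway model at the given times.

    The sinusoid puts sine on AP and cosine on ML (quadrature) so the
    planar trajectory is a circle rather than a degenerate line.
    """
    ap = np.zeros(times.size)
    ml = np.zeros(times.size)
    if cfg.model in ("ou", "mixed"):
        ap = ap + _ou_path(times, cfg.ou_theta, cfg.ou_sigma, rng)
        ml = ml + _ou_path(times, cfg.ou_theta, cfg.ou_sigma, rng)
    if cfg.model in ("sinusoid", "mixed"):
        w = 2.0 * math.pi * cfg.sine_freq
        ap = ap + cfg.sine_amplitude * np.sin(w * times)
        ml = ml + cfg.sine_amplitude * np.cos(w * times)
    return ap, ml


def _regular_times(cfg: SwaySimConfig) -> np.ndarray:
    n = int(round(cfg.duration * cfg.rate))
    return np.arange(n) / cfg.rate


def simulate_sway(cfg: SwaySimConfig) -> CoPTrajectory:
    """Simulate a CoP trajectory on the regular grid at ``cfg.rate``."""
    rng = np.random.default_rng(cfg.seed)
    times = _regular_times(cfg)
    ap, ml = _sway_at(cfg, times, rng)
    return CoPTrajectory(rate=cfg.rate, cp_ap=ap, cp_ml=ml)


def simulate_board_recording(
    cfg: SwaySimConfig, total_load: float = 100.0, board_id: str = "synthetic"
) -> BoardRecording:
    """Generate four corner channels whose CoP contrasts equal the sway.

    The corner split holds the total load constant and distributes the AP
    and ML contrasts symmetrically:

        FL = L/4 - ap/4 + ml/4      FR = L/4 + ap/4 + ml/4
        PL = L/4 - ap/4 - ml/4      PR = L/4 + ap/4 - ml/4

    so (FR+PR)-(FL+PL) = ap and (FL+FR)-(PL+PR) = ml exactly.  A split
    that would drive any channel negative (|ap| + |ml| > L) is refused.

    With ``timestamp_jitter_sd == 0`` the timestamps are the regular grid
    and rebuilding the trajectory recovers the simulated sway to machine
    precision.  The same seed with and without jitter evaluates the same
    sway model, just at perturbed times.
    """
    rng = np.random.default_rng(cfg.seed)
    times = _regular_times(cfg)
    if cfg.timestamp_jitter_sd > 0:
        dt = 1.0 / cfg.rate
        jitter_rng = np.random.default_rng([cfg.seed, 0x6A69])  # distinct stream
        jitter = jitter_rng.normal(0.0, cfg.timestamp_jitter_sd, size=times.size)
        limit = 0.499 * dt
        jitter = np.clip(jitter, -limit, limit)
        jitter[0] = abs(jitter[0])  # keep t0 >= 0
        times = times + jitter
    ap, ml = _sway_at(cfg, times, rng)
    if np.any(np.abs(ap) + np.abs(ml) > total_load):
        worst = float(np.max(np.abs(ap) + np.abs(ml)))
        raise GenerationError(
            f"sway amplitude {worst:.2f} exceeds total load {total_load}; "
            "a corner channel would be negative"
        )
    quarter = total_load / 4.0
    return BoardRecording(
        timestamps=times,
        fl=quarter - ap / 4.0 + ml / 4.0,
        fr=quarter + ap / 4.0 + ml / 4.0,
        pl=quarter - ap / 4.0 - ml / 4.0,
        pr=quarter + ap / 4.0 - ml / 4.0,
        board_id=board_id,
        nominal_rate=cfg.rate,
    )


def simulate_dbt_trace(
    script: Sequence[tuple[float, float, float]],
    cfg: DBTConfig,
    seed: int = 0,
    transition_seconds: float = 0.5,
) -> np.ndarray:
    """Scripted mediolateral trace: (target_offset, hold_seconds, wander_sd).

    Each entry parks the cursor at ``target_offset`` for ``hold_seconds``
    with Gaussian wander of the given SD.  Between entries a short
    out-of-zone excursion (toward 0) is inserted so consecutive holds are
    unambiguous.  With small wander, replaying the trace through the DBT
    scorer completes exactly the entries whose hold covers the configured
    hold duration.
    """
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    total = 0.0
    for k, (offset, hold, wander_sd) in enumerate(script):
        if hold < 0 or wander_sd < 0:
            raise GenerationError(f"script entry {k}: negative hold or wander")
        if k > 0:
            n_trans = max(1, int(round(transition_seconds * cfg.rate)))
            chunks.append(np.zeros(n_trans))  # midline: outside both zones
            total += n_trans / cfg.rate
        n_hold = int(math.ceil(hold * cfg.rate))
        chunks.append(offset + rng.normal(0.0, wander_sd, size=n_hold))
        total += n_hold / cfg.rate
    if total > cfg.total_time:
        raise GenerationError(
            f"script needs {total:.1f} s but total_time is {cfg.total_time} s"
        )
    if not chunks:
        return np.zeros(1)
    return np.concatenate(chunks)


_ARM_UPPER = 0.30  # shoulder->elbow length, length units
_ARM_FORE = 0.25   # elbow->wrist length

LandmarkMotion = Literal["static", "elbow_flexion", "sinusoid_joint"]


def simulate_landmarks(
    motion: LandmarkMotion,
    duration: float = 5.0,
    rate: float = 20.0,
    seed: int = 0,
    start_angle: float = 180.0,
    end_angle: float = 90.0,
    mean_angle: float = 90.0,
    amplitude: float = 20.0,
    freq: float = 0.25,
    noise_sd: float = 0.0,
) -> LandmarkSeries:
    """Arm landmarks (shoulder/elbow/wrist, left) with a known elbow angle.

    * ``static`` — frozen pose at ``start_angle``.
    * ``elbow_flexion`` — interior elbow angle moves linearly from
      ``start_angle`` to ``end_angle`` (default 180 -> 90 degrees, i.e.
      flexing from full extension by 90 degrees).
    * ``sinusoid_joint`` — angle = mean_angle + amplitude * sin(2 pi f t).

    ``noise_sd`` adds isotropic Gaussian positional noise (length units)
    to every landmark, for robustness experiments.
    """
    if motion not in ("static", "elbow_flexion", "sinusoid_joint"):
        raise ParameterError(f"unknown motion {motion!r}")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    if motion == "static":
        theta = np.full(n, start_angle)
    elif motion == "elbow_flexion":
        theta = np.linspace(start_angle, end_angle, n)
    else:
        theta = mean_angle + amplitude * np.sin(2.0 * math.pi * freq * t)

    shoulder = np.tile([0.0, 0.0, 0.0], (n, 1))
    elbow = np.tile([0.0, -_ARM_UPPER, 0.0], (n, 1))
    # Wrist in the x-y plane: the elbow->shoulder ray is +y, so placing the
    # wrist at polar angle theta from +y makes the interior angle theta.
    rad = np.radians(theta)
    wrist = elbow + _ARM_FORE * np.column_stack(
        [np.sin(rad), np.cos(rad), np.zeros(n)]
    )
    landmarks = {"shoulder_l": shoulder, "elbow_l": elbow, "wrist_l": wrist}
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        landmarks = {
            k: v + rng.normal(0.0, noise_sd, size=v.shape)
            for k, v in landmarks.items()
        }
    return LandmarkSeries(rate=rate, landmarks=landmarks)
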