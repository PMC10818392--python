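"""Dynamic balance test (DBT) scoring.

The subject stands on the board and shifts weight left or right toward an
on-screen target, holding the cursor inside a tolerance zone around the
target for a fixed hold time (3 s by default).  Each completed round
narrows the zone, demanding finer control; the score is the number of
rounds completed within the allotted test time.

Scoring here is a deterministic replay over a recorded mediolateral CoP
trace: round k uses the zone [offset_k - h_k, offset_k + h_k] with
h_k = initial_halfwidth * narrowing_factor**(k-1); a round completes at
the first sample that ends a run of ceil(hold_duration * rate)
consecutive in-zone samples, and leaving the zone resets the run.
Samples exactly on a zone boundary count as in-zone (closed interval).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import ComparisonError, InsufficientDataError, ParameterError

DEFAULT_TARGET_OFFSETS = (-10.0, 10.0, -10.0, 10.0, -10.0, 10.0,
                          -10.0, 10.0, -10.0, 10.0)


@dataclass(frozen=True)
class DBTConfig:
    """Protocol parameters for the dynamic balance test.

    ``target_offsets`` is the ordered list of signed zone centers in board
    units, alternating left (negative) / right (positive) by default; the
    list also bounds the number of scoreable rounds.
    """

    hold_duration: float = 3.0
    total_time: float = 60.0
    initial_halfwidth: float = 5.0
    narrowing_factor: float = 0.8
    target_offsets: tuple[float, ...] = DEFAULT_TARGET_OFFSETS
    rate: float = 20.0

    def __post_init__(self) -> None:
        if self.hold_duration <= 0:
            raise ParameterError("hold_duration must be positive")
        if self.total_time <= self.hold_duration:
            raise ParameterError("total_time must exceed hold_duration")
        if not 0 < self.narrowing_factor < 1:
            raise ParameterError("narrowing_factor must be in (0, 1)")
        if self.initial_halfwidth <= 0:
            raise ParameterError("initial_halfwidth must be positive")
        if self.rate <= 0:
            raise ParameterError("rate must be positive")
        if len(self.target_offsets) == 0:
            raise ParameterError("target_offsets must be non-empty")

    def halfwidth(self, round_index: int) -> float:
        """Zone half-width for round k (1-based)."""
        return self.initial_halfwidth * self.narrowing_factor ** (round_index - 1)

    @property
    def hold_samples(self) -> int:
        return math.ceil(self.hold_duration * self.rate)

    def digest(self) -> str:
        """Deterministic hash of the configuration (for comparability)."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RoundOutcome:
    target_offset: float
    halfwidth: float
    time_to_complete: float | None  # seconds from test start; None = incomplete

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class DBTResult:
    rounds_completed: int
    per_round: list[RoundOutcome]
    elapsed: float
    config_digest: str

    def as_dict(self) -> dict:
        return {
            "rounds_completed": self.rounds_completed,
            "per_round": [r.as_dict() for r in self.per_round],
            "elapsed": self.elapsed,
            "config_digest": self.config_digest,
        }


def score_dbt(traj_ml: np.ndarray, cfg: DBTConfig) -> DBTResult:
    """Replay a mediolateral CoP trace through the DBT state machine.

    Sample i occurs at time (i+1)/rate (the sample closes its interval);
    scoring stops when the trace is exhausted or total_time elapses.
    """
    x = np.asarray(traj_ml, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InsufficientDataError("DBT trace is empty")
    max_samples = min(x.size, int(math.floor(cfg.total_time * cfg.rate)))
    if x.size > int(math.ceil(cfg.total_time * cfg.rate)) + 1:
        raise ParameterError(
            f"trace covers {x.size / cfg.rate:.2f} s, longer than "
            f"total_time={cfg.total_time} s; truncate or fix the rate"
        )

    need = cfg.hold_samples
    per_round: list[RoundOutcome] = []
    round_idx = 1
    run = 0
    i = 0
    while i < max_samples and round_idx <= len(cfg.target_offsets):
        offset = cfg.target_offsets[round_idx - 1]
        h = cfg.halfwidth(round_idx)
        if offset - h <= x[i] <= offset + h:
            run += 1
        else:
            run = 0
        if run >= need:
            per_round.append(
                RoundOutcome(offset, h, time_to_complete=(i + 1) / cfg.rate)
            )
            round_idx += 1
            run = 0
        i += 1

    for k in range(round_idx, len(cfg.target_offsets) + 1):
        per_round.append(RoundOutcome(cfg.target_offsets[k - 1], cfg.halfwidth(k), None))

    completed = sum(1 for r in per_round if r.time_to_complete is not None)
    return DBTResult(
        rounds_completed=completed,
        per_round=per_round,
        elapsed=min(x.size, max_samples) / cfg.rate,
        config_digest=cfg.digest(),
    )


def dbt_progress_delta(before: DBTResult, after: DBTResult) -> int:
    """Signed change in rounds completed between two sessions.

    Both results must come from the same configuration; comparing scores
    obtained under different protocols is refused.
    """
    if before.config_digest != after.config_digest:
        raise ComparisonError(
            "cannot compare DBT results from different configurations "
            f"({before.config_digest} vs {after.config_digest})"
        )
    return after.rounds_completed - before.rounds_completed
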