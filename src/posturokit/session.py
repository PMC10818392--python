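"""Session records, longitudinal aggregation, and report rendering.

A :class:`SessionRecord` stores one assessment outcome (static balance,
DBT, or RoM) together with a digest of the settings that produced it.
Longitudinal trend queries return one parameter as a chronological time
series over a date window; sessions whose settings differ from the most
common configuration in the selection are flagged rather than silently
mixed, because parameter values are only comparable under identical
processing settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Any, Iterable, Literal

from .errors import ParameterError, PosturoKitError

TestType = Literal["static", "dbt", "rom"]


def settings_digest(settings: dict) -> str:
    """Deterministic 16-hex-digit digest of a settings mapping."""
    payload = json.dumps(settings, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def canonical_json(payload: Any) -> str:
    """Stable JSON: sorted keys, full float precision (repr round-trip)."""
    return json.dumps(payload, sort_keys=True, indent=1, allow_nan=False)


@dataclass
class SessionRecord:
    session_id: str
    timestamp: datetime
    test_type: TestType
    result: dict
    settings_hash: str

    def as_dict(self) -> dict:
        return {
            "session_id": self.session_id,
            "timestamp": self.timestamp.isoformat(),
            "test_type": self.test_type,
            "result": self.result,
            "settings_hash": self.settings_hash,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionRecord":
        return cls(
            session_id=str(d["session_id"]),
            timestamp=datetime.fromisoformat(d["timestamp"]),
            test_type=d["test_type"],
            result=d["result"],
            settings_hash=str(d["settings_hash"]),
        )


@dataclass
class TrendPoint:
    timestamp: datetime
    value: float
    session_id: str
    settings_mismatch: bool = False


def _extract_parameter(record: SessionRecord, parameter: str) -> float:
    r = record.result
    if record.test_type == "static":
        mean = r.get("mean", {})
        if parameter not in mean:
            raise ParameterError(
                f"unknown static-balance parameter {parameter!r}; "
                f"available: {sorted(mean)}"
            )
        return float(mean[parameter])
    if record.test_type == "dbt":
        if parameter not in r:
            raise ParameterError(
                f"unknown DBT parameter {parameter!r}; available: "
                f"{sorted(k for k, v in r.items() if isinstance(v, (int, float)))}"
            )
        return float(r[parameter])
    if record.test_type == "rom":
        # parameter syntax: "<joint>.<metric>", e.g. "elbow_l.rom"
        joint, _, metric = parameter.partition(".")
        if joint not in r or metric not in r.get(joint, {}):
            raise ParameterError(f"unknown RoM parameter {parameter!r}")
        return float(r[joint][metric])
    raise ParameterError(f"unknown test type {record.test_type!r}")


def aggregate_sessions(
    records: Iterable[SessionRecord],
    test_type: TestType,
    parameter: str,
    period: tuple[datetime, datetime] | None = None,
) -> list[TrendPoint]:
    """Chronological series of one parameter across sessions.

    Sessions outside ``period`` (inclusive start, inclusive end) or of a
    different test type are dropped; an empty selection returns an empty
    list.  Points whose settings hash differs from the majority hash in
    the selection carry ``settings_mismatch=True``.
    """
    selected = [r for r in records if r.test_type == test_type]
    if period is not None:
        start, end = period
        selected = [r for r in selected if start <= r.timestamp <= end]
    selected.sort(key=lambda r: r.timestamp)
    if not selected:
        return []
    hashes = [r.settings_hash for r in selected]
    majority = max(set(hashes), key=hashes.count)
    return [
        TrendPoint(
            timestamp=r.timestamp,
            value=_extract_parameter(r, parameter),
            session_id=r.session_id,
            settings_mismatch=r.settings_hash != majority,
        )
        for r in selected
    ]


def load_sessions(path: str | Path) -> list[SessionRecord]:
    """Read a JSON session archive (a list of session objects)."""
    payload = json.loads(Path(path).read_text())
    records = [SessionRecord.from_dict(d) for d in payload]
    records.sort(key=lambda r: r.timestamp)
    return records


def save_sessions(records: Iterable[SessionRecord], path: str | Path) -> None:
    Path(path).write_text(
        canonical_json([r.as_dict() for r in sorted(records, key=lambda r: r.timestamp)])
    )


def _fmt(x: Any) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def render_report(
    payload: dict | list[TrendPoint],
    out_json: str | Path,
    out_text: str | Path | None = None,
) -> str:
    """Write canonical JSON plus a plain-text summary; returns the text.

    Accepts a report dict (static/DBT/RoM payloads) or a trend series.
    """
    lines: list[str] = []
    if isinstance(payload, list):  # trend series
        json_payload = [
            {
                "timestamp": p.timestamp.isoformat(),
                "value": p.value,
                "session_id": p.session_id,
                "settings_mismatch": p.settings_mismatch,
            }
            for p in payload
        ]
        lines.append("Longitudinal trend")
        if not payload:
            lines.append("no sessions in period")
        for p in payload:
            flag = "  [settings mismatch]" if p.settings_mismatch else ""
            lines.append(f"{p.timestamp.isoformat()}  {_fmt(p.value)}{flag}")
    else:
        json_payload = payload
        lines.extend(_render_dict(payload))
    try:
        Path(out_json).write_text(canonical_json(json_payload))
    except OSError as exc:
        raise PosturoKitError(f"cannot write report to {out_json}: {exc}") from exc
    text = "\n".join(lines) + "\n"
    if out_text is not None:
        Path(out_text).write_text(text)
    return text


def _render_dict(d: dict, indent: int = 0) -> list[str]:
    pad = "  " * indent
    lines = []
    for key in d:
        val = d[key]
        if isinstance(val, dict):
            lines.append(f"{pad}{key}:")
            lines.extend(_render_dict(val, indent + 1))
        elif isinstance(val, list) and val and isinstance(val[0], dict):
            for i, item in enumerate(val, start=1):
                lines.append(f"{pad}{key} [{i}]:")
                lines.extend(_render_dict(item, indent + 1))
        else:
            lines.append(f"{pad}{key}: {_fmt(val)}")
    return lines
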