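"""Symbolic feedback emission and JSON-lines trace serialization.

Detected cognitive events are mapped onto a small user-facing vocabulary of
(label, glyph) markers.  NoEvent markers are suppressed by default so traces
stay sparse; ``verbose=True`` keeps them.  Traces serialise losslessly to
UTF-8 JSON-lines with plain seconds-since-episode-start timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .discriminator import CognitiveEvent, EventType

SCHEMA_VERSION = "1"

#: glyph for ConflictEscalate (a stable stand-in for the vocabulary's
#: original display glyph); override via ``emit(..., conflict_code=...)``
DEFAULT_CONFLICT_CODE = "⚠"  # ⚠

#: event type -> (label, glyph).  Sigma1's row is a reconstruction: the core
#: vocabulary covers drift/conflict/reject/accept/no-event, but the initial
#: commitment marker pervades the trace semantics and needs a stable glyph.
MARKER_VOCABULARY: dict[EventType, tuple[str, str]] = {
    EventType.DRIFT: ("System diverging", "Δ"),          # Δ
    EventType.CONFLICT: ("Conflict rising", DEFAULT_CONFLICT_CODE),
    EventType.REJECT_H1: ("Hypothesis rejected", "⊘"),   # ⊘
    EventType.ACCEPT_H1: ("Hypothesis accepted", "✓"),   # ✓
    EventType.NO_EVENT: ("Stable state", "•"),           # •
    EventType.SIGMA1: ("Intent committed", "σ1"),        # σ1
}


class MappingError(KeyError):
    """An event type has no symbolic mapping."""


class TraceOrderError(ValueError):
    """Marker timestamps are not non-decreasing."""


class TraceParseError(ValueError):
    """A trace line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class SymbolicMarker:
    label: str
    code: str
    timestamp: float
    event_type: EventType
    detail: dict = field(default_factory=dict)
    source_event: CognitiveEvent | None = field(default=None, compare=False)


@dataclass
class SymbolicTrace:
    episode_id: str
    markers: list[SymbolicMarker] = field(default_factory=list)
    config_fingerprint: str = ""

    def __post_init__(self) -> None:
        if not self.episode_id:
            raise ValueError("episode_id must be non-empty")
        self._check_order()

    def _check_order(self) -> None:
        ts = [m.timestamp for m in self.markers]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise TraceOrderError("marker timestamps must be non-decreasing")

    def of_type(self, event_type: EventType) -> list[SymbolicMarker]:
        return [m for m in self.markers if m.event_type == event_type]


def emit(
    events: list[CognitiveEvent],
    *,
    episode_id: str = "episode",
    config_fingerprint: str = "",
    verbose: bool = False,
    conflict_code: str = DEFAULT_CONFLICT_CODE,
) -> SymbolicTrace:
    """Map an ordered event stream onto the symbolic vocabulary.

    NoEvent entries are suppressed unless ``verbose``; every other event maps
    to exactly one marker, in order.
    """
    markers: list[SymbolicMarker] = []
    for event in events:
        try:
            label, code = MARKER_VOCABULARY[event.type]
        except KeyError:
            raise MappingError(f"no symbolic mapping for event type {event.type!r}")
        if event.type is EventType.NO_EVENT and not verbose:
            continue
        if event.type is EventType.CONFLICT:
            code = conflict_code
        markers.append(
            SymbolicMarker(
                label=label,
                code=code,
                timestamp=event.timestamp,
                event_type=event.type,
                detail=dict(event.detail),
                source_event=event,
            )
        )
    return SymbolicTrace(
        episode_id=episode_id, markers=markers, config_fingerprint=config_fingerprint
    )


def write_trace(trace: SymbolicTrace, destination) -> None:
    """Serialise a trace as JSON-lines (header line + one marker per line)."""
    trace._check_order()
    lines = [
        json.dumps(
            {
                "schema_version": SCHEMA_VERSION,
                "episode_id": trace.episode_id,
                "config_fingerprint": trace.config_fingerprint,
            },
            ensure_ascii=False,
        )
    ]
    for m in trace.markers:
        record = {
            "episode_id": trace.episode_id,
            "t": m.timestamp,
            "event_type": m.event_type.value,
            "label": m.label,
            "code": m.code,
        }
        if m.detail:
            record["detail"] = m.detail
        lines.append(json.dumps(record, ensure_ascii=False))
    Path(destination).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(source) -> SymbolicTrace:
    """Parse a JSON-lines trace; raises :class:`TraceParseError` with the
    offending line number on malformed input."""
    text = Path(source).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TraceParseError(1, "empty trace file")
    header = _parse_line(lines[0], 1)
    episode_id = header.get("episode_id", "")
    fingerprint = header.get("config_fingerprint", "")
    markers = []
    for i, line in enumerate(lines[1:], start=2):
        rec = _parse_line(line, i)
        try:
            markers.append(
                SymbolicMarker(
                    label=rec["label"],
                    code=rec["code"],
                    timestamp=float(rec["t"]),
                    event_type=EventType(rec["event_type"]),
                    detail=rec.get("detail", {}),
                )
            )
        except (KeyError, ValueError) as exc:
            raise TraceParseError(i, f"invalid marker record: {exc}") from exc
    try:
        return SymbolicTrace(episode_id, markers, fingerprint)
    except TraceOrderError as exc:
        raise TraceParseError(2, str(exc)) from exc


def _parse_line(line: str, number: int) -> dict:
    try:
        rec = json.loads(line)
    except json.JSONDecodeError as exc:
        raise TraceParseError(number, f"malformed JSON: {exc}") from exc
    if not isinstance(rec, dict):
        raise TraceParseError(number, "expected a JSON object")
    return rec


def format_timeline(trace: SymbolicTrace, width: int = 72, duration: float | None = None) -> str:
    """Render an aligned textual timeline of a trace (replay view)."""
    if not trace.markers:
        return f"[{trace.episode_id}] (empty trace)"
    t_max = duration or max(m.timestamp for m in trace.markers) or 1.0
    lines = [f"[{trace.episode_id}]  0s {'-' * width} {t_max:.0f}s"]
    for m in trace.markers:
        pos = int(min(m.timestamp / t_max, 1.0) * width)
        lines.append(f"  {' ' * pos}{m.code}  t={m.timestamp:7.2f}s  {m.label}")
    return "\n".join(lines)
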