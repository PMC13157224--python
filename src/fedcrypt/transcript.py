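"""Protocol transcripts.

Every value any party reveals on the wire (masked Beaver openings, masked
conversions, comparison openings, PSI group elements, declared final
outputs) is appended to a session transcript. The transcript doubles as the
audit surface: tests replay it to confirm that nothing other than masked
values and declared outputs was ever opened.
"""

from __future__ import annotations

import json
from typing import Any, Iterable


class Transcript:
    """Append-only log of protocol messages, JSONL-serializable."""

    def __init__(self, session_id: str = "") -> None:
        self.session_id = session_id
        self.entries: list[dict[str, Any]] = []
        self._round = 0

    def next_round(self) -> int:
        self._round += 1
        return self._round

    def log(self, op: str, tag: str, value: Any, **extra: Any) -> None:
        entry = {
            "round": self.next_round(),
            "op": op,
            "tag": tag,
            "value": value,
        }
        if extra:
            entry.update(extra)
        self.entries.append(entry)

    def openings(self, prefix: str | None = None) -> list[dict[str, Any]]:
        """All opened values, optionally filtered by tag prefix."""
        out = [e for e in self.entries if e["op"] == "open"]
        if prefix is not None:
            out = [e for e in out if str(e["tag"]).startswith(prefix)]
        return out

    def revealed(self) -> list[dict[str, Any]]:
        """Entries explicitly declared as protocol outputs."""
        return [e for e in self.entries if str(e["tag"]).startswith("reveal:")]

    def masked_openings(self) -> list[dict[str, Any]]:
        """Openings that are NOT declared outputs (must all be masked)."""
        return [
            e
            for e in self.entries
            if e["op"] == "open" and not str(e["tag"]).startswith("reveal:")
        ]

    def to_jsonl(self) -> str:
        return "\n".join(
            json.dumps({"session": self.session_id, **e}, default=str)
            for e in self.entries
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_jsonl() + "\n")


def audit_openings(
    transcript: Transcript,
    sensitive_values: Iterable[float],
    *,
    decoder=None,
    atol: float = 1e-6,
) -> list[dict[str, Any]]:
    """Return masked openings whose decoded value collides with a sensitive
    intermediate. An empty list means the transcript never opened an
    unmasked intermediate.

    ``decoder`` maps a logged ring integer to a real value; identity for
    already-real entries.
    """
    sens = list(sensitive_values)
    violations = []
    for e in transcript.masked_openings():
        v = e["value"]
        if not isinstance(v, (int, float)):
            continue
        x = decoder(v) if decoder is not None else float(v)
        for s in sens:
            if abs(x - s) <= atol * max(1.0, abs(s)):
                violations.append({**e, "collides_with": s})
                break
    return violations
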