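"""Plain-text ``key = value`` configuration files.

One flat namespace per file; blank lines and ``#`` comments ignored. Values
are parsed as float where possible, otherwise kept as strings. Consumers
(dataclass constructors) reject unknown keys, so typos fail fast.
"""

from __future__ import annotations

import os
from typing import Any


def parse_config_text(text: str) -> dict[str, Any]:
    """Parse ``key = value`` lines into a dict.

    Raises ``ValueError`` on malformed lines (no ``=``) or duplicate keys.
    """
    out: dict[str, Any] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if not key:
            raise ValueError(f"line {lineno}: empty key")
        if key in out:
            raise ValueError(f"line {lineno}: duplicate key {key!r}")
        out[key] = _coerce(value)
    return out


def read_config(path: str | os.PathLike) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return parse_config_text(fh.read())


def _coerce(value: str) -> Any:
    low = value.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        f = float(value)
    except ValueError:
        return value
    if f == int(f) and "." not in value and "e" not in low:
        return int(f)
    return f


def format_config(mapping: dict[str, Any], header: str | None = None) -> str:
    """Render a dict back to ``key = value`` text (used to persist the
    fully-resolved configuration next to run outputs)."""
    lines = []
    if header:
        lines.extend(f"# {h}" for h in header.splitlines())
    for key, value in mapping.items():
        lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"
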