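"""JSON Lines helpers with byte-stable serialization."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Iterator


def dumps_canonical(obj: Any) -> str:
    """Serialize with sorted keys and no insignificant whitespace."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def write_jsonl(path: str | Path, records: Iterable[dict]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(dumps_canonical(rec))
            fh.write("\n")


def read_jsonl(path: str | Path) -> Iterator[dict]:
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)
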