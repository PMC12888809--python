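"""Gene identifier resolution to HGNC symbols.

The gene benchmark needs each gene/protein CURIE mapped to official HGNC
symbols.  Resolution is an injected contract so that an offline mapping table
(the default) and a live identifier service (an optional plugin) are
interchangeable.  A CURIE resolving to zero symbols is treated as deprecated;
one resolving to two or more is ambiguous — both are excluded upstream.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Protocol, Sequence, runtime_checkable

__all__ = ["GeneResolver", "MappingResolver"]


@runtime_checkable
class GeneResolver(Protocol):
    def resolve(self, curie: str) -> tuple[str, ...]:
        """Return zero, one, or many HGNC symbols for a gene/protein CURIE."""
        ...


class MappingResolver:
    """Deterministic resolver backed by an in-memory mapping table.

    The table maps CURIE -> sequence of HGNC symbols. Unknown CURIEs resolve
    to zero symbols.
    """

    def __init__(self, table: Mapping[str, Sequence[str]]):
        self._table = {k: tuple(v) for k, v in table.items()}

    def resolve(self, curie: str) -> tuple[str, ...]:
        return self._table.get(curie, ())

    @classmethod
    def from_file(cls, path: str | Path) -> "MappingResolver":
        """Load a JSON mapping file ``{curie: [symbol, ...]}``."""
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    def to_file(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump({k: list(v) for k, v in sorted(self._table.items())}, fh, indent=1)
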