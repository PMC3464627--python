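"""Genome description shared by tracks, enrichment and I/O."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator


@dataclass(frozen=True)
class GenomeSizes:
    """Ordered mapping of sequence name to length (bp)."""

    items: tuple[tuple[str, int], ...]

    def __init__(self, items: Iterable[tuple[str, int]] | dict):
        if isinstance(items, dict):
            items = items.items()
        tup = tuple((str(n), int(l)) for n, l in items)
        names = [n for n, _ in tup]
        if len(set(names)) != len(names):
            raise ValueError("duplicate sequence names in genome sizes")
        if any(l <= 0 for _, l in tup):
            raise ValueError("sequence lengths must be > 0")
        object.__setattr__(self, "items", tup)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.items]

    def __getitem__(self, name: str) -> int:
        for n, l in self.items:
            if n == name:
                return l
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(n == name for n, _ in self.items)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.items)
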