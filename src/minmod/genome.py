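"""Chromosome-size bookkeeping (1-based inclusive site coordinates)."""

from __future__ import annotations

from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field


@dataclass(frozen=True)
class ChromSizes(Mapping):
    """Mapping chromosome name -> length in bp.

    Site positions throughout the package are 1-based inclusive; BED-style
    outputs convert to 0-based half-open at the boundary.
    """

    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __getitem__(self, name: str) -> int:
        try:
            return self.sizes[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.sizes)

    def __len__(self) -> int:
        return len(self.sizes)

    @property
    def autosomes(self) -> list[str]:
        """Chromosome names excluding the sex chromosomes."""
        return [c for c in self.sizes if c.upper() not in {"X", "Y"}]

    @property
    def total_bp(self) -> int:
        return sum(self.sizes.values())
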