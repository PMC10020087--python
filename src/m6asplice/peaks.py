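"""m6A peak intervals with summits (0-based half-open coordinates)."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Peak:
    contig: str
    start: int
    end: int
    summit: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"peak {self.contig}:{self.start}-{self.end} is empty")
        if not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside peak "
                f"{self.contig}:{self.start}-{self.end}"
            )


@dataclass
class PeakSet:
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def contigs(self) -> set[str]:
        return {p.contig for p in self.peaks}
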