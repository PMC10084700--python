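"""Labeled behavioral intervals (bouts) over one deployment.

A :class:`BoutSet` is an ordered, non-overlapping partition of (part of) a
deployment timeline into labeled intervals.  Candidate bouts come out of the
HMM state path; the post-processing rule chain relabels and reshapes them
into finalized brooding bouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

#: Allowed interval labels.
LABELS = ("brooding", "active", "other_inactive")


@dataclass(frozen=True)
class Bout:
    """One labeled half-open interval [start_s, end_s) in deployment seconds."""

    start_s: float
    end_s: float
    label: str
    provenance: str = "hmm"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(
                f"bout end ({self.end_s}) must exceed start ({self.start_s})"
            )
        if self.label not in LABELS:
            raise ValueError(f"unknown bout label {self.label!r}")


@dataclass
class BoutSet:
    """Ordered, non-overlapping labeled intervals for one chick."""

    chick_id: str
    bouts: list[Bout] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for prev, cur in zip(self.bouts, self.bouts[1:]):
            if cur.start_s < prev.end_s - 1e-9:
                raise ValueError(
                    f"overlapping bouts: [{prev.start_s}, {prev.end_s}) and "
                    f"[{cur.start_s}, {cur.end_s})"
                )

    def __len__(self) -> int:
        return len(self.bouts)

    def __iter__(self) -> Iterator[Bout]:
        return iter(self.bouts)

    def with_bouts(self, bouts: Iterable[Bout]) -> "BoutSet":
        return BoutSet(self.chick_id, sorted(bouts, key=lambda b: b.start_s))

    def select(self, label: str) -> list[Bout]:
        return [b for b in self.bouts if b.label == label]

    def total_duration(self, label: str | None = None) -> float:
        return sum(
            b.duration_s for b in self.bouts if label is None or b.label == label
        )

    def relabel(self, index: int, label: str, provenance: str) -> None:
        self.bouts[index] = replace(
            self.bouts[index], label=label, provenance=provenance
        )
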