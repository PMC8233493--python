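"""Genomic masks: repeat-like random masks, centromeres, exon masks."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import numpy as np

__all__ = ["MaskSet", "sample_repeat_masks", "centromere_mask", "exon_mask_set"]


def _merge(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


@dataclass
class MaskSet:
    """Half-open masked intervals per chromosome, merged and sorted."""

    intervals: dict[int, tuple[tuple[int, int], ...]] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        self.intervals = {c: _merge(ivs) for c, ivs in self.intervals.items()}

    def masked_bp(self, chrom: int = 0) -> int:
        return sum(e - s for s, e in self.intervals.get(chrom, ()))

    def is_masked(self, chrom: int, positions: np.ndarray) -> np.ndarray:
        """Boolean vector: True where a position falls in a masked interval."""
        positions = np.asarray(positions)
        out = np.zeros(positions.shape, dtype=bool)
        ivs = self.intervals.get(chrom, ())
        if not ivs:
            return out
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = idx >= 0
        out[valid] = positions[valid] < ends[idx[valid]]
        return out

    def union(self, other: "MaskSet") -> "MaskSet":
        chroms = set(self.intervals) | set(other.intervals)
        return MaskSet(
            intervals={
                c: _merge(list(self.intervals.get(c, ())) + list(other.intervals.get(c, ())))
                for c in chroms
            },
            label=f"{self.label}+{other.label}".strip("+"),
        )


def sample_repeat_masks(
    chrom_length: int,
    fraction: float,
    length_sampler: Callable[[np.random.Generator], float],
    rng: np.random.Generator,
    chrom: int = 0,
    max_tries: int = 100_000,
) -> MaskSet:
    """Random non-overlapping segments totalling ``fraction`` of a chromosome.

    Segment lengths come from ``length_sampler`` (emulating e.g. the human
    repeat-length distribution); segments are placed uniformly without
    overlap until the masked total reaches ``fraction * chrom_length``, the
    last segment being truncated to hit the target exactly.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    target = fraction * chrom_length
    placed: list[tuple[int, int]] = []
    total = 0
    tries = 0
    while total < target:
        ln = int(round(length_sampler(rng)))
        if ln <= 0:
            raise ValueError("length_sampler produced a non-positive length")
        ln = min(ln, int(target - total) or 1)
        start = int(rng.integers(0, max(chrom_length - ln, 1)))
        cand = (start, start + ln)
        if any(cand[0] < e and s < cand[1] for s, e in placed):
            tries += 1
            if tries > max_tries:
                raise RuntimeError("could not place non-overlapping mask segments")
            continue
        placed.append(cand)
        total += ln
    return MaskSet(intervals={chrom: tuple(placed)}, label="repeats")


def centromere_mask(
    chrom_length: int, chroms: Iterable[int] = (0,)
) -> MaskSet:
    """The fixed 4 Mb centromeric mask at 48.5-52.5 Mb of a 150 Mb chromosome."""
    start, end = 48_500_000, 52_500_000
    if chrom_length < end:
        raise ValueError(f"chromosome of {chrom_length} bp has no centromere at 48.5-52.5 Mb")
    return MaskSet(intervals={c: ((start, end),) for c in chroms}, label="centromere")


def exon_mask_set(layout, chroms: Iterable[int] = (0,)) -> MaskSet:
    """Mask covering the exonic (directly selected) intervals of a layout."""
    return MaskSet(
        intervals={c: tuple(layout.exon_intervals) for c in chroms}, label="exons"
    )
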