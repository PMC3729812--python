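"""Candidate loci → fixed 50-kb analysis windows, and locus clustering.

Risk loci reported by association studies vary in length.  The scan scores
fixed-size windows: a locus no longer than the window is replaced by one
window centred on its midpoint (±25 kb by default); a longer locus is tiled
with ⌊L/50 kb⌋ consecutive non-overlapping windows anchored at its start,
dropping any trailing remainder shorter than a full window.

Loci that lie close together on one chromosome are not genetically
independent; ``cluster_loci`` groups them by single linkage at a configurable
gap (2 Mb by default) so network-level tests can collapse each cluster to a
single representative.

All coordinates are 0-based, half-open (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["Region", "WINDOW_SIZE", "MIN_INDEPENDENT_GAP", "build_windows", "cluster_loci"]

WINDOW_SIZE = 50_000
MIN_INDEPENDENT_GAP = 2_000_000


@dataclass(frozen=True)
class Region:
    """A half-open genomic interval with optional provenance labels."""

    chrom: str
    start: int
    end: int
    source_locus: str = ""
    cluster_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.start < 0:
            raise ValueError(f"negative start {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def build_windows(loci: Sequence[Region], window: int = WINDOW_SIZE) -> list[Region]:
    """Convert candidate loci into fixed-size analysis windows.

    A locus of length <= ``window`` yields one window centred on its midpoint;
    a longer locus yields ``floor(L / window)`` consecutive windows tiled from
    its start (remainder dropped).  A centred window that would extend below
    position 0 is rejected with a ``ValueError``.  Windows inherit the source
    locus label; windows tiled from one locus are suffixed ``.1``, ``.2``, ...
    """
    out: list[Region] = []
    for locus in loci:
        name = locus.source_locus or f"{locus.chrom}:{locus.start}-{locus.end}"
        if locus.length <= window:
            mid = (locus.start + locus.end) // 2
            start = mid - window // 2
            if start < 0:
                raise ValueError(
                    f"window for locus {name} would start at {start} < 0; "
                    "loci this close to the chromosome start cannot be centred"
                )
            out.append(Region(locus.chrom, start, start + window, source_locus=name,
                              cluster_id=locus.cluster_id))
        else:
            n_tiles = locus.length // window
            for k in range(n_tiles):
                start = locus.start + k * window
                out.append(
                    Region(locus.chrom, start, start + window,
                           source_locus=f"{name}.{k + 1}", cluster_id=locus.cluster_id)
                )
    return out


def cluster_loci(loci: Sequence[Region], min_gap: int = MIN_INDEPENDENT_GAP) -> list[Region]:
    """Assign cluster ids by single-linkage proximity.

    Loci on the same chromosome whose inter-interval gap is smaller than
    ``min_gap`` share a cluster (transitively); loci on different chromosomes
    never do.  Returns new ``Region`` objects in the input order with
    ``cluster_id`` set to ``"<chrom>:<smallest start in cluster>"``, so the
    assignment is invariant to input order.
    """
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].start, loci[i].end))
    cluster_start: dict[int, int] = {}  # input index -> representative start of its chain
    chain_chrom: str | None = None
    chain_max_end = -1
    chain_rep = -1
    for i in order:
        loc = loci[i]
        # single linkage on sorted intervals: a chain extends while the gap to
        # the furthest end seen so far stays below min_gap
        if loc.chrom == chain_chrom and loc.start - chain_max_end < min_gap:
            chain_max_end = max(chain_max_end, loc.end)
        else:
            chain_chrom = loc.chrom
            chain_rep = loc.start
            chain_max_end = loc.end
        cluster_start[i] = chain_rep

    return [
        replace(loci[i], cluster_id=f"{loci[i].chrom}:{cluster_start[i]}")
        for i in range(len(loci))
    ]
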