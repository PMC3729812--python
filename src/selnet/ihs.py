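"""Network randomization test on precomputed normalized iHS scores.

The integrated haplotype score (iHS) is a standardized haplotype-decay
statistic; extreme values of either sign mark recent positive selection.
Scores are consumed here as a precomputed position-scored track.

The test asks whether a candidate set of genomic regions (a "network", e.g.
the loci of a disease-risk gene set) carries stronger sweep signals than
random sets of loci: the observed statistic is the mean over regions of each
region's maximum |score|, and its null distribution comes from many random
networks of the same size, with same-chromosome loci forced at least 2 Mb
apart so the random loci are effectively independent.  The reported p-value
is the fraction of random networks whose mean is as high or higher; ties
count and no pseudo-count is added, so p may be exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import MIN_INDEPENDENT_GAP, Region, WINDOW_SIZE

__all__ = [
    "IhsTrack",
    "NetworkScore",
    "region_max_ihs",
    "sample_random_network",
    "sample_random_networks",
    "randomization_p",
]


class IhsTrack:
    """Genome-positioned normalized scores, sorted within each chromosome."""

    def __init__(self, df: pd.DataFrame, chrom_lengths: Mapping[str, int] | None = None):
        required = {"chrom", "pos", "score"}
        if not required <= set(df.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if not np.isfinite(df["score"]).all():
            raise ValueError("track scores must be finite")
        df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            df = df.drop_duplicates(["chrom", "pos"], keep="first").reset_index(drop=True)
        self.df = df
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {
            str(c): (g["pos"].to_numpy(np.int64), g["score"].to_numpy(float))
            for c, g in df.groupby("chrom", sort=True)
        }
        if chrom_lengths is None:
            chrom_lengths = {c: int(p.max()) + 1 for c, (p, _) in self._by_chrom.items()}
        self.chrom_lengths = dict(chrom_lengths)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        return self._by_chrom[str(chrom)]

    def _rmq(self, chrom: str, signed: bool) -> list[np.ndarray]:
        """Cached range-maximum sparse table over scores (or |scores|)."""
        if not hasattr(self, "_rmq_cache"):
            self._rmq_cache: dict[tuple[str, bool], list[np.ndarray]] = {}
        key = (str(chrom), signed)
        if key not in self._rmq_cache:
            _, score = self._by_chrom[str(chrom)]
            vals = score if signed else np.abs(score)
            self._rmq_cache[key] = _sparse_table(vals)
        return self._rmq_cache[key]

    def site_count(self, region: Region) -> int:
        if region.chrom not in self._by_chrom:
            return 0
        pos, _ = self._by_chrom[region.chrom]
        lo, hi = np.searchsorted(pos, (region.start, region.end))
        return int(hi - lo)


@dataclass
class NetworkScore:
    """Result of the network randomization test."""

    region_maxima: list[float]
    network_mean: float
    n_regions: int
    p_value: float
    n_random: int
    min_spacing: int
    n_unevaluable: int = 0


def region_max_ihs(region: Region, track: IhsTrack, signed: bool = False) -> float | None:
    """Highest score in a region: max |score| by default, max raw score with
    ``signed=True``.  Returns None when the region contains no scored site
    (unevaluable)."""
    if region.chrom not in track.chrom_lengths or track.site_count(region) == 0:
        return None
    pos, score = track.chrom_arrays(region.chrom)
    lo, hi = np.searchsorted(pos, (region.start, region.end))
    window = score[lo:hi]
    return float(window.max() if signed else np.abs(window).max())


def _sparse_table(vals: np.ndarray) -> list[np.ndarray]:
    """Range-maximum sparse table: level k holds max over vals[i : i + 2^k]."""
    levels = [vals]
    k = 1
    while (1 << k) <= len(vals):
        prev = levels[-1]
        span = 1 << (k - 1)
        levels.append(np.maximum(prev[: len(vals) - (1 << k) + 1],
                                 prev[span: span + len(vals) - (1 << k) + 1]))
        k += 1
    return levels


def _range_max(levels: list[np.ndarray], lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Vectorised max over half-open index ranges [lo, hi), all non-empty."""
    length = hi - lo
    out = np.empty(len(lo))
    k = np.floor(np.log2(length)).astype(np.int64)
    for kk in np.unique(k):
        m = k == kk
        tab = levels[kk]
        out[m] = np.maximum(tab[lo[m]], tab[hi[m] - (1 << int(kk))])
    return out


def _network_means(
    track: IhsTrack,
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    window: int,
    signed: bool,
) -> np.ndarray:
    """Mean per-network of per-window max scores; windows as (chrom_idx, start)
    arrays of shape (n_networks, n_regions), every window known non-empty."""
    chroms = sorted(track.chrom_lengths)
    maxima = np.empty(chrom_idx.shape, dtype=float)
    flat_c = chrom_idx.ravel()
    flat_s = starts.ravel()
    flat_m = maxima.ravel()
    for ci, chrom in enumerate(chroms):
        sel = np.flatnonzero(flat_c == ci)
        if len(sel) == 0:
            continue
        pos, _ = track.chrom_arrays(chrom)
        levels = track._rmq(chrom, signed)
        lo = np.searchsorted(pos, flat_s[sel])
        hi = np.searchsorted(pos, flat_s[sel] + window)
        flat_m[sel] = _range_max(levels, lo, hi)
    return maxima.mean(axis=1)


def sample_random_networks(
    track: IhsTrack,
    n_networks: int,
    n_regions: int,
    window: int = WINDOW_SIZE,
    min_spacing: int = MIN_INDEPENDENT_GAP,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    max_rounds: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw many spacing-constrained random networks at once.

    Windows are drawn uniformly over the track's chromosome lengths.  Within
    each network, a draw whose start is closer than ``min_spacing`` to any
    already-accepted same-chromosome start is rejected and redrawn, as is a
    window containing no scored site.  Returns ``(chrom_idx, starts)`` arrays
    of shape ``(n_networks, n_regions)``; chromosome indices refer to
    ``sorted(track.chrom_lengths)``.

    Raises ``RuntimeError`` when placement does not finish within
    ``max_rounds`` redraw rounds (infeasible genome/spacing combinations).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = sorted(track.chrom_lengths)
    lengths = np.array([track.chrom_lengths[c] for c in chroms], dtype=np.int64)
    if np.any(lengths < window):
        raise ValueError("every chromosome must be at least one window long")
    weights = (lengths - window + 1) / (lengths - window + 1).sum()

    # quick feasibility bound: capacity at min_spacing per chromosome
    capacity = int((np.maximum(lengths - window, 0) // min_spacing + 1).sum())
    if n_regions > capacity:
        raise ValueError(
            f"cannot place {n_regions} windows at spacing {min_spacing}: "
            f"genome capacity is {capacity}"
        )

    pos_sorted = {c: track.chrom_arrays(c)[0] for c in chroms}
    chrom_idx = np.empty((n_networks, n_regions), dtype=np.int64)
    starts = np.empty((n_networks, n_regions), dtype=np.int64)

    def attempt(n: int, inner_rounds: int = 50):
        """One placement pass over n networks; returns arrays plus an alive
        mask (False where a network stalled and must restart from scratch —
        an early accepted window can make later same-chromosome placements
        infeasible, so per-draw rejection alone may deadlock)."""
        c_out = np.empty((n, n_regions), dtype=np.int64)
        s_out = np.empty((n, n_regions), dtype=np.int64)
        alive = np.ones(n, dtype=bool)
        for j in range(n_regions):
            pending = np.flatnonzero(alive)
            rounds = 0
            while len(pending):
                rounds += 1
                if rounds > inner_rounds:
                    alive[pending] = False
                    break
                c = rng.choice(len(chroms), size=len(pending), p=weights)
                offs = rng.random(len(pending))
                s = (offs * (lengths[c] - window + 1)).astype(np.int64)
                # reject empty windows
                has_site = np.zeros(len(pending), dtype=bool)
                for ci in np.unique(c):
                    m = c == ci
                    pos = pos_sorted[chroms[ci]]
                    lo = np.searchsorted(pos, s[m])
                    hi = np.searchsorted(pos, s[m] + window)
                    has_site[m] = hi > lo
                ok = has_site
                if j > 0:
                    prev_c = c_out[pending, :j]
                    prev_s = s_out[pending, :j]
                    clash = (
                        (prev_c == c[:, None])
                        & (np.abs(prev_s - s[:, None]) < min_spacing)
                    ).any(axis=1)
                    ok = ok & ~clash
                accepted = pending[ok]
                c_out[accepted, j] = c[ok]
                s_out[accepted, j] = s[ok]
                pending = pending[~ok]
        return c_out, s_out, alive

    filled = 0
    passes = 0
    while filled < n_networks:
        passes += 1
        if passes > max_rounds:
            raise RuntimeError(
                f"window placement stalled after {passes - 1} passes "
                f"({n_networks - filled} networks unplaced); genome too small "
                f"for {n_regions} windows at spacing {min_spacing}"
            )
        c_out, s_out, alive = attempt(n_networks - filled)
        k = int(alive.sum())
        chrom_idx[filled:filled + k] = c_out[alive]
        starts[filled:filled + k] = s_out[alive]
        filled += k
    return chrom_idx, starts


def sample_random_network(
    track: IhsTrack,
    n_regions: int,
    window: int = WINDOW_SIZE,
    min_spacing: int = MIN_INDEPENDENT_GAP,
    seed: int | None = None,
    max_rounds: int = 1000,
) -> list[Region]:
    """Draw one spacing-constrained random network as ``Region`` objects."""
    chrom_idx, starts = sample_random_networks(
        track, 1, n_regions, window=window, min_spacing=min_spacing,
        seed=seed, max_rounds=max_rounds,
    )
    chroms = sorted(track.chrom_lengths)
    return [
        Region(chroms[c], int(s), int(s) + window, source_locus=f"random_{k}")
        for k, (c, s) in enumerate(zip(chrom_idx[0], starts[0]))
    ]


def randomization_p(
    network_regions: Sequence[Region],
    track: IhsTrack,
    n_random: int = 100_000,
    seed: int | None = None,
    collapse_clusters: bool = False,
    n_cluster_draws: int = 10,
    window: int = WINDOW_SIZE,
    min_spacing: int = MIN_INDEPENDENT_GAP,
    signed: bool = False,
) -> NetworkScore:
    """Randomization p-value for a candidate network's mean top score.

    The observed statistic is the mean over evaluable regions of the region
    maximum score.  With ``collapse_clusters`` one region is drawn uniformly
    per ``cluster_id``, the network mean is computed, and the statistic is the
    average over ``n_cluster_draws`` such draws (non-independent nearby loci
    then contribute once).  Random networks match the (collapsed) region
    count.  ``p = #(random mean >= observed mean) / n_random``.
    """
    rng = np.random.default_rng(seed)
    maxima: dict[int, float] = {}
    unevaluable = 0
    evaluable: list[int] = []
    for i, r in enumerate(network_regions):
        m = region_max_ihs(r, track, signed=signed)
        if m is None:
            unevaluable += 1
        else:
            maxima[i] = m
            evaluable.append(i)
    if not evaluable:
        raise ValueError("no candidate region overlaps a scored site")

    if collapse_clusters:
        clusters: dict[str, list[int]] = {}
        for i in evaluable:
            key = network_regions[i].cluster_id or f"__solo_{i}"
            clusters.setdefault(key, []).append(i)
        members = list(clusters.values())
        draws = np.empty(n_cluster_draws)
        for d in range(n_cluster_draws):
            picks = [m[rng.integers(len(m))] for m in members]
            draws[d] = np.mean([maxima[i] for i in picks])
        observed = float(draws.mean())
        n_regions = len(members)
    else:
        observed = float(np.mean([maxima[i] for i in evaluable]))
        n_regions = len(evaluable)

    chrom_idx, starts = sample_random_networks(
        track, n_random, n_regions, window=window, min_spacing=min_spacing, rng=rng
    )
    random_means = _network_means(track, chrom_idx, starts, window, signed)
    p = float(np.count_nonzero(random_means >= observed) / n_random)

    return NetworkScore(
        region_maxima=[maxima[i] for i in evaluable],
        network_mean=observed,
        n_regions=n_regions,
        p_value=p,
        n_random=n_random,
        min_spacing=min_spacing,
        n_unevaluable=unevaluable,
    )
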