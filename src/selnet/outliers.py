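"""Region outlier scan: high-F_ST fractions, empirical P-values, network test.

The scan scores each candidate 50-kb region by the fraction of its qualifying
SNPs whose F_ST exceeds the genome-wide 99% empirical boundary for the
comparison (estimated from a large random SNP sample; 2,200,000 at full
scale).  A region is flagged when that fraction exceeds 1%.

Significance is empirical: many same-size windows (11,000 at full scale) are
drawn uniformly from the genome and scored by the identical procedure; a
region's P-value is the fraction of random windows whose high-F_ST fraction
is as large or larger.  The test is one-tailed — it screens for an *excess*
of highly differentiated SNPs only.

At the network level, the count of regions significant at level α is compared
to a Binomial(m, α) upper tail.  Regions from the same locus cluster are
collapsed before counting so overlapping flanks are not double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .regions import Region, WINDOW_SIZE

__all__ = [
    "ThresholdEstimate",
    "RegionScore",
    "NetworkTestResult",
    "genome_threshold",
    "region_fraction",
    "score_regions",
    "sample_null_fractions",
    "empirical_p",
    "network_test",
]


@dataclass(frozen=True)
class ThresholdEstimate:
    """Genome-wide empirical significance boundary for one comparison."""

    comparison: str
    t99: float
    n_sampled: int
    q: float = 0.99


@dataclass(frozen=True)
class RegionScore:
    """One region's qualifying-SNP count, high-F_ST count and empirical P."""

    region: Region
    n_qualifying: int
    n_high: int
    fraction: float
    flagged: bool
    empirical_p: float | None = None
    evaluable: bool = True


@dataclass(frozen=True)
class NetworkTestResult:
    """Binomial excess test on the count of significant regions."""

    m: int
    k: int
    alpha: float
    network_p: float


def genome_threshold(
    fst_sample: np.ndarray, q: float = 0.99, comparison: str = ""
) -> ThresholdEstimate:
    """Empirical upper boundary of a qualifying-F_ST sample.

    Uses the inverse-ECDF (type-1) quantile: the smallest sampled value ``v``
    such that at least a fraction ``q`` of the sample is <= ``v``.  Outliers
    downstream are values *strictly greater* than the boundary, so at most
    ``1 − q`` of the estimation sample itself is an outlier.
    """
    v = np.asarray(fst_sample, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("empty F_ST sample")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    v = np.sort(v)
    idx = int(np.ceil(q * len(v))) - 1
    return ThresholdEstimate(comparison=comparison, t99=float(v[idx]), n_sampled=len(v))


def _fst_arrays(fst_table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q = fst_table["qualifying"].to_numpy(bool)
    return (
        fst_table["chrom"].to_numpy(),
        fst_table["pos"].to_numpy(np.int64),
        np.where(q, fst_table["fst"].to_numpy(float), np.nan),
    )


def region_fraction(
    region: Region, fst_table: pd.DataFrame, threshold: ThresholdEstimate
) -> RegionScore:
    """Score one region: fraction of qualifying SNPs above the boundary.

    Only qualifying SNPs enter numerator and denominator.  A region with no
    qualifying SNP (or lying outside the scanned extent) is unevaluable and
    is excluded from network counts.
    """
    return score_regions([region], fst_table, threshold)[0]


def score_regions(
    regions: Sequence[Region], fst_table: pd.DataFrame, threshold: ThresholdEstimate,
    flag_level: float = 0.01,
) -> list[RegionScore]:
    """Vectorised ``region_fraction`` over many regions."""
    chrom, pos, fst_q = _fst_arrays(fst_table)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for c in np.unique(chrom):
        m = chrom == c
        p = pos[m]
        f = fst_q[m]
        qual = ~np.isnan(f)
        # cumulative counts of qualifying / high-F_ST sites for O(log n) lookup
        cum_q = np.concatenate(([0], np.cumsum(qual)))
        cum_h = np.concatenate(([0], np.cumsum(qual & (f > threshold.t99))))
        by_chrom[str(c)] = (p, cum_q, cum_h)

    out: list[RegionScore] = []
    for r in regions:
        if r.chrom not in by_chrom:
            out.append(RegionScore(r, 0, 0, float("nan"), False, evaluable=False))
            continue
        p, cum_q, cum_h = by_chrom[r.chrom]
        lo, hi = np.searchsorted(p, (r.start, r.end))
        n_q = int(cum_q[hi] - cum_q[lo])
        n_h = int(cum_h[hi] - cum_h[lo])
        if n_q == 0:
            out.append(RegionScore(r, 0, 0, float("nan"), False, evaluable=False))
        else:
            f = n_h / n_q
            out.append(RegionScore(r, n_q, n_h, f, f > flag_level))
    return out


def sample_null_fractions(
    fst_table: pd.DataFrame,
    threshold: ThresholdEstimate,
    chrom_lengths: Mapping[str, int],
    n_random: int = 11_000,
    window: int = WINDOW_SIZE,
    seed: int | None = None,
    max_rounds: int = 1000,
) -> np.ndarray:
    """High-F_ST fractions of random same-size genomic windows.

    Windows are drawn uniformly over the chromosome lengths (with
    replacement; overlap between draws is allowed).  A window with zero
    qualifying SNPs is redrawn, so every returned fraction is defined.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=np.int64)
    if np.any(lengths < window):
        raise ValueError("every chromosome must be at least one window long")
    weights = (lengths - window + 1) / (lengths - window + 1).sum()

    chrom, pos, fst_q = _fst_arrays(fst_table)
    per_chrom = {}
    for ci, c in enumerate(chroms):
        m = chrom == c
        p = pos[m]
        f = fst_q[m]
        qual = ~np.isnan(f)
        cum_q = np.concatenate(([0], np.cumsum(qual)))
        cum_h = np.concatenate(([0], np.cumsum(qual & (f > threshold.t99))))
        per_chrom[ci] = (p, cum_q, cum_h)

    fractions = np.empty(n_random)
    pending = np.arange(n_random)
    rounds = 0
    while len(pending):
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError(
                f"{len(pending)} random windows still empty after {max_rounds} "
                "redraw rounds; the scanned genome has too few qualifying SNPs"
            )
        c = rng.choice(len(chroms), size=len(pending), p=weights)
        offs = rng.random(len(pending))
        s = (offs * (lengths[c] - window + 1)).astype(np.int64)
        got = np.zeros(len(pending), dtype=bool)
        vals = np.empty(len(pending))
        for ci in np.unique(c):
            m = c == ci
            p, cum_q, cum_h = per_chrom[ci]
            lo = np.searchsorted(p, s[m])
            hi = np.searchsorted(p, s[m] + window)
            n_q = cum_q[hi] - cum_q[lo]
            n_h = cum_h[hi] - cum_h[lo]
            with np.errstate(divide="ignore", invalid="ignore"):
                vals[m] = np.where(n_q > 0, n_h / np.maximum(n_q, 1), np.nan)
            got[m] = n_q > 0
        fractions[pending[got]] = vals[got]
        pending = pending[~got]
    return fractions


def empirical_p(
    scores: Sequence[RegionScore] | RegionScore,
    null_fractions: np.ndarray,
) -> list[RegionScore] | RegionScore:
    """Attach empirical P-values from a shared null-window fraction sample.

    ``P = #(null fraction >= observed fraction) / n_random``; ties count, no
    pseudo-count is added (P may be exactly 0).  The same null sample should
    be reused for every region of one comparison, which makes P monotone
    non-increasing in the observed fraction.
    """
    single = isinstance(scores, RegionScore)
    items = [scores] if single else list(scores)
    null = np.sort(np.asarray(null_fractions, dtype=float))
    n = len(null)
    out = []
    for s in items:
        if not s.evaluable:
            out.append(s)
            continue
        n_ge = n - np.searchsorted(null, s.fraction, side="left")
        out.append(replace(s, empirical_p=float(n_ge / n)))
    return out[0] if single else out


def network_test(
    scores: Sequence[RegionScore], alpha: float = 0.05, by_cluster: bool = True
) -> NetworkTestResult:
    """Binomial upper-tail test for an excess of significant regions.

    ``m`` counts evaluable regions (collapsed to locus clusters when
    ``by_cluster``, so overlapping flanks of nearby loci count once);
    ``k`` counts those with empirical P < alpha (a cluster is significant
    when any of its regions is).  ``network_p = P(X >= k)`` for
    ``X ~ Binomial(m, alpha)``.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    usable = [s for s in scores if s.evaluable and s.empirical_p is not None]
    if not usable:
        raise ValueError("no evaluable regions with empirical P-values")
    if by_cluster:
        best: dict[str, float] = {}
        for i, s in enumerate(usable):
            key = s.region.cluster_id or f"__solo_{i}"
            best[key] = min(best.get(key, 1.0), s.empirical_p)
        m = len(best)
        k = sum(1 for p in best.values() if p < alpha)
    else:
        m = len(usable)
        k = sum(1 for s in usable if s.empirical_p < alpha)
    network_p = float(stats.binom.sf(k - 1, m, alpha))
    return NetworkTestResult(m=m, k=k, alpha=alpha, network_p=network_p)
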