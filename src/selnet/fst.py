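"""Sample-weighted F_ST from per-population allele counts.

The estimator is the mean-squares (ANOVA) form of F_ST computed from allele
counts in ``r`` population samples.  For population ``i`` let ``n_i`` be the
number of sampled chromosomes (twice the number of non-missing diploid
individuals), ``p_i = a_i / n_i`` the sample alternate-allele frequency and
``p̄ = Σ n_i p_i / Σ n_i`` the weighted mean frequency.  With

    MSP = Σ n_i (p_i − p̄)² / (r − 1)          (between-sample mean square)
    MSG = Σ n_i p_i (1 − p_i) / Σ (n_i − 1)    (within-sample mean square)
    n_c = (Σ n_i − Σ n_i² / Σ n_i) / (r − 1)   (corrected average sample size)

the per-site estimate is

    F_ST = (MSP − MSG) / (MSP + (n_c − 1) MSG).

The estimate is bounded above by 1 (MSG = 0 with MSP > 0 gives exactly 1) and
may be negative; identical sample frequencies give −1/(n_c − 1).  A site at
which every sample is fixed for the same allele has MSP = MSG = 0 and no
defined estimate; such sites are flagged monomorphic.

A site is *qualifying* when its estimate is defined and strictly positive;
downstream outlier fractions count qualifying sites only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SiteCounts",
    "FstValue",
    "weighted_fst",
    "fst_two_groups",
    "multilocus_fst",
    "pairwise_scan",
]

MIN_CHROMOSOMES = 2  # a population sample needs >= 1 non-missing diploid


@dataclass(frozen=True)
class SiteCounts:
    """Allele counts for one biallelic site across ``r`` population samples.

    Parameters
    ----------
    n : chromosome counts per population (2 × non-missing individuals).
    a : alternate-allele counts per population, ``0 <= a_i <= n_i``.
    """

    n: tuple[int, ...]
    a: tuple[int, ...]

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        a = np.asarray(self.a)
        if n.shape != a.shape or n.ndim != 1:
            raise ValueError("n and a must be 1-d and of equal length")
        if len(n) < 2:
            raise ValueError("at least two populations are required")
        if np.any(a < 0) or np.any(a > n):
            raise ValueError("allele counts must satisfy 0 <= a_i <= n_i")


@dataclass(frozen=True)
class FstValue:
    """Per-site estimate with its qualifying status.

    ``value`` is NaN for monomorphic (undefined) sites; ``qualifying`` is True
    iff the estimate is defined and strictly positive.
    """

    value: float
    qualifying: bool
    monomorphic: bool = False
    site_id: str | None = None


def _mean_squares(n: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    r = len(n)
    n_tot = n.sum()
    p = a / n
    p_bar = (n * p).sum() / n_tot
    msp = (n * (p - p_bar) ** 2).sum() / (r - 1)
    msg = (n * p * (1.0 - p)).sum() / (n - 1).sum()
    n_c = (n_tot - (n**2).sum() / n_tot) / (r - 1)
    return msp, msg, n_c


def weighted_fst(counts: SiteCounts, site_id: str | None = None) -> FstValue:
    """Weighted F_ST for one site.

    Populations with fewer than two sampled chromosomes are dropped; if fewer
    than two populations remain the site cannot be evaluated and a
    ``ValueError`` is raised (scans skip and log such sites instead).
    """
    n = np.asarray(counts.n, dtype=float)
    a = np.asarray(counts.a, dtype=float)
    keep = n >= MIN_CHROMOSOMES
    n, a = n[keep], a[keep]
    if len(n) < 2:
        raise ValueError("fewer than two populations with n_i >= 2")
    msp, msg, n_c = _mean_squares(n, a)
    if msp == 0.0 and msg == 0.0:
        return FstValue(float("nan"), False, monomorphic=True, site_id=site_id)
    value = (msp - msg) / (msp + (n_c - 1.0) * msg)
    return FstValue(value, bool(value > 0.0), site_id=site_id)


def fst_two_groups(
    n_a: np.ndarray, alt_a: np.ndarray, n_b: np.ndarray, alt_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-sample weighted F_ST over many sites.

    Parameters are per-site chromosome and alternate-allele counts for the two
    (possibly pooled) samples.  Returns ``(fst, qualifying, status)`` where
    ``fst`` is NaN wherever undefined, and ``status`` codes each site:
    0 = ok, 1 = monomorphic in both samples, 2 = skipped (a sample has fewer
    than two chromosomes).
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    alt_a = np.asarray(alt_a, dtype=float)
    alt_b = np.asarray(alt_b, dtype=float)

    status = np.zeros(n_a.shape, dtype=np.int8)
    skipped = (n_a < MIN_CHROMOSOMES) | (n_b < MIN_CHROMOSOMES)
    status[skipped] = 2

    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = alt_a / n_a
        p_b = alt_b / n_b
        n_tot = n_a + n_b
        p_bar = (alt_a + alt_b) / n_tot
        msp = n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2  # r - 1 = 1
        msg = (n_a * p_a * (1 - p_a) + n_b * p_b * (1 - p_b)) / (n_tot - 2.0)
        n_c = n_tot - (n_a**2 + n_b**2) / n_tot
        fst = (msp - msg) / (msp + (n_c - 1.0) * msg)

    mono = (msp == 0.0) & (msg == 0.0) & ~skipped
    status[mono] = 1
    fst[mono | skipped] = np.nan
    qualifying = np.where(np.isnan(fst), False, fst > 0.0)
    return fst, qualifying, status


def multilocus_fst(fst_table: pd.DataFrame) -> tuple[float, float]:
    """Genome-wide weighted F_ST across a scan: ratio of summed mean squares.

    The combined estimate ``Σ(MSP − MSG) / Σ(MSP + (n_c − 1) MSG)`` over all
    evaluable sites is the standard multi-locus form of the estimator; unlike
    the mean of per-site ratios it is consistent for the drift parameter
    under the Balding–Nichols model.  Returns ``(estimate, standard_error)``
    with a linearisation (delta-method) standard error over sites.
    """
    ok = fst_table["status"].to_numpy() == 0
    n_a = fst_table["n_A"].to_numpy(float)[ok]
    n_b = fst_table["n_B"].to_numpy(float)[ok]
    p_a = fst_table["p_A"].to_numpy(float)[ok]
    p_b = fst_table["p_B"].to_numpy(float)[ok]
    if len(n_a) == 0:
        raise ValueError("no evaluable sites in the scan")
    n_tot = n_a + n_b
    p_bar = (n_a * p_a + n_b * p_b) / n_tot
    msp = n_a * (p_a - p_bar) ** 2 + n_b * (p_b - p_bar) ** 2
    msg = (n_a * p_a * (1 - p_a) + n_b * p_b * (1 - p_b)) / (n_tot - 2.0)
    n_c = n_tot - (n_a**2 + n_b**2) / n_tot
    num = msp - msg
    den = msp + (n_c - 1.0) * msg
    estimate = num.sum() / den.sum()
    resid = num - estimate * den
    se = float(np.sqrt(len(resid) * resid.var()) / den.sum())
    return float(estimate), se


def _group_counts(panel, sample_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = panel.genotypes[sample_idx, :]
    present = g >= 0
    n = 2 * present.sum(axis=0)
    alt = np.where(present, g, 0).sum(axis=0)
    return n.astype(np.int64), alt.astype(np.int64)


def pairwise_scan(
    panel,
    group_a: Iterable[str],
    group_b: Iterable[str],
    sites: "tuple[str, int, int] | None" = None,
) -> pd.DataFrame:
    """Per-site weighted F_ST between two pooled population groups.

    Each group is the union of its populations' samples treated as one sample
    (so ``r = 2`` always).  Per-site chromosome counts reflect non-missing
    genotypes only.  ``sites`` optionally restricts the scan to a half-open
    interval ``(chrom, start, end)``; an empty intersection yields an empty
    table, not an error.

    Returns a DataFrame in genome order with columns ``chrom, pos, id, n_A,
    n_B, p_A, p_B, fst, qualifying, status`` (status 0=ok, 1=monomorphic,
    2=skipped for insufficient data).  Skip counts are recorded in
    ``df.attrs["n_skipped"]`` and ``df.attrs["n_monomorphic"]``.
    """
    group_a = set(group_a)
    group_b = set(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"groups share populations: {sorted(group_a & group_b)}")

    pops = panel.samples["population"]
    idx_a = np.flatnonzero(pops.isin(group_a).to_numpy())
    idx_b = np.flatnonzero(pops.isin(group_b).to_numpy())
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("a group matched no samples in the panel")

    mask = np.ones(panel.n_snps, dtype=bool)
    if sites is not None:
        chrom, start, end = sites
        mask = (panel.chrom == chrom) & (panel.pos >= start) & (panel.pos < end)

    site_sel = np.flatnonzero(mask)
    n_a_all, alt_a_all = _group_counts(panel, idx_a)
    n_b_all, alt_b_all = _group_counts(panel, idx_b)
    n_a = n_a_all[site_sel]
    n_b = n_b_all[site_sel]
    alt_a = alt_a_all[site_sel]
    alt_b = alt_b_all[site_sel]

    fst, qualifying, status = fst_two_groups(n_a, alt_a, n_b, alt_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_a = np.where(n_a > 0, alt_a / np.maximum(n_a, 1), np.nan)
        p_b = np.where(n_b > 0, alt_b / np.maximum(n_b, 1), np.nan)

    df = pd.DataFrame(
        {
            "chrom": panel.chrom[site_sel],
            "pos": panel.pos[site_sel],
            "id": panel.ids[site_sel],
            "n_A": n_a,
            "n_B": n_b,
            "p_A": p_a,
            "p_B": p_b,
            "fst": fst,
            "qualifying": qualifying,
            "status": status,
        }
    )
    df.attrs["n_skipped"] = int((status == 2).sum())
    df.attrs["n_monomorphic"] = int((status == 1).sum())
    df.attrs["group_a"] = sorted(group_a)
    df.attrs["group_b"] = sorted(group_b)
    return df
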