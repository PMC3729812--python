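"""Low-coverage ancient-genome heterozygosity versus modern panels.

A single ancient individual's mean multilocus heterozygosity (fraction of
heterozygous calls across a small set of risk SNPs) is compared to the
distribution of the same quantity across individuals of modern population
panels.  Low read depth hides heterozygotes: with ``c`` reads and no
sequencing error, a true heterozygote shows both alleles with probability
``1 − 2^(1−c)``.  Two resampling distributions quantify this:

* *expected* — genotypes drawn per site under Hardy–Weinberg at the modern
  reference derived-allele frequency ``q_s`` (het probability ``2q_s(1−q_s)``),
  repeated ``n_genotype_reps`` times (500 at full scale);
* *coverage-resampled* — for each such genotype vector, reads are resampled
  at the ancient individual's observed per-site depths ``n_read_reps`` times
  (2,500 at full scale; 500 × 2,500 = 1,250,000 values), a site scoring
  heterozygous only when both alleles are seen.

The coverage-resampled distribution is stochastically below the expected one;
if the ancient individual's observed value sits low even against the
coverage-resampled distribution, low coverage alone does not explain it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AncientSiteTable",
    "HetDistribution",
    "mean_observed_het",
    "panel_het_distribution",
    "simulate_expected_het",
    "resample_reads_het",
    "het_detection_probability",
    "percentile_placement",
]

CALL_CODES = {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": -1}
CALL_NAMES = {v: k for k, v in CALL_CODES.items()}


class AncientSiteTable:
    """Per-site read depth, genotype call and reference derived-allele
    frequency for one ancient individual.

    Wraps a DataFrame with columns ``site_id, chrom, pos, depth, call, freq``
    where ``call`` is coded 0=hom-ref, 1=het, 2=hom-alt, −1=missing.  Sites
    with depth 0 must be missing.
    """

    def __init__(self, df: pd.DataFrame):
        required = {"site_id", "chrom", "pos", "depth", "call", "freq"}
        if not required <= set(df.columns):
            raise ValueError(f"site table needs columns {sorted(required)}")
        if len(df) < 1:
            raise ValueError("site table must contain at least one site")
        if (df["depth"] < 0).any():
            raise ValueError("read depths must be non-negative")
        if ((df["depth"] == 0) & (df["call"] != -1)).any():
            raise ValueError("sites with depth 0 must have a missing call")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depths(self) -> np.ndarray:
        return self.df["depth"].to_numpy(np.int64)

    @property
    def calls(self) -> np.ndarray:
        return self.df["call"].to_numpy(np.int64)

    @property
    def freqs(self) -> np.ndarray:
        return self.df["freq"].to_numpy(float)

    @property
    def mean_depth(self) -> float:
        return float(self.depths.mean())


@dataclass
class HetDistribution:
    """A labelled sample of mean-heterozygosity values in [0, 1]."""

    label: str
    values: np.ndarray
    n_genotype_reps: int | None = None
    n_read_reps: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("mean heterozygosities must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def mean_observed_het(calls: np.ndarray) -> float:
    """Fraction of non-missing genotype calls that are heterozygous."""
    c = np.asarray(calls)
    present = c != -1
    if not present.any():
        raise ValueError("all calls are missing")
    return float((c[present] == 1).mean())


def panel_het_distribution(panel, sites, group: Iterable[str],
                           label: str = "") -> HetDistribution:
    """Per-individual mean heterozygosity across a site list, for one group.

    ``sites`` is a sequence of ``(chrom, pos)`` pairs or site ids; sites
    absent from the panel are dropped (count recorded in
    ``dist.values``-independent attribute ``n_dropped_sites`` on return).
    """
    sites = list(sites)
    if sites and isinstance(sites[0], str):
        wanted = pd.Index(panel.ids).get_indexer(sites)
    else:
        key = pd.Index(zip(panel.chrom.tolist(), panel.pos.tolist()))
        wanted = key.get_indexer([(c, p) for c, p in sites])
    found = wanted[wanted >= 0]
    n_dropped = int((wanted < 0).sum())
    if len(found) == 0:
        raise ValueError("none of the requested sites are present in the panel")

    idx = panel.sample_indices(group)
    if len(idx) == 0:
        raise ValueError("group matched no samples")
    g = panel.genotypes[np.ix_(idx, found)]
    present = g >= 0
    with np.errstate(invalid="ignore"):
        values = (g == 1).sum(axis=1) / present.sum(axis=1)
    dist = HetDistribution(label or "+".join(sorted(set(group))), values)
    dist.n_dropped_sites = n_dropped  # type: ignore[attr-defined]
    return dist


def simulate_expected_het(
    freqs: np.ndarray, n_reps: int = 500, seed: int | None = None,
    label: str = "expected",
) -> HetDistribution:
    """Mean heterozygosity expected from allele frequencies alone.

    Per replicate, a genotype is drawn per site under HWE at derived-allele
    frequency ``q_s`` (het with probability ``2 q_s (1 − q_s)``); the
    replicate's value is its fraction of heterozygous sites.
    """
    q = np.asarray(freqs, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    het_p = 2.0 * q * (1.0 - q)
    draws = rng.random((n_reps, len(q))) < het_p
    return HetDistribution(label, draws.mean(axis=1), n_genotype_reps=n_reps)


def het_detection_probability(depth: np.ndarray) -> np.ndarray:
    """P(both alleles of a heterozygote seen among c reads) = 1 − 2^(1−c)."""
    c = np.asarray(depth, dtype=float)
    return np.where(c > 0, 1.0 - 2.0 ** (1.0 - c), 0.0)


def resample_reads_het(
    freqs: np.ndarray,
    depths: np.ndarray,
    n_genotype_reps: int = 500,
    n_read_reps: int = 2500,
    seed: int | None = None,
    label: str = "coverage_resampled",
) -> HetDistribution:
    """Two-stage resampling: HWE genotypes, then reads at observed depths.

    For each of ``n_genotype_reps`` genotype vectors (drawn as in
    :func:`simulate_expected_het`; only heterozygous status matters, as a
    homozygote can never be read as heterozygous without an error model), every
    site is re-read ``n_read_reps`` times: ``c_s`` reads each copy one of the
    genotype's two alleles with probability 1/2, and the site scores
    heterozygous iff both alleles are observed.  Sites with depth 0 are
    excluded from the denominator.  Returns
    ``n_genotype_reps × n_read_reps`` values.
    """
    q = np.asarray(freqs, dtype=float)
    c = np.asarray(depths, dtype=np.int64)
    if len(q) != len(c):
        raise ValueError("freqs and depths must have equal length")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    if np.any(c < 0):
        raise ValueError("depths must be non-negative")
    keep = c > 0
    if not keep.any():
        raise ValueError("all sites have depth 0")
    q = q[keep]
    c = c[keep]
    s = len(q)

    rng = np.random.default_rng(seed)
    het_p = 2.0 * q * (1.0 - q)
    values = np.empty(n_genotype_reps * n_read_reps)
    for g in range(n_genotype_reps):
        het = rng.random(s) < het_p  # only heterozygotes can be called het
        n_het = int(het.sum())
        if n_het == 0:
            values[g * n_read_reps:(g + 1) * n_read_reps] = 0.0
            continue
        # alternate-allele reads at het sites; het called iff 0 < k < c
        k = rng.binomial(c[het], 0.5, size=(n_read_reps, n_het))
        called = (k > 0) & (k < c[het])
        values[g * n_read_reps:(g + 1) * n_read_reps] = called.sum(axis=1) / s
    return HetDistribution(
        label, values, n_genotype_reps=n_genotype_reps, n_read_reps=n_read_reps
    )


def percentile_placement(value: float, dist: HetDistribution) -> float:
    """Rank of ``value`` within a distribution as a fraction, ties averaged."""
    return float(stats.percentileofscore(dist.values, value, kind="mean") / 100.0)
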