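"""Synthetic genotype panels, iHS-like score tracks and ancient read pileups.

Every downstream stage of the scan is exercised on data with known ground
truth generated here.

*Genotype panels* follow the Balding–Nichols model: each SNP has an ancestral
allele frequency ``p`` (Uniform(0.05, 0.95) by default, so sites are mostly
segregating), and each population's frequency is an independent draw from
``Beta(p(1−F)/F, (1−p)(1−F)/F)`` — mean ``p``, variance ``F·p(1−p)`` — where
``F`` is the population's drift parameter.  Diploid genotypes are then
``Binomial(2, population frequency)`` per individual.  Under this model the
expectation of the weighted F_ST estimator equals ``F``, which gives a
parameter-recovery surface for testing the estimator.  SNPs inside a planted
``fst_shift`` sweep use the sweep's elevated ``F`` instead.

*iHS-like tracks* are standard-normal scores at uniformly placed positions;
an ``ihs_shift`` sweep adds a constant offset to scores inside its region,
mimicking the inflated |iHS| of a selective sweep.

*Ancient pileups* draw a Poisson read depth per site and copy one of the two
genotype alleles per read with probability 1/2 (no sequencing-error model);
a site is called heterozygous iff both alleles are observed, so a true
heterozygote at depth ``c`` is detected with probability ``1 − 2^(1−c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancient import AncientSiteTable
from .ihs import IhsTrack
from .panel import GenotypePanel
from .regions import Region

__all__ = [
    "PopulationSpec",
    "SweepSpec",
    "simulate_panel",
    "simulate_ihs_track",
    "simulate_pileup",
]

DEFAULT_ANCESTRAL_RANGE = (0.05, 0.95)
DEFAULT_BP_PER_SNP = 100  # ~10 SNPs/kb, full-depth variant-call density


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population sample."""

    name: str
    continent: str
    n_individuals: int
    divergence_F: float

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if not (0.0 <= self.divergence_F < 1.0):
            raise ValueError("divergence_F must lie in [0, 1)")


@dataclass(frozen=True)
class SweepSpec:
    """A planted selection signal over a half-open genomic interval.

    ``effect="fst_shift"`` replaces the drift parameter of every population by
    ``value`` for SNPs inside the region (must exceed every background F);
    ``effect="ihs_shift"`` adds ``value`` (> 0) to track scores in the region.
    """

    region: Region
    effect: str
    value: float

    def __post_init__(self) -> None:
        if self.effect not in ("fst_shift", "ihs_shift"):
            raise ValueError(f"unknown sweep effect {self.effect!r}")
        if self.effect == "ihs_shift" and self.value <= 0:
            raise ValueError("ihs_shift offset must be > 0")
        if self.effect == "fst_shift" and not (0.0 < self.value < 1.0):
            raise ValueError("fst_shift F must lie in (0, 1)")


def _check_sweeps(sweeps: Sequence[SweepSpec], effect: str,
                  background_F: float | None = None) -> list[SweepSpec]:
    sel = [s for s in sweeps if s.effect == effect]
    by_chrom: dict[str, list[SweepSpec]] = {}
    for s in sel:
        by_chrom.setdefault(s.region.chrom, []).append(s)
    for chrom_sweeps in by_chrom.values():
        chrom_sweeps.sort(key=lambda s: s.region.start)
        for a, b in zip(chrom_sweeps, chrom_sweeps[1:]):
            if b.region.start < a.region.end:
                raise ValueError(
                    f"overlapping sweep regions {a.region} and {b.region}"
                )
    if background_F is not None:
        for s in sel:
            if s.value <= background_F:
                raise ValueError(
                    f"sweep F {s.value} must exceed background F {background_F}"
                )
    return sel


def _place_positions(rng: np.random.Generator, chrom_lengths: Mapping[str, int],
                     n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    """Allocate sites to chromosomes ∝ length, positions uniform without ties."""
    chroms = list(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(n_sites, lengths / lengths.sum())
    chrom_col = []
    pos_col = []
    for c, k in zip(chroms, alloc):
        if k == 0:
            continue
        if k > chrom_lengths[c]:
            raise ValueError(f"chromosome {c} too short for {k} distinct sites")
        p = np.sort(rng.choice(chrom_lengths[c], size=k, replace=False))
        chrom_col.append(np.full(k, c, dtype=object))
        pos_col.append(p)
    return np.concatenate(chrom_col), np.concatenate(pos_col).astype(np.int64)


def _in_regions(chrom: np.ndarray, pos: np.ndarray, regions: Sequence[Region]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for r in regions:
        mask |= (chrom == r.chrom) & (pos >= r.start) & (pos < r.end)
    return mask


def simulate_panel(
    pops: Sequence[PopulationSpec],
    n_snps: int,
    sweeps: Sequence[SweepSpec] = (),
    seed: int = 0,
    chrom_lengths: Mapping[str, int] | None = None,
    ancestral_range: tuple[float, float] = DEFAULT_ANCESTRAL_RANGE,
    missing_rate: float = 0.0,
) -> GenotypePanel:
    """Simulate a multi-population diploid panel under Balding–Nichols drift.

    Parameters
    ----------
    pops : population specs (name, continent, sample size, drift F).
    n_snps : number of biallelic SNPs.
    sweeps : planted ``fst_shift`` regions (elevated drift inside the region).
    seed : RNG seed; identical seeds give bit-identical panels.
    chrom_lengths : genome layout; defaults to one chromosome sized for
        ~10 SNPs/kb.
    ancestral_range : support of the uniform ancestral-frequency draw.
    missing_rate : per-genotype missingness probability (default 0).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not pops:
        raise ValueError("at least one population is required")
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must lie in [0, 1)")
    background = max(p.divergence_F for p in pops)
    fst_sweeps = _check_sweeps(sweeps, "fst_shift", background_F=background)

    rng = np.random.default_rng(seed)
    if chrom_lengths is None:
        chrom_lengths = {"1": max(1_000_000, n_snps * DEFAULT_BP_PER_SNP)}
    chrom, pos = _place_positions(rng, chrom_lengths, n_snps)

    lo, hi = ancestral_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("ancestral_range must satisfy 0 < lo < hi < 1")
    anc = rng.uniform(lo, hi, size=n_snps)

    sweep_mask = _in_regions(chrom, pos, [s.region for s in fst_sweeps])
    sweep_F = np.zeros(n_snps)
    for s in fst_sweeps:
        m = (chrom == s.region.chrom) & (pos >= s.region.start) & (pos < s.region.end)
        sweep_F[m] = s.value

    rows = []
    sample_rows = []
    for spec in pops:
        F = np.where(sweep_mask, sweep_F, spec.divergence_F)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = anc * (1.0 - F) / F
            b = (1.0 - anc) * (1.0 - F) / F
        freq = np.where(F > 0, rng.beta(np.where(F > 0, a, 1.0), np.where(F > 0, b, 1.0)), anc)
        geno = rng.binomial(2, freq, size=(spec.n_individuals, n_snps)).astype(np.int8)
        rows.append(geno)
        sample_rows.extend(
            {"sample_id": f"{spec.name}_{i:04d}", "population": spec.name,
             "continent": spec.continent}
            for i in range(spec.n_individuals)
        )

    genotypes = np.vstack(rows)
    if missing_rate > 0:
        miss = rng.random(genotypes.shape) < missing_rate
        genotypes[miss] = -1

    return GenotypePanel(
        genotypes=genotypes,
        chrom=chrom,
        pos=pos,
        ids=np.array([f"snp_{c}_{p}" for c, p in zip(chrom, pos)], dtype=object),
        samples=pd.DataFrame(sample_rows),
        ancestral_freqs=anc,
        chrom_lengths=dict(chrom_lengths),
        seed=seed,
    )


def simulate_ihs_track(
    chrom_lengths: Mapping[str, int],
    density: float,
    sweeps: Sequence[SweepSpec] = (),
    seed: int = 0,
) -> IhsTrack:
    """Simulate a normalized-score track: N(0, 1) scores at uniform positions.

    ``density`` is in scored sites per megabase.  Sites inside an
    ``ihs_shift`` sweep get the sweep's offset added to their score.
    """
    if not chrom_lengths:
        raise ValueError("chromosome map must be non-empty")
    if density <= 0:
        raise ValueError("density must be > 0")
    ihs_sweeps = _check_sweeps(sweeps, "ihs_shift")

    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    n_sites = max(1, int(round(density * total / 1e6)))
    chrom, pos = _place_positions(rng, chrom_lengths, n_sites)
    scores = rng.standard_normal(n_sites)
    for s in ihs_sweeps:
        m = (chrom == s.region.chrom) & (pos >= s.region.start) & (pos < s.region.end)
        scores[m] += s.value

    return IhsTrack(
        pd.DataFrame({"chrom": chrom, "pos": pos, "score": scores}),
        chrom_lengths=dict(chrom_lengths),
    )


def simulate_pileup(
    genotypes: np.ndarray,
    mean_coverage: float,
    seed: int = 0,
    freqs: np.ndarray | None = None,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    fixed_depth: int | None = None,
) -> AncientSiteTable:
    """Simulate low-coverage read sampling and genotype calling at known sites.

    Per site the read depth is Poisson(``mean_coverage``) (or ``fixed_depth``
    at every site when given).  Each read copies one of the two alleles of the
    true diploid genotype with probability 1/2; there is no error model.  The
    called genotype is heterozygous iff both alleles appear among the reads,
    homozygous for the observed allele otherwise, and missing at depth 0.

    ``genotypes`` are alternate-allele dosages {0, 1, 2}; ``freqs`` optionally
    attaches reference-population derived-allele frequencies to the table.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    g = np.asarray(genotypes)
    if not np.isin(g, (0, 1, 2)).all():
        raise ValueError("genotypes must be diploid dosages in {0, 1, 2}")
    n = len(g)
    rng = np.random.default_rng(seed)
    if fixed_depth is not None:
        depth = np.full(n, int(fixed_depth), dtype=np.int64)
    else:
        depth = rng.poisson(mean_coverage, size=n)

    # reads carrying the alternate allele; only heterozygotes are stochastic
    alt_reads = np.where(
        g == 1, rng.binomial(depth, 0.5), np.where(g == 2, depth, 0)
    )
    call = np.full(n, -1, dtype=np.int8)
    covered = depth > 0
    het = covered & (alt_reads > 0) & (alt_reads < depth)
    hom_alt = covered & (alt_reads == depth)
    hom_ref = covered & (alt_reads == 0)
    call[het] = 1
    call[hom_alt] = 2
    call[hom_ref] = 0

    df = pd.DataFrame(
        {
            "site_id": [f"site_{i:05d}" for i in range(n)],
            "chrom": chrom if chrom is not None else np.full(n, "1", dtype=object),
            "pos": pos if pos is not None else np.arange(n, dtype=np.int64),
            "depth": depth,
            "call": call,
            "freq": freqs if freqs is not None else np.full(n, np.nan),
        }
    )
    return AncientSiteTable(df)
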