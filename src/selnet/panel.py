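"""In-memory container for a diploid genotype panel."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel"]


@dataclass
class GenotypePanel:
    """Diploid genotypes for many samples at many biallelic SNPs.

    Attributes
    ----------
    genotypes : (n_samples, n_snps) int8 array of alternate-allele dosages
        {0, 1, 2}, with −1 for missing.
    chrom, pos, ids : per-SNP chromosome label, 0-based position and site id;
        positions are strictly increasing within each chromosome.
    samples : DataFrame with columns ``sample_id``, ``population``,
        ``continent`` (one row per genotype row).
    ancestral_freqs : per-SNP ancestral allele frequency when known (set by
        the simulator, None for panels read from disk).
    chrom_lengths : chromosome extents used for random-window sampling; when
        None, callers fall back to the maximum observed position.
    """

    genotypes: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    samples: pd.DataFrame
    ancestral_freqs: np.ndarray | None = None
    chrom_lengths: dict[str, int] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-d samples × SNPs matrix")
        n_samples, n_snps = self.genotypes.shape
        if not (len(self.chrom) == len(self.pos) == len(self.ids) == n_snps):
            raise ValueError("per-SNP arrays must match the genotype matrix width")
        if len(self.samples) != n_samples:
            raise ValueError("sample table must match the genotype matrix height")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype values must be in {0, 1, 2, -1}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        return sorted(self.samples["population"].unique())

    def sample_indices(self, populations) -> np.ndarray:
        mask = self.samples["population"].isin(set(populations)).to_numpy()
        return np.flatnonzero(mask)

    def effective_chrom_lengths(self) -> dict[str, int]:
        """Chromosome extents, falling back to max observed position + 1."""
        if self.chrom_lengths is not None:
            return dict(self.chrom_lengths)
        out: dict[str, int] = {}
        for c in np.unique(self.chrom):
            out[str(c)] = int(self.pos[self.chrom == c].max()) + 1
        return out
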