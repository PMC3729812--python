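"""Readers and writers for the formats the pipeline consumes and produces.

Genotypes travel as VCF plus a sample→population→continent TSV map; candidate
loci as BED (0-based half-open); iHS tracks as bedGraph; the ancient site
table and all result tables as TSV; summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ancient import AncientSiteTable, CALL_CODES, CALL_NAMES
from .ihs import IhsTrack, NetworkScore
from .outliers import RegionScore, ThresholdEstimate
from .panel import GenotypePanel
from .regions import Region

__all__ = [
    "read_panel",
    "write_vcf",
    "write_sample_map",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_ancient_table",
    "write_ancient_table",
    "write_fst_table",
    "write_region_scores",
    "write_network_json",
]

AUTOSOME_EXCLUDE = {"X", "Y", "MT", "M"}
_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def _is_autosome(chrom: str) -> bool:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() not in AUTOSOME_EXCLUDE


def read_panel(
    vcf_path: str | Path,
    sample_map_path: str | Path,
    on_unmapped: str = "error",
    autosomes_only: bool = True,
) -> GenotypePanel:
    """Load a diploid genotype panel from VCF plus a sample-map TSV.

    Keeps biallelic SNPs only (multi-allelic and non-SNP records are dropped
    and counted in ``panel.dropped_records``); applies the autosome filter by
    default.  Genotypes are coded 0/1/2 alternate-allele dosage, −1 missing.
    ``on_unmapped`` controls samples absent from the map: ``"error"`` raises,
    ``"drop"`` removes them from the panel.
    """
    from cyvcf2 import VCF

    if on_unmapped not in ("error", "drop"):
        raise ValueError("on_unmapped must be 'error' or 'drop'")
    smap = pd.read_csv(sample_map_path, sep="\t", dtype=str)
    required = {"sample_id", "population", "continent"}
    if not required <= set(smap.columns):
        raise ValueError(f"sample map needs columns {sorted(required)}")
    smap = smap.set_index("sample_id")

    vcf = VCF(str(vcf_path), gts012=True)
    vcf_samples = list(vcf.samples)
    unmapped = [s for s in vcf_samples if s not in smap.index]
    if unmapped and on_unmapped == "error":
        raise ValueError(f"VCF samples absent from the map: {unmapped[:5]}...")
    keep_samples = np.array([s in smap.index for s in vcf_samples])

    chroms, poss, ids, rows = [], [], [], []
    dropped = 0
    for v in vcf:
        if (
            len(v.ALT) != 1
            or len(v.REF) != 1
            or len(v.ALT[0]) != 1
            or not v.is_snp
        ):
            dropped += 1
            continue
        if autosomes_only and not _is_autosome(v.CHROM):
            dropped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=np.int8)  # 0,1,2, 3=unknown
        gt[gt == 3] = -1
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)  # VCF is 1-based; internal coords 0-based
        ids.append(v.ID if v.ID not in (None, ".") else f"snp_{v.CHROM}_{v.POS - 1}")
        rows.append(gt[keep_samples] if not all(keep_samples) else gt)
    vcf.close()
    if not rows:
        raise ValueError(f"no usable biallelic SNPs in {vcf_path}")

    kept_samples = [s for s, k in zip(vcf_samples, keep_samples) if k]
    samples = pd.DataFrame(
        {
            "sample_id": kept_samples,
            "population": smap.loc[kept_samples, "population"].to_numpy(),
            "continent": smap.loc[kept_samples, "continent"].to_numpy(),
        }
    )
    panel = GenotypePanel(
        genotypes=np.vstack(rows).T,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ids=np.array(ids, dtype=object),
        samples=samples,
    )
    panel.dropped_records = dropped  # type: ignore[attr-defined]
    return panel


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal VCF 4.2 (one ALT per record, GT only)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##source=selnet\n')
        for c, length in sorted(panel.effective_chrom_lengths().items()):
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.samples["sample_id"])
            + "\n"
        )
        for j in range(panel.n_snps):
            gts = "\t".join(_GT_STRINGS[int(g)] for g in panel.genotypes[:, j])
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j] + 1}\t{panel.ids[j]}\t"
                f"A\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_sample_map(panel: GenotypePanel, path: str | Path) -> None:
    panel.samples[["sample_id", "population", "continent"]].to_csv(
        path, sep="\t", index=False
    )


def read_bed(path: str | Path) -> list[Region]:
    """Read regions from BED (chrom, start, end[, name]); 0-based half-open."""
    out: list[Region] = []
    with Path(path).open() as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            name = parts[3] if len(parts) > 3 else ""
            out.append(Region(parts[0], int(parts[1]), int(parts[2]), source_locus=name))
    return out


def write_bed(regions: Sequence[Region], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.source_locus or '.'}\n")


def read_bedgraph(path: str | Path,
                  chrom_lengths: Mapping[str, int] | None = None) -> IhsTrack:
    """Read a position-scored track (bedGraph dialect: chrom, start, end,
    score); each interval's start is the scored position."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str},
    )
    return IhsTrack(
        pd.DataFrame({"chrom": df["chrom"], "pos": df["start"], "score": df["score"]}),
        chrom_lengths=chrom_lengths,
    )


def write_bedgraph(track: IhsTrack, path: str | Path) -> None:
    df = track.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos"],
            "end": df["pos"] + 1,
            "score": df["score"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def read_ancient_table(path: str | Path) -> AncientSiteTable:
    """Read the ancient-individual site table TSV (site_id, chrom, pos, depth,
    called_genotype, derived_allele_freq)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    rename = {"called_genotype": "call", "derived_allele_freq": "freq"}
    df = df.rename(columns=rename)
    if df["call"].dtype == object:
        df["call"] = df["call"].map(CALL_CODES)
        if df["call"].isna().any():
            raise ValueError(f"unrecognised genotype call labels in {path}")
        df["call"] = df["call"].astype(np.int64)
    return AncientSiteTable(df)


def write_ancient_table(table: AncientSiteTable, path: str | Path) -> None:
    df = table.df.copy()
    df["call"] = df["call"].map(CALL_NAMES)
    df = df.rename(columns={"call": "called_genotype", "freq": "derived_allele_freq"})
    df.to_csv(path, sep="\t", index=False)


def write_fst_table(fst_table: pd.DataFrame, path: str | Path,
                    header_lines: Iterable[str] = ()) -> None:
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fst_table.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_region_scores(
    scores: Sequence[RegionScore], path: str | Path, comparison: str = "",
    header_lines: Iterable[str] = (),
) -> None:
    rows = [
        {
            "chrom": s.region.chrom,
            "start": s.region.start,
            "end": s.region.end,
            "source_locus": s.region.source_locus,
            "cluster_id": s.region.cluster_id,
            "comparison": comparison,
            "n_qualifying": s.n_qualifying,
            "n_high": s.n_high,
            "fraction": s.fraction,
            "flagged": s.flagged,
            "empirical_P": s.empirical_p,
            "evaluable": s.evaluable,
        }
        for s in scores
    ]
    with Path(path).open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_network_json(result, path: str | Path, extra: Mapping | None = None) -> None:
    """Serialise a NetworkTestResult or NetworkScore as JSON."""
    from dataclasses import asdict, is_dataclass

    payload = asdict(result) if is_dataclass(result) else dict(result)
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
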