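"""Run configuration and orchestration of the three analyses.

A run bundles up to three analyses on shared inputs:

1. *region differentiation* — per-comparison F_ST scan, 50-kb region scoring
   with empirical P-values from random genomic windows, and the network-level
   binomial excess test;
2. *iHS network test* — randomization p-value for the candidate network's
   mean top score on a precomputed iHS track;
3. *ancient heterozygosity* — observed mean heterozygosity of an ancient
   individual against frequency-expected and coverage-resampled
   distributions (and modern panel distributions when a panel is given).

Reproducibility: every stage derives its seed from the master seed by a fixed
integer offset (documented in ``STAGE_SEED_OFFSETS``), so stages can be rerun
independently yet bit-identically; every output file carries the config hash
and master seed in a comment header.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import ancient as anc
from . import io as sio
from . import outliers
from .fst import pairwise_scan
from .ihs import randomization_p
from .regions import MIN_INDEPENDENT_GAP, WINDOW_SIZE, build_windows, cluster_loci

__all__ = ["RunConfig", "run_pipeline", "STAGE_SEED_OFFSETS", "stage_seed"]

STAGE_SEED_OFFSETS = {
    "threshold": 11,
    "region_null": 101,  # + comparison index
    "ihs": 211,
    "ancient_expected": 307,
    "ancient_resample": 311,
}
_SEED_MOD = 2**31


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Per-stage seed: master seed plus a fixed documented offset (mod 2^31)."""
    return (int(master_seed) + STAGE_SEED_OFFSETS[stage] + index) % _SEED_MOD


@dataclass
class RunConfig:
    """All inputs, thresholds and replicate counts for one run.

    Defaults are the full-scale analysis settings: the genome-wide boundary is
    the 99% quantile, a region is flagged above a 1% high-F_ST fraction,
    region significance is at α = 0.05 against 11,000 random windows, the iHS
    test uses 100,000 random networks at 2 Mb spacing, and the heterozygosity
    resampling uses 500 genotype × 2,500 read replicates.
    """

    # inputs
    vcf: str | None = None
    sample_map: str | None = None
    loci_bed: str | None = None
    ihs_bedgraph: str | None = None
    ancient_table: str | None = None
    comparisons: list[dict] = field(default_factory=list)  # {name, group_a, group_b}
    chrom_lengths: dict[str, int] | None = None
    # thresholds
    q: float = 0.99
    flag_level: float = 0.01
    alpha: float = 0.05
    # replicate counts
    threshold_sample_size: int | None = 2_200_000
    n_random_regions: int = 11_000
    n_random_networks: int = 100_000
    genotype_reps: int = 500
    read_reps: int = 2_500
    cluster_draws: int = 10
    # geometry
    window: int = WINDOW_SIZE
    min_spacing: int = MIN_INDEPENDENT_GAP
    # behaviour
    collapse_clusters: bool = False
    signed_ihs: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("q", "flag_level", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in (
            "n_random_regions", "n_random_networks", "genotype_reps",
            "read_reps", "cluster_draws", "window", "min_spacing",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.threshold_sample_size is not None and self.threshold_sample_size < 100:
            raise ValueError("threshold_sample_size must be >= 100 (or None for all)")
        for comp in self.comparisons:
            if not {"name", "group_a", "group_b"} <= set(comp):
                raise ValueError("each comparison needs name, group_a, group_b")

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("rb") as fh:
            data = tomllib.load(fh)
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(config: RunConfig, stage: str) -> list[str]:
    return [f"selnet stage={stage} config_hash={config.config_hash()} seed={config.seed}"]


def run_region_test(config: RunConfig, panel, windows, outdir: Path) -> dict:
    results = {}
    chrom_lengths = config.chrom_lengths or panel.effective_chrom_lengths()
    for i, comp in enumerate(config.comparisons):
        name = comp["name"]
        scan = pairwise_scan(panel, comp["group_a"], comp["group_b"])
        qualifying = scan.loc[scan["qualifying"], "fst"].to_numpy()
        if (
            config.threshold_sample_size is not None
            and len(qualifying) > config.threshold_sample_size
        ):
            rng = np.random.default_rng(stage_seed(config.seed, "threshold", i))
            qualifying = rng.choice(qualifying, config.threshold_sample_size, replace=False)
        threshold = outliers.genome_threshold(qualifying, q=config.q, comparison=name)
        scores = outliers.score_regions(windows, scan, threshold,
                                        flag_level=config.flag_level)
        null = outliers.sample_null_fractions(
            scan, threshold, chrom_lengths,
            n_random=config.n_random_regions, window=config.window,
            seed=stage_seed(config.seed, "region_null", i),
        )
        scores = outliers.empirical_p(scores, null)
        network = outliers.network_test(scores, alpha=config.alpha)
        sio.write_fst_table(scan, outdir / f"fst_{name}.tsv",
                            header_lines=_header(config, f"fst-scan:{name}"))
        sio.write_region_scores(scores, outdir / f"regions_{name}.tsv", comparison=name,
                                header_lines=_header(config, f"region-test:{name}"))
        sio.write_network_json(
            network, outdir / f"network_{name}.json",
            extra={"comparison": name, "t99": threshold.t99,
                   "n_threshold_sample": threshold.n_sampled},
        )
        results[name] = {"threshold": threshold, "scores": scores, "network": network}
    return results


def run_ihs_test(config: RunConfig, track, windows, outdir: Path) -> dict:
    score = randomization_p(
        windows, track,
        n_random=config.n_random_networks,
        seed=stage_seed(config.seed, "ihs"),
        collapse_clusters=config.collapse_clusters,
        n_cluster_draws=config.cluster_draws,
        window=config.window,
        min_spacing=config.min_spacing,
        signed=config.signed_ihs,
    )
    sio.write_network_json(
        {
            "network_mean": score.network_mean,
            "n_regions": score.n_regions,
            "p_value": score.p_value,
            "n_random": score.n_random,
            "min_spacing": score.min_spacing,
            "n_unevaluable": score.n_unevaluable,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        outdir / "ihs_network.json",
    )
    return {"ihs": score}


def run_ancient_het(config: RunConfig, table, outdir: Path, panel=None) -> dict:
    observed = anc.mean_observed_het(table.calls)
    expected = anc.simulate_expected_het(
        table.freqs[table.depths > 0],
        n_reps=config.genotype_reps,
        seed=stage_seed(config.seed, "ancient_expected"),
    )
    resampled = anc.resample_reads_het(
        table.freqs, table.depths,
        n_genotype_reps=config.genotype_reps, n_read_reps=config.read_reps,
        seed=stage_seed(config.seed, "ancient_resample"),
    )
    summary = {
        "observed_mean_het": observed,
        "n_sites": len(table),
        "mean_depth": table.mean_depth,
        "expected_mean": expected.mean,
        "resampled_mean": resampled.mean,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    panel_dists = {}
    site_keys = list(zip(table.df["chrom"].tolist(), table.df["pos"].tolist()))
    panel_has_sites = panel is not None and any(
        bool(((panel.chrom == c) & (panel.pos == p)).any()) for c, p in site_keys
    )
    if panel is not None and not panel_has_sites:
        summary["panel_comparison"] = "skipped: no ancient site present in the panel"
    if panel_has_sites:
        for group, grp_df in panel.samples.groupby("continent"):
            pops = grp_df["population"].unique().tolist()
            dist = anc.panel_het_distribution(panel, site_keys, pops, label=str(group))
            panel_dists[str(group)] = dist
            summary[f"panel_{group}_mean"] = dist.mean
            summary[f"panel_{group}_min"] = float(dist.values.min())
            summary[f"panel_{group}_percentile_of_ancient"] = anc.percentile_placement(
                observed, dist
            )
    np.savetxt(outdir / "het_expected.tsv", expected.values, fmt="%.8f",
               header=_header(config, "ancient-het")[0])
    np.savetxt(outdir / "het_resampled.tsv", resampled.values, fmt="%.8f",
               header=_header(config, "ancient-het")[0])
    (outdir / "ancient_het.json").write_text(json.dumps(summary, indent=2) + "\n")
    return {
        "observed": observed, "expected": expected, "resampled": resampled,
        "panel_distributions": panel_dists, "summary": summary,
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every analysis the config provides inputs for.

    Returns a result bundle keyed ``region_test``, ``ihs_test``,
    ``ancient_het`` (present only when the matching inputs were configured);
    result files are written under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    panel = None
    if config.vcf and config.sample_map:
        panel = sio.read_panel(config.vcf, config.sample_map)
        if config.chrom_lengths:
            panel.chrom_lengths = dict(config.chrom_lengths)

    windows = None
    if config.loci_bed:
        loci = cluster_loci(sio.read_bed(config.loci_bed), min_gap=config.min_spacing)
        windows = build_windows(loci, window=config.window)

    if panel is not None and windows is not None and config.comparisons:
        results["region_test"] = run_region_test(config, panel, windows, outdir)
    if config.ihs_bedgraph and windows is not None:
        track = sio.read_bedgraph(config.ihs_bedgraph, chrom_lengths=config.chrom_lengths)
        results["ihs_test"] = run_ihs_test(config, track, windows, outdir)
    if config.ancient_table:
        table = sio.read_ancient_table(config.ancient_table)
        results["ancient_het"] = run_ancient_het(config, table, outdir, panel=panel)

    if not results:
        raise ValueError("config provides inputs for no analysis")
    return results
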