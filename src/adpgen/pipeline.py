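"""End-to-end pipeline orchestration with a reproducible run manifest.

Two composed runs are provided: the mitochondrial report (primer trim ->
haplotype collapse -> clade assignment -> group distances with bootstrap SEs)
and the genotype report (QC -> optional merge -> PCA -> per-comparison FST
scan -> interval intersection). Every stage logs its input/output dimensions
and all effective settings are echoed into ``manifest.json`` so a run can be
reproduced from its output directory alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .alignment import SeqAlignment, trim_primers
from .distances import DistanceConfig, bootstrap_se, group_mean, pairwise_matrix
from .genotypes import GenotypeMatrix
from .haplotypes import assign_clades, collapse_haplotypes
from .qc import filter_genotypes, infer_sex, run_pca
from .scan import FstScan, intersect_comparisons, intervals_to_bed

logger = logging.getLogger("adpgen")

REGION_ZONES = {
    "UWR": "Guinea Savannah", "NR": "Guinea Savannah",
    "AR": "Forest", "ER": "Forest",
    "CR": "Coastal", "GAR": "Coastal",
}


@dataclass
class RunConfig:
    """Settings for a pipeline run; loadable from a YAML file.

    Unset values fall back to the module defaults (QC thresholds 10%/5%/10%,
    100 kb windows, 99th/95th percentiles, gamma shape 0.33, 500 bootstrap
    replicates).
    """

    out_dir: str = "run_output"
    seed: int = 0
    # mtDNA
    fasta: str | None = None
    metadata: str | None = None
    panel_fasta: str | None = None
    panel_clades: dict[str, str] = field(default_factory=dict)
    fwd_primer: str | None = "CTCCGCCATCAGCACCCAAAG"
    rev_primer: str | None = "ATRGCTGAGTCYAAGCATCC"
    gamma_shape: float = 0.33
    bootstrap_reps: int = 500
    # genotypes
    plink_prefix: str | None = None
    snp_miss_max: float = 0.10
    maf_min: float = 0.05
    ind_miss_max: float = 0.10
    window_half_width: int = 50_000
    snp_percentile: float = 0.99
    window_percentile: float = 0.95
    comparisons: list[tuple[str, str]] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for name in ("fasta", "metadata", "panel_fasta"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        return cfg

    def manifest(self) -> dict:
        out = dict(self.__dict__)
        out["comparisons"] = [list(c) for c in self.comparisons]
        return out


def _write_manifest(config: RunConfig, out_dir: Path, extra: dict) -> None:
    manifest = {"config": config.manifest(), **extra}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_mtdna(
    config: RunConfig,
    aln: SeqAlignment | None = None,
    regions: dict[str, str] | None = None,
    panel: SeqAlignment | None = None,
    panel_clades: dict[str, str] | None = None,
) -> dict:
    """Mitochondrial report: trim, collapse, assign clades, group distances.

    Inputs may be passed in memory or read from the paths in ``config``.
    Writes the haplotype table, clade frequencies by region/zone, and the
    distance tables with bootstrap SEs under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if aln is None:
        if config.fasta is None:
            raise ValueError("stage input: no FASTA given")
        aln = SeqAlignment.from_fasta(config.fasta)
    if regions is None and config.metadata is not None:
        meta = pd.read_csv(config.metadata, sep="\t")
        regions = dict(zip(meta.iloc[:, 0].astype(str), meta["region"]))
    if panel is None and config.panel_fasta is not None:
        panel = SeqAlignment.from_fasta(config.panel_fasta)
        panel_clades = panel_clades or config.panel_clades
    logger.info("mtdna: %d sequences of length %d", len(aln), aln.length)

    if config.fwd_primer and config.rev_primer:
        trimmed = trim_primers(aln, config.fwd_primer, config.rev_primer)
        aln = trimmed.alignment
        logger.info("trim: %d sequences lacked a primer match", len(trimmed.unmatched))

    table = collapse_haplotypes(aln, regions)
    logger.info("collapse: %d haplotypes from %d samples", len(table), table.total_samples)
    if panel is not None and panel_clades:
        table = assign_clades(table, panel, panel_clades, config.gamma_shape)
    table.to_frame().to_csv(out_dir / "haplotypes.tsv", sep="\t", index=False)

    clade_freq = None
    if regions is not None and table.region_counts is not None:
        hap_clades = {h.haplotype_id: h.clade for h in table.haplotypes}
        rc = table.region_counts.copy()
        rc["clade"] = [hap_clades[h] for h in rc.index]
        clade_freq = rc.groupby("clade").sum()
        zone_cols = {}
        for region in clade_freq.columns:
            zone_cols.setdefault(REGION_ZONES.get(region, region), []).append(region)
        zone_freq = pd.DataFrame(
            {z: clade_freq[cols].sum(axis=1) for z, cols in zone_cols.items()}
        )
        clade_freq.to_csv(out_dir / "clade_by_region.tsv", sep="\t")
        zone_freq.to_csv(out_dir / "clade_by_zone.tsv", sep="\t")

    dist_results = None
    hap_clades = {h.haplotype_id: h.clade for h in table.haplotypes}
    if len(table) >= 2 and len({c for c in hap_clades.values() if c != "unassigned"}) >= 1:
        rep_aln = SeqAlignment(
            [h.haplotype_id for h in table.haplotypes],
            [h.sequence for h in table.haplotypes],
        )
        dcfg = DistanceConfig(
            gamma_shape=config.gamma_shape,
            bootstrap_reps=config.bootstrap_reps,
            seed=config.seed,
        )
        grouping = {
            h: (c if c != "unassigned" else "unassigned") for h, c in hap_clades.items()
        }
        dist_results = bootstrap_se(rep_aln, grouping, dcfg)
        pd.DataFrame(
            [
                {
                    "group_a": r.group_a, "group_b": r.group_b,
                    "mean_distance": r.mean_distance, "se": r.se,
                    "n_pairs": r.n_pairs,
                }
                for r in dist_results
            ]
        ).to_csv(out_dir / "group_distances.tsv", sep="\t", index=False)

    _write_manifest(config, out_dir, {"stage": "mtdna", "n_haplotypes": len(table)})
    return {
        "haplotypes": table,
        "clade_by_region": clade_freq,
        "distances": dist_results,
    }


def run_scan(
    config: RunConfig,
    gm: GenotypeMatrix | None = None,
    metadata: pd.DataFrame | None = None,
) -> dict:
    """Genotype report: QC, sex check, PCA, FST scans, interval intersection.

    ``comparisons`` in the config names pairs of population labels (matched
    against the metadata ``population`` column); each pair is scanned
    independently and the candidate intervals of all comparisons are
    intersected.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if gm is None:
        if config.plink_prefix is None:
            raise ValueError("stage input: no genotype data given")
        gm = GenotypeMatrix.from_plink(config.plink_prefix)
    if metadata is None and config.metadata is not None:
        metadata = pd.read_csv(config.metadata, sep="\t")
    if metadata is None:
        raise ValueError("stage metadata: sample metadata required")
    metadata = metadata.set_index(metadata.columns[0], drop=False)
    logger.info("scan: %d samples x %d SNPs", gm.n_samples, gm.n_snps)

    filtered, report = filter_genotypes(
        gm, config.snp_miss_max, config.maf_min, config.ind_miss_max
    )
    logger.info(
        "qc: removed %d SNPs (missingness), %d SNPs (MAF), %d samples",
        report.snps_removed_missingness, report.snps_removed_maf,
        report.samples_removed_missingness,
    )
    report.to_frame().to_csv(out_dir / "qc_report.tsv", sep="\t", index=False)

    sex_table = None
    if any(str(c) in ("X", "Y", "23", "24") for c in set(gm.chrom.astype(str))):
        recorded = (
            dict(zip(metadata.index.astype(str), metadata["sex"]))
            if "sex" in metadata.columns
            else None
        )
        sex_table = infer_sex(gm, recorded)
        sex_table.to_csv(out_dir / "sex_check.tsv", sep="\t", index=False)

    coords, var_frac = run_pca(filtered, n_components=10)
    pca_frame = pd.DataFrame(
        coords, columns=[f"PC{i + 1}" for i in range(coords.shape[1])]
    )
    pca_frame.insert(0, "sample", filtered.sample_ids)
    pca_frame.to_csv(out_dir / "pca_coordinates.tsv", sep="\t", index=False)

    pop_of = dict(zip(metadata.index.astype(str), metadata["population"]))
    runs = []
    summary_rows = []
    for pop_a, pop_b in config.comparisons:
        wanted = [
            s for s in filtered.sample_ids if pop_of.get(s) in (pop_a, pop_b)
        ]
        sub = filtered.take_samples(
            [filtered.sample_ids.index(s) for s in wanted]
        )
        scan = FstScan(
            window_half_width=config.window_half_width,
            snp_percentile=config.snp_percentile,
            window_percentile=config.window_percentile,
        ).fit(sub, {s: pop_of[s] for s in wanted})
        tag = f"{pop_a}_vs_{pop_b}"
        scan.result_.table.to_csv(out_dir / f"fst_{tag}.tsv", sep="\t", index=False)
        intervals_to_bed(scan.intervals_).to_csv(
            out_dir / f"candidates_{tag}.bed", sep="\t", index=False, header=False
        )
        summary_rows.append(
            {
                "comparison": tag,
                "fst_weighted": scan.fst_weighted_,
                "fst_mean": scan.fst_mean_,
                "n_intervals": len(scan.intervals_),
            }
        )
        logger.info(
            "fst %s: weighted %.4f, %d candidate intervals",
            tag, scan.fst_weighted_, len(scan.intervals_),
        )
        runs.append(scan.intervals_)

    shared = intersect_comparisons(runs) if runs else []
    if runs:
        intervals_to_bed(shared).to_csv(
            out_dir / "candidates_intersection.bed", sep="\t", index=False, header=False
        )
    summary = pd.DataFrame(summary_rows)
    if len(summary):
        summary.to_csv(out_dir / "genome_fst_summary.tsv", sep="\t", index=False)

    _write_manifest(
        config, out_dir,
        {"stage": "scan", "qc": report.__dict__, "n_shared_intervals": len(shared)},
    )
    return {
        "qc_report": report,
        "sex_check": sex_table,
        "pca": pca_frame,
        "variance_fractions": var_frac,
        "summary": summary,
        "comparison_intervals": runs,
        "intersection": shared,
    }
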