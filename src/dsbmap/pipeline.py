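"""Pipeline orchestration: digestion -> BLISS ranking -> gammaH2AX scoring ->
consensus -> expression impact, driven by a validated configuration.

Every stage logs per-stage record counts (reads kept/dropped, sites called):
the read filters are the main failure surface in practice. Outputs are
deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bliss, digest, expression, h2ax, io

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the run seed for one end-to-end analysis."""

    out_dir: str
    fasta: str | None = None
    sites_bed: str | None = None
    motif: str = digest.ASISI_MOTIF
    flank: int = 100
    bliss_induced: str | None = None
    bliss_uninduced: str | None = None
    barcode: str | None = None
    max_mismatch: int = 1
    dedup: bool = True
    rc_mode: str = "pileup-origin"
    pseudocount: float = 1.0
    log2ratio_cutoff: float = 1.0
    min_induced_rc: int = 3
    h2ax_induced: str | None = None
    h2ax_uninduced: str | None = None
    h2ax_window: int = 250
    z_threshold: float = 3.0
    merge_n: int = 2000
    top_k: int = 100
    score_flank: int = 5000
    score_dip: int = 1000
    genes_bed12: str | None = None
    counts_tsv: str | None = None
    conditions_yaml: str | None = None
    atmi_counts_tsv: str | None = None
    gene_flank: int = 2000
    decay_edges_kb: tuple = expression.DEFAULT_DECAY_EDGES_KB
    constant_bin_kb: float = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.flank <= 0 or self.gene_flank <= 0:
            raise ValueError("flanks must be positive")
        if self.merge_n <= 0:
            raise ValueError("merge_n must be positive")
        if not (self.score_flank > self.score_dip >= 0):
            raise ValueError("need score_flank > score_dip >= 0")
        if self.fasta is None and self.sites_bed is None:
            raise ValueError("need either a FASTA to digest or a sites BED")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "decay_edges_kb" in data:
            data["decay_edges_kb"] = tuple(data["decay_edges_kb"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["decay_edges_kb"] = list(self.decay_edges_kb)
        return d


@dataclass
class PipelineResult:
    sites: list = field(default_factory=list)
    bliss_table: pd.DataFrame | None = None
    h2ax_scores: pd.DataFrame | None = None
    clusters: list = field(default_factory=list)
    consensus: pd.DataFrame | None = None
    logfc: pd.Series | None = None
    shift_test: object = None
    decay: dict = field(default_factory=dict)
    proximity: dict | None = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the stages in dependency order; optional stages skip with a warning."""
    config.validate()
    result = PipelineResult()

    # --- stage: digestion ---------------------------------------------------
    if config.sites_bed:
        sites = io.read_sites_bed(config.sites_bed)
        chrom_lengths = None
    else:
        sequences = io.read_fasta(config.fasta)
        sites = digest.find_restriction_sites(sequences, motif=config.motif)
        chrom_lengths = {c: len(s) for c, s in sequences.items()}
    logger.info("digestion: %d restriction sites", len(sites))
    result.sites = sites
    if chrom_lengths is None:
        # windows still need bounds; infer generous bounds from the sites
        chrom_lengths = {}
        for s in sites:
            chrom_lengths[s.chrom] = max(
                chrom_lengths.get(s.chrom, 0), s.motif_end + 10 * config.flank
            )
    windows = digest.make_site_windows(sites, config.flank, chrom_lengths)

    # --- stage: BLISS ranking ----------------------------------------------
    called_ids: set[str] = set()
    if config.bliss_induced and config.bliss_uninduced:
        reads_i = io.read_reads(config.bliss_induced)
        reads_u = io.read_reads(config.bliss_uninduced)
        if config.barcode:
            fi = bliss.filter_reads(
                reads_i, config.barcode, config.max_mismatch, dedup=config.dedup
            )
            fu = bliss.filter_reads(
                reads_u, config.barcode, config.max_mismatch, dedup=config.dedup
            )
            logger.info(
                "BLISS filter: induced kept %d/%d, uninduced kept %d/%d",
                len(fi.reads), fi.n_input, len(fu.reads), fu.n_input,
            )
            reads_i, reads_u = fi.reads, fu.reads
        table = bliss.call_cut_sites(
            sites, windows, reads_i, reads_u,
            mode=config.rc_mode,
            pseudocount=config.pseudocount,
            min_induced_rc=config.min_induced_rc,
            log2ratio_cutoff=config.log2ratio_cutoff,
        )
        result.bliss_table = table
        called_ids = set(table.index[table["called"]])
        logger.info("BLISS ranking: %d sites called", len(called_ids))
    else:
        logger.warning("BLISS stage skipped: read libraries not configured")

    # --- stage: gammaH2AX ---------------------------------------------------
    topk_ids: set[str] = set()
    if config.h2ax_induced and config.h2ax_uninduced:
        track_i = io.read_bedgraph_track(config.h2ax_induced, config.h2ax_window)
        track_u = io.read_bedgraph_track(config.h2ax_uninduced, config.h2ax_window)
        zscores = h2ax.compute_window_zscores(track_i)
        peaks = h2ax.call_enriched_windows(
            zscores, track_i.window_size, config.z_threshold
        )
        result.clusters = h2ax.merge_into_clusters(peaks, config.merge_n)
        scores = h2ax.score_sites(
            sites, track_i, track_u,
            flank_bp=config.score_flank,
            dip_exclusion_bp=config.score_dip,
            pseudocount=config.pseudocount,
            top_k=config.top_k,
        )
        result.h2ax_scores = scores
        topk_ids = set(scores.index[scores["topk_member"]])
        logger.info(
            "gammaH2AX: %d peaks, %d clusters, top-%d flagged",
            len(peaks), len(result.clusters), config.top_k,
        )
    else:
        logger.warning("gammaH2AX stage skipped: tracks not configured")

    # --- stage: consensus ---------------------------------------------------
    if called_ids and topk_ids:
        result.consensus = h2ax.consensus_sites(called_ids, topk_ids)
        n_both = int((result.consensus["category"] == "both").sum())
        logger.info("consensus: %d sites in both callers", n_both)
    elif called_ids:
        logger.warning("consensus skipped: BLISS-only calls propagate")

    # --- stage: expression impact -------------------------------------------
    if config.genes_bed12 and config.counts_tsv and config.conditions_yaml:
        genes = io.read_genes_bed12(config.genes_bed12)
        counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        with open(config.conditions_yaml) as fh:
            conditions = yaml.safe_load(fh)
        gold_ids = (
            set(result.consensus.index[result.consensus["category"] == "both"])
            if result.consensus is not None
            else called_ids
        )
        site_by_id = {s.site_id: s for s in sites}
        centers = {
            sid: (site_by_id[sid].chrom, site_by_id[sid].center) for sid in gold_ids
        }
        assignments = expression.assign_sites_to_genes(
            centers, genes, flank=config.gene_flank
        )
        logfc = expression.gene_fold_changes(counts, conditions)
        result.logfc = logfc
        cut_genes = set(assignments["gene_id"])
        fc_cut = logfc[logfc.index.isin(cut_genes)]
        fc_rest = logfc[~logfc.index.isin(cut_genes)]
        if len(fc_cut) and len(fc_rest):
            result.shift_test = expression.compare_fc_distributions(
                fc_cut, fc_rest, alternative="less"
            )
            logger.info(
                "shift test: %d cut genes vs %d rest, p=%.3g",
                len(fc_cut), len(fc_rest), result.shift_test.p_value,
            )
        cut_centers = [centers[sid] for sid in sorted(gold_ids)]
        dists = _gene_distances(genes, cut_centers)
        dist_vec = np.array([dists[g.gene_id] for g in genes])
        fc_vec = logfc.reindex([g.gene_id for g in genes]).to_numpy()
        for scheme in ("cumulative", "disjoint"):
            result.decay[scheme] = expression.distance_decay(
                dist_vec, fc_vec, edges_kb=config.decay_edges_kb, scheme=scheme
            )
        result.decay["constant"] = expression.distance_decay(
            dist_vec, fc_vec, edges_kb=(config.constant_bin_kb,), scheme="constant"
        )
        lengths = chrom_lengths
        result.proximity = expression.gene_proximity_enrichment(
            cut_centers, genes, lengths, flank=config.gene_flank
        )
    else:
        logger.warning("expression stage skipped: inputs not configured")

    return result


def _gene_distances(genes, centers) -> dict[str, float]:
    out = {}
    for g in genes:
        ds = [
            expression.site_gene_distance(c, g) for chrom, c in centers if chrom == g.chrom
        ]
        out[g.gene_id] = float(min(ds)) if ds else np.inf
    return out


def write_report(result: PipelineResult, config: PipelineConfig) -> list[Path]:
    """Write the deterministic output file set and the echoed configuration."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _mark(path: Path) -> Path:
        written.append(path)
        return path

    with open(_mark(out / "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    io.write_sites_bed(result.sites, _mark(out / "sites.bed"))
    if result.bliss_table is not None:
        result.bliss_table.to_csv(_mark(out / "bliss_ranked.tsv"), sep="\t")
        called = result.bliss_table[result.bliss_table["called"]]
        with open(_mark(out / "called_sites.bed"), "w") as fh:
            for sid, row in called.iterrows():
                fh.write(
                    f"{row['chrom']}\t{int(row['motif_start'])}\t"
                    f"{int(row['motif_start']) + 8}\t{sid}\t0\t+\n"
                )
    if result.h2ax_scores is not None:
        result.h2ax_scores.to_csv(_mark(out / "h2ax_scores.tsv"), sep="\t")
    if result.clusters:
        with open(_mark(out / "h2ax_clusters.bed"), "w") as fh:
            for c in result.clusters:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.cluster_id}\t0\t+\n")
    if result.consensus is not None:
        result.consensus.to_csv(_mark(out / "consensus.tsv"), sep="\t")
    if result.logfc is not None:
        result.logfc.to_csv(_mark(out / "gene_log2fc.tsv"), sep="\t")
    summary = {}
    if result.shift_test is not None:
        summary["shift_test"] = {
            "statistic": result.shift_test.statistic,
            "p_value": result.shift_test.p_value,
            "n_cut": result.shift_test.n_cut,
            "n_rest": result.shift_test.n_rest,
            "method": result.shift_test.method,
        }
    if result.proximity is not None:
        summary["gene_proximity"] = result.proximity
    for scheme, decay in result.decay.items():
        summary[f"decay_{scheme}"] = {
            "labels": decay.bin_labels,
            "mean_logfc": [None if not np.isfinite(m) else float(m) for m in decay.mean_logfc],
            "gene_counts": [int(n) for n in decay.gene_counts],
            "fit_slope": None if not np.isfinite(decay.fit_slope) else decay.fit_slope,
            "fit_intercept": None
            if not np.isfinite(decay.fit_intercept)
            else decay.fit_intercept,
        }
    with open(_mark(out / "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return written
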