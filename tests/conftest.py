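"""Shared fixtures: the default synthetic scenario, computed once per session."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from dsbmap import bliss, digest, expression, h2ax
from dsbmap.simulate import (
    SimConfig,
    generate_genome_and_genes,
    simulate_bliss_reads,
    simulate_expression_counts,
    simulate_h2ax_coverage,
)

# The scenario seed is fixed once for the whole suite.
SCENARIO_SEED = 7

logging.getLogger("dsbmap").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=SCENARIO_SEED)


@pytest.fixture(scope="session")
def scenario(sim_config):
    """Default synthetic scenario: genome, genes, truth, digested sites."""
    sequences, genes, truth = generate_genome_and_genes(sim_config)
    sites = digest.find_restriction_sites(sequences, motif=sim_config.motif)
    chrom_lengths = {c: len(s) for c, s in sequences.items()}
    windows = digest.make_site_windows(sites, sim_config.flank, chrom_lengths)
    return {
        "config": sim_config,
        "sequences": sequences,
        "genes": genes,
        "truth": truth,
        "sites": sites,
        "windows": windows,
        "chrom_lengths": chrom_lengths,
    }


@pytest.fixture(scope="session")
def bliss_table(scenario):
    """Ranked BLISS table for the default scenario (filtered, deduplicated)."""
    cfg = scenario["config"]
    reads_i, reads_u = simulate_bliss_reads(scenario["truth"], cfg)
    kept_i = bliss.filter_reads(reads_i, cfg.barcode, 1, dedup=True).reads
    kept_u = bliss.filter_reads(reads_u, cfg.barcode, 1, dedup=True).reads
    table = bliss.call_cut_sites(
        scenario["sites"], scenario["windows"], kept_i, kept_u
    )
    return table.join(
        scenario["truth"].sites.set_index("site_id")["efficiency"]
    )


@pytest.fixture(scope="session")
def h2ax_tracks(scenario):
    return simulate_h2ax_coverage(scenario["truth"], scenario["config"])


@pytest.fixture(scope="session")
def h2ax_scores(scenario, h2ax_tracks):
    track_i, track_u = h2ax_tracks
    scores = h2ax.score_sites(
        scenario["sites"], track_i, track_u, top_k=10
    )
    return scores.join(
        scenario["truth"].sites.set_index("site_id")["efficiency"]
    )


@pytest.fixture(scope="session")
def gene_sets(scenario):
    """Cut / rest / control gene masks from the planted truth geometry."""
    gt = scenario["truth"].genes
    d = gt["distance"].to_numpy()
    cut = d <= 2000
    rest = ~np.isfinite(d) | (d > 50_000)
    return {
        "table": gt,
        "distance": d,
        "cut": cut,
        "rest": rest,
        "control_genes": gt.loc[rest, "gene_id"],
    }


@pytest.fixture(scope="session")
def vehicle_logfc(scenario, gene_sets):
    """Observed log2 fold changes for the vehicle (no inhibitor) contrast."""
    counts, layout = simulate_expression_counts(
        scenario["truth"], scenario["config"]
    )
    libs = list(layout[layout["treatment"] == "vehicle"].index)
    conditions = {l: layout.loc[l, "condition"] for l in libs}
    return expression.gene_fold_changes(
        counts[libs], conditions, control_genes=gene_sets["control_genes"]
    )
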