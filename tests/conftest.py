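"""Shared fixtures: toy tracks, toy genes, and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from tssmeta import clustering as clu
from tssmeta import coverage as cov
from tssmeta import occupancy as occ
from tssmeta import simulate as sim
from tssmeta.annotations import GeneModel


def random_track(rng: np.random.Generator, chrom: str = "chr1",
                 n_intervals: int = 10, span: int = 10_000) -> cov.CoverageTrack:
    """A random sparse track of non-overlapping intervals with gaps."""
    cuts = np.sort(rng.choice(np.arange(1, span), size=2 * n_intervals, replace=False))
    intervals = []
    for i in range(0, len(cuts) - 1, 2):
        value = float(rng.uniform(0, 10))
        if value > 0.5:  # leave some gaps
            intervals.append((chrom, int(cuts[i]), int(cuts[i + 1]), value))
    return cov.CoverageTrack.from_intervals(intervals)


def per_base_mean(track: cov.CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Brute-force per-base averaging oracle; uncovered or negative bases are 0."""
    total = 0.0
    if chrom in track.chroms:
        ci = track.chroms[chrom]
        for pos in range(start, end):
            if pos < 0:
                continue
            for s, e, v in zip(ci.starts, ci.ends, ci.values):
                if s <= pos < e:
                    total += v
                    break
    return total / (end - start)


def brute_force_row(gene: GeneModel, track: cov.CoverageTrack,
                    cfg: occ.OccupancyConfig) -> np.ndarray:
    """Per-base brute-force occupancy row, strand-oriented."""
    left = gene.tss - cfg.window_bp
    row = np.array([
        per_base_mean(track, gene.chrom, left + i * cfg.bin_bp, left + (i + 1) * cfg.bin_bp)
        for i in range(cfg.n_bins)
    ])
    if gene.strand == "-" and cfg.orient_by_strand:
        row = row[::-1]
    return row


@pytest.fixture(scope="session")
def small_study():
    """A 300-gene synthetic study: models, truth, scaled WT/Mut tracks, matrices."""
    _, models = sim.simulate_annotation(300, seed=11)
    truth = sim.assign_truth(models, seed=11)
    wt_raw, n_wt = sim.simulate_tracks(models, truth, "WT", seed=12)
    mut_raw, n_mut = sim.simulate_tracks(models, truth, "Mut", seed=13)
    wt = cov.scale_to_million(wt_raw, n_wt)
    mut = cov.scale_to_million(mut_raw, n_mut)
    cfg = occ.OccupancyConfig()
    return {
        "models": models,
        "truth": truth,
        "wt": wt,
        "mut": mut,
        "matrix_wt": occ.build_matrix(models, wt, cfg),
        "matrix_mut": occ.build_matrix(models, mut, cfg),
    }


@pytest.fixture(scope="session")
def small_assignment(small_study):
    return clu.kmeans_occupancy(small_study["matrix_wt"], clu.ClusterConfig(seed=5))
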