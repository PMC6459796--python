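"""Strand-oriented TSS occupancy matrices.

Each gene contributes one row: the mean depth-scaled signal in fixed-width
bins tiling a window centered on its TSS (defaults: 100-bp bins over +/- 5 kb,
giving 100 bins).  Rows are oriented 5'->3' relative to the gene: bin 0 is
the most upstream bin, bin B-1 the most downstream, so minus-strand rows are
the genomic mirror image of plus-strand rows.  Bins that would extend past
the chromosome start are zero-filled and the gene is flagged, never dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
import pandas as pd

from tssmeta.annotations import GeneModel
from tssmeta.coverage import CoverageTrack

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OccupancyConfig:
    """Geometry of the TSS window.

    ``window_bp`` is the half-window on each side of the TSS; ``bin_bp`` the
    bin width.  The full window ``2 * window_bp`` must tile evenly into bins.
    ``orient_by_strand`` flips minus-strand rows so bin order is gene-relative
    (set False for purely genomic left-to-right rows).
    """

    window_bp: int = 5000
    bin_bp: int = 100
    orient_by_strand: bool = True

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.bin_bp <= 0:
            raise ValueError("window_bp and bin_bp must be positive")
        if (2 * self.window_bp) % self.bin_bp != 0:
            raise ValueError("2 * window_bp must be divisible by bin_bp")

    @property
    def n_bins(self) -> int:
        return 2 * self.window_bp // self.bin_bp

    @property
    def offsets(self) -> np.ndarray:
        """Bin midpoint offsets relative to the TSS (gene-oriented)."""
        left = np.arange(self.n_bins) * self.bin_bp - self.window_bp
        return left + self.bin_bp // 2


@dataclass
class OccupancyMatrix:
    """Genes x bins matrix of mean signal, rows oriented 5'->3' per gene."""

    gene_names: list[str]
    values: np.ndarray        # (n_genes, n_bins) float64, finite, >= 0
    offsets: np.ndarray       # bin midpoint offsets, bp relative to TSS
    edge_clipped: np.ndarray  # bool per gene: window ran past the chromosome start

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_names), len(self.offsets)):
            raise ValueError("values shape does not match gene/offset counts")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("occupancy values must be finite")

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def row(self, gene_name: str) -> np.ndarray:
        return self.values[self.gene_names.index(gene_name)]

    def subset(self, genes: Sequence[str]) -> "OccupancyMatrix":
        idx = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [idx[g] for g in genes]
        return OccupancyMatrix(
            gene_names=list(genes),
            values=self.values[rows],
            offsets=self.offsets,
            edge_clipped=self.edge_clipped[rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.offsets)


def _bin_edges(gene: GeneModel, cfg: OccupancyConfig) -> np.ndarray:
    """Genomic (left-to-right) bin edges of the gene's window, length n_bins + 1."""
    # the genomic window is [tss - W, tss + W) for both strands; minus-strand
    # rows are reversed after querying so bin 0 ends up 5' of the gene
    left = gene.tss - cfg.window_bp
    return left + np.arange(cfg.n_bins + 1, dtype=np.int64) * cfg.bin_bp


def build_matrix(
    genes: Sequence[GeneModel],
    track: CoverageTrack,
    cfg: OccupancyConfig | None = None,
) -> OccupancyMatrix:
    """Average a depth-scaled track in TSS-centered bins for every gene.

    For a plus-strand gene, bin ``i`` covers
    ``[tss - window_bp + i * bin_bp, tss - window_bp + (i+1) * bin_bp)``; the
    bin immediately downstream of the TSS begins at the TSS itself.  Rows of
    minus-strand genes are the mirror image (bin 0 is 5' of the gene).  Bins
    reaching past position 0 read as zero and set the gene's edge-clip flag.
    Genes on chromosomes absent from the track get all-zero rows with a
    logged warning.
    """
    if cfg is None:
        cfg = OccupancyConfig()
    if not genes:
        raise ValueError("no genes supplied")

    values = np.zeros((len(genes), cfg.n_bins))
    clipped = np.zeros(len(genes), dtype=bool)
    missing_chroms: set[str] = set()
    for i, gene in enumerate(genes):
        edges = _bin_edges(gene, cfg)
        if edges[0] < 0:
            clipped[i] = True
        if gene.chrom not in track.chroms:
            missing_chroms.add(gene.chrom)
            continue
        row = track.binned_means(gene.chrom, edges)
        if clipped[i]:
            # zero-fill bins that lie fully or partly below position 0:
            # binned_means clamps negative edges, so recompute those bins as
            # (mass over the in-range part) / full bin width, which is the
            # zero-filled mean
            full_widths = np.diff(edges)
            in_range = np.diff(np.maximum(edges, 0))
            row = row * in_range / full_widths
        if gene.strand == "-" and cfg.orient_by_strand:
            row = row[::-1]
        values[i] = row
    if missing_chroms:
        logger.warning(
            "%d gene(s) on chromosomes absent from track (%s); rows set to zero",
            int(sum(g.chrom in missing_chroms for g in genes)),
            sorted(missing_chroms),
        )
    return OccupancyMatrix(
        gene_names=[g.gene_name for g in genes],
        values=values,
        offsets=cfg.offsets,
        edge_clipped=clipped,
    )


def write_matrix(matrix: OccupancyMatrix, handle: IO[str]) -> None:
    """Write the matrix as TSV: header of bin-midpoint offsets, one row per gene."""
    handle.write("gene\t" + "\t".join(str(int(o)) for o in matrix.offsets) + "\n")
    for gene, row in zip(matrix.gene_names, matrix.values):
        handle.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix(source) -> OccupancyMatrix:
    """Read a matrix written by :func:`write_matrix` (lossless round-trip)."""
    frame = pd.read_csv(source, sep="\t", index_col=0, float_precision="round_trip")
    if frame.isna().any().any():
        raise ValueError("ragged or non-numeric occupancy matrix")
    offsets = np.array([int(c) for c in frame.columns])
    return OccupancyMatrix(
        gene_names=[str(g) for g in frame.index],
        values=frame.to_numpy(dtype=np.float64),
        offsets=offsets,
        edge_clipped=np.zeros(len(frame), dtype=bool),
    )
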