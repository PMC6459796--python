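"""Synthetic annotation, coverage, term-table and Ct fixtures with ground truth.

The generator emulates the statistical structure of a TSS-centered
H3K27me3 ChIP-seq comparison between two genotypes, so that every pipeline
stage can be exercised offline against a known answer.  Genes fall into four
occupancy archetypes:

* ``broad`` — a high plateau across the whole TSS window (Polycomb domain);
* ``tss_strong`` — a sharp Gaussian summit at the TSS;
* ``tss_weak`` — a lower, equally wide TSS summit;
* ``unmarked`` — background only.

A genotype effect multiplies the broad-domain amplitude by ``1 + delta_broad``
(default +0.3, i.e. more signal in the mutant) and the TSS-summit amplitude
by ``1 + delta_summit`` (default -0.3, less signal in the mutant).  Depth
noise is Poisson on 100-bp segments: realized segment values are counts drawn
around expectation x (reads / 1e6), so scaling the declared mappable read
count back to one million recovers the expectation scale.  A variance-zero
mode supports exact tests.

Defaults (plateau 8, summits 12 and 4, baseline 0.5, sigma 500 bp, class
proportions 2/10/55/33%) are fixture choices shaped like real data, not
measured values.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from tssmeta.annotations import GeneModel, write_refgene
from tssmeta.coverage import CoverageTrack
from tssmeta.genesets import TermAnnotation

CLASSES = ("broad", "tss_strong", "tss_weak", "unmarked")


@dataclass(frozen=True)
class ArchetypeParams:
    """Shape, mixture and genotype-effect parameters of the four archetypes."""

    broad_height: float = 8.0          # plateau across the window, signal units
    tss_strong_height: float = 12.0    # Gaussian summit height above baseline
    tss_strong_sigma: float = 500.0    # summit width, bp
    tss_weak_height: float = 4.0
    tss_weak_sigma: float = 500.0
    baseline: float = 0.5              # background signal everywhere
    proportions: tuple[float, float, float, float] = (0.02, 0.10, 0.55, 0.33)
    delta_broad: float = 0.3           # mutant broad amplitude multiplier - 1
    delta_summit: float = -0.3         # mutant summit amplitude multiplier - 1

    def __post_init__(self) -> None:
        if not (
            self.broad_height > self.baseline >= 0
            and self.tss_strong_height > self.baseline
            and self.tss_weak_height > self.baseline
        ):
            raise ValueError("archetype heights must exceed the baseline (>= 0)")
        if self.tss_weak_height >= self.tss_strong_height:
            raise ValueError("tss_weak must be lower than tss_strong")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.tss_strong_sigma, self.tss_weak_sigma) <= 0:
            raise ValueError("summit widths must be positive")

    @classmethod
    def from_yaml(cls, source) -> "ArchetypeParams":
        if isinstance(source, (str, Path)):
            with open(source) as handle:
                data = yaml.safe_load(handle)
        else:
            data = yaml.safe_load(source)
        if "proportions" in data:
            data["proportions"] = tuple(data["proportions"])
        return cls(**data)

    def to_yaml(self, handle) -> None:
        data = asdict(self)
        data["proportions"] = list(data["proportions"])
        yaml.safe_dump(data, handle)


@dataclass
class GroundTruth:
    """Gene -> archetype map plus the parameters and seed that produced it."""

    classes: dict[str, str]
    params: ArchetypeParams
    seed: int

    def genes_of(self, cls_name: str) -> list[str]:
        return [g for g, c in self.classes.items() if c == cls_name]


def _require_seed(seed: int) -> int:
    if not 0 <= seed < 2**31:
        raise ValueError("seed must be a non-negative 31-bit integer")
    return seed


def simulate_annotation(
    n_genes: int,
    seed: int = 0,
    chrom_length: int | None = None,
    window_bp: int = 5000,
    chrom: str = "chrS",
) -> tuple[str, list[GeneModel]]:
    """Lay out genes on one synthetic chromosome; return refGene text + models.

    TSS positions sit on a 100-bp grid with spacing >= 2*window_bp + 1 kb, so
    no two TSS windows overlap.  Strands alternate +/-; transcript lengths are
    drawn uniformly in 2-8 kb.  Deterministic for a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(_require_seed(seed))
    spacing = 2 * window_bp + 2000
    margin = window_bp + 1000
    needed = margin + spacing * (n_genes - 1) + margin + 8000
    if chrom_length is None:
        chrom_length = needed
    elif chrom_length < needed:
        raise ValueError(f"chromosome too short: need >= {needed} bp for {n_genes} genes")

    width = len(str(n_genes))
    models: list[GeneModel] = []
    for i in range(n_genes):
        tss = margin + spacing * i  # multiple of 100 by construction
        strand = "+" if i % 2 == 0 else "-"
        length = int(rng.integers(2000, 8001))
        if strand == "+":
            tx_start, tx_end = tss, tss + length
        else:
            tx_end = tss + 1
            tx_start = tx_end - length
        models.append(
            GeneModel(
                gene_name=f"G{i:0{width}d}",
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                transcript_id=f"NM_{i:06d}",
            )
        )
    buf = io.StringIO()
    write_refgene(models, buf)
    return buf.getvalue(), models


def assign_truth(
    genes: Sequence[GeneModel], params: ArchetypeParams | None = None, seed: int = 0
) -> GroundTruth:
    """Assign each gene an archetype, hitting the class proportions exactly.

    Class counts follow the largest-remainder rule on ``params.proportions``;
    which gene gets which class is a seeded shuffle.
    """
    if params is None:
        params = ArchetypeParams()
    rng = np.random.default_rng(_require_seed(seed))
    n = len(genes)
    quotas = np.array(params.proportions) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    for idx in np.argsort(-(quotas - counts))[:remainder]:
        counts[idx] += 1
    labels = np.repeat(np.array(CLASSES, dtype=object), counts)
    rng.shuffle(labels)
    return GroundTruth(
        classes={g.gene_name: str(c) for g, c in zip(genes, labels)},
        params=params,
        seed=seed,
    )


def _expected_profile(
    midpoints: np.ndarray, tss: int, cls_name: str, params: ArchetypeParams, mutant: bool
) -> np.ndarray:
    """Expected signal at segment midpoints inside a gene's TSS window."""
    if cls_name == "broad":
        height = params.broad_height * (1 + params.delta_broad if mutant else 1.0)
        return np.full(midpoints.shape, height)
    if cls_name in ("tss_strong", "tss_weak"):
        height = params.tss_strong_height if cls_name == "tss_strong" else params.tss_weak_height
        sigma = params.tss_strong_sigma if cls_name == "tss_strong" else params.tss_weak_sigma
        if mutant:
            height *= 1 + params.delta_summit
        return params.baseline + height * np.exp(-((midpoints - tss) ** 2) / (2 * sigma**2))
    if cls_name == "unmarked":
        return np.full(midpoints.shape, params.baseline)
    raise ValueError(f"unknown archetype class {cls_name!r}")


def simulate_tracks(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    genotype: str = "WT",
    depth_reads: int = 1_000_000,
    seed: int = 0,
    noise: bool = True,
    window_bp: int = 5000,
    segment_bp: int = 100,
    chrom_length: int | None = None,
) -> tuple[CoverageTrack, int]:
    """Simulate one genotype's pileup track; return (raw track, mappable reads).

    Expected signal is the archetype shape inside each TSS window and the
    baseline elsewhere.  With ``noise`` on, each ``segment_bp`` segment's value
    is Poisson-distributed around expectation x (depth_reads / 1e6); passing
    the returned read count to ``scale_to_million`` recovers the expectation
    scale.  With ``noise`` off, values equal expectation x depth factor
    exactly.  Broad-class windows scale wholesale in the mutant, so the
    noise-free mutant row is exactly (1 + delta_broad) x the wild-type row.
    """
    if genotype not in ("WT", "Mut"):
        raise ValueError("genotype must be 'WT' or 'Mut'")
    if depth_reads <= 0:
        raise ValueError("depth_reads must be positive")
    missing = [g.gene_name for g in genes if g.gene_name not in truth.classes]
    if missing:
        raise ValueError(f"ground truth does not cover genes: {missing[:5]}")
    mutant = genotype == "Mut"
    params = truth.params
    rng = np.random.default_rng(_require_seed(seed))

    chroms = sorted({g.chrom for g in genes})
    if len(chroms) != 1:
        raise ValueError("simulate_tracks expects a single-chromosome layout")
    chrom = chroms[0]
    if chrom_length is None:
        chrom_length = max(g.tss for g in genes) + window_bp + 1000
    n_seg = int(np.ceil(chrom_length / segment_bp))
    edges = np.arange(n_seg + 1, dtype=np.int64) * segment_bp
    midpoints = edges[:-1] + segment_bp / 2.0

    expected = np.full(n_seg, params.baseline)
    for gene in genes:
        lo = max(gene.tss - window_bp, 0)
        hi = min(gene.tss + window_bp, chrom_length)
        s0, s1 = lo // segment_bp, int(np.ceil(hi / segment_bp))
        expected[s0:s1] = _expected_profile(
            midpoints[s0:s1], gene.tss, truth.classes[gene.gene_name], params, mutant
        )

    depth_factor = depth_reads / 1e6
    if noise:
        values = rng.poisson(expected * depth_factor).astype(float)
    else:
        values = expected * depth_factor
    keep = values > 0  # bedGraph convention: zero runs are implicit
    track = CoverageTrack.from_intervals(
        (chrom, int(edges[i]), int(edges[i + 1]), float(values[i]))
        for i in np.nonzero(keep)[0]
    )
    return track, depth_reads


def simulate_ct(
    n_wt: int,
    n_ko: int,
    planted_shift_e: float,
    sd: float,
    seed: int = 0,
    gene: str = "Tgt",
    reference: str = "Hprt",
    base_delta_ct: float = 2.0,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Unpaired WT/Mut Ct table with a planted mutant dCt shift.

    Target dCt ~ Normal(base_delta_ct + e * 1[mutant], sd); the reference gene
    is emitted at a fixed Ct so all variation sits in the target.  At sd = 0
    the mutant fold is exactly 2^-e.
    """
    if min(n_wt, n_ko) < 2:
        raise ValueError("need at least 2 samples per arm")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(_require_seed(seed))
    rows = []
    for arm, n, shift in (("WT", n_wt, 0.0), ("Mut", n_ko, planted_shift_e)):
        delta = base_delta_ct + shift + rng.normal(0.0, sd, size=n)
        for j in range(n):
            sample = f"{arm}{j + 1}"
            rows.append((sample, reference, reference_ct, arm))
            rows.append((sample, gene, reference_ct + delta[j], arm))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ct", "arm"])


def simulate_ct_paired(
    n_pairs: int,
    planted_ddct: float,
    sd: float,
    seed: int = 0,
    gene: str = "Tgt",
    reference: str = "Hprt",
    base_delta_ct: float = 2.0,
    between_sd: float = 0.5,
    reference_ct: float = 20.0,
) -> pd.DataFrame:
    """Paired vehicle/drug Ct table: per-pair baseline plus a planted ddCt.

    Each pair's vehicle dCt varies between embryos (``between_sd``); the drug
    side adds ``planted_ddct`` plus Normal(0, sd) within-pair noise, so at
    sd = 0 every treated fold is exactly 2^-planted_ddct.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    if sd < 0 or between_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(_require_seed(seed))
    rows = []
    for i in range(n_pairs):
        pair = f"E{i + 1}"
        dct_v = base_delta_ct + rng.normal(0.0, between_sd)
        dct_d = dct_v + planted_ddct + rng.normal(0.0, sd)
        for arm, dct in (("vehicle", dct_v), ("drug", dct_d)):
            sample = f"{pair}_{arm}"
            rows.append((sample, reference, reference_ct, arm, pair))
            rows.append((sample, gene, reference_ct + dct, arm, pair))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "ct", "arm", "pair_id"])


def simulate_term_table(
    truth: GroundTruth,
    seed: int = 0,
    n_planted: int = 4,
    planted_size: int = 40,
    enrichment_odds: float = 8.0,
    n_null: int = 50,
    null_size: int = 100,
) -> list[TermAnnotation]:
    """Annotation-term table with synaptic/neuronal terms planted on summit genes.

    Planted terms carry "synaptic"/"neuron" names and draw their member genes
    with weight ``enrichment_odds`` for TSS-summit (tss_strong/tss_weak)
    archetypes versus 1 for the rest; at odds 1 they are unplanted.  Null
    terms draw members uniformly, giving an approximately uniform EASE-p null
    for calibration.  Deterministic under a fixed seed.
    """
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")
    rng = np.random.default_rng(_require_seed(seed))
    genes = np.array(sorted(truth.classes), dtype=object)
    summit = np.array(
        [truth.classes[g] in ("tss_strong", "tss_weak") for g in genes], dtype=bool
    )
    weights = np.where(summit, enrichment_odds, 1.0)
    weights = weights / weights.sum()

    annotations: list[TermAnnotation] = []
    planted_names = [
        ("synaptic vesicle transport {}", "biological_process"),
        ("synapse assembly {}", "biological_process"),
        ("neuron projection {}", "cellular_component"),
        ("synaptic membrane {}", "cellular_component"),
    ]
    for t in range(n_planted):
        template, branch = planted_names[t % len(planted_names)]
        members = rng.choice(genes, size=min(planted_size, len(genes)), replace=False, p=weights)
        for g in members:
            annotations.append(TermAnnotation(str(g), template.format(t + 1), branch))
    for t in range(n_null):
        members = rng.choice(genes, size=min(null_size, len(genes)), replace=False)
        for g in members:
            annotations.append(
                TermAnnotation(str(g), f"metabolic process {t + 1}", "biological_process")
            )
    return annotations


def write_term_table(annotations: Sequence[TermAnnotation], handle) -> None:
    for ann in annotations:
        handle.write(f"{ann.gene_name}\t{ann.term_name}\t{ann.branch}\n")


def write_truth(truth: GroundTruth, handle) -> None:
    handle.write("gene\tarchetype\n")
    for gene in sorted(truth.classes):
        handle.write(f"{gene}\t{truth.classes[gene]}\n")
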