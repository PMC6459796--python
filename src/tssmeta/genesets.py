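"""Gene-set classification, cluster distributions, and EASE-score enrichment.

The neuronal gene set is defined by annotation-term text: any term (any
ontology branch) containing "synapse" or "synaptic", or a cellular-component
term containing "neuron" (case-insensitive substring matching).  Enrichment
uses the EASE score — the conservatively modified one-sided Fisher's exact
test popularized by DAVID, in which the list-term overlap count is
decremented by one before computing the hypergeometric upper tail — with
Benjamini-Hochberg correction across terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from tssmeta.clustering import ClusterAssignment

logger = logging.getLogger(__name__)

BRANCHES = ("biological_process", "cellular_component", "molecular_function")


@dataclass(frozen=True)
class TermAnnotation:
    """One gene-to-term link with its ontology branch."""

    gene_name: str
    term_name: str
    branch: str

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"unknown branch {self.branch!r}; expected one of {BRANCHES}")


@dataclass
class EnrichmentResult:
    """EASE enrichment of one term: 2x2 counts, EASE p, BH q."""

    term_name: str
    a: int  # list & term
    b: int  # list only
    c: int  # term only
    d: int  # background, neither
    ease_p: float
    bh_q: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.bh_q < 0.05


def classify_neuronal(
    annotations: Iterable[TermAnnotation], genes: Iterable[str] | None = None
) -> set[str]:
    """Select neuronal genes from annotation-term text.

    A gene qualifies if any of its terms (any branch) contains "synapse" or
    "synaptic", or if a cellular_component term contains "neuron"
    (case-insensitive substrings).  If ``genes`` is given, the result is
    intersected with it.
    """
    hits: set[str] = set()
    for ann in annotations:
        name = ann.term_name.lower()
        if "synapse" in name or "synaptic" in name:
            hits.add(ann.gene_name)
        elif ann.branch == "cellular_component" and "neuron" in name:
            hits.add(ann.gene_name)
    if genes is not None:
        hits &= set(genes)
    return hits


def cluster_distribution(
    assignment: ClusterAssignment, geneset: Iterable[str]
) -> dict[int, float]:
    """Percentage of a gene set falling in each occupancy cluster.

    Genes absent from the assignment are dropped (their count is logged);
    percentages are over the retained genes and sum to 100.
    """
    geneset = set(geneset)
    retained = [g for g in geneset if g in assignment.labels]
    dropped = len(geneset) - len(retained)
    if dropped:
        logger.info("%d gene(s) of the set absent from the assignment; dropped", dropped)
    if not retained:
        raise ValueError("no genes of the set are present in the assignment")
    counts = {label: 0 for label in range(1, assignment.k + 1)}
    for g in retained:
        counts[assignment.labels[g]] += 1
    return {label: 100.0 * n / len(retained) for label, n in counts.items()}


def ease_score(a: int, b: int, c: int, d: int) -> float:
    """EASE p-value of a 2x2 table: one-sided Fisher upper tail with a -> max(a-1, 0).

    ``a`` = genes in list and term, ``b`` = list only, ``c`` = term only,
    ``d`` = background in neither.  The decrement makes single-gene overlaps
    uninformative (p = 1), penalizing terms supported by few genes.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    a2 = max(a - 1, 0)
    # hypergeometric upper tail P(X >= a2) on the decremented table
    pop, successes, draws = a2 + b + c + d, a2 + c, a2 + b
    return float(min(1.0, hypergeom.sf(a2 - 1, pop, successes, draws)))


def ease_enrichment(
    gene_list: Iterable[str],
    background: Iterable[str],
    term2genes: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """EASE-score enrichment of every term, BH-adjusted across terms.

    Each term's gene set is intersected with ``background`` before counting.
    Results are sorted by ascending EASE p; ``significant`` flags terms with
    BH q below ``alpha`` (default 0.05).
    """
    background = set(background)
    gene_list = set(gene_list)
    if not background:
        raise ValueError("background gene set is empty")
    stray = gene_list - background
    if stray:
        raise ValueError(f"gene list not contained in background: {sorted(stray)[:5]}")

    results: list[EnrichmentResult] = []
    for term, genes in term2genes.items():
        term_genes = set(genes) & background
        a = len(gene_list & term_genes)
        b = len(gene_list) - a
        c = len(term_genes) - a
        d = len(background) - a - b - c
        results.append(
            EnrichmentResult(term_name=term, a=a, b=b, c=c, d=d, ease_p=ease_score(a, b, c, d))
        )
    if results:
        qvals = multipletests([r.ease_p for r in results], method="fdr_bh")[1]
        for r, q in zip(results, qvals):
            r.bh_q = float(q)
    results.sort(key=lambda r: (r.ease_p, r.term_name))
    return results


def read_term_table(source) -> list[TermAnnotation]:
    """Read a 3-column TSV (gene, term_name, branch) of annotation links."""
    import pandas as pd

    frame = pd.read_csv(source, sep="\t", header=None, names=["gene", "term", "branch"])
    return [
        TermAnnotation(gene_name=str(g), term_name=str(t), branch=str(b))
        for g, t, b in frame.itertuples(index=False)
    ]


def read_gmt(source) -> dict[str, set[str]]:
    """Read a GMT file (term, description, genes...) into a term -> gene-set map."""
    term2genes: dict[str, set[str]] = {}
    close = False
    if isinstance(source, str):
        source = open(source)
        close = True
    try:
        for line in source:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            term2genes[fields[0]] = set(fields[2:])
    finally:
        if close:
            source.close()
    return term2genes


def terms_from_annotations(
    annotations: Iterable[TermAnnotation],
    branches: Sequence[str] | None = None,
) -> dict[str, set[str]]:
    """Pivot annotation links into a term -> gene-set map, optionally by branch."""
    out: dict[str, set[str]] = {}
    for ann in annotations:
        if branches is not None and ann.branch not in branches:
            continue
        out.setdefault(ann.term_name, set()).add(ann.gene_name)
    return out
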