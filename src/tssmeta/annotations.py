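"""refGene annotation parsing and longest-transcript gene models.

UCSC refGene tables carry one row per transcript.  Metagene analysis anchors
on a single transcription start site (TSS) per gene, so transcripts are
collapsed to the genome-wide longest one per gene symbol.  Coordinates follow
the UCSC convention: 0-based, half-open ``[tx_start, tx_end)``; the TSS of a
minus-strand gene is ``tx_end - 1``, the last covered base.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

logger = logging.getLogger(__name__)

#: 1-based column positions in the UCSC refGene dialect.
_COL_NAME = 1      # transcript accession (0-based index)
_COL_CHROM = 2
_COL_STRAND = 3
_COL_TXSTART = 4
_COL_TXEND = 5
_COL_NAME2 = 12    # gene symbol
_MIN_COLS = 16

PathOrStream = Union[str, Path, IO[str], IO[bytes], Iterable[str]]


class RefGeneParseError(ValueError):
    """A refGene line that cannot be interpreted (column count, coordinates, strand)."""


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript row of a refGene table."""

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise RefGeneParseError(f"unknown strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise RefGeneParseError(
                f"tx_start must be < tx_end, got [{self.tx_start}, {self.tx_end})"
            )

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass(frozen=True)
class GeneModel:
    """A gene represented by its selected (longest) transcript.

    ``tss`` is the 0-based genomic position of the transcription start:
    ``tx_start`` on the plus strand, ``tx_end - 1`` on the minus strand.
    """

    gene_name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    transcript_id: str = ""

    @property
    def tss(self) -> int:
        return tss_of(self)

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start


def tss_of(model: GeneModel) -> int:
    """Strand-aware TSS: first transcribed base of the gene (0-based)."""
    return model.tx_start if model.strand == "+" else model.tx_end - 1


def _open_text(source: PathOrStream) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:  # type: ignore[operator]
            yield from handle
        return
    if isinstance(source, io.IOBase) and isinstance(source, io.BufferedIOBase):
        # raw byte stream; may be gzipped
        data = source.read()
        if data[:2] == b"\x1f\x8b":
            data = gzip.decompress(data)
        yield from io.StringIO(data.decode())
        return
    for line in source:
        if isinstance(line, bytes):
            line = line.decode()
        yield line


def parse_refgene(source: PathOrStream) -> list[TranscriptRecord]:
    """Parse a header-less UCSC refGene table into transcript records.

    Accepts a path (``.gz`` transparently decompressed), an open text or byte
    stream, or any iterable of lines.  Each line must carry at least 16
    tab-separated fields in refGene column order.

    Raises
    ------
    RefGeneParseError
        On short lines, non-integer coordinates or unknown strand symbols,
        citing the 1-based line number.
    """
    records: list[TranscriptRecord] = []
    for lineno, line in enumerate(_open_text(source), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < _MIN_COLS:
            raise RefGeneParseError(
                f"line {lineno}: expected >= {_MIN_COLS} tab-separated fields, got {len(fields)}"
            )
        try:
            tx_start = int(fields[_COL_TXSTART])
            tx_end = int(fields[_COL_TXEND])
        except ValueError as exc:
            raise RefGeneParseError(f"line {lineno}: non-integer coordinates: {exc}") from None
        strand = fields[_COL_STRAND]
        if strand not in ("+", "-"):
            raise RefGeneParseError(f"line {lineno}: unknown strand symbol {strand!r}")
        try:
            records.append(
                TranscriptRecord(
                    transcript_id=fields[_COL_NAME],
                    gene_name=fields[_COL_NAME2],
                    chrom=fields[_COL_CHROM],
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                )
            )
        except RefGeneParseError as exc:
            raise RefGeneParseError(f"line {lineno}: {exc}") from None
    return records


def select_longest_transcripts(
    records: list[TranscriptRecord],
    chroms: Iterable[str] | None = None,
) -> list[GeneModel]:
    """Collapse transcripts to one GeneModel per gene symbol, keeping the longest.

    Ties break by ``(chrom, tx_start, transcript_id)`` ascending.  Gene symbols
    appearing on multiple chromosomes collapse to the single genome-wide
    longest transcript (a warning is logged).  If ``chroms`` is given, records
    on other chromosomes are dropped first.

    Output is sorted by gene_name for deterministic downstream processing.
    """
    if chroms is not None:
        allowed = set(chroms)
        records = [r for r in records if r.chrom in allowed]
    if not records:
        raise ValueError("no transcript records to collapse")

    by_gene: dict[str, list[TranscriptRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene_name, []).append(rec)

    models: list[GeneModel] = []
    for gene, txs in sorted(by_gene.items()):
        if len({t.chrom for t in txs}) > 1:
            logger.warning(
                "gene %s has transcripts on multiple chromosomes (%s); "
                "keeping the genome-wide longest",
                gene,
                sorted({t.chrom for t in txs}),
            )
        best = min(txs, key=lambda t: (-t.length, t.chrom, t.tx_start, t.transcript_id))
        models.append(
            GeneModel(
                gene_name=gene,
                chrom=best.chrom,
                strand=best.strand,
                tx_start=best.tx_start,
                tx_end=best.tx_end,
                transcript_id=best.transcript_id,
            )
        )
    return models


def write_refgene(models: Iterable[GeneModel], handle: IO[str]) -> None:
    """Write gene models back in the 16-column refGene dialect (unused columns zeroed)."""
    for m in models:
        fields = [
            "0", m.transcript_id or m.gene_name, m.chrom, m.strand,
            str(m.tx_start), str(m.tx_end), str(m.tx_start), str(m.tx_end),
            "1", f"{m.tx_start},", f"{m.tx_end},", "0", m.gene_name,
            "unk", "unk", "-1,",
        ]
        handle.write("\t".join(fields) + "\n")


def write_tss_bed(models: Iterable[GeneModel], handle: IO[str]) -> None:
    """Write 6-column BED of TSS points: chrom, tss, tss+1, gene, 0, strand."""
    for m in models:
        handle.write(f"{m.chrom}\t{m.tss}\t{m.tss + 1}\t{m.gene_name}\t0\t{m.strand}\n")
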