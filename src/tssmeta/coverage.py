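"""Piecewise-constant coverage tracks (bedGraph) with depth scaling.

A pileup assigns a constant tag density to each interval of the genome;
bases not covered by any interval have implicit value zero (the bedGraph
convention — pileup writers omit zero runs).  Tracks are scaled to a common
depth of one million mappable reads before any cross-sample comparison.

Interval queries are answered through a per-chromosome cumulative "mass"
function M(x) = integral of the signal over [0, x); the mean over [s, e) is
then (M(e) - M(s)) / (e - s), which vectorizes over many query intervals.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import numpy as np
from scipy import stats

PathOrStream = Union[str, Path, IO[str], Iterable[str]]


class BedGraphFormatError(ValueError):
    """Malformed bedGraph input (bad columns, negative values, overlapping intervals)."""


@dataclass
class _ChromIntervals:
    """Sorted, non-overlapping intervals of one chromosome plus cumulative mass."""

    starts: np.ndarray   # int64, sorted
    ends: np.ndarray     # int64
    values: np.ndarray   # float64, >= 0
    cummass: np.ndarray = field(init=False)  # mass of intervals 0..i-1

    def __post_init__(self) -> None:
        mass = self.values * (self.ends - self.starts)
        self.cummass = np.concatenate([[0.0], np.cumsum(mass)])

    def mass_upto(self, pos: np.ndarray) -> np.ndarray:
        """Integral of the signal over [0, pos) for an array of positions."""
        pos = np.asarray(pos, dtype=np.int64)
        idx = np.searchsorted(self.starts, pos, side="right") - 1
        idx_c = np.clip(idx, 0, len(self.starts) - 1)
        inside = (idx >= 0) & (pos > self.starts[idx_c])
        partial = np.where(
            inside,
            self.values[idx_c] * (np.minimum(pos, self.ends[idx_c]) - self.starts[idx_c]),
            0.0,
        )
        full = self.cummass[np.clip(idx, 0, None)]
        return full + partial


@dataclass
class CoverageTrack:
    """Genome coverage as per-chromosome sorted non-overlapping intervals.

    ``scale_factor`` records the depth multiplier already applied (1.0 for a
    raw pileup); :func:`scale_to_million` updates it multiplicatively.
    """

    chroms: dict[str, _ChromIntervals]
    scale_factor: float = 1.0

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[tuple[str, int, int, float]],
        scale_factor: float = 1.0,
    ) -> "CoverageTrack":
        """Build a track from (chrom, start, end, value) tuples, validating invariants."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if start >= end:
                raise BedGraphFormatError(f"{chrom}:{start}-{end}: start must be < end")
            if not np.isfinite(value) or value < 0:
                raise BedGraphFormatError(f"{chrom}:{start}-{end}: invalid value {value}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        chroms: dict[str, _ChromIntervals] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            starts = np.array([s for s, _, _ in ivs], dtype=np.int64)
            ends = np.array([e for _, e, _ in ivs], dtype=np.int64)
            values = np.array([v for _, _, v in ivs], dtype=np.float64)
            overlap = np.nonzero(starts[1:] < ends[:-1])[0]
            if overlap.size:
                i = int(overlap[0])
                raise BedGraphFormatError(
                    f"overlapping intervals on {chrom}: "
                    f"[{starts[i]}, {ends[i]}) and [{starts[i + 1]}, {ends[i + 1]})"
                )
            chroms[chrom] = _ChromIntervals(starts, ends, values)
        return cls(chroms=chroms, scale_factor=scale_factor)

    def intervals(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self.chroms):
            ci = self.chroms[chrom]
            for s, e, v in zip(ci.starts, ci.ends, ci.values):
                yield chrom, int(s), int(e), float(v)

    def total_mass(self) -> float:
        return float(sum(ci.cummass[-1] for ci in self.chroms.values()))

    def binned_means(self, chrom: str, edges: np.ndarray) -> np.ndarray:
        """Mean signal in the bins delimited by sorted ``edges`` (len B+1 -> B means).

        Edges below 0 are clamped; bases outside any interval contribute 0.
        A chromosome absent from the track yields all-zero means.
        """
        edges = np.asarray(edges, dtype=np.int64)
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if chrom not in self.chroms:
            return np.zeros(len(edges) - 1)
        mass = self.chroms[chrom].mass_upto(np.maximum(edges, 0))
        return np.diff(mass) / widths


def read_bedgraph(source: PathOrStream) -> CoverageTrack:
    """Read a 4-column bedGraph into a :class:`CoverageTrack` (scale_factor 1.0).

    ``track``/``browser`` header lines and ``#`` comments are skipped.  Lines
    may appear in any order; intervals are sorted internally.  Overlapping
    intervals or negative values raise :class:`BedGraphFormatError`.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_bedgraph(handle)

    def gen() -> Iterable[tuple[str, int, int, float]]:
        for lineno, line in enumerate(source, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedGraphFormatError(f"line {lineno}: expected 4 columns, got {len(fields)}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedGraphFormatError(f"line {lineno}: {exc}") from None
            if value < 0:
                raise BedGraphFormatError(f"line {lineno}: negative value {value}")
            yield fields[0], start, end, value

    return CoverageTrack.from_intervals(gen())


def write_bedgraph(track: CoverageTrack, handle: IO[str], merge: bool = True) -> None:
    """Write a track as 4-column bedGraph, merging adjacent equal-valued intervals."""
    pending: tuple[str, int, int, float] | None = None
    for chrom, start, end, value in track.intervals():
        if (
            merge
            and pending is not None
            and pending[0] == chrom
            and pending[2] == start
            and pending[3] == value
        ):
            pending = (chrom, pending[1], end, value)
            continue
        if pending is not None:
            handle.write(f"{pending[0]}\t{pending[1]}\t{pending[2]}\t{pending[3]:g}\n")
        pending = (chrom, start, end, value)
    if pending is not None:
        handle.write(f"{pending[0]}\t{pending[1]}\t{pending[2]}\t{pending[3]:g}\n")


def scale_to_million(track: CoverageTrack, mappable_reads: int) -> CoverageTrack:
    """Return a copy scaled to a depth of one million mappable reads.

    Every value is multiplied by ``1e6 / mappable_reads`` and the track's
    ``scale_factor`` is updated by the same factor, so the applied scaling
    stays auditable.
    """
    if mappable_reads <= 0:
        raise ValueError(f"mappable_reads must be positive, got {mappable_reads}")
    factor = 1e6 / mappable_reads
    chroms = {
        chrom: _ChromIntervals(ci.starts, ci.ends, ci.values * factor)
        for chrom, ci in track.chroms.items()
    }
    return CoverageTrack(chroms=chroms, scale_factor=track.scale_factor * factor)


def mean_signal(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Mean signal per base over [start, end); uncovered bases count as 0."""
    if start >= end:
        raise ValueError(f"start must be < end, got [{start}, {end})")
    if chrom not in track.chroms:
        return 0.0
    ci = track.chroms[chrom]
    mass = ci.mass_upto(np.array([max(start, 0), max(end, 0)]))
    return float((mass[1] - mass[0]) / (end - start))


def track_similarity(
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    chrom_sizes: Mapping[str, int],
    bin_bp: int = 1000,
) -> float:
    """Pearson correlation of two tracks over genome-wide fixed-width bins.

    Operationalizes a qualitative "no redistribution of binding sites"
    comparison as a single global statistic: both tracks are averaged in
    ``bin_bp`` bins across every chromosome in ``chrom_sizes`` and the two
    binned vectors are correlated.  Scale-invariant, so differing depths do
    not matter once both tracks are on a common per-bp scale.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    vec_a: list[np.ndarray] = []
    vec_b: list[np.ndarray] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        edges = np.arange(0, size, bin_bp, dtype=np.int64)
        edges = np.append(edges, size)  # last bin may be short
        if len(edges) < 2:
            continue
        vec_a.append(track_a.binned_means(chrom, edges))
        vec_b.append(track_b.binned_means(chrom, edges))
    a = np.concatenate(vec_a)
    b = np.concatenate(vec_b)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("binned vector is constant; Pearson correlation undefined")
    return float(stats.pearsonr(a, b).statistic)
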