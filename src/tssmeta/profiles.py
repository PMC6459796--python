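"""Metagene profiles: per-bin averages over gene groups and genotype differences."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from tssmeta.occupancy import OccupancyMatrix


@dataclass
class MetageneProfile:
    """Average occupancy profile of a gene group on the common TSS bin grid.

    ``sem`` is the per-bin standard error of the mean across genes (ddof=1;
    zero for a single gene).  The band is descriptive only — no per-bin
    inference is attached to it.
    """

    offsets: np.ndarray  # bp relative to TSS, bin midpoints
    mean: np.ndarray
    sem: np.ndarray
    n_genes: int
    label: str = ""


def metagene(matrix: OccupancyMatrix, label: str = "") -> MetageneProfile:
    """Per-bin arithmetic mean and SEM across the genes of ``matrix``."""
    n = matrix.values.shape[0]
    if n == 0:
        raise ValueError("empty gene selection")
    mean = matrix.values.mean(axis=0)
    if n > 1:
        sem = matrix.values.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return MetageneProfile(offsets=matrix.offsets, mean=mean, sem=sem, n_genes=n, label=label)


def genotype_difference(
    profile_wt: MetageneProfile, profile_mut: MetageneProfile
) -> MetageneProfile:
    """Per-bin mutant - wild-type difference with SEMs added in quadrature.

    The returned ``n_genes`` is the smaller of the two groups.  The sign
    convention is mutant minus wild-type: positive bins mean more signal in
    the mutant.
    """
    if len(profile_wt.offsets) != len(profile_mut.offsets) or np.any(
        profile_wt.offsets != profile_mut.offsets
    ):
        raise ValueError("profiles are on different bin grids")
    return MetageneProfile(
        offsets=profile_wt.offsets,
        mean=profile_mut.mean - profile_wt.mean,
        sem=np.sqrt(profile_wt.sem**2 + profile_mut.sem**2),
        n_genes=min(profile_wt.n_genes, profile_mut.n_genes),
        label=f"{profile_mut.label}-{profile_wt.label}",
    )


def write_profiles(profiles: list[MetageneProfile], handle) -> None:
    """Write profiles as long TSV: label, offset, mean, sem, n."""
    handle.write("label\toffset\tmean\tsem\tn\n")
    for p in profiles:
        for off, m, s in zip(p.offsets, p.mean, p.sem):
            handle.write(f"{p.label}\t{int(off)}\t{m!r}\t{s!r}\t{p.n_genes}\n")
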