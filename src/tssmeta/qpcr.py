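"""ddCt relative-expression statistics for qPCR designs.

Relative expression is computed by the ddCt method against a single
reference gene (Hprt in the original assays).  Two designs are supported:

* unpaired genotype comparison — per-sample dCt = Ct(target) - Ct(reference);
  the wild-type mean dCt (dCt_mean) normalizes both arms, so folds are
  2^-(dCt_i - dCt_mean) and the wild-type log2 folds average exactly zero.
  Arms are compared with the classical equal-variance two-sample Student's
  t test on the fold values, two-sided.

* paired vehicle/drug comparison — each pair (one embryo's culture split in
  two) yields fold_d = 2^-(dCt_d - dCt_v) with the vehicle side defined as 1;
  pairs are tested with a paired t test of the folds against 1, two-sided.

Technical replicates (several Ct rows for one sample x gene) are averaged on
the Ct scale before any dCt.  Zero-variance degenerate inputs return t = 0,
p = 1 with a warning instead of failing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample_id", "gene", "ct", "arm")


@dataclass
class ExpressionResult:
    """Per-sample folds and the group-comparison test for one target gene."""

    gene: str
    folds: pd.DataFrame        # columns: sample_id, arm, delta_ct, fold (+ pair_id if paired)
    group_means: dict[str, float]
    t: float
    df: int
    p: float
    design: str = "unpaired"
    reference: str = "Hprt"
    note: str = field(default="")


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCt = Ct(target) - Ct(reference); larger dCt means lower expression."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    return float(ct_target - ct_reference)


def _validate(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("non-finite Ct values in table")
    if reference not in set(table["gene"]):
        raise ValueError(f"reference gene {reference!r} absent from table")
    return table


def _delta_ct_table(table: pd.DataFrame, gene: str, reference: str, extra: list[str]) -> pd.DataFrame:
    """Per-sample dCt for one target gene; technical replicates averaged on Ct scale."""
    keys = ["sample_id", "arm"] + extra
    ct = (
        table[table["gene"].isin([gene, reference])]
        .groupby(keys + ["gene"], as_index=False)["ct"]
        .mean()
        .pivot_table(index=keys, columns="gene", values="ct")
        .reset_index()
    )
    if gene not in ct.columns:
        raise ValueError(f"target gene {gene!r} absent from table")
    if ct[reference].isna().any():
        bad = ct.loc[ct[reference].isna(), "sample_id"].tolist()
        raise ValueError(f"samples lacking a {reference} record: {bad}")
    ct = ct.dropna(subset=[gene])
    ct["delta_ct"] = ct[gene] - ct[reference]
    return ct[keys + ["delta_ct"]]


def _safe_t(stat: float, p: float, df: int) -> tuple[float, float, str]:
    if np.isnan(stat) or np.isnan(p):
        warnings.warn("zero-variance fold values; reporting t=0, p=1", stacklevel=3)
        return 0.0, 1.0, "degenerate: zero variance"
    return float(stat), float(p), ""


def unpaired_expression(
    table: pd.DataFrame,
    gene: str,
    reference: str = "Hprt",
    arms: tuple[str, str] = ("WT", "Mut"),
) -> ExpressionResult:
    """ddCt folds and Student's t test for an unpaired two-arm design.

    ``arms[0]`` is the baseline arm whose mean dCt (dCt_mean) anchors the
    normalization; folds in both arms are 2^-(dCt - dCt_mean).  The arms are
    compared by the classical pooled-variance two-sample t test on folds.
    """
    table = _validate(table, reference)
    base_arm, alt_arm = arms
    dct = _delta_ct_table(table, gene, reference, extra=[])
    dct = dct[dct["arm"].isin(arms)]
    for arm in arms:
        if (dct["arm"] == arm).sum() < 2:
            raise ValueError(f"arm {arm!r} has fewer than 2 samples for {gene}")
    dct_mean = dct.loc[dct["arm"] == base_arm, "delta_ct"].mean()
    dct["fold"] = 2.0 ** -(dct["delta_ct"] - dct_mean)
    base = dct.loc[dct["arm"] == base_arm, "fold"].to_numpy()
    alt = dct.loc[dct["arm"] == alt_arm, "fold"].to_numpy()
    res = stats.ttest_ind(alt, base, equal_var=True)
    t, p, note = _safe_t(res.statistic, res.pvalue, 0)
    return ExpressionResult(
        gene=gene,
        folds=dct.reset_index(drop=True),
        group_means={base_arm: float(base.mean()), alt_arm: float(alt.mean())},
        t=t,
        df=len(base) + len(alt) - 2,
        p=p,
        design="unpaired",
        reference=reference,
        note=note,
    )


def paired_expression(
    table: pd.DataFrame,
    gene: str,
    reference: str = "Hprt",
    arms: tuple[str, str] = ("vehicle", "drug"),
    on_delta_scale: bool = False,
) -> ExpressionResult:
    """ddCt folds and paired t test for a split-culture vehicle/drug design.

    Each ``pair_id`` must contribute exactly one record per arm.  The treated
    fold per pair is 2^-(dCt_d - dCt_v); the vehicle side is 1 by definition.
    The paired test compares treated folds against 1 (equivalently a
    one-sample t test of fold - 1).  ``on_delta_scale=True`` instead tests
    the per-pair ddCt values against 0 — an alternative presentation, not
    the default.
    """
    table = _validate(table, reference)
    if "pair_id" not in table.columns:
        raise ValueError("paired design requires a pair_id column")
    vehicle_arm, drug_arm = arms
    dct = _delta_ct_table(table, gene, reference, extra=["pair_id"])
    dct = dct[dct["arm"].isin(arms)]
    wide = dct.pivot_table(index="pair_id", columns="arm", values="delta_ct")
    unmatched = wide.index[wide.isna().any(axis=1)].tolist()
    if unmatched or vehicle_arm not in wide.columns or drug_arm not in wide.columns:
        raise ValueError(f"unmatched vehicle/drug pairs for {gene}: {unmatched}")
    if len(wide) < 2:
        raise ValueError("paired test needs at least 2 complete pairs")
    ddct = (wide[drug_arm] - wide[vehicle_arm]).to_numpy()
    folds = 2.0 ** -ddct
    if on_delta_scale:
        res = stats.ttest_1samp(ddct, 0.0)
    else:
        res = stats.ttest_1samp(folds, 1.0)
    t, p, note = _safe_t(res.statistic, res.pvalue, 0)
    fold_table = pd.DataFrame(
        {
            "pair_id": wide.index,
            "delta_ct_vehicle": wide[vehicle_arm].to_numpy(),
            "delta_ct_drug": wide[drug_arm].to_numpy(),
            "fold_vehicle": 1.0,
            "fold_drug": folds,
        }
    )
    return ExpressionResult(
        gene=gene,
        folds=fold_table.reset_index(drop=True),
        group_means={vehicle_arm: 1.0, drug_arm: float(folds.mean())},
        t=t,
        df=len(wide) - 1,
        p=p,
        design="paired",
        reference=reference,
        note=note,
    )


def read_ct_table(source) -> pd.DataFrame:
    """Read a long-format Ct TSV (sample_id, gene, ct, arm[, pair_id])."""
    return pd.read_csv(source, sep="\t")
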