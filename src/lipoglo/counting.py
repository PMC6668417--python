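"""Plate-based ApoB particle counting.

Each ApoB-containing lipoprotein carries exactly one ApoB molecule, so the
NanoLuc luminescence of a larval homogenate is directly proportional to
particle number.  This module summarizes per-well relative luminescence
(RLU) by group and timepoint, checks reporter allele dosage (homozygotes
carry two tagged alleles and should show twice the heterozygote signal),
and assembles tidy time-course tables for the stats module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample_id", "group", "timepoint", "rlu")


def _check_reads(reads: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"plate-read table missing columns: {missing}")
    if (reads["rlu"] < 0).any():
        raise ValueError("RLU values must be non-negative")
    return reads


def summarize_groups(reads: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD and n per (group, timepoint) cell.

    Cells with a single well get SD 0 and are flagged ``low_n``.
    """
    reads = _check_reads(reads)
    if reads.empty:
        raise ValueError("empty plate-read table")
    out = (
        reads.groupby(["group", "timepoint"], sort=True)["rlu"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    out["low_n"] = out["n"] < 2
    return out


@dataclass(frozen=True)
class DosageRatio:
    """Homozygote / heterozygote mean-signal fold change with bootstrap CI."""

    ratio: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_hom: int
    n_het: int
    n_boot: int

    def summary(self) -> str:
        return (
            f"fold change = {self.ratio:.3f} "
            f"[{self.ci_low:.3f}, {self.ci_high:.3f}] "
            f"({self.ci_level:.0%} percentile bootstrap, B={self.n_boot}, "
            f"n={self.n_hom}/{self.n_het})"
        )


def dosage_ratio(
    hom_values,
    het_values,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> DosageRatio:
    """Ratio of group means (hom / het) with a percentile bootstrap interval.

    Scale-invariant: multiplying every well by a positive constant leaves
    the ratio unchanged.  The heterozygote mean must be positive.
    """
    hom = np.asarray(hom_values, dtype=float)
    het = np.asarray(het_values, dtype=float)
    if hom.size == 0 or het.size == 0:
        raise ValueError("both groups must be non-empty")
    if het.mean() <= 0:
        raise ValueError("heterozygote mean must be positive")
    ratio = float(hom.mean() / het.mean())
    rng = np.random.default_rng(seed)
    bh = rng.integers(0, hom.size, size=(n_boot, hom.size))
    bt = rng.integers(0, het.size, size=(n_boot, het.size))
    boot = hom[bh].mean(axis=1) / het[bt].mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return DosageRatio(ratio, float(lo), float(hi), ci_level, hom.size, het.size, n_boot)


def assemble_timecourse(reads: pd.DataFrame) -> pd.DataFrame:
    """Tidy (sample, group, timepoint, value) series with per-cell summaries.

    Rejects duplicate (sample, timepoint) records; a missing cell in any
    group is flagged (``missing_cells`` attribute on the frame), never
    imputed.  Requires at least 2 timepoints.
    """
    reads = _check_reads(reads)
    if reads["timepoint"].nunique() < 2:
        raise ValueError("a time course needs >= 2 timepoints")
    dup = reads.duplicated(subset=["sample_id", "timepoint"])
    if dup.any():
        bad = reads.loc[dup, ["sample_id", "timepoint"]].iloc[0]
        raise ValueError(f"duplicate (sample, timepoint) record: {tuple(bad)}")
    tidy = reads.rename(columns={"sample_id": "sample", "rlu": "value"})[
        ["sample", "group", "timepoint", "value"]
    ].sort_values(["group", "timepoint", "sample"]).reset_index(drop=True)
    summaries = summarize_groups(reads)
    tidy = tidy.merge(summaries, on=["group", "timepoint"], how="left")
    # Flag cells absent from the full group x timepoint grid.
    grid = pd.MultiIndex.from_product(
        [reads["group"].unique(), reads["timepoint"].unique()], names=["group", "timepoint"]
    )
    present = pd.MultiIndex.from_frame(summaries[["group", "timepoint"]])
    tidy.attrs["missing_cells"] = [tuple(c) for c in grid.difference(present)]
    return tidy
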