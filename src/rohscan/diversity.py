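"""Per-individual nucleotide diversity and ROH summary statistics.

Within one diploid individual, nucleotide diversity is measured as the
density of heterozygous sites: the mean coverage-corrected snpbin over
covered bins, reported as SNPs per kb. Diversity *outside* ROHs
(pi-out) excludes every bin intersecting a called ROH and proxies the
haplotype diversity of the ancestral population, undiluted by recent
autozygosity; it can never fall below total diversity because ROH bins
are below-average by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinGrid
from .caller import ROH, SIZE_CLASSES
from . import intervals


@dataclass
class IndividualSummary:
    individual_id: str
    group: str
    pi_total: float          # SNPs per kb, all covered bins
    pi_out: float            # SNPs per kb, covered bins outside ROHs (NaN if none)
    pi_out_defined: bool
    n_roh: int
    n_roh_by_class: dict
    cum_roh_bp_by_class: dict
    cum_roh_bp: int
    froh: float              # fraction of the autosomal genome inside ROHs
    mean_roh_bp: float       # NaN when no ROHs

    def to_row(self) -> dict:
        row = {
            "individual_id": self.individual_id,
            "group": self.group,
            "pi_total": self.pi_total,
            "pi_out": self.pi_out,
            "n_roh": self.n_roh,
            "cum_roh_bp": self.cum_roh_bp,
            "froh": self.froh,
            "mean_roh_bp": self.mean_roh_bp,
        }
        for c in SIZE_CLASSES:
            row[f"n_roh_{c}"] = self.n_roh_by_class[c]
            row[f"cum_bp_{c}"] = self.cum_roh_bp_by_class[c]
        return row


def _roh_bin_mask(grid: BinGrid, rohs: Sequence[ROH]) -> np.ndarray:
    """Boolean mask over grid.frame rows: bin overlaps some ROH of this individual."""
    frame = grid.frame
    mask = np.zeros(len(frame), dtype=bool)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in rohs:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, ivals in by_chrom.items():
        merged = intervals.merge(ivals)
        sel = frame["chrom"] == chrom
        starts = frame.loc[sel, "bin_start"].to_numpy()
        ends = frame.loc[sel, "bin_end"].to_numpy()
        m = np.zeros(starts.size, dtype=bool)
        for s, e in merged:
            m |= (starts < e) & (ends > s)
        mask[np.nonzero(sel.to_numpy())[0]] = m
    return mask


def pi_total(grid: BinGrid) -> float:
    """Mean snpbin over covered bins, as SNPs per kb."""
    covered = grid.frame["covered"].to_numpy()
    if not covered.any():
        raise ValueError("no covered bins")
    return float(grid.frame.loc[covered, "snpbin"].mean()) / (grid.bin_size / 1000.0)


def pi_outside(grid: BinGrid, rohs: Sequence[ROH]) -> tuple[float, bool]:
    """Mean snpbin over covered bins not intersecting any ROH, as SNPs per kb.

    Returns (value, defined); when every covered bin lies inside a ROH the
    value is NaN and ``defined`` is False.
    """
    covered = grid.frame["covered"].to_numpy()
    outside = covered & ~_roh_bin_mask(grid, rohs)
    if not outside.any():
        return float("nan"), False
    return float(grid.frame.loc[outside, "snpbin"].mean()) / (grid.bin_size / 1000.0), True


def summarize_individual(
    grid: BinGrid,
    rohs: Sequence[ROH],
    group: str = "",
    *,
    froh_denominator: str = "total",
) -> IndividualSummary:
    """Assemble the per-individual summary used in all group comparisons.

    ``froh_denominator``: "total" divides cumulative ROH bp by the total
    autosomal length (the default reading of 'proportion of the genome');
    "covered" divides by the covered-bin footprint instead.
    """
    counts = {c: 0 for c in SIZE_CLASSES}
    cum = {c: 0 for c in SIZE_CLASSES}
    for r in rohs:
        counts[r.size_class] += 1
        cum[r.size_class] += r.length
    cum_bp = sum(cum.values())
    if froh_denominator == "total":
        denom = sum(grid.chrom_lengths.values()) or int(
            (grid.frame["bin_end"] - grid.frame["bin_start"]).sum()
        )
    elif froh_denominator == "covered":
        denom = int(grid.frame.loc[grid.frame["covered"], "covered_bp"].sum())
    else:
        raise ValueError("froh_denominator must be 'total' or 'covered'")
    pi_out, defined = pi_outside(grid, rohs)
    return IndividualSummary(
        individual_id=grid.individual_id,
        group=group,
        pi_total=pi_total(grid),
        pi_out=pi_out,
        pi_out_defined=defined,
        n_roh=len(rohs),
        n_roh_by_class=counts,
        cum_roh_bp_by_class=cum,
        cum_roh_bp=cum_bp,
        froh=cum_bp / denom if denom else float("nan"),
        mean_roh_bp=cum_bp / len(rohs) if rohs else float("nan"),
    )


def summaries_to_frame(summaries: Sequence[IndividualSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_row() for s in summaries])


def compare_groups(
    summaries: Sequence[IndividualSummary],
    statistic: str = "pi_out",
) -> dict:
    """Between-group test of one summary statistic.

    Continuous statistics (pi_total, pi_out, n_roh, mean_roh_bp, froh,
    cum_roh_bp) are tested by one-way ANOVA over individual means;
    ``statistic="class_proportions"`` contrasts the per-group ROH
    size-class counts with a chi-square test of homogeneity.
    """
    groups: dict[str, list[IndividualSummary]] = {}
    for s in summaries:
        groups.setdefault(s.group, []).append(s)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")

    if statistic == "class_proportions":
        table = np.array(
            [[sum(s.n_roh_by_class[c] for s in members) for c in SIZE_CLASSES]
             for members in groups.values()]
        )
        table = table[:, table.sum(axis=0) > 0]
        if np.allclose(table.astype(float) / table.sum(axis=1, keepdims=True),
                       (table.sum(axis=0) / table.sum())[None, :]):
            chi2, p = 0.0, 1.0
            dof = (table.shape[0] - 1) * (table.shape[1] - 1)
        else:
            chi2, p, dof, _ = stats.chi2_contingency(table)
        return {"test": "chi2", "statistic": float(chi2), "p": float(p), "dof": int(dof),
                "groups": list(groups)}

    samples = []
    for name, members in groups.items():
        vals = [getattr(s, statistic) for s in members]
        vals = [v for v in vals if not (isinstance(v, float) and math.isnan(v))]
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has < 2 usable values for ANOVA")
        samples.append(vals)
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    if np.allclose(pooled, pooled[0]):
        # identical values everywhere: no between- or within-group variance
        return {"test": "anova", "statistic": 0.0, "p": 1.0, "groups": list(groups)}
    f, p = stats.f_oneway(*samples)
    return {"test": "anova", "statistic": float(f), "p": float(p), "groups": list(groups)}
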