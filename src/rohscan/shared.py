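"""Shared homozygosity across individuals and gene/term enrichment arithmetic.

A region is *shared* within a group when every member's ROH set covers it
(base-pair-level intersection); a region is *exclusive* to a group when
it is additionally absent from every non-member. Genes overlapping shared
regions can be tested for over-represented annotation terms with a
one-sided hypergeometric test and Benjamini–Hochberg correction, against
a user-supplied term -> gene map (the ontology itself is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .caller import ROH
from . import intervals


@dataclass
class SharedRegionSet:
    group: str
    members: list[str]
    regions: list[tuple[str, int, int]]          # (chrom, start, end), disjoint, sorted
    cumulative_bp: int
    genes_per_region: list[list[str]] = field(default_factory=list)


def _rohs_by_chrom(rohs: Sequence[ROH]) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for r in rohs:
        out.setdefault(r.chrom, []).append((r.start, r.end))
    return out


def intersect_rohs(
    roh_sets: Mapping[str, Sequence[ROH]], group: str = ""
) -> SharedRegionSet:
    """Base-pair intersection of ROHs across all members of a group."""
    if not roh_sets:
        raise ValueError("need >= 1 individual")
    per_member = {m: _rohs_by_chrom(rohs) for m, rohs in roh_sets.items()}
    chroms = sorted(set().union(*[set(d) for d in per_member.values()]))
    regions: list[tuple[str, int, int]] = []
    for chrom in chroms:
        sets = [d.get(chrom, []) for d in per_member.values()]
        if any(len(s) == 0 for s in sets):
            continue
        for s, e in intervals.intersect_many(sets):
            regions.append((chrom, s, e))
    cum = sum(e - s for _, s, e in regions)
    return SharedRegionSet(group=group, members=list(roh_sets), regions=regions, cumulative_bp=cum)


def exclusive_regions(
    shared: SharedRegionSet, other_roh_sets: Mapping[str, Sequence[ROH]]
) -> SharedRegionSet:
    """Parts of the shared regions with zero overlap with any non-member's ROHs."""
    other = [_rohs_by_chrom(rohs) for rohs in other_roh_sets.values()]
    regions: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in shared.regions:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, ivals in by_chrom.items():
        acc = ivals
        for d in other:
            acc = intervals.subtract(acc, d.get(chrom, []))
            if not acc:
                break
        for s, e in acc:
            regions.append((chrom, s, e))
    regions.sort()
    cum = sum(e - s for _, s, e in regions)
    return SharedRegionSet(
        group=f"{shared.group}-exclusive", members=shared.members,
        regions=regions, cumulative_bp=cum,
    )


def genes_in_regions(
    regions: Sequence[tuple[str, int, int]], genes: pd.DataFrame
) -> list[list[str]]:
    """Per region, names of genes whose span overlaps it by >= 1 bp (half-open)."""
    out = []
    for chrom, s, e in regions:
        sub = genes[genes["chrom"] == chrom]
        hit = sub[(sub["start"] < e) & (sub["end"] > s)]
        out.append(hit["name"].tolist())
    return out


def term_enrichment(
    gene_set: set[str],
    background_set: set[str],
    term_map: Mapping[str, set[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of annotation terms, BH-corrected.

    For a term annotating K of the M background genes, with k of the n
    study genes annotated, p = P[X >= k] for X ~ Hypergeom(M, K, n).
    """
    extra = gene_set - background_set
    if extra:
        raise ValueError(f"gene_set not contained in background: {sorted(extra)[:5]} ...")
    M, n = len(background_set), len(gene_set)
    rows = []
    for term, term_genes in term_map.items():
        anno = term_genes & background_set
        K = len(anno)
        k = len(anno & gene_set)
        p = 1.0 if k == 0 else float(hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": term, "n_background": K, "n_set": k, "p": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["term", "n_background", "n_set", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q"] = pd.Series(dtype=float)
    return df.sort_values("p", kind="stable").reset_index(drop=True)


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term, gene) -> term -> gene-set map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], comment="#")
    out: dict[str, set[str]] = {}
    for term, sub in df.groupby("term"):
        out[str(term)] = set(sub["gene"].astype(str))
    return out


def write_regions_bed(shared: SharedRegionSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in shared.regions:
            fh.write(f"{chrom}\t{s}\t{e}\t{shared.group}\n")
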