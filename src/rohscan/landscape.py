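"""Chromosomal-landscape profiles over relative position.

Chromosomes differ in length, so positional structure (telomeric GC
enrichment, the U-shaped recombination landscape, the mid-chromosome
concentration of large ROHs) is compared on a relative axis: a feature at
physical position p on a chromosome of length L sits at relative position
p/L, and values are averaged within 20 half-open positional bins of width
0.05 (the last bin closed at 1.0), then across chromosomes.

Recombination rate is estimated from a genetic map as the ratio of
genetic to physical distance (cM/Mb) of neighbouring marker pairs, each
pair's rate being assigned to both of its markers. ROH positional
density is the fraction of a size class's constituent 10-kb bins whose
midpoints fall in each positional bin. Gene density uses 20 equal-sized
segments per chromosome with genes assigned by start coordinate.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .caller import ROH, SIZE_CLASSES

N_POS_BINS = 20


def relative_bin_index(rel_pos) -> np.ndarray:
    """Map relative positions in [0, 1] to the 20 positional bins.

    Bins are half-open [k/20, (k+1)/20) except the last, closed at 1.0.
    """
    rel = np.asarray(rel_pos, dtype=float)
    if np.any((rel < 0) | (rel > 1)):
        raise ValueError("relative positions must lie in [0, 1]")
    return np.minimum((rel * N_POS_BINS).astype(int), N_POS_BINS - 1)


def _average_over_chromosomes(per_chrom: list[np.ndarray]) -> np.ndarray:
    """Mean per positional bin across chromosomes, ignoring NaNs."""
    stack = np.vstack(per_chrom)
    ok = ~np.isnan(stack)
    n = ok.sum(axis=0)
    total = np.where(ok, stack, 0.0).sum(axis=0)
    return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def gc_profile(reference_fasta, bin_size: int = 10_000) -> tuple[pd.DataFrame, np.ndarray]:
    """GC fraction per bin and its relative-position profile.

    N bases are excluded from the denominator; all-N bins are undefined
    and excluded from the averages.
    """
    from pyfaidx import Fasta

    fa = Fasta(str(reference_fasta))
    rows = []
    per_chrom_profiles = []
    for chrom in fa.keys():
        seq = np.frombuffer(str(fa[chrom][:]).upper().encode(), dtype="S1")
        clen = seq.size
        n_bins = max(1, -(-clen // bin_size))
        gc_bins = np.full(n_bins, np.nan)
        for b in range(n_bins):
            chunk = seq[b * bin_size : min((b + 1) * bin_size, clen)]
            valid = chunk != b"N"
            nv = int(valid.sum())
            if nv:
                gc = int(((chunk == b"G") | (chunk == b"C")).sum())
                gc_bins[b] = gc / nv
        starts = np.arange(n_bins) * bin_size
        ends = np.minimum(starts + bin_size, clen)
        mids = (starts + ends) / 2.0
        for s, g in zip(starts, gc_bins):
            rows.append({"chrom": chrom, "bin_start": int(s), "gc": g})
        idx = relative_bin_index(mids / clen)
        prof = np.full(N_POS_BINS, np.nan)
        for k in range(N_POS_BINS):
            vals = gc_bins[(idx == k) & ~np.isnan(gc_bins)]
            if vals.size:
                prof[k] = vals.mean()
        per_chrom_profiles.append(prof)
    return pd.DataFrame(rows), _average_over_chromosomes(per_chrom_profiles)


def read_genetic_map(path) -> pd.DataFrame:
    """Genetic map TSV with columns chrom, bp, cM (header optional)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if not {"chrom", "bp", "cM"}.issubset(df.columns):
        df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "bp", "cM"], comment="#")
    return df


def recombination_profile(
    gmap: pd.DataFrame, chrom_lengths: Mapping[str, int]
) -> np.ndarray:
    """Relative-position profile of recombination rate (cM/Mb).

    Each adjacent marker pair yields a rate assigned to both markers;
    markers' rates are averaged within each relative bin per chromosome,
    then across chromosomes. Zero physical-distance pairs are skipped;
    an unsorted map is an error.
    """
    per_chrom = []
    for chrom, sub in gmap.groupby("chrom", sort=False):
        chrom = str(chrom)
        if chrom not in chrom_lengths:
            raise ValueError(f"no length for chromosome {chrom!r}")
        bp = sub["bp"].to_numpy(dtype=float)
        cm = sub["cM"].to_numpy(dtype=float)
        if np.any(np.diff(bp) < 0):
            raise ValueError(f"genetic map not sorted by bp on {chrom}")
        if np.any(np.diff(cm) < -1e-9):
            raise ValueError(f"genetic positions decrease on {chrom}")
        prof = np.full(N_POS_BINS, np.nan)
        if bp.size >= 2:
            dbp = np.diff(bp)
            dcm = np.diff(cm)
            ok = dbp > 0
            rates = np.full(dbp.size, np.nan)
            rates[ok] = dcm[ok] / (dbp[ok] / 1e6)
            # rate of each marker = mean of its adjacent-interval rates
            marker_rates = np.full(bp.size, np.nan)
            for i in range(bp.size):
                adj = []
                if i > 0 and ok[i - 1]:
                    adj.append(rates[i - 1])
                if i < bp.size - 1 and ok[i]:
                    adj.append(rates[i])
                if adj:
                    marker_rates[i] = float(np.mean(adj))
            idx = relative_bin_index(np.clip(bp / chrom_lengths[chrom], 0, 1))
            for k in range(N_POS_BINS):
                vals = marker_rates[(idx == k) & ~np.isnan(marker_rates)]
                if vals.size:
                    prof[k] = vals.mean()
        per_chrom.append(prof)
    if not per_chrom:
        raise ValueError("empty genetic map")
    return _average_over_chromosomes(per_chrom)


def pi_profile(grid, chrom_lengths: Mapping[str, int] | None = None) -> np.ndarray:
    """Relative-position profile of snpbin (covered bins only), averaged across chromosomes."""
    lengths = chrom_lengths or grid.chrom_lengths
    per_chrom = []
    for chrom, sub in grid.per_chromosome():
        clen = lengths[chrom]
        covered = sub["covered"].to_numpy(dtype=bool)
        mids = ((sub["bin_start"] + sub["bin_end"]) / 2.0).to_numpy()
        vals = sub["snpbin"].to_numpy(dtype=float)
        idx = relative_bin_index(np.clip(mids / clen, 0, 1))
        prof = np.full(N_POS_BINS, np.nan)
        for k in range(N_POS_BINS):
            sel = (idx == k) & covered
            if sel.any():
                prof[k] = vals[sel].mean()
        per_chrom.append(prof)
    return _average_over_chromosomes(per_chrom)


def roh_positional_distribution(
    rohs: Sequence[ROH],
    chrom_lengths: Mapping[str, int],
    size_class: str,
    bin_size: int = 10_000,
) -> np.ndarray:
    """Positional distribution of one size class's ROH bins.

    Every constituent bin of every ROH in the class contributes its
    relative midpoint; counts are normalised to the class total, so the
    vector sums to 1 for a non-empty class and is all-NaN otherwise.
    """
    if size_class not in SIZE_CLASSES:
        raise ValueError(f"unknown size class {size_class!r}")
    counts = np.zeros(N_POS_BINS, dtype=float)
    total = 0
    for r in rohs:
        if r.size_class != size_class:
            continue
        clen = chrom_lengths[r.chrom]
        starts = np.arange(r.start, r.end, bin_size, dtype=float)
        ends = np.minimum(starts + bin_size, r.end)
        mids = (starts + ends) / 2.0
        idx = relative_bin_index(np.clip(mids / clen, 0, 1))
        counts += np.bincount(idx, minlength=N_POS_BINS)
        total += idx.size
    if total == 0:
        return np.full(N_POS_BINS, np.nan)
    return counts / total


def correlate(profile_a, profile_b) -> tuple[float, float]:
    """Pearson correlation of two profiles, over their non-NaN pairs."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles differ in length")
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        raise ValueError("need >= 3 non-NaN pairs")
    if np.allclose(a[ok], a[ok][0]) or np.allclose(b[ok], b[ok][0]):
        raise ValueError("zero variance in a profile; correlation undefined")
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r), float(p)


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene records (chrom, start, end, name) from a BED or GFF3 file."""
    path = str(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 8 and parts[3].isdigit() and parts[4].isdigit():
                # GFF3: 1-based inclusive; keep only gene features
                if parts[2] != "gene":
                    continue
                name = parts[8].split("ID=")[-1].split(";")[0] if len(parts) > 8 else ""
                rows.append(
                    {"chrom": parts[0], "start": int(parts[3]) - 1, "end": int(parts[4]), "name": name}
                )
            else:
                # BED: 0-based half-open
                name = parts[3] if len(parts) > 3 else ""
                rows.append({"chrom": parts[0], "start": int(parts[1]), "end": int(parts[2]), "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def gene_density_segments(
    genes: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    n_segments: int = N_POS_BINS,
) -> dict[str, np.ndarray]:
    """Relative gene content per equal-sized chromosome segment.

    Genes are assigned to segments by start coordinate and counts are
    normalised per chromosome; a gene-less chromosome yields NaNs.
    """
    out: dict[str, np.ndarray] = {}
    for chrom, clen in chrom_lengths.items():
        sub = genes[genes["chrom"] == chrom]
        if len(sub) == 0:
            out[chrom] = np.full(n_segments, np.nan)
            continue
        rel = np.clip(sub["start"].to_numpy(dtype=float) / clen, 0, 1)
        idx = np.minimum((rel * n_segments).astype(int), n_segments - 1)
        counts = np.bincount(idx, minlength=n_segments).astype(float)
        out[chrom] = counts / counts.sum()
    return out


def gene_density_profile(genes: pd.DataFrame, chrom_lengths: Mapping[str, int]) -> np.ndarray:
    """Per-segment gene content averaged over chromosomes (for correlation with ROH density)."""
    segs = gene_density_segments(genes, chrom_lengths)
    return _average_over_chromosomes(list(segs.values()))
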