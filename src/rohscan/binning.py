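"""Per-chromosome binning of heterozygous variants with coverage correction.

Whole-genome resequencing at modest depth (~8x) leaves a fluctuating
fraction of each genomic bin inadequately covered, which would bias raw
per-bin heterozygous-SNP counts downward. This module ingests a filtered
single-sample VCF plus a depth-of-coverage track and produces, for 10-kb
bins along every chromosome, a coverage-corrected heterozygosity value
("SNPbin"): the heterozygous-SNV count rescaled to a full bin of covered
bases,

    snpbin = snp_count * bin_size / covered_bp,

where ``covered_bp`` counts bases whose read depth falls inside the
acceptance window ``[min_dp, max_dp]``. Bins whose covered fraction falls
below ``cov_frac`` are flagged uncovered and excluded from all averages.
The mean snpbin over covered autosomal bins — the "genomic average" — is
the unit in which every downstream ROH-calling threshold is expressed.

Coordinates are 0-based half-open throughout; bins are exactly
``bin_size`` wide except the terminal bin of each chromosome, whose
coverage requirement is measured against its actual width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 10_000
DEFAULT_COV_FRAC = 0.10

BIN_COLUMNS = ["chrom", "bin_start", "bin_end", "snp_count", "covered_bp", "snpbin", "covered"]


@dataclass(frozen=True)
class DepthFilter:
    """Per-base / per-site read-depth acceptance window.

    min_dp
        Minimum depth for a base to count as covered and for a
        heterozygous SNV to be counted (default 7 reads).
    max_dp
        Maximum depth; sites above it are treated as suspect (collapsed
        repeats, CNVs). ``None`` means "twice the individual's mean depth",
        resolved from the depth track at read time.
    exclude_indels
        Indel records never contribute to snp_count.
    """

    min_dp: int = 7
    max_dp: int | None = None
    exclude_indels: bool = True

    def __post_init__(self) -> None:
        if self.min_dp < 1:
            raise ValueError("min_dp must be >= 1")
        if self.max_dp is not None and self.max_dp <= self.min_dp:
            raise ValueError("max_dp must exceed min_dp")


@dataclass
class BinGrid:
    """Binned heterozygosity of one individual across its autosomes.

    ``frame`` holds one row per bin with columns
    chrom, bin_start, bin_end, snp_count, covered_bp, snpbin, covered.
    """

    individual_id: str
    bin_size: int
    frame: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def per_chromosome(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for chrom, sub in self.frame.groupby("chrom", sort=False):
            yield str(chrom), sub.reset_index(drop=True)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, individual_id: str, bin_size: int | None = None) -> "BinGrid":
        frame = pd.read_csv(path, sep="\t")
        missing = set(BIN_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"binned table lacks columns: {sorted(missing)}")
        if bin_size is None:
            bin_size = int((frame["bin_end"] - frame["bin_start"]).max())
        lengths = frame.groupby("chrom")["bin_end"].max().astype(int).to_dict()
        return cls(individual_id, bin_size, frame, lengths)


def compute_snpbin(snp_count, covered_bp, bin_size: int):
    """Coverage-corrected SNP count: ``snp_count * bin_size / covered_bp``.

    Scales the raw count to a full bin of covered bases, so a half-covered
    bin with 5 SNVs reads the same as a fully covered bin with 10.
    Vectorised; covered_bp must be > 0 (uncovered bins are flagged, not
    corrected).
    """
    covered_bp = np.asarray(covered_bp, dtype=float)
    if np.any(covered_bp <= 0):
        raise ValueError("compute_snpbin requires covered_bp > 0; flag the bin uncovered instead")
    return np.asarray(snp_count, dtype=float) * float(bin_size) / covered_bp


def build_bins(
    het_positions: Mapping[str, np.ndarray],
    covered_intervals: Mapping[str, Sequence[tuple[int, int]]],
    chrom_lengths: Mapping[str, int],
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
    cov_frac: float = DEFAULT_COV_FRAC,
    individual_id: str = "sample",
) -> BinGrid:
    """Assemble a :class:`BinGrid` from in-memory site and coverage data.

    ``het_positions`` maps chromosome -> sorted 0-based positions of
    heterozygous SNVs that already passed the depth filter;
    ``covered_intervals`` maps chromosome -> half-open intervals of bases
    whose depth lies in the acceptance window. This is the core used both
    by the VCF/depth-track reader and by the synthetic-data generator.
    """
    missing = sorted(set(het_positions) - set(chrom_lengths))
    if missing:
        raise ValueError(f"no chromosome length for: {missing}")
    rows = []
    for chrom in chrom_lengths:
        clen = int(chrom_lengths[chrom])
        n_bins = max(1, -(-clen // bin_size))
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, clen)

        counts = np.zeros(n_bins, dtype=np.int64)
        pos = np.asarray(het_positions.get(chrom, ()), dtype=np.int64)
        if pos.size:
            if pos.min() < 0 or pos.max() >= clen:
                raise ValueError(f"variant position outside chromosome {chrom} (length {clen})")
            counts = np.bincount(pos // bin_size, minlength=n_bins)

        covered_bp = np.zeros(n_bins, dtype=np.int64)
        for s, e in covered_intervals.get(chrom, ()):
            s, e = max(0, int(s)), min(clen, int(e))
            if e <= s:
                continue
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                covered_bp[b0] += e - s
            else:
                covered_bp[b0] += (b0 + 1) * bin_size - s
                covered_bp[b1] += e - b1 * bin_size
                if b1 > b0 + 1:
                    covered_bp[b0 + 1 : b1] += bin_size

        widths = ends - starts
        covered = covered_bp >= cov_frac * widths
        snpbin = np.zeros(n_bins, dtype=float)
        ok = covered_bp > 0
        snpbin[ok] = counts[ok] * float(bin_size) / covered_bp[ok]

        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": starts,
                    "bin_end": ends,
                    "snp_count": counts,
                    "covered_bp": covered_bp,
                    "snpbin": snpbin,
                    "covered": covered,
                }
            )
        )
    frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=BIN_COLUMNS)
    return BinGrid(individual_id, bin_size, frame, dict(chrom_lengths))


def read_depth_track(path) -> tuple[dict[str, list[tuple[int, int, int]]], dict[str, int], float]:
    """Read a depth track as (chrom -> [(start, end, depth)]), lengths, mean depth.

    Accepts BEDGRAPH (chrom, start, end, depth; 0-based half-open) or
    samtools-depth output (chrom, 1-based pos, depth). Mean depth is
    length-weighted over all reported bases (absent bases count as 0 for
    neither mean nor coverage — they are simply uncovered).
    """
    segs: dict[str, list[tuple[int, int, int]]] = {}
    lengths: dict[str, int] = {}
    tot_bp = 0
    tot_depth = 0.0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) >= 4:
                chrom, s, e, d = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            elif len(parts) == 3:
                chrom, p, d = parts[0], int(parts[1]), float(parts[2])
                s, e = p - 1, p
            else:
                raise ValueError(f"unparseable depth line: {line!r}")
            segs.setdefault(chrom, []).append((s, e, int(d)))
            lengths[chrom] = max(lengths.get(chrom, 0), e)
            tot_bp += e - s
            tot_depth += d * (e - s)
    mean_depth = tot_depth / tot_bp if tot_bp else 0.0
    return segs, lengths, mean_depth


def read_filtered_variants(
    vcf_source,
    depth_source,
    depth_filter: DepthFilter | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    *,
    cov_frac: float = DEFAULT_COV_FRAC,
    chrom_lengths: Mapping[str, int] | None = None,
    individual_id: str | None = None,
) -> BinGrid:
    """Bin a single-sample VCF against a depth track.

    A variant contributes to ``snp_count`` iff it is a heterozygous SNV
    whose per-site depth lies inside the filter window; indels are
    excluded. ``covered_bp`` is computed from the depth track with the
    same window. Chromosomes present in the VCF but absent from the depth
    track are a hard error (coordinate-system mismatch).
    """
    from cyvcf2 import VCF

    depth_filter = depth_filter or DepthFilter()
    segs, track_lengths, mean_depth = read_depth_track(depth_source)
    max_dp = depth_filter.max_dp
    if max_dp is None:
        max_dp = max(depth_filter.min_dp + 1, int(round(2 * mean_depth)))
    min_dp = depth_filter.min_dp

    covered: dict[str, list[tuple[int, int]]] = {
        chrom: [(s, e) for s, e, d in seglist if min_dp <= d <= max_dp]
        for chrom, seglist in segs.items()
    }

    het: dict[str, list[int]] = {}
    vcf = VCF(str(vcf_source))
    sample_id = individual_id or (vcf.samples[0] if vcf.samples else "sample")
    vcf_chroms: set[str] = set()
    for var in vcf:
        vcf_chroms.add(var.CHROM)
        if var.is_indel:
            if depth_filter.exclude_indels:
                continue
        elif not var.is_snp:
            continue
        gt = var.gt_types  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        if len(gt) == 0 or gt[0] != 1:
            continue
        fmt_dp = var.format("DP")
        dp = int(fmt_dp[0][0]) if fmt_dp is not None and fmt_dp.size else -1
        if dp < 0:
            dp = var.INFO.get("DP", -1)
        if dp < min_dp or dp > max_dp:
            continue
        het.setdefault(var.CHROM, []).append(var.start)
    vcf.close()

    unknown = sorted(vcf_chroms - set(track_lengths))
    if unknown:
        raise ValueError(
            f"chromosomes in VCF but not in depth track: {unknown}; "
            f"depth track has {sorted(track_lengths)}"
        )
    lengths = dict(chrom_lengths) if chrom_lengths else track_lengths
    het_arr = {c: np.asarray(sorted(p), dtype=np.int64) for c, p in het.items()}
    return build_bins(
        het_arr, covered, lengths, bin_size=bin_size, cov_frac=cov_frac, individual_id=sample_id
    )


def genomic_average(grid: BinGrid) -> float:
    """Mean snpbin over covered autosomal bins — the individual's heterozygosity unit.

    Uncovered bins are excluded; a grid with no covered bins, or with no
    variation at all, yields degenerate thresholds and is refused.
    """
    mask = grid.frame["covered"].to_numpy()
    if not mask.any():
        raise ValueError("no covered bins: cannot form a genomic average")
    avg = float(grid.frame.loc[mask, "snpbin"].mean())
    if avg == 0.0:
        raise ValueError(
            "genomic average is 0 (no heterozygosity in covered bins); "
            "ROH thresholds would be degenerate"
        )
    return avg
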