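"""Sliding-window detection of regions of homozygosity (ROHs).

A ROH is a stretch of one diploid genome with far less heterozygosity
than the individual's own genomic average, usually because both
haplotypes are identical by descent. Detection runs on the binned,
coverage-corrected heterozygosity grid (see :mod:`rohscan.binning`):

1. *Candidate extraction.* A bin is a candidate when a window of
   ``window_len`` consecutive bins anchored at it — forward or reverse —
   has mean snpbin strictly below the genomic average. Uncovered bins
   contribute to neither numerator nor denominator of the window mean.
2. *Concatenation.* Adjacent candidate bins form candidate stretches.
3. *Threshold + relaxation.* A stretch must stay below a hard per-bin
   ceiling, the larger of ``rel_threshold`` x genomic average and an
   absolute floor (false-discovery rate per bin plus the per-bin mutation
   expectation). A single aberrant bin — typically a local assembly or
   alignment artefact — may be retained if it stays below
   ``relax_bin_cap_factor`` x average, every ``window_len``-bin window of
   the stretch containing it stays below ``relax_window_cap_factor`` x
   average, and the stretch mean without it still meets the ceiling;
   otherwise the stretch is split at that bin.
4. *Coverage rules.* Uncovered terminal bins are trimmed; a stretch is
   accepted only with at most ``max_uncovered_frac`` uncovered bins and a
   span of at least ``min_roh_bp``. Uncovered interior bins still count
   toward the ROH's size.
5. *Size classes.* small < 100 kb, medium 100 kb – 5 Mb, large > 5 Mb
   (both boundaries inclusive for medium).

``permutation_calibration`` justifies the relative threshold: snpbin
values are shuffled genome-wide over the covered bins and candidate
stretches are re-extracted without any ceiling; the observed and permuted
length distributions separate only below ~0.25 x the genomic average.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .binning import BinGrid, genomic_average

SIZE_CLASSES = ("small", "medium", "large")


@dataclass(frozen=True)
class DetectionParams:
    """Every tunable of the ROH caller, in genomic-average units where noted."""

    window_len: int = 10                     # bins per sliding window
    rel_threshold: float = 0.25              # x genomic average, per-bin ceiling
    fdr_per_bin: float = 2.0                 # expected spurious het calls per bin
    mu_per_bp: float = 2.5e-8                # mutation rate per bp per generation
    mu_per_bin: float | None = None          # explicit per-bin override of mu
    relax_bin_cap_factor: float = 2.0        # x average, hard cap on a relaxed bin
    relax_window_cap_factor: float = 2.0 / 3.0  # x average, cap on local window mean
    max_uncovered_frac: float = 2.0 / 3.0    # max fraction of uncovered bins per ROH
    min_roh_bp: int = 10_000                 # minimum ROH span
    small_upper_bp: int = 100_000            # small:  span <  this
    large_lower_bp: int = 5_000_000          # large:  span >  this
    window_mode: str = "anchored"            # "anchored" or "any"

    def __post_init__(self) -> None:
        if not 0 < self.rel_threshold < 1:
            raise ValueError("rel_threshold must lie in (0, 1)")
        if self.window_len < 2:
            raise ValueError("window_len must be >= 2")
        if not 0 <= self.max_uncovered_frac < 1:
            raise ValueError("max_uncovered_frac must lie in [0, 1)")
        if self.window_mode not in ("anchored", "any"):
            raise ValueError("window_mode must be 'anchored' or 'any'")

    def mu_bin(self, bin_size: int) -> float:
        return self.mu_per_bin if self.mu_per_bin is not None else self.mu_per_bp * bin_size


@dataclass(frozen=True)
class ROH:
    """One called region of homozygosity (half-open bp coordinates)."""

    individual_id: str
    chrom: str
    start: int
    end: int
    n_bins: int
    n_uncovered: int
    mean_snpbin: float
    size_class: str

    @property
    def length(self) -> int:
        return self.end - self.start


def roh_bin_threshold(genome_avg: float, params: DetectionParams, bin_size: int = 10_000) -> float:
    """Per-bin SNP-count ceiling: max of the relative threshold and the absolute floor.

    The floor (fdr_per_bin + mu per bin) guards low-heterozygosity genomes
    where a fraction of the average would dip below the expected noise.
    """
    if genome_avg <= 0:
        raise ValueError("genomic average must be positive")
    return max(params.rel_threshold * genome_avg, params.fdr_per_bin + params.mu_bin(bin_size))


def _window_means(snpbin: np.ndarray, covered: np.ndarray, window_len: int) -> np.ndarray:
    """Mean snpbin over covered bins for every window start; NaN if no covered bin."""
    x = np.where(covered, snpbin, 0.0)
    c = covered.astype(float)
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cc = np.concatenate(([0.0], np.cumsum(c)))
    sums = cs[window_len:] - cs[:-window_len]
    cnts = cc[window_len:] - cc[:-window_len]
    means = np.full(sums.shape, np.nan)
    ok = cnts > 0
    means[ok] = sums[ok] / cnts[ok]
    return means


def candidate_bins(
    snpbin: np.ndarray,
    covered: np.ndarray,
    genome_avg: float,
    window_len: int,
    mode: str = "anchored",
) -> np.ndarray:
    """Boolean mask of bins belonging to a below-average sliding window.

    ``anchored``: the window starts (forward) or ends (reverse) at the bin.
    ``any``: any window containing the bin qualifies (a superset).
    Chromosomes shorter than ``window_len`` yield an empty mask.
    """
    snpbin = np.asarray(snpbin, dtype=float)
    covered = np.asarray(covered, dtype=bool)
    n = snpbin.size
    mask = np.zeros(n, dtype=bool)
    if n < window_len:
        return mask
    means = _window_means(snpbin, covered, window_len)
    with np.errstate(invalid="ignore"):
        low = means < genome_avg  # NaN compares False
    if mode == "anchored":
        mask[: n - window_len + 1] |= low           # forward: window starts at bin
        mask[window_len - 1 :] |= low               # reverse: window ends at bin
    elif mode == "any":
        delta = np.zeros(n + 1, dtype=np.int64)
        for j in np.nonzero(low)[0]:
            delta[j] += 1
            delta[j + window_len] -= 1
        mask = np.cumsum(delta[:-1]) > 0
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    return mask


def concatenate_stretches(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of adjacent flagged bins as half-open (start, stop) bin indices."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0 or not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    stops = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def _local_window_ok(
    snpbin: np.ndarray,
    covered: np.ndarray,
    a: int,
    b: int,
    i: int,
    window_len: int,
    cap: float,
) -> bool:
    """Rule (b): every window of window_len bins inside [a, b) containing bin i
    must have mean snpbin (over covered bins) <= cap. For stretches shorter
    than window_len the window is clipped to the stretch."""
    w = min(window_len, b - a)
    lo = max(a, i - w + 1)
    hi = min(b - w, i)
    for j in range(lo, hi + 1):
        sel = covered[j : j + w]
        if not sel.any():
            continue
        if float(snpbin[j : j + w][sel].mean()) > cap:
            return False
    return True


def apply_threshold_and_relaxation(
    stretches: Sequence[tuple[int, int]],
    snpbin: np.ndarray,
    covered: np.ndarray,
    genome_avg: float,
    params: DetectionParams,
    bin_size: int = 10_000,
) -> list[tuple[int, int, frozenset[int]]]:
    """Enforce the per-bin ceiling with single-bin relaxation; split where it fails.

    Returns surviving (start, stop, relaxed_bins) stretches. A covered bin
    above the ceiling is retained (relaxed) only if it passes the hard cap
    (a), the local-window cap (b), and the stretch mean without it still
    meets the ceiling (c); any failing bin splits the stretch.
    """
    snpbin = np.asarray(snpbin, dtype=float)
    covered = np.asarray(covered, dtype=bool)
    threshold = roh_bin_threshold(genome_avg, params, bin_size)
    bin_cap = params.relax_bin_cap_factor * genome_avg
    win_cap = params.relax_window_cap_factor * genome_avg

    out: list[tuple[int, int, frozenset[int]]] = []
    for a, b in stretches:
        nonconf = [
            i for i in range(a, b) if covered[i] and snpbin[i] > threshold
        ]
        hard = [
            i
            for i in nonconf
            if snpbin[i] > bin_cap
            or not _local_window_ok(snpbin, covered, a, b, i, params.window_len, win_cap)
        ]
        candidates = set(nonconf) - set(hard)
        for a2, b2 in _split_at(a, b, hard):
            relaxed = sorted(i for i in candidates if a2 <= i < b2)
            keep = [i for i in range(a2, b2) if covered[i] and i not in relaxed]
            if keep and (not relaxed or float(snpbin[keep].mean()) <= threshold):
                out.append((a2, b2, frozenset(relaxed)))
            elif relaxed:
                # rule (c) failed: the aberrant bins cannot be absorbed — split
                for a3, b3 in _split_at(a2, b2, relaxed):
                    keep3 = [i for i in range(a3, b3) if covered[i]]
                    if keep3:
                        out.append((a3, b3, frozenset()))
            # no covered bins at all: drop (coverage rules would reject anyway)
    return out


def _split_at(a: int, b: int, cut_bins: Iterable[int]) -> list[tuple[int, int]]:
    """Split [a, b) at the given bins (which are removed), keeping non-empty pieces."""
    pieces = []
    cur = a
    for i in sorted(cut_bins):
        if i > cur:
            pieces.append((cur, i))
        cur = i + 1
    if cur < b:
        pieces.append((cur, b))
    return pieces


def apply_coverage_rules(
    stretch: tuple[int, int],
    covered: np.ndarray,
    snpbin: np.ndarray,
    bin_starts: np.ndarray,
    bin_ends: np.ndarray,
    params: DetectionParams,
    *,
    individual_id: str,
    chrom: str,
) -> ROH | None:
    """Trim uncovered ends, enforce the uncovered-bin quota and minimum span."""
    a, b = stretch[0], stretch[1]
    covered = np.asarray(covered, dtype=bool)
    while a < b and not covered[a]:
        a += 1
    while b > a and not covered[b - 1]:
        b -= 1
    if b <= a:
        return None
    n_bins = b - a
    n_unc = int((~covered[a:b]).sum())
    if n_unc / n_bins > params.max_uncovered_frac:
        return None
    start, end = int(bin_starts[a]), int(bin_ends[b - 1])
    if end - start < params.min_roh_bp:
        return None
    sel = covered[a:b]
    mean_snpbin = float(np.asarray(snpbin, dtype=float)[a:b][sel].mean())
    roh = ROH(
        individual_id=individual_id,
        chrom=chrom,
        start=start,
        end=end,
        n_bins=n_bins,
        n_uncovered=n_unc,
        mean_snpbin=mean_snpbin,
        size_class="",
    )
    return replace(roh, size_class=classify_roh(roh, params))


def classify_roh(roh: ROH, params: DetectionParams) -> str:
    """small < 100 kb; medium 100 kb – 5 Mb inclusive; large > 5 Mb."""
    size = roh.end - roh.start
    if size < params.small_upper_bp:
        return "small"
    if size > params.large_lower_bp:
        return "large"
    return "medium"


def call_rohs(
    grid: BinGrid, params: DetectionParams | None = None
) -> tuple[list[ROH], dict]:
    """Run the full caller on one individual's bin grid.

    Returns the called ROHs (sorted, disjoint) and a summary with the
    genomic average, the per-bin ceiling, and per-size-class counts and
    cumulative spans.
    """
    params = params or DetectionParams()
    avg = genomic_average(grid)
    threshold = roh_bin_threshold(avg, params, grid.bin_size)
    rohs: list[ROH] = []
    for chrom, sub in grid.per_chromosome():
        snpbin = sub["snpbin"].to_numpy(dtype=float)
        covered = sub["covered"].to_numpy(dtype=bool)
        starts = sub["bin_start"].to_numpy()
        ends = sub["bin_end"].to_numpy()
        mask = candidate_bins(snpbin, covered, avg, params.window_len, params.window_mode)
        stretches = concatenate_stretches(mask)
        trimmed = apply_threshold_and_relaxation(
            stretches, snpbin, covered, avg, params, grid.bin_size
        )
        for st in trimmed:
            roh = apply_coverage_rules(
                (st[0], st[1]), covered, snpbin, starts, ends, params,
                individual_id=grid.individual_id, chrom=chrom,
            )
            if roh is not None:
                rohs.append(roh)
    summary = summarize_calls(rohs, avg, threshold, grid.individual_id)
    return rohs, summary


def summarize_calls(rohs: Sequence[ROH], genome_avg: float, threshold: float, individual_id: str) -> dict:
    counts = {c: 0 for c in SIZE_CLASSES}
    cum = {c: 0 for c in SIZE_CLASSES}
    for r in rohs:
        counts[r.size_class] += 1
        cum[r.size_class] += r.length
    return {
        "individual_id": individual_id,
        "genomic_average": genome_avg,
        "threshold": threshold,
        "n_roh": len(rohs),
        "n_roh_by_class": counts,
        "cum_bp_by_class": cum,
        "cum_bp": sum(cum.values()),
    }


def rohs_to_frame(rohs: Sequence[ROH]) -> pd.DataFrame:
    cols = ["individual_id", "chrom", "start", "end", "n_bins", "n_uncovered", "mean_snpbin", "size_class"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rohs], columns=cols)


def write_bed(rohs: Sequence[ROH], path) -> None:
    with open(path, "w") as fh:
        for r in rohs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.size_class}\n")


# ---------------------------------------------------------------------------
# permutation calibration of the relative threshold


@dataclass
class CalibrationResult:
    """Observed vs permuted candidate-stretch statistics.

    ``observed``/``permuted`` carry one row per candidate stretch
    (length_bins, rel_mean = stretch mean snpbin / genomic average);
    ``divergence`` reports, per 0.05-wide relative-mean level, the
    two-sample Kolmogorov–Smirnov distance between the observed and
    permuted stretch-length distributions.
    """

    observed: pd.DataFrame
    permuted: pd.DataFrame
    divergence: pd.DataFrame


def _candidate_stretch_stats(
    per_chrom: list[tuple[np.ndarray, np.ndarray]], genome_avg: float, params: DetectionParams
) -> list[tuple[int, float]]:
    stats = []
    for snpbin, covered in per_chrom:
        mask = candidate_bins(snpbin, covered, genome_avg, params.window_len, params.window_mode)
        for a, b in concatenate_stretches(mask):
            sel = covered[a:b]
            if not sel.any():
                continue
            stats.append((b - a, float(snpbin[a:b][sel].mean()) / genome_avg))
    return stats


def permutation_calibration(
    grid: BinGrid,
    n_perm: int = 10,
    seed: int = 0,
    params: DetectionParams | None = None,
) -> CalibrationResult:
    """Shuffle snpbin over covered bins genome-wide and compare stretch lengths.

    No ceiling is applied: stretches are raw candidate runs, so the table
    shows at which relative-mean level the observed genome departs from a
    randomised one — the empirical basis for ``rel_threshold``.
    """
    params = params or DetectionParams()
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    avg = genomic_average(grid)

    per_chrom = []
    for _, sub in grid.per_chromosome():
        per_chrom.append(
            (sub["snpbin"].to_numpy(dtype=float), sub["covered"].to_numpy(dtype=bool))
        )
    obs = _candidate_stretch_stats(per_chrom, avg, params)

    cov_values = np.concatenate([s[c] for s, c in per_chrom]) if per_chrom else np.empty(0)
    perm_stats: list[tuple[int, float]] = []
    for _ in range(n_perm):
        shuffled = rng.permutation(cov_values)
        pos = 0
        perm_chrom = []
        for snpbin, covered in per_chrom:
            new = snpbin.copy()
            k = int(covered.sum())
            new[covered] = shuffled[pos : pos + k]
            pos += k
            perm_chrom.append((new, covered))
        perm_stats.extend(_candidate_stretch_stats(perm_chrom, avg, params))

    observed = pd.DataFrame(obs, columns=["length_bins", "rel_mean"])
    permuted = pd.DataFrame(perm_stats, columns=["length_bins", "rel_mean"])

    levels = np.round(np.arange(0.0, 1.0, 0.05), 10)
    rows = []
    for lo in levels:
        hi = lo + 0.05
        o = observed.loc[(observed.rel_mean >= lo) & (observed.rel_mean < hi), "length_bins"]
        p = permuted.loc[(permuted.rel_mean >= lo) & (permuted.rel_mean < hi), "length_bins"]
        if len(o) == 0 and len(p) == 0:
            d = 0.0
        elif len(o) == 0 or len(p) == 0:
            d = 1.0
        else:
            d = float(ks_2samp(o, p).statistic)
        rows.append({"level": lo, "n_observed": len(o), "n_permuted": len(p), "divergence": d})
    return CalibrationResult(observed, permuted, pd.DataFrame(rows))
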