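from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rohscan.binning import BinGrid


def make_grid(chrom_data, bin_size=10_000, individual_id="t", chrom_lengths=None):
    """BinGrid from {chrom: (snpbin array, covered bool array)}.

    snp_count / covered_bp are filled consistently (full coverage for
    covered bins, zero for uncovered) — caller logic only reads snpbin
    and covered.
    """
    rows = []
    lengths = {}
    for chrom, (snpbin, covered) in chrom_data.items():
        snpbin = np.asarray(snpbin, dtype=float)
        covered = np.asarray(covered, dtype=bool)
        n = snpbin.size
        starts = np.arange(n) * bin_size
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "bin_start": starts,
            "bin_end": starts + bin_size,
            "snp_count": np.round(snpbin).astype(int),
            "covered_bp": np.where(covered, bin_size, 0),
            "snpbin": np.where(covered, snpbin, 0.0),
            "covered": covered,
        }))
        lengths[chrom] = n * bin_size
    frame = pd.concat(rows, ignore_index=True)
    return BinGrid(individual_id, bin_size, frame, chrom_lengths or lengths)


def random_grid(rng, n_bins=300, avg_level=10.0, n_tracts=2, tract_len=(12, 40),
                uncov_frac=0.08, chrom="chr1"):
    """Random heterozygosity grid with planted low-snpbin tracts."""
    snpbin = rng.poisson(avg_level, size=n_bins).astype(float)
    for _ in range(n_tracts):
        length = min(int(rng.integers(*tract_len)), n_bins - 1)
        start = int(rng.integers(0, max(1, n_bins - length)))
        snpbin[start : start + length] = rng.poisson(0.05 * avg_level, size=length)
    covered = rng.random(n_bins) >= uncov_frac
    return make_grid({chrom: (snpbin, covered)})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120)
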