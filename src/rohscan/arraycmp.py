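"""Concordance of sequence-based ROH calls with SNP-array ROH tables.

Genotyping arrays resolve only the largest ROHs, so the sequence calls
are filtered to the large class (> 5 Mb by default) before per-individual
cumulative ROH sizes are paired and their agreement summarised as the
squared Pearson correlation of the paired sums. Known outliers (e.g. an
individual whose array calls are inflated by ascertainment bias) can be
excluded from the R^2 while remaining in the table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .caller import ROH

REQUIRED_COLUMNS = ("IID", "CHR", "POS1", "POS2")


def read_array_roh_table(path) -> dict[str, list[tuple[str, int, int]]]:
    """Read a PLINK ``.hom``-dialect table into per-individual interval lists (bp)."""
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"array ROH table lacks columns: {missing}")
    out: dict[str, list[tuple[str, int, int]]] = {}
    for iid, sub in df.groupby("IID", sort=False):
        out[str(iid)] = [
            (str(r.CHR), int(r.POS1), int(r.POS2)) for r in sub.itertuples()
        ]
    return out


def compare_methods(
    seq_rohs: Mapping[str, Sequence[ROH]],
    array_rohs: Mapping[str, Sequence[tuple[str, int, int]]],
    min_size: int = 5_000_000,
    exclude: Sequence[str] = (),
) -> tuple[pd.DataFrame, float]:
    """Pair per-individual cumulative ROH sizes from the two methods.

    Sequence calls below ``min_size`` are dropped (the array only sees
    large ROHs). Returns the per-individual table and the R^2 of the
    paired sums over individuals not listed in ``exclude``; R^2 is NaN
    with fewer than two usable pairs.
    """
    ids = sorted(set(seq_rohs) & set(array_rohs))
    rows = []
    for iid in ids:
        cum_seq = sum(r.length for r in seq_rohs[iid] if r.length >= min_size)
        cum_array = sum(e - s for _, s, e in array_rohs[iid])
        rows.append(
            {"individual_id": iid, "cum_seq": cum_seq, "cum_array": cum_array,
             "excluded": iid in set(exclude)}
        )
    table = pd.DataFrame(rows, columns=["individual_id", "cum_seq", "cum_array", "excluded"])
    used = table[~table["excluded"]]
    if len(used) < 2:
        return table, float("nan")
    x = used["cum_seq"].to_numpy(dtype=float)
    y = used["cum_array"].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return table, float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return table, r * r
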