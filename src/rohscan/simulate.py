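"""Synthetic diploid resequencing data with planted autozygous tracts.

The generator emulates the statistical structure the ROH pipeline
assumes, so every stage can be exercised and scored offline:

* heterozygous SNVs as a Poisson process at a background rate of
  ~1.7 sites/kb, dropping to a small residual rate (mutations accumulated
  since the common ancestor) inside planted autozygous tracts;
* tract number Poisson-distributed and tract lengths log-normal, with
  optional placement bias toward low-recombination mid-chromosome
  regions;
* a ~8x depth-of-coverage track, piecewise constant with negative-
  binomial noise and exponential-length dropout segments of depth 0;
* a U-shaped recombination map (high cM/Mb near chromosome ends), a GC
  gradient elevated toward the telomeres, and a random gene annotation.

Everything is deterministic under (spec, seed), and the planted tracts
are exported as a truth set for precision/recall scoring of the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import intervals
from .binning import BinGrid, DepthFilter, build_bins
from .caller import ROH


def _default_chroms() -> dict[str, int]:
    return {f"chr{i}": 20_000_000 for i in range(1, 6)}


@dataclass(frozen=True)
class TractModel:
    """Planted-autozygosity model of one population group."""

    n_tracts_lambda: float = 40.0        # Poisson mean, tracts per genome
    length_log_mean: float = np.log(4e5)  # log-normal mu (bp)
    length_log_sd: float = 0.7
    residual_het_factor: float = 0.05    # x theta inside tracts
    min_length_bp: int = 10_000
    min_gap_bp: int = 50_000             # spacing between planted tracts


@dataclass(frozen=True)
class SimSpec:
    """Study conditions of one simulated individual/group."""

    chrom_lengths: Mapping[str, int] = field(default_factory=_default_chroms)
    theta: float = 1.7e-3                # het sites per bp (1.7 per kb)
    tracts: TractModel = field(default_factory=TractModel)
    mean_depth: float = 8.0
    depth_dispersion: float = 6.0        # NB size parameter of segment depths
    depth_segment_bp: int = 1_000
    dropout_per_mb: float = 2.0          # dropout segments per Mb
    dropout_mean_bp: float = 5_000.0
    recomb_min: float = 0.3              # cM/Mb at mid-chromosome
    recomb_max: float = 3.0              # cM/Mb at the ends (U-shape)
    gc_base: float = 0.40
    gc_amplitude: float = 0.06           # added toward the telomeres
    tract_placement: str = "uniform"     # or "recomb_biased"

    def recomb_rate(self, rel_pos) -> np.ndarray:
        """U-shaped recombination rate (cM/Mb) at relative position(s) in [0, 1]."""
        x = np.asarray(rel_pos, dtype=float)
        return self.recomb_min + (self.recomb_max - self.recomb_min) * (2 * x - 1) ** 2

    def gc_at(self, rel_pos) -> np.ndarray:
        x = np.asarray(rel_pos, dtype=float)
        return self.gc_base + self.gc_amplitude * (2 * x - 1) ** 2


@dataclass
class TruthSet:
    individual_id: str
    tracts: list[tuple[str, int, int]]   # disjoint, sorted
    spec: SimSpec

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.tracts:
                fh.write(f"{chrom}\t{s}\t{e}\t{self.individual_id}\n")


@dataclass
class IndividualSim:
    individual_id: str
    group: str
    het_positions: dict[str, np.ndarray]                  # 0-based site positions
    depth_segments: dict[str, list[tuple[int, int, int]]]  # half-open, constant depth
    truth: TruthSet
    spec: SimSpec


# ---------------------------------------------------------------------------
# core simulation


def _place_tracts(spec: SimSpec, rng: np.random.Generator) -> list[tuple[str, int, int]]:
    model = spec.tracts
    n = int(rng.poisson(model.n_tracts_lambda))
    chroms = list(spec.chrom_lengths)
    lens = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    genome = lens.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    total_mass = 0
    for _ in range(n):
        length = int(rng.lognormal(model.length_log_mean, model.length_log_sd))
        length = max(length, model.min_length_bp)
        total_mass += length
        if total_mass > 0.8 * genome:
            raise ValueError("planted tract mass exceeds 80% of the genome; thin the model")
        for _attempt in range(200):
            ci = int(rng.choice(len(chroms), p=lens / genome))
            chrom, clen = chroms[ci], int(lens[ci])
            if length >= clen:
                continue
            if spec.tract_placement == "recomb_biased":
                # sample start position with probability ~ 1 / recombination rate
                grid = (np.arange(200) + 0.5) / 200
                w = 1.0 / spec.recomb_rate(grid)
                w /= w.sum()
                start = int((rng.choice(200, p=w) + rng.random()) / 200 * (clen - length))
            else:
                start = int(rng.integers(0, clen - length))
            lo, hi = start - model.min_gap_bp, start + length + model.min_gap_bp
            if not intervals.overlaps_any(lo, hi, placed[chrom]):
                placed[chrom].append((start, start + length))
                break
        else:
            raise ValueError("could not place tract without overlap; genome too crowded")
    out = []
    for chrom in chroms:
        for s, e in sorted(placed[chrom]):
            out.append((chrom, s, e))
    return out


def _simulate_het_sites(
    spec: SimSpec, tracts: Sequence[tuple[str, int, int]], rng: np.random.Generator
) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in tracts:
        by_chrom.setdefault(chrom, []).append((s, e))
    out: dict[str, np.ndarray] = {}
    for chrom, clen in spec.chrom_lengths.items():
        n = int(rng.poisson(spec.theta * clen))
        pos = np.sort(rng.integers(0, clen, size=n))
        pos = np.unique(pos)
        if chrom in by_chrom and pos.size:
            in_tract = np.zeros(pos.size, dtype=bool)
            for s, e in by_chrom[chrom]:
                in_tract |= (pos >= s) & (pos < e)
            keep = ~in_tract | (rng.random(pos.size) < spec.tracts.residual_het_factor)
            pos = pos[keep]
        out[chrom] = pos.astype(np.int64)
    return out


def _simulate_depth(spec: SimSpec, rng: np.random.Generator) -> dict[str, list[tuple[int, int, int]]]:
    out: dict[str, list[tuple[int, int, int]]] = {}
    size = spec.depth_dispersion
    p = size / (size + spec.mean_depth)
    for chrom, clen in spec.chrom_lengths.items():
        n_seg = -(-clen // spec.depth_segment_bp)
        depth = rng.negative_binomial(size, p, size=n_seg).astype(np.int64)
        # dropout: exponential-length runs of depth 0
        n_drop = int(rng.poisson(spec.dropout_per_mb * clen / 1e6))
        for _ in range(n_drop):
            dlen = max(1, int(rng.exponential(spec.dropout_mean_bp)))
            dstart = int(rng.integers(0, clen))
            s0 = dstart // spec.depth_segment_bp
            s1 = min(n_seg, -(-(dstart + dlen) // spec.depth_segment_bp))
            depth[s0:s1] = 0
        # compress to constant runs
        segs: list[tuple[int, int, int]] = []
        run_start = 0
        for i in range(1, n_seg + 1):
            if i == n_seg or depth[i] != depth[run_start]:
                s = run_start * spec.depth_segment_bp
                e = min(i * spec.depth_segment_bp, clen)
                segs.append((s, e, int(depth[run_start])))
                run_start = i
        out[chrom] = segs
    return out


def simulate_individual(spec: SimSpec, seed: int, individual_id: str = "sim", group: str = "") -> IndividualSim:
    """One synthetic diploid individual: het sites, depth track, truth tracts."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    tracts = _place_tracts(spec, rng)
    het = _simulate_het_sites(spec, tracts, rng)
    depth = _simulate_depth(spec, rng)
    truth = TruthSet(individual_id=individual_id, tracts=tracts, spec=spec)
    return IndividualSim(individual_id, group, het, depth, truth, spec)


def depth_at(sim: IndividualSim, chrom: str, pos: int) -> int:
    for s, e, d in sim.depth_segments[chrom]:
        if s <= pos < e:
            return d
    return 0


def bin_individual(
    sim: IndividualSim,
    depth_filter: DepthFilter | None = None,
    bin_size: int = 10_000,
    cov_frac: float = 0.10,
) -> BinGrid:
    """Bin a simulated individual directly (no file round-trip).

    Applies the same depth window as the VCF/depth-track reader: sites and
    bases in segments outside [min_dp, max_dp] are excluded.
    """
    df = depth_filter or DepthFilter()
    max_dp = df.max_dp if df.max_dp is not None else int(round(2 * sim.spec.mean_depth))
    covered: dict[str, list[tuple[int, int]]] = {}
    het: dict[str, np.ndarray] = {}
    for chrom, segs in sim.depth_segments.items():
        ok = [(s, e) for s, e, d in segs if df.min_dp <= d <= max_dp]
        covered[chrom] = ok
        pos = sim.het_positions.get(chrom, np.empty(0, dtype=np.int64))
        if pos.size and ok:
            starts = np.array([s for s, _ in ok])
            ends = np.array([e for _, e in ok])
            i = np.searchsorted(starts, pos, side="right") - 1
            inside = (i >= 0) & (pos < ends[np.clip(i, 0, len(ok) - 1)])
            het[chrom] = pos[inside]
        else:
            het[chrom] = np.empty(0, dtype=np.int64)
    return build_bins(
        het, covered, dict(sim.spec.chrom_lengths),
        bin_size=bin_size, cov_frac=cov_frac, individual_id=sim.individual_id,
    )


# ---------------------------------------------------------------------------
# cohort and companion tracks


GROUP_PRESETS: dict[str, SimSpec] = {
    # many medium ROHs, lower ancestral diversity (post-glacial bottlenecks)
    "eu-wild": SimSpec(
        theta=1.4e-3,
        tracts=TractModel(n_tracts_lambda=60, length_log_mean=np.log(3.0e5), length_log_sd=0.6),
    ),
    # many ROHs but higher diversity (admixed commercial lines)
    "eu-domestic": SimSpec(
        theta=1.7e-3,
        tracts=TractModel(n_tracts_lambda=40, length_log_mean=np.log(4.0e5), length_log_sd=0.7),
    ),
    # few but large ROHs (recent decline of a large source population)
    "as-domestic": SimSpec(
        theta=2.0e-3,
        tracts=TractModel(n_tracts_lambda=10, length_log_mean=np.log(1.5e6), length_log_sd=0.8),
    ),
    # few ROHs, high diversity (large stable wild population)
    "as-wild": SimSpec(
        theta=2.3e-3,
        tracts=TractModel(n_tracts_lambda=5, length_log_mean=np.log(3.0e5), length_log_sd=0.6),
    ),
}


@dataclass
class Cohort:
    individuals: list[IndividualSim]
    genetic_map: pd.DataFrame
    genes: pd.DataFrame
    chrom_lengths: dict[str, int]

    def by_group(self) -> dict[str, list[IndividualSim]]:
        out: dict[str, list[IndividualSim]] = {}
        for ind in self.individuals:
            out.setdefault(ind.group, []).append(ind)
        return out


def simulate_genetic_map(spec: SimSpec, marker_spacing: int = 200_000) -> pd.DataFrame:
    """Markers at regular spacing with genetic positions integrating the U-shaped rate."""
    rows = []
    for chrom, clen in spec.chrom_lengths.items():
        bp = np.arange(0, clen + 1, marker_spacing, dtype=np.int64)
        x = bp / clen
        # closed-form integral of recomb_rate over [0, x], in cM (rate is per Mb)
        delta = spec.recomb_max - spec.recomb_min
        cm = (spec.recomb_min * x + delta * ((2 * x - 1) ** 3 + 1) / 6.0) * clen / 1e6
        for b, c in zip(bp, cm):
            rows.append({"chrom": chrom, "bp": int(b), "cM": float(c)})
    return pd.DataFrame(rows)


def simulate_annotation(spec: SimSpec, seed: int, genes_per_mb: float = 10.0) -> pd.DataFrame:
    """Random gene annotation: uniform starts, modest exponential lengths."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 977]))
    rows = []
    k = 0
    for chrom, clen in spec.chrom_lengths.items():
        n = int(rng.poisson(genes_per_mb * clen / 1e6))
        starts = np.sort(rng.integers(0, clen, size=n))
        for s in starts:
            length = 1000 + int(rng.exponential(20_000))
            rows.append({"chrom": chrom, "start": int(s), "end": int(min(s + length, clen)),
                         "name": f"GENE{k:05d}"})
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def simulate_cohort(
    group_specs: Mapping[str, SimSpec] | None = None,
    n_per_group: int = 3,
    seed: int = 0,
) -> Cohort:
    """Independent individuals per group, sharing one genome, map, and annotation."""
    specs = dict(group_specs) if group_specs is not None else dict(GROUP_PRESETS)
    if not specs:
        raise ValueError("need at least one group spec")
    first = next(iter(specs.values()))
    individuals: list[IndividualSim] = []
    idx = 0
    for group, spec in specs.items():
        if dict(spec.chrom_lengths) != dict(first.chrom_lengths):
            raise ValueError("all groups must share one set of chromosome lengths")
        for j in range(n_per_group):
            sub_seed = int(
                np.random.SeedSequence([seed & 0x7FFFFFFF, idx]).generate_state(1)[0] & 0x7FFFFFFF
            )
            ind = simulate_individual(
                spec, sub_seed, individual_id=f"{group}-{j + 1}", group=group
            )
            individuals.append(ind)
            idx += 1
    gmap = simulate_genetic_map(first)
    genes = simulate_annotation(first, seed)
    return Cohort(individuals, gmap, genes, dict(first.chrom_lengths))


def simulate_reference(spec: SimSpec, seed: int, gc_bin_bp: int = 10_000) -> dict[str, bytes]:
    """Reference sequence with the spec's telomere-elevated GC gradient."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 1259]))
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out: dict[str, bytes] = {}
    for chrom, clen in spec.chrom_lengths.items():
        chunks = []
        for s in range(0, clen, gc_bin_bp):
            e = min(s + gc_bin_bp, clen)
            gc = float(spec.gc_at(((s + e) / 2) / clen))
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            chunks.append(rng.choice(bases, size=e - s, p=p))
        out[chrom] = np.concatenate(chunks).tobytes()
    return out


# ---------------------------------------------------------------------------
# file emission (plain-text standard formats)


def write_fasta(sequences: Mapping[str, bytes], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            s = seq.decode()
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_depth_bedgraph(sim: IndividualSim, path) -> None:
    with open(path, "w") as fh:
        for chrom, segs in sim.depth_segments.items():
            for s, e, d in segs:
                fh.write(f"{chrom}\t{s}\t{e}\t{d}\n")


def write_vcf(sim: IndividualSim, path, seed: int = 0) -> None:
    """Minimal single-sample VCF 4.2 with GT:DP; ALT bases drawn deterministically."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 421]))
    bases = "ACGT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Site depth">\n')
        for chrom, clen in sim.spec.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={clen}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sim.individual_id}\n")
        for chrom in sim.spec.chrom_lengths:
            segs = sim.depth_segments[chrom]
            seg_starts = np.array([s for s, _, _ in segs])
            seg_ends = np.array([e for _, e, _ in segs])
            seg_depth = np.array([d for _, _, d in segs])
            pos = sim.het_positions.get(chrom, np.empty(0, dtype=np.int64))
            refs = rng.integers(0, 4, size=pos.size)
            alts = (refs + rng.integers(1, 4, size=pos.size)) % 4
            i = np.searchsorted(seg_starts, pos, side="right") - 1
            dp = np.where(
                (i >= 0) & (pos < seg_ends[np.clip(i, 0, len(segs) - 1)]),
                seg_depth[np.clip(i, 0, len(segs) - 1)], 0,
            )
            for p, r, a, d in zip(pos, refs, alts, dp):
                fh.write(
                    f"{chrom}\t{p + 1}\t.\t{bases[r]}\t{bases[a]}\t.\tPASS\t"
                    f"DP={d}\tGT:DP\t0/1:{d}\n"
                )


def write_genetic_map(gmap: pd.DataFrame, path) -> None:
    gmap.to_csv(path, sep="\t", index=False)


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples():
            fh.write(
                f"{r.chrom}\trohscan-sim\tgene\t{r.start + 1}\t{r.end}\t.\t+\t.\tID={r.name}\n"
            )


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_report(
    truth: Sequence[tuple[str, int, int]],
    called: Sequence[ROH] | Sequence[tuple[str, int, int]],
    min_overlap_frac: float = 0.5,
    *,
    min_size: int = 0,
    bin_size: int = 10_000,
) -> dict:
    """Precision/recall of planted tracts at a fractional-overlap criterion.

    A truth tract is recovered when called ROHs cover at least
    ``min_overlap_frac`` of it; a called ROH is a true positive when at
    least that fraction of it lies in truth. ``min_size`` restricts both
    sides to intervals at least that long. Boundary error is the mean
    absolute breakpoint offset of recovered tracts, in bins.
    """
    call_iv: dict[str, list[tuple[int, int]]] = {}
    for c in called:
        chrom, s, e = (c.chrom, c.start, c.end) if isinstance(c, ROH) else c
        call_iv.setdefault(chrom, []).append((int(s), int(e)))
    truth_iv: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in truth:
        truth_iv.setdefault(chrom, []).append((int(s), int(e)))

    truth_big = [(c, s, e) for c, s, e in truth if e - s >= min_size]
    n_recovered = 0
    boundary_offsets: list[float] = []
    for chrom, s, e in truth_big:
        cov = intervals.intersect([(s, e)], call_iv.get(chrom, []))
        covered_bp = sum(b - a for a, b in cov)
        if covered_bp >= min_overlap_frac * (e - s) and covered_bp > 0:
            n_recovered += 1
            boundary_offsets.append(abs(cov[0][0] - s) / bin_size)
            boundary_offsets.append(abs(cov[-1][1] - e) / bin_size)
    recall = n_recovered / len(truth_big) if truth_big else float("nan")

    called_big = [
        (chrom, s, e)
        for chrom, ivs in call_iv.items()
        for s, e in ivs
        if e - s >= min_size
    ]
    n_tp = 0
    for chrom, s, e in called_big:
        cov = intervals.intersect([(s, e)], truth_iv.get(chrom, []))
        if sum(b - a for a, b in cov) >= min_overlap_frac * (e - s):
            n_tp += 1
    precision = n_tp / len(called_big) if called_big else float("nan")
    return {
        "n_truth": len(truth_big),
        "n_called": len(called_big),
        "n_recovered": n_recovered,
        "n_true_positive": n_tp,
        "recall": recall,
        "precision": precision,
        "boundary_error_bins": float(np.mean(boundary_offsets)) if boundary_offsets else float("nan"),
    }
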