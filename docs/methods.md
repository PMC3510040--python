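# Methods

## Model and assumptions

`rohscan` treats a single diploid genome as a sequence of 10-kb bins whose
heterozygous-SNV counts, after coverage correction, fluctuate around a
genome-wide mean `a`. Autozygous segments (both haplotypes identical by
descent) appear as long runs of bins far below `a`; the caller's job is to
separate those runs from the low tail of ordinary sampling noise. Three
assumptions matter:

* **Self-calibration.** All thresholds are multiples of the individual's
  own genomic average, not of population allele frequencies. This makes
  the method applicable to unbalanced samples and to related species
  without an ascertainment panel, at the cost of not distinguishing
  autozygosity from hemizygous artefacts the way a likelihood model
  might.
* **Residual mutation.** Old autozygous tracts accumulate new mutations,
  so ROHs are defined by a heterozygosity *ceiling* (0.25 × a per bin,
  with an absolute floor of the per-bin false-discovery rate plus the
  per-bin mutation expectation) rather than by zero tolerance.
* **Coverage honesty.** At ~8× depth many bases fail the depth window;
  counts are rescaled to 10,000 *covered* bases, bins under 10 % coverage
  are excluded from averages but still count toward ROH spans (up to ⅔
  of a ROH's bins), and a ROH must begin and end on covered bins.

## Detection procedure and numerical choices

Candidate extraction flags a bin when the 10-bin window starting at it
*or* ending at it has mean SNPbin strictly below `a` (uncovered bins
enter neither numerator nor denominator; windows with no covered bin are
indeterminate and never flag). A `window_mode="any"` variant flags a bin
when *any* containing window is below average; it is a superset and is
exposed for sensitivity analysis, with "anchored" the default. Strict
inequality makes a perfectly constant genome yield no candidates, which
is the correct degenerate answer. Chromosomes shorter than one window
yield no calls; stretches shorter than a window can still be called when
flagged via windows extending beyond them.

The relaxation rule exists because local assembly or alignment errors
put a spike of spurious heterozygous calls inside true ROHs. A
non-conforming covered bin is retained iff (a) its SNPbin ≤ 2a, (b) every
10-bin window of the stretch containing it has mean ≤ ⅔ a, and (c) the
stretch mean excluding relaxed bins still meets the ceiling; otherwise
the stretch is split at that bin and the pieces are re-checked. Runs of
adjacent aberrant bins are handled naturally: the windows in rule (b)
contain all of them jointly. For stretches shorter than 10 bins the
window in rule (b) is clipped to the stretch length.

The per-bin mutation expectation defaults to `mu_per_bp × bin_size`
(2.5 × 10⁻⁸ × 10⁴ = 2.5 × 10⁻⁴); an explicit `mu_per_bin` override
exists for users who prefer to state the floor directly. Size classes
use strict outer bounds: exactly 100 kb and exactly 5 Mb are both
"medium". Minimum ROH span is 10 kb (one bin).

Permutation calibration shuffles SNPbin values across covered bins
genome-wide, holding the coverage mask in place, and re-extracts
candidate stretches with *no* ceiling. Per 0.05-wide band of
stretch-mean/`a`, the two-sample Kolmogorov–Smirnov distance between
observed and permuted stretch-length distributions is reported (an empty
band on both sides scores 0; one-sided emptiness scores 1). On genomes
with real autozygosity the divergence concentrates below 0.25 — the
empirical justification of the relative threshold. The KS statistic is
this package's choice of divergence measure; any distributional distance
would serve.

## Diversity, landscape, and shared regions

π is the mean SNPbin over covered bins divided by 10 (SNPs per kb);
π-out repeats this over covered bins not intersecting any called ROH and
is undefined (flagged, NaN) when ROHs swallow every covered bin. π-out ≥
π always, since ROH bins are below average by construction. F_ROH
divides cumulative ROH span by the *total* autosomal length by default
("proportion of the genome"); a `froh_denominator="covered"` alternative
uses the covered footprint. Group contrasts use one-way ANOVA on
per-individual means (scipy) and a χ² homogeneity test on per-group
size-class counts; a pooled zero-variance input short-circuits to
F = 0, p = 1 rather than scipy's NaN.

Landscape profiles use 20 half-open relative-position bins (last bin
closed at 1.0), with a bin's position defined by its midpoint over the
chromosome length and chromosome averages weighted equally (no
centromere-aware reflection; chromosomes are taken in reference
orientation). Recombination rates come from adjacent genetic-map marker
pairs as ΔcM/ΔMb assigned to *both* markers, then averaged per positional
bin ("averaged over all markers in the bin"); zero-Δbp pairs are skipped.
Gene density uses 20 equal segments per chromosome with genes assigned by
start coordinate and counts normalised per chromosome.

Shared regions are strict base-pair intersections across *all* group
members (a k-of-n relaxation would be a trivial extension of the interval
layer but n-of-n is the default and the only mode exposed); "exclusive"
regions additionally subtract every non-member's ROHs. A gene overlaps a
region with ≥ 1 bp of its half-open span. Term enrichment is the exact
hypergeometric upper tail with Benjamini–Hochberg adjustment
(statsmodels); terms with zero study-set genes report p = 1. Array
concordance filters sequence calls at 5 Mb (arrays cannot resolve less)
and reports the squared Pearson correlation of per-individual cumulative
sizes, with an optional exclusion list for known outliers.

## Synthetic data: what it emulates and what it does not

The generator plants non-overlapping autozygous tracts (Poisson count,
log-normal lengths, ≥ 50 kb spacing) into chromosomes of configurable
length, places heterozygous sites as a Poisson process at θ per bp
(default 1.7 × 10⁻³, i.e. 1.7 SNPs/kb) thinned to 5 % of θ inside
tracts, and overlays a depth track with mean 8× — negative-binomial per
1-kb segment (dispersion 6) plus exponential-length dropout segments at
depth 0, emitted as BEDGRAPH, which is inherently piecewise-constant.
The four demographic presets differ in θ and tract model: many medium
tracts at low θ (European-wild-like), many tracts at moderate θ
(European-domestic-like), few large tracts (Asian-domestic-like), few
tracts at high θ (Asian-wild-like), chosen so that default cohorts land
near the field-typical anchors (≈ 1.4–2.3 SNPs/kb, ≈ 20 % of the genome
in ROH for the inbred presets). Tract placement can be biased by the
inverse of the U-shaped recombination-rate function
`r(x) = r_min + (r_max − r_min)(2x − 1)²` to exercise the landscape
correlations; the default is unbiased. The genetic map integrates `r`
in closed form; the reference sequence draws bases per 10-kb bin with a
GC target `g(x) = 0.40 + 0.06(2x − 1)²`.

What the generator does **not** emulate: linkage structure and realistic
haplotypes (sites are independent), read-level error and mapping bias
(false heterozygous calls enter only through the FDR floor, not the
data), coalescent variation in tract age and decay, repeat content, and
sex chromosomes. Passing the recovery tests therefore demonstrates that
the detection rules are implemented correctly and are well-conditioned
at realistic densities — not that the caller is robust to alignment
artefacts in real data, which is precisely what the relaxation rule and
FDR floor exist to absorb and can only be validated against genotyping
arrays.

Everything is deterministic under (spec, seed): per-individual generators
are spawned from numpy `SeedSequence`, and repeated runs are
byte-identical including emitted VCF/BEDGRAPH/BED files.

## Problem sizes

Tests and examples run cohorts of 4 groups × 3 individuals on five 20-Mb
autosomes (100 Mb per genome, ~1.7 × 10⁵ heterozygous sites each), a
scale at which every stage — simulation, binning, calling, calibration,
landscape profiles — completes in seconds while leaving hundreds of
planted tracts for recovery scoring. The caller itself is linear in bin
count and handles full mammalian genomes (~2.5 Gb → 2.5 × 10⁵ bins)
without modification.

## Known limitations

* The forward/reverse window rule is anchored (window starting or ending
  at the bin); the "any containing window" reading is available but not
  default, and the two differ at stretch margins.
* The per-bin ceiling plus per-stretch mean cap is the conservative
  intersection of two plausible readings of the detection rule; a
  stretch-mean-only variant would call slightly wider ROHs.
* π within an individual counts heterozygous genotypes only;
  homozygous-alternate calls are ignored, as ROH detection concerns the
  absence of heterozygosity, not divergence from the reference.
* Uncovered bins inside ROHs count toward size; ROH spans are therefore
  upper bounds under heavy dropout.
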