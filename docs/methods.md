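# Methods

This note documents the models, defaults, and numerical choices behind each
stage, what the synthetic generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite does not
itself compute.

## Coordinate conventions

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted at the I/O boundary. A position s is inside gene g iff
`coding_start ≤ s < coding_end`. The predicted translation start codon
(TSC) is `coding_start` for a forward-strand gene and `coding_end − 1` for
a reverse-strand gene. The model is single-chromosome (the target organisms
are bacteria with one chromosome); the chromosome is flagged circular as
metadata, but all distances are computed linearly — sites within a few
hundred bp of the origin may be assigned slightly wrong nearest genes, a
deliberate simplification.

## Peak calling

The caller is a minimal kernel-density detector, a deliberately simplified
stand-in for full-featured KDE callers whose internals are not specified
here. Given read 5'-start positions with strands:

- forward reads are shifted +`shift`, reverse reads −`shift`
  (default 50 bp, half the expected fragment size), collapsing the two
  strand-specific read pileups onto the fragment center;
- shifted starts are binned to a grid (default 10 bp) and convolved with a
  Gaussian kernel (σ = `bandwidth`, default 30 bp, truncated at ±4σ), giving
  a density in reads/bp whose integral equals the read count up to the
  truncation error;
- the control density is scaled by the read-count ratio
  `n_chip / n_control`, floored by a pseudocount (0.1 × mean ChIP density)
  so the fold ratio is finite in control deserts;
- peaks are interior local maxima of the ChIP density with fold ≥ 10 over
  the scaled control and absolute density ≥ 5 × the genome-wide mean ChIP
  density; maxima closer than 2σ are merged keeping the higher one, and the
  surviving maxima are refined to 1 bp by parabolic interpolation of the
  three neighboring grid values.

The false-positive rate of the whole procedure is the count of peaks
obtained when a random half of the control is called against the other
half, divided by the real ChIP peak count, in percent. A control of fewer
than 10 reads cannot be partitioned meaningfully; the estimate is reported
as 0 with a warning rather than failing, to keep toy examples runnable.

No attempt is made to reproduce any published caller's scores; the peak
*lists* are the unit of downstream analysis, and the pipeline accepts them
from any caller.

## Replicate concordance

Matching is mutual-nearest-neighbor: every peak nominates its nearest peak
in the other replicate (exact distance ties resolve toward the lower
coordinate), and candidate pairs are accepted greedily by ascending
distance (ties by the coordinate pair), skipping any pair touching an
already-used peak and stopping at the cutoff. This guarantees the merged
set is never larger than the smaller replicate list, is symmetric in the
two replicates, and is monotone in the cutoff. The merged coordinate is
the arithmetic mean of the two maxima rounded half up (integers are what
the final table reports); overall ranks come from descending mean replicate
enrichment because per-peak read counts are not available downstream of
arbitrary callers.

The summary's F(30) — the fraction of nearest-neighbor distances ≤ 30 bp —
is computed over both directions pooled, before any cutoff; the median
distance is over retained merged pairs only. The default 65-bp cutoff is
the published operating point for this analysis family; it is configurable.

## Annotation

Signed distance is measured in the gene's reading orientation
(d = peak − TSC forward, TSC − peak reverse; negative = upstream). The
promoter window default is [−400, +100], inclusive at both bounds — the
source convention says "between −400 and +100" without strictness, so
inclusivity is a documented choice and the window is configurable. A
position is coding if any annotated coding span covers it (overlapping
genes make a position coding once). Divergence requires an opposite-strand
pair among the window hits whose TSCs flank the peak (forward gene's TSC at
or right of the peak, reverse gene's at or left); same-strand double hits
are recorded but not divergent. Distances use the merged (averaged)
coordinate, not the per-replicate maxima.

Operon collapsing removes list members with operon position > 1, because an
operon's promoter is upstream of its first gene only; genes without operon
information are retained.

## Monte Carlo null

Random sites are single base pairs drawn i.i.d. uniform on the chromosome
with replacement, not matched for peak width or GC — the null asks only
"where would this many point locations fall." The headline comparison uses
one randomized replicate (matching the published single randomized
dataset); `n_replicates > 1` attaches a 2.5–97.5 percentile Monte Carlo
interval to the coding proportion. The generator is `numpy`'s PCG64 with
the seed recorded in the result.

## Enrichment

Counting is gene-level: a gene counts once toward "observed" regardless of
how many peaks hit its window, and a divergent site counts toward both
flanking genes. The expected count is `n_category × near_total /
genome_total`, displayed rounded half away from zero (this rounding reproduces
standard printed tables). The universe for category tables is the
categorized genes only; for arbitrary gene lists it is all annotated genes.
Each row's 2×2 is

```
[[observed,              category − observed],
 [near − observed,       (universe − category) − (near − observed)]]
```

tested two-sided by the minimum-likelihood Fisher rule (scipy's
implementation; the test suite checks it against full hypergeometric
enumeration). No multiple-testing correction is applied by default, since
the row-wise raw p-value presentation is the convention being reproduced;
a clearly-non-default Benjamini–Hochberg column is available.

Exact-test p-values are discrete and slightly super-uniform under the null;
at the reference contrast scale (410-gene lists, 1393 hit genes of 7379)
the discreteness is mild and null p-values pass a KS uniformity check at
the 1 % level, but they are not exactly uniform by construction.

## Motif discovery

The EM implements the OOPS model: each sequence contains exactly one motif
occurrence at a uniformly-distributed (position, strand). The background is
0-order, estimated from the input composition (important for GC-rich
genomes; a uniform background would absorb AT-richness into the motif).
Defaults: width 15, 10 restarts, pseudocount 0.25 per cell, stop when the
objective improves by < 1e-4 or at 200 iterations. Restarts are seeded
from data windows (70 % weight on the observed base) drawn from a
canonically sorted copy of the input so results do not depend on sequence
order. With a Dirichlet pseudocount the M-step maximizes a penalized (MAP)
objective, and it is that objective — data log-likelihood plus
`pseudocount · Σ log pwm` — which EM guarantees non-decreasing; the
implementation asserts this every iteration. The reported log-likelihood
omits the constant background term of non-motif positions.

Because OOPS must place an occurrence in every sequence, motifs fitted to
pure noise are not flat: on 100 random 101-mers the best spurious alignment
reaches roughly 1 bit in its sharpest column. Interpretation should rest on
the gap to genuine signal (planted conserved columns reach ~2 bits), not on
a zero baseline. The tests encode that separation.

The IUPAC consensus picks, per column, the smallest degeneracy class whose
summed frequency reaches the threshold (default 0.85; ≥ rule), preferring
larger coverage then the lexicographically smallest base set on ties.
Scanning reports every (offset, strand) whose bases are compatible with the
pattern, overlaps included; non-ACGT sequence characters fail every pattern
position except N. On planted palindromic data the EM occasionally
converges to a register shifted by one base (the reverse-complement phase
of the palindrome scores nearly identically); the conserved arm structure
is recovered either way.

## Synthetic data

The generator states one world and keeps it fixed:

- **Genome**: 800 genes (Gamma-distributed lengths, shape 10, mean 1 kb)
  alternating with Gamma gaps sized for 90 % coding, ~1 Mb total; random
  strands; GC 0.69 (the GC-rich regime of the motivating organism; a
  uniform-composition mode exists for analytically clean tests); functional
  categories drawn from a fixed 10-category table; runs of same-strand
  neighbors grouped into operons (probability 0.3, geometric sizes).
- **Sites**: 150 planted instances of `TGTYN8RAC` (Y/R/N sampled uniformly,
  reverse-complemented with probability ½, never overlapping), 66 % placed
  at a uniform distance in [−250, 0] upstream of a random gene's TSC — the
  promoter-biased placement regime — and the rest uniform. The planted
  category enrichment (default: "Regulatory functions" at 3×) biases which
  genes receive promoter sites.
- **Replicates**: 80 % of sites appear in both replicates with independent
  Laplace(0, 6) coordinate jitter (heavy-tailed, matching the long tail of
  observed replicate disagreement); the rest appear in one replicate, plus
  50 uniform false peaks per replicate. Enrichment scores are a per-site
  log-normal strength shared across replicates times log-normal replicate
  noise, so ranks correlate between replicates and true sites outrank false
  ones.
- **Gene lists**: sampled without replacement with odds
  `w = f(G−h)/(G−fh)` on promoter-hit genes, which makes the expected hit
  fraction exactly f times the genome-wide rate; the default configuration
  plants an "up-regulated" list at f = 1.7 and two null lists.
- **Reads**: per site, strand-balanced 5' starts offset by
  |Normal(fragment/2, fragment/4)| upstream (forward) / downstream
  (reverse), plus uniform background; the control is uniform at matched
  depth.

What the generator does **not** emulate: mappability and repeat structure,
PCR duplicates, sequencing errors, GC bias in coverage, operon-internal
promoters, peak width variation, and any correlation between binding
strength and sequence match quality. A green closed-loop test therefore
establishes that the algorithms recover what was planted under idealized
noise — not that they would behave identically on a real library.

Everything is reproducible: all stage seeds derive from one master seed via
SHA-256 (`derive_seed`), stay below 2³¹, and are recorded in the run
manifest together with SHA-256 digests of every output file.

## Known limitations

- Linear distances on a circular chromosome (origin-adjacent sites).
- Two replicates only; no irreproducible-discovery-rate modeling.
- The peak caller has no broad-peak mode, duplicate handling, or per-peak
  q-values; it exists to exercise the pipeline and for closed-loop tests.
- OOPS-only motif model: no ZOOPS/ANR, no E-value stopping rule, so motif
  significance must be judged against the noise baseline described above.
- Exact-test p-values are reported per row without correction by default,
  mirroring the table convention being reproduced.
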