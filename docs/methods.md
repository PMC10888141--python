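# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the simulator does and does not emulate, and the
numerical conventions, so results can be interpreted and the open design
choices audited.

## Coordinate and strand conventions

All internal arithmetic and all BED/bedGraph I/O are 0-based, half-open;
human-readable report tables additionally carry 1-based inclusive positions.
The template is stored 5′→3′ in the direction of transcription and the model
is single-strand: there is no reverse-complement arithmetic anywhere
downstream. Antisense and out-of-template reads are filtered with logged
counts rather than errors, so mixed genome-wide BED files can be passed
through unmodified.

The last incorporated nucleotide (LNT) of a read is taken to be its
alignment 3′ end (`end − 1` in half-open coordinates). This is the standard
NET-seq identification of the nascent-RNA 3′ end with the polymerase active
site; it is an assumption of this implementation, adopted because the
difference-logo construction is explicitly LNT-centered.

## Deduplication

The molecular identity key is (start, end, strand, UMI), not the UMI alone:
two fragments that share a UMI but map to different coordinates are distinct
molecules, while a PCR duplicate is a verbatim copy and shares all four
fields. Retention is first-seen in input order, which makes deduplication
idempotent and deterministic. No UMI error correction (directional
clustering of near-identical UMIs) is attempted; sequencing errors in UMIs
are out of scope.

## Normalization

Each sample's track is divided by its own total count over the analyzed
unit, giving per-position occupancy fractions that sum to 1. Whether the
proper denominator is the unit-mapped total or the library-wide total is
genuinely ambiguous for this analysis style; the unit-mapped total is the
default because the pipeline's data frame covers only the unit, and an
explicit `total=` override on `normalize()` supports library-wide totals.
An all-zero track normalizes to all zeros and is flagged degenerate rather
than erroring, so a failed library surfaces in QC instead of crashing the
run.

## Replicate QC

Spearman rank correlation (average ranks for ties) is computed on the
normalized tracks for every replicate pair; constant tracks have undefined
rank correlation and are reported as NaN with a warning. The sample PCA
treats samples as observations and positions as features, centered but not
scaled (occupancy fractions are already on a common scale); components come
from a full SVD. With six samples the coordinates on PC1–PC2 are the useful
summary, and with a real between-strain effect the strains should separate
along PC1 by more than replicates scatter.

## Differential tests

**Per-position t-test.** A two-sided pooled-variance Student's t-test
(df = n₁+n₂−2) is applied to the normalized values at every position,
perturbed vs reference. Student's rather than Welch's form is the default
because it is the named test of this analysis style; `welch=True` is
available. No multiple-testing correction is applied by default — the
significance track deliberately reports raw p < α per position, matching
the visual significance-bar convention. Degenerate positions (zero variance
in both groups) get p = 1 when means agree and p = 0 otherwise, and are
flagged; positions with no signal in either condition are marked untestable
and excluded from any calibration statement. With n = 3 per group on
discrete counts the test is only approximately t-distributed; the null
false-positive fraction at α = 0.05 sits near but not exactly at 0.05,
which is why calibration is checked against a band (0.02–0.09) rather than
a point.

**Region KS test.** For each region the two strains' per-position median
occupancy values are compared with a two-sample Kolmogorov–Smirnov test
(D = sup ECDF difference; p from the asymptotic Kolmogorov distribution at
the standard two-sample effective n). This reads "difference in
distribution patterns" as a difference in the distribution of occupancy
*values* within the region. A weighted-positional variant (comparing
cumulative occupancy along the region) is a defensible alternative reading
that is noted but not implemented. Adjacent positions are not independent
observations, so the KS p-values should be read as descriptive summaries,
consistent with their figure-annotation role.

## Pause calling and the difference logo

Pause sites are called per condition on the median normalized profile (not
per replicate): spacer positions with median > 0 are ranked descending,
ties broken by ascending coordinate, and the top ceil(q·n_eligible) are
selected, q = 0.025 by default. Zero-median positions are excluded from the
eligible set so that the quantile refers to observed positions. Per
replicate calling with intersection across replicates is intentionally not
the default; the median already enforces replicate support.

Sequence contexts are LNT-centered windows of width W = 21 (±10 nt; the
window width of the original figure is not recoverable, so this default is
a documented choice). Windows crossing a template end are dropped and
counted. Base frequencies get a per-cell pseudocount of 0.5, which keeps
columns positive on 50-context pause sets without visibly distorting them.

The difference logo computes, per column, the Jensen–Shannon divergence in
bits between the two conditions' base distributions, and apportions it to
bases as signed heights proportional to the base-frequency differences
(positive = enriched in the perturbed condition). The divergence of a
column is therefore exactly the sum of its absolute letter heights, the
construction is antisymmetric under swapping the conditions, and 0 ≤ JSD ≤ 1
bit for a 4-letter alphabet.

A structural note on effect sizes: because the pause boost is
multiplicative on the baseline, a strong perturbed-condition boost implies
the reference condition also ranks most planted motifs inside its own top
2.5%. The two pause sets then overlap heavily, and since shared contexts
contribute identically to both frequency matrices, the per-column JSD of
the difference logo is intrinsically small (order 0.01 bits at the default
effect sizes) even when motif recovery is perfect. The informative output
at desk scale is the *sign pattern* of the heights over the planted motif
offsets, not the magnitude of the divergence.

## The synthetic-data generator

The generator encodes the standard NET-seq reading that occupancy is
proportional to dwell time: the probability that a read's 3′ end falls at
position i is

    w(i) = 1 + A·(1 + sin(2πi/T))/2,

boosted multiplicatively at planted motif LNT positions (factor 5 in the
reference condition, ×5 again in the perturbed condition by default) and
normalized. Defaults: 7 kb template tiled ETS1 10% / 18S 25% / ITS1 5% /
5.8S 3% / ITS2 7% / 25S 40% / ETS2 10%; period T = 200 nt and amplitude
A = 16, i.e. a 17-fold peak-to-trough range — occupancy profiles over this
unit are strongly peaked and quasi-periodic, and this amplitude keeps the
perturbed motif weight (25× local baseline) above every baseline peak so
that planted-pause recovery is a property of the method, not of sampling
luck. Twenty TTTTGGGG motifs are planted at uniform-random spacer positions
with ≥ 25 nt separation; accidental occurrences of the motif string in the
background are disrupted so the truth record is exact. Three replicates of
2×10⁵ reads per condition are drawn multinomially; 30% of reads are
contamination placed uniformly on mature regions (the fraction in real
libraries is unknown; this value is an arbitrary, documented default); 10%
of the final read list are verbatim PCR copies of already-emitted reads;
each unique read receives a random 8-mer UMI; read lengths are uniform on
20–100 nt with starts clipped at zero. Everything derives from a single
integer seed and is byte-reproducible.

The truth record carries the planted LNT positions, both occupancy
distributions, and per-replicate pre-duplication, duplicate, contamination
and UMI-collision counts, so conservation through deduplication and
counting can be asserted exactly.

**What the simulator does not emulate:** sequencing errors and quality
scores, alignment artifacts (reads are emitted pre-aligned), UMI errors,
copy-number variation among rDNA repeats, batch effects between replicates,
non-uniform contamination, and any correlation structure in pausing beyond
the planted motifs and sinusoidal baseline. Passing tests therefore show
that the pipeline's inference is correct *under its own statistical
assumptions* at realistic depth — not that those assumptions hold for any
particular real library.

## Numerical choices and degenerate inputs

- Moving averages are centered boxcar means with shrinking edges (output
  length = input length); even windows extend ⌊(w−1)/2⌋ left and ⌊w/2⌋
  right. Implemented with cumulative sums for exactness and speed.
- Median over an even number of replicates is the mean of the two central
  order statistics.
- Pause-ranking ties break by ascending coordinate, making the call
  deterministic.
- JSD values are clipped at zero to absorb −1e-17-scale floating-point
  round-off; identical columns give exactly zero divergence and zero
  heights.
- Templates containing N are rejected at load; lowercase bases are
  uppercased with a log message; multi-record FASTA is an "ambiguous
  reference" error.

## Problem sizes

The bundled tests and the reproduction script run the full default study
conditions — 7 kb template, 2×10⁵ reads × 3 replicates × 2 conditions per
experiment, three experiments (null, strong-effect, contamination-free) —
which completes in well under a minute on one CPU. These sizes were chosen
as the package's standard desk-scale conditions: deep enough that replicate
correlation, null calibration and motif recovery are stable properties,
small enough to iterate on freely.
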