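# Methods

## Coordinates and the dyad convention

Internally all intervals are 0-based half-open (BED); report output uses
1-based inclusive coordinates. A single midpoint convention is used
everywhere: the dyad of a fragment `[start, end)` is the central base,
rounded **up** for even lengths — `dyad = start + length // 2`, equal to
the 1-based round-half-up central coordinate (a 147-bp fragment with first
base s has dyad s+73; a 148-bp fragment, s+74). This one rule feeds the
region-exclusion filter, the center anchor mode, dyad histograms, and the
positional (+1/−1/+2) selection.

Nucleosomal fragments are strandless double-stranded intervals. "Both
strands" in the correlation functions means the left-anchor histogram plus
the right-anchor histogram: a fragment's start on the minus strand is its
right end. For fixed-length fragments the two are identical; for pooled
147–152-bp fragments they differ slightly. The center anchor pairs the
round-half-up dyad with its minus-strand counterpart (round-half-down).

## Distance correlation functions

`compute_dac` forms, per chromosome, the count vector of anchor positions
and evaluates `values[d] = Σ_i c_i c_{i+d}` for d = 1..D by FFT
autocorrelation (`scipy.signal.fftconvolve`); an exhaustive O(n²) pair
enumeration lives in the test suite as the independent oracle. Counts are
integers, so the float correlation is rounded to the nearest integer
(exact below 2⁵³). The d = 0 bin is defined as the within-position pair
count Σ c(c−1)/2 and flagged as a self-distance: plots and peak searches
skip it by default. `coincidence` weighting clamps counts to 1 before the
same sum. `compute_dcc` sums ordered cross-dataset pairs at |x − y| = d
(lags +d and −d of the cross-correlation), with the d = 0 bin (shared
positions) included. Distances are only defined within a chromosome.

Region restriction (`restrict_to_regions`) is a fragment filter applied
before DAC: a fragment is kept when its dyad lies in
`[body_start − pad, body_end + pad)` of any listed gene. Both members of a
retained pair therefore passed the filter individually; the paper-style
"gene body ± 200 bp" analysis is this filter followed by a plain DAC.

## Periodicity estimation

Peaks are local maxima of a centered moving average (window 3 bp for
sub-peaks, 21 bp for main peaks — the fine structure sits on a ~10-bp
lattice, the main peaks on a ~160-bp one; neither window is prescribed by
the data, both are configurable). The prominence threshold is a fraction
(default 5%) of the median smoothed value inside the search range, which
makes peak positions invariant under scaling of the histogram.

Each peak gets a harmonic index `round(position / period_guess)`; members
of a split first peak within half a period of one period all receive index
1 (the 151/162/171-bp triplet regresses at index 1 alongside single peaks
at indices 2–6). An index of 0 raises instead of clamping — it means the
period guess is wrong. The period estimate is the OLS slope of position on
index (`scipy.stats.linregress`), reported raw and rounded for display
(0.01 bp for sub-peak fits, 1 bp for main-peak fits).

The envelope diagnostic takes the histogram values at the sub-peak
positions and scores the largest positive jump between consecutive
envelope values inside a probe window (default 70–100 bp), normalized by
the median absolute consecutive change outside the window; a score above
3 reports a discontinuity at the midpoint of the flanking sub-peaks.
**Limitation:** in ensembles mixing a fixed spacing with longer spacings,
the cross-population distance mass at d is mirrored at (spacing − d), so
it fills the 20–140-bp range symmetrically: the observed signature is a
*flattened, elevated* envelope through the trough rather than a localized
step, and the jump score does not separate mixed from uniform ensembles on
the simulated conditions (both score ≈ 0.5). The score does detect genuine
value steps, e.g. a single re-positioned cluster adding a spike at one
distance on a locus-level profile.

## Occupancy and composites

Occupancy at a base is the number of covering fragments divided by the
genome-wide mean coverage per bp, so the normalized track has genome-wide
mean 1 (coverage is accumulated by difference arrays and prefix sums).
Composite TSS profiles average the track over genes without weighting
(each gene counts equally); minus-strand genes are flipped so positive
offsets run with transcription, and genes whose window would cross a
chromosome end are dropped with a warning rather than padded — padding
would bias the mean near the edges. The default window is 500 bp upstream
to 2000 bp downstream.

## Sequence patterns

`extract_aligned` places every fragment in a fixed frame of
147 + 2·extension bases centered on its dyad, so dyads of 147–152-bp
cores coincide at the matrix center (the frame is genomic sequence either
way; pooled variable lengths share the 73.5 dyad step). Fragments of
minus-strand genes are reverse-complemented so the axis runs with
transcription. Dimer-class fractions (WW = AA:TT/AT/TA, SS = GG:CC/GC/CG,
plus WS/SW) are computed per base-pair step; steps containing N are
excluded from that step's denominator, keeping WW+SS+WS+SW = 1 exact.
Smoothing is a centered 3-bp running mean with truncated edges;
symmetrization averages each step with its mirror about the dyad step
(mirroring the step axis is a reverse complement, so WS mirrors onto SW
and the self-complementary WW/SS mirror onto themselves).

Cut-site coordinates: position 0 is the last genomic base 5′ of the
fragment, +1 the first fragment base; the 3′ cleavage site is
reverse-complemented into the same frame and both ends of every fragment
contribute. `end_consensus` reports per-position base frequencies, a
degenerate consensus string with the cut bar, and the fraction of ends
whose (0, +1) dimer is W|W. `filter_end_subset` keeps fragments whose cut
dimer is **not** W|W at both ends (default `rule="no-ww"`); at ~80% W|W
cleavage this retains a few percent of fragments, the scale reported for
such subsets. The stricter reading — no A or T at either position,
`rule="no-w"` — retains ~10× fewer and is exposed as an option, as is a
single-end variant.

+1 nucleosomes are fragments whose dyad falls in [+1, +140] of a gene in
transcription coordinates, where the TSS itself is coordinate +1 and there
is no coordinate 0. The −1 and +2 windows ([−180, −41] and [+141, +300])
are package defaults, configurable and recorded in output metadata.
Induction grouping sorts genes by fold change (ties broken by gene id for
determinism) and takes the top/bottom ⌈fraction·n⌉; a hand-picked group
size (e.g. 45 of 234, which is not any rounding of 20%) can be passed
explicitly.

## Simulator

`simulate_arrays` realises a population of cells over one locus (or a
chromosome-scale region): all cells anchor their first dyad at the same
offset — the phasing imposed by a promoter NDR — and each cell draws an
array spacing model. Per nucleosome, a rotational cluster offset of k
helical turns is drawn (default distribution ∝ 0.6^|k| for |k| ≤ 6, wide
enough to populate the sub-peak fine structure over 10–120 bp), a fragment
length is drawn uniformly from 147–152 bp, and the fragment is emitted
centered on the jittered dyad. The non-integer helical period 10.25 bp is
realised on the integer lattice by cyclic 10/10/10/11 steps (offsets 10,
20, 30, 41, 51, …), so regression of recovered sub-peaks returns 10.25.
Arrays are truncated at the region boundary. The ground-truth record (one
row per nucleosome: cell, component, nominal and realised dyad, jitter,
length) is a first-class output, so recovery tests never reach into the
generator. The mixture preset draws each cell as either a fixed-160-bp
array or an irregular array with every gap uniform on 180–250 bp.

`simulate_genome_and_cuts` draws an i.i.d. genome at 60% AT (the yeast
scale) with the per-position W probability modulated around each nominal
dyad by amplitude·cos(2π(i − dyad)/10.25). The default amplitude 0.06
matches the size of observed WW-fraction oscillations (~0.30–0.42 about
the 0.36 i.i.d. level). Each fragment end is then re-sampled among shifts
of up to ±3 bp, weighting a candidate by `cut_bias_strength` (default 25)
when its cut dimer is W|W; the default is calibrated so ~80% of realised
cleavage sites are W|W, the observed MNase preference. All randomness
flows through one `numpy` generator per run; identical seeds give
byte-identical outputs.

What the generator does *not* emulate: sequence-directed translational
positioning (positions are imposed, not read from the genome), linker
histones and remodeler dynamics, chromosome-scale heterogeneity of repeat
length, and correlated genome composition (real genomes are not i.i.d.).
Passing tests therefore demonstrate correctness of the estimators under
the stated generative assumptions, not performance on real chromatin.

A known generator artifact: because cut re-sampling moves fragment ends,
fragment midpoints shift by up to ±3 bp, weakly coupling end-context
selection to the planted cosine phase; at realistic amplitude this
contributes well under 0.01 to profile differences, and the end-filtered
vs full-set comparison is made over the core interior (beyond one helical
turn from each core terminus), where the end-selection effect has died
off — mirroring the claim that the two profiles agree *within* the core
while differing at the termini by construction.

## Problem sizes

The test suite runs ensembles of 2000 cells over 2-kb loci for the
distance-correlation recoveries (~24k fragments, seconds) and a 2-Mb
genome sampled by 100 cells for the end-filter robustness comparison
(~750k fragments, ~1 minute), chosen so that the subset retains enough
distinct genome positions (~25k sequences) for a 0.02-level comparison.
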