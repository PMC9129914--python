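# Methods

## Signal model

A dihydrouridine site, once chemically reduced, halts reverse transcriptase
one nucleotide 3′ of the modified base. In a library built from truncated
cDNAs this produces a sharp, strand-specific excess of cDNA 3′ termini at
the peak position `d + 1`. The pipeline therefore works on *end-count
tracks*: per-transcript integer arrays where `counts[i]` is the number of
accepted reads whose RT stop projects to transcript position `i`
(coordinates 0-based, half-open, 5′→3′ on the RNA; on the minus strand
transcript position 0 is the genomically rightmost exon base).

Which read end is the RT stop depends on the library chemistry after PCR;
the extractor's `end_convention` (default: the 5′ end of the read on the
transcript strand, i.e. the base that abuts the cDNA's 5′ sequencing
adapter) is configurable, and the simulator shares the same convention so
round trips are exact. Only primary alignments at or above a mapping-quality
threshold (default 10) are counted, excluding multi-mappers; reads on the
strand opposite every local transcript are tallied separately as an
orientation diagnostic, and stops outside any transcript go to a spill
bucket so that `sum(counts) + spill = accepted reads` always holds.

## Window scores

Both metrics compare the end count at a test position with its local
background in a `window_size` window centered on the position
(default 101 nt, i.e. ± 50; an odd width is required for exact centering).
Windows are truncated at transcript ends, never padded, and each record
carries the actual window length so callers can filter.

- Modified Z: the test position is excluded from the window mean and
  standard deviation; the population (n, not n−1) standard deviation is
  used — either is defensible, one is fixed and documented. Zero spread
  makes the position *unscorable* (flagged, never silently 0 or ±inf).
- MAD score: window median and median absolute deviation, test position
  included by default; `exclude_center=True` is available for both metrics.
  A zero MAD (fewer than half the window positions carrying signal) is
  unscorable. The MAD path additionally records whether the window median
  is positive (`pass_median`), which the ncRNA calling rule requires.

The coverage filter is `window_sum >= coverage_min` (default 50), boundary
inclusive. Median of an even number of values is the mean of the central
two. The vectorized scorer (sliding windows over full-width positions, a
scalar path at the edges) agrees with the definitional scalar functions;
counts are integers, so the windowed sums it uses are exact in float64.

Why two metrics: one strong stop in a window inflates the mean and standard
deviation and so dampens the Z of a second stop nearby — common in tRNA,
where modification and structure create many penetrant stops. The median
and MAD are insensitive to a few such positions, at the price of requiring
ends mapped to more than half the window for a nonzero denominator, hence
much higher coverage.

## Calling, cutoffs and FDR

A position is called when (i) every library passes coverage (plus the
median rule under the MAD metric), (ii) the score is defined in every
library — an unscorable position in any library disqualifies the call
rather than passing silently, (iii) every treated replicate scores strictly
above `treated_min`, and (iv) every control replicate scores strictly below
`control_max` (a `control_rule="mean"` variant relaxes (iv) to the control
mean). Published class defaults ship in `defaults.json`: mRNA Z 10/7, tRNA
MAD 40/40, snRNA/snoRNA MAD 12/8, coverage 50; CLI flags override. The
empirical machinery — per-library inverse-CDF survival curves and a
divergence-point suggestion (smallest grid score at which the mean control
survival fraction falls to a chosen fraction of the treated one) — is
advisory only and never overrides the shipped defaults unless the user opts
in.

The D coordinate is `peak − 1` in transcript coordinates (undefined and
flagged when the peak sits at position 0); on the minus strand the genomic
D coordinate is the genomic peak coordinate + 1 by the same projection.

FDR is estimated by inverting the analysis: swap the treated/control roles
and count surviving "sites"; `FDR = n_inverted / n_forward` (not applicable
when no forward calls exist). With no true signal the two counts are
exchangeable by construction, which the null-symmetry test exercises.

Shadow annotation is purely descriptive and removes nothing: a called site
within `shadow_range` nt (default 80, the upper bound of the 70–80 nt RNA
size selection) 5′ of a *stronger* called site is flagged as a possible
shadow artifact, and any candidate position with a called site within that
range on its 3′ side is reported as potentially shadowed, explaining its
non-detection. Feature annotation labels each call by the segment
containing the D coordinate and reports the feature distribution of all
positions interrogated in every library as the comparison background.

## DMS meta-analysis

Reactivity is mutations/coverage from a mutational-profiling experiment.
Positions enter the analysis only with coverage strictly greater than 350
and base A or C. Reactivities are pooled per offset in a 25-nt window
around each D coordinate; the per-offset median is the profile. For
visualization, 70 draws of `|sites|` background positions (sampled without
replacement within a draw, independently across draws, from interrogated
positions below both score cutoffs) give the background band; significance
per offset comes from a two-sided Mann–Whitney U test of the site pool
against the pool around the *full* background set, not the draws. The U
test enumerates all group assignments exactly (tie-aware) when both samples
have ≤ 8 observations and otherwise uses the normal approximation with tie
correction. Empty pools yield gaps, never interpolation. The background
sampling seed is mandatory and recorded in the output.

## Intron retention

For a gene model with intron features, the retention index per replicate is
intronic reads / exonic reads by counted position (for whole alignments,
junction-spanning reads count as intronic by default since they evidence an
unspliced molecule; configurable). Conditions are compared with a
two-sample, two-sided, equal-variance Student's t test (df `nA + nB − 2`;
Welch via flag). Raw counts are used without length normalization, as the
segments are fixed across the compared conditions. Degenerate zero-variance
inputs with equal means return t = 0, p = 1 instead of NaN.

## Simulator

Per fragment: length uniform on 70–80 nt, placement uniform among valid
positions; the RT starts at the fragment 3′ end and walks 5′-ward. After
each copied nucleotide it stops with background probability `b`; before
copying a planted site that is modified on this molecule (probability
`stoichiometry`) in a treated library it stops with probability
`stop_efficiency`, leaving the terminus at `site + 1`. Truncated cDNAs are
retained when 50–80 nt long and contribute one end count at the stop;
runoffs (full-length cDNAs) are tracked separately and, when emitted, model
the matched full-length RNA-seq control libraries. Control libraries run
the identical process with all stop efficiencies forced to zero.
Stoichiometry and stop efficiency are deliberately separate parameters;
neither is biologically pinned down, so recovery studies sweep them.

The batch implementation draws the background stop offset as a geometric
variable and each planted site as an independent Bernoulli, realizing the
3′-most firing event — equivalent in distribution to the sequential
reference walk, which is kept as the readable scalar implementation and
cross-checked against closed-form expectations (expected retained stops =
covering fragments in the retention range × s × e × background survival
along the path). One root seed spawns a substream per (condition,
replicate), so adding a replicate never perturbs existing libraries.
Shadowing is emergent, not scripted: a penetrant 3′ stop consumes the
fragments that would have reported a 5′ site.

Defaults used by the validation studies (and `scripts/acceptance.py`): one
2,000-nt transcript, 3+3 replicates, 65,000 fragments per library and
background stop probability 0.003/nt — together giving a mean 101-nt window
coverage a little above 200 — with planted sites at stoichiometry 1 and
stop efficiency 0.3, spaced ≥ 200 nt apart to keep them independent of
shadowing. The background rate is an order-of-magnitude choice (no
experimental estimate exists) and is exposed in the config, never asserted
as biological truth.

What the simulator does *not* model: sequence-level reads (no FASTQ), PCR
duplication, alignment error, transcript-abundance skew beyond copy-number
weights, or chemistry side reactions on other modified nucleosides (these
appear only as generic background stops). Passing recovery tests therefore
demonstrates the statistical machinery under the stated generative
assumptions, not performance on real libraries with correlated noise,
mappability artifacts or m2,2G-type confounding stops.

## Numerical and design notes

- Coordinates are 0-based half-open internally; bedGraph is emitted
  0-based and wig 1-based per their standards; zero positions are omitted
  on write and restored as zeros on read, so raw integer tracks round-trip
  losslessly.
- Survival-curve grids default to the union of observed scores; the
  divergence suggestion returns the smallest qualifying grid score, which
  can coincide with the smallest true-signal score when the score
  distribution is strongly bimodal — it is a suggestion to inspect, not a
  decision rule.
- Assigning a read whose stop falls in two same-strand overlapping
  transcripts is resolved deterministically (lexicographically smallest
  transcript id) and affects only annotation, not counts.
- Paired-end input: only read 1 is counted, since the RT stop is defined by
  a single cDNA terminus.
- GFF3 mRNAs become unspliced (pre-mRNA) models by default so intronic
  stops are observable in genome space; BED12 yields spliced models, where
  intron features do not exist by construction.
- Known limitations: no motif or conservation analysis around sites, no
  per-enzyme site assignment, no MaP-style mutation scoring of D, and the
  paired 70–80/50–80 size windows are treated as hard cutoffs rather than
  efficiency curves.
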