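# Methods

This note documents the models, conventions and numerical choices behind
mitocodon, in the order of the pipeline.

## Coordinate model

All public interfaces use 1-based inclusive coordinates, matching the way
mitogenome annotation tables are printed; half-open 0-based coordinates
appear nowhere outside internal slicing.  Circular topology is explicit: a
feature with `end < start` wraps the origin, and the adjacency between the
last and the first feature is evaluated across the origin.  `N` bases are
allowed in sequences and are excluded from every composition denominator.

The bundled reference annotation (`data/aphid_mitogenome_features.tsv`) is a
transcription of the printed feature table of a 15,772 bp aphid
mitochondrial genome: 13 protein-coding genes, 22 tRNAs, 2 rRNAs, the
control region (CR, 1109 bp) and the aphid-specific repeat region (RR,
193 bp), 39 features in all.  Its integrity is pinned by a checksum test.
The sequence itself is not distributed; every sequence-based analysis is
exercised on synthetic data instead.

## Organization arithmetic

For consecutive features sorted by start, `gap = start(next) − end(prev) − 1`.
Positive gaps are intergenic spacers, negative gaps overlaps, and zero
(abutting) counts in neither class — this single convention reproduces every
value of the reference table's intergenic column, including the
across-the-origin entry.  CR and RR participate in adjacency exactly like
genes, because their intergenic entries are printed in the source table.

Protein-coding totals are reported both as the raw sum of annotated sizes
(10,952 bp for the reference table) and with annotated stop codons removed
(10,917 bp, 3,639 codons).  Published grand totals occasionally disagree
with the per-gene column by a few stop-codon bases, so no attempt is made to
pick a winner.

## Composition and skews

AT skew = (A−T)/(A+T) and GC skew = (G−C)/(G+C) are computed from counts;
because both are ratios they can equally be evaluated from printed
percentages, which is how a published composition table is replayed without
the sequence.  The signed convention of the defining formula is used
throughout (an AT-rich insect mitogenome typically shows a strongly
*negative* GC skew on the majority strand).  Zero denominators yield an
explicit `None`, never a silently propagating NaN.

For groupings over stranded features (PCGs, tRNAs) two labeled profiles are
emitted — one concatenating plus-strand slices, one concatenating
annotated-strand readings — because published tables do not always state
which convention they used.  `by_strand` always uses the annotated reading.

## Codon usage

Synonymous families group codons sharing amino acid *and* first two bases.
This reproduces the conventional Leu1/Leu2 and Ser1/Ser2 split and, under
the invertebrate mitochondrial code (NCBI table 5, the package default),
partitions all 62 sense codons into 13 two-fold and 9 four-fold families.
Consequences used throughout:

* GC3s equals GC3 under this code, since every sense codon sits in a
  degenerate family; both are still computed and labeled separately so that
  other codes behave correctly.
* The ENc upper bound under uniform usage is 62 (sum of family sizes),
  slightly above the textbook 61 derived for the standard code.

Stop codons and incomplete terminal stops (the single `T` completed by
polyadenylation in mitochondrial transcripts) are excluded from all usage
statistics; a trailing 1–2 nt remainder of a CDS is dropped as an
incomplete stop.  Internal stops raise a warning naming the codon position.

ENc is Wright's estimator: per family, F̂ = (nΣp²−1)/(n−1); families with
n < 2 or F̂ = 0 are excluded from their degeneracy-class mean; ENc is the
sum over classes of N_class/F̄_class.  A class with no usable family is
imputed at the uniform expectation 1/k with a warning (with only two
degeneracy classes under the split convention there is no flanking class to
average, so the uniform value is the least-informative choice).  Values
above the nominal maximum are reported raw and flagged, not clamped.

The ENc-plot expectation is ENc_exp = 2 + GC3s + 29/[GC3s² + (1−GC3s)²].
Note the curve is *not* symmetric about GC3s = 0.5 — the linear term breaks
the symmetry of the homozygosity denominator — so the tests assert symmetry
of ENc_exp(s) − s rather than of the curve itself.

The neutrality regression is ordinary least squares of GC12 on GC3 with a
two-sided t-test (n − 2 df) for the slope; a flat response is reported as
slope 0 with R² 0 rather than NaN.

## Ka/Ks

Nei–Gojobori (1986) counting with Jukes–Cantor correction, the documented
default of the DnaSP lineage of tools:

* Synonymous site fractions per codon come from the code: at each position,
  the fraction of the three possible changes that are synonymous; changes
  creating a stop count as nonsynonymous, so S + N = 3 per codon exactly.
* Codons differing at 2–3 positions are averaged with equal weight over all
  orderings of the changes; orderings passing through a stop codon are
  excluded unless that removes every pathway (then all orderings count and
  stop-crossing steps count as nonsynonymous).
* Codons containing a gap or N in either sequence are wholly excluded from
  sites and differences (pairwise deletion).
* p ≥ 3/4 leaves the JC distance undefined (NaN, flagged); Ks = 0 leaves
  ω undefined (`None`).

Gene-level summaries average ω over defined pairs and compare Ka against Ks
with a plain paired t statistic across pairs.  The per-gene ANOVA-with-
letters presentation sometimes seen in publications is out of scope.

## Nucleotide diversity

π per window is the mean over sequence pairs of differences per comparable
site, excluding sites with a gap or ambiguity in either row of the pair;
windows with no comparable site are emitted as missing.  With gapless data
and tiling windows the window mean equals the overall π exactly, which the
suite asserts.

## Repeats

* **SSRs**: perfect repeats only, motif lengths 1–6 at minimum repeat
  numbers (10, 5, 4, 3, 3, 3).  Only maximal runs with a primitive motif
  are reported, which prevents an (A)₁₀ run from also appearing as (AA)₅.
  Compound-SSR merging (the interruption rule of microsatellite web tools)
  is deliberately not implemented.  A `circular` flag doubles the sequence
  and de-duplicates by modular position so origin-crossing runs are found.
* **Dispersed repeats**: maximal *exact* repeat pairs ≥ 30 bp by
  seed-and-extend, in four orientation classes (forward, reverse,
  complementary, palindromic).  Web tools in this niche allow mismatches
  under an E-value; exact matching at the published length threshold is the
  reproducible core.  Every reported repeat re-verifies its class relation
  by direct string comparison before being returned.
* **Tandem decomposition**: the principal period is the smallest lag whose
  exact-match autocorrelation reaches 80% identity (lags up to twice the
  unit-size cap are scanned so alternating two-unit arrangements are
  caught).  If the trailing partial unit matches a prefix of the period,
  the period is split there into two unit types, turning an (AB)ⁿA layout
  into the alternating decomposition I-II-I-II-I; unit types are labeled by
  first occurrence.  Finding no periodicity is a valid outcome and yields
  an empty decomposition.  The 80% identity threshold tolerates the unit
  variation seen between real control-region variants; it is a package
  choice, not a published constant.
* **Stem-loops**: purely combinatorial inverted-repeat arms (default stem
  ≥ 5 pairs, loop ≤ 50 nt), grown outward from innermost base pairs; no
  thermodynamic folding.

## Synthetic data

The generators define the study conditions for all stochastic tests.

* `make_genome` lays features head-to-tail from a plan of lengths and gaps
  (negative gaps create overlaps; plans must tile the circle exactly).  The
  background sequence uses an exact-count shuffle at the AT target (default
  replays use 84.34%, the AT content of the reference genome), so regional
  composition matches the target up to rounding; protein-coding features
  receive a valid ATN start and a TAA/TA/T stop matching length mod 3;
  planted repeats are written last so their ground truth is exact.  A plan
  transcribed from the reference annotation replays the published
  organization arithmetic exactly.
* `make_codon_set` draws codons i.i.d. from a user profile — multinomial
  ground truth for RSCU/ENc/PR2 recovery tests.
* `evolve_pair` runs a Gillespie simulation of a codon substitution process
  on a star tree: uniform sense-codon ancestor, single
  transition/transversion ratio κ (default 2), ω multiplying nonsynonymous
  rates, rates normalised so the neutral process has unit expected
  substitutions per codon per unit time.  True synonymous/nonsynonymous
  event counts are recorded per lineage.

What the generators do *not* emulate: real codon-frequency profiles,
among-site rate variation, indels, and the base-composition asymmetry
between strands.  Passing recovery tests therefore demonstrates estimator
correctness under the stated model, not robustness to every property of
real mitogenomes.

On estimator calibration: the ω = 0.1 recovery test runs at κ = 2 and
passes within its band even though Nei–Gojobori ignores transition bias;
the ω = 1 interval test runs at κ = 1, matching the estimator's equal-rate
assumption, because under κ > 1 the method is known to deflate ω (transition
bias makes synonymous changes more frequent than the site counts assume).
Pairs drawn from a star tree share lineages, so the neutral-ω interval uses
the effective number of independent pairs (⌊n_taxa/2⌋) rather than the
nominal pair count.

## Problem sizes

The default suite and the acceptance script use: 500 random codon-sequence
pairs (20–60 codons) for the Ka/Ks oracle comparison; 25 sequences of
1–2 kb each for the SSR and dispersed-repeat oracle comparisons (half with
planted repeats, since exact ≥ 30 bp repeats essentially never occur by
chance in random sequence); 500-codon, 10-taxon simulations for ω recovery;
a 2 kb, 4-row alignment for the diversity check; and a 612 bp planted
I-II-I-II-I region (142/93 bp units) for tandem decomposition.  These sizes
were chosen so the whole battery runs in well under a minute while keeping
every stochastic tolerance comfortably resolvable.

## Known limitations

* Only frame-0, pre-aligned coding sequences are analysed; no alignment or
  annotation is performed.
* Dispersed-repeat detection is exact-match only and can be verbose on
  low-complexity sequence (every pair of homopolymer offsets is a maximal
  repeat).
* The tandem decomposer assumes at most two alternating unit types per
  region; deeper unit hierarchies collapse onto the principal period.
* ENc missing-class imputation departs from tools that interpolate between
  flanking degeneracy classes, which do not exist under the two-class
  split-family code.
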