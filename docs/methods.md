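# Methods

This note documents the models and algorithmic choices behind
`haplotile`: what the synthetic diploid chromosome emulates, how tiling
paths are phased and extended, how collinearity is measured, and how
the three chromosome maps (genetic, cytogenetic, sequence) are
reconciled.  Parameter defaults are given with their rationale; every
number quoted here is either a configured default or is computed by the
test-suite / acceptance script.

## The synthetic diploid chromosome

`synthetic_genome` generates a haploid reference (`REF`) and two
homologues (`HAP0`, `HAP1`) of a heterozygous diploid.  The chromosome
is divided into five regions in fixed order — north euchromatin, north
heterochromatin border, central heterochromatin, south heterochromatin
border, south euchromatin — with default proportions 20.1 / 25.7 /
34.7 / 3.6 / 15.8 % taken from the per-region sizes of the reference
chromosome the simulation mimics (they sum to 1 by construction).

Each region carries a zygosity plan of sub-tracts:

* **homozygous** — both homologues are identical (they still share
  substitutions relative to the reference at the reference rate);
  placed in the euchromatic arms, mimicking the observed alternation of
  polymorphic and non-polymorphic intervals.
* **heterozygous_collinear** — the workhorse tract.  Substitutions are
  split into a shared component (rate `snp_rate_vs_ref −
  snp_rate_between_haps/2`, default 0.0075/bp) present in both
  homologues and private components (rate `snp_rate_between_haps/2 =
  0.0175`/bp per homologue), so that homologue-vs-reference identity is
  ~97.5% and homologue-vs-homologue identity ~96.5%.  Small indels
  (default 2×10⁻⁵ events/bp between homologues, geometric lengths
  truncated to 1–50 bp) are private per homologue.
* **cluster_break** — a tandem gene-cluster analogue: the head of the
  tract is replaced by `c` copies of a unit (default unit ~3 kb, copy
  numbers 2 vs 5, unit divergence 10%) *per homologue*, consuming the
  tract head so length is conserved.  With ≥2-fold copy-number
  difference the pairwise collinearity over the tract drops below the
  green band.
* **hemizygous_insert** — a heterozygous-collinear background carrying
  one large one-sided insert (uniform length, default range scaled from
  the full-size 200–450 kb to the simulated chromosome, ~7.7–17.3 kb at
  2 Mb) in a randomly chosen homologue.
* **non_alignable** — the central heterochromatin: the homologues are
  independent random sequences except for a configurable number
  (default 3) of planted shared segments (default scaled from
  50–250 kb), each placed at the *allelic* (same tract-relative)
  position with probability 0.5 and at a displaced position otherwise —
  reproducing the situation where co-aligning blocks on opposite
  homologues need not mark the same physical locus.

Every stochastic event is recorded in a `TruthTable`: tract and region
bookkeeping, individual structural events with exact per-homologue
length deltas (length conservation is asserted exactly), per-homologue
polymorphic sites/intervals (used to place markers), and monotone
piecewise liftover maps reference↔homologue.  Sequence is i.i.d.
uniform at the configured GC (0.5); there is no repeat-library or
N-gap realism, so tests on this generator say nothing about assembly
behaviour in high-copy repeat space — only about the phasing/
collinearity logic under the configured divergence structure.

Scaling note: the chromosome defaults to 2 Mb (1/26 of full size).
Structural-variant and shared-segment length laws scale linearly with
chromosome length; clone lengths intentionally do **not** (they keep
the empirical library distribution), which makes clones relatively
~26× longer than at full scale.  Consequences are discussed under
tiling.

## Clone resources

`bac_resources` samples the library: clone counts per homologue equal
`equivalents_per_hap · hap_len / mean_len` (default 4.8 equivalents,
the design depth at which expected random-library coverage is
`1 − e^{−4.8}` = 99.2%); lengths are truncated-normal (mean 122,651 bp,
sd 25,000, bounds 14,260–216,437 — the empirical clone-length summary);
starts are uniform.  End sequences are exact 500 bp prefixes/suffixes
(read length is not documented for the real library; 500 bp is a
typical Sanger end read and is configurable).  The coverage law is the
L ≪ G limit; at desk scale the uncovered mass concentrates at
chromosome ends (edge effect ~2/n), which the tests account for by
checking the law with proportionally small clones.

Fingerprints are in-silico digests at two 6-bp motifs with an
electrophoresis sizing window of 50–1500 bp and a band-matching
tolerance of 3 bp; contigs are single-linkage components of pairs
sharing ≥60% of the smaller clone's bands.  The digest model is a
simplification (band-count overlap instead of a Sulston score); what
matters downstream — and what is tested — is its contig behaviour:
clones from identical sequence co-assemble, clones from ≤96%-identity
tracts separate by haplotype, distant clones link in <1% of pairs.

Markers emulate phase-specific tags of an ultradense genetic map:
each haplotype-specific site (private SNP/indel positions; every bp of
hemizygous inserts, cluster arrays and non-alignable tracts) becomes a
marker with probability `marker_density` (default 10⁻³ — chosen so a
~120 kb euchromatic clone carries ~2 markers, enough to anchor and
phase-check every clone; real marker densities are far lower, which is
one reason real projects need the BES verification step at all).  The
bin map divides the euchromatic arms evenly into bins 1–45 and 47–78
and collapses the whole heterochromatin (borders included, where
recombination is already suppressed) into bin 46 of a 78-bin map.

## Tiling paths

Paths are seeded in marker-anchored clones and extended greedily in
both directions.  A candidate clone (from the contig reservoir of the
current members, pre-screened by shared fingerprint bands with the end
clones) is accepted only if an end sequence matches the consensus at
100% identity — the rule that separates the ~96.5%-identity alternate
haplotype (an *allelic* match, 96–100% exclusive) and non-specific
matches (≤96%) from true same-haplotype overlaps.  Two guards harden
this rule where the homologues are locally indistinguishable:

* a placed candidate's *other* end, when it falls inside the consensus,
  must also match exactly (rejects clones straddling a homozygous-tract
  boundary that were placed by their homozygous-side end);
* marker phases veto candidates: a phased path never recruits a clone
  anchored to the opposite phase, an unphased path only recruits
  marker-free clones.

After extension, phased paths are trimmed back to marker-anchored
territory: terminal marker-free clones are released (the phase label is
vouched for by markers; beyond the last marker the path may have
entered a homozygous tract where phase is undefined).  Released and
unseeded clones start unphased paths; an unphased path whose observed
clone depth is ≥1.5× the per-haplotype library depth is relabelled
*monomorphic* — on identical sequence the clones of both homologues
co-assemble, doubling apparent depth.  With these rules, clone-level
phase accuracy in heterozygous tracts is 100% across the default
replicate set (the acceptance threshold is ≥98%).

Two desk-scale devices keep the path set well-behaved: a seed whose
end sequences already locate inside a built consensus is retired
(its region is sequenced; re-seeding it would duplicate coverage), and
a single path's consensus is capped at `max_path_span` (default
300 kb).  The cap stands in for the physical-map gaps and project
pragmatics that bounded real tiling paths: with full-length clones on a
2 Mb chromosome, uncapped extension would otherwise produce one or two
chromosome-scale paths and no order statistics to test.  Greedy
tie-breaking is: longest extension, then highest end-sequence identity,
then lexicographic clone id.  Consensus construction is splicing of
exact clone overlaps (interval union); no base-level reconciliation is
needed because simulated clones are error-free substrings — the
`same_hap_min_identity` knob (<100%) switches the BES rule to an
edit-distance alignment for error-containing input, but v1 performs no
consensus polishing.

## Collinearity

`find_anchors` enumerates maximal exact matches of length ≥ `w`
(default 20, the word length of the dot plots being emulated; 25 is the
other common setting) on both strands, via 2-bit-packed words (hence
`8 ≤ w ≤ 32`).  Words occurring more than `max_freq` (default 50) times
on either sequence are dropped before seeding so tandem arrays do not
flood the anchor set; merged seed runs are re-extended by direct
character comparison, so reported anchors remain maximal.

Chaining groups anchors into diagonal bands by single linkage on the
diagonal offset (tolerance `max_diag_drift`, default 5 kb) and splits
bands at positional gaps > `max_gap` (default 10 kb); reverse-strand
anchors are chained in the reverse-complement frame.  Segments are then
made non-overlapping on *both* coordinates by greedy admission in
decreasing anchor support with edge clipping — this is what prevents a
duplication block (one region matching many) from being counted more
than once.  Defaults are tuned to megabase-scale comparisons; for
kilobase-scale inputs they should be scaled down (the oracle tests use
300 bp), exactly as a dot-plot zoom would be.

The collinear fraction is `C = 2·O/(L1+L2)` with `O` defined as the
mean of the merged segment projections on the two sequences — the
definition leaves the projection side open, and the mean makes
`C(A,B) = C(B,A)` exact.  Bands: green ≥ 0.75 (the documented
good-alignment threshold, boundary inclusive), yellow ≥ 0.50, orange
≥ 0.25, red below — the sub-green cut-offs are conventional choices,
configurable, with no external anchor.  Insert calls: a gap of
≥ `min_insert` (default 20 kb, the size class of structural variation
targeted) on one sequence faced by ≤5 kb on the other, between
collinear flanks on the plus strand, is a hemizygous insert on the
gapped sequence; planted-insert recall at default settings is 100%
with sub-percent size error (flank anchors end within tens of bp of
the breakpoints at 3.5% background divergence, and exactly at them on
clean flanks).

`overlap_matrix` quantifies all-versus-all overlap between named
sequence collections (the central-heterochromatin comparison): per-set
coverages are merged per sequence before summing, the upper triangle
reports O in kb, the lower triangle the percentage of the row set
recovered in the column set — asymmetric by construction, since it is
normalised by the row set's total length.

## Chromosome map integration

A FISH signal is summarised as fraction length `FL = (S/T)·binT` per
cell (S = distance from the north end, T = total chromosome length,
binT = 78), reported as mean ± sample sd.  `simulate_fish` maps a
sequence position to a cytogenetic fraction through a piecewise-linear
condensation model — the heterochromatin (~65% of the sequence)
occupies only a configured 40% of the pachytene chromosome length, and
the arms share the rest proportionally — then adds per-cell Gaussian
noise (default sd 2 bin units over 20 cells, giving a standard error of
~0.45 bins; cell counts are an explicit input because real per-probe
cell numbers vary).

Ordering policy (`order_paths`): region assignment prefers a *good*
reference alignment (C ≥ 0.75, unique: ≥50% of the path covered), then
the marker bin; bin-46-only paths fall to the central pool because the
heterochromatin bin cannot separate borders from the centre.  Sorting
quantizes evidence to its true resolution: marker-bin medians round to
integers; an FL is converted to a *bin equivalent* through the inverse
condensation model (bins and FL otherwise live on incommensurate axes)
and is good to about one bin; the reference coordinate refines order
within a bin.  Opposite-phase paths whose good reference spans overlap
reciprocally ≥50% are *allelic partners*: they occupy one chromosome
position, so they share a rank (their listing order comes from the
reference coordinate).  Central-heterochromatin paths are ordered only
by a direct FISH anchor or by a good alignment overlapping a
FISH-anchored path's span; everything else is placed arbitrarily and
flagged, never silently interpolated.  Evidence conflicts (bin order
inverted against reference order) are flagged on both placements, not
resolved.  Euchromatic order recovery against ground truth is Kendall's
tau-b ≈ 0.99 over the default replicate set (physically co-located
partners counted as ties on both sides).

The allelism test compares two FL estimates: *different* if the
mean ± k·SE intervals are disjoint (default k = 2), *consistent* if the
separation is within k pooled-scale standard errors, *ambiguous*
otherwise; at 5 bins separation (sd 2, 20 cells) its power exceeds 95%.

The region table sums non-redundant consensus bp per haplotype class
(haplotype 0/1, monomorphic, unknown) × region; paths spanning a region
boundary are split pro rata by reference-span overlap with integer
remainders assigned to the last region, so the grand total equals the
summed consensus lengths exactly, and the totals row/column are always
computed, never supplied.

## Reproducibility and problem sizes

One integer seed drives every stage (stage seeds are fixed offsets);
two runs with one seed are byte-identical in all primary outputs, which
the manifest records as checksums.  Default problem sizes — a 2 Mb
chromosome for pipeline replicates (10 seeds in the test-suite, 3 in
the acceptance script), 100 kb tracts for identity calibration
(100/40 replicates), 150 kb pairs for insert detection, ≤5 kb pairs for
the O-statistic oracle — were chosen as the smallest systems in which
each tested effect is well separated from sampling noise.

## Known limitations

* No sequencing error, chimeric clones, vector contamination or
  assembly gaps; the 100%-BES rule would need the relaxed-identity mode
  on real reads, and consensus polishing is absent.
* No repeat-library realism: anchors in real pericentromeric
  heterochromatin face high-copy repeat families far beyond the
  word-frequency cap's i.i.d. setting.
* Insert detection works on the plus strand only; strand '−' segments
  count toward O but inversions are not called as variants.
* The condensation model is piecewise linear with a single compression
  plateau; real pachytene condensation varies continuously.
* The genetic map is idealised: bins are evenly spaced in the arms, and
  marker bins are always correct (no missing-score noise).
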