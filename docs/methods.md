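# Methods

`dsbmap` maps off-target DNA double-strand breaks (DSBs) from Nbs1 ChIP-Seq.
Nbs1, the DSB-binding subunit of the MRN complex, is immunoprecipitated from
activated B cells together with the chromatin flanking a break; deep
sequencing of the pulled-down fragments yields strand-oriented tags whose
geometry distinguishes break sites from ordinary protein-binding sites.
Comparing a wild-type library against an AID-knockout control separates
AID-dependent breaks (the off-target footprint of activation-induced
cytidine deaminase) from AID-independent ones.  This note records the models,
parameters, and numerical choices behind each stage.

## Read geometry at a break

After sonication, a fragment abutting a break retains the break end at a
fixed position while its other end is random.  Sequencing from the break end
of the left-hand fragment produces a minus-strand tag whose 5' end sits at
`b - 1` (immediately left of break position `b`); the right-hand fragment
produces a plus-strand tag at `b`.  A transcription-factor site shows the
mirror image: plus tags pile roughly a fragment length *left* of the bound
site and minus tags a fragment length *right* of it, because there both
fragment ends are sonication ends that must flank the protected site.  A
one-ended break (a nick converted to a DSB by a replication fork) retains
only one side, so its tags fall on a single strand.

These three signatures drive the classifiers and are exactly what the
synthetic-data generator plants.

## Pipeline stages

### Duplicate capping

Tags sharing (chromosome, 5' position, strand) beyond a cap are discarded.
The cap is 1 for sparse libraries ("remove all duplicates") and 3 when two
duplicates are to be retained alongside the original; both readings of the
latter phrase are supported through the `max_per_position` parameter.  The
operation is idempotent and order-independent because capped duplicates are
indistinguishable.

### Fragment-length estimation

The mean sequenced-fragment length is the shift `d` in
`[read_length, max_shift]` (default bounds 36 and 500 bp) maximizing the
Pearson cross-correlation between the plus-strand 5'-end density and the
minus-strand density displaced by `d`, computed on 1-bp bins per chromosome
(chromosomes holding >= 10,000 tags when any qualify) and summed; ties break
to the smallest shift.  In this assay the correlation signal comes from
break-anchored read piles pairing with their fragments' sonicated-end
clouds, not from the uniform background (a single-end read carries no
information about its mate's position).  Under the default simulation (true
mean 200 bp, SD 50) single-run estimates land within roughly +-20 bp and the
median over 20 replicate simulations is within +-10 bp of truth.  An
optional boxcar smoother over the correlation curve exists for very sparse
libraries but defaults off so that point-mass fixtures are recovered
exactly.

### Candidate calling and the tier filter

A 500-bp window slides at 1-bp steps counting WT tag 5' ends after shifting
each tag half a fragment length toward its fragment midpoint, so the two
strand piles flanking a break land in one window.  Local maxima are accepted
greedily by descending count with >= 500 bp between accepted centers; each
accepted window is then re-anchored on the centroid of the tags it contains,
which collapses the tie plateau of equal-count windows onto the pile itself
(called centers land within ~50 bp of simulated breaks).  A candidate
requires:

* `wt_tags >= 10` (the floor sits below every tier so the tier filter, not
  the caller, is the binding constraint);
* fold enrichment >= 2.0 over the control count scaled to the WT library
  size, with a pseudocount of 0.5 added to the scaled control so empty
  control windows stay finite.

The local background ratio divides the window's tag density by the density
of the surrounding 10-kb span (window excluded, pseudocount 0.5, span
clamped and renormalized at chromosome edges).

Surviving candidates pass through an experiment-specific tier filter on the
raw window tag count:

| profile | tag count | WT:control | local background | rule |
|---------|-----------|------------|------------------|------|
| exp1    | >= 18     | >= 2.0     | >= 6.0           | OR   |
| exp1    | 16-17     | >= 2.5     | >= 4.0           | AND  |
| exp1    | 14-15     | >= 3.6     | >= 4.0           | AND  |
| exp1    | 13        | >= 9.0     | >= 8.0           | AND  |
| exp2    | >= 53     | >= 2.2     | >= 6.0           | OR   |
| exp2    | 22-52     | >= 2.2     | >= 6.0           | AND  |
| exp2    | 19-21     | >= 4.0     | >= 10.0          | AND  |

Candidates below the lowest tier are rejected.  Tier tables are validated
for non-overlapping tag ranges and can be supplied as TSV.  Survivors become
AID-dependent sites; each called 500-bp window is extended 1000 bp from its
center (clamped, never shifted, at chromosome edges) for all downstream
analyses, reflecting that Nbs1 binds within ~1 kb of a break.

"Tag count" in the tiers means the raw (duplicate-capped, unnormalized) WT
count in the called window; whether the original scheme used normalized
counts is not recoverable, and raw counts keep the tiers interpretable.

### AID-independent sites

The same windowed caller runs on the WT library with no control in the
enrichment test: candidates need `wt_tags >= 10` and local background
ratio >= 4.0.  Intervals whose library-normalized WT:control tag ratio
exceeds 1.4 are then removed, leaving sites with matched signal in both
libraries — breaks that do not depend on AID.

### Strand classification

Per-strand WT tag counts are taken over the extended 2-kb interval (the
called window is selectable).  The one-ended rule is `|log2(plus/minus)| >
1.5`, i.e. a 2^1.5 ~ 2.83-fold imbalance; the commonly quoted "2.8-fold" is
treated as a rounding of the exact log2 form, and a boundary case (28:10)
is deliberately *not* one-ended.  If one strand has zero tags the site is
one-ended only when the other holds >= 10 tags (an invented guard; with
fewer tags the evidence is too thin), and a site with no tags at all is
indeterminate rather than an error.

Orientation (break-like vs transcription-factor-like) is diagnosed for
sites not flagged one-ended, from the per-strand **median** 5' position:
`tf_like` iff `median(minus) - median(plus) >= fragment_length / 2`, else
`dsb_like`; either strand under 5 tags gives `indeterminate`.  The median
was chosen over the mean because at a true break the mean is dominated by
the diffuse sonicated-end cloud (whose geometry is exactly the TF pattern)
and flips sign even at modest sonicated-end fractions, while the median
tracks the sharp break pile as long as break-end reads are the majority; it
is also exactly equivariant under reverse-complement mirroring of the
experiment, which the modal-bin alternative (selectable as
`statistic="peak"`) is not because of argmax tie-breaking.  A literal
mean-centroid rule with a +-20 bp indeterminate band is selectable as
`statistic="mean"` but cannot recognize the canonical sharp break (centroid
gap ~1 bp) as break-like.

### Tandem repeats and the WGCW hotspot motif

Two repeat families matter: tandem pentamers dense in the AID hotspot WGCW
(W = A/T; the motif is self-complementary, so a hotspot on one strand is a
hotspot on the other — the precondition for nearby opposite-strand nicks
forming a DSB), and long CA dinucleotide arrays capable of adopting Z-DNA.

The detector scores position `i` as +2 when `seq[i] == seq[i-p]` and -7
otherwise (N always mismatches) for each period `p` in 1..12, and extracts
maximal-scoring disjoint segments above the minimum score by recursive
Kadane-style splitting (ties: smallest end, then shortest segment); a
segment spanning scored positions implies a repeat region
`[segment_start - p, segment_end)`, kept when at least two periods long.
Overlaps across periods resolve to the highest score, ties to the smallest
period (so a CA array is reported at period 2, not 4).  This indel-free
scoring replaces a full wraparound alignment: the repeats of interest here
are near-pure microsatellites where indel states add nothing, and the
match/mismatch weights mirror the conventional 2/7 parameterization.
Periods above 12 and probabilistic match/indel criteria are out of scope.
Equivalence with an exhaustive brute-force enumeration is asserted over
1,000 random short sequences in the test suite.

Classification: a repeat whose region is >= 90% CA/AC/TG/GT dinucleotide
steps is class CA; otherwise >= 2.0 WGCW motifs per 100 bp makes it WGCW;
otherwise OTHER.  CA precedes WGCW so no repeat carries both labels.  The
"core motif" CA content is measured on the realized region (step fraction)
rather than the consensus, which is robust to point mutations inside long
arrays; a consensus-based alternative would differ only for heavily mutated
arrays.

Per-site summaries run two passes over the extended interval: a strict pass
(min score 100) supplies WGCW-class and OTHER totals, a permissive pass
(min score 60) supplies CA totals — matching the two published
parameterizations.  A site "has" WGCW repeats when their summed length is
>= 400 bp and CA repeats at >= 100 bp; the sum (rather than the single
longest tract) is used because closely spaced tracts separated by a few
mutations are one biological array.  Genome background draws random
intervals matched to the site set's length and chromosome distribution
(resampling templates with replacement, uniform starts, re-drawing
templates longer than their chromosome) and summarizes them identically.

### Interval statistics

Interval merging coalesces >= 1 bp overlaps (touching intervals stay
separate; a slop parameter is available) and records per-source provenance;
reproducible sites are merged intervals supported by both experiments'
extended site sets.  Intersection counting asks how many query intervals
touch >= 1 target interval, each query counted once.  Significance comes
from redrawing the target set (query selectable) with each interval's
length and chromosome preserved and starts uniform, 1000 trials by default;
`p = (1 + #{null >= observed}) / (trials + 1)` so p is never 0 and the
smallest reportable value with 1000 trials is ~0.001.  Calibration: with
independently placed query and target sets the p-value distribution is
approximately Uniform(0,1) (KS < 0.12 over 200 repetitions) provided the
overlap counts are large enough to be quasi-continuous; with very sparse
sets the discrete, +1-corrected p is conservative (piles toward 1), which
is the safe direction.

## The synthetic-data generator

The generator emulates the study's structure with known truth; its defaults
are the package's study conditions:

| parameter | default | rationale |
|-----------|---------|-----------|
| genome | 3 chromosomes x 5 Mb, GC 0.42 | mouse-like GC; large enough for ~140 well-separated sites |
| planted sites | 100 two-ended + 10 one-ended AID-dependent, 20 AID-independent, 10 TF-pattern | mirrors the catalog structure: hundreds of AID-dependent sites, ~10% one-ended, a smaller AID-independent set; TF sites exercise the orientation control |
| site reads (lambda) | 30 WT reads/site | clears the exp1 tiers with Poisson headroom while leaving the tier filter binding |
| background | 0.002 tags/bp (WT) | ~30k background tags vs ~4k site tags: realistic signal:noise for a shallow ChIP |
| control depth | 3x WT | the two libraries differed ~3x in depth; exercises library-size normalization |
| fragment length | Normal(200, 50), min = read length | typical sonication profile |
| read length | 36 | single-end short reads |
| break-pile jitter | SD 5 bp | end-processing heterogeneity; invented, configurable |
| sonicated-end read fraction | 0.1 | break-end reads dominate observed libraries (one-ended sites show essentially one strand); 0.1 keeps that dominance while retaining the sonicated-end cloud |
| site separation | >= 5 kb | keeps extended intervals disjoint |

WGCW pentamer arrays (CAGCA x 90 = 450 bp, 2% per-base point mutations) are
planted at 40% of two-ended AID-dependent sites and CA arrays (CA x 160 =
320 bp) at a further 25%, with short CA arrays at two AID-independent sites
and 20 standalone arrays at unoccupied positions — echoing the observed
repeat enrichment at AID-dependent sites over background.  Reads are
emitted directly as aligned 5'-end positions: alignment is upstream of the
pipeline, so no sequencing-error or mappability model is applied.
Background reads are single reads from a random end of a uniformly placed
sonication fragment.  AID-independent sites emit into both libraries with
the control's site rate scaled by the control depth factor, so their
library-normalized enrichment ratio is ~1 as required for the 1.4 ratio
filter to retain them.  Everything is a deterministic function of
(config, seed); child generator streams are derived per stage so genome and
reads can be regenerated independently.

What the generator does **not** model — and hence what passing tests do not
show about real data: mappability gaps and blacklist artifacts, copy-number
variation, chromatin-accessibility bias in the pulldown, PCR-duplicate
structure beyond position identity, broad multi-break domains that blur the
orientation signature, and any sequence dependence of break placement
(sites are planted independently of the planted repeats' sequence, except
where co-located by construction).  Recovery/precision figures on this
generator are an internal-consistency check of the pipeline, not an
estimate of sensitivity on real libraries.

## Recovery scoring

A called site matches a planted site when their centers are within 500 bp
(the called half-window); matching is one-to-one, greedy by distance.
Precision is reported over all calls (1.0 with an explicit flag when there
are no calls), recall per planted type, optionally restricted to sites
with expected reads above a floor.  Classifier accuracy is scored among
matched sites: the one-ended flag against planted one-endedness, and
orientation among sites that entered orientation diagnosis (not flagged
one-ended) — a spurious one-ended flag is one error, charged to the
strand-bias classifier, not two.

## Problem sizes used by the shipped analyses

The acceptance script and test suite run the default simulation above
(~34k WT / ~92k control tags, 140 planted sites), 2,000 matched background
intervals (10,000 remains the library default for standalone use), and
1000-trial permutation tests.  These sizes were chosen so the whole
analysis replays in well under a minute while every reported fraction has
enough support to be stable across seeds.

## Known limitations

* The caller's greedy spacing rule approximates, not reproduces, the
  reference peak caller's internal spacing/normalization logic; fold
  enrichment uses shifted 5'-end counts rather than fragment-extended
  coverage (the published description does not disambiguate).
* The repeat finder has no indel states; a microsatellite with frequent
  indels will fragment into multiple tracts (the per-site summed-length
  thresholds partly compensate).
* The permutation test randomizes interval placement uniformly per
  chromosome; it does not condition on mappability or gap structure.
* One-ended detection at the |log2| > 1.5 boundary is subject to binomial
  strand-split noise at moderate coverage: at lambda = 30, roughly 0.5% of
  genuinely two-ended sites cross the threshold by chance.
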