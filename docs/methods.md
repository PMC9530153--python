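# Methods

## The segment model

A SCRaMbLE-competent chromosome is represented by its loxPsym partition:
an ordered list of segments (the intervals between consecutive sites), each
carrying an `essential` and a `centromere` flag. The site sequence defaults
to the canonical 34 bp symmetric loxPsym
(`ATAACTTCGTATAATGTACATTATACGAAGTTAT`); any sequence may be substituted but
it must equal its own reverse complement — the palindromy is what makes
recombination orientation-free and what lets the caller treat a read and
its reverse complement as the same junction observation. Coordinates are
0-based half-open; BED is the on-disk dialect. Circular chromosomes are
stored rotated so that site 1 begins at coordinate 0, which keeps every
segment interval wrap-free. Subtelomeric terminal segments of a linear
chromosome, which lack a distal site, are modelled as ordinary segments
whose outer ends simply never participate in junctions.

## Recombination simulator

A strain's history is a sequence of events applied to the evolving signed
segment list. An event picks two distinct inter-segment boundaries (every
boundary carries an intact loxPsym site — Cre-lox recombination regenerates
sites, so earlier events never consume recombination substrate) and one of:

* **deletion** — the block between the loci is excised (on a ring, the
  chosen arc; the complementary arc survives);
* **inversion** — the block is reversed and every sign flipped;
* **duplication** — the block is tandem-duplicated in place, same
  orientation. Whether real duplications arise intra- or inter-chromatid is
  not observable from short reads; the tandem model is the simplest one
  producing the detected signature (a head-to-tail novel junction plus a
  copy ≥ 2 run) and is an explicit simplification.

Viability is enforced after every single event, modelling death during
induction (an end-state-only mode exists behind
`SimConfig.viability_each_event=False`). Haploids die when any
essential-flagged segment reaches copy 0 or the centromere copy leaves 1;
heterozygous diploids — a rearranged synthetic chromosome over a
loxPsym-free native homolog — are constrained only by the centromere.

Within one event the type is drawn once from `type_probs` and *held* while
locus pairs are resampled against the viability filter (up to
`max_resample`, default 200); the other types are tried only if the drawn
type admits no viable pair at all. Held-type resampling means rejection
reshapes *where* events land, not the realized type frequencies — with
equal type probabilities a diploid cohort's deletion:inversion balance stays
at 1:1, while haploid deletions are funnelled onto non-essential blocks.

Event records log the type, the reference-site loci adjacent to the block's
inner flanks (the only sequence evidence a split-read caller can see), the
reference segments of the block, and the structure-coordinate loci, so a
history can be replayed exactly.

When a contact matrix is supplied, locus pairs are drawn with probability
proportional to the matrix entry of the bins containing the two loci (a
locus inherits the genomic bin of the reference site adjacent to its
left-hand flank — the best observable proxy once the structure has been
rearranged).

## Diploid genomes

The native homolog is the reference with the engineered loxPsym insertions
absent, carrying random substitutions at `snp_density` (default 0.01/bp —
the divergence between a synthetic chromosome and its wild-type counterpart
is dominated by PCRTags and recoding, well above natural polymorphism; the
accepted range is (0, 0.05]). Substitutions are excluded from 40 bp windows
around the site-removal points so flank matching stays exact. A density of
0 is rejected: indistinguishable homologs cannot be depth-resolved.

## Read factory

Defaults model the genotyping runs of SCRaMbLE screens: 100 bp paired-end
reads from normal(300, 30) inserts truncated to [read length, 600] bp
(a 200–400 bp library), uniform fragment starts (rings are sampled across
the origin), substitution errors at `error_rate` (default 0.001/bp) with
the erroneous base's quality lowered. `mean_depth` is per genome copy, so a
diploid locus sequenced at `mean_depth=60` sees ~120× total. The QC rule
drops a read pair when either mate has more than `max_bad_fraction`
(default 0.05, *strictly* greater — a 100 bp read with exactly 5 offending
bases survives) of bases that are N **or** below Phred 10; the two
conditions are pooled into one count, configurable separately.

## Junction calling

1. **Candidate selection.** A read is a split-read candidate when it
   contains the site (≤ 1 mismatch, exact match tried first) with at least
   `min_flank` = 15 bp on *both* sides — the trisection needs two mappable
   flanks, so single-flank salvage is deliberately out of scope — and does
   not place end-to-end (≤ 3 mismatches) on the reference or, for diploids,
   the native homolog. Placement uses a built-in exact-k-mer seed-and-vote
   mapper (31-mers at four offsets, unique best with ≥ 1 mismatch margin);
   circular references are extended 99 bp past the origin so origin-spanning
   reads still place, with the extension kept below the read length so
   placements stay unique. A SAM ingestion path accepts external aligners
   for real data.
2. **Parental evidence.** Site-containing reads that *do* map end-to-end
   and cover a site with both flank margins attest that the reference
   adjacency across that site is retained; they are counted toward the
   parental junction of the spanned site. Split-read search alone can only reveal novel junctions, but the
   reconstruction it feeds needs retained parental junctions identified
   too; spanning-read counting is the natural complement and uses the same
   support threshold.
3. **Trisection and assignment.** Each flank (up to `flank_index_len` =
   30 bp) is compared against the per-segment-end flank library; a hit must
   be within `max_mismatch_per_flank` = 1 and beat the runner-up by ≥ 1
   mismatch, otherwise the observation is discarded as ambiguous (counted
   per reason). Palindromic canonicalization makes a read and its reverse
   complement yield the same unordered segment-end pair.
4. **Support.** Junctions are supported by distinct read *pairs* (mates
   collapse); junctions below `min_support` = 5 pairs are dropped. Mate
   placement is recorded but not used for rescue.

## Copy number and reconstruction

Per-segment depth is the mean per-base coverage over the segment's
reference interval (loxPsym intervals lie outside all segments). For
diploids, a read is assigned to the homolog it matches with strictly fewer
mismatches; ties — reads covering no distinguishing substitution — count
half a read toward the synthetic chromosome, so an unrearranged synthetic
segment reports about half the total locus depth and integer ratios are
preserved to within rounding for copies ≤ 3.

The per-copy **baseline** is anchored on the centromeric segment, whose
copy number the viability rule pins at exactly 1, and refined as the median
of segments that are (i) not named by any novel junction, (ii) within
[0.66, 1.5]× the anchor, and (iii) not terminal segments of a linear
chromosome — the fragment-start coverage ramp depresses terminal means by
~10%. A plain "median of novel-free segments" baseline collapses when most
novel-free segments are deleted, and under the diploid half-read floor
(deleted synthetic segments still show ~0.2 units of ambiguous coverage);
the anchor is immune to both. Copies are the nearest integer
(ties-to-even); depths further than `mosaic_tol` = 0.3 from an integer
multiple are flagged mosaic (possible mixed colony) rather than forced.

**Reconstruction** enumerates chromosome walks that traverse each segment
exactly its copy number of times, cross only observed junctions, use every
observed junction at least once, and — for linear chromosomes — start and
end at the telomeric segments (which site-pair recombination cannot
detach). Enumeration is depth-first with deterministic tie-breaks (smallest
segment id, `+` orientation first), capped at 16 structures and 500 000
search steps; circular walks are reported in canonical rotation/reflection.
Status is `unique`, `ambiguous` (all candidates enumerated, none guessed)
or `inconsistent` (with the unconnected segment ends as diagnostics).

**Event classification is walk-invariant.** Several walks can traverse the
same junction multiset with the same copy numbers (e.g. an inverted tandem
duplication), and no read-level evidence distinguishes them, so events are
typed from the signature that all walks share — the novel-junction set plus
the copy-number vector. Deletion = maximal run of copy-0 reference
segments; duplication = maximal run of copy ≥ 2; inversion = block bounded
by its two tell-tale novel junctions {(i−1)R, jR} and {iL, (j+1)L}; novel
junctions explained by none of these are emitted as `complex` events, never
silently dropped. A ground-truth structure and a correct reconstruction
therefore always classify identically. One "event" is one contiguous
signature run: overlapping simulated events merge into a single maximal-run
event, which is the convention used consistently in every cohort statistic.
Circular structures compare up to rotation and reflection; for reporting,
a ring is orientation-normalized to the representative with fewer inverted
segments (a ring has no intrinsic strand).

**Retention rate** is 100 × (base pairs of segments with copy ≥ 1) / (total
segment base pairs), reported to two decimals; loxPsym sites themselves are
excluded from both numerator and denominator.

## Cohort statistics

Occurrence rate = 100 × (strains with ≥ 1 event) / strains, with the
denominator defined as all strains entering analysis. "Events per strain"
is reported over SCRaMbLEd strains only (the whole-cohort mean is also
derivable). The per-site landscape increments every site among an event's
loci. Type proportions are reported two ways: per event, and per rearranged
segment (the pie-chart convention), which weights multi-segment deletions
by their extent.

## Contact analysis

Synthetic matrices follow `M[i,j] ∝ max(d,1)^α` with α < 0 (default −1),
`d = |i−j|` on a line and `min(|i−j|, n−|i−j|)` on a ring, optional
multiplicative lognormal noise (symmetrized by the geometric mean), and
normalization to a fixed total. Hi-C matrix balancing itself is not
reimplemented; matrices are consumed already normalized.

The moving-average correlation annotates every between-bin pair with its
event count and contact value, drops pairs with zero events or zero
contacts (the alternative both-zero reading is available behind
`drop="both_zero"`), sorts ascending by contact, averages windows of 10
advanced by 3, and reports Pearson's r plus the least-squares line on the
averaged points. Two deliberate statistical choices:

* **Within-bin (diagonal) pairs are excluded by default.** The number of
  available locus pairs inside one bin scales as C(k,2) versus k·k′
  between bins, which couples raw event counts to the contact-decay
  singularity and produces strong spurious correlations even for
  conformation-blind recombination.
* **The p-value uses an effective sample size.** Consecutive window means
  share 7 of 10 points; the naive Pearson p on the smoothed series is
  anticonservative (~27% false positives on a multinomial null). The
  two-sided p is computed from r with degrees of freedom based on the
  number of *non-overlapping* windows, which calibrates the null while
  leaving genuinely coupled cohorts overwhelmingly significant.

One caveat the correlation tests respect: deletion lethality across the
centromere restricts deletion loci to short genomic ranges — a *real*
distance structure that correlates with any distance-decay map. The
conformation-independence control therefore uses inversion-only cohorts,
whose locus pairs are genuinely unconstrained.

ROI bait profiles average normalized contacts between the bait bins (two
30 kb subtelomeric windows by default) and every other bin; the event
counterpart counts events joining the ROI to each bin.

## Pipeline and reproducibility

A design is a list of groups (ploidy, topology, Cre-variant and dose labels
mapped to a Poisson event-rate parameter — the dose→enzyme→frequency chain
is wet-lab biology outside this package's scope, exposed as a monotone
knob) with inductions × colonies replication. Per-strain seeds are the
first four bytes of `sha256("{master_seed}:{group}:{induction}:{colony}")`
mod 2³¹, with deterministic collision bumping — stated so other
implementations can reproduce manifests. All TSV outputs are byte-identical
across reruns of the same config and master seed.

## Problem sizes

The test and acceptance workloads run on deliberately small instances
chosen to keep the per-segment event density in the regime of real
SCRaMbLEd chromosomes (hundreds of segments sharing a handful of events):
a 12-segment ~20 kb chromosome for caller-vs-oracle exactness (20 strains,
error-free, 100×), a 24-segment ~30 kb chromosome for event recovery
(200 strains, ≤ 10 events, 100×, error 0.001), simulation-only cohorts of
450–1200 strains for the ploidy contrast, and a 40-segment ~112 kb
chromosome (12 bins at 10 kb) for the contact correlation.

## What the simulator does and does not emulate

Emulated: segment-resolution Cre/loxPsym recombination with per-event
viability, haploid vs heterozygous-diploid tolerance, site regeneration,
contact-biased locus choice, paired-end sequencing with substitution errors
and quality-based QC, ring topology including origin-spanning fragments,
and distance-decay contact maps.

Not emulated — so passing tests say nothing about these: platform-specific
error profiles (indels, quality ramps, duplicates), repeat-induced mapping
ambiguity of real genomes (random sequence is effectively repeat-free, so
flank assignment is easier than on real DNA), inter-chromosomal events
(none were observed in multi-synthetic cohorts; the model is
single-chromosome per run), mechanistic Cre kinetics and induction
dynamics, mixed-colony mosaicism (flagged but not simulated), and real Hi-C
normalization artifacts. Reconstruction assumes rearrangements respect
loxPsym boundaries; breakpoints inside segments are out of scope.
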