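# Methods

`miniolc` is a desk-scale hierarchical overlap–layout–consensus assembler
for noisy long reads (PacBio/Nanopore-like, roughly 70–95% per-base
identity). The pipeline has three independently runnable stages —
correction, trimming, assembly — each of which begins by recomputing
all-vs-all overlaps for its own inputs. This note documents the model
behind each stage, the tunable parameters and their defaults, the
synthetic-data generator that defines the test conditions, and the
numerical and design choices made where the design was genuinely open.

## Overlap detection

Overlapping is a two-stage filter.

**Stage one: weighted MinHash.** Every read is summarized by a sketch of
`sketch_size` slots (default 512 for raw reads). Slot *i* of a read's
sketch holds the base hash of the k-mer (default k = 16, strand-canonical)
that minimizes a deterministic per-slot hash; a k-mer with integer weight
*w* receives *w* draws per slot, so heavier k-mers are more likely to be
selected. Weights follow tf–idf:

    w_q   = tf_q · idf_q            (capped at idf_max · tf_cap = 12)
    idf_q = T( log(f_max / f_q − a) )

where `tf_q` is the k-mer's count in the read, `f_q` its global count,
`f_max` the maximum global count, `a = 0.9` controls how strongly rare
k-mers are preferred, and `T` linearly rescales onto `[1, idf_max]`
(default idf_max = 3) with round-half-up. Only the most abundant fraction
of distinct k-mers is recorded in the spectrum; unrecorded k-mers take
`idf_max`. The classic recording cutoff of 5 × 10⁻⁶ presumes corpora with
billions of distinct k-mers; at desk-scale corpus sizes (10⁵–10⁶ distinct
k-mers) that records almost nothing and the weighting degenerates to
uniform, so the pipeline default is 0.02 — the same mechanism with the
fraction scaled to the corpus. The upper endpoint of `T` plugs in the
count at the recording cutoff (`cutoff_interpretation="count"`; a
"fraction" interpretation is available behind the same flag).

Down-weighting abundant k-mers flattens the frequency distribution of
sketched k-mers (measurably lower Gini coefficient on repeat-heavy
genomes) without the all-or-nothing loss of a fixed count filter: a
multi-copy replicon at several times chromosome depth keeps ≥ 85%
candidate sensitivity under tf–idf where a chromosome-calibrated count
cutoff discards most of its k-mers.

Two reads become a candidate pair when ≥ `min_slot_matches` slots agree
(default 2). Under the null of unrelated reads the expected number of
falsely matching slots is far below one (64-bit hashes; shared k-mers
between unrelated desk-scale reads are rare), so the threshold is set by
sensitivity at high error rather than specificity: at 10% per-read error,
two overlapping 3 kb reads share 16-mers at rate ≈ 0.81¹⁶ ≈ 0.034,
giving only a handful of expected slot matches for partial overlaps.

**Stage two: bottom sketch.** Each read also gets a bottom sketch — the
`bottom_size` (default 1500) smallest canonical k-mer hashes under a
single hash function, each with its first position in the read. For a
candidate pair the merged bottom sketch gives a Jaccard estimate *j*,
converted to an error rate by the Mash distance
`d = −ln(2j/(1+j))/k`, with `d = 1` at `j = 0`. Relative orientation is
the sign of the position trend of shared min-mers (canonical k-mers make
sketches strand-oblivious, so orientation cannot come from stage one);
the overlap extent is the maximal diagonal through the median position
offset, and *j* is re-estimated from min-mers inside that extent.

**Gapped confirmation.** Stages that need precise coordinates and exact
error rates (correction scoring, trimming, error adjustment, graph
construction) confirm candidates with a bit-parallel edit-distance
alignment (edlib) along the estimated diagonal. Terminal windows (200
columns, stride 50) whose error exceeds `0.08 + 1.5·(expected error)`
(capped at 0.45) are clipped: a true overlap that ends inside both reads
— at a repeat boundary or a chimeric junction — degrades to
random-sequence identity (~0.5 error/column) beyond its end, and the
threshold must sit between the genuine pairwise error and that flank.
Overlaps are then classified `containment` (one read fully aligned),
`dovetail` (both alignment ends at read ends), or `partial` (an end
interior to both reads — the branching signal used for repeat
annotation). Dovetail end tolerance is `max(100 bp, 3%)` of the shorter
read.

## Overlap store

Overlaps are kept in an indexed store listing all overlaps of each read
contiguously, each overlap present twice (A→B and B→A). The build is a
bucket sort: reads are partitioned into ranges balanced by overlap count
under a bucket-size cap, buckets sort independently on
`(read, partner, start)`, and concatenation plus a read→(offset, count)
index gives the final store. The result is byte-identical for any bucket
count, so the parallel and sequential paths agree by construction.

## Correction

Evidence selection is a two-filter scheme with C = expected read depth
(derived as total read bases / configured genome size unless set):

* **global filter** — each read donates evidence to at most C partners,
  its top overlaps by score;
* **local filter** — each target accepts at most 2C donated overlaps.

The classic score is `overlap_length × identity`. At desk-scale read
lengths (~3 kb) that product is dominated by length: the identity gap
between same-copy and cross-copy overlaps of a few-percent-diverged
repeat (~2 points) is smaller than the length spread, and measured
same-copy evidence purity collapses to ~54%, which erases copy-specific
variants during consensus. The pipeline therefore ranks donations by
confirmed error rate first with length as tie-break
(`cor_score="error"`, measured purity ~0.96 at 3% divergence); the
classic score remains available (`cor_score="length_identity"`). For the
same reason correction scores use gapped-alignment-confirmed error rates
rather than sketch estimates — the sketch estimator's spread (1.5–2
points) is as large as the gap it must resolve. The confirmation costs
~0.3 ms per candidate pair at these sizes.

Corrected length per read is estimated as the bases covered by ≥ 2
accepted evidence intervals; the longest reads up to `cor_out_coverage`
(default 40×) are corrected. Each read is rebuilt by consensus over an
alignment DAG: evidence reads (clipped to their overlap region, oriented)
are aligned to the read and vote per column for a base or a gap, and for
insertion slots between columns; the read itself contributes weight 1.
The highest-weight path is emitted; wherever every parallel edge has
weight < 4 the output splits, and pieces < 500 bp are dropped. Corrected
pieces are named `origId_p<i>_<startOffset>` so provenance survives
splitting. Multiple correction rounds can be chained (`cor_rounds`); each
round re-overlaps its input. With the default k = 16 the overlapper needs
roughly ≤ 20% per-read error to find overlaps at all (pairwise shared
16-mer rate falls off as identity¹⁶), which bounds the error regime the
iterative mode can start from.

## Trimming

Corrected reads are re-overlapped with gapped alignments and each read is
trimmed to the largest interval covered to depth ≥ C = 2 by overlaps with
error ≤ E = 4.5% and length ≥ L = 500 bp (defaults; the numbers are
technology-dependent choices, not published constants). Two artifact
detectors run on the trimmed range:

* **hairpin adapters** — ≥ 5 partners overlap the read in both
  orientations around a common pivot and ≤ 2 overlaps span it; the read
  keeps the larger side of the pivot;
* **chimeric junctions** — interior positions spanned
  (covering pos ± 100 bp) by ≤ 1 overlap; the read keeps the largest
  supported region.

On injected chimeras at ~30× the detector reaches ≥ 90% sensitivity with
≤ 2% false splits of clean reads.

## Overlap error adjustment

A two-pass majority vote separates residual sequencing error from true
sequence difference. Pass one aligns every partner to each read and
proposes an edit where the read's symbol disagrees with a strict majority
of covering partners *and* fewer than 25% agree with the read (columns
below depth 3 are never edited; indel columns vote with gap symbols, and
single-base insertion edits are proposed when a majority of partners
carry the base). A balanced column — a diverged repeat copy or
heterozygous site, where the read's own copy supports it — is preserved.
Pass two applies both reads' edits to temporary copies of each overlap's
substrings, realigns, and replaces the stored error rate; read sequences
and overlap intervals are never rewritten. On a mixture of same-copy and
3%-diverged-copy overlaps at 2% read error this turns overlapping error
distributions into separated modes near 0 and near the true divergence.

## Graph construction

All adjusted overlaps feed a best-overlap-graph: per read end (5′, 3′)
only the longest qualifying dovetail overlap is kept. The error cutoff is
estimated from the data: an initial best-edge set gives the median and
MAD of best-edge error rates, and the cutoff is `median + 6·MAD`
(`mad_multiplier`), floored at 0.5% (`error_floor`) when the distribution
degenerates. Before the final pick, suspicious reads are excluded:
contained reads; chimeric suspects not fully covered by sub-cutoff
overlaps; and nonmutual suspects whose best edge's reciprocal best
differs in implied overlap length by > 500 bp.

Initial contigs are maximal mutual-best chains walked in both directions;
offsets accumulate from overlap hangs, orientation propagates through
flipped overlaps, and a chain closing on its seed marks a circular
contig. Each contig gets an error profile: per 1 kb window, the median
and MAD of the errors of overlaps projected into it (empty windows
inherit neighbors). Contained and filtered reads are then placed at their
lowest-mean-error candidate placement, rejected where that error exceeds
the local `window median + 5·MAD` (floored at `error_floor`) — which is
what keeps diverged repeat copies and haplotype variants out of the wrong
contig. Small contigs (< 3 reads) or contigs with > 75% of reads
overlapping another contig are re-placed read-by-read: fully absorbed
ones disappear, unplaceable ones are labeled `bubble`.

**Repeat annotation and splitting.** Conflicting evidence marks candidate
repeat regions: qualifying `partial` overlaps from reads outside the
contig (the read matches the region but branches away), and overlaps
between layout reads whose implied relative placement contradicts the
layout by > 1 kb (collapsed identical copies). Merged conflict regions
are confirmed — left intact — when a layout read spans them, or when the
best internal joining overlap has error lower than the best conflicting
overlap by ≥ 3 local MADs. Otherwise the contig splits into left flank,
repeat-labeled middle, and right flank. This is the mechanism behind the
headline property: with no reads spanning an 8 kb two-copy repeat, copies
at ≥ 3% divergence assemble into their correct flanking contigs (the
automatically estimated cutoff excludes cross-copy overlaps), while at
low divergence the collapsed region is honestly split out as a repeat.

## Consensus

A template is spliced from backbone layout reads (each contributes its
non-redundant extension); every layout read is then realigned to its
template region and merged into the same alignment DAG used for
correction, with min weight 1 and ties broken toward the template. Two
passes are run: indel placement wobbles against a noisy template and
splits votes across adjacent columns, and a second pass against the
round-one consensus aligns consistently. Terminal columns supported only
by the template (trailing read noise at contig ends) are dropped.
Consensus evidence uses temporary copies of the reads with the
error-adjustment edits applied — residual errors on corrected reads are
correlated because reads share correction evidence, so the per-read vote
across all overlap partners removes error that column voting at
consensus time cannot; the stored reads and overlaps are never
rewritten. At
≥ 20× evidence of ~1%-error reads the consensus reaches ≥ 99.9% identity
and length within 0.5% of truth.

## Synthetic data

The generator defines the study conditions for every test:

* **genomes** — i.i.d. uniform ACGT; repeat families planted from one
  random unit consensus, each copy mutated independently at rate d/2 so
  the *pairwise* copy divergence is d. Divergence is substitutions-only,
  making "3% divergence" unambiguous against identity-fraction
  thresholds. Placements must not overlap; truth records exact
  coordinates and per-copy mutation lists. Circular genomes are handled
  by virtual concatenation at sampling time.
* **reads** — log-normal lengths (default μ = 8.0, σ = 0.4 in ln-bp,
  ≈ 3 kb mean, truncated to [1000, 6000]), uniform position, both
  strands, coverage-targeted; per-base errors at `error_rate` split
  evenly between substitution, insertion and deletion (an intentionally
  neutral default — the generator exposes the mix, and no
  instrument-specific profile is claimed). Truth stores each read's
  exact source interval and strand.
* **spanning-read exclusion** — for repeat experiments, any read whose
  source interval contains a repeat copy is removed, so separation must
  come from error statistics, not spanning.

What the generator does **not** emulate: homopolymer-biased and otherwise
sequence-dependent errors, chimeric/adapter artifacts occurring naturally
(tests inject them explicitly), quality values, non-uniform coverage
(GC bias), and heterozygosity. Passing tests therefore demonstrate the
statistical machinery (filters, cutoffs, vote rules, graph decisions)
under the stated error model, not robustness to instrument-specific
artifacts.

Coordinates are 0-based, half-open, forward-strand everywhere; the base
hash is a splitmix64-style 64-bit finalizer with a fixed seed so k-mers
index identically across reads and stages, and per-slot draws derive
deterministically from (base hash, slot salt, draw index) — identical
seeds give identical outputs on any platform.

## Problem sizes

The test suite and the reproduction script run at desk scale, chosen so a
full repeat-separation sweep and the structural checks complete on one
CPU in minutes: repeat experiments use a 60 kb genome with a two-copy
8 kb repeat (flanks ≥ 2× the maximum read length, so resolution cannot
come from spanning), 30× coverage, 10% read error; structural-correctness
checks use 40 kb repeat-free genomes at 30× and 12% error across several
seeds; estimator checks use constructed k-mer sets and read pairs at 2,
5 and 10% divergence. The divergence sweep ascends from 0% and reports
the first resolved step as the minimum.

## Known limitations

* The first-stage filter with k = 16 loses sensitivity above ~20%
  per-read error; assembling noisier reads needs smaller k and larger
  sketches than the defaults.
* Contig ends lose roughly half a read length of sequence: end coverage
  ramps down and trimming requires depth 2.
* Haplotype phasing is out of scope; diverged alternate loci are kept as
  labeled bubbles, not phased.
* The per-slot weighted MinHash loop is the runtime hot spot of stage
  one; it is compiled (numba) but still linear in s × L × w.
* `place_contained_reads` positions reads by clustering implied offsets;
  placements are accurate to ~±100 bp, adequate for layout and consensus
  but not a substitute for per-read realignment.
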