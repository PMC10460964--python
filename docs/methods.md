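# Methods

`tagedit` models what happens when a single guide RNA cuts every member of
a tandemly arrayed gene (TAG) family at once, and how the resulting repair
outcomes — small indels, local deletions, genomic dropouts with fusion
alleles, inversions, translocations, and templated-insert fusions — can be
decoded from amplicon deep sequencing, PCR banding, and target-capture
short-read data. Everything runs on synthetic data with ground truth; this
note records the model, the parameters that matter, and the design choices
made where the design was genuinely open.

## Coordinate and strand conventions

A tandem array lives on a left-to-right *axis* (a contig) in 0-based,
half-open coordinates. Paralogs are placed on the **minus strand** of the
axis by default. Under that convention a deletion between the Cas9 cuts of
gene *i* (left on the axis) and gene *j* (right) joins the 5' portion of
*j* to the 3' portion of *i*, so the fusion is named `j-i` — the naming
used for fusion alleles in tandem-array editing work, where a high-index
partner's 5' side recombines with a low-index partner's 3' side and the
intervening copies are lost. Strand is configurable per locus.

Each gene also has *transcription coordinates* (`t`): 0 at the 5' end of
the transcript. Junction sides, cut offsets, and amplicon windows are
reported in `t` so that homologous positions in different paralogs carry
the same number.

Cas9 is modeled as a blunt cut 3 bp PAM-proximal within the spacer
(`cut_offset = 3`); the experimental literature supports this for SpCas9
and nothing in the modeled data distinguishes 3 from, say, 4.

## The forward model

An allele is an `AlleleArchitecture`: an ordered list of oriented source
intervals (segments) plus inline small-indel edits pinned to source
boundaries. Events compose sequentially; breakpoints are given in
source-axis coordinates and translated through the current architecture,
so a breakpoint falling in already-deleted sequence raises a "stale
breakpoint" error rather than silently landing somewhere else. A
breakpoint sitting on an old segment edge (e.g. re-using an inversion
breakpoint) maps to both edges of the moved block; two-breakpoint events
take the widest spanned interval, which makes a repeated inversion an
exact involution.

Event semantics:

* `small_indel` — inline edit at a cut point; |size| ≤ 25 by default.
* `local_deletion` — two breakpoints inside one gene's neighbourhood
  (300–2000 bp in the simulator), one of them the cut.
* `dropout_fusion` — deletes between two cut points and joins the flanks;
  an optional joint indel rides on the junction.
* `inversion` — reverse-complements the enclosed block in place.
* `translocation` — joins the axis prefix (up to the cut) to a position on
  a different contig. This single-junction flank-join is deliberately
  simpler than a reciprocal exchange: it produces exactly the
  interchromosomal read-pair signal the reconstructor consumes, and keeps
  the invariant that every one-event edit creates one junction (two for an
  inversion).
* `templated_insert_fusion` — a dropout whose junction carries a sequence
  block copied from a third locus (capped at 200 bp), modeled as
  junction-level inserted sequence rather than a third segment.

`junction_set` emits one `Junction` per adjacent segment pair that is not
reference-adjacent, classifying each joint as *productive* (transcription
direction preserved across the joint) or *opposing* (antiparallel strands
joined; no contiguous ORF possible). The junction's `net_indel` is the
transcript-length change relative to an exact cut-point fusion; with the
equal-length, colinear paralogs the simulator builds, `net mod 3` plus a
CDS-membership check gives the reading-frame class (`frame_status`).
Microhomology makes the exact joint position ambiguous over the interval
where the two partners are locally identical; joints are reported at the
leftmost-equivalent position, and all downstream logic treats offsets
within that interval as the same joint.

A nested double inversion (between cuts 2–6, then between the moved cut 3
and cut 7) produces five segments and four junctions, of which exactly one
is the productive 5'-g7/3'-g3 fusion (plus one reciprocal 5'-g3/3'-g7
productive joint and two opposing joints). The reversed event order yields
a different junction set without the g7–g3 fusion — event order is
recoverable from end-point data in this case.

## The synthetic data generator

`build_array` derives seven paralogs from one ancestral 2.4 kb gene
(4 exons; guide spacer + NGG in exon 2, cut at t = 917) by seeded random
substitution at 1%/bp, *except* in protected windows: the spacer+PAM, the
short-amplicon primer sites, the multigene (long) PCR primer sites, and
four diagnostic sites. Each paralog receives a unique 2-base diagnostic
code on each side of the cut (t = 870/885 and 950/990), guaranteeing that
every native and fusion amplicon is distinguishable; with divergence set
to 0 the codes are omitted and all targets collapse into one ambiguity
class, which the target enumerator flags rather than resolves. Genes sit
16 kb apart, so the seven-gene span is ~98 kb on a ~108 kb contig —
the scale at which multi-cut dropouts reach tens of kilobases.

Four pseudogene loci emulate the relatives a real tandem array carries:
a 5'-truncated copy downstream on the main contig, two remnants on a
sibling contig (one with a 1 kb internal deletion that keeps the long-PCR
primer sites and yields the ~1 kb loading-control band; one
truncation that serves as the translocation partner), and a full-length
copy on a homoeologous contig whose amplicon primer sites are intact — the
built-in PCR control that distinguishes "no amplification" from reaction
failure. All pseudogenes carry spacer-disrupting substitutions and 6–8%
divergence.

The population simulator draws 1–4 events per line (uniform; reported
mutant complexity reaches about three events per line and no distribution
is published) from a mix of 50% small indels, 20% dropout fusions, 10%
local deletions, 10% inversions, 5% translocations, and 5%
templated-insert fusions. Indel sizes follow the observed spectrum shape:
P(−1) = P(+1) = 0.3 and the remaining mass geometric over 2–25 bp
(deletions with probability 0.6 — larger size classes skew toward
deletions). Events use cut points as breakpoints except local deletions
(one non-cut breakpoint within 2 kb downstream of a cut) and each gene is
used by at most one event, so ground truth is identifiable where physics
allows. The array is hemizygous: one editable haplotype, with the sibling
and homoeologous contigs present unedited in every simulated genome.

Reads are **error-free by default** (a uniform substitution rate is
available): the inference problem here is structural signal in
near-identical paralogs, not base-calling noise, and the exact-match
classifier documents explicitly that reads with errors would simply drop
out under the 0%-mismatch rule. Amplicon products get `depth` identical
PE150 pairs each (products are clonal; products over 400 bp get
depth/20, standing in for short-cycle PCR's length bias). Capture
fragments are Normal(550, 60); a fragment is retained with probability
equal to its best 100 bp probe-window identity to the probe source gene
(gene 7) when that identity clears 0.85, else at the 1% off-target
background rate. The 0.85 threshold and the identity-proportional
retention are free parameters — no capture-efficiency model is published —
and are exposed in the configuration. Consequences: gene bodies are
enriched, the diverged pseudogenes are captured "to a lesser extent",
intergenic sequence is dark, and coverage-based dropout detection is
restricted to gene-body windows.

## Amplicon genotyping

The amplicon spans t[840, 1040) — a 200 bp product with the cut at offset
77 — chosen so that every legitimate product merges from its PE150 pair by
exact overlap (native ±25 bp indels and the +80 bp templated-insert
product at 280 bp all retain ≥ 15 bp overlap). Target enumeration builds
the 7 native + 42 ordered fusion targets (5' of A to A's cut + 3' of B
from B's cut) plus the control locus; self-fusions are excluded
(indistinguishable from native ± indel) and only productive-orientation
fusions are enumerated, since opposing joints cannot amplify with a
convergent pair. Targets with identical sequences merge into ambiguity
classes that propagate to calling — forced tie-breaking of near-identical
paralogs is how a fusion gets mis-called as its native look-alike.

A read matches a target iff it aligns end-to-end with zero substitutions
and at most one contiguous indel (leftmost-equivalent placement, position
reported relative to the cut); best = fewest indels, then smallest |size|;
ties keep all targets. Variants survive calling at ≥ 1% of the line's
reads and ≥ 5 reads — declared defaults, as published thresholds were
manually curated; a wild-type calibration run can override them. Genes
with no surviving reads are NA only if the control locus amplified;
otherwise the whole run is flagged and no NA is called. Population
summaries count a fusion in both partner cells as a linked pair, count
genes lost to its dropout as NA, and tally each fusion allele's net indel
once in the indel spectrum.

## In-silico PCR

Primer sites allow ≤ 2 mismatches with an exact 3'-terminal base: doubly
mismatched primers still make (weak, nonspecific) products while a single
3' mispair kills extension — both behaviours are needed to reproduce
hybrid-primer fusion assays and their nonspecific bands. All four
primer-orientation combinations are considered (single-primer products are
real artefacts); every convergent site pair within 3 kb yields a product.
There is no thermodynamic model: amplification is boolean with a weak
flag. A gene is predicted NA iff no product from the panel covers at least
one of its diagnostic positions, and the control locus must amplify for NA
predictions to stand. On deletion-only populations the NA prediction
equals the truth's "absent" set exactly; a local deletion that removes a
primer site makes a *present* gene NA — that gap between presence and
amplifiability is the point, and is what the reconciliation layer flags.

## Capture analysis

Mapping is a seed-and-extend k-mer mapper (k = 15, both strands) placing
each end at its best exact-extension location with the deterministic
"first best" tie rule (lowest contig, then position). Two consequences of
near-identical paralogs shape everything downstream:

* **Pair rescue.** A read from a conserved window ties across paralogs and
  first-best placement would systematically fake discordance; when the
  first-best pair looks discordant but some tied-best combination is a
  proper pair, the proper combination wins.
* **Tie abstention.** A flank whose best exact match ties between two
  reference placements cannot name its source paralog; segmentation
  abstains rather than guesses.

Coverage is computed in 200 bp windows; dropout calls are maximal runs of
≥ 3 sub-threshold gene-body windows at 10% of a per-line reference depth
(the 90th percentile of gene windows, floored by the median pseudogene
window depth so that a line that lost its whole array still has an
anchor), merged across ≤ 2-window blips. Discordant pairs (FF/RR,
outward, long-insert, interchromosomal) cluster by orientation class and
end proximity with ≥ 3 supporting pairs.

Junction discovery is **read-vote first**: every inexactly mapped end is
segmented against the references by maximal exact-match switching, and a
junction is accepted at ≥ 3 independent read votes. Greedy exact-overlap
assembly of cluster (plus joint-window) reads is the fallback for joints
no single read resolves. Assembled joints must pass validation that read
votes get implicitly: the joint window (microhomology region plus flanks
reaching locus-specific sequence) must be novel against the references and
attested verbatim by a sequenced read — greedy assembly happily chains two
intact paralogs through an identical 40 bp overlap, faking a joint no read
ever saw. Cluster orientation is used as a prior (FF/RR clusters imply
opposing joints), and the cluster's locus hull breaks assignment ties in
near-palindromic joint neighbourhoods.

Three further evidence filters deal with paralog pathology observed during
development: (i) a cross-locus "fusion" whose whole sequence is explained
by one source plus a single small indel is a misread indel — a small indel
in one paralog makes the wrong paralog's reference extend further past it;
(ii) an "insert" copied from immediately beside one of the joint's own
sides is that gene's own continuation, not a templated insert; (iii)
same-locus opposing (foldback) joints are outside the event model and are
always misassignments here. Finally, junctions competing for the same
transcript portion of a locus (head = [0,t), tail = [t,L); an opposing
signature claims both pairs, as an inversion's two joints do) are
mutually exclusive on one haplotype, and the better-supported junction
wins, with read votes outranking assembled contigs.

A templated insert's host joint is visible only through its two edge
views (a 150 bp read cannot span flank + 80 bp insert + flank with
nameable flanks); the two opposing edge joints into the donor locus are
paired, the implied insert-carrying fusion is forward-built, its joint
windows are verified against the reads, and the edge views are then
suppressed as views of the recovered host.

## Reconstruction

Per line, the junction graph collects amplicon fusion calls, capture
junctions (black edges), and unassembled clusters (gray edges, breakpoint
hints only). Candidate events take breakpoints from cut points of evidence
loci plus evidence-implied non-cut offsets (offsets within 110 bp of a cut
— the microhomology drift — are snapped to the cut, with the raw offsets
kept as refinement alternatives). The search enumerates ordered event
sequences up to `d_max = 3` breadth-first, with visited-architecture
deduplication (orderings that reach the same architecture have equal
junction sets and are one scenario), pruning of mismatch-0 states (any
further event adds junctions), and inversion candidates generated only
when opposing or unknown-orientation evidence exists. Scoring is
`|predicted junction-signature set Δ observed| + 0.5 × events`; all
mismatch-0 scenarios are reported as ties, ordered by score, event count,
and disagreement with the evidence joint offsets (so a joint observed
120 bp upstream of a cut is reconstructed there, not at the cut). The
top scenarios get a local refinement pass substituting raw evidence
offsets where that lowers the offset disagreement. When nothing reaches
mismatch 0, the best few scenarios are reported with the orphan
signatures as an "unexplained" record.

Reconciliation takes the best scenario as arbiter and annotates
per-gene disagreements with the amplicon layer: `AMPLICON_BLINDSPOT` when
a fused gene's native amplicon window survives verbatim in the
reconstructed sequence (the joint lies outside the amplicon, so the
classifier calls it native-like), `PRIMER_SITE_LOST` when a gene present
in the scenario is silent on the amplicon, `AMBIGUOUS_PARALOG` when an
ambiguity-class call is not resolved by a mismatch-0 scenario, and
`UNEXPLAINED_JUNCTION` for evidence no scenario covers.

## What passing tests do and do not show

The test suite and the reproduction script run the full loop on 50
simulated lines (200× amplicon, 30× capture, one CPU, a few minutes) and
verify: 100% per-site amplicon accuracy against the truth's
amplicon-visible projection; recall 1.0 for deletions ≥ 2 kb; recovery of
every *identifiable* truth scenario (≤ 3 cut-point structural events whose
junction evidence was not erased by a later event — a dropout whose fusion
junction is itself deleted by a second, larger dropout is unrecoverable
from end-point data by any method) among the mismatch-0 ties; and exact
agreement between simulated read presence and in-silico product
predictions. Because reads are error-free and paralogs carry guaranteed
diagnostic codes, these are statements about the structural logic, not
about robustness to sequencing error, PCR chimerism, polymorphism between
individuals, or reference mis-assembly — real data adds all four, which is
why the thresholds (noise fractions, capture efficiency, binding rules)
are exposed rather than hard-coded.

## Numerical and degenerate-input choices

Deterministic seeding everywhere (`numpy.random.default_rng`); identical
seeds give byte-identical outputs. Ties are never broken silently: tied
read matches keep all targets, tied scenarios are all reported, tied
mapper placements follow the documented first-best rule. Zero-depth
simulations return empty read sets; an empty junction graph returns the
unedited scenario; guide validation rejects non-ACGT spacers; events with
stale breakpoints or colliding inline edits raise typed errors.

## Known limitations

* The segment model is single-molecule: a translocation is a flank join,
  not a reciprocal exchange, and multi-haplotype co-existence of fusion
  alleles is reported as scenario ties rather than asserted.
* Junction offsets are exact only up to microhomology; joints are
  leftmost-placed and compared at signature level.
* Scenario search is capped at three events and evidence-implied
  breakpoints; deeper histories or breakpoints invisible to all three
  assays are out of reach by construction.
* No thermodynamic PCR model, no quality scores, no UMI handling, no
  protein-level consequence prediction beyond reading-frame arithmetic.
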