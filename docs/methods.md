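# Methods

This note documents the models, parameter choices and numerical conventions
behind `piclust`, and what the synthetic validation does and does not show.

## Coordinates and data containers

All in-memory coordinates are 0-based half-open; files follow their format's
convention (GFF3 1-based inclusive, BED half-open).  Annotations are pandas
DataFrames with fixed column sets (`synthio.GENE_COLUMNS`,
`synthio.TE_COLUMNS`); alignments live in `smallrna.AlignmentSet`, which
carries the records, the mapping mode, the miRNA normalization ledger, the
total of genome-mapped reads and the contig lengths.

Deletion intervals printed in genome-browser style (`chr2L:20104769-20243057`)
are stored with the printed endpoints as a half-open interval, so the length
is `end − start`.  Browser conventions differ by ±1 bp on such ranges; all
reporting is at kb scale, where the ambiguity vanishes.

## Read processing and mapping

Reads are collapsed to unique sequences with a copy count (U→T at ingest).
Annotation screening removes any read that aligns within 2 substitutions
(no indels, either orientation) of a supplied ncRNA/miRNA/coding/pseudogene
sequence; reads matching a mature miRNA *exactly* are additionally tallied
into the miRNA ledger, the denominator for cross-sample normalization
(rpm = count × 10⁶ / miRNA-matching reads).  The exact-match tolerance for
the ledger and the 2-mismatch tolerance for removal are deliberately
different: normalization wants an unambiguous miRNA count, filtering wants
to be permissive.  Survivors are size-selected to 23–29 nt.

No-mismatch mapping is exactly substring search, so the mapper is a sorted
2-bit 23-mer index over the plus strand; minus-strand hits come from
searching the reverse complement.  `unique` mode keeps reads with exactly
one genomic hit; `all_best` keeps all hits and downstream analyses weight
each placement by 1/n_hits.  Contigs shorter than 50 kb are dropped before
mapping by default (configurable), and a user-supplied exclusion BED can
mask regions (e.g. externally derived highly structured loci, which this
package does not re-derive).  Pre-computed alignments can be ingested as
BED instead of using the built-in mapper.

## Cluster calling

The read-density model is a Poisson null per window: λ = N·w/G with windows
of w = 1000 bp advanced by 500 bp, rejecting at P(X ≥ k) < 0.05.  This is a
documented stand-in for the heuristic of dedicated cluster-prediction
tools, whose exact internal density model is not restated anywhere usable;
window and step are configurable.  Candidate bounds are tightened to the
extent of the reads inside the chained significant windows.  Thresholds:
minimum size 5 kb; minimum 1U-or-10A composition 30%, evaluated
strand-agnostically on the unique-mapper reads used for calling (inclusive
at the boundary, i.e. exactly 0.30 passes); uni-strand classification is a
strict > 95% majority (exactly 95% is dual).  Merging of closely adjacent
clusters (gap < combined length) iterates to a fixed point.

The ping-pong z-score accumulates weighted opposite-strand 5′–5′ overlap
counts c(o) for o = 1..20 and scores bin 10 against the mean and population
standard deviation of **all twenty** bins.  With the entire mass at o = 10
this gives z = √19 ≈ 4.36, which is also the statistic's ceiling; a flat
signature gives z = 0, and a region with no opposite-strand pairs reports
not-available.  (Scoring against the 19 non-10 bins instead is undefined in
exactly the all-signal case that the 20-bin form handles; that drove the
choice.)

Expression metrics: rpm is miRNA-normalized; rpkm uses per-million
*genome-mapped* 23–29 nt reads per kilobase of cluster, because a
length-normalized quantity wants a denominator on the same mapping scale.
On fully synthetic worlds, which contain no miRNA loci, the ledger falls
back to the genome-mapped count so rpm stays defined.

## Repeat landscape

Per-insertion divergence is normally ingested from RepeatMasker-style
annotation; `kimura2p` implements K = −½·ln((1−2P−Q)√(1−2Q)) for
recomputation from pairwise substitution proportions, raising on model
saturation rather than returning infinities.  The CpG-adjusted variant is
intentionally omitted.  Border profiles use 500 bp windows (10 kb flanking,
5 kb internal for content; same defaults for divergence, plus a
percent-rescaled mode where each cluster contributes its inner half and a
flank of the same physical length, split into 10 bins).  Windows with no TE
bp are skipped in cross-cluster averaging — an empty window carries no
divergence information, and zero-filling would drag profiles toward zero.
Heterochromatin: 50 kb windows, density ≥ 2× the genomic average, maximal
runs that include a contig end.  This replaces any manual validation step
with a deterministic rule.  Insertions are assigned to
cluster/heterochromatin/euchromatin compartments by their midpoint to avoid
boundary double-counting.

## Synteny tracing

Flank gene arrays cover 200 kb per side; genes must lie wholly within the
span.  Homology search is ortholog-ID lookup (synthetic worlds carry exact
ortholog tags; real data supplies ortholog tables) — sequence-level homology
search is external tooling whose output this logic consumes.  Candidate
ranking: same-contig placements first, then smallest summed query distance
of the innermost anchors, then longest collinear run.  The locus is an
inversion break when the adjacency between the innermost left and right
flank genes does not survive in the subject (checked on the signed
permutation of the combined flank arrays).  Otherwise the locus is active
when a piRNA-expressing region inside it passes all five thresholds
(≥ 100 rpm, ≥ 10 rpkm, ≥ 5 kb, ≥ 25% TE bp, ≤ 25% gene bp).  When the
subject species has called clusters, "a piRNA-expressing region" means one
of those clusters overlapping the locus; the raw interval is evaluated only
when no cluster calling was done.  On desk-scale genomes (hundreds of kb)
this matters: per-million thresholds are scale-free, so a handful of
background reads in a 10 kb interval of a 3000-read library clears 100 rpm
even though no cluster is there.  Anchoring activity on called clusters
keeps the decision meaningful at any library size.

Homology groups are the transitive closure of any-overlap (> 0 bp) between
same-species loci plus the query↔subject links of the calls; no reciprocal
overlap fraction is imposed.  Group age is the divergence time of the MRCA
of the species where the locus is active; single-species groups are
species-specific with age 0.

## Breakpoint enrichment

Signed permutations are padded with 0 and n+1 so terminal inversions count.
Breakpoints are adjacencies with p_{i+1} − p_i ≠ 1; the inversion flag
marks sign reversals (padding treated as +).  A breakpoint's genomic
position is the midpoint of the intergenic span between the two anchoring
subject genes.  The profile bins events in 15 kb windows out to ±150 kb
around locus borders by default; events between the flanks feed the x₀ bin.
Only inversion-flagged breakpoints are profiled by default (configurable).

Two conventions matter for calibration.  First, an event is a junction in a
*genome*: detections of the same junction from different query species are
deduplicated (within 2 kb) per subject genome before binning, and each
genome's events are profiled against that genome's own loci — without this,
one physical breakpoint is counted once per species pair and the z-test's
independence assumption collapses.  Second, σ is the population standard
deviation over flank-window frequencies, and p is the one-sided upper
normal tail; σ = 0 reports not-available.  Background locus sets (10 sets,
length-matched, uniformly placed) are available for profile comparison.

## Synthetic worlds

The generator emulates a clade related by segment inversions.  The
ancestral genome carries ordered ortholog-numbered genes (default 1.5 kb),
planted TE-dense clusters with 1 kb annotation-free "hotspot" windows at
their borders, and a three-compartment TE landscape: cluster bodies ~70%
TE coverage at ~3% divergence, a terminal heterochromatic zone (last 15% of
each contig) ~60% coverage at ~8%, euchromatin ~5% coverage at ~15% —
reproducing the low-divergence-cluster / mid-heterochromatin /
high-euchromatin ordering the landscape analytics are meant to detect.
Divergence is annotation only; there is no substitution model, no
duplication and no translocation.  Inversion breakpoints are sampled in
annotation-free intergenic space (hotspot windows included — they are
ordinary intergenic DNA), so genes, insertions and clusters move as whole
units and gene-anchored synteny stays well defined.  With `hotspot_bias`,
that fraction of inversions draws both breakpoints from hotspot windows of
two different clusters on one contig, disrupting the gene order between
them.  Hotspot windows are derived state, recomputed from cluster borders
after every applied inversion.  Cluster death on a branch is modelled by
silencing listed clusters in a leaf (`cluster_losses`).

Reads: 23–29 nt, uniform length, drawn from active clusters with a 1U bias
(default 0.75, by rejection sampling of start positions); a configurable
fraction (default 0.3) is emitted as ping-pong pairs whose 5′ ends overlap
by exactly 10 nt, which gives responders a 10A by complementarity;
uni-strand clusters emit 98% of reads from one strand; noise (default 10%
of the cluster budget) is uniform over the genome.  Total read count equals
the cluster budgets plus the noise budget.  DNA-seq counts per family are
Poisson around family bp × coverage / 300.

## Validation studies and their scope

`studies.py` fixes one design per claim; the same code backs the test suite
and `scripts/acceptance.py`.  Problem sizes are deliberately scaled-down
genomes (0.3–1.2 Mb total per species, read budgets of a few thousand):

* **Cluster recovery** — 5 clusters (2 uni-strand) on 500 kb; recovery is
  Jaccard ≥ 0.5 against planted intervals.
* **Breakpoint enrichment** — 5 species on a star tree (20 My branches), 4
  contigs × 2 clusters, ~2 inversions per branch, euchromatic TE coverage
  raised to 25% so that breakpoint-eligible space is comparable inside and
  outside the inter-flank windows.  The star tree makes every event private
  to one leaf — maximal differentiating power per event.  Planted hotspot
  worlds must give Z₀ > 3; null worlds |Z₀| < 2 in ≥ 9/10 seeds.
* **Kimura oracle** — 10 kb sequence pairs diverged by an explicit per-site
  Poisson substitution process (transitions twice as likely as each
  transversion type); the realized events per site is the reference, and
  the estimator must agree within 5% for K ≤ 0.3.
* **Reversal oracle** — every single segment reversal of the identity for
  n ≤ 8, plus exhaustive enumeration of all signed permutations for n ≤ 4,
  against a brute-force search over reversals.  (Enumerating all 2ⁿ·n!
  permutations at n = 8 is ~10⁷ cases; the reduced enumeration checks the
  same equivalence.)
* **In-silico deletion** — delete the top called cluster of a 3-cluster
  world; its log₂FC must be < −2 with other clusters |log₂FC| < 0.5, and
  total TE-piRNA loss must match the planted share within 2 points.

What passing shows: the estimators recover planted truth under the
generator's assumptions (exact-match reads, uniform read placement within
clusters, annotation-only divergence, inversions-only evolution, one-to-one
orthologs).  What it does not show: robustness to sequencing error,
mismatch mapping, nested/fragmented repeats sharing sequence across loci,
gene duplication and loss, assembly artifacts, or library-preparation
biases — real data brings all of these, and the mapping and ortholog layers
then have to come from the dedicated external tools whose outputs this
package ingests.

## Known limitations

* Multi-mapping behaviour is exercised only lightly: synthetic TE copies do
  not share sequence, so `all_best` weighting is validated on constructed
  cases rather than end to end.
* The Poisson window model is a stand-in for proTRAC-style density
  heuristics; absolute cluster boundaries can differ by up to one window.
* Fold-change pseudo-count is 1 rpm (configurable); with n = 1 libraries no
  dispersion estimate is attempted.
* Telomere-associated families (Het-A, TAHRE, TART) are excluded from
  attribution by default because their copy number is strain-variable.
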