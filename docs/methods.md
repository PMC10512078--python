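# Methods

## Scope and model

`neofusion` analyses one class of chimeric RNA: a transcriptional read-through
between two adjacent genes on the same strand, spliced so that the mature
fusion cDNA is the 5' gene's exons 1..b5 followed by the 3' gene's exons
b3..n. Antisense and inter-chromosomal fusion classes are rejected with a
clear error — the event model, not an implementation shortcut, defines that
boundary. All internal coordinates are 0-based half-open; GTF is written and
read 1-based inclusive.

Because input reads derive from mature mRNA, alignment targets the *spliced
transcriptome* (one transcript per gene) rather than the genome; spliced
genomic alignment of wild-type introns is deliberately out of scope.
Transcript coordinates are lifted to genomic coordinates through the exon
models wherever breakpoints are reported.

## Synthetic cohort generator

The generator emulates the statistical structure the caller depends on, not
the biology of a real transcriptome:

* a single contig carrying `n_genes` plus-strand genes (2–4 exons of
  120–200 nt, introns 60–120 nt, intergenic gaps 150–300 nt), so any
  consecutive pair can host a read-through fusion;
* gene sequences that are coding by construction (frame-0 ATG→stop CDS, no
  internal frame-0 stops, an in-frame ATG planted after each internal exon
  start) so truncation ORFs exist downstream;
* paired-end fragments (truncated normal length, mean 180 sd 25, resampled
  into [read_len, transcript length]) drawn uniformly across wild-type
  transcripts or, with probability `expression_weight`, from a planted
  fusion cDNA; mate 2 reverse-complemented; per-base substitution errors at
  rate 0.001 (the study's assumed error rate); read length 76 by default;
* per-pair truth labels. A fusion fragment is *junction-crossing* when a
  mate's footprint covers at least 6 nt (one breakpoint-motif hexamer) on
  each side of the junction, *spanning* when the mates bracket the junction
  without crossing it, and otherwise indistinguishable from wild type. The
  6-nt anchor reflects the smallest junction signal the downstream consensus
  machinery uses; overhangs thinner than that carry no recoverable evidence.

What the generator does **not** model: indels in reads, PCR duplicates,
expression dispersion between genes, fragment-length biases, strand-specific
protocols, base-quality variation (qualities are written as constant Q40 and
never used — the pipeline filters on alignment, not quality). Passing tests
therefore demonstrate the *logic* of detection and filtering under the
stated error model, not performance on real FFPE RNA-seq.

The default cohort mirrors the study design at desk scale: six tumors (two
per subtype TNBC / HER2+ / HR+) carrying the planted fusion at expression
weight 0.08, two cancer-free controls, and a decoy fusion planted in one
control plus three tumors so the control-exclusion filter is exercised on
every run.

## Read mapping

The mapper reproduces the *semantics* of the study's alignment configuration
— integer costs (mismatch 2, insertion 3, deletion 3), length fraction 0.8,
similarity fraction 0.8, at most 10 hits per read, both strands — with an
exact-seed (k = 16) + extension engine that is adequate at toy scale; the
contract is the cost model, not the engine. Seeded placements are first
evaluated ungapped; placements failing the similarity gate fall back to a
banded (±5) semi-global dynamic program under the same cost model with full
traceback. The whole read is aligned (coverage 1.0 ≥ length fraction);
identity is counted as matches / aligned columns — a documented dialect
choice for how the similarity fraction treats indels. Ties are broken by
(cost, target, position) so output is independent of hash order. On
references ≤ 2 kb the best reported cost equals an exhaustive
dynamic-programming oracle (property-tested).

A consequence worth knowing: a junction-crossing read whose short arm is
≲ 20 nt still passes the 0.8 similarity gate as a full-length alignment to
the longer side's gene (≈ one mismatch per four overhang bases) and is
absorbed as ordinary discordant-pair evidence; only reads whose both arms
exceed the tolerance become split-read evidence. This matches the minimum
unaligned length of 15 with the mismatch tolerance stacked on top.

Split mapping anchors seeds (k = 12) near both read ends, and for every
anchor pair on two different genes scores all split points with ≥ 15 nt per
arm by total matches (per-arm identity ≥ 0.8), choosing the maximum with
leftmost-split tie-breaking. Split reads are always reported on the fusion-
forward sense, so the left segment names the 5' gene. Pair classification:
concordant (same gene, opposite strands, forward mate upstream, span ≤
1000 nt — the broken-pair distance), discordant_two_genes, half_mapped, or
unmapped (also the catch-all for unusable same-gene orientations).

## Fusion detection and refinement

A candidate (G5, G3) requires both evidence kinds: ≥ 1 discordant pair whose
mates lie within the broken-pair distance of the breakpoints, and ≥ 1 split
read whose breakpoints agree with a cluster (split reads merging within 5 nt
to the modal breakpoint — absorbs alignment jitter) and fall within 10 nt of
annotated exon boundaries. Genes with more than 7 distinct discordant
partners are removed with all their candidates (the pseudogene/repeat
mis-mapping guard). Evidence counts are distinct read/pair identifiers — no
double counting.

Refinement rebuilds a fusion reference of ±150 nt around each candidate
junction (≈ twice the read length, so any junction-crossing 76-mer fits) and
scans previously unusable reads (no full alignment, no split) at every
offset on both strands; a placement with identity ≥ 0.8 crossing the
junction with ≥ 15 nt on each side increments the junction-read count.
Counts are monotone non-decreasing by construction.

## Cohort filters

All filters are pure per-gene-pair predicates, hence order-independent and
invariant to sample relabelling (both property-tested):

* **control exclusion** — a pair called in *any* cancer-free control is
  removed from every tumor; pairs confined to adjacent-normal samples are
  retained. The design reading: adjacent-normal tissue may carry
  pre-malignant clones, so excluding on it would inflate false negatives,
  whereas cancer-free tissue is a clean null.
* **recurrence** — ≥ 1 junction-crossing read in ≥ 3 distinct case samples,
  pooled across subtypes (not per subtype).
* **external recurrence** — optional membership test against an independent
  dataset's gene-pair table; a flag-controlled no-op when no table is given.
  It is applied last by default (the natural place for corroborating
  evidence); a caller can reorder since the predicates commute.

The prevalence report counts positive samples and the mean junction-read
count over positive samples per subtype, rounded half-up to integers to
match the conventional integer presentation (full precision available).

## Junction, transcript, PCR

The consensus junction is a per-column majority vote over split reads
anchored at their split points; zero-coverage columns are trimmed and exact
ties resolved alphabetically (A<C<G<T) — deterministic, and no IUPAC codes
that would break translation downstream. Reads supporting breakpoints more
than 5 nt apart raise a cluster-conflict error rather than averaging
incompatible events. Breakpoint motifs are the terminal hexamers either side
of the junction (6 nt mirrors the motif length used in junction reporting).

Exon boundaries: the 5' breakpoint is matched to the nearest annotated exon
*end*, the 3' breakpoint to the nearest exon *start*, within the 10-nt
tolerance; distance 0 flags an exact boundary. The fusion cDNA is assembled
exon-by-exon from the genome on each gene's coding strand.

In-silico PCR requires the forward primer verbatim and the reverse primer as
its reverse complement downstream; the product is counted inclusively from
the forward primer's 5' end to the reverse primer's 5' end (the conventional
product definition), and all products are reported.

## Neopeptides

ORF discovery scans the three forward frames (fusion orientation is known;
reverse frames behind a flag) for ATG→stop ORFs, reporting the outermost
start per stop, translated by the standard code. The novel residues of a
truncation ORF are *computed*, not trusted from annotation: the ORF is
classified by its longer shared terminus (N-terminal prefix with the 5'
wild-type protein ⇒ five_truncation; C-terminal suffix with the 3' protein ⇒
three_truncation) and the novel run is the maximal terminal stretch absent
from the wild-type continuation. The peptide context is the novel run plus
k−1 flanking wild-type residues, so exactly the k-mers overlapping ≥ 1 novel
residue are enumerable; duplicates keep their first occurrence, and the two
truncations are reported per-region rather than globally deduplicated.

k defaults to 8 with 8–11 supported. On the two published junction regions
(C-terminal novel run KFPRKLYFLH, N-terminal novel run MISNQ), k = 8 yields
10 + 5 = 15 peptides. In the synthetic pipeline the 5'-truncation ORF always
exists (the 5' gene's CDS runs past the junction to the first downstream
stop); a 3'-truncation ORF with novel N-terminal residues additionally needs
an upstream in-frame ATG clear of stops, which random toy sequence does not
guarantee — the 3'-side logic is therefore exercised with constructed
proteins in the tests.

## MHC ranking

The binding predictor is an interface, not a dependency: any (peptide, HLA
allele, IC50 nM) TSV feeds the module, and allele names are normalized to
`HLA-X*NN:NN`. Thresholding is strict (`IC50 < 500`), so boundary records at
exactly 500 (or 50) are excluded — documented because printed summary tables
sometimes count them. Promiscuity profiles report distinct-allele counts at
50/500/1000 nM; ranking is by the 500-nM count, ties by best IC50 then
peptide. An optional lower bound can drop ultra-strong binders (< 50 nM,
argued by some not to initiate responses); it is off by default since the
published tables include such binders. The study's printed binding table for
the 15 junction peptides ships as a package fixture
(`data/study_binding_table.tsv`, 59 + 18 rows).

## ELISpot

Replicates are background-subtracted by the negative-control mean (the
adjusted NC mean is identically zero — property-tested); negatives are kept
for testing but clamped to zero for fold-change display. A condition is
positive iff its adjusted mean reaches 20 SFC/10⁶ cells *and* a Mann–Whitney
U test against the positive-control wells gives p ≤ α = 0.05, uncorrected.
The test is exact (enumeration-equivalent) for untied samples up to 6+6 and
falls back to the mid-rank normal approximation with tie correction
otherwise; scipy provides the engine, and the test suite checks it against a
hand-written full-enumeration oracle. Sidedness is two-sided by default and
flag-switchable — published assay p-values rarely state it, and raw
replicate counts are rarely printed.

One statistical consequence shaped the demo-plate generator: a 3-vs-3
two-sided exact test can never reach p ≤ 0.05 (its minimum is 2/20 = 0.1),
so the generator emits 4 replicates per condition, with 10% replicate CV
(the commonly quoted ELISpot intra-assay variability) and one planted
responder at twice the positive control.

## Pipeline, determinism, problem sizes

`run_all` executes simulate → align → detect → filter → consensus →
peptides → rank (→ elispot when a plate is supplied) from one validated
config; unknown keys and type errors are reported together. Every stage is a
pure function of (inputs, config, seed): per-sample seeds derive from the
global seed, set/dict iteration never influences output order, and artifacts
carry a config hash, so reruns are byte-identical.

Default problem sizes — 6 genes, 8 samples × 2000 pairs, 2 kb-scale
transcripts — were chosen so the complete cohort analysis runs in seconds
while still producing tens of junction-crossing reads per positive sample;
the oracle-equivalence and sweep tests use smaller instances (≤ 2 kb
references, hundreds of pairs) where exhaustive oracles are feasible.

## Known limitations

* The aligner is a toy: exact seeding misses placements when errors corrupt
  all seed positions (the refinement pass recovers such junction reads), and
  there is no FM-index or spliced genomic alignment.
* Junction reads with one arm shorter than ~20 nt are absorbed as mismatched
  full-length alignments (see above) and contribute only discordant-pair
  evidence.
* Fusion expression is a single fragment-fraction weight; no attempt is made
  to model allele-specific expression or tumor purity.
* The ELISpot module evaluates printed-style summary statistics; it does not
  model spot-count overdispersion or plate effects.
* Real-data concerns — multi-mapping in gene families, FFPE degradation,
  library-prep chimeras — are outside what the synthetic cohort can show.
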