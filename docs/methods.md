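# Methods

## The model

Small 18–25 nt RNAs in a fungal silencing system arise from two routes
with distinct genetics and sequence statistics, and the pipeline's job is
to tell them apart from multi-genotype sRNA-seq alone.

**Canonical ex-siRNAs** are Dicer products from exons: 23–24 nt, mixed
sense/antisense reads, a 5′-uracil bias, Ago-1-bound (classes I and II).
Their biogenesis requirements define four classes: class I needs Dcl-2
but not RdRP-1; class II needs Dcl-2 and RdRP-1; class III is redundant
between the Dicers (depleted only in the *dcl1 dcl2* double mutant) and
needs both RdRPs; class IV needs Dcl-1.

**rdRNAs** are not sRNAs in the canonical sense but mRNA degradation
fragments. An RNase (R3B2) cleaves transcripts two nucleotides downstream
of uracils; fragments whose two generating uracils are 18–24 nt apart end
up in the sequencing library. Consequences, all of which the package
measures: fragments are exclusively sense to the mRNA; the size spectrum
is flat rather than peaked at 23–24; every cut-delimited fragment has a
uracil at its penultimate position (index L−2); and the uracil that made
the fragment's 5′ cut sits at flank position −2. Accumulation requires
RdRP-1 and/or RdRP-2 but no Dicer.

## Classification procedure

Loci are single-linkage clusters of mapped reads: sorted by start, a read
joins the open cluster when its start is within `gap` (default 200 nt,
inclusive, end-to-start between interval hulls) of the running cluster
end; strands are pooled. Clustering runs on reads pooled across **all**
libraries so that every genotype contrast is evaluated on identical locus
boundaries. Clusters below `min_reads_per_locus` total weight (default 2)
are dropped as singleton noise.

Abundance is reads per million, with the denominator the library's total
genome-mapped weight (not total sequenced reads). Multi-mapping reads are
split fractionally across their placements by default so that total
weight is conserved; `unique-only` and `all` policies are available.

Per locus and mutant contrast, log₂ FC = log₂((mut + pc)/(wt + pc)) with
zero pseudocount by default; a zero-in-mutant locus whose WT passes the
floor yields −∞ and counts as depleted (it is excluded from mean-FC
summaries, which average finite values only). A locus is *depleted* at
log₂ FC ≤ −2 (fourfold) and *unchanged* at |log₂ FC| < 2; the depletion
side is the published criterion, and the symmetric no-change band is this
package's operationalisation of "no significant change" (configurable).
Classification applies, most specific pattern first: class IV (depleted
*dcl1*, unchanged *dcl2*), class III (unchanged in both single *dcl*
mutants, depleted in the double and in both *rdrp* mutants), class II
(depleted *dcl2* and *rdrp1*), class I (depleted *dcl2*, unchanged
*rdrp1*); otherwise, loci unchanged in all three *dcl* contrasts and
depleted in *rdrp1* and/or *rdrp2* are rdRNAs subtyped by which *rdrp*
contrasts are depleted. Loci with WT ≤ 50 RPM are never classified.
R3B2 dependence (depleted in the *r3b2* contrast) and Ago-1 binding
(wild-type IP over *ago1* IP, log₂ FC ≥ +2) are independent per-locus
flags. Class I membership does not require an *rdrp2* call; the *rdrp2*
fold change is recorded alongside.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `gap` | 200 nt | locus merge distance (inclusive) |
| `min_reads_per_locus` | 2 | total read weight to keep a cluster |
| `wt_min_rpm` | 50 RPM | wild-type abundance floor (strict >) |
| `fc_threshold` | 2 log₂ | depletion threshold (fourfold) |
| `no_change_band` | 2 log₂ | \|FC\| below this is "unchanged" |
| `offset` | 2 nt | cut distance downstream of a uracil |
| `eligible_range` | [18, 24] nt | fragment lengths entering the library |
| flank width | 5 nt | genomic context in composition matrices |
| size window | [18, 25] nt | read lengths mapped |
| seed `k` | 12 (9 for 1-mismatch) | k-mer seed length of the mapper index |

All thresholds are configuration values recorded in the run manifest.

## The synthetic-data generator

The simulator emulates the study design: nine libraries (WT, *dcl1*,
*dcl2*, *dcl1dcl2*, *rdrp1*, *rdrp2*, *r3b2*, and the two Ago-1 IP
fractions) at a depth of 10⁶ reads each, with 50 planted loci per class
(three rdRNA subtypes, ex-siRNA classes I–IV) hosted inside exon
features, plus 100 unaffected intergenic background loci.

Per-genotype expected abundance is WT × multiplier: 1/8 for genotypes a
class depends on (safely past the fourfold threshold), exactly 1 for WT,
and a mild lognormal jitter clipped to [0.55, 1.8] — inside the
no-change band — for unaffected mutants. Ago-1-bound classes (I, II) are
up-weighted 8× in the WT IP library. A per-class fraction of loci is
additionally R3B2-dependent (1.0 for rdRNA subtypes and class III, 0.66
for class II, 0.33 for class I, 0.8 for class IV), mirroring the graded
involvement of the RNase across classes. Libraries are realised
multinomially, so each sums to its depth exactly.

rdRNA locus sequences are designed with uracils spaced 18–24 nt apart, so
exhaustive U+2 cleavage yields fragments spanning the whole library
window (the flat size spectrum); non-U positions are purine-biased,
echoing the A/G skew of real sRNA populations. Reads are drawn from the
enumerated fragment spectrum: with per-cut efficiency e (default 0.9,
a free parameter — no measured value exists for the RNase), a fragment
skipping j intermediate cuts occurs with weight e²(1−e)ʲ. ex-siRNA reads
have uniform starts, sizes from {23: 0.5, 24: 0.5}, sense probability
0.5, and with probability 0.9 the start is shifted to the nearest
position giving a 5′ U (ties toward the locus centre).

Background loci carry 70 % of each library's mass with strongly
dispersed weights (lognormal σ = 2, straddling the 50-RPM floor). This
dominance of unaffected mass matters: it keeps RPM renormalisation
shifts in mutant libraries small, as in real genome-wide libraries where
regulated loci are a minority of mapped reads. A thin uniform noise
component (2 × 10⁻⁴ of depth) is sprinkled genome-wide; the density is
deliberately low because uniform reads at even 1 % of depth would chain
the entire genome into one cluster under the 200-bp merge rule. Genomic
items are laid down with ≥ 300 nt spacing so planted loci are separated
by more than the merge gap.

**What the simulator does not model** (and what passing tests therefore
do not show about real data): adapter-ligation bias, sequencing errors
and quality scores, expression-correlated backgrounds, splicing/UTR
structure (annotated features are treated as transcribed units),
overlapping genes, and the IP chemistry of Ago-1 pull-downs (modelled as
re-weighted libraries). Reads are emitted in DNA alphabet; all uracil
logic keys on T.

## Numerical and design choices

* **Mapper**: exact matching is the default; the settings of the original
  alignment tool are not published, so exact matching is the reproducible
  choice, with 1-mismatch behind a flag (requiring seed k ≤ L_min/2 so
  the two-seed lookup is exhaustive). Every candidate placement is
  verified against the genome. Reads are mapped irrespective of
  annotation; annotation intersection happens at the locus stage.
* **Locus caller**: with reads sorted by start, a new cluster opens
  exactly when a read's start exceeds the per-contig running maximum end
  by more than the gap — provably equal to the transitive closure of the
  pairwise relation, and tested against a quadratic union-find oracle.
  Merging is order-independent. Under dense uniform noise, adjacent loci
  can legitimately chain through interstitial reads; this is a property
  of the 200-bp rule itself and accounts for the rare (< 4 %)
  recovery losses at study scale.
* **Strand bias** is referenced to the assigned feature's strand; for
  intergenic loci the + strand is used and flagged arbitrary.
* **Yates chi-squared**: each cell contributes max(|O−E|−0.5, 0)²/E (the
  correction floored at zero); the uncorrected statistic is available.
  The p-value uses the χ²(1 df) survival function. The enrichment table
  compares the regulated set against the whole-genome background
  (regulated genes included), with genes carrying several functional
  classes counted once per class and unannotated genes forming their own
  category. No multiple-testing correction is applied to the primary
  p-values; a Bonferroni column is emitted as an extra.
* **Cleavage score**: 5′-at-cut, 3′-at-cut and penultimate-U fractions
  are reported separately because real 3′ ends could be exonucleolytically
  trimmed; the headline score requires both ends at predicted cuts.
  Antisense reads are tallied but never credited.
* **Composition profiles**: count-weighted over raw reads by default
  (unique-placement weighting behind a flag; which weighting published
  logos used is unstated). Reads whose flank window runs off the contig
  count toward read columns only.
* **Degenerate inputs**: a transcript without uracils yields an empty
  read set, not an error; an empty read population yields a report with
  undefined (None) fractions; empty call sets produce all-zero summary
  tables with full headers; a zero-total library or a zero 2×2 margin is
  an error.

## Problem sizes

The bundled acceptance run simulates nine libraries at depth 10⁶ over a
0.9 Mb genome with 450 planted loci (~30 s end to end on one CPU) and
checks oracle equivalences on 5 000 reads (locus caller), a 50 kb genome
(mapper), 1 000 random 2×2 tables (Yates statistic, agreement to 1e-9)
and all 3⁵ depletion-flag combinations (classifier). Worked-example
percentages (3.95 % of 531 regulated genes; 66.2 % of 222 class II loci)
are computed exactly by the summary modules from their stated counts.

## Known limitations

Genome-scale re-analysis of the original deposited libraries is out of
scope here (it requires external downloads and is sensitive to unstated
alignment parameters); correctness is instead established by parameter
recovery on the generative model plus brute-force oracles. The classifier
is a pure threshold rule — no replicate dispersion modelling or
statistical testing of differential abundance, matching the published
fold-change criterion. rdRNA subtype boundaries inherit the threshold's
hard edges: a locus depleted 3.9-fold in *rdrp2* counts as unchanged
there, so "*rdrp1*-only" subtypes may include loci with sub-threshold
*rdrp2* depletion.
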