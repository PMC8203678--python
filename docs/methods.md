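# Methods

## Scope and data flow

The package analyses pooled-deletion-collection barseq screens: tag-level
barcode counts (or single-end 50-bp reads) with a sample design table go in;
per-gene, per-screen fitness-defect (FD) scores with calls, pruned gene-set
enrichment with an enrichment map, and cofitness/coinhibition similarity
with Ward dendrograms come out. A synthetic-data generator produces every
input with planted ground truth, so each stage is validated by recovery
rather than by fixtures.

## Barcode counting

Each deletion strain carries two unique 20-nt barcodes. Reads are modelled
as `5'-flank + tag + 3'-flank` truncated to 50 nt; the flanks are the
internal segments of the sequencing primers adjacent to the barcode (uptag:
`GATGTCCACGAGGTCTCT` / `CGTACGCTGCAGGTCGAC`; downtag: `CGGTGTCGGTCTCGTAG` /
`CGATGAATTCGAGCTCGTTTTC`, the 3' flanks being reverse complements of the
opposite-strand primer segments). Counting locates the best 5'-flank
placement (fewest mismatches, leftmost on ties, up to `max_flank_mm = 2`),
takes the following 20-mer, and matches it against the combined
uptag+downtag index: an exact hit wins, otherwise the unique tag within
Hamming distance `max_mm = 1`; two equally-near tags make the read
*ambiguous*, none in range *unmatched*. Per-sample QC enforces
`assigned + unmatched + ambiguous = total_reads`.

The catalog generator enforces a minimum pairwise Hamming distance of 5
between all tags (the published collection guarantees only uniqueness).
With distance >= 2·max_mm + 1 = 3 this makes 1-mismatch matching provably
unambiguous for reads with at most one tag error; the distance-5 default
leaves additional margin and is verified by exhaustive 1-error corruption in
the tests. At a 1% per-base error rate the binomial tail implies ~98.3% of
tags carry at most one error, which bounds the expected assignment yield;
assignment *accuracy* among assigned reads is essentially 1.

No quality-score filtering is applied by default: the counting contract is
purely sequence-based, and the upstream protocol's exact tolerances are not
part of this package's inputs.

## Fitness model

1. **Collapse.** Uptag and downtag counts are summed per gene (a missing tag
   row counts as zero).
2. **Normalization.** Median-of-ratios size factors: `s_j = median_g
   (y_gj / geomean_j y_gj)` over genes positive in every sample, reported
   unnormalized. Only factor *ratios* are identified; all downstream
   quantities depend on ratios alone.
3. **Dispersion.** Per gene, a method-of-moments estimate on normalized
   counts with replicate-group means removed (groups: a screen's treatment
   replicates; a diluent+date control batch): `alpha_g = (s2 - xi*mu)/mu^2`
   with `xi = mean_j(1/s_j)` the Poisson term, floored at 1e-8. A trend
   `a0 + a1/mu` is fit by least squares over informative genes and the raw
   estimate is averaged with the trend in log space (weight 0.5). Genes with
   zero residual variance return the floor; all-zero genes the trend. The
   log-space average stabilises the very noisy per-gene moments (6 samples)
   while letting genuinely high-dispersion genes keep elevated values.
4. **Per-screen fit.** For each screen, treatment replicates are fit jointly
   against the matched controls (controls are matched by diluent and date,
   mirroring batch structure; replicates collapse to one FD per gene per
   screen). The NB MLE of each group's normalized mean solves
   `sum_j (y_j - s_j q)/(1 + alpha s_j q) = 0` by Newton iterations on
   `ln q`; `raw_lfc = log2(q_t/q_c)`, Wald `se` from the Fisher information
   `I = sum_j mu_j/(1 + alpha mu_j)`, and a two-sided normal p-value on
   `raw_lfc/se`. Genes with zero counts in both conditions get
   `raw_lfc = 0, p = 1`; a group with zero total counts is floored at half a
   count so fold changes stay finite.
5. **Shrinkage.** The prior scale is estimated from the screen's LFC
   population: `tau^2 = max(trimmed second moment - mean se^2, 0.25)` (5%
   trim per tail). The default shrinker is the posterior mean under a
   zero-centered Cauchy prior with scale `tau`, computed by 64-node
   Gauss–Hermite quadrature. The heavy tail pulls noise-level estimates
   toward zero but leaves decisively non-null effects nearly unshrunk, so FD
   scores of strongly depleted strains remain close to the true log2
   depletion — a property a normal-prior posterior mean (`raw *
   tau^2/(tau^2 + se^2)`, also provided as `prior="normal"`) cannot deliver
   at realistic per-gene standard errors (se ~ 0.2–0.3 log2 units at
   triplicate depth), since it would shrink a two-fold-squared effect by
   20–40%. Both variants contract toward zero, preserve sign, and reduce to
   the raw estimate as `se -> 0`.
6. **Scores and calls.** `FD = -(shrunken lfc)`: depleted strains positive,
   enriched strains negative. BH FDR is computed within each screen.
   `FD >= 1` (at least two-fold depletion, boundary inclusive) calls
   *sensitive*; `FD <= -1` *resistant*. Screens whose treatment replicates
   correlate below r = 0.7 (Pearson on log normalized counts) are flagged in
   logs but never dropped — dose-quality exclusion is a judgement call left
   to the analyst.

## Enrichment

Query = a screen's sensitive genes; universe = assayed genes ∩ annotated
genes (configurable to assayed-only). Annotations are propagated up the
ontology (is_a and part_of collapsed, any number of hops) *before* the size
filter removes terms with < 5 or > 300 genes; lineage relations are
evaluated on the full DAG so filtered-out intermediates still connect
lineages. Hypergeometric upper-tail p-values, BH FDR, significance at
FDR < 0.1 (strict).

Pruning follows the GO-Elite idea: (a) among significant terms, every
ancestor/descendant pair keeps only the smaller-p member (ties: smaller
term, then lexicographically smaller id), leaving an antichain; (b) the
survivors are single-linkage clustered on the Jaccard similarity of their
driver sets, merging at J >= 0.5, and each cluster keeps its most
significant term. The merge threshold and linkage are this package's
choices; the published procedure names the coefficient but not the
algorithm. The enrichment map keeps retained terms as nodes (size
`-log10(FDR)`, FDR floored at 1e-300 to avoid infinities; the term's gene
count is exported alongside for drawings that scale nodes by set size) and
connects term pairs whose overlap coefficient `|A∩B|/min(|A|,|B|)` is at
least 0.5 (inclusive), carrying the overlap count as a second weight.

## Similarity and clustering

Coinhibition (screens) and cofitness (genes) are pairwise-complete Pearson
correlations of FD profiles; zero-variance profiles are reported missing
with a warning, and genes observed in fewer than 6 screens are excluded from
cofitness (correlation on fewer points is noise; configurable). Clustering
uses distance `1 - r` with the classical Ward (ward.D) criterion — the
Lance–Williams recurrence applied to the dissimilarities themselves,
matching the era's default of the quoted clustering routine; it is obtained
from scipy's Ward implementation by feeding sqrt-distances and squaring the
merge heights, and a ward.D2 variant is available. Missing correlations are
imputed as r = 0 with a warning before clustering. Dendrograms export to
Newick; flat cuts use scipy's maxclust criterion.

## Growth curves

Percent inhibition is `100 * (1 - AUC_t/AUC_c)` with AUC the trapezoidal
area under the baseline-subtracted OD600 curve (`od - od[0]`, clipped at 0);
the baseline subtraction makes the metric invariant to plate offsets, and
area (rather than endpoint or rate) is robust to lag-phase shifts. The
screening dose is the dilution whose inhibition falls in the 10–20% band,
closest to 20% (ties: lower dose) — reflecting the target of roughly 20%
wild-type inhibition.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:
~4800 strains with two unique 20-nt tags each (pairwise Hamming >= 5);
triplicate treatment screens with diluent/date-matched control batches and
`<compound>_<dose>_<date>` screen ids; lognormal baseline strain abundances
(log-mean ln 500, log-sd 0.7 per tag) with independent NB draws for the two
tags around a shared strain expectation (the analysis sums them, implying
separate measurements); per-sample library-size scaling; planted log2
depletions per (gene, screen), including whole planted ontology terms and
groups of screens sharing signatures; 50-bp reads with the primer-derived
flanks and i.i.d. substitution errors; and toy ontologies whose child sets
are nested in their ancestors with term sizes spanning both sides of the
[5, 300] filter. Defaults for the abundance distribution and dispersion
(0.05) are plausible-barseq stand-ins — the real pool's values are not
published — and are exposed in `NBParams`.

Not emulated: PCR jackpotting and chimeras, indel or quality-correlated
sequencing errors, growth-curve dynamics of individual strains within the
pool, batch effects beyond the diluent/date control structure, and
essential-gene (heterozygous) profiling. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated noise
model, not robustness to every artefact of real libraries.

## Benchmark problem sizes

The validation scenarios (in `chemofit.benchmarks`, shared by the test suite
and `scripts/acceptance.py`) use: 20 noise seeds of a 4800-gene 3v3 screen
with 100 genes planted at log2 FC -2 (dispersion 0.05) for recovery and
null calibration — one catalog is generated once and shared, since it
depends only on its own seed; a 200-term/1000-gene toy ontology with one
planted mid-sized term for enrichment pruning; 22 screens (three groups of
five sharing 60-gene signatures plus seven singletons) over a 1200-gene
catalog for clustering recovery, and six replicate-level screens of two
compounds for replicate adjacency; a 960-strain catalog at ~1e5 reads for
the counting round trip. These sizes keep the full suite at roughly ten
seconds while preserving the regime the defaults describe (triplicates,
hundreds of counts per tag, ~2% planted genes).

## Numerical choices and degenerate inputs

- Newton fits run 30 damped iterations on `ln q` from the moment estimate;
  the expected-information step is monotone for the NB log-likelihood.
- Gauss–Hermite posterior means are clamped to the interval [0, raw] so the
  contraction and sign-preservation contracts hold exactly despite
  quadrature error.
- p-values are clipped into (0, 1]; FDR values are floored at 1e-300 only
  for map export.
- Hypergeometric bounds are validated; `k = 0` returns exactly 1.
- Empty sensitive-gene queries return an empty enrichment result (logged),
  not an error; an all-zero count matrix fails size-factor estimation with
  a message suggesting a pseudocount.
- Tag-space feasibility is checked before catalog generation; the
  resample-until-separated loop is bounded and fails loudly rather than
  spinning.
- All generators and the pipeline are pure functions of their seeds; the
  pipeline derives per-stage streams from the top-level seed and writes a
  SHA-256-checksummed manifest, so reruns are bit-identical.

## Known limitations

- The Wald p-values come from unshrunken estimates; the sensitive/resistant
  decision rule is the FD threshold, not the p-value, so p and FDR are
  descriptive companions rather than the gatekeeper.
- Dispersion moments at triplicate depth are noisy; the trend shrinkage
  (fixed weight 0.5) is deliberately simple and can over- or under-disperse
  individual genes without materially moving FD calls.
- The 104-to-22 screen collapse of replicate batches is implemented as a
  joint fit of replicates per screen; averaging per-replicate FDs is not
  provided.
- Coinhibition on few genes, or cofitness on few screens, is statistically
  fragile; the `min_screens` guard is a blunt instrument.
- The enrichment universe choice (assayed ∩ annotated) changes p-values for
  sparsely annotated genomes; both supported options are documented.
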