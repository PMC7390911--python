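# Methods

`tumorchar` re-implements, as a tested library, the desk-side analysis
chain used to characterize a syngeneic tumor cell line from exome and
RNA-Seq derived tables: replicate-consensus somatic variant metrics,
VAF-based ploidy inference, trinucleotide mutation spectra with signature
decomposition, ensemble fusion-call consensus, the neoantigen
selection/vaccine-design/ELISpot chain, expression summarization with DE
classification and gene-set overlap testing, and viral gene RPKM. Every
stage runs on synthetic data produced in-repo, so the whole pipeline is
exercisable without sequencing data.

## Replicate consensus and variant summaries

Somatic calls made independently on two technical replicates are matched
by exact `(chrom, pos, ref, alt)` key — no positional fuzzing, since both
replicates come from the same caller and reference. The consensus
fraction is `100 * |A ∩ B| / |A ∪ B|`, rounded half-up to an integer, as
are all reported percentages (half-up reproduces every percentage this
kind of report prints; Python's default banker's rounding does not).
Consequence annotation is codon-level against the standard genetic code,
strand-aware (minus-strand codons are complemented base by base in coding
order); indels inside the CDS are frameshift unless the length change is
a multiple of 3; exonic positions outside the CDS are UTR. When a variant
hits several transcripts the most severe consequence is reported
(stop_gain > frameshift > stop_loss > missense > inframe_indel >
synonymous > UTR). A variant counts as expressed iff its RNA VAF is
strictly positive; an undefined RNA VAF (no RNA coverage) counts as not
expressed. DNA–RNA VAF concordance is the squared Pearson correlation
over records with both VAFs defined.

## Ploidy inference from VAF clusters

A locus mutated on k of c copies has expected allele fraction k/c, so a
copy-number-c gene puts SNV VAFs on the grid {k/c : k = 1..c}. Running
the copy-number caller once per assumed ploidy p in {2, 3, 4, 5} yields
one segment profile per candidate; each gene takes the copy number of the
segment with maximal overlap of its exon-union span. The concordance
statistic is the mean, over SNVs with defined DNA VAF and gene copy
number in [1, 10], of the minimum absolute distance to the gene's cluster
grid; genes at extreme copy number (focal amplicons) are excluded because
their grids are too dense to be informative. This is the simplest
statistic consistent with comparing observed VAFs to the expected cluster
profile; a binomial-likelihood variant that models depth-dependent
cluster width is available via `concordance_score(..., depth_weight=True)`.
VAFs are pooled genome-wide with per-gene cluster sets.

**Parsimony tie-break.** The grid for copy number 2c contains the grid
for c, so the profile of a doubled ploidy can never score worse than the
true one by more than sampling noise — a pure argmin would drift to 2x
the true ploidy for diploid-like genomes. `select_best_ploidy` therefore
treats candidates within `tie_tol = 0.005` of the best score as tied and
returns the lowest tied ploidy. The band was set analytically: the
superset advantage of a doubled grid is bounded by the expected excess of
|VAF − k/c| beyond half the finer grid spacing, which at depth ≥ 100 is
below 1e-3, while genuine grid misfit (e.g. thirds vs. quarters) costs
0.02–0.15 per variant. 0.005 sits an order of magnitude above the former
and below the latter.

## Mutation spectra and signatures

SNVs are collapsed to the pyrimidine-reference representation (purine
references are reverse-complemented together with both flanks) and binned
into the conventional 96 classes, ordered substitution-type major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3' flank. XCG
enrichment is the share of C>T mass at the four NCG contexts divided by
its expectation — 4/16 under uniform context usage, or the genome-wide
NCG/NCN trinucleotide frequency when a genome is supplied. Exposures are
estimated by non-negative least squares (Lawson–Hanson, via
`scipy.optimize.nnls`) of the normalized spectrum on a column-normalized
signature matrix, renormalized to fractions; exposures below 1e-6 are
reported as exactly 0, matching the convention of omitting 0% signatures.
A synthetic five-signature toy matrix ships in code (deaminaton-style
C>T at NCG; APOBEC-style C>T/C>G at TCW; flat; T>C-heavy; T>A-heavy);
its focused signatures carry no uniform background so the catalogue is
well conditioned, and it is not fitted to any real catalogue.

## Fusion consensus

Per-tool calls are normalized to ordered (5' gene, 3' gene) symbol pairs
— breakpoints are ignored because the four tool dialects report them in
incompatible conventions — and combined as the union of tools within each
replicate followed by the intersection across replicates ("wisdom of
crowds"). Self-fusions are rejected with a count. Under the generator's
model (per-tool sensitivity s_t on a truth set of size T; Poisson(λ_t)
decoys drawn uniformly from a pool of D pairs, independent per tool and
replicate) the expected high-confidence size has the closed form
`T(1 − Π(1 − s_t))² + D(1 − Π(1 − λ_t/D))²`, which the test suite checks
by Monte Carlo.

## Neoantigen chain

The SNV filter cascade keeps variants that are (i) present in both
replicates, (ii) coding (outside UTR), (iii) missense (no stop gain or
loss), (iv) mean replicate expression > 0, (v) DNA VAF > 0, (vi) RNA VAF
> 0.1 (strict), and (vii) absent from the control transcriptome (control
RNA VAF exactly 0). Indels use RNA VAF > 0 and retain frameshifts; an
optional orthogonal-confirmation flag drops unconfirmed indels. The
passing set is a conjunction (order-independent); criterion order only
attributes each rejection to its first failing criterion.

Constructs: an SNV is flanked by 13 wild-type residues each side (27-mer
when not truncated by a protein terminus); in-frame indels get 15-residue
flanks around the altered segment; frameshifts keep 15 upstream wild-type
residues plus the novel translated tail up to (not including) the first
stop — if no stop is reached before the transcript end the construct is
flagged. Constructs are tiled into 15-mers overlapping by 11 (step 4);
when L − 15 is not a multiple of 4 one extra tile anchored at L − 14 is
appended so the full sequence is spanned — the anchored-tail rule is this
package's documented choice for lengths the even case does not cover.
ELISpot positivity is strict: mean candidate spots > 2 x mean background;
a fold of exactly 2.0 is negative. Mutation specificity means the
candidate is positive while its tested wild-type counterpart is not.

## Expression and viral quantification

Transcript TPM is summed to gene level and then averaged over the two
replicates (sum-then-average, matching gene-level reporting of summed
transcript values). DE status is up/down at FDR ≤ 0.05 (inclusive) and
|log2 fold-change| > 1 (strict), with Benjamini–Hochberg adjustment
(`statsmodels`). The built-in DE screen — Welch t on log2(TPM + 1) with
replicates as samples — exists only so the pipeline classifies DE
end-to-end on desk-scale data; it is deliberately simple and underpowered
at n = 2, and a negative-binomial count model is the right tool on real
libraries. Gene-set overlap uses a one-sided (enrichment) Fisher exact
test on the 2x2 membership table over an explicit background. Viral
expression counts any read overlapping the union of a gene's isoform
intervals (merged, so multi-isoform overlap counts once) and reports
RPKM = count / (union_kb) / (mapped reads / 1e6); within a taxonomic
group only the accession with the highest total count is kept.

## The synthetic bundle

`synthetic.generate_bundle(SimConfig(...))` draws everything from one
`numpy` Generator seeded by the config, so a fixed seed reproduces the
bundle byte-for-byte. Defaults are the study conditions of the
characterized cell line; the main ones:

| parameter | default | meaning |
|---|---|---|
| `true_ploidy` | 5 | modal segment copy number (segments at P±1 with 15% each) |
| `n_snvs` / `n_indels` | 505 / 20 | somatic variant counts |
| `dna_depth` / `rna_depth` | 150 | binomial read-sampling depth for VAFs (typical capture depth; not printed in any report) |
| `replicate_overlap_target` | 0.66 | expected intersection/union of the two replicate call sets |
| `frac_expressed` | 0.34 | fraction of genes transcribed (unexpressed genes have zero RNA coverage) |
| `signature_exposures` | AC3 .55, AC1 .30, AC6 .10, AC20 .05, AC2 0 | generating mixture over the toy catalogue |
| `fusion_truth_size` | 12 | true fusion pairs; four tools at sensitivity 0.9, ~2 decoys each |
| `replicate_tpm_corr_target` | 0.99 | raw-scale Pearson between expression replicates |
| `n_elispot_candidates` / positives | 49 / 22 | planted ELISpot truth |

The toy genome is two chromosomes of concatenated two-exon genes whose
CDS regions are rewritten as clean ORFs (ATG, no internal stops, terminal
stop), ~60–150 codons each. SNV positions are chosen so their
trinucleotide context follows the signature mixture; allele multiplicity
k is uniform on 1..c; DNA and RNA allele counts are independent binomial
draws at the same underlying fraction k/c — binomial rather than Gaussian
noise so cluster width shrinks with depth, which is what the concordance
score must tolerate, and RNA resampled at the DNA fraction because
alleles are transcribed in proportion to their DNA frequency. Replicate
membership is drawn per variant as both/only-A/only-B with probabilities
t, (1−t)/2, (1−t)/2, making the expected overlap/union ratio equal the
target t. Expression replicates share a lognormal gene mean (log-sigma
1.5 around 20 TPM) with multiplicative noise whose sigma is solved in
closed form from the raw-scale Pearson target. ELISpot counts are Poisson
per well; planted positives sit at 4x background (the config enforces
≥ 3x). The 4x default comes from a normal-approximation power analysis:
with triplicate candidate wells and six background wells at mean 20, the
fold estimator's standard error is ~0.45, so 4x keeps the per-candidate
misclassification probability below 1e-5, whereas exactly 3x would
misclassify ~2% of candidates per plate set and planted-truth recovery
could not be exact.

What the generator does not emulate: read-level errors and mapping
artifacts, germline contamination, subclonal (non-integer multiplicity)
populations, GC/coverage bias in copy-number segments, correlated
tool errors in fusion calling, overdispersion beyond Poisson in ELISpot
wells, and count-level mean–variance structure in expression. Passing
recovery tests therefore demonstrates the correctness of the analysis
logic under the stated statistical model, not robustness to real-data
artifacts.

## Numerical choices and degenerate inputs

Percentages round half-up (integer, or one decimal for the candidate DE
fraction). VAFs with zero depth are undefined, excluded from concordance
and counted as not expressed. Copy number 0 yields an empty cluster grid
and such genes are skipped. Concordance scoring with no usable variant,
empty reference sets, empty ELISpot tables, a zero background mean, and
union size 0 all raise rather than return sentinels. NNLS exposures below
1e-6 are clamped to exactly 0 and the rest renormalized. Fisher tests on
degenerate tables return p = 1. Tiling deduplicates identical
(sequence, start) tiles and anchors the final tile at the C-terminus.

## Problem sizes used in the test-suite experiments

Parameter-recovery experiments run on desk-scale bundles chosen to keep
the statistical claims sharp while the suite stays quick: ploidy recovery
uses 40 genes / 300 SNVs / depth 100 over 40 seeds per true ploidy;
fusion Monte Carlo uses 200 instances on a 40-gene pool; signature
recovery uses 500-SNV multinomial draws (20 seeds) and 10,000-SNV bundles
for the pure-signature total-variation bound; the Fisher oracle sweep
covers every 2x2 table with total ≤ 30.

## Known limitations

The DE stand-in has low power at two replicates and its DE fractions on
synthetic data undershoot the generating truth; only classification
boundaries and the BH step are contract-tested. Fusion matching by gene
symbol cannot separate distinct breakpoints of the same gene pair. The
ploidy score assumes clonal integer multiplicities; subclonal fractions
would blur the grid and the parsimony band may then be too narrow. The
mutations-per-megabase utility is a raw ratio; it is reported but not
validated against any external figure.
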