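# Methods

## Coordinate convention and input model

All analysis is in transcript space: each reference sequence is one gene's
coding sequence extended 25 nt upstream of the start codon (the common
reference convention for start-codon metagene work). Positions are 0-based
with position 0 = the first base of the AUG; upstream positions are
negative, so valid 5'-end positions are ≥ −25. Reads are therefore
implicitly sense-strand; genome-space (GFF/BAM) handling, alignment and
trimming are out of scope — the package consumes already-assigned
(gene, 5'-position, length) records from a TSV or a minimal SAM dialect.
Multi-mapped reads are assumed resolved upstream to a single best hit; one
gene per record. Reads shorter than 24 nt are removed by default
(`filter_by_length`), the standard floor below which fragments are not
credible footprints.

## QC metrics

*Frame fractions.* The frame of a read is ((pos mod 3) + 3) mod 3, with
labels 0 → "0", 1 → "+1", 2 → "−1". The sign convention for the two
off-frames is fixed here (conventions differ between tools); the
main-frame fraction, which carries the diagnostic content, is
convention-independent.

*Metagene profile.* Raw 5'-end counts are summed across all genes long
enough to span the window (−25..+114; shorter genes are excluded and
counted), then divided by the mean over the first 140 window positions, so
a uniform profile has density ≡ 1. A per-gene-normalised variant (each
gene's positional histogram scaled to mean 1 before summing) is available
behind a flag for libraries dominated by few genes; raw summation is the
default because the aggregate profile is the classical presentation.

*Peak call.* The start-codon dwell peak is called when the density maximum
is ≥ 3× the median density (configurable). A threshold is necessary to make
"no peak" a testable outcome; 3× is far above the fluctuation ceiling of a
flat profile at realistic depth and far below a genuine dwell peak (tens of
× in practice). The codon coordinate is floor division of the nt position
by 3, so −12 nt = codon −4.

*Replicate correlation.* Pearson r on log₂(RPM + 0.5); the 0.5 pseudocount
admits zero counts while shifting well-expressed genes negligibly.

## Binomial-partitioning threshold

Given replicate counts A and B with library sizes L_A, L_B, the per-gene
fraction f = A/(A+B) has expectation p = L_A/(L_A+L_B) and counting-noise
SD √(p(1−p)/N) with N = A+B. Using p from the library sizes (not a fixed
0.5) prevents unequal depth from masquerading as biological variation.
Genes are binned by mean count on 20 log₁₀-spaced bins between the 1st and
99th percentile (bins with <5 genes dropped); comparison is on the fraction
scale, not variance-decomposed. "Stably larger than counting statistics"
is operationalised as observed SD ≥ k·predicted for m consecutive bins,
defaults k = 1.2, m = 3; the selected threshold is the first such bin's
lower edge converted to RPM with the mean library size. With observed² =
counting² + biological², the rule's analytic crossover is
N* = p(1−p)(k²−1)/sd_bio² (`crossover_mean_count`), which the tests use as
the recovery oracle. When filtering genes with a threshold, the default
rule is mean RPM across all samples > threshold; per-sample "all"/"any"
variants are available.

## Translational efficiency and the TOP shift

TE per condition divides the replicate-mean footprint RPM by the
replicate-mean mRNA RPM (a per-replicate-TE-then-average variant sits
behind a flag); genes with zero mRNA signal are excluded and logged.
Ratios are kept as natural logs internally and converted to log₂ for
display. The TOP vs non-TOP comparison uses the two-sample KS test with
asymptotic p-values at effective size n₁n₂/(n₁+n₂) — adequate at the
intended group sizes (tens vs hundreds of genes); exact small-sample
p-values are not implemented. Group medians are reported so the direction
(TOP shifted down = mTOR-suppression signature) is explicit. PCA operates
on gene-mean-centred log₂(RPM + 0.5) via SVD; each component's sign is
fixed so the alphabetically first gene's loading is non-negative, making
scores reproducible and gene-order invariant.

## Panel regression

The pooled regression uses the NoEx/0h/1h groups (design n = 18) with an
intercept and no group dummies — the pooled-association question, not a
time-course model; a group-covariate variant is a caller-side extension of
`ols_fit`. Backward elimination drops the predictor with the largest
p-value while it exceeds `alpha_stay` (default 0.3) and more than
`min_predictors` remain, and always returns the full trace so any stopping
rule can be audited. The 0.3 default reflects that a plain p < 0.05 stay
rule is too aggressive for an 8-predictor screen at n = 18 (it would evict
marginal but real effects such as a p ≈ 0.27 retained coefficient);
setting `alpha_stay = 0` forces a complete significance ranking, which the
tests use to check elimination order. Variables enter in their measured
relative units without standardisation, so coefficients stay on the
raw scale. Rank deficiency raises an error naming the collinear columns.

## Synthetic-data generator

The generator emulates the target study design:

- **Design.** Two biological replicates per condition, each the arithmetic
  mean of 3 mice's abundances (equal aliquot pooling), so between-replicate
  biological variance scales as mouse_cv²/3. Mouse multipliers are
  lognormal(0, mouse_cv) per gene per mouse, drawn independently per
  condition (different animals) but shared between the RPF and mRNA
  libraries of a replicate (same pooled lysate). The helper
  `mouse_cv_for_fraction_sd` inverts the linearised relation
  sd_f ≈ p(1−p)·√2·cv/√n_mice to hit a target biological fraction SD.
- **Expression.** Base RNA abundance lognormal (σ = 1.5, spanning the
  several decades typical of expression data); baseline TE lognormal
  (σ = 0.5). Condition effects multiply RNA by a per-gene transcription
  fold and ribosome loading by transcription × translation folds; TOP genes
  additionally lose `top_te_fold` of their loading under the stimulus
  (default 0.7, a moderate mTOR-suppression signature; tests and the
  acceptance run use 0.5 where a strong planted effect is wanted). The
  default census is 1010 genes with 60 TOP.
- **Counting.** Multinomial across genes at fixed depth (default 10⁶ per
  library) — library sizes are exact, which is precisely the regime the
  binomial-partitioning threshold assumes. `simulate_counts` exposes the
  count-level law directly; the read-level simulators assign genes from the
  same multinomial.
- **Footprints.** Lengths 26–34 nt peaked at 30. Within a gene a read is
  either a start-peak read (point mass at −12 nt, i.e. a P-site-on-AUG
  ribosome with a 12-nt 5' flank, relative weight `start_peak_fold` = 20
  against 1 per body position) or a CDS-body read on a uniformly drawn
  codon with frame offset 0 with probability q (`frame0_bias`, default
  0.85) and ±1 with (1−q)/2 each. The dwell peak is placed at a
  configurable 5' offset because only the peak position, not its mechanism,
  matters downstream. mRNA-Seq fragments are uniform over the extended
  reference with no frame structure.
- **Panel.** Predictors Gaussian around per-group means following the
  qualitative trajectories of the measured panel (transcript burst at 0h,
  Nrf2/Mmp2 induction, Immp2l dip, later Pmpca/Yme1l1 rise); the response
  is a planted linear combination (defaults Pmpca +2.81, Immp2l −3.32,
  Nrf2 −0.59, Mmp2 +0.275, others 0) plus Gaussian noise.

What the generator does *not* model: nucleotide sequence (no FASTA, no
adapter or rRNA contamination), codon-specific dwell times, UTR/isoform
structure, overdispersion beyond the lognormal-mouse layer, batch or lane
effects. Passing tests therefore certify the statistical machinery — the
estimators recover what was planted under the stated noise model — not
robustness to artefacts absent from that model.

## Determinism and numerics

All randomness flows from one integer seed through purpose-keyed
`SeedSequence` streams (CRC32 of the purpose tokens), so stages can be
rerun in isolation and identical configs give byte-identical outputs. Ties
in the KS statistic are handled by right-continuous ECDFs; two identical
degenerate samples give D = 0, p = 1. RPM requires positive library sizes
and errors naming the offending sample. Metagene normalisation errors out
when the window is empty; genes shorter than the window are excluded, not
padded.

## Problem sizes

The test suite and acceptance script run the method at desk scale, chosen
to keep every statistical check comfortably powered: 10⁴ genes for the
counting-noise calibration, 4000 genes × 1.5·10⁶ reads for threshold
recovery, 10⁵ reads for periodicity, 100 seeds × 4·10⁴ reads for the peak
detector and its null, 100–400 seeds of 1010-gene × 10⁶-read count tables
for the TE-shift power and null calibration, and 100 seeds of the n = 18
panel for elimination order.

## Validating against deposited data

The pipeline consumes any aligned-read TSV/SAM in the transcript-space
convention above. To validate against a deposited ribosome-profiling
study (e.g. GEO accession GSE69699): download the runs, align to CDS
references extended 25 nt upstream of the AUG keeping best hits only,
export (gene, 5'-position, length) records, then run `riboshift qc`,
`riboshift threshold` on the footprint replicate pair, and `riboshift te`
with a TOP-gene-flagged annotation. No downloader is bundled.
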