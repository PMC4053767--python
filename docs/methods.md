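# Methods

## Coordinate model and reference construction

All analysis happens in transcript coordinates (0-based, half-open).
Genomic annotations (Ensembl-dialect GTF or BED12 with thickStart/thickEnd
as the CDS) are flattened once at load: exons are concatenated 5'→3' with
the strand resolved, and the CDS span is projected onto the spliced
transcript, giving a 5'UTR of length `cds_start`, a CDS of
`cds_end − cds_start`, and a 3'UTR of `length − cds_end`. Protein-coding
records without a CDS are skipped with a warning; a transcript whose FASTA
sequence length disagrees with its annotated length is an error, because a
silent mismatch would corrupt motif scanning.

Each gene is represented by a single isoform: the one with the longest CDS;
among CDS ties, the one with the longest *total* UTR; remaining ties break
lexicographically on transcript id so the choice is deterministic and
independent of input order. "Longest UTR" is interpreted as total
(5' + 3') UTR length — choosing 3'UTR alone changes the pick only for exact
CDS ties with opposing UTR asymmetries, which are rare in curated
annotations. rRNA transcripts (biotype `rRNA`) are carried so that
contaminant alignments have a reference to land on, but they are flagged,
given no CDS, and excluded from every per-gene analysis and from all FPKM
denominators.

## Quantification

Reads come from transcript-space SAM/BAM. Primary mapped records are kept;
uniqueness is taken from the NH tag when present (NH = 1), otherwise from a
mapping-quality threshold (default MAPQ ≥ 10, configurable). Counting rules:

- RNA-Seq: every unique read on the transcript counts; feature length for
  FPKM is the transcript length.
- Ribo-Seq: a unique read counts iff its 5' end offset lies in
  `[cds_start, cds_end)`; feature length is the CDS length. Membership is
  judged on the 5' end alone — no P-site offset is applied — which makes
  the counting rule consistent with the frame statistic computed on read
  starts and avoids an offset calibration the rest of the analysis never
  uses.
- The FPKM denominator for *both* assays is the sample's total of unique,
  non-rRNA, transcript-mapped reads. Restricting the Ribo denominator to
  CDS-mapped reads would rescale all Ribo FPKM by a common factor
  (cancelling in ΔTE but shifting TE itself); using the common denominator
  keeps per-sample totals comparable across assays.

FPKM below 1.0 is floored to 1.0 before any logarithm. The floor damps fold
changes of barely-detected transcripts; together with the coverage filter
(≥ 40 reads in both assays in at least one condition, replicates pooled by
summing counts) it keeps the low-abundance tail from dominating selection.

Replicates within an (assay, condition, batch) cell are averaged on the
log2 floored FPKM scale for all condition-level values; the 40-read filter
is the only place replicate counts are summed.

## QC statistics

Three footprint-library diagnostics: the frame distribution (fraction of
CDS reads whose 5' end falls in frame 0/1/2 relative to the start codon),
region densities (reads per kb of aggregate 5'UTR, CDS, 3'UTR) with the
3'UTR/CDS density ratio as a depletion score, and the Pearson correlation
of log2 floored FPKM between replicate pairs. Genuine footprint libraries
show a dominant frame-0 fraction and near-zero 3'UTR depletion scores;
RNA-Seq libraries show a flat frame distribution, which the test suite
checks as a negative control.

## Differential analysis

Fold changes are computed strictly within batch: each test condition is
compared to the control profiled in the same sequencer run, and
`ΔTE = ribo_log2fc − expr_log2fc` holds by construction. A batch without a
control is a hard error.

Selection uses an abundance-dependent threshold
`θ(a) = t_inf + slope/√a`, with `a` the geometric mean of condition and
control floored RNA FPKM. `t_inf` defaults to log2 1.5 ≈ 0.585 — the same
1.5-fold asymptote the variable-subset rule uses — and `slope` defaults to
4.0, chosen so the threshold at the FPKM floor (4.585) demands ~24-fold
changes from barely-covered transcripts while decaying to the asymptote by
a few hundred FPKM; the √a form mirrors the Poisson standard error of a
count-derived log ratio. Both parameters are exposed, and
`calibrate_slope` adjusts the slope by bisection to hit a target selection
fraction for users who want to mimic a particular study-scale selection
rate (e.g. ~29% of covered transcripts). Selection is deliberately
threshold-based; no p-values or multiple-testing correction enter, and a
count-model significance test for differential TE is out of scope.

## Clustering

Responsive transcripts contribute a profile of condition-level log2 floored
RNA FPKM followed by the Ribo values in the same condition order (the
control column averages its per-batch controls). Rows are standardized to
mean 0, SD 1 (sample SD, ddof = 1); constant rows are removed since their
standardization is undefined. Partitioning is k-means with k-means++
initialization, Euclidean distance and 20 restarts keeping the best
objective; given a seed the partition is deterministic. Labels are
canonicalized by descending cluster size (ties by first member id), so runs
are comparable. Cluster summaries report the per-point mean and population
SD (a singleton cluster has SD 0, with a warning). The default k of 13 in
the pipeline configuration echoes the 5 + 4 + 2 + 2 pattern structure of
the emulated study but carries no optimality claim; k is a parameter.

## Gene-set statistics

Enrichment of a set within a cluster is the hypergeometric upper tail
P(X ≥ overlap) after intersecting both with the analysis universe.
Distribution shifts are two-sided Wilcoxon rank-sum tests of the set's fold
changes (expression or ΔTE) against all other genes in the dataset, with
the exact null used when the smaller group has ≤ 25 members and the data
are tie-free, and the tie-corrected normal approximation otherwise; the
reported direction is the sign of the median difference. The variable-
subset rule retains set members whose maximal |log2FC| across all
conditions reaches log2 1.5.

The 5'-TOP caller operationalizes the classical TOP consensus: a C at the
cap-proximal position followed by an uninterrupted pyrimidine run of at
least `min_run` (default 5) bases in total. This targeted scanner — plus an
optional 6-mer over-representation report (per-k-mer hypergeometric with
Bonferroni correction) — is a deliberate simplification of de novo motif
discovery and is not a motif-finding algorithm.

## The simulator

The generator emulates the statistical structure the analysis assumes, not
sequencing chemistry. Per gene it draws a 5'UTR of 50–200 nt, a CDS of
100–500 codons and a 3'UTR of 100–500 nt of uniform random sequence;
optionally 1–3 decoy isoforms with strictly shorter CDS exercise
representative selection. Baseline abundances are lognormal (σ = 1).
Condition responses come from archetypes — per-condition expression and TE
multiplier vectors with a gene fraction each; the defaults place 30% of
genes in seven patterns (RNA induction specific to quiescence, senescence
or transformation; RNA repression of cell-cycle-like and ribosome-
biogenesis-like sets; TE repression of a ribosomal-protein-like set, which
also receives a planted 5'-TOP start of 6–12 pyrimidines; and a TE-up
pattern), with effect sizes of 2–4-fold matching the magnitude of the
strongest observed responses. Two batches each carry their own control
(batch 2 at 1.3× depth), two replicates per sample, 2M reads per library by
default.

Reads are realized as gamma-Poisson (negative-binomial) counts per
transcript with dispersion 0.003 — low, technical-scale overdispersion
consistent with same-run replicate correlations above 0.95 — then placed:
RNA reads of 50 nt uniform over the transcript; footprints of 30–33 nt
(weights 0.15/0.35/0.35/0.15) with 5' ends in the CDS at frame 0 with
probability 0.85 (else frames 1/2 equally), except a 4% 5'UTR and 1% 3'UTR
leak; 5% of each footprint library goes to five rRNA transcripts; 2% of
records are flagged as multimappers (NH = 2) and ignored downstream.
Everything derives from one integer seed and regenerates byte-identically.

What the simulator does **not** model — and hence what passing tests do not
establish about real data: sequencing errors and mapping ambiguity (
multimapping is only a flag), P-site offsets and codon-level pausing,
isoform-level expression mixtures (decoys receive no reads), biological
replicate variability beyond count overdispersion, batch effects beyond a
depth multiplier, and nucleotide composition biases.

## Numerical and design notes

- **Compositional normalization.** FPKM is a relative measure: if the
  planted multipliers change a library's total expected output, every
  gene's measured fold change shifts by the log of that total. This is a
  property of the assay, not a bug; the archetype defaults therefore
  induce a small (~0.1 log2) compositional offset on flat genes in strongly
  induced conditions. The TE-recovery experiment in the acceptance script
  uses composition-balanced class fractions (expected mean TE multiplier
  exactly 1: 4/15 at ×0.25, 1/15 at ×4) so that it measures estimator error
  rather than this offset, and the batch-pairing unbiasedness test uses an
  all-flat design for the same reason.
- **Degenerate inputs.** Empty libraries (mapped total 0) are errors;
  zero-CDS-read frame distributions and zero-length-3'UTR depletions are
  reported as missing rather than 0/0; constant replicate vectors yield a
  missing correlation with a warning.
- **Problem sizes.** The test suite and acceptance script run the recovery
  experiments at 1,000–2,000 genes and 0.3–2M reads per library — the
  depths at which the per-gene estimates are count-noise limited in the
  same way study-scale data are, while a full run stays within a few
  minutes on one CPU.
- **Tolerances.** Exact oracles (hand arithmetic, brute-force counting,
  combinatorial enumeration) are compared at 1e-12 relative or exactly;
  stochastic recoveries use pre-registered bands (frame-0 within its 99%
  binomial CI, ΔTE RMSE < 0.25, ARI ≥ 0.8, Wilcoxon null rejection in
  [0.03, 0.07]) evaluated on seeded runs.
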