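# Methods

`amplimeth` implements a quantitative pipeline for promoter CpG-island
methylation of the TRAIL death-receptor genes *DR4* (TNFRSF10A) and *DR5*
(TNFRSF10B): calling per-CpG methylation from bisulfite amplicon
sequencing reads, classifying samples by methylation and TRAIL-sensitivity
thresholds, associating methylation with expression and TRAIL response in
a cell-line panel, and aggregating 450k-array-style cohort methylation.
Because the raw reads and cohort matrices of the original assays are not
shipped with the package, every input can be produced by the synthetic
generators in `amplimeth.simulate`, which are first-class, tested code.

## Amplicon model and in-silico bisulfite PCR

An amplicon is the unconverted genomic top strand (primer inclusive,
0-based half-open coordinates) plus the offsets of the C of every CG
dinucleotide. Bisulfite primers live in converted space and must contain
no CG, so that primer binding — and hence amplification — is independent
of template methylation; `validate_primer` enforces this and the shipped
DR4/DR5 primer pairs satisfy it.

`in_silico_pcr` fully converts the top strand (every C→T; legitimate
precisely because the primers are CG-free), finds the leftmost
forward-primer site with at most `max_mismatches` mismatches (default 0;
N never matches), then the nearest downstream site of the
reverse-complemented reverse primer under a product-size cap (default
2000 bp). More than one product under the cap is an
`AmbiguousAmplificationError`. The amplicon is mapped back to the
unconverted sequence and its CpG offsets computed there. A
`strand="bottom"` search runs the identical procedure on the reverse
complement and maps coordinates back.

The genome assembly and coordinates of the real amplicons are not part of
the packaged data; `simulate.synthetic_promoter` instead builds a
*synthetic* promoter stand-in per gene — a generated GC-rich backbone with
the real primer pair embedded — reproducing the assay geometry exactly: a
136-bp product containing 6 CpG sites (DR4) and a 212-bp product
containing 13 CpG sites (DR5). Against the real genome the same
`in_silico_pcr` call applies unchanged; only the template differs.

## Read simulator

`simulate_reads` models the bisulfite amplicon assay per read:

- strand ~ Bernoulli(`frac_top_strand`, default 0.5);
- each CpG methylation state ~ Bernoulli(profile_i), independent across
  sites within a read (per-site levels within a sample are near-uniform
  in this assay, so epiallele correlation is not modelled);
- an unmethylated or non-CpG C converts to T with probability `c`
  (default 0.995); a methylated CpG C converts inappropriately with
  probability `e_m` (default 0.005);
- uniform substitution errors at `subst_error` (default 0.005/base);
  indels — the characteristic homopolymer failure of the original
  semiconductor sequencing chemistry — are not modelled;
- bottom-strand reads are emitted in sequencing orientation (reverse
  complement of the converted bottom strand), so they align to the
  top-strand amplicon under a G→A-tolerant model;
- qualities are constant Q30 (the caller ignores them).

Reads are full amplicon length. The truth table records each read's
strand and drawn per-site states, which is what makes exact
caller-vs-truth tests possible. Everything is driven by one
`numpy.random.default_rng(seed)` stream with a fixed draw order, so equal
seeds give byte-identical FASTQ output.

The conversion and error rates are stipulated defaults, not values fitted
to any particular run of the assay.

## Methylation caller

Each read is globally aligned (Biopython `PairwiseAligner`) against the
unconverted amplicon under two asymmetric substitution models: top-strand
model scores reference C vs read C or T as a match; bottom-strand model
scores reference G vs read G or A as a match. Match +1, mismatch −1,
linear gap −2, end gaps free (partial reads are not charged for reference
overhang); the higher-scoring model decides the strand, ties going to
top.

Per read and CpG site: top strand C→M, T→U, anything else (including a
gap) →N; bottom strand G→M, A→U, else N. Conversion efficiency is the
converted fraction of non-CpG reference C (top) / G (bottom) positions —
these are assumed unmethylated, so the statistic estimates per-read
bisulfite conversion. Identity is the matching fraction of aligned
columns whose reference base is not bisulfite-ambiguous under the chosen
model.

QC (defaults; the original vendor plug-in documents none, so these are
the package's own): identity ≥ 0.90, conversion ≥ 0.90, length ≥ 50.
A failing read is counted under the first failing rule in that order.
Site summaries tally M and U ignoring N (per site, not per read — this
maximizes usable coverage), report percent = 100·M/(M+U), and mark sites
with coverage < `min_coverage` (default 100) as missing. The amplicon
mean is the **unweighted** mean over passing sites, matching the "mean
percent methylation of N CG dinucleotides" convention; it is not
coverage-weighted. No conversion-bias correction is applied: with
conversion rate c, an unmethylated site reads ≈(1−c)·100 percent, i.e.
≈0.5% at the defaults. This bias is visible in the examples and is
documented rather than corrected, because the assay convention reports
raw percents.

## Classification thresholds

On mean percent methylation: the (DR4%, DR5%) plane is split at 1% into
UNMETHYLATED (both <1), DR4-preferentially unmethylated (DR4 <1, DR5 ≥1),
DR5-preferentially unmethylated (DR4 ≥1, DR5 <1), and METHYLATED (both
≥1); `highly_methylated` flags both ≥10%. Single-gene bands are [0,1)
unmethylated, [1,10) weak, [10,100] high. The 10% boundary is treated as
inclusive (≥10) uniformly, matching the cohort analysis that drives the
headline counts. TRAIL sensitivity partitions percent inhibition at ≥80
(sensitive) and <25 (resistant), intermediate between. Percent inhibition
is 100·(1 − treated/untreated counts), negative values retained (clipped
at −100) so rank tests see the full ordering; RFI is the specific/control
MFI ratio.

## Statistics

Correlations are Spearman rank correlations computed on log10 percent
methylation with a 0.1% floor — below roughly 1/coverage (100× default) a
percent is not distinguishable from zero, and the floor only ties values
at or under it because Spearman is invariant to strictly increasing
transforms. The squared rho is reported as R², following the convention
of the assay's figure captions. Mann–Whitney U uses exact enumeration for
tie-free samples with n1+n2 ≤ 10 and the tie-corrected normal
approximation otherwise; Fisher's exact test is two-sided
(hypergeometric, tables no more probable than observed); the chi-square
test is Pearson's without continuity correction. All tests are two-sided;
no multiple-testing correction is applied (none is part of the procedure
being reproduced). The scipy implementations stand behind this module's
interface; the test suite checks them against independent brute-force
enumerations rather than trusting either side.

## Cell-line panel generator

Thirty-two lines in the karyotype layout of the modelled panel (9
MLL-rearranged, 6 BCR-ABL1, 7 TCF3-PBX1, 4 TCF3-HLF, 2 ETV6-RUNX1, 2
MEF2D-rearranged, 2 DUX4-rearranged). Per line and gene, methylation is
drawn from a two-mode prior: hypermethylated with a per-group probability
(1 for MLLr/MEF2Dr DR4, 0 for TCF3-HLF and ETV6-RUNX1, intermediate
elsewhere), around mean 0.70 — high enough that a line methylated on both
genes loses most receptor availability and lands TRAIL-resistant — or
essentially unmethylated around 0.004. Both genes share one uniform for
the mode choice, making the indicators nested and the genes' methylation
positively correlated, as observed across lines.

Phenotype links: log10 relative expression = α − β·m + N(0, σ_E) with
α=0, β=2, σ_E=0.15 (fully methylated ⇒ ~100-fold silencing); RFI = 1 +
9·(1−m)·lognormal noise; availability s = max(1−m_DR4, 1−m_DR5) — either
death receptor suffices for killing — and percent inhibition =
100·logistic(θ·(s−s0)) + N(0, σ_T) with θ=10, s0=0.5, σ_T=3, clipped to
[−10, 100].

## Array-cohort generator and aggregation

The diagnostic cross-section has 459 samples in the subtype proportions
of the modelled cohort (187 high-hyperdiploid, 164 ETV6-RUNX1, 23
TCF3-PBX1, 10 iAMP21, 20 dic(9;20), 19 BCR-ABL1, 28 MLL-rearranged, 5
hypodiploid, 3 polyploid), plus remission and normal control samples and
24 diagnosis/relapse pairs (pairs reuse diagnostic samples, keeping the
cross-section at exactly 459). Default per-subtype hypermethylation
probabilities are the empirical frequencies of ≥10% promoter methylation
in that cohort (e.g. DR5: 5/20 for dic(9;20), 10/28 for MLLr, 1/5 for
hypodiploid; zero where none was seen), with DR4 and DR5 indicators
nested via a shared uniform.

Gene-level beta values are bimodal, as promoter array methylation is:
baseline draws sit around 0.025 (the 2–3% of remission marrow and normal
lymphocytes) with a shared per-sample component — cellularity and global
methylation vary per sample, not per gene — plus per-gene deviation
(sd 0.008), clipped to ≤0.07; hypermethylated draws sit around 0.30,
clipped to ≥0.13. The deliberate gap between the modes means the ≥10%
observable coincides with the generator's truth label, so recovery tests
can demand exact counts. Probe-level values jitter (sd 0.01) around the
gene level; six DR4 and five DR5 probes are annotated TSS200 ∩ CpG
island, alongside decoy probes in other feature groups, island relations
and genes. Relapse samples of unmethylated pairs convert to the
hypermethylated mode with probability 0.2.

Aggregation selects probes annotated to the gene with feature group
TSS200 and island relation Island, averages betas per sample (missing
excluded pairwise; percent = 100·beta), counts samples ≥ a threshold
(default 10%) per subtype, reports per-pair diagnosis→relapse deltas with
an upregulation flag (delta > 5 percentage points), and correlates the two
genes' log-floored percents. The annotation is consumed as a generic TSV
with the standard manifest column semantics (probe, gene, UCSC feature
group, relation to island); converting a vendor manifest means keeping
those four columns.

## What the synthetic data does and does not show

The generators reproduce the *structure* of the study — amplicon
geometry, conversion chemistry, strand mixture, karyotype-dependent
hypermethylation frequencies, bimodal array betas, silencing and
receptor-availability links. They do not reproduce PCR bias, homopolymer
indels, epiallele structure, array normalization artifacts, tumor-purity
dilution, or the actual (unreleased) per-line measurements; passing tests
therefore demonstrate correctness of the computational procedure under
the modelled assay, not re-derivation of the original study's printed
correlation values, which depend on data the package does not contain.

## Numerical and design notes

- Problem sizes in tests and the acceptance script (1,000–2,000 reads per
  sample, 10–20 replicate seeds, a 0.1-resolution classification sweep,
  full Fisher enumeration to table total 20) were chosen so each check is
  statistically meaningful at three-binomial-SE tolerances while the whole
  suite stays quick on a single CPU.
- Ties in strand-model score go to top; ties in ranks use average ranks.
- Degenerate inputs raise typed errors: non-DNA characters, CG-containing
  primers, absent primer sites, ambiguous products, profile/amplicon
  length mismatches, empty FASTQ, all-sites-below-coverage, constant
  vectors in correlation, zero-margin contingency tables, broken
  diagnosis/relapse pairs.
- Determinism: every stochastic component takes a seed; the pipeline
  writes a manifest with the config hash, and re-running a config+seed
  reproduces every output byte-for-byte.
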