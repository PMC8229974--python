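# amplimeth

Promoter CpG-island methylation of the TRAIL death receptors **DR4**
(TNFRSF10A) and **DR5** (TNFRSF10B), measured from bisulfite amplicon
sequencing and from HumanMethylation450-style array cohorts.

TRAIL on cytotoxic T cells kills B-cell precursor acute lymphoblastic
leukemia (BCP-ALL) cells through DR4/DR5, so silencing of these receptors
by promoter CpG-island hypermethylation is a candidate mechanism of
resistance to T-cell immunotherapies. `amplimeth` is for analysts who
want to quantify that methylation and its phenotype associations: it
re-implements the full computational path from bisulfite reads to per-CpG
percent methylation, classifies samples by methylation and
TRAIL-sensitivity thresholds, runs the association statistics, and
aggregates array cohorts by karyotype subtype — with synthetic-data
generators for every input, so the whole pipeline runs and is tested
without any external download.

## The core quantities

- **Per-site percent methylation.** Reads are aligned to the unconverted
  amplicon under bisulfite-aware asymmetric models (top strand: reference
  C matches read C/T; bottom: reference G matches read G/A). At each CG
  dinucleotide a retained C (or G on the bottom strand) is a methylated
  call M, a converted T (A) an unmethylated call U, and
  percent = 100·M/(M+U). The amplicon summary is the unweighted mean over
  sites; per-read conversion efficiency (non-CpG cytosines read as
  converted) and identity gate QC.
- **Classification.** (DR4%, DR5%) partitioned at 1% into
  unmethylated / DR4-preferentially unmethylated / DR5-preferentially
  unmethylated / methylated, with a highly-methylated flag at ≥10% on
  both; percent inhibition by rhsTRAIL (100·(1 − treated/untreated))
  partitioned at ≥80 (sensitive) and <25 (resistant).
- **Associations.** Spearman rank correlation (reported with R² = ρ²) of
  log10 percent methylation (floored at 0.1%) against expression,
  cell-surface RFI and TRAIL inhibition; Mann–Whitney between category
  groups; Fisher/chi-square for category tables.
- **Cohort aggregation.** Gene methylation per array sample =
  100 × mean beta over probes annotated TSS200 ∩ CpG island for the gene
  (6 probes for DR4, 5 for DR5); per-subtype counts of samples ≥10%;
  paired diagnosis/relapse deltas.

See `docs/methods.md` for the full model, parameter defaults and
limitations.

## Worked example

Simulate reads from the 6-CpG DR4 amplicon with a known methylation
profile and recover it (`examples/02_simulate_and_call.py`):

```python
from amplimeth import (CallerParams, MethylationProfile, ReadSimParams,
                       quantify, simulate_reads)
from amplimeth.simulate import synthetic_amplicon

amplicon = synthetic_amplicon("DR4")          # 136 bp, 6 CpG sites
truth = [0.0, 0.0, 0.30, 0.30, 0.90, 0.94]
reads, _ = simulate_reads(amplicon, MethylationProfile(truth),
                          ReadSimParams(n_reads=2000, seed=7))
result = quantify(reads, amplicon, CallerParams(min_coverage=100))
```

prints (via the example script):

```
site  truth%  called%  coverage
   0     0.0     0.90      1989
   1     0.0     0.45      1990
   2    30.0    29.67      1992
   3    30.0    30.40      1997
   4    90.0    89.51      1993
   5    94.0    92.68      1995
mean percent methylation: 40.60% (truth 40.67%)
reads passing QC: 2000/2000 (filtered: {'identity': 0, 'conversion': 0, 'length': 0})
```

Every site is recovered within a couple of percentage points; the ~0.5%
at truly unmethylated sites is the incomplete bisulfite conversion rate
(c = 0.995) showing through, as expected for raw uncorrected percents.

The other examples cover in-silico bisulfite PCR
(`examples/01_in_silico_pcr.py`: 136 bp / 6 CpGs for DR4, 212 bp / 13
CpGs for DR5), the 32-line panel with classification and association
statistics (`examples/03_panel_associations.py`), and the 459-sample
array cohort (`examples/04_cohort_summary.py`, where hypermethylated
samples concentrate in dic(9;20), MLL-rearranged and hypodiploid
karyotypes and the two genes' methylation correlates positively).

A thin CLI wraps the same functions:

```sh
amplimeth simulate-panel --seed 1 --out panel.tsv
amplimeth associate --panel panel.tsv --out associations.tsv
amplimeth run --seed 1 --outdir run1/     # full pipeline + manifest
```

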