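"""Array-style cohort: TSS200+island probe aggregation, per-subtype
hypermethylation counts and paired diagnosis/relapse changes.

Simulates a 459-sample diagnostic BCP-ALL cohort (per-subtype
hypermethylation frequencies, shared-baseline beta values, 24 paired
relapses), selects the 6 DR4 / 5 DR5 promoter probes, and summarizes.
"""

from amplimeth import (
    CohortGenParams,
    cohort_correlation,
    gene_methylation,
    paired_delta,
    select_probes,
    simulate_array_cohort,
    subtype_summary,
)

beta, samples, annotation, _ = simulate_array_cohort(CohortGenParams(seed=1))
diagnostic = samples[samples.phase == "diagnosis"]

pct = {}
for gene, symbol in (("DR4", "TNFRSF10A"), ("DR5", "TNFRSF10B")):
    probes = select_probes(annotation, symbol)  # TSS200 + CpG island
    pct[gene] = gene_methylation(beta, probes)
    summary = subtype_summary(pct[gene].loc[diagnostic.sample_id], samples)
    print(f"{gene} ({len(probes)} probes), samples >=10% methylated by subtype:")
    print(summary[summary.n_ge_threshold > 0].to_string(index=False), "\n")

corr = cohort_correlation(pct["DR4"].loc[diagnostic.sample_id],
                          pct["DR5"].loc[diagnostic.sample_id])
print(f"DR4 vs DR5 methylation: rho={corr.rho:.3f}, R^2={corr.r_squared:.3f}, "
      f"p={corr.p_value:.2g} (n={corr.n})")

pairs = paired_delta(pct["DR4"], samples, gene="DR4")
up = pairs[pairs.upregulated]
print(f"paired diagnosis/relapse (DR4): {len(pairs)} pairs, "
      f"{len(up)} upregulated at relapse by >5 points")

# Hypermethylation concentrates in the unfavourable karyotypes (dic(9;20),
# MLL-rearranged, hypodiploid) while hyperdiploid and ETV6-RUNX1 samples
# stay near the ~2-3% remission baseline.
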