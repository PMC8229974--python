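"""In-silico bisulfite PCR: locate the DR4/DR5 promoter amplicons.

Builds a synthetic promoter region for each gene (a stand-in with the
real CG-free bisulfite primer pair embedded), fully converts the top
strand, finds the primer sites and reports the primer-inclusive amplicon
mapped back to unconverted coordinates.
"""

from amplimeth import in_silico_pcr
from amplimeth.amplicon import DR4_PRIMERS, DR5_PRIMERS
from amplimeth.simulate import synthetic_promoter

for gene, primers in (("DR4", DR4_PRIMERS), ("DR5", DR5_PRIMERS)):
    region = synthetic_promoter(gene)
    amp = in_silico_pcr(region, *primers, name=gene)
    _, _, start, end = amp.source_coords
    print(f"{gene}: {len(amp)} bp amplicon at [{start}, {end}) "
          f"with {amp.n_sites} CpG sites at offsets {list(amp.cpg_offsets)}")

# The amplicon lengths and CpG counts are the assay geometry: a methylation
# profile for DR4 is a vector of 6 per-site fractions, for DR5 one of 13.
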