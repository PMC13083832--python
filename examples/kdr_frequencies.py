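"""Per-population kdr allele frequencies with triallelic decomposition.

The codon-402 locus carries two alternate alleles (g>t and g>c) encoding the
same Val->Leu change; each is reported separately plus a cumulative row, the
convention needed to compare 402L carriage against 1527T.
"""

from kdrkit.effects_freqs import allele_frequencies, filter_by_frequency
from kdrkit.diplotypes import default_kdr_config
from kdrkit.simgen import CohortGroupSpec, KdrCohortSpec, simulate_kdr_cohort

cfg = default_kdr_config()
spec = KdrCohortSpec(
    groups=[
        CohortGroupSpec("coluzzii", "Bana", 70,
                        {"FL1T": 0.4, "FL2T": 0.08, "LVI": 0.52}),
        CohortGroupSpec("coluzzii", "Nassan", 50, {"FL1T": 0.55, "LVI": 0.45}),
    ],
    n_background_sites=0,
    seed=23,
)
cohort = simulate_kdr_cohort(spec)

table = allele_frequencies(cohort.genotypes, cohort.samples,
                           grouping="taxon_site", named_alleles=cfg)
kdr = table[table["pos"] == cfg.loci[1].pos]  # the triallelic 402 site
print(kdr.to_string(index=False))
print()
common = filter_by_frequency(table, min_freq=0.05)
print(f"alleles above 0.05 in at least one group: "
      f"{common.attrs['n_surviving_alleles']}")
# The cumulative 402L row (g>t + g>c) tracks the 1527T frequency when the
# two sites travel on the same haplotypes.
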