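"""Simulate a synthetic An. gambiae s.l. cohort with known kdr backgrounds.

Two coluzzii villages segregating the FL1T (995F + 402L(g>t) + 1527T) and
wild-type LVI backgrounds, plus a gambiae s.s. group nearly fixed for FVI —
the haplotype structure under which every downstream stage is exercised.
"""

from kdrkit.simgen import CohortGroupSpec, KdrCohortSpec, simulate_kdr_cohort

spec = KdrCohortSpec(
    groups=[
        CohortGroupSpec("coluzzii", "Bana", 60, {"FL1T": 0.45, "FL2T": 0.05, "LVI": 0.5}),
        CohortGroupSpec("coluzzii", "Nassan", 40, {"FL1T": 0.6, "LVI": 0.4}),
        CohortGroupSpec("gambiae_ss", "Gama", 50, {"FVI": 0.95, "LVI": 0.05}),
    ],
    n_background_sites=40,
    seed=7,
)
cohort = simulate_kdr_cohort(spec)

print(f"samples:  {cohort.genotypes.n_samples}")
print(f"variants: {cohort.genotypes.n_variants} "
      f"({sum(v.is_multiallelic for v in cohort.genotypes.variants)} multiallelic)")
print("\ntruth diplotype counts (first group):")
sub = cohort.truth[cohort.truth.sample_id.str.contains("Bana")]
print(sub["group_label"].value_counts().to_string())
# The counts follow Hardy-Weinberg at the haplotype level: with FL1T at 0.45
# and LVI at 0.5 in Bana, FL1T/LVI heterozygotes are the largest class.
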