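"""Classify kdr diplotypes and summarize group frequencies.

A diplotype is the unordered pair of multi-locus haplotype labels (one
symbol per kdr locus: 995 L/F/S, 402 V/L1/L2, 1527 I/T). Phased input is
read directly; unphased input is resolved by enumeration plus cohort-EM.
"""

import numpy as np

from kdrkit.diplotypes import (
    call_diplotypes,
    default_kdr_config,
    diplotype_frequencies,
    pca_dosage,
)
from kdrkit.simgen import CohortGroupSpec, KdrCohortSpec, simulate_kdr_cohort

cfg = default_kdr_config()
spec = KdrCohortSpec(
    groups=[
        CohortGroupSpec("coluzzii", "Bana", 80,
                        {"FL1T": 0.35, "FL2T": 0.08, "LVI": 0.47, "FVI": 0.1}),
        CohortGroupSpec("gambiae_ss", "Gama", 60, {"FVI": 0.97, "LVI": 0.03}),
    ],
    n_background_sites=0,
    seed=29,
)
cohort = simulate_kdr_cohort(spec)

# unphased route: enumeration, EM where several pairs remain compatible
calls, excluded = call_diplotypes(cohort.genotypes, cfg)
sources = {s: sum(c.phase_source == s for c in calls)
           for s in {"unambiguous", "em_resolved"}}
print(f"classified {len(calls)} samples ({sources}), excluded {len(excluded)}")

truth = dict(zip(cohort.truth["sample_id"], cohort.truth["group_label"]))
acc = np.mean([truth[c.sample_id] == c.group_label for c in calls])
print(f"agreement with generator truth: {100 * acc:.1f}%\n")

table = diplotype_frequencies(calls, cohort.samples, grouping="taxon")
print(table.to_string(index=False))

coords, evr, _ = pca_dosage(cohort.genotypes, n_components=2)
print(f"\nPCA on kdr dosages: PC1 explains {100 * evr[0]:.1f}% of variance")
# Groups sharing a haplotype background (e.g. FVI/FVI in both taxa) land on
# the same side of PC1; fully wild-type LVI/LVI samples sit at the far end.
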