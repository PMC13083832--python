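"""Copy-number variant summaries for detoxification genes.

Consumes a samples × genes integer copy-number table (as produced upstream
by coverage-depth callers), classifies amplifications and deletions against
sex-aware baseline ploidy and reports per-population frequencies.
"""

import pandas as pd

from kdrkit.cnv_summary import classify_cnv, cnv_frequencies
from kdrkit.simgen import (
    CNVSimSpec,
    CohortGroupSpec,
    KdrCohortSpec,
    simulate_cnv_table,
    simulate_kdr_cohort,
)

cohort = simulate_kdr_cohort(
    KdrCohortSpec(
        groups=[
            CohortGroupSpec("coluzzii", "Bana", 70, {"LVI": 1.0}),
            CohortGroupSpec("gambiae_ss", "Gama", 50, {"FVI": 1.0}),
        ],
        n_background_sites=0,
        seed=41,
    )
)
genes = pd.DataFrame(
    [
        {"gene_id": "COEAE60", "chrom": "2L", "start": 28548433, "end": 28550000, "family": "COE"},
        {"gene_id": "GSTD5", "chrom": "2R", "start": 3489405, "end": 3490000, "family": "GST"},
        {"gene_id": "CYP9K1", "chrom": "X", "start": 15240572, "end": 15242000, "family": "CYP"},
    ]
)
spec = CNVSimSpec(
    genes=genes,
    dists={
        "COEAE60": {"coluzzii": {2: 0.2, 5: 0.5, 12: 0.3}},
        "GSTD5": {"*": {0: 0.8, 2: 0.2}},
        "CYP9K1": {"gambiae_ss": {2: 0.1, 4: 0.9}},
    },
    seed=43,
)
table = simulate_cnv_table(spec, cohort.samples)
calls = classify_cnv(table, cohort.samples)
freq, tallies = cnv_frequencies(calls, cohort.samples, table, grouping="taxon")

print(freq[freq["n_carriers"] > 0].to_string(index=False))
print()
print(tallies.to_string(index=False))
# frequency_pct is carriers / samples assayed; max_copies shows the largest
# amplification seen in the group (up to 12 copies of COEAE60 here), and a
# gene deleted in every sample prints a 100% del frequency.
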