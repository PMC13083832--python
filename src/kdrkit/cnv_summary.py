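"""Classification and frequency summaries of detoxification-gene copy-number
variants (CYP / COE / GST families, plus Ace1).

Copy-number *discovery* happens upstream (coverage-depth callers); this
module consumes integer copy-number tables. A gene copy number above the
baseline ploidy is an amplification (amp), below it a deletion (del); zero
copies is a complete deletion. Baselines are 2 on autosomes and sex-aware on
the X chromosome (2 in females, 1 in males).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from kdrkit.core_io import CopyNumberTable, SampleTable


@dataclass(frozen=True)
class CNVCall:
    sample_id: str
    gene_id: str
    copies: int
    baseline: int
    state: str  # amp | del | normal

    @property
    def complete_deletion(self) -> bool:
        return self.copies == 0


def _baseline(chrom: str, sex: str, unknown_sex_baseline: int | None) -> int | None:
    if chrom.upper() not in ("X", "CHRX"):
        return 2
    if sex == "F":
        return 2
    if sex == "M":
        return 1
    return unknown_sex_baseline


def classify_cnv(
    t: CopyNumberTable,
    samples: SampleTable,
    unknown_sex_baseline: int | None = None,
) -> list[CNVCall]:
    """One amp/del/normal call per (sample, gene).

    X-chromosome genes in samples of unknown sex are skipped with a warning
    unless ``unknown_sex_baseline`` supplies a fallback ploidy.
    """
    sex_by_id = dict(zip(samples.df["sample_id"], samples.df["sex"]))
    calls: list[CNVCall] = []
    n_skipped = 0
    genes = t.genes.reset_index(drop=True)
    for si, sid in enumerate(t.sample_ids):
        sex = sex_by_id.get(sid, "unknown")
        for gi, gene in genes.iterrows():
            base = _baseline(str(gene["chrom"]), sex, unknown_sex_baseline)
            if base is None:
                n_skipped += 1
                continue
            c = int(t.copies[si, gi])
            state = "amp" if c > base else ("del" if c < base else "normal")
            calls.append(CNVCall(sid, gene["gene_id"], c, base, state))
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} X-linked sample-gene pair(s) of unknown sex"
        )
    return calls


def cnv_frequencies(
    calls: list[CNVCall],
    samples: SampleTable,
    t: CopyNumberTable,
    grouping: str = "taxon",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group CNV frequency table plus per-chromosome/family gene tallies.

    First frame: one row per (group, gene, state in {amp, del}) with
    frequency = carriers / samples assayed, in percent (2 decimals), plus the
    gene's max copy number within the group. Second frame: per chromosome and
    per family, the number of genes with >= 1 amp carrier and with >= 1 del
    carrier anywhere in the cohort — a gene with both kinds of carriers
    counts in both tallies, but never twice within one tally.
    """
    if not calls:
        raise ValueError("no CNV calls")
    df = pd.DataFrame([c.__dict__ for c in calls])
    meta = samples.df.set_index("sample_id")
    if grouping == "taxon":
        df["group"] = df["sample_id"].map(meta["taxon"])
    elif grouping == "site":
        df["group"] = df["sample_id"].map(meta["site"])
    elif grouping in ("taxon_site", "taxon×site"):
        df["group"] = (
            df["sample_id"].map(meta["taxon"]) + "/" + df["sample_id"].map(meta["site"])
        )
    else:
        raise ValueError(f"unknown grouping: {grouping!r}")
    gene_info = t.genes.set_index("gene_id")

    rows = []
    for (group, gene_id), sub in df.groupby(["group", "gene_id"], sort=True):
        assayed = len(sub)
        max_copies = int(sub["copies"].max())
        for state in ("amp", "del"):
            carriers = int((sub["state"] == state).sum())
            rows.append(
                {
                    "group": group,
                    "gene_id": gene_id,
                    "family": gene_info.loc[gene_id, "family"],
                    "chrom": gene_info.loc[gene_id, "chrom"],
                    "state": state,
                    "n_carriers": carriers,
                    "n_assayed": assayed,
                    "frequency_pct": round(100.0 * carriers / assayed, 2),
                    "max_copies": max_copies,
                    "n_complete_deletion": int((sub["copies"] == 0).sum()),
                }
            )
    freq = pd.DataFrame(rows)

    # cohort-wide gene tallies: which genes have any amp / any del carrier
    state_by_gene = df.groupby("gene_id")["state"].agg(
        has_amp=lambda s: (s == "amp").any(), has_del=lambda s: (s == "del").any()
    )
    state_by_gene = state_by_gene.join(gene_info[["chrom", "family"]])
    tallies = []
    for by in ("chrom", "family"):
        for val, sub in state_by_gene.groupby(by, sort=True):
            tallies.append(
                {
                    "level": by,
                    "key": val,
                    "n_genes_with_cnv": int((sub["has_amp"] | sub["has_del"]).sum()),
                    "n_genes_amp": int(sub["has_amp"].sum()),
                    "n_genes_del": int(sub["has_del"].sum()),
                }
            )
    return freq, pd.DataFrame(tallies)
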