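"""Codon-aware effect annotation against a transcript model, and
per-population allele frequencies with multiallelic decomposition.

Every alternate allele of a coding SNP gets its own effect record, so a
triallelic site like codon 402 (G>T and G>C, both Val→Leu) yields two
records. Frequencies are computed per group with non-missing chromosome
denominators; named multiallelic alleles are reported both separately and as
a cumulative per-site row (e.g. 402L(g>t) + 402L(g>c)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.cluster.hierarchy import leaves_list, linkage, optimal_leaf_ordering
from scipy.spatial.distance import pdist

from kdrkit.core_io import (
    MISSING,
    GeneModel,
    GenotypeMatrix,
    SampleTable,
    VariantRecord,
    revcomp,
)
from kdrkit.diplotypes import KdrAlleleConfig


@dataclass(frozen=True)
class EffectRecord:
    variant_index: int
    allele_index: int  # 1-based alt index (matches GenotypeMatrix coding)
    codon_number: int | None  # transcript numbering; None outside CDS
    ref_aa: str | None
    alt_aa: str | None
    effect: str  # synonymous | nonsynonymous | non_coding


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def annotate_effects(
    variants: list[VariantRecord], model: GeneModel
) -> list[EffectRecord]:
    """Annotate each alt allele of each SNP as synonymous / nonsynonymous /
    non_coding against the transcript model.

    Minus-strand transcripts are handled by complementing genomic alleles
    into transcript orientation before substitution. Indel alleles are
    skipped with a warning.
    """
    if model.cds_seq is None:
        raise ValueError(
            "GeneModel.cds_seq is required for effect annotation; "
            "load the model with a reference FASTA"
        )
    out: list[EffectRecord] = []
    n_skipped = 0
    for vi, v in enumerate(variants):
        if v.chrom != model.chrom:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} not on model chromosome {model.chrom}"
            )
        cds_i = model.cds_index(v.pos)
        for ai, alt in enumerate(v.alts, start=1):
            if len(v.ref) != 1 or len(alt) != 1:
                n_skipped += 1
                continue
            if cds_i is None:
                out.append(EffectRecord(vi, ai, None, None, None, "non_coding"))
                continue
            codon_no, codon_pos = cds_i // 3 + 1, cds_i % 3  # codon_pos 0-based
            codon = model.cds_seq[3 * (codon_no - 1): 3 * codon_no]
            ref_t = v.ref if model.strand == "+" else revcomp(v.ref)
            alt_t = alt if model.strand == "+" else revcomp(alt)
            if codon[codon_pos] != ref_t:
                raise ValueError(
                    f"{v.chrom}:{v.pos}: reference allele {v.ref!r} disagrees "
                    f"with CDS base {codon[codon_pos]!r} in codon {codon_no}"
                )
            mutated = codon[:codon_pos] + alt_t + codon[codon_pos + 1:]
            ref_aa, alt_aa = _translate(codon), _translate(mutated)
            effect = "synonymous" if ref_aa == alt_aa else "nonsynonymous"
            out.append(EffectRecord(vi, ai, codon_no, ref_aa, alt_aa, effect))
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-SNP allele(s)")
    return out


def effects_to_frame(effects: list[EffectRecord]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in effects])


def allele_frequencies(
    g: GenotypeMatrix,
    samples: SampleTable,
    grouping: str = "taxon_site",
    named_alleles: KdrAlleleConfig | None = None,
    effects: list[EffectRecord] | None = None,
) -> pd.DataFrame:
    """Long-form per-group allele-frequency table.

    One row per (group, site, alt allele): frequency = focal-allele count /
    non-missing chromosomes in the group. For sites carrying >=2 alt alleles
    an extra ``cumulative`` row sums the alt-allele frequencies (the
    convention used for the triallelic 402 locus). Groups with zero
    non-missing chromosomes at a site get frequency NaN.

    ``named_alleles`` attaches display labels (e.g. '995F', '402L1') to
    configured kdr loci; ``effects`` attaches amino-acid labels to the rest.
    """
    label_by_site_allele: dict[tuple[str, int, int], str] = {}
    if named_alleles is not None:
        for locus in named_alleles.loci:
            for k, lab in enumerate(locus.alt_labels, start=1):
                label_by_site_allele[(locus.chrom, locus.pos, k)] = f"{locus.name}{lab}"
    aa_by_index: dict[tuple[int, int], str] = {}
    if effects is not None:
        for e in effects:
            if e.codon_number is not None:
                aa_by_index[(e.variant_index, e.allele_index)] = (
                    f"{e.ref_aa}{e.codon_number}{e.alt_aa}"
                )

    groups = samples.group_indices(grouping)
    rows = []
    for key, idx in groups.items():
        gname = "/".join(str(k) for k in key)
        calls = g.calls[:, idx, :]
        flat = calls.reshape(g.n_variants, -1)
        n_chrom = (flat != MISSING).sum(axis=1)
        for i, v in enumerate(g.variants):
            denom = int(n_chrom[i])
            alt_freqs = []
            for k in range(1, v.n_alleles):
                count = int((flat[i] == k).sum())
                freq = count / denom if denom else np.nan
                alt_freqs.append(freq)
                label = label_by_site_allele.get(
                    (v.chrom, v.pos, k), aa_by_index.get((i, k), "")
                )
                rows.append(
                    {
                        "group": gname,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "change": f"{v.ref}>{v.alts[k - 1]}",
                        "aa_label": label,
                        "frequency": freq,
                        "n_chromosomes": denom,
                    }
                )
            if v.is_multiallelic:
                cum = np.nan if denom == 0 else float(np.nansum(alt_freqs))
                rows.append(
                    {
                        "group": gname,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "change": "cumulative",
                        "aa_label": "",
                        "frequency": cum,
                        "n_chromosomes": denom,
                    }
                )
    return pd.DataFrame(rows)


def filter_by_frequency(table: pd.DataFrame, min_freq: float = 0.05) -> pd.DataFrame:
    """Keep an allele row iff its frequency strictly exceeds ``min_freq`` in
    at least one group (cumulative rows are filtered on their own values)."""
    if not len(table):
        return table.copy()
    key_cols = ["chrom", "pos", "change"]
    keep_keys = set(
        map(
            tuple,
            table.loc[table["frequency"] > min_freq, key_cols].itertuples(index=False),
        )
    )
    mask = table[key_cols].apply(tuple, axis=1).isin(keep_keys)
    out = table[mask].reset_index(drop=True)
    out.attrs["n_surviving_alleles"] = len(keep_keys)
    return out


def frequency_matrix(table: pd.DataFrame):
    """Alleles × groups frequency matrix with hierarchical co-clustering.

    Average linkage on Euclidean distances between frequency vectors, rows
    and columns independently; leaf order is made deterministic by sorting
    labels before clustering (ties then resolve by label). Returns
    (matrix, row_order, col_order, row_linkage, col_linkage); single
    rows/columns get identity ordering and a None linkage.
    """
    if not len(table):
        raise ValueError("empty frequency table")
    sub = table[table["change"] != "cumulative"].copy()
    sub["allele"] = (
        sub["chrom"].astype(str)
        + ":"
        + sub["pos"].astype(str)
        + ":"
        + sub["change"]
        + sub["aa_label"].apply(lambda s: f" ({s})" if s else "")
    )
    mat = sub.pivot_table(
        index="allele", columns="group", values="frequency", aggfunc="first"
    ).sort_index(axis=0).sort_index(axis=1)
    mat = mat.fillna(0.0)

    def _order(m: np.ndarray):
        if m.shape[0] < 2:
            return list(range(m.shape[0])), None
        d = pdist(m, metric="euclidean")
        Z = linkage(d, method="average")
        Z = optimal_leaf_ordering(Z, d)
        return list(leaves_list(Z)), Z

    row_order, row_Z = _order(mat.to_numpy())
    col_order, col_Z = _order(mat.to_numpy().T)
    return mat, row_order, col_order, row_Z, col_Z
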