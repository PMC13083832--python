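"""Synthetic-data generators reproducing the statistical structure the
analysis stages assume, so the whole pipeline is testable without any
sequencing download.

Three generators:

* a Kingman coalescent with infinite-sites mutation (no recombination,
  constant population size) for calibrating the diversity estimators
  against closed forms (E[S] = θ·a_{n−1}, E[π] = θ, E[D] ≈ 0);
* a kdr cohort generator: diploid individuals draw two multi-locus
  haplotype labels i.i.d. from a per-(taxon, site) frequency table
  (Hardy–Weinberg at the haplotype level), expanded to allele indices at
  the configured kdr sites plus independent biallelic background sites —
  all linkage structure therefore lives in the haplotype table;
* a copy-number generator drawing per-(sample, gene) integer copies from
  per-taxon distributions with support within 0..12.

One global integer seed feeds a named-substream scheme (one substream per
replicate / population / stage), so adding a population does not perturb
the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kdrkit.core_io import (
    GenotypeMatrix,
    HaplotypeMatrix,
    SampleTable,
    VariantRecord,
)
from kdrkit.diplotypes import KdrAlleleConfig, default_kdr_config


def substream(seed: int, *names) -> np.random.Generator:
    """Named random substream: the same (seed, names) always yields the same
    generator, independent of any other substream."""
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


# ---------------------------------------------------------------------------
# Coalescent
# ---------------------------------------------------------------------------


@dataclass
class CoalescentParams:
    n_haplotypes: int
    theta: float  # scaled mutation rate per locus, 4*N*mu
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_haplotypes < 2:
            raise ValueError("n_haplotypes must be >= 2")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (columns pair into samples)")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


def _one_coalescent(rng: np.random.Generator, n: int, theta: float) -> np.ndarray:
    """One infinite-sites replicate: haplotypes × segregating sites (0/1).

    Lineages coalesce pairwise at rate k(k−1)/2 (time units of 2N
    generations); each branch accumulates Poisson(θ/2 · length) mutations,
    each creating one new segregating column carried by the branch's leaves.
    """
    lineages = [(frozenset([i]), 0.0) for i in range(n)]  # (leaf set, birth time)
    t = 0.0
    columns: list[frozenset[int]] = []
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (leaves_j, birth_j) = lineages.pop(j)
        (leaves_i, birth_i) = lineages.pop(i)
        for leaves, birth in ((leaves_i, birth_i), (leaves_j, birth_j)):
            n_mut = rng.poisson(theta / 2.0 * (t - birth))
            columns.extend([leaves] * n_mut)
        lineages.append((leaves_i | leaves_j, t))
    out = np.zeros((n, len(columns)), dtype=np.int16)
    for s, leaves in enumerate(columns):
        out[list(leaves), s] = 1
    return out


def simulate_coalescent(params: CoalescentParams) -> list[HaplotypeMatrix]:
    """Neutral coalescent replicates as phased haplotype matrices.

    Sites are laid out at positions 1..S on contig 'sim' with ref A / alt T;
    θ = 0 gives zero segregating sites. Identical parameters (incl. seed)
    give identical output; replicate r uses substream (seed, 'coalescent', r).
    """
    reps = []
    sample_ids = [f"sim{i:03d}" for i in range(params.n_haplotypes // 2)]
    for r in range(params.n_replicates):
        rng = substream(params.seed, "coalescent", r)
        mat = _one_coalescent(rng, params.n_haplotypes, params.theta)
        S = mat.shape[1]
        variants = [VariantRecord("sim", p + 1, "A", ("T",)) for p in range(S)]
        reps.append(HaplotypeMatrix(variants, mat.T.copy(), sample_ids, phased=True))
    return reps


# ---------------------------------------------------------------------------
# kdr cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortGroupSpec:
    taxon: str
    site: str
    n_samples: int
    hap_freqs: dict[str, float]
    zone: str = ""

    def __post_init__(self):
        tot = sum(self.hap_freqs.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(
                f"haplotype frequencies for ({self.taxon}, {self.site}) "
                f"sum to {tot}, not 1"
            )


@dataclass
class KdrCohortSpec:
    groups: list[CohortGroupSpec]
    kdr: KdrAlleleConfig = field(default_factory=default_kdr_config)
    n_background_sites: int = 50
    background_freq_range: tuple[float, float] = (0.05, 0.5)
    region: tuple[str, int, int] = ("2L", 2358158, 2431617)
    seed: int = 0

    def __post_init__(self):
        for g in self.groups:
            for label in g.hap_freqs:
                self.kdr.parse_label(label)  # raises on out-of-alphabet labels


@dataclass
class SimulatedCohort:
    samples: SampleTable
    genotypes: GenotypeMatrix
    haplotypes: HaplotypeMatrix
    truth: pd.DataFrame  # sample_id, hap1, hap2, group_label


def _background_positions(spec: KdrCohortSpec) -> list[int]:
    chrom, start, end = spec.region
    taken = {l.pos for l in spec.kdr.loci}
    pos = np.linspace(start, end, spec.n_background_sites + 2)[1:-1]
    out = []
    for p in np.round(pos).astype(int):
        while p in taken:
            p += 1
        taken.add(int(p))
        out.append(int(p))
    return out


def simulate_kdr_cohort(spec: KdrCohortSpec) -> SimulatedCohort:
    """Simulate a multi-site diploid cohort with known kdr backgrounds.

    Each individual draws two haplotype labels i.i.d. from its (taxon, site)
    table; labels expand to allele indices at the configured kdr loci.
    Background biallelic sites are in linkage equilibrium by construction,
    with per-site allele frequencies drawn uniformly from
    ``background_freq_range``. The phased matrix is the ground truth; truth
    labels are kept in ``truth``.
    """
    cfg = spec.kdr
    chrom = spec.region[0]
    bg_pos = _background_positions(spec)
    bg_rng = substream(spec.seed, "background-freqs")
    lo, hi = spec.background_freq_range
    bg_freqs = bg_rng.uniform(lo, hi, size=len(bg_pos))

    kdr_records = {l.pos: l.variant_record() for l in cfg.loci}
    bg_records = {p: VariantRecord(chrom, p, "C", ("G",)) for p in bg_pos}
    all_pos = sorted({*kdr_records, *bg_records})
    variants = [kdr_records.get(p) or bg_records[p] for p in all_pos]
    row_of = {p: i for i, p in enumerate(all_pos)}
    kdr_rows = [row_of[l.pos] for l in cfg.loci]
    bg_rows = [row_of[p] for p in bg_pos]

    meta_rows, truth_rows = [], []
    hap_cols: list[np.ndarray] = []
    for gspec in spec.groups:
        rng = substream(spec.seed, "cohort", gspec.taxon, gspec.site)
        labels = sorted(gspec.hap_freqs)
        probs = np.array([gspec.hap_freqs[l] for l in labels])
        probs = probs / probs.sum()
        label_alleles = {l: cfg.label_to_indices(l) for l in labels}
        for k in range(gspec.n_samples):
            sid = f"{gspec.taxon[:4]}_{gspec.site}_{k:04d}"
            h1, h2 = (labels[i] for i in rng.choice(len(labels), size=2, p=probs))
            cols = np.zeros((len(variants), 2), dtype=np.int16)
            for hap_i, lab in enumerate((h1, h2)):
                cols[kdr_rows, hap_i] = label_alleles[lab]
                cols[bg_rows, hap_i] = (
                    rng.random(len(bg_rows)) < bg_freqs
                ).astype(np.int16)
            hap_cols.append(cols)
            a, b = cfg.canonical_pair(h1, h2)
            meta_rows.append(
                {"sample_id": sid, "taxon": gspec.taxon, "site": gspec.site,
                 "zone": gspec.zone, "sex": "F"}
            )
            truth_rows.append(
                {"sample_id": sid, "hap1": h1, "hap2": h2, "group_label": f"{a}/{b}"}
            )

    haps = np.concatenate(hap_cols, axis=1)
    sample_ids = [r["sample_id"] for r in meta_rows]
    hm = HaplotypeMatrix(variants, haps, sample_ids, phased=True)
    samples = SampleTable(pd.DataFrame(meta_rows))
    return SimulatedCohort(samples, hm.to_genotypes(), hm, pd.DataFrame(truth_rows))


def table_r2(hap_freqs: dict[str, float], cfg: KdrAlleleConfig,
             locus_a: str, label_a: str, locus_b: str, label_b: str) -> float:
    """The r² a haplotype-frequency table implies between two focal alleles:
    D²/(p_A q_A p_B q_B) computed directly from the table (the generator-side
    truth the LD estimator should recover)."""
    names = [l.name for l in cfg.loci]
    ia, ib = names.index(locus_a), names.index(locus_b)
    pA = pB = pAB = 0.0
    for label, f in hap_freqs.items():
        syms = cfg.parse_label(label)
        a = syms[ia] == label_a
        b = syms[ib] == label_b
        pA += f * a
        pB += f * b
        pAB += f * (a and b)
    D = pAB - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom == 0:
        raise ValueError("monomorphic focal allele in table")
    return D * D / denom


# ---------------------------------------------------------------------------
# Copy-number tables
# ---------------------------------------------------------------------------


@dataclass
class CNVSimSpec:
    """Per-taxon copy-number distributions for a list of genes.

    ``dists[gene_id]`` maps a taxon (or '*' for any taxon) to a distribution
    {copies: probability} with support within 0..12.
    """

    genes: pd.DataFrame  # gene_id, chrom, start, end, family
    dists: dict[str, dict[str, dict[int, float]]]
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.genes, pd.DataFrame):
            self.genes = pd.DataFrame(self.genes)
        for gid, by_taxon in self.dists.items():
            for taxon, dist in by_taxon.items():
                for c in dist:
                    if c < 0:
                        raise ValueError(f"{gid}/{taxon}: negative copy support {c}")
                    if c > 12:
                        raise ValueError(f"{gid}/{taxon}: copy support {c} > 12")
                tot = sum(dist.values())
                if abs(tot - 1.0) > 1e-9:
                    raise ValueError(f"{gid}/{taxon}: probabilities sum to {tot}")


def simulate_cnv_table(spec: CNVSimSpec, samples: SampleTable):
    """Independent per-(sample, gene) copy-number draws; seed-deterministic.

    Genes without a distribution for a sample's taxon (and no '*' fallback)
    sit at the autosomal baseline of 2 copies.
    """
    from kdrkit.core_io import CopyNumberTable

    gene_ids = list(spec.genes["gene_id"])
    n, m = len(samples), len(gene_ids)
    copies = np.full((n, m), 2, dtype=np.int64)
    taxa = list(samples.df["taxon"])
    for gi, gid in enumerate(gene_ids):
        by_taxon = spec.dists.get(gid, {})
        rng = substream(spec.seed, "cnv", gid)
        for si in range(n):
            dist = by_taxon.get(taxa[si], by_taxon.get("*"))
            if dist is None:
                continue
            support = sorted(dist)
            probs = np.array([dist[c] for c in support])
            copies[si, gi] = support[rng.choice(len(support), p=probs / probs.sum())]
    return CopyNumberTable(spec.genes, copies, samples.sample_ids)
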