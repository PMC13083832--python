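"""kdr diplotype classification and genetic-background analyses.

A *diplotype* is the unordered pair of multi-locus haplotype labels an
individual carries at the configured kdr loci — e.g. ``FL1T/LVI`` for a
mosquito heterozygous for the 995F + 402L(g>t) + 1527T background over the
fully wild-type background. Labels concatenate one symbol per locus
(995: L/F/S, 402: V/L1/L2, 1527: I/T).

Phased input is read directly off the two haplotype columns. Unphased input
is resolved by enumerating the haplotype-label pairs compatible with the
genotypes; when more than one pair is compatible the ambiguity is resolved
by an EM estimate of cohort haplotype-label frequencies (maximum product of
frequencies), recording the posterior of the chosen pair and the runner-up.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from kdrkit.core_io import (
    MISSING,
    GenotypeMatrix,
    HaplotypeMatrix,
    SampleTable,
    VariantRecord,
)


@dataclass(frozen=True)
class KdrLocus:
    """One resistance locus: genomic site, reference allele + label, and the
    alternate alleles keyed by their display label (e.g. {'L1': 'T', 'L2': 'C'}
    for the triallelic codon-402 site)."""

    name: str
    chrom: str
    pos: int
    ref: str
    ref_label: str
    alt_labels: dict[str, str] = field(hash=False)

    def __post_init__(self):
        labels = [self.ref_label, *self.alt_labels]
        if len(set(labels)) != len(labels):
            raise ValueError(f"locus {self.name}: labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [self.ref_label, *self.alt_labels.keys()]

    @property
    def alts(self) -> tuple[str, ...]:
        return tuple(self.alt_labels.values())

    def label_of_index(self, idx: int) -> str:
        return self.labels[idx]

    def index_of_label(self, label: str) -> int:
        return self.labels.index(label)

    def variant_record(self) -> VariantRecord:
        return VariantRecord(self.chrom, self.pos, self.ref, self.alts)


@dataclass
class KdrAlleleConfig:
    """Ordered kdr loci defining the haplotype-label alphabet.

    The default emulates the Vgsc configuration used in An. gambiae s.l.
    surveillance — a triallelic codon-995 site (L995F, L995S), the triallelic
    codon-402 site (V402L via g>t and g>c) and the codon-1527 site (I1527T) —
    at synthetic coordinates inside the gene span; real-data coordinates are
    supplied by the user.
    """

    loci: list[KdrLocus]  # label (display) order, e.g. 995, 402, 1527

    def __post_init__(self):
        if len({l.name for l in self.loci}) != len(self.loci):
            raise ValueError("locus names must be unique")
        if len({(l.chrom, l.pos) for l in self.loci}) != len(self.loci):
            raise ValueError("locus positions must be unique")

    @property
    def positions(self) -> list[tuple[str, int]]:
        return [(l.chrom, l.pos) for l in self.loci]

    def parse_label(self, label: str) -> list[str]:
        """Split a concatenated label (e.g. 'FL1T') into one symbol per locus."""
        out, rest = [], label
        for locus in self.loci:
            for sym in sorted(locus.labels, key=len, reverse=True):
                if rest.startswith(sym):
                    out.append(sym)
                    rest = rest[len(sym):]
                    break
            else:
                raise ValueError(f"label {label!r}: no symbol for locus {locus.name}")
        if rest:
            raise ValueError(f"label {label!r}: trailing symbols {rest!r}")
        return out

    def label_to_indices(self, label: str) -> list[int]:
        return [l.index_of_label(s) for l, s in zip(self.loci, self.parse_label(label))]

    def indices_to_label(self, indices) -> str:
        return "".join(l.label_of_index(int(i)) for l, i in zip(self.loci, indices))

    def mutant_score(self, label: str) -> int:
        return sum(
            1 for l, s in zip(self.loci, self.parse_label(label)) if s != l.ref_label
        )

    def canonical_pair(self, h1: str, h2: str) -> tuple[str, str]:
        """Mutant-bearing label first; ties broken lexicographically."""
        a, b = sorted((h1, h2), key=lambda h: (-self.mutant_score(h), h))
        return a, b

    def variant_indices(self, variants: list[VariantRecord]) -> list[int]:
        """Index of each configured locus in a variant list (error if absent,
        or if alt ordering disagrees with the config)."""
        lookup = {(v.chrom, v.pos): i for i, v in enumerate(variants)}
        out = []
        for locus in self.loci:
            key = (locus.chrom, locus.pos)
            if key not in lookup:
                raise ValueError(f"configured locus {locus.name} at "
                                 f"{key[0]}:{key[1]} absent from variants")
            i = lookup[key]
            v = variants[i]
            if v.ref != locus.ref or tuple(v.alts[: len(locus.alts)]) != locus.alts:
                raise ValueError(
                    f"locus {locus.name}: variant alleles {v.ref}>{v.alts} do not "
                    f"match config {locus.ref}>{locus.alts}"
                )
            out.append(i)
        return out


def default_kdr_config(chrom: str = "2L") -> KdrAlleleConfig:
    """Synthetic default kdr configuration (positions inside the Vgsc span)."""
    return KdrAlleleConfig(
        loci=[
            KdrLocus("995", chrom, 2422652, "A", "L", {"F": "T", "S": "C"}),
            KdrLocus("402", chrom, 2391228, "G", "V", {"L1": "T", "L2": "C"}),
            KdrLocus("1527", chrom, 2429556, "A", "I", {"T": "C"}),
        ]
    )


@dataclass
class DiplotypeCall:
    sample_id: str
    hap1_label: str
    hap2_label: str
    group_label: str
    phase_source: str  # phased_input | unambiguous | em_resolved
    posterior: float = 1.0
    runner_up_prob: float = 0.0


def _compatible_pairs(
    cfg: KdrAlleleConfig, genotype: list[tuple[int, int]]
) -> list[tuple[str, str]]:
    """All unordered haplotype-label pairs consistent with per-locus genotypes."""
    per_locus = []
    for (a, b) in genotype:
        per_locus.append([(a, b)] if a == b else [(a, b), (b, a)])
    pairs = set()
    for choice in itertools.product(*per_locus):
        h1 = cfg.indices_to_label([c[0] for c in choice])
        h2 = cfg.indices_to_label([c[1] for c in choice])
        pairs.add(cfg.canonical_pair(h1, h2))
    return sorted(pairs)


def _em_label_frequencies(
    sample_pairs: list[list[tuple[str, str]]],
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> dict[str, float]:
    """EM over per-sample compatible-pair sets for cohort haplotype-label
    frequencies (the standard multi-locus genotype-to-haplotype EM)."""
    labels = sorted({h for pairs in sample_pairs for pair in pairs for h in pair})
    freq = {h: 1.0 / len(labels) for h in labels}
    n = len(sample_pairs)
    for _ in range(max_iter):
        counts = dict.fromkeys(labels, 0.0)
        for pairs in sample_pairs:
            ws = []
            for h1, h2 in pairs:
                w = freq[h1] * freq[h2] * (2.0 if h1 != h2 else 1.0)
                ws.append(w)
            tot = sum(ws)
            if tot == 0.0:
                ws = [1.0] * len(pairs)
                tot = float(len(pairs))
            for (h1, h2), w in zip(pairs, ws):
                counts[h1] += w / tot
                counts[h2] += w / tot
        new = {h: counts[h] / (2.0 * n) for h in labels}
        delta = max(abs(new[h] - freq[h]) for h in labels)
        freq = new
        if delta < tol:
            break
    return freq


def call_diplotypes(
    data: HaplotypeMatrix | GenotypeMatrix,
    cfg: KdrAlleleConfig,
) -> tuple[list[DiplotypeCall], list[tuple[str, str]]]:
    """Classify every sample into a kdr diplotype.

    Returns (calls, excluded) where ``excluded`` lists (sample_id, reason)
    for samples that could not be classified (missing genotype at a
    configured locus). Phased input is deterministic; unphased input falls
    back to enumeration and, where several haplotype pairs remain, to
    cohort-EM resolution.
    """
    if isinstance(data, HaplotypeMatrix):
        idx = cfg.variant_indices(data.variants)
        calls = []
        for j, sid in enumerate(data.sample_ids):
            h1 = cfg.indices_to_label(data.haps[idx, 2 * j])
            h2 = cfg.indices_to_label(data.haps[idx, 2 * j + 1])
            a, b = cfg.canonical_pair(h1, h2)
            calls.append(DiplotypeCall(sid, a, b, f"{a}/{b}", "phased_input"))
        return calls, []

    idx = cfg.variant_indices(data.variants)
    excluded: list[tuple[str, str]] = []
    sample_pairs: list[list[tuple[str, str]]] = []
    kept: list[int] = []
    for j, sid in enumerate(data.sample_ids):
        geno = []
        bad = None
        for i, locus in zip(idx, cfg.loci):
            a, b = (int(x) for x in data.calls[i, j])
            if a == MISSING or b == MISSING:
                bad = f"missing genotype at locus {locus.name}"
                break
            geno.append((a, b))
        if bad:
            excluded.append((sid, bad))
            continue
        kept.append(j)
        sample_pairs.append(_compatible_pairs(cfg, geno))

    freq = None
    if any(len(p) > 1 for p in sample_pairs):
        freq = _em_label_frequencies(sample_pairs)

    calls = []
    for j, pairs in zip(kept, sample_pairs):
        sid = data.sample_ids[j]
        if len(pairs) == 1:
            a, b = pairs[0]
            calls.append(DiplotypeCall(sid, a, b, f"{a}/{b}", "unambiguous"))
            continue
        ws = []
        for h1, h2 in pairs:
            ws.append(freq[h1] * freq[h2] * (2.0 if h1 != h2 else 1.0))
        tot = sum(ws)
        probs = [w / tot for w in ws] if tot > 0 else [1.0 / len(ws)] * len(ws)
        order = sorted(range(len(pairs)), key=lambda k: (-probs[k], pairs[k]))
        best, second = order[0], order[1]
        a, b = pairs[best]
        calls.append(
            DiplotypeCall(
                sid, a, b, f"{a}/{b}", "em_resolved",
                posterior=probs[best], runner_up_prob=probs[second],
            )
        )
    return calls, excluded


def diplotype_frequencies(
    calls: list[DiplotypeCall],
    samples: SampleTable,
    grouping: str = "taxon",
    od_min_count: int = 3,
) -> pd.DataFrame:
    """Per-group diplotype-group frequencies (count / classified samples).

    Diplotype groups whose cohort-wide count falls below ``od_min_count``
    are pooled into an 'OD' (other diplotypes) bucket. Unclassified samples
    appear in the ``n_excluded`` column, outside the denominators.
    """
    if not calls:
        raise ValueError("no diplotype calls")
    by_sample = {c.sample_id: c.group_label for c in calls}
    overall = pd.Series(list(by_sample.values())).value_counts()
    pooled = set(overall[overall < od_min_count].index)

    rows = []
    for key, idx in samples.group_indices(grouping).items():
        ids = [samples.df["sample_id"].iloc[i] for i in idx]
        labels = [by_sample[s] for s in ids if s in by_sample]
        n_excluded = len(ids) - len(labels)
        if not labels:
            continue
        counts: dict[str, int] = {}
        for lab in labels:
            lab = "OD" if lab in pooled else lab
            counts[lab] = counts.get(lab, 0) + 1
        for lab in sorted(counts):
            rows.append(
                {
                    "group": "/".join(str(k) for k in key),
                    "diplotype": lab,
                    "count": counts[lab],
                    "n_classified": len(labels),
                    "n_excluded": n_excluded,
                    "frequency": counts[lab] / len(labels),
                }
            )
    return pd.DataFrame(rows)


def _dosage_matrix(g: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Samples × (site, alt-allele) alternate-allele dosage, biallelic-decomposed.

    Missing calls contribute 0 dosage (complete-case handling is done by the
    callers that need it)."""
    cols, names = [], []
    for i, v in enumerate(g.variants):
        for k in range(1, v.n_alleles):
            dose = (g.calls[i] == k).sum(axis=1)
            cols.append(dose)
            names.append(f"{v.chrom}:{v.pos}:{v.alts[k - 1]}")
    if not cols:
        raise ValueError("no variants to build dosage matrix from")
    return np.stack(cols, axis=1).astype(float), names


def diplotype_clustering(
    g: GenotypeMatrix,
    height: float | None = None,
    n_clusters: int | None = None,
):
    """Hierarchical clustering of samples on alternate-allele dosage vectors.

    Manhattan distance, average linkage. Flat clusters come from a height
    threshold or a requested cluster count (``n_clusters`` wins if both are
    given). Returns (linkage_matrix, flat_cluster_labels, sample_ids).
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples to cluster")
    X, _ = _dosage_matrix(g)
    d = pdist(X, metric="cityblock")
    Z = linkage(d, method="average")
    if n_clusters is not None:
        flat = fcluster(Z, t=n_clusters, criterion="maxclust")
    elif height is not None:
        flat = fcluster(Z, t=height, criterion="distance")
    else:
        flat = np.ones(g.n_samples, dtype=int)
    return Z, flat, list(g.sample_ids)


def pca_dosage(g: GenotypeMatrix, n_components: int = 2):
    """PCA of the mean-centered dosage matrix via SVD.

    Sign convention: within each component the largest-magnitude loading is
    made positive, so coordinates are reproducible across runs. Returns
    (coordinates, explained_variance_ratio, loadings).
    """
    if g.n_samples < 2:
        raise ValueError("need >= 2 samples")
    X, _ = _dosage_matrix(g)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("zero-variance dosage matrix")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n_components, len(s))
    for c in range(k):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    coords = U[:, :k] * s[:k]
    var = s**2
    evr = var[:k] / var.sum()
    return coords, evr, Vt[:k]
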