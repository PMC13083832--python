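"""Nucleotide-diversity statistics with multiallelic-aware bookkeeping.

A site is segregating when at least two distinct non-missing allele indices
are observed, and multiallelic when at least three are. Pairwise differences
treat alleles as categories (any two distinct alleles count 1), so a
triallelic site is never split into biallelic rows. Watterson's theta and
Tajima's D use the modal non-missing chromosome count across sites as the
sample size m; per-site pair counts use the per-site non-missing count.

Tajima's D follows the 1989 definitions:

    a1 = sum_{i=1}^{m-1} 1/i          a2 = sum_{i=1}^{m-1} 1/i^2
    b1 = (m+1)/(3(m-1))               b2 = 2(m^2+m+3)/(9m(m-1))
    c1 = b1 - 1/a1                    c2 = b2 - (m+2)/(a1 m) + a2/a1^2
    e1 = c1/a1                        e2 = c2/(a1^2 + a2)
    D  = (pi_total - S/a1) / sqrt(e1 S + e2 S (S-1))

where pi_total is the mean number of pairwise differences (not per base).
With S = 0 the statistic is undefined and reported as NaN, never 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from kdrkit.core_io import MISSING, GenotypeMatrix, SampleTable


@dataclass
class DiversityStats:
    group: str
    n_samples: int
    S: int
    n_multiallelic: int
    frac_multiallelic: float
    n_nonsynonymous: int
    frac_nonsynonymous: float
    theta_pi: float
    theta_w: float
    tajima_d: float
    variant_density: float
    span_bp: int


def _allele_counts(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per site: counts of each allele index (columns) and non-missing totals."""
    max_alleles = max((v.n_alleles for v in g.variants), default=1)
    flat = g.calls.reshape(g.n_variants, -1)
    counts = np.zeros((g.n_variants, max_alleles), dtype=np.int64)
    for a in range(max_alleles):
        counts[:, a] = (flat == a).sum(axis=1)
    return counts, counts.sum(axis=1)


def segregating_sites(g: GenotypeMatrix) -> tuple[int, int]:
    """(S, n_multiallelic): sites with >=2 and >=3 distinct observed alleles.

    A multiallelic site counts once in S. Sites where every call is missing
    are excluded (with a warning)."""
    if g.n_samples < 1:
        raise ValueError("need at least one sample")
    counts, totals = _allele_counts(g)
    n_observed = (counts > 0).sum(axis=1)
    n_empty = int((totals == 0).sum())
    if n_empty:
        warnings.warn(f"{n_empty} site(s) with all calls missing excluded from S")
    S = int((n_observed >= 2).sum())
    n_multi = int((n_observed >= 3).sum())
    return S, n_multi


def _pi_per_site(g: GenotypeMatrix) -> np.ndarray:
    """Mean pairwise categorical difference per site, with per-site
    non-missing denominators. Sites with <2 non-missing alleles contribute 0."""
    counts, totals = _allele_counts(g)
    pairs_total = totals * (totals - 1) / 2.0
    pairs_same = (counts * (counts - 1) / 2.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(pairs_total > 0, (pairs_total - pairs_same) / pairs_total, 0.0)
    n_thin = int((totals < 2).sum())
    if n_thin:
        warnings.warn(f"{n_thin} site(s) with <2 non-missing alleles contribute 0 to pi")
    return pi


def nucleotide_diversity(g: GenotypeMatrix, span_bp: int) -> float:
    """Per-base nucleotide diversity: mean pairwise difference per site,
    summed over sites, divided by the analyzed span."""
    if span_bp < 1:
        raise ValueError("span_bp must be >= 1")
    return float(_pi_per_site(g).sum() / span_bp)


def _modal_chromosomes(g: GenotypeMatrix) -> int:
    _, totals = _allele_counts(g)
    totals = totals[totals > 0]
    if len(totals) == 0:
        return 0
    vals, freq = np.unique(totals, return_counts=True)
    return int(vals[np.argmax(freq)])


def harmonic(k: int) -> float:
    return sum(1.0 / i for i in range(1, k + 1))


def watterson_theta(g: GenotypeMatrix, span_bp: int) -> float:
    """Watterson's estimator theta_w = S / (a1 * span) with
    a1 = sum_{i<m} 1/i and m the modal non-missing chromosome count."""
    if span_bp < 1:
        raise ValueError("span_bp must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        S, _ = segregating_sites(g)
    if S == 0:
        return 0.0
    m = _modal_chromosomes(g)
    if m < 2:
        raise ValueError("need >= 2 non-missing chromosomes for Watterson's theta")
    return S / (harmonic(m - 1) * span_bp)


def tajima_d(g: GenotypeMatrix) -> float:
    """Tajima's D; NaN when S = 0 (undefined, deliberately not 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        S, _ = segregating_sites(g)
        pi_total = float(_pi_per_site(g).sum())
    if S == 0:
        return math.nan
    m = _modal_chromosomes(g)
    if m < 2:
        raise ValueError("need >= 2 non-missing chromosomes for Tajima's D")
    a1 = harmonic(m - 1)
    a2 = sum(1.0 / i**2 for i in range(1, m))
    b1 = (m + 1) / (3.0 * (m - 1))
    b2 = 2.0 * (m * m + m + 3) / (9.0 * m * (m - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (m + 2) / (a1 * m) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    denom = math.sqrt(e1 * S + e2 * S * (S - 1))
    if denom == 0.0:
        return 0.0
    return (pi_total - S / a1) / denom


def diversity_summary(
    g: GenotypeMatrix,
    samples: SampleTable,
    span_bp: int,
    grouping: str = "taxon",
    effects: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-group diversity table (one row per taxon or taxon×site group).

    ``effects`` is the long-form effect-annotation table (columns
    variant_index, effect); a group's non-synonymous count is the number of
    its segregating sites carrying >=1 non-synonymous alt allele. Groups with
    zero samples are omitted with a warning.
    """
    nonsyn_sites: set[int] = set()
    if effects is not None and len(effects):
        nonsyn_sites = set(
            effects.loc[effects["effect"] == "nonsynonymous", "variant_index"]
        )
    rows = []
    for key, idx in samples.group_indices(grouping).items():
        if len(idx) == 0:
            warnings.warn(f"group {key} has no samples; omitted")
            continue
        sub = g.take_samples(idx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            S, n_multi = segregating_sites(sub)
            counts, totals = _allele_counts(sub)
            seg_mask = (counts > 0).sum(axis=1) >= 2
            n_nonsyn = sum(1 for i in np.flatnonzero(seg_mask) if i in nonsyn_sites)
            theta_pi = nucleotide_diversity(sub, span_bp)
            theta_w = watterson_theta(sub, span_bp) if S else 0.0
            d = tajima_d(sub)
        rows.append(
            DiversityStats(
                group="/".join(str(k) for k in key),
                n_samples=len(idx),
                S=S,
                n_multiallelic=n_multi,
                frac_multiallelic=n_multi / S if S else 0.0,
                n_nonsynonymous=n_nonsyn,
                frac_nonsynonymous=n_nonsyn / S if S else 0.0,
                theta_pi=theta_pi,
                theta_w=theta_w,
                tajima_d=d,
                variant_density=S / span_bp,
                span_bp=span_bp,
            )
        )
    return pd.DataFrame([asdict(r) for r in rows])
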