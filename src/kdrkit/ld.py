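"""Allele-specific linkage disequilibrium r² from unphased genotypes.

Each locus is collapsed to a focal-allele indicator (focal vs all other
alleles), which is what makes the triallelic 402 site analyzable: 402L(g>t)
and 402L(g>c) are treated as two separate focal alleles against 1527T. The
two-locus haplotype frequency p_AB is estimated by EM maximum likelihood over
the double-heterozygote phase ambiguity, run from three starts (linkage
equilibrium, full coupling, full repulsion) to avoid the saddle point that a
double-het-only sample produces. Then

    D_AB = p_AB − p_A p_B,   r² = D_AB² / (p_A (1−p_A) p_B (1−p_B)).

A monomorphic focal allele leaves r² undefined; it is reported as 0 with
``defined=False`` so tabulated output matches the field convention of
printing 0 while machine-readable output keeps the distinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from kdrkit.core_io import MISSING, GenotypeMatrix, SampleTable


@dataclass
class LDResult:
    allele_A: str
    allele_B: str
    n: int
    p_A: float
    p_B: float
    p_AB: float
    D_AB: float
    r2: float
    defined: bool
    loglik: float
    iterations: int


def _loglik(counts: np.ndarray, pAB: float, pAb: float, paB: float, pab: float) -> float:
    probs = {
        (2, 2): pAB * pAB,
        (2, 1): 2 * pAB * pAb,
        (2, 0): pAb * pAb,
        (1, 2): 2 * pAB * paB,
        (1, 1): 2 * pAB * pab + 2 * pAb * paB,
        (1, 0): 2 * pAb * pab,
        (0, 2): paB * paB,
        (0, 1): 2 * paB * pab,
        (0, 0): pab * pab,
    }
    ll = 0.0
    for (i, j), p in probs.items():
        n = counts[i, j]
        if n:
            if p <= 0.0:
                return -math.inf
            ll += n * math.log(p)
    return ll


def em_haplotype_freq(
    counts: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> tuple[float, float, int]:
    """Maximum-likelihood p_AB from 3×3 two-locus genotype counts.

    ``counts[i, j]`` is the number of diploids carrying i copies of focal
    allele A and j copies of focal allele B. The allele-frequency marginals
    are fixed by the data; EM only resolves how double heterozygotes split
    between coupling (AB/ab) and repulsion (Ab/aB). Three starts — linkage
    equilibrium and the two boundary phases — are run and the solution with
    the highest log-likelihood wins. The log-likelihood is checked to be
    non-decreasing at every EM step.

    Returns (p_AB, loglik, iterations) for the winning start.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3, 3):
        raise ValueError("counts must be a 3x3 genotype table")
    n = counts.sum()
    if n == 0:
        raise ValueError("empty genotype table")
    two_n = 2.0 * n
    nA = 2 * counts[2, :].sum() + counts[1, :].sum()
    nB = 2 * counts[:, 2].sum() + counts[:, 1].sum()
    pA, pB = nA / two_n, nB / two_n
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError("focal allele absent or fixed; p_AB has no freedom")

    lo = max(0.0, pA + pB - 1.0)
    hi = min(pA, pB)
    eps = 1e-6 * (hi - lo) if hi > lo else 0.0
    starts = [pA * pB, lo + eps, hi - eps]

    ndh = counts[1, 1]

    def haps(pAB: float):
        return pAB, pA - pAB, pB - pAB, 1.0 - pA - pB + pAB

    best = None
    for start in starts:
        pAB = min(max(start, lo), hi)
        prev_ll = _loglik(counts, *haps(pAB))
        iters = 0
        for it in range(1, max_iter + 1):
            iters = it
            pAB_, pAb_, paB_, pab_ = haps(pAB)
            coup = pAB_ * pab_
            rep = pAb_ * paB_
            x = coup / (coup + rep) if (coup + rep) > 0 else 0.5
            new_pAB = (
                2 * counts[2, 2] + counts[2, 1] + counts[1, 2] + x * ndh
            ) / two_n
            ll = _loglik(counts, *haps(new_pAB))
            if ll < prev_ll - 1e-9:
                raise AssertionError(
                    f"EM log-likelihood decreased: {prev_ll} -> {ll}"
                )
            delta = abs(new_pAB - pAB)
            pAB = new_pAB
            prev_ll = ll
            if delta < tol:
                if delta == 0.0 and it > 1:
                    iters = it - 1  # last step only confirmed a fixed point
                break
        if best is None or prev_ll > best[1]:
            best = (pAB, prev_ll, iters)
    return best


def _focal_dosage(
    g: GenotypeMatrix, locus, allele
) -> tuple[np.ndarray, str]:
    """Per-sample copies of the focal allele at a locus; MISSING rows -> -1.

    ``locus`` is a variant index or a (chrom, pos) pair; ``allele`` is an
    allele index or an allele string (matched against ref/alts).
    """
    if isinstance(locus, tuple):
        hits = [
            i for i, v in enumerate(g.variants) if (v.chrom, v.pos) == tuple(locus)
        ]
        if not hits:
            raise ValueError(f"locus {locus} not present")
        i = hits[0]
    else:
        i = int(locus)
    v = g.variants[i]
    if isinstance(allele, str):
        alleles = (v.ref, *v.alts)
        if allele not in alleles:
            raise ValueError(f"allele {allele!r} not at {v.chrom}:{v.pos}")
        k = alleles.index(allele)
    else:
        k = int(allele)
        if not 0 <= k < v.n_alleles:
            raise ValueError(f"allele index {k} out of range at {v.chrom}:{v.pos}")
    calls = g.calls[i]
    dose = (calls == k).sum(axis=1)
    dose = np.where((calls == MISSING).any(axis=1), -1, dose)
    name = f"{v.chrom}:{v.pos}:{(v.ref, *v.alts)[k]}"
    return dose.astype(int), name


def allele_r2(
    g: GenotypeMatrix,
    locus_a,
    allele_a,
    locus_b,
    allele_b,
    sample_idx=None,
) -> LDResult:
    """Allele-specific r² between two focal alleles, EM on complete cases.

    ``sample_idx`` restricts the computation to one group. When either focal
    allele is absent (or fixed) among complete cases the result is flagged
    ``defined=False`` and r² is reported as 0.
    """
    da, name_a = _focal_dosage(g, locus_a, allele_a)
    db, name_b = _focal_dosage(g, locus_b, allele_b)
    if sample_idx is not None:
        da, db = da[list(sample_idx)], db[list(sample_idx)]
    ok = (da >= 0) & (db >= 0)
    da, db = da[ok], db[ok]
    n = int(ok.sum())

    def undefined(pA=0.0, pB=0.0):
        return LDResult(
            name_a, name_b, n, pA, pB, p_AB=0.0, D_AB=0.0, r2=0.0,
            defined=False, loglik=math.nan, iterations=0,
        )

    if n < 2:
        return undefined()
    counts = np.zeros((3, 3))
    for i, j in zip(da, db):
        counts[i, j] += 1
    pA = (2 * counts[2, :].sum() + counts[1, :].sum()) / (2 * n)
    pB = (2 * counts[:, 2].sum() + counts[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return undefined(pA, pB)
    pAB, ll, iters = em_haplotype_freq(counts)
    D = pAB - pA * pB
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    r2 = min(max(r2, 0.0), 1.0)
    return LDResult(name_a, name_b, n, pA, pB, pAB, D, r2, True, ll, iters)


def ld_table(
    g: GenotypeMatrix,
    samples: SampleTable,
    pairs,
    grouping: str = "site",
    digits: int = 3,
) -> pd.DataFrame:
    """Table-1-shaped LD summary: one row per (group, allele pair), plus a
    pooled 'global' row per pair over all samples in the table.

    ``pairs`` is a list of (locus_a, allele_a, locus_b, allele_b[, name])
    tuples. Pooling (rather than averaging per-group r²) defines the global
    row, so opposite coupling phases in different groups legitimately pull
    the global value below the per-group ones.
    """
    rows = []
    groups = samples.group_indices(grouping)
    for pair in pairs:
        la, aa, lb, ab = pair[:4]
        name = pair[4] if len(pair) > 4 else None
        for key, idx in groups.items():
            if len(idx) == 0:
                continue
            res = allele_r2(g, la, aa, lb, ab, sample_idx=idx)
            rows.append(_row("/".join(map(str, key)), res, name, digits))
        res = allele_r2(g, la, aa, lb, ab)
        rows.append(_row("global", res, name, digits))
    return pd.DataFrame(rows)


def _row(group: str, res: LDResult, name: str | None, digits: int) -> dict:
    return {
        "group": group,
        "pair": name or f"{res.allele_A} vs {res.allele_B}",
        "n": res.n,
        "r2": round(res.r2, digits),
        "defined": res.defined,
    }
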