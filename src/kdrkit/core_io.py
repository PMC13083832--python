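"""Domain types shared by all analysis stages, plus readers/writers for the
standard formats the pipeline touches (VCF 4.x, GFF3, TSV metadata, CSV/JSON
results).

Conventions
-----------
* All genomic coordinates are 1-based inclusive (VCF/GFF convention).
* Multiallelic VCF records are kept as single variant records at ingest;
  decomposition into per-allele rows happens only downstream (frequency and
  LD operations), so triallelic resistance loci stay one site.
* Missing genotypes are propagated as allele index -1, never imputed.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

TAXA = ("coluzzii", "gambiae_ss", "arabiensis", "other")
SEXES = ("F", "M", "unknown")

MISSING = -1


class KdrkitError(Exception):
    """Base class for pipeline errors."""


class VcfParseError(KdrkitError):
    pass


class MetadataError(KdrkitError):
    pass


class GeneModelError(KdrkitError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class SampleTable:
    """Cohort metadata: one row per sequenced mosquito.

    Wraps a pandas DataFrame with columns ``sample_id``, ``taxon``, ``site``,
    ``zone``, ``sex``, ``lat``, ``lon``. ``sample_id`` is unique; taxa outside
    the An. gambiae complex vocabulary are mapped to ``other``.
    """

    REQUIRED = ("sample_id", "taxon", "site")

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise MetadataError(f"missing required column: {col!r}")
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if len(dup):
            raise MetadataError(
                "duplicate sample_id(s): " + ", ".join(sorted(set(dup.astype(str))))
            )
        unknown = sorted(set(df["taxon"]) - set(TAXA))
        if unknown:
            warnings.warn(f"unknown taxa mapped to 'other': {unknown}")
            df.loc[df["taxon"].isin(unknown), "taxon"] = "other"
        if "zone" not in df.columns:
            df["zone"] = ""
        if "sex" not in df.columns:
            df["sex"] = "unknown"
        df["sex"] = df["sex"].fillna("unknown").replace("", "unknown")
        bad_sex = sorted(set(df["sex"]) - set(SEXES))
        if bad_sex:
            raise MetadataError(f"invalid sex value(s): {bad_sex}")
        for col in ("lat", "lon"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def group_indices(self, grouping: str) -> dict[tuple, np.ndarray]:
        """Partition sample indices by 'taxon', 'site' or 'taxon_site'.

        Keys are always tuples so callers can treat groupings uniformly.
        """
        if grouping == "taxon":
            cols = ["taxon"]
        elif grouping == "site":
            cols = ["site"]
        elif grouping in ("taxon_site", "taxon×site"):
            cols = ["taxon", "site"]
        else:
            raise ValueError(f"unknown grouping: {grouping!r}")
        out: dict[tuple, np.ndarray] = {}
        for key, sub in self.df.groupby(cols, sort=True):
            if not isinstance(key, tuple):
                key = (key,)
            out[key] = sub.index.to_numpy()
        return out

    def subset(self, idx: Sequence[int]) -> "SampleTable":
        return SampleTable(self.df.iloc[list(idx)].reset_index(drop=True))


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site: chrom, 1-based position, ref and 1-3 alt alleles."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]

    def __post_init__(self):
        if not self.alts:
            raise ValueError(f"{self.chrom}:{self.pos}: alts must be non-empty")
        if len(set(self.alts)) != len(self.alts):
            raise ValueError(f"{self.chrom}:{self.pos}: duplicate alt alleles")
        if self.ref in self.alts:
            raise ValueError(f"{self.chrom}:{self.pos}: alt equals ref")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) >= 2


def _check_sorted(variants: Sequence[VariantRecord]) -> None:
    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variant records must be sorted by (chrom, pos)")


@dataclass
class GenotypeMatrix:
    """Diploid calls: variants × samples × 2 allele indices (-1 = missing).

    ``phased_mask`` records per-call phase status ('|' vs '/'), so writing a
    matrix back to VCF preserves the GT field exactly."""

    variants: list[VariantRecord]
    calls: np.ndarray  # (n_variants, n_samples, 2) int8/int16
    sample_ids: list[str]
    phased_mask: np.ndarray | None = None  # (n_variants, n_samples) bool

    def __post_init__(self):
        if self.phased_mask is not None:
            self.phased_mask = np.asarray(self.phased_mask, dtype=bool)
            if self.phased_mask.shape != self.calls.shape[:2]:
                raise ValueError("phased_mask shape must be (variants, samples)")
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (variants, samples, 2)")
        if self.calls.shape[0] != len(self.variants):
            raise ValueError("calls/variants length mismatch")
        if self.calls.shape[1] != len(self.sample_ids):
            raise ValueError("calls/sample_ids length mismatch")
        _check_sorted(self.variants)
        for i, v in enumerate(self.variants):
            mx = int(self.calls[i].max(initial=MISSING))
            if mx >= v.n_alleles:
                raise ValueError(
                    f"{v.chrom}:{v.pos}: allele index {mx} out of range "
                    f"for {v.n_alleles} alleles"
                )

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_samples(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = list(idx)
        return GenotypeMatrix(
            self.variants,
            self.calls[:, idx, :],
            [self.sample_ids[i] for i in idx],
            None if self.phased_mask is None else self.phased_mask[:, idx],
        )


@dataclass
class HaplotypeMatrix:
    """Phased alleles: variants × (2·samples); columns 2i, 2i+1 belong to sample i."""

    variants: list[VariantRecord]
    haps: np.ndarray  # (n_variants, 2*n_samples)
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self):
        self.haps = np.asarray(self.haps, dtype=np.int16)
        if self.haps.ndim != 2:
            raise ValueError("haps must be 2-D")
        if self.haps.shape[1] != 2 * len(self.sample_ids):
            raise ValueError("haps must have 2 columns per sample")
        if self.haps.shape[0] != len(self.variants):
            raise ValueError("haps/variants length mismatch")
        _check_sorted(self.variants)
        if self.phased and (self.haps == MISSING).any():
            raise ValueError("phased haplotype matrix cannot contain missing calls")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[1]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype columns 2i, 2i+1 back to diploid calls."""
        n = self.n_samples
        calls = np.stack([self.haps[:, 0::2], self.haps[:, 1::2]], axis=2)
        return GenotypeMatrix(self.variants, calls, list(self.sample_ids))

    def sample_of_column(self, col: int) -> str:
        return self.sample_ids[col // 2]


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """Transcript model for codon-aware annotation.

    ``cds_exons`` are 1-based inclusive genomic intervals ordered 5'→3' in
    transcript orientation (descending genomic start on the minus strand).
    ``cds_seq`` is the spliced coding sequence in transcript orientation; it
    is required for synonymous/non-synonymous annotation and is loaded from a
    reference FASTA by :func:`read_gene_model` when one is supplied.
    """

    transcript_id: str
    chrom: str
    strand: str
    cds_exons: list[tuple[int, int]]
    cds_seq: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GeneModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_exons:
            raise GeneModelError(f"{self.transcript_id}: no CDS exons")
        genomic_sorted = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 <= e1:
                raise GeneModelError(f"{self.transcript_id}: overlapping CDS exons")
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if list(self.cds_exons) != expected:
            raise GeneModelError(
                f"{self.transcript_id}: CDS exons not in transcript orientation"
            )
        if self.cds_length % 3 != 0:
            raise GeneModelError(
                f"{self.transcript_id}: CDS length {self.cds_length} "
                "not divisible by 3"
            )
        if self.cds_seq is not None and len(self.cds_seq) != self.cds_length:
            raise GeneModelError(
                f"{self.transcript_id}: cds_seq length {len(self.cds_seq)} "
                f"!= CDS length {self.cds_length}"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_exons)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def cds_index(self, pos: int) -> int | None:
        """0-based position within the spliced CDS of genomic ``pos``,
        or None if ``pos`` is non-coding."""
        offset = 0
        for s, e in self.cds_exons:
            if s <= pos <= e:
                if self.strand == "+":
                    return offset + (pos - s)
                return offset + (e - pos)
            offset += e - s + 1
        return None

    def codon_of(self, pos: int) -> tuple[int, int] | None:
        """(codon_number, position_in_codon), both 1-based, or None."""
        i = self.cds_index(pos)
        if i is None:
            return None
        return i // 3 + 1, i % 3 + 1


@dataclass
class CopyNumberTable:
    """Per-gene integer copy numbers, as produced by upstream coverage-based
    CNV callers. ``genes`` rows: (gene_id, chrom, start, end, family)."""

    genes: pd.DataFrame  # columns gene_id, chrom, start, end, family
    copies: np.ndarray  # (n_samples, n_genes) int
    sample_ids: list[str]

    FAMILIES = ("CYP", "COE", "GST", "ACE1", "other")

    def __post_init__(self):
        self.copies = np.asarray(self.copies, dtype=np.int64)
        need = {"gene_id", "chrom", "start", "end", "family"}
        if not need <= set(self.genes.columns):
            raise ValueError(f"gene table needs columns {sorted(need)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in copy-number table")
        if (self.copies < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if self.copies.shape != (len(self.sample_ids), len(self.genes)):
            raise ValueError("copies shape must be (samples, genes)")
        bad = set(self.genes["family"]) - set(self.FAMILIES)
        if bad:
            raise ValueError(f"unknown gene families: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_region(region: str) -> tuple[str, int, int]:
    try:
        chrom, span = region.rsplit(":", 1)
        start, end = span.replace(",", "").split("-")
        return chrom, int(start), int(end)
    except ValueError as exc:
        raise ValueError(f"malformed region {region!r}; expected 'chrom:start-end'") from exc


def read_vcf(path: str | Path, region: str | None = None):
    """Read a VCF into (variants, GenotypeMatrix, HaplotypeMatrix-or-None).

    Multiallelic records stay single records. A haplotype matrix is returned
    only when every call at every retained site is phased ('|') and
    non-missing; otherwise the third element is None. A region with no
    overlapping records yields empty matrices, not an error.
    """
    import pysam

    path = str(path)
    want = _parse_region(region) if region else None
    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    phase_rows: list[np.ndarray] = []
    with pysam.VariantFile(path) as vf:
        sample_ids = list(vf.header.samples)
        for rec in vf:
            if want is not None:
                chrom, start, end = want
                if rec.chrom != chrom or not (start <= rec.pos <= end):
                    continue
            if rec.alts is None:
                raise VcfParseError(f"{path}: record without ALT at {rec.chrom}:{rec.pos}")
            try:
                variants.append(
                    VariantRecord(rec.chrom, rec.pos, rec.ref, tuple(rec.alts))
                )
            except ValueError as exc:
                raise VcfParseError(f"{path}: {exc}") from exc
            row = np.full((len(sample_ids), 2), MISSING, dtype=np.int16)
            prow = np.zeros(len(sample_ids), dtype=bool)
            for j, sid in enumerate(sample_ids):
                call = rec.samples[sid]
                gt = call["GT"]
                if gt is None:
                    gt = (None, None)
                if len(gt) != 2:
                    raise VcfParseError(
                        f"{path}: non-diploid GT at {rec.chrom}:{rec.pos} sample {sid}"
                    )
                row[j] = [MISSING if a is None else a for a in gt]
                prow[j] = call.phased
            rows.append(row)
            phase_rows.append(prow)
    if variants:
        order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
        variants = [variants[i] for i in order]
        calls = np.stack([rows[i] for i in order], axis=0)
        phased_mask = np.stack([phase_rows[i] for i in order], axis=0)
    else:
        calls = np.empty((0, len(sample_ids), 2), dtype=np.int16)
        phased_mask = np.empty((0, len(sample_ids)), dtype=bool)
    gm = GenotypeMatrix(variants, calls, sample_ids, phased_mask)
    all_phased = bool(phased_mask.all() and (calls != MISSING).all())
    hm = None
    if all_phased and len(variants):
        haps = np.empty((len(variants), 2 * len(sample_ids)), dtype=np.int16)
        haps[:, 0::2] = calls[:, :, 0]
        haps[:, 1::2] = calls[:, :, 1]
        hm = HaplotypeMatrix(variants, haps, sample_ids, phased=True)
    return variants, gm, hm


def write_vcf(
    path: str | Path,
    g: GenotypeMatrix,
    haplotypes: HaplotypeMatrix | None = None,
    contigs: Mapping[str, int] | None = None,
) -> None:
    """Write genotypes (or phased haplotypes) to an uncompressed VCF.

    When ``haplotypes`` is given its columns are written as phased '|' calls;
    otherwise unphased calls come from ``g``. CHROM/POS/REF/ALT/GT round-trip
    exactly through :func:`read_vcf`.
    """
    import pysam

    header = pysam.VariantHeader()
    if contigs is None:
        contigs = {}
        for v in g.variants:
            contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + 1000)
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("GT", 1, "String", "Genotype")
    for sid in g.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i, v in enumerate(g.variants):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, *v.alts),
            )
            for j, sid in enumerate(g.sample_ids):
                if haplotypes is not None:
                    a, b = int(haplotypes.haps[i, 2 * j]), int(haplotypes.haps[i, 2 * j + 1])
                    rec.samples[sid]["GT"] = (a, b)
                    rec.samples[sid].phased = True
                else:
                    a, b = (int(x) for x in g.calls[i, j])
                    rec.samples[sid]["GT"] = (
                        None if a == MISSING else a,
                        None if b == MISSING else b,
                    )
                    if g.phased_mask is not None:
                        rec.samples[sid].phased = bool(g.phased_mask[i, j])
            out.write(rec)


def read_sample_metadata(path: str | Path) -> SampleTable:
    """Read tab-separated cohort metadata (sample_id, taxon, site, ...)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in SampleTable.REQUIRED:
        if col not in df.columns:
            raise MetadataError(f"{path}: missing required column {col!r}")
    return SampleTable(df)


def write_sample_metadata(samples: SampleTable, path: str | Path) -> None:
    samples.df.to_csv(path, sep="\t", index=False)


def read_gene_model(
    gff3_path: str | Path,
    transcript_id: str,
    fasta_path: str | Path | None = None,
) -> GeneModel:
    """Assemble a transcript's CDS model from GFF3 (+ optional reference FASTA).

    CDS features with Parent=<transcript_id> are collected and ordered 5'→3'
    in transcript orientation. When a FASTA is given, the spliced CDS sequence
    is extracted (reverse-complemented on the minus strand) so downstream
    effect annotation can translate codons.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    cds = [
        f for f in db.features_of_type("CDS")
        if transcript_id in f.attributes.get("Parent", [])
    ]
    if not cds:
        raise GeneModelError(f"transcript {transcript_id!r} not found in {gff3_path}")
    chrom = cds[0].seqid
    strand = cds[0].strand
    exons = sorted((f.start, f.end) for f in cds)
    if strand == "-":
        exons = exons[::-1]
    seq = None
    if fasta_path is not None:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta_path))
        parts = []
        for s, e in sorted((a, b) for a, b in exons):
            parts.append(str(fa[chrom][s - 1:e]).upper())
        seq = "".join(parts)
        if strand == "-":
            seq = revcomp(seq)
    return GeneModel(transcript_id, chrom, strand, exons, cds_seq=seq)


def read_copy_number(copies_csv: str | Path, genes_csv: str | Path) -> CopyNumberTable:
    """Read a samples × genes copy-number matrix plus its gene annotation.

    ``copies_csv``: first column sample_id, remaining columns one per gene_id.
    ``genes_csv``: columns gene_id, chrom, start, end, family.
    """
    genes = pd.read_csv(genes_csv, dtype={"gene_id": str, "chrom": str})
    wide = pd.read_csv(copies_csv)
    if "sample_id" not in wide.columns:
        raise ValueError(f"{copies_csv}: first column must be sample_id")
    sample_ids = list(wide["sample_id"].astype(str))
    gene_ids = list(genes["gene_id"])
    missing = [gid for gid in gene_ids if gid not in wide.columns]
    if missing:
        raise ValueError(f"{copies_csv}: missing gene column(s) {missing}")
    copies = wide[gene_ids].to_numpy(dtype=np.int64)
    return CopyNumberTable(genes, copies, sample_ids)


def write_copy_number(t: CopyNumberTable, copies_csv: str | Path, genes_csv: str | Path) -> None:
    t.genes.to_csv(genes_csv, index=False)
    wide = pd.DataFrame(t.copies, columns=t.gene_ids)
    wide.insert(0, "sample_id", t.sample_ids)
    wide.to_csv(copies_csv, index=False)


def write_table(
    rows: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    format: str = "csv",
    float_digits: int = 6,
) -> None:
    """Write result rows as csv/tsv/json with a deterministic column order
    and explicit float precision (default 6 significant digits)."""
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        df = pd.DataFrame(rows)
    if format not in ("csv", "tsv", "json"):
        raise ValueError(f"unknown format {format!r}")

    def fmt(x):
        if isinstance(x, (float, np.floating)):
            if np.isnan(x):
                return ""
            return f"{x:.{float_digits}g}"
        if isinstance(x, (np.integer,)):
            return int(x)
        return x

    out = df.map(fmt) if len(df) else df
    path = Path(path)
    if format == "json":
        records = out.to_dict(orient="records")
        path.write_text(json.dumps(records, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")
    else:
        sep = "," if format == "csv" else "\t"
        out.to_csv(path, sep=sep, index=False, encoding="utf-8",
                   quoting=csv.QUOTE_MINIMAL)
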