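"""Shared domain types for allele-specific expression analysis.

All genomic intervals held by these types are half-open and 0-based.
External formats that use other conventions (VCF and GTF are 1-based;
GTF intervals are closed) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

HET_GENOTYPES = ("0|1", "1|0")
#: genotype strings accepted from a phased VCF; anything else is "missing"
KNOWN_GENOTYPES = ("0|0", "0|1", "1|0", "1|1")

# observed-allele codes for a single variant on a single read
REF = "ref"
ALT = "alt"
OTHER = "other"
# haplotype labels used in phased orientation mode
HAP1 = "hap1"
HAP2 = "hap2"
# molecule-level outcome
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PhasedVariant:
    """A biallelic SNP with per-individual phased genotype calls.

    ``pos`` is the 1-based coordinate exactly as printed in the VCF;
    use :attr:`pos0` for the internal 0-based convention.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    genotypes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt allele must differ")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref_base}:{self.alt_base}"

    def genotype(self, individual: str) -> str:
        return self.genotypes.get(individual, ".")

    def is_het(self, individual: str) -> bool:
        return self.genotype(individual) in HET_GENOTYPES


@dataclass(frozen=True)
class IsoformModel:
    """One transcript (or the per-gene unspliced pseudo-isoform).

    ``exon_blocks`` are sorted, non-overlapping half-open 0-based intervals.
    The unspliced isoform of a gene has a single block covering the full
    gene span and represents pre-mRNA, the dominant species in
    single-nucleus data.
    """

    isoform_id: str
    gene_id: str
    exon_blocks: tuple
    spliced: bool = True

    def __post_init__(self) -> None:
        if not self.exon_blocks:
            raise ValueError(f"isoform {self.isoform_id} has no exon blocks")
        blocks = tuple(tuple(b) for b in self.exon_blocks)
        object.__setattr__(self, "exon_blocks", blocks)
        prev_end = None
        for start, end in blocks:
            if end <= start:
                raise ValueError(f"empty exon block ({start},{end}) in {self.isoform_id}")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"exon blocks of {self.isoform_id} unsorted or overlapping")
            prev_end = end

    @property
    def span(self) -> tuple:
        return (self.exon_blocks[0][0], self.exon_blocks[-1][1])

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its spliced isoforms plus exactly one unspliced isoform."""

    gene_id: str
    chrom: str
    strand: str
    span: tuple
    isoforms: tuple
    utr3_blocks: tuple = ()
    utr5_blocks: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        object.__setattr__(self, "span", tuple(self.span))
        object.__setattr__(self, "isoforms", tuple(self.isoforms))
        object.__setattr__(self, "utr3_blocks", tuple(tuple(b) for b in self.utr3_blocks))
        object.__setattr__(self, "utr5_blocks", tuple(tuple(b) for b in self.utr5_blocks))
        unspliced = [i for i in self.isoforms if not i.spliced]
        if len(unspliced) != 1:
            raise ValueError(f"gene {self.gene_id} needs exactly one unspliced isoform")
        if unspliced[0].span != self.span:
            raise ValueError(f"unspliced isoform of {self.gene_id} must cover the gene span")
        for iso in self.isoforms:
            if iso.span[0] < self.span[0] or iso.span[1] > self.span[1]:
                raise ValueError(f"isoform {iso.isoform_id} extends outside gene span")

    @property
    def exon_union(self) -> tuple:
        """Merged union of all spliced-isoform exon blocks."""
        blocks = sorted(
            b for iso in self.isoforms if iso.spliced for b in iso.exon_blocks
        )
        merged: list = []
        for s, e in blocks:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return tuple((s, e) for s, e in merged)


@dataclass
class ReadRecord:
    """One alignment with its droplet tags and per-variant allele evidence.

    ``variant_evidence`` pairs each covered :class:`PhasedVariant` with the
    allele observed on the read (``ref``/``alt``/``other``); ``other`` means
    the read base matched neither allele. ``feature_tags`` maps a namespace
    (``gene``, ``peak``, ``isoform``, ``region``) to one or more labels.
    """

    read_id: str
    chrom: str
    strand: str
    alignment_blocks: Sequence
    cell_barcode: Optional[str] = None
    umi: Optional[str] = None
    cigar_ops: Sequence = ()
    feature_tags: dict = field(default_factory=dict)
    n_alignments: int = 1
    wasp_pass: Optional[bool] = None
    alignment_score: Optional[int] = None
    variant_evidence: list = field(default_factory=list)

    def __post_init__(self) -> None:
        blocks = [tuple(b) for b in self.alignment_blocks]
        prev_end = None
        for start, end in blocks:
            if end <= start:
                raise ValueError(f"empty alignment block in read {self.read_id}")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"alignment blocks of {self.read_id} unsorted/overlapping")
            prev_end = end
        self.alignment_blocks = blocks
        for variant, allele in self.variant_evidence:
            if not self.covers(variant.pos0):
                raise ValueError(
                    f"evidence for {variant.key} outside alignment blocks of {self.read_id}"
                )
            if allele not in (REF, ALT, OTHER):
                raise ValueError(f"bad observed allele {allele!r}")

    def covers(self, pos0: int) -> bool:
        return any(s <= pos0 < e for s, e in self.alignment_blocks)

    @property
    def span(self) -> tuple:
        return (self.alignment_blocks[0][0], self.alignment_blocks[-1][1])

    def genes(self) -> tuple:
        return tuple(self.feature_tags.get("gene", ()))


@dataclass(frozen=True)
class PileupRow:
    """Depth summary at one candidate SNP from a pileup of expression data."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    dp: int
    ad: int

    def __post_init__(self) -> None:
        if not (0 <= self.ad <= self.dp):
            raise ValueError(f"need 0 <= AD <= DP, got AD={self.ad}, DP={self.dp}")


@dataclass(frozen=True)
class UmiCall:
    """One molecule -- a (cell barcode, UMI, feature) triple -- resolved to an allele."""

    cell_barcode: str
    umi: str
    feature_id: str
    allele: str
    n_supporting_reads: int
    individual_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_supporting_reads < 1:
            raise ValueError("a UMI call needs at least one supporting read")


COUNT_COLUMNS = ["unit_id", "individual_id", "feature_id", "n_ref", "n_alt", "n_ambiguous"]


class AseCountTable:
    """Long-format allele counts: one row per (unit, feature).

    A *unit* is a cell barcode (cell-level tables) or an individual id
    (pseudobulk tables). ``n_ref``/``n_alt`` hold reference/alternative
    molecule counts in unphased mode and haplotype-1/haplotype-2 counts
    in phased mode; ``n_ambiguous`` counts molecules whose reads
    disagreed, which never enter downstream ratios.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns: {missing}")
        df = df.reset_index(drop=True)
        for col in ("n_ref", "n_alt", "n_ambiguous"):
            if (df[col] < 0).any():
                raise ValueError(f"negative counts in column {col}")
            df[col] = df[col].astype(int)
        if df.duplicated(subset=["unit_id", "feature_id"]).any():
            raise ValueError("duplicate (unit_id, feature_id) keys in count table")
        # keep required columns first, extra grouping columns after
        extra = [c for c in df.columns if c not in COUNT_COLUMNS]
        self.df = df[COUNT_COLUMNS + extra]

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AseCountTable):
            return NotImplemented
        a = self.df.sort_values(["unit_id", "feature_id"]).reset_index(drop=True)
        b = other.df.sort_values(["unit_id", "feature_id"]).reset_index(drop=True)
        return a.equals(b[a.columns]) if set(a.columns) == set(b.columns) else False

    @property
    def extra_columns(self) -> list:
        return [c for c in self.df.columns if c not in COUNT_COLUMNS]

    def total_molecules(self) -> int:
        return int(self.df[["n_ref", "n_alt", "n_ambiguous"]].to_numpy().sum())
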