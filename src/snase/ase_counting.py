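"""Allele-resolved molecule counting and read-level QC.

The central pipeline: each tagged read is resolved to an allele from the
heterozygous SNPs it covers, reads sharing a (cell barcode, UMI, feature)
triple are collapsed into one molecule, and molecules are tallied per
cell or per individual. Molecules whose reads disagree are counted as
*ambiguous* and never enter allelic ratios.

Two orientation modes exist. In ``unphased`` mode alleles are labelled
reference/alternative per SNP. In ``phased`` mode each observation is
translated to haplotype 1/2 through the individual's phased genotype
(ref under ``0|1`` lies on haplotype 1, ref under ``1|0`` on haplotype 2),
so molecules covering different SNPs of one gene aggregate consistently.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import (
    ALT,
    AMBIGUOUS,
    AseCountTable,
    GeneModel,
    HAP1,
    HAP2,
    OTHER,
    PhasedVariant,
    PileupRow,
    ReadRecord,
    REF,
    UmiCall,
)

logger = logging.getLogger(__name__)

EXCLUDED = "excluded"

REGION_CATEGORIES = ["UTR3", "UTR5", "exon", "intron", "antisense", "intergenic"]


@dataclass(frozen=True)
class ResolvedRead:
    cell_barcode: str
    umi: str
    feature_id: str
    allele: str
    individual_id: Optional[str] = None


# ---------------------------------------------------------------------------
# read -> allele


def resolve_read_allele(
    read: ReadRecord,
    individual: str,
    *,
    mode: str = "unphased",
    threshold: float = 0.95,
) -> str:
    """Resolve one read to an allele, or ``"excluded"``.

    Multimappers and WASP-failing reads are excluded outright. Evidence
    at non-heterozygous variants or with an off-allele base is dropped.
    If the remaining observations disagree, the majority allele wins only
    when its share is strictly greater than ``threshold`` (the 95% rule);
    otherwise the read is excluded.
    """
    if mode not in ("unphased", "phased"):
        raise ValueError(f"unknown mode {mode!r}")
    if read.n_alignments > 1 or read.wasp_pass is False:
        return EXCLUDED
    votes: List[str] = []
    for variant, observed in read.variant_evidence:
        if observed == OTHER:
            continue
        if not variant.is_het(individual):
            logger.warning(
                "read %s: evidence at non-het variant %s dropped", read.read_id, variant.key
            )
            continue
        if mode == "unphased":
            votes.append(observed)
        else:
            gt = variant.genotype(individual)
            if gt == "0|1":
                votes.append(HAP1 if observed == REF else HAP2)
            else:  # 1|0
                votes.append(HAP2 if observed == REF else HAP1)
    if not votes:
        return EXCLUDED
    counts = Counter(votes)
    if len(counts) == 1:
        return votes[0]
    allele, n_major = counts.most_common(1)[0]
    if n_major / len(votes) > threshold:
        return allele
    return EXCLUDED


def resolve_reads(
    reads: Iterable[ReadRecord],
    individual: str,
    *,
    mode: str = "unphased",
    threshold: float = 0.95,
    feature_namespace: str = "gene",
) -> List[ResolvedRead]:
    """Resolve reads and expand them over their feature tags.

    A read tagged with several features (e.g. overlapping peaks)
    contributes once per feature; excluded reads contribute nothing.
    """
    out: List[ResolvedRead] = []
    for read in reads:
        allele = resolve_read_allele(read, individual, mode=mode, threshold=threshold)
        if allele == EXCLUDED:
            continue
        if read.cell_barcode is None or read.umi is None:
            continue
        for feat in read.feature_tags.get(feature_namespace, ()):
            out.append(ResolvedRead(read.cell_barcode, read.umi, feat, allele, individual))
    return out


# ---------------------------------------------------------------------------
# UMI collapsing and counting


def collapse_umis(resolved_reads: Iterable[ResolvedRead]) -> List[UmiCall]:
    """Collapse resolved reads into molecules keyed by (cell, UMI, feature).

    All reads of a molecule agreeing -> that allele; any disagreement ->
    ambiguous.
    """
    groups: Dict[Tuple, List[ResolvedRead]] = defaultdict(list)
    for r in resolved_reads:
        groups[(r.cell_barcode, r.umi, r.feature_id)].append(r)
    calls = []
    for (cbc, umi, feat), rs in groups.items():
        alleles = {r.allele for r in rs}
        allele = rs[0].allele if len(alleles) == 1 else AMBIGUOUS
        calls.append(UmiCall(cbc, umi, feat, allele, len(rs), rs[0].individual_id))
    return calls


def count_feature_ase(
    umi_calls: Iterable[UmiCall],
    unit: str = "cell",
    extra_labels: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> AseCountTable:
    """Tally molecules into an :class:`AseCountTable`.

    ``unit="cell"`` keys rows by cell barcode; ``unit="individual"``
    produces pseudobulk rows keyed by individual. In phased mode the
    ``n_ref``/``n_alt`` columns carry haplotype-1/haplotype-2 counts.
    ``extra_labels`` maps column name -> (unit_id -> label), e.g. cell types.
    """
    if unit not in ("cell", "individual"):
        raise ValueError("unit must be 'cell' or 'individual'")
    rows: Dict[Tuple, List[int]] = defaultdict(lambda: [0, 0, 0])
    for call in umi_calls:
        unit_id = call.cell_barcode if unit == "cell" else call.individual_id
        if unit_id is None:
            raise ValueError("UMI call lacks the id needed for this unit level")
        key = (unit_id, call.individual_id, call.feature_id)
        if call.allele in (REF, HAP1):
            rows[key][0] += 1
        elif call.allele in (ALT, HAP2):
            rows[key][1] += 1
        else:
            rows[key][2] += 1
    df = pd.DataFrame(
        [
            {
                "unit_id": u,
                "individual_id": ind,
                "feature_id": f,
                "n_ref": c[0],
                "n_alt": c[1],
                "n_ambiguous": c[2],
            }
            for (u, ind, f), c in rows.items()
        ],
        columns=["unit_id", "individual_id", "feature_id", "n_ref", "n_alt", "n_ambiguous"],
    )
    if extra_labels:
        for col, mapping in extra_labels.items():
            df[col] = df["unit_id"].map(mapping)
    return AseCountTable(df)


def pseudobulk(table: AseCountTable) -> AseCountTable:
    """Aggregate a cell-level table to one row per (individual, feature)."""
    extra = [c for c in table.extra_columns]
    agg = {c: "sum" for c in ("n_ref", "n_alt", "n_ambiguous")}
    for c in extra:
        agg[c] = "first"
    df = (
        table.df.groupby(["individual_id", "feature_id"], as_index=False)
        .agg(agg)
        .assign(unit_id=lambda d: d["individual_id"])
    )
    return AseCountTable(df)


def count_gene_ase(
    reads: Iterable[ReadRecord],
    individual: str,
    *,
    mode: str = "unphased",
    unit: str = "cell",
    threshold: float = 0.95,
) -> AseCountTable:
    """End-to-end gene-level counting for one individual's reads."""
    resolved = resolve_reads(reads, individual, mode=mode, threshold=threshold)
    return count_feature_ase(collapse_umis(resolved), unit=unit)


def count_snp_ase(
    reads: Iterable[ReadRecord],
    individual: str,
    *,
    unit: str = "cell",
) -> AseCountTable:
    """Per-SNP counting from reads that directly cover each het SNP.

    Each read contributes to every heterozygous SNP it covers, using that
    SNP's own observed allele -- no information is shared across SNPs, so
    this is always an unphased (reference/alternative) table keyed by
    ``chrom:pos:ref:alt``.
    """
    resolved: List[ResolvedRead] = []
    for read in reads:
        if read.n_alignments > 1 or read.wasp_pass is False:
            continue
        if read.cell_barcode is None or read.umi is None:
            continue
        for variant, observed in read.variant_evidence:
            if observed == OTHER or not variant.is_het(individual):
                continue
            resolved.append(
                ResolvedRead(read.cell_barcode, read.umi, variant.key, observed, individual)
            )
    return count_feature_ase(collapse_umis(resolved), unit=unit)


def count_peak_ase(
    reads: Iterable[ReadRecord],
    individual: str,
    *,
    mode: str = "unphased",
    unit: str = "cell",
    threshold: float = 0.95,
) -> AseCountTable:
    """Peak-level counting: gene logic applied to the ``peak`` tag namespace."""
    resolved = resolve_reads(
        reads, individual, mode=mode, threshold=threshold, feature_namespace="peak"
    )
    return count_feature_ase(collapse_umis(resolved), unit=unit)


def assign_peaks(reads: Iterable[ReadRecord], peaks: pd.DataFrame) -> None:
    """Tag reads in place with the peaks that contain them.

    ``peaks`` is a BED frame (chrom/start/end/name/strand); entries
    sharing a name form one peak. A read belongs to a peak when it is on
    the same strand and every alignment block lies within the union of
    that peak's entries (full-containment semantics).
    """
    if "strand" not in peaks.columns or "name" not in peaks.columns:
        raise ValueError("peak BED needs name and strand columns")
    peak_map: Dict[Tuple[str, str], Dict[str, List[Tuple[int, int]]]] = defaultdict(dict)
    for r in peaks.itertuples():
        peak_map[(r.chrom, r.strand)].setdefault(r.name, []).append((int(r.start), int(r.end)))
    for read in reads:
        labels = []
        for name, entries in peak_map.get((read.chrom, read.strand), {}).items():
            if blocks_contained(read.alignment_blocks, entries):
                labels.append(name)
        if labels:
            read.feature_tags["peak"] = tuple(sorted(labels))


def blocks_contained(blocks: Sequence[Tuple[int, int]], intervals: Sequence[Tuple[int, int]]) -> bool:
    """True iff every block lies inside the merged union of ``intervals``."""
    merged: List[List[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return all(any(ms <= s and e <= me for ms, me in merged) for s, e in blocks)


# ---------------------------------------------------------------------------
# het-SNP calling from pileups


def call_het_snps_from_pileup(
    rows: Iterable[PileupRow],
    sample: str = "sample",
    *,
    min_dp: int = 10,
    low: float = 0.1,
    high: float = 0.9,
) -> List[PhasedVariant]:
    """Likely-heterozygous sites from expression pileups.

    Keeps sites with DP strictly above ``min_dp`` and allele ratio AD/DP
    strictly inside (``low``, ``high``); every kept site is emitted with a
    synthetic ``0|1`` genotype so downstream phased machinery can run on
    genotype-free data.
    """
    kept = []
    for row in rows:
        if row.dp == 0 or row.dp <= min_dp:
            continue
        ratio = row.ad / row.dp
        if low < ratio < high:
            kept.append(
                PhasedVariant(row.chrom, row.pos, row.ref_base, row.alt_base, {sample: "0|1"})
            )
    return kept


# ---------------------------------------------------------------------------
# region QC


def annotate_read_region(read: ReadRecord, gene_models: Mapping[str, GeneModel]) -> str:
    """Classify a read into one region category.

    Precedence UTR3 > UTR5 > exon > intron > antisense > intergenic;
    membership needs full containment of all alignment blocks (same strand
    for gene-linked categories, opposite strand for antisense).
    """
    same = [
        g for g in gene_models.values() if g.chrom == read.chrom and g.strand == read.strand
    ]
    anti = [
        g for g in gene_models.values() if g.chrom == read.chrom and g.strand != read.strand
    ]
    blocks = read.alignment_blocks
    if any(g.utr3_blocks and blocks_contained(blocks, g.utr3_blocks) for g in same):
        return "UTR3"
    if any(g.utr5_blocks and blocks_contained(blocks, g.utr5_blocks) for g in same):
        return "UTR5"
    if any(g.exon_union and blocks_contained(blocks, g.exon_union) for g in same):
        return "exon"
    if any(blocks_contained(blocks, [g.span]) for g in same):
        return "intron"
    if any(blocks_contained(blocks, [g.span]) for g in anti):
        return "antisense"
    return "intergenic"


def phasing_rate_by_region(
    reads: Iterable[ReadRecord],
    het_variants: Sequence[PhasedVariant],
    gene_models: Mapping[str, GeneModel],
    individual: Optional[str] = None,
) -> pd.DataFrame:
    """Fraction of uniquely mapped reads per region that cover a het SNP.

    The numerator is reads overlapping at least one heterozygous SNP
    (phaseable reads); multimappers are excluded from both numerator and
    denominator. Categories with no reads report a missing fraction.
    """
    if individual is not None:
        het_variants = [v for v in het_variants if v.is_het(individual)]
    by_chrom: Dict[str, List[int]] = defaultdict(list)
    for v in het_variants:
        by_chrom[v.chrom].append(v.pos0)
    n_reads = Counter()
    n_phased = Counter()
    for read in reads:
        if read.n_alignments != 1:
            continue
        cat = annotate_read_region(read, gene_models)
        n_reads[cat] += 1
        if any(read.covers(p) for p in by_chrom.get(read.chrom, ())):
            n_phased[cat] += 1
    rows = []
    for cat in REGION_CATEGORIES:
        n = n_reads[cat]
        rows.append(
            {
                "category": cat,
                "n_reads": n,
                "n_overlapping_het_snp": n_phased[cat],
                "fraction": (n_phased[cat] / n) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CIGAR profiling

_READ_CONSUMING = set("MIS=X")
_ALIGNED = set("M=X")


def cigar_profile(reads: Iterable[ReadRecord]) -> Tuple[pd.DataFrame, dict]:
    """Per-read and aggregate alignment-error profile from CIGAR strings.

    ``mapped_bases`` counts aligned read bases (M/=/X operations).
    Mismatches need the =/X distinction; with match-agnostic M CIGARs they
    are reported as missing. Error rates are per matched (=) base.
    """
    recs = []
    for read in reads:
        ops = Counter()
        for op, length in read.cigar_ops:
            ops[op] += length
        has_eq_x = ("=" in ops) or ("X" in ops)
        mapped = sum(n for op, n in ops.items() if op in _ALIGNED)
        matched = ops.get("=", 0) if has_eq_x else np.nan
        mismatches = ops.get("X", 0) if has_eq_x else np.nan
        recs.append(
            {
                "read_id": read.read_id,
                "mapped_bases": mapped,
                "matches": matched,
                "mismatches": mismatches,
                "insertions": ops.get("I", 0),
                "deletions": ops.get("D", 0),
            }
        )
    per_read = pd.DataFrame(
        recs,
        columns=["read_id", "mapped_bases", "matches", "mismatches", "insertions", "deletions"],
    )
    tot_match = per_read["matches"].sum(skipna=True)
    agg = {
        "mapped_bases": int(per_read["mapped_bases"].sum()),
        "matches": float(tot_match),
        "mismatches": float(per_read["mismatches"].sum(skipna=True)),
        "insertions": int(per_read["insertions"].sum()),
        "deletions": int(per_read["deletions"].sum()),
    }
    if tot_match and not np.isnan(tot_match):
        agg["mismatch_rate"] = agg["mismatches"] / tot_match
        agg["insertion_rate"] = agg["insertions"] / tot_match
        agg["deletion_rate"] = agg["deletions"] / tot_match
    else:
        agg["mismatch_rate"] = agg["insertion_rate"] = agg["deletion_rate"] = np.nan
    return per_read, agg


# ---------------------------------------------------------------------------
# bait design


def _merge_intervals(intervals: Iterable[Tuple[str, int, int]]) -> List[Tuple[str, int, int]]:
    """Merge overlapping or bookended intervals per chromosome."""
    out: List[List] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1][2] = max(out[-1][2], e)
        else:
            out.append([chrom, s, e])
    return [tuple(x) for x in out]


def design_bait_regions_snp_flank(
    snps: Sequence[PhasedVariant],
    support: Optional[Mapping[str, Mapping[str, int]]] = None,
    *,
    min_support: int = 2,
    flank: int = 130,
) -> pd.DataFrame:
    """Bait regions as merged symmetric windows around supported het SNPs.

    ``support`` maps sample -> (variant key -> read count); a SNP
    qualifies when every sample shows at least ``min_support`` reads
    (i.e. more than one read by default). Windows extend ``flank`` bases
    on either side of the SNP and overlapping windows are merged.
    """
    windows = []
    for v in snps:
        if support is not None:
            if not all(tab.get(v.key, 0) >= min_support for tab in support.values()):
                continue
        windows.append((v.chrom, max(0, v.pos0 - flank), v.pos0 + flank + 1))
    merged = _merge_intervals(windows)
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def design_bait_regions_coverage(
    sample_beds: Mapping[str, pd.DataFrame],
    sample_het_snps: Mapping[str, Sequence[PhasedVariant]],
    *,
    extension: int = 200,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Bait regions from pooled read footprints near het SNPs.

    Per sample: read-footprint BED entries overlapping that sample's het
    SNPs are extended ``extension`` bases in the 3' direction, sorted and
    merged. Merged entries from all samples are pooled, and regions
    covered by at least ``min_depth`` pooled entries are emitted.
    """
    pooled: List[Tuple[str, int, int]] = []
    for sample, bed in sample_beds.items():
        if "strand" not in bed.columns or bed["strand"].isna().any():
            raise ValueError(f"coverage-mode entries for {sample} need strands for 3' extension")
        het_pos = defaultdict(list)
        for v in sample_het_snps.get(sample, ()):
            het_pos[v.chrom].append(v.pos0)
        entries = []
        for r in bed.itertuples():
            s, e = int(r.start), int(r.end)
            if not any(s <= p < e for p in het_pos.get(r.chrom, ())):
                continue
            if r.strand == "+":
                entries.append((r.chrom, s, e + extension))
            else:
                entries.append((r.chrom, max(0, s - extension), e))
        pooled.extend(_merge_intervals(entries))
    # sweep line over pooled entries; emit regions with depth >= min_depth
    events: Dict[str, List[Tuple[int, int]]] = defaultdict(list)
    for chrom, s, e in pooled:
        events[chrom].append((s, 1))
        events[chrom].append((e, -1))
    out = []
    for chrom in sorted(events):
        depth = 0
        open_start = None
        for pos, delta in sorted(events[chrom]):
            new_depth = depth + delta
            if depth < min_depth <= new_depth:
                open_start = pos
            elif new_depth < min_depth <= depth and open_start is not None:
                if pos > open_start:
                    out.append((chrom, open_start, pos))
                open_start = None
            depth = new_depth
    return pd.DataFrame(_merge_intervals(out), columns=["chrom", "start", "end"])


def design_bait_regions(mode: str, **kwargs) -> pd.DataFrame:
    if mode == "snp_flank":
        return design_bait_regions_snp_flank(**kwargs)
    if mode == "coverage":
        return design_bait_regions_coverage(**kwargs)
    raise ValueError(f"unknown bait design mode {mode!r}")


# ---------------------------------------------------------------------------
# downsampling


def downsample_molecules(data, fraction: float, seed: int):
    """Keep each record independently with probability ``fraction``.

    Accepts a sequence of reads/UMI calls (record-level thinning, as when
    downsampling alignment files) or an :class:`AseCountTable` (binomial
    thinning of every count). Deterministic given the seed.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(data, AseCountTable):
        df = data.df.copy()
        for col in ("n_ref", "n_alt", "n_ambiguous"):
            df[col] = rng.binomial(df[col].to_numpy(), fraction)
        return AseCountTable(df)
    data = list(data)
    keep = rng.random(len(data)) < fraction
    return [d for d, k in zip(data, keep) if k]
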