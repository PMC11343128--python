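"""Isoform assignment for long-read (and isoform-tagged short-read) data.

Each uniquely best-scoring alignment is compared against every isoform
whose genomic extent it overlaps, including the per-gene unspliced
pseudo-isoform. A candidate's exon blocks are trimmed to the read's
extent and the base overlap with the read's (gap-merged) blocks is
computed; candidates are dropped when the overlap falls below 95% of
the trimmed-isoform length or of the read length. The largest
surviving overlap wins unless a runner-up comes within 10 bases, in
which case the read is left unassigned as a tie.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

from .ase_counting import collapse_umis, count_feature_ase, resolve_reads
from .types import AseCountTable, GeneModel, IsoformModel, ReadRecord

# assignment outcomes
ASSIGNED = "assigned"
NO_CANDIDATE = "no_candidate"
BELOW_95 = "below_95"
TIE_WITHIN_10BP = "tie_within_10bp"
MULTI_BEST_ALIGNMENT = "multi_best_alignment"


@dataclass(frozen=True)
class IsoformAssignment:
    read_id: str
    isoform_id: Optional[str]
    overlap_bases: int
    reason: str

    def __post_init__(self) -> None:
        if self.reason == ASSIGNED and self.overlap_bases <= 0:
            raise ValueError("an assigned read must have positive overlap")


class IsoformIndex:
    """Per-chromosome interval trees over isoform extents plus an exon map."""

    def __init__(self, gene_models: Mapping[str, GeneModel]):
        self.trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.exon_map: Dict[str, IsoformModel] = {}
        self.strand: Dict[str, str] = {}
        for gene in gene_models.values():
            for iso in gene.isoforms:
                if iso.isoform_id in self.exon_map:
                    raise ValueError(f"duplicate isoform id {iso.isoform_id}")
                self.exon_map[iso.isoform_id] = iso
                self.strand[iso.isoform_id] = gene.strand
                s, e = iso.span
                self.trees[gene.chrom].addi(s, e, iso.isoform_id)

    def __len__(self) -> int:
        return len(self.exon_map)

    def candidates(self, chrom: str, start: int, end: int, strand: Optional[str] = None) -> List[str]:
        """Isoform ids whose extent overlaps [start, end); optionally same-strand only."""
        hits = [iv.data for iv in self.trees.get(chrom, IntervalTree()).overlap(start, end)]
        if strand is not None:
            hits = [h for h in hits if self.strand[h] == strand]
        return sorted(hits)


def build_isoform_index(gene_models: Mapping[str, GeneModel]) -> IsoformIndex:
    return IsoformIndex(gene_models)


def read_blocks(read: ReadRecord, merge_gap: int = 10) -> List[Tuple[int, int]]:
    """The read's alignment blocks with gaps of at most ``merge_gap`` bases closed."""
    merged: List[List[int]] = []
    for s, e in read.alignment_blocks:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def filter_alignments(alignments: Sequence[ReadRecord]) -> Optional[ReadRecord]:
    """Reduce one read's alignments to its unique best-scoring one, if any.

    Alignments below the read's maximum alignment score are dropped; a
    read whose maximum is shared by several alignments is discarded.
    Without scores, a single alignment passes and multiples are discarded.
    """
    if not alignments:
        return None
    scores = [a.alignment_score for a in alignments]
    if any(s is None for s in scores):
        return alignments[0] if len(alignments) == 1 else None
    best = max(scores)
    top = [a for a, s in zip(alignments, scores) if s == best]
    return top[0] if len(top) == 1 else None


def _intersect_length(a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _trim(blocks: Sequence[Tuple[int, int]], start: int, end: int) -> List[Tuple[int, int]]:
    out = []
    for s, e in blocks:
        s2, e2 = max(s, start), min(e, end)
        if e2 > s2:
            out.append((s2, e2))
    return out


def assign_isoform(
    read: ReadRecord,
    index: IsoformIndex,
    *,
    min_overlap_fraction: float = 0.95,
    tie_margin: int = 10,
    merge_gap: int = 10,
    stranded: bool = False,
    strict_95: bool = True,
) -> IsoformAssignment:
    """Assign one (already score-filtered) read to an isoform.

    With ``strict_95`` (default) a candidate must reach the 95%
    threshold against *both* the trimmed isoform and the read. This is
    what lets junction-spanning reads beat the unspliced pseudo-isoform
    (whose trimmed extent always covers the whole read): the unspliced
    candidate fails the isoform-side criterion there, while a contiguous
    exonic read -- genuinely ambiguous between mature and pre-mRNA --
    ties and is discarded. ``strict_95=False`` keeps any candidate that
    meets either criterion instead.
    """
    blocks = read_blocks(read, merge_gap=merge_gap)
    rstart, rend = blocks[0][0], blocks[-1][1]
    read_len = sum(e - s for s, e in blocks)
    cands = index.candidates(read.chrom, rstart, rend, read.strand if stranded else None)
    if not cands:
        return IsoformAssignment(read.read_id, None, 0, NO_CANDIDATE)

    survivors: List[Tuple[str, int]] = []
    for iso_id in cands:
        trimmed = _trim(index.exon_map[iso_id].exon_blocks, rstart, rend)
        iso_len = sum(e - s for s, e in trimmed)
        overlap = _intersect_length(trimmed, blocks)
        if overlap <= 0:
            continue
        fails_iso = overlap < min_overlap_fraction * iso_len
        fails_read = overlap < min_overlap_fraction * read_len
        excluded = (fails_iso or fails_read) if strict_95 else (fails_iso and fails_read)
        if not excluded:
            survivors.append((iso_id, overlap))
    if not survivors:
        return IsoformAssignment(read.read_id, None, 0, BELOW_95)
    survivors.sort(key=lambda t: (-t[1], t[0]))
    best_id, best_overlap = survivors[0]
    ties = [iso for iso, ov in survivors[1:] if best_overlap - ov < tie_margin]
    if ties:
        return IsoformAssignment(read.read_id, None, best_overlap, TIE_WITHIN_10BP)
    return IsoformAssignment(read.read_id, best_id, best_overlap, ASSIGNED)


def assign_reads(
    reads: Iterable[ReadRecord],
    index: IsoformIndex,
    **kwargs,
) -> List[IsoformAssignment]:
    """Score-filter all alignments per read, then assign each read once.

    Every read id receives exactly one assignment; reads losing the
    best-score filter get reason ``multi_best_alignment``.
    """
    by_read: Dict[str, List[ReadRecord]] = defaultdict(list)
    for r in reads:
        by_read[r.read_id].append(r)
    out = []
    for read_id, alns in by_read.items():
        chosen = filter_alignments(alns)
        if chosen is None:
            out.append(IsoformAssignment(read_id, None, 0, MULTI_BEST_ALIGNMENT))
        else:
            out.append(assign_isoform(chosen, index, **kwargs))
    return out


def tag_reads_with_isoform(
    reads: Iterable[ReadRecord], assignments: Sequence[IsoformAssignment]
) -> List[ReadRecord]:
    """Attach XT-style isoform labels; returns only the assigned reads."""
    by_id = {a.read_id: a for a in assignments}
    tagged = []
    for read in reads:
        a = by_id.get(read.read_id)
        if a is not None and a.reason == ASSIGNED:
            read.feature_tags["isoform"] = (a.isoform_id,)
            tagged.append(read)
    return tagged


def isoform_ase(
    reads: Iterable[ReadRecord],
    assignments: Sequence[IsoformAssignment],
    index: IsoformIndex,
    individual: str,
    *,
    mode: str = "unphased",
    unit: str = "cell",
) -> Tuple[AseCountTable, "object"]:
    """Isoform-level allele counts plus a spliced/unspliced summary.

    Counts use the standard molecule collapsing keyed by (cell, UMI,
    isoform). The summary reports, per gene, how the phased molecules
    split between spliced isoforms and the unspliced pseudo-isoform.
    """
    import pandas as pd

    tagged = tag_reads_with_isoform(list(reads), assignments)
    resolved = resolve_reads(tagged, individual, mode=mode, feature_namespace="isoform")
    table = count_feature_ase(collapse_umis(resolved), unit=unit)

    df = table.df.copy()
    df["gene_id"] = df["feature_id"].map(lambda i: index.exon_map[i].gene_id)
    df["spliced"] = df["feature_id"].map(lambda i: index.exon_map[i].spliced)
    df["n_phased"] = df["n_ref"] + df["n_alt"]
    summary = (
        df.groupby(["gene_id", "spliced"])["n_phased"].sum().unstack(fill_value=0)
        .rename(columns={True: "spliced", False: "unspliced"})
        .reset_index()
    )
    for col in ("spliced", "unspliced"):
        if col not in summary.columns:
            summary[col] = 0
    tot = summary["spliced"] + summary["unspliced"]
    summary["spliced_fraction"] = summary["spliced"] / tot.where(tot > 0)
    return table, summary
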