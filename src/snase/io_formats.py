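"""Readers and writers for the external formats the toolkit touches.

VCF (phased genotypes), GTF gene annotation, BED peak/bait regions,
tagged SAM alignments and TSV count/pileup tables are converted here into
the shared domain types; nothing outside this module parses files.

Coordinate conventions: VCF positions stay 1-based inside
:class:`~snase.types.PhasedVariant` (mirroring the file); everything else
is half-open 0-based. GTF closed 1-based intervals are converted on read.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence

import cyvcf2
import pandas as pd
import pysam
import pyranges

from .types import (
    AseCountTable,
    COUNT_COLUMNS,
    GeneModel,
    IsoformModel,
    OTHER,
    PhasedVariant,
    PileupRow,
    ReadRecord,
    REF,
    ALT,
)

logger = logging.getLogger(__name__)

# SAM tag vocabulary (STARSolo-style):
#   CB cell barcode, UB UMI, GN gene(s), NH number of alignments,
#   vW WASP status (1 = pass), vG variant indices into the companion VCF,
#   vA allele codes (1 = ref, 2 = alt, 3 = other), PK peak label(s),
#   XT isoform label, AS alignment score, GR region label(s).
VA_CODE_TO_ALLELE = {1: REF, 2: ALT, 3: OTHER}
ALLELE_TO_VA_CODE = {REF: 1, ALT: 2, OTHER: 3}


# ---------------------------------------------------------------------------
# VCF


def read_phased_vcf(
    path: str,
    individuals: Optional[Sequence[str]] = None,
    *,
    allow_unphased: bool = False,
) -> List[PhasedVariant]:
    """Load biallelic SNPs with phased genotypes from a VCF.

    Multiallelic records and indels are skipped (counts logged). Unphased
    heterozygous genotypes are treated as missing unless ``allow_unphased``
    is set, in which case the written allele order is taken at face value.
    """
    vcf = cyvcf2.VCF(path)
    samples = list(vcf.samples)
    if individuals is None:
        individuals = samples
    else:
        absent = [s for s in individuals if s not in samples]
        if absent:
            raise KeyError(f"individuals not in VCF header: {absent}")
    idx = [samples.index(s) for s in individuals]

    variants: List[PhasedVariant] = []
    n_multi = n_indel = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_indel += 1
            continue
        genotypes = {}
        for sample, i in zip(individuals, idx):
            call = rec.genotypes[i]  # [allele_a, allele_b, phased]
            a, b, phased = call[0], call[1], bool(call[-1])
            if a < 0 or b < 0:
                genotypes[sample] = "."
            elif phased or a == b or allow_unphased:
                genotypes[sample] = f"{a}|{b}"
            else:
                logger.warning(
                    "unphased het genotype for %s at %s:%d treated as missing",
                    sample, rec.CHROM, rec.POS,
                )
                genotypes[sample] = "."
        variants.append(
            PhasedVariant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], genotypes)
        )
    if n_multi:
        logger.warning("skipped %d multiallelic records", n_multi)
    if n_indel:
        logger.warning("skipped %d indel records", n_indel)
    return variants


def write_phased_vcf(
    variants: Sequence[PhasedVariant],
    path: str,
    individuals: Optional[Sequence[str]] = None,
) -> None:
    """Write variants as a minimal phased VCF 4.2 file."""
    if individuals is None:
        seen: Dict[str, None] = {}
        for v in variants:
            for s in v.genotypes:
                seen.setdefault(s, None)
        individuals = list(seen)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = {v.chrom: None for v in variants}
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if individuals:
            cols += ["FORMAT"] + list(individuals)
        fh.write("\t".join(cols) + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            line = f"{v.chrom}\t{v.pos}\t.\t{v.ref_base}\t{v.alt_base}\t.\tPASS\t."
            if individuals:
                gts = "\t".join(
                    ".|." if v.genotypes.get(s, ".") == "." else v.genotypes[s]
                    for s in individuals
                )
                line += "\tGT\t" + gts
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# GTF


def read_gene_models(gtf_path: str) -> Dict[str, GeneModel]:
    """Build :class:`GeneModel` objects (with per-gene unspliced isoforms) from a GTF.

    Spliced isoforms come from exon records grouped by ``transcript_id``;
    every gene additionally receives one unspliced isoform spanning the
    full gene body. 3'/5' UTR records are collected when present so that
    reads can later be categorised by region.
    """
    df = pyranges.read_gtf(gtf_path).df
    if df.empty:
        raise ValueError(f"no GTF records in {gtf_path}")
    if "transcript_id" not in df.columns:
        df["transcript_id"] = None

    genes: Dict[str, GeneModel] = {}
    for gene_id, gdf in df.groupby("gene_id", sort=True):
        gene_rows = gdf[gdf.Feature == "gene"]
        exon_rows = gdf[gdf.Feature == "exon"]
        bad = exon_rows[exon_rows.transcript_id.isna()]
        if len(bad):
            logger.warning("%d exon records of %s lack transcript_id; skipped", len(bad), gene_id)
            exon_rows = exon_rows[~exon_rows.transcript_id.isna()]
        if len(gene_rows):
            span = (int(gene_rows.Start.min()), int(gene_rows.End.max()))
            strand = str(gene_rows.Strand.iloc[0])
        else:
            lo = int(gdf.Start.min())
            hi = int(gdf.End.max())
            span, strand = (lo, hi), str(gdf.Strand.iloc[0])

        isoforms = []
        for tx_id, tdf in exon_rows.groupby("transcript_id", sort=True):
            blocks = sorted((int(s), int(e)) for s, e in zip(tdf.Start, tdf.End))
            isoforms.append(
                IsoformModel(f"{tx_id}_{gene_id}", gene_id, tuple(blocks), spliced=True)
            )
        isoforms.append(
            IsoformModel(f"unspliced_{gene_id}", gene_id, (span,), spliced=False)
        )

        def _utr(names):
            rows = gdf[gdf.Feature.isin(names)]
            return tuple(sorted((int(s), int(e)) for s, e in zip(rows.Start, rows.End)))

        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=str(gdf.Chromosome.iloc[0]),
            strand=strand,
            span=span,
            isoforms=tuple(isoforms),
            utr3_blocks=_utr(["three_prime_utr", "3UTR"]),
            utr5_blocks=_utr(["five_prime_utr", "5UTR"]),
        )
    return genes


def write_gtf(genes: Iterable[GeneModel], path: str) -> None:
    """Write gene models back out as an Ensembl-dialect GTF (1-based closed)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0])):
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{g.chrom}\tsnase\tgene\t{g.span[0] + 1}\t{g.span[1]}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for iso in g.isoforms:
                if not iso.spliced:
                    continue
                tx = iso.isoform_id.replace(f"_{g.gene_id}", "")
                a = f'gene_id "{g.gene_id}"; transcript_id "{tx}";'
                s, e = iso.span
                fh.write(f"{g.chrom}\tsnase\ttranscript\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{a}\n")
                for s, e in iso.exon_blocks:
                    fh.write(f"{g.chrom}\tsnase\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{a}\n")
            for label, blocks in (("three_prime_utr", g.utr3_blocks), ("five_prime_utr", g.utr5_blocks)):
                for s, e in blocks:
                    fh.write(f"{g.chrom}\tsnase\t{label}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# BED


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3-6 into a frame with columns chrom/start/end[/name/score/strand]."""
    gr = pyranges.read_bed(path)
    df = gr.df.rename(
        columns={"Chromosome": "chrom", "Start": "start", "End": "end",
                 "Name": "name", "Score": "score", "Strand": "strand"}
    )
    return df[[c for c in BED_COLUMNS if c in df.columns]]


def write_bed(df: pd.DataFrame, path: str) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# TSV tables


def read_count_table(path: str) -> AseCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"unit_id": str, "individual_id": str, "feature_id": str})
    return AseCountTable(df)


def write_count_table(table: AseCountTable, path: str) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_pileup_table(path: str) -> List[PileupRow]:
    """TSV with columns chrom, pos, ref, alt, DP, AD (one row per candidate SNP)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        PileupRow(r.chrom, int(r.pos), str(r.ref), str(r.alt), int(r.DP), int(r.AD))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Tagged SAM alignments

_CIGAR_OPS = "MIDNSHP=XB"


def _list_tag(aln, tag):
    if not aln.has_tag(tag):
        return ()
    return tuple(str(aln.get_tag(tag)).split(","))


def read_tagged_alignments(
    path: str, variants: Optional[Sequence[PhasedVariant]] = None
) -> List[ReadRecord]:
    """Load tagged alignments (SAM/BAM) into :class:`ReadRecord` objects.

    ``variants`` must be the list read from the companion VCF, in file
    order: the vG tag stores 0-based indices into it and vA the matching
    allele codes (1 = ref, 2 = alt, 3 = neither).
    """
    reads = []
    warned_no_variants = False
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            evidence = []
            if aln.has_tag("vG"):
                if variants is None:
                    if not warned_no_variants:
                        logger.warning(
                            "alignments carry vG tags but no variants were supplied; "
                            "allele evidence ignored"
                        )
                        warned_no_variants = True
                else:
                    v_idx = aln.get_tag("vG")
                    v_codes = aln.get_tag("vA")
                    for i, code in zip(v_idx, v_codes):
                        evidence.append((variants[i], VA_CODE_TO_ALLELE[int(code)]))
            tags = {}
            for namespace, tag in (("gene", "GN"), ("peak", "PK"), ("isoform", "XT"), ("region", "GR")):
                labels = _list_tag(aln, tag)
                if labels:
                    tags[namespace] = labels
            reads.append(
                ReadRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    strand="-" if aln.is_reverse else "+",
                    alignment_blocks=aln.get_blocks(),
                    cigar_ops=tuple(
                        (_CIGAR_OPS[op], length) for op, length in (aln.cigartuples or ())
                    ),
                    cell_barcode=aln.get_tag("CB") if aln.has_tag("CB") else None,
                    umi=aln.get_tag("UB") if aln.has_tag("UB") else None,
                    feature_tags=tags,
                    n_alignments=int(aln.get_tag("NH")) if aln.has_tag("NH") else 1,
                    wasp_pass=(int(aln.get_tag("vW")) == 1) if aln.has_tag("vW") else None,
                    alignment_score=int(aln.get_tag("AS")) if aln.has_tag("AS") else None,
                    variant_evidence=evidence,
                )
            )
    return reads


def write_tagged_alignments(
    reads: Sequence[ReadRecord],
    path: str,
    chrom_lengths: Dict[str, int],
    variants: Optional[Sequence[PhasedVariant]] = None,
) -> None:
    """Write :class:`ReadRecord` objects as a SAM file with the tag vocabulary above."""
    key = {v.key: i for i, v in enumerate(variants)} if variants is not None else {}
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for read in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = read.read_id
            a.reference_name = read.chrom
            a.reference_start = read.alignment_blocks[0][0]
            a.mapping_quality = 255
            a.flag = 16 if read.strand == "-" else 0
            if read.cigar_ops:
                a.cigarstring = "".join(f"{n}{op}" for op, n in read.cigar_ops)
            else:
                # synthesise blocks joined by N skips
                parts, prev_end = [], None
                for s, e in read.alignment_blocks:
                    if prev_end is not None:
                        parts.append(f"{s - prev_end}N")
                    parts.append(f"{e - s}M")
                    prev_end = e
                a.cigarstring = "".join(parts)
            a.query_sequence = "N" * sum(
                n for op, n in _parse_cigar(a.cigarstring) if op in "MIS=X"
            )
            tags = []
            if read.cell_barcode:
                tags.append(("CB", read.cell_barcode))
            if read.umi:
                tags.append(("UB", read.umi))
            for namespace, tag in (("gene", "GN"), ("peak", "PK"), ("isoform", "XT"), ("region", "GR")):
                if read.feature_tags.get(namespace):
                    tags.append((tag, ",".join(read.feature_tags[namespace])))
            tags.append(("NH", read.n_alignments))
            if read.wasp_pass is not None:
                tags.append(("vW", 1 if read.wasp_pass else 2))
            if read.alignment_score is not None:
                tags.append(("AS", read.alignment_score))
            if read.variant_evidence:
                if variants is None:
                    raise ValueError("writing variant evidence requires the variant list")
                tags.append(("vG", [key[v.key] for v, _ in read.variant_evidence]))
                tags.append(("vA", [ALLELE_TO_VA_CODE[a_] for _, a_ in read.variant_evidence]))
            a.set_tags(tags)
            fh.write(a)


def _parse_cigar(cig: str):
    num = ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        else:
            yield ch, int(num)
            num = ""
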