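"""Synthetic fixtures: count-level simulations and read-level toy data.

Two generators with complete truth tables:

* :func:`simulate_counts` draws cell-level allele counts from the same
  generative model the mixed test assumes -- a beta-binomial with a
  per-individual random intercept on the logit scale -- so statistical
  properties (calibration, parameter recovery) can be checked against
  known truth.
* :func:`simulate_read_fixture` builds a toy genome (GTF), a phased VCF
  and tagged alignments whose gene, isoform, peak and allele of origin
  are all known, to exercise the counting and isoform-assignment layers.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit

from . import io_formats
from .ase_stats import permute_alleles
from .types import (
    ALT,
    AseCountTable,
    GeneModel,
    IsoformModel,
    PhasedVariant,
    ReadRecord,
    REF,
)


# ---------------------------------------------------------------------------
# count-level simulation


@dataclass
class SimConfig:
    """Conditions for the cell-level count simulation.

    ``gene_effects`` maps gene id -> true intercept beta0 on the logit
    scale; alternatively ``n_genes`` genes are created with effect
    ``beta0`` each, or drawn from Normal(0, ``draw_effects_sd``^2) when
    that is set. ``sigma_b`` is the SD of the per-individual random
    intercept, ``rho`` the beta-binomial overdispersion, and the phased
    molecule depth per cell-gene is negative binomial (``depth_mean``,
    size ``depth_size``), mimicking sparse snRNA-seq. ``condition_effects``
    adds a per-gene logit shift for individuals in the second condition.
    """

    n_individuals: int = 40
    cells_per_individual: int = 50
    n_genes: int = 50
    beta0: float = 0.0
    draw_effects_sd: Optional[float] = None
    gene_effects: Optional[Mapping[str, float]] = None
    sigma_b: float = 0.5
    rho: float = 0.05
    depth_mean: float = 5.0
    depth_size: float = 2.0
    condition_effects: Optional[Mapping[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")
        if self.sigma_b < 0:
            raise ValueError("sigma_b must be >= 0")


def _betabin_draws(rng, n, mu, rho):
    """Sample y ~ BetaBinomial(n, mu, rho) element-wise."""
    n = np.asarray(n)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), n.shape)
    if rho <= 0:
        return rng.binomial(n, mu)
    phi = (1 - rho) / rho
    p = rng.beta(np.clip(mu * phi, 1e-8, None), np.clip((1 - mu) * phi, 1e-8, None))
    return rng.binomial(n, p)


def simulate_counts(config: SimConfig) -> Tuple[AseCountTable, pd.DataFrame]:
    """Cell-level ASE counts plus the per-gene truth table.

    For gene g and individual j, b_jg ~ Normal(0, sigma_b^2); each cell c
    gets a phased molecule total n from the depth model and
    y ~ BetaBinomial(n, logit^-1(beta0_g + condition shift + b_jg), rho).
    Cells with zero depth for a gene yield no row, as in real count data.
    """
    rng = np.random.default_rng(config.seed)
    if config.gene_effects is not None:
        effects = dict(config.gene_effects)
    else:
        genes = [f"gene{i:03d}" for i in range(config.n_genes)]
        if config.draw_effects_sd is not None:
            vals = rng.normal(0.0, config.draw_effects_sd, size=config.n_genes)
            effects = dict(zip(genes, vals))
        else:
            effects = {g: config.beta0 for g in genes}
    individuals = [f"ind{j:03d}" for j in range(config.n_individuals)]
    conditions = {
        ind: ("A" if j < config.n_individuals / 2 else "B")
        for j, ind in enumerate(individuals)
    }
    p_nb = config.depth_size / (config.depth_size + config.depth_mean)

    rows = []
    truth_rows = []
    for gene, beta0 in effects.items():
        shift = (config.condition_effects or {}).get(gene, 0.0)
        truth_rows.append(
            {
                "feature_id": gene, "beta0": beta0, "sigma_b": config.sigma_b,
                "rho": config.rho, "condition_effect": shift,
            }
        )
        b = rng.normal(0.0, config.sigma_b, size=config.n_individuals)
        for j, ind in enumerate(individuals):
            eta = beta0 + b[j] + (shift if conditions[ind] == "B" else 0.0)
            mu = expit(eta)
            n = rng.negative_binomial(config.depth_size, p_nb, size=config.cells_per_individual)
            keep = n > 0
            y = _betabin_draws(rng, n[keep], mu, config.rho)
            for c_idx, (nc, yc) in enumerate(zip(n[keep], y)):
                rows.append(
                    {
                        "unit_id": f"{ind}_cell{np.flatnonzero(keep)[c_idx]:04d}",
                        "individual_id": ind,
                        "feature_id": gene,
                        "n_ref": int(yc),
                        "n_alt": int(nc - yc),
                        "n_ambiguous": 0,
                        "condition": conditions[ind],
                    }
                )
    table = AseCountTable(pd.DataFrame(rows))
    return table, pd.DataFrame(truth_rows)


def permuted_null_dataset(config: SimConfig) -> Tuple[AseCountTable, pd.DataFrame]:
    """Simulate counts, then destroy any true imbalance by allele permutation.

    The ref/alt labels of every (individual, gene) pair are swapped with
    probability 1/2 (seeded from the config), so whatever imbalance was
    simulated becomes symmetric noise; row totals are preserved.
    """
    table, truth = simulate_counts(config)
    permuted = permute_alleles(table, seed=(config.seed + 1) % (2**31))
    return permuted, truth


# ---------------------------------------------------------------------------
# read-level fixture


@dataclass
class ReadSimConfig:
    """Layout and sampling parameters for the toy read-level fixture.

    Genes are laid out on one chromosome with ``n_exons`` exons of
    ``exon_len`` separated by ``intron_len`` introns; each gene gets two
    spliced isoforms (the second skips one internal exon) plus the
    implicit unspliced isoform. One het SNP sits mid-exon and mid-intron
    so both spliced and unspliced molecules can be phased.
    ``category_probs`` give the molecule truth mix: ``unspliced`` (block
    overlapping an intron), ``spliced`` (junction-spanning read) and
    ``exonic`` (contiguous exon-contained block, which is genuinely
    ambiguous between mature and pre-mRNA). ``error_rate`` flips each
    SNP observation, exercising the majority rule and ambiguous UMIs.
    """

    n_molecules: int = 300
    n_cells: int = 20
    n_genes: int = 3
    n_exons: int = 5
    exon_len: int = 400
    intron_len: int = 800
    gene_gap: int = 5000
    read_len: int = 600
    reads_per_molecule_mean: float = 1.4
    category_probs: Tuple[float, float, float] = (0.6, 0.3, 0.1)
    individual: str = "donor0"
    gene_effects: Optional[Mapping[str, float]] = None
    error_rate: float = 0.0
    frac_multimapped: float = 0.05
    frac_wasp_fail: float = 0.05
    seed: int = 0


@dataclass
class ReadFixture:
    """A complete in-memory fixture with its truth tables."""

    genes: Dict[str, GeneModel]
    variants: List[PhasedVariant]
    reads: List[ReadRecord]
    peaks: pd.DataFrame
    truth: pd.DataFrame          # one row per read
    molecule_truth: pd.DataFrame  # one row per molecule
    chrom_lengths: Dict[str, int]
    individual: str

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        io_formats.write_gtf(self.genes.values(), os.path.join(outdir, "genes.gtf"))
        io_formats.write_phased_vcf(self.variants, os.path.join(outdir, "variants.vcf"))
        io_formats.write_tagged_alignments(
            self.reads, os.path.join(outdir, "reads.sam"), self.chrom_lengths, self.variants
        )
        io_formats.write_bed(self.peaks, os.path.join(outdir, "peaks.bed"))
        self.truth.to_csv(os.path.join(outdir, "read_truth.tsv"), sep="\t", index=False)
        self.molecule_truth.to_csv(
            os.path.join(outdir, "molecule_truth.tsv"), sep="\t", index=False
        )


def _build_toy_genes(cfg: ReadSimConfig) -> Dict[str, GeneModel]:
    genes: Dict[str, GeneModel] = {}
    gene_len = cfg.n_exons * cfg.exon_len + (cfg.n_exons - 1) * cfg.intron_len
    for g in range(cfg.n_genes):
        gene_id = f"G{g}"
        start = 1000 + g * (gene_len + cfg.gene_gap)
        strand = "+" if g % 2 == 0 else "-"
        exons = [
            (start + i * (cfg.exon_len + cfg.intron_len),
             start + i * (cfg.exon_len + cfg.intron_len) + cfg.exon_len)
            for i in range(cfg.n_exons)
        ]
        span = (start, exons[-1][1])
        skip = cfg.n_exons - 2  # second isoform skips this internal exon
        isoforms = (
            IsoformModel(f"T1_{gene_id}", gene_id, tuple(exons), spliced=True),
            IsoformModel(
                f"T2_{gene_id}", gene_id,
                tuple(e for i, e in enumerate(exons) if i != skip), spliced=True,
            ),
            IsoformModel(f"unspliced_{gene_id}", gene_id, (span,), spliced=False),
        )
        if strand == "+":
            utr3 = ((exons[-1][1] - 200, exons[-1][1]),)
            utr5 = ((exons[0][0], exons[0][0] + 100),)
        else:
            utr3 = ((exons[0][0], exons[0][0] + 200),)
            utr5 = ((exons[-1][1] - 100, exons[-1][1]),)
        genes[gene_id] = GeneModel(
            gene_id, "chr1", strand, span, isoforms, utr3_blocks=utr3, utr5_blocks=utr5
        )
    return genes


def _build_toy_variants(
    genes: Mapping[str, GeneModel], cfg: ReadSimConfig, rng
) -> List[PhasedVariant]:
    variants = []
    for gene in genes.values():
        t1 = next(i for i in gene.isoforms if i.isoform_id.startswith("T1"))
        exons = t1.exon_blocks
        positions = [s + (e - s) // 2 for s, e in exons]
        positions += [exons[i][1] + cfg.intron_len // 2 for i in range(len(exons) - 1)]
        for pos0 in sorted(positions):
            gt = "0|1" if rng.random() < 0.5 else "1|0"
            variants.append(
                PhasedVariant("chr1", pos0 + 1, "A", "G", {cfg.individual: gt})
            )
    return sorted(variants, key=lambda v: v.pos)


def _observed_allele(variant: PhasedVariant, individual: str, hap: int) -> str:
    """Which base a molecule from haplotype ``hap`` shows at a het SNP."""
    gt = variant.genotype(individual)
    if gt == "0|1":
        return REF if hap == 1 else ALT
    return REF if hap == 2 else ALT


def simulate_read_fixture(cfg: ReadSimConfig) -> ReadFixture:
    """Toy genome, phased VCF and tagged reads with full truth tables.

    Molecule categories are constructed so their isoform identity is
    unambiguous by margin (except the deliberately ambiguous ``exonic``
    class): unspliced molecules overlap >= ~1/3 intron bases, spliced
    molecules span an isoform-discriminating junction. Allele evidence
    matches the molecule's haplotype through the phased genotypes, with
    per-observation flips at ``error_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _build_toy_genes(cfg)
    variants = _build_toy_variants(genes, cfg, rng)
    var_by_chrom = [(v.pos0, v) for v in variants]
    gene_ids = list(genes)
    effects = {g: (cfg.gene_effects or {}).get(g, 0.0) for g in gene_ids}
    cells = [f"CB{c:04d}" for c in range(cfg.n_cells)]
    skip = cfg.n_exons - 2

    reads: List[ReadRecord] = []
    truth_rows = []
    mol_rows = []
    for m in range(cfg.n_molecules):
        gene_id = gene_ids[int(rng.integers(len(gene_ids)))]
        gene = genes[gene_id]
        t1 = next(i for i in gene.isoforms if i.isoform_id.startswith("T1"))
        exons = list(t1.exon_blocks)
        cat = ["unspliced", "spliced", "exonic"][
            int(rng.choice(3, p=list(cfg.category_probs)))
        ]
        if cat == "unspliced":
            # single block: ~250 bases of an exon tail + the intron after it
            i = int(rng.integers(cfg.n_exons - 1))
            start = exons[i][1] - 250 + int(rng.integers(0, 50))
            blocks = [(start, start + cfg.read_len)]
            true_iso = f"unspliced_{gene_id}"
        elif cat == "spliced":
            # junction read on the isoform-discriminating part of T1 or T2
            if rng.random() < 0.5:
                true_iso = f"T1_{gene_id}"
                a, b = exons[skip - 1], exons[skip]
            else:
                true_iso = f"T2_{gene_id}"
                a, b = exons[skip - 1], exons[skip + 1]
            half = cfg.read_len // 2
            blocks = [(a[1] - half, a[1]), (b[0], b[0] + half)]
        else:
            # contiguous exon-contained block: pre-mRNA vs mRNA ambiguous
            i = int(rng.integers(cfg.n_exons))
            start = exons[i][0] + 50
            blocks = [(start, start + min(cfg.read_len // 2, cfg.exon_len - 100))]
            true_iso = None
        hap = 1 if rng.random() < expit(effects[gene_id]) else 2
        cbc = cells[int(rng.integers(cfg.n_cells))]
        umi = f"UMI{m:05d}"
        n_reads = 1 + int(rng.poisson(max(cfg.reads_per_molecule_mean - 1, 0)))
        mol_rows.append(
            {
                "molecule_id": m, "cell_barcode": cbc, "umi": umi, "gene_id": gene_id,
                "category": cat, "true_isoform": true_iso, "true_hap": hap,
                "n_reads": n_reads,
            }
        )
        for r in range(n_reads):
            evidence = []
            for pos0, v in var_by_chrom:
                if any(s <= pos0 < e for s, e in blocks):
                    obs = _observed_allele(v, cfg.individual, hap)
                    if rng.random() < cfg.error_rate:
                        obs = ALT if obs == REF else REF
                    evidence.append((v, obs))
            multi = rng.random() < cfg.frac_multimapped
            wasp_fail = (not multi) and rng.random() < cfg.frac_wasp_fail
            cigar = []
            prev_end = None
            for s, e in blocks:
                if prev_end is not None:
                    cigar.append(("N", s - prev_end))
                cigar.append(("=", e - s))
                prev_end = e
            read_id = f"read{m:05d}_{r}"
            reads.append(
                ReadRecord(
                    read_id=read_id,
                    chrom="chr1",
                    strand=gene.strand,
                    alignment_blocks=blocks,
                    cell_barcode=cbc,
                    umi=umi,
                    cigar_ops=tuple(cigar),
                    feature_tags={"gene": (gene_id,)},
                    n_alignments=2 if multi else 1,
                    wasp_pass=not wasp_fail,
                    alignment_score=sum(e - s for s, e in blocks),
                    variant_evidence=evidence,
                )
            )
            truth_rows.append(
                {
                    "read_id": read_id, "molecule_id": m, "cell_barcode": cbc,
                    "umi": umi, "gene_id": gene_id, "category": cat,
                    "true_isoform": true_iso, "true_hap": hap,
                    "n_het_snps": len(evidence),
                    "excluded": multi or wasp_fail,
                    "exclusion_reason": (
                        "multimapped" if multi else ("wasp_fail" if wasp_fail else "")
                    ),
                }
            )

    peak_rows = []
    for gene in genes.values():
        s, e = gene.span
        peak_rows.append(
            {"chrom": gene.chrom, "start": s, "end": e,
             "name": f"{gene.gene_id}_peakAll", "score": 0, "strand": gene.strand}
        )
        t1 = next(i for i in gene.isoforms if i.isoform_id.startswith("T1"))
        last = t1.exon_blocks[-1] if gene.strand == "+" else t1.exon_blocks[0]
        peak_rows.append(
            {"chrom": gene.chrom, "start": last[0], "end": last[1],
             "name": f"{gene.gene_id}_peak3p", "score": 0, "strand": gene.strand}
        )
    peaks = pd.DataFrame(peak_rows)

    last_gene = genes[gene_ids[-1]]
    chrom_lengths = {"chr1": last_gene.span[1] + 10000}
    return ReadFixture(
        genes=genes,
        variants=variants,
        reads=reads,
        peaks=peaks,
        truth=pd.DataFrame(truth_rows),
        molecule_truth=pd.DataFrame(mol_rows),
        chrom_lengths=chrom_lengths,
        individual=cfg.individual,
    )
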