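"""Allele resolution, UMI collapsing, counting oracles and read QC."""

from collections import defaultdict

import numpy as np
import pandas as pd
import pytest

from snase import ase_counting as ac
from snase.types import ALT, AMBIGUOUS, AseCountTable, HAP1, HAP2, PhasedVariant, PileupRow, ReadRecord, REF
from conftest import make_variant

IND = "ind"


def make_read(evidence, read_id="r", n_alignments=1, wasp_pass=True, cbc="c1", umi="u1",
              gene="G", blocks=None):
    """A read whose evidence is a list of (pos, observed_allele, genotype)."""
    if blocks is None:
        lo = min(p for p, _, _ in evidence) - 1 if evidence else 0
        hi = max(p for p, _, _ in evidence) + 1 if evidence else 100
        blocks = [(lo, hi)]
    ev = [(make_variant(p, gt, IND), a) for p, a, gt in evidence]
    return ReadRecord(
        read_id=read_id, chrom="chr1", strand="+", alignment_blocks=blocks,
        cell_barcode=cbc, umi=umi, feature_tags={"gene": (gene,)},
        n_alignments=n_alignments, wasp_pass=wasp_pass, variant_evidence=ev,
    )


class TestResolveReadAllele:
    def test_unanimous_evidence(self):
        read = make_read([(10, REF, "0|1"), (20, REF, "0|1"), (30, REF, "0|1")])
        assert ac.resolve_read_allele(read, IND) == REF

    def test_majority_rule_boundary(self):
        # 20/21 ~ 0.952 exceeds 95% strictly -> majority wins
        ev = [(10 * (i + 1), REF, "0|1") for i in range(20)] + [(500, ALT, "0|1")]
        assert ac.resolve_read_allele(make_read(ev), IND) == REF
        # 19/20 = 0.95 exactly is not strictly greater -> excluded
        ev = [(10 * (i + 1), REF, "0|1") for i in range(19)] + [(500, ALT, "0|1")]
        assert ac.resolve_read_allele(make_read(ev), IND) == ac.EXCLUDED

    def test_phase_translation(self):
        # GT 1|0: the alt base sits on haplotype 1
        read = make_read([(10, ALT, "1|0")])
        assert ac.resolve_read_allele(read, IND, mode="phased") == HAP1
        read = make_read([(10, REF, "1|0")])
        assert ac.resolve_read_allele(read, IND, mode="phased") == HAP2
        read = make_read([(10, REF, "0|1")])
        assert ac.resolve_read_allele(read, IND, mode="phased") == HAP1

    def test_exclusions(self):
        assert ac.resolve_read_allele(make_read([(10, REF, "0|1")], n_alignments=2), IND) == ac.EXCLUDED
        assert ac.resolve_read_allele(make_read([(10, REF, "0|1")], wasp_pass=False), IND) == ac.EXCLUDED
        # 'other' bases and non-het variants drop out; nothing left -> excluded
        assert ac.resolve_read_allele(make_read([(10, "other", "0|1")]), IND) == ac.EXCLUDED
        assert ac.resolve_read_allele(make_read([(10, REF, "1|1")]), IND) == ac.EXCLUDED
        assert ac.resolve_read_allele(make_read([]), IND) == ac.EXCLUDED

    def test_phased_all_01_matches_unphased_labels(self, clean_read_fixture):
        fx = clean_read_fixture
        for read in fx.reads:
            if not read.variant_evidence:
                continue
            if any(v.genotype(fx.individual) != "0|1" for v, _ in read.variant_evidence):
                continue
            unphased = ac.resolve_read_allele(read, fx.individual)
            phased = ac.resolve_read_allele(read, fx.individual, mode="phased")
            expected = {REF: HAP1, ALT: HAP2, ac.EXCLUDED: ac.EXCLUDED}[unphased]
            assert phased == expected


class TestCollapseAndCount:
    def test_agreeing_reads_collapse(self):
        rr = [ac.ResolvedRead("c1", "u1", "G", REF, IND)] * 3
        (call,) = ac.collapse_umis(rr)
        assert call.allele == REF and call.n_supporting_reads == 3

    def test_conflicting_reads_ambiguous(self):
        rr = [ac.ResolvedRead("c1", "u1", "G", REF, IND),
              ac.ResolvedRead("c1", "u1", "G", ALT, IND)]
        (call,) = ac.collapse_umis(rr)
        assert call.allele == AMBIGUOUS

    def test_collapse_matches_groupby_oracle(self):
        rng = np.random.default_rng(0)
        rr = [
            ac.ResolvedRead(f"c{rng.integers(5)}", f"u{rng.integers(40)}",
                            f"g{rng.integers(4)}", REF if rng.random() < 0.6 else ALT, IND)
            for _ in range(1000)
        ]
        calls = {(c.cell_barcode, c.umi, c.feature_id): c for c in ac.collapse_umis(rr)}
        oracle = defaultdict(list)
        for r in rr:
            oracle[(r.cell_barcode, r.umi, r.feature_id)].append(r.allele)
        assert set(calls) == set(oracle)
        for key, alleles in oracle.items():
            expected = alleles[0] if len(set(alleles)) == 1 else AMBIGUOUS
            assert calls[key].allele == expected
            assert calls[key].n_supporting_reads == len(alleles)

    def test_count_row_and_pseudobulk_additivity(self):
        calls = (
            [ac.collapse_umis([ac.ResolvedRead("c1", f"u{i}", "G", REF, IND)])[0] for i in range(5)]
            + [ac.collapse_umis([ac.ResolvedRead("c1", f"v{i}", "G", ALT, IND)])[0] for i in range(3)]
            + ac.collapse_umis(
                [ac.ResolvedRead("c1", "w0", "G", REF, IND), ac.ResolvedRead("c1", "w0", "G", ALT, IND)]
            )
        )
        table = ac.count_feature_ase(calls, unit="cell")
        assert table.df.iloc[0][["n_ref", "n_alt", "n_ambiguous"]].tolist() == [5, 3, 1]

    def test_pseudobulk_equals_column_sum(self, read_fixture):
        fx = read_fixture
        cell = ac.count_gene_ase(fx.reads, fx.individual, unit="cell")
        pb = ac.pseudobulk(cell)
        sums = cell.df.groupby("feature_id")[["n_ref", "n_alt", "n_ambiguous"]].sum()
        for r in pb.df.itertuples():
            assert [r.n_ref, r.n_alt, r.n_ambiguous] == sums.loc[r.feature_id].tolist()


def brute_force_counts(reads, individual, *, namespace="gene", mode="unphased"):
    """Independent tally: per-read resolution re-derived with plain loops."""
    groups = defaultdict(list)
    for read in reads:
        if read.n_alignments > 1 or read.wasp_pass is False:
            continue
        votes = []
        for v, obs in read.variant_evidence:
            if obs == "other" or v.genotype(individual) not in ("0|1", "1|0"):
                continue
            if mode == "phased":
                flip = v.genotype(individual) == "1|0"
                votes.append(("hap2" if flip else "hap1") if obs == REF else ("hap1" if flip else "hap2"))
            else:
                votes.append(obs)
        if not votes:
            continue
        top = max(set(votes), key=votes.count)
        if votes.count(top) == len(votes):
            allele = top
        elif votes.count(top) / len(votes) > 0.95:
            allele = top
        else:
            continue
        for feat in read.feature_tags.get(namespace, ()):
            groups[(read.cell_barcode, read.umi, feat)].append(allele)
    tally = defaultdict(lambda: [0, 0, 0])
    for (cbc, _, feat), alleles in groups.items():
        if len(set(alleles)) > 1:
            tally[(cbc, feat)][2] += 1
        elif alleles[0] in (REF, "hap1"):
            tally[(cbc, feat)][0] += 1
        else:
            tally[(cbc, feat)][1] += 1
    return dict(tally)


def table_as_dict(table):
    return {
        (r.unit_id, r.feature_id): [r.n_ref, r.n_alt, r.n_ambiguous]
        for r in table.df.itertuples()
    }


class TestCountingOracles:
    @pytest.mark.parametrize("mode", ["unphased", "phased"])
    def test_gene_counts_match_brute_force(self, read_fixture, mode):
        fx = read_fixture
        table = ac.count_gene_ase(fx.reads, fx.individual, mode=mode)
        assert table_as_dict(table) == brute_force_counts(fx.reads, fx.individual, mode=mode)

    def test_snp_counts_match_brute_force(self, read_fixture):
        fx = read_fixture
        table = ac.count_snp_ase(fx.reads, fx.individual)
        oracle = defaultdict(lambda: [0, 0, 0])
        groups = defaultdict(list)
        for read in fx.reads:
            if read.n_alignments > 1 or read.wasp_pass is False:
                continue
            for v, obs in read.variant_evidence:
                if obs == "other" or not v.is_het(fx.individual):
                    continue
                groups[(read.cell_barcode, read.umi, v.key)].append(obs)
        for (cbc, _, key), obs in groups.items():
            if len(set(obs)) > 1:
                oracle[(cbc, key)][2] += 1
            elif obs[0] == REF:
                oracle[(cbc, key)][0] += 1
            else:
                oracle[(cbc, key)][1] += 1
        assert table_as_dict(table) == dict(oracle)

    def test_read_over_two_snps_contributes_to_each(self):
        read = make_read([(10, REF, "0|1"), (20, ALT, "0|1")])
        table = ac.count_snp_ase([read], IND)
        d = table_as_dict(table)
        assert d[("c1", "chr1:10:A:G")] == [1, 0, 0]
        assert d[("c1", "chr1:20:A:G")] == [0, 1, 0]

    def test_full_span_peak_counts_equal_gene_counts(self, read_fixture):
        fx = read_fixture
        ac.assign_peaks(fx.reads, fx.peaks)
        peak = ac.count_peak_ase(fx.reads, fx.individual)
        gene = ac.count_gene_ase(fx.reads, fx.individual)
        gene_d = table_as_dict(gene)
        peak_d = table_as_dict(peak)
        for (cbc, feat), counts in gene_d.items():
            assert peak_d[(cbc, f"{feat}_peakAll")] == counts
        assert table_as_dict(peak) == brute_force_counts(
            fx.reads, fx.individual, namespace="peak"
        )

    def test_conservation_of_molecules(self, read_fixture):
        # n_ref + n_alt + n_ambiguous over the whole table equals the number
        # of distinct (cell, UMI, gene) triples with >= 1 non-excluded read
        fx = read_fixture
        table = ac.count_gene_ase(fx.reads, fx.individual)
        triples = set()
        for read in fx.reads:
            if read.n_alignments > 1 or read.wasp_pass is False:
                continue
            votes = [
                obs for v, obs in read.variant_evidence
                if obs != "other" and v.is_het(fx.individual)
            ]
            if not votes:
                continue
            top = max(votes.count(REF), votes.count(ALT))
            if top < len(votes) and top / len(votes) <= 0.95:
                continue  # mixed evidence below the majority rule: excluded
            for g in read.feature_tags.get("gene", ()):
                triples.add((read.cell_barcode, read.umi, g))
        assert table.total_molecules() == len(triples)

    def test_allele_swap_symmetry(self, read_fixture):
        fx = read_fixture
        swapped = []
        for read in fx.reads:
            ev = [(v, {REF: ALT, ALT: REF}.get(a, a)) for v, a in read.variant_evidence]
            swapped.append(
                ReadRecord(
                    read_id=read.read_id, chrom=read.chrom, strand=read.strand,
                    alignment_blocks=read.alignment_blocks, cell_barcode=read.cell_barcode,
                    umi=read.umi, feature_tags=read.feature_tags,
                    n_alignments=read.n_alignments, wasp_pass=read.wasp_pass,
                    variant_evidence=ev,
                )
            )
        orig = table_as_dict(ac.count_gene_ase(fx.reads, fx.individual))
        flip = table_as_dict(ac.count_gene_ase(swapped, fx.individual))
        assert set(orig) == set(flip)
        for key, (r, a, m) in orig.items():
            assert flip[key] == [a, r, m]


class TestHetCalling:
    @pytest.mark.parametrize(
        "dp,ad,kept",
        [
            (11, 5, True),    # ratio 0.4545, DP just above threshold
            (10, 5, False),   # DP must be strictly > 10
            (100, 9, False),  # ratio 0.09 below the open interval
            (100, 10, False), # ratio exactly 0.1 rejected (strict bound)
            (100, 90, False), # ratio exactly 0.9 rejected
            (100, 11, True),
            (100, 89, True),
        ],
    )
    def test_dp_and_ratio_bounds(self, dp, ad, kept):
        rows = [PileupRow("chr1", 100, "A", "G", dp, ad)]
        variants = ac.call_het_snps_from_pileup(rows, "s1")
        assert (len(variants) == 1) == kept
        if kept:
            assert variants[0].genotype("s1") == "0|1"


class TestRegionAnnotation:
    def region_read(self, blocks, strand="+"):
        return ReadRecord("r", "chr1", strand, blocks, cell_barcode="c", umi="u")

    def test_precedence_categories(self, toy_gene):
        gm = {"G": toy_gene}
        assert ac.annotate_read_region(self.region_read([(2450, 2550)]), gm) == "UTR3"
        assert ac.annotate_read_region(self.region_read([(1000, 1080)]), gm) == "UTR5"
        assert ac.annotate_read_region(self.region_read([(1150, 1350)]), gm) == "exon"
        assert ac.annotate_read_region(self.region_read([(1500, 2100)]), gm) == "intron"
        assert ac.annotate_read_region(self.region_read([(1500, 2100)], "-"), gm) == "antisense"
        assert ac.annotate_read_region(self.region_read([(5000, 5100)]), gm) == "intergenic"

    def test_phasing_rate_extremes(self, toy_gene):
        gm = {"G": toy_gene}
        intronic = [self.region_read([(1500 + i, 1700 + i)]) for i in range(3)]
        exonic = [self.region_read([(1150, 1350)])]
        het = [make_variant(1601)]  # pos0=1600, inside every intronic read
        rates = ac.phasing_rate_by_region(intronic + exonic, het, gm).set_index("category")
        assert rates.loc["intron", "fraction"] == 1.0
        assert rates.loc["exon", "fraction"] == 0.0
        assert np.isnan(rates.loc["intergenic", "fraction"])
        norates = ac.phasing_rate_by_region(intronic, [], gm).set_index("category")
        assert norates.loc["intron", "fraction"] == 0.0

    def test_multimappers_excluded_from_qc(self, toy_gene):
        read = ReadRecord("r", "chr1", "+", [(1500, 1700)], cell_barcode="c", umi="u",
                          n_alignments=3)
        rates = ac.phasing_rate_by_region([read], [], {"G": toy_gene})
        assert rates["n_reads"].sum() == 0


class TestCigarProfile:
    def prof(self, ops):
        read = ReadRecord("r", "chr1", "+", [(0, 1000)], cigar_ops=ops)
        return ac.cigar_profile([read])

    def test_mismatch_rate(self):
        per_read, agg = self.prof([("=", 10), ("X", 1), ("=", 10)])
        assert agg["mapped_bases"] == 21 and agg["matches"] == 20
        assert agg["mismatches"] == 1 and agg["mismatch_rate"] == pytest.approx(0.05)

    def test_insertion_rate(self):
        _, agg = self.prof([("=", 5), ("I", 2), ("=", 5)])
        assert agg["insertion_rate"] == pytest.approx(0.2)
        assert agg["mapped_bases"] == 10

    def test_deletion_not_read_consuming(self):
        _, agg = self.prof([("=", 5), ("D", 1), ("=", 5)])
        assert agg["deletions"] == 1 and agg["mapped_bases"] == 10

    def test_match_agnostic_cigar_reports_missing(self):
        per_read, agg = self.prof([("M", 20)])
        assert np.isnan(per_read["mismatches"].iloc[0])
        assert agg["mapped_bases"] == 20


class TestBaitDesign:
    def test_snp_flank_windows_merge(self):
        snps = [make_variant(1000), make_variant(1100)]
        bed = ac.design_bait_regions(mode="snp_flank", snps=snps)
        # 1-based 870..1130 and 970..1230 merge into 870..1230
        assert bed.values.tolist() == [["chr1", 869, 1230]]

    def test_snp_flank_support_filter(self):
        snps = [make_variant(1000), make_variant(5000)]
        support = {"s1": {snps[0].key: 2, snps[1].key: 1}, "s2": {snps[0].key: 3}}
        bed = ac.design_bait_regions_snp_flank(snps, support)
        assert len(bed) == 1 and bed.start[0] == 869

    def test_coverage_three_prime_extension(self):
        bed = pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 200, "name": "e", "score": 0, "strand": "+"}]
        )
        het = {"s": [make_variant(150)]}
        out = ac.design_bait_regions_coverage({"s": bed}, het, min_depth=1)
        assert out.values.tolist() == [["chr1", 100, 400]]
        minus = bed.assign(strand="-")
        out = ac.design_bait_regions_coverage({"s": minus}, het, min_depth=1)
        assert out.values.tolist() == [["chr1", 0, 200]]

    def test_coverage_depth_threshold(self):
        bed = pd.DataFrame(
            [{"chrom": "chr1", "start": 100, "end": 300, "name": "e", "score": 0, "strand": "+"}]
        )
        het = {f"s{i}": [make_variant(150)] for i in range(9)}
        beds = {s: bed for s in het}
        assert ac.design_bait_regions_coverage(beds, het, min_depth=10).empty
        het10 = {f"s{i}": [make_variant(150)] for i in range(10)}
        beds10 = {s: bed for s in het10}
        out = ac.design_bait_regions_coverage(beds10, het10, min_depth=10)
        assert out.values.tolist() == [["chr1", 100, 500]]

    def test_strandless_coverage_entries_rejected(self):
        bed = pd.DataFrame([{"chrom": "chr1", "start": 100, "end": 200}])
        with pytest.raises(ValueError, match="strand"):
            ac.design_bait_regions_coverage({"s": bed}, {"s": [make_variant(150)]})


class TestDownsampling:
    def test_fraction_one_is_identity(self, read_fixture):
        assert ac.downsample_molecules(read_fixture.reads, 1.0, seed=1) == read_fixture.reads

    def test_deterministic_given_seed(self, read_fixture):
        a = ac.downsample_molecules(read_fixture.reads, 0.5, seed=9)
        b = ac.downsample_molecules(read_fixture.reads, 0.5, seed=9)
        assert [r.read_id for r in a] == [r.read_id for r in b]

    def test_kept_count_within_binomial_bound(self):
        items = list(range(10_000))
        kept = ac.downsample_molecules(items, 0.5, seed=2)
        # 99% binomial interval around 5000 (sd 50)
        assert 4871 <= len(kept) <= 5129

    def test_table_thinning_and_errors(self):
        df = pd.DataFrame(
            [{"unit_id": "c", "individual_id": "i", "feature_id": "g",
              "n_ref": 1000, "n_alt": 1000, "n_ambiguous": 0}]
        )
        out = ac.downsample_molecules(AseCountTable(df), 0.5, seed=3)
        assert 400 < out.df.n_ref[0] < 600
        with pytest.raises(ValueError):
            ac.downsample_molecules(df_or := AseCountTable(df), 0.0, seed=1)
        with pytest.raises(ValueError):
            ac.downsample_molecules(df_or, 1.5, seed=1)
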