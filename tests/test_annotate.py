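import numpy as np
import pytest

from g4kit.annotate import (
    FEATURE_CLASSES,
    FeatureMap,
    GeneModel,
    assign_region,
    build_feature_map,
    density_table,
    read_gene_table,
    region_fractions,
    tss_profile,
    write_gene_table,
)
from g4kit.evidence import EvidenceGroups
from g4kit.intervals import FormatError, GenomicInterval, IntervalSet


def one_gene(strand="+"):
    return GeneModel(
        gene_id="g1",
        chrom="chr1",
        strand=strand,
        tx_start=20_000,
        tx_end=30_000,
        cds_start=21_000,
        cds_end=29_000,
        exons=((20_000, 30_000),),
    )


CHROMS = {"chr1": 100_000}


def groups_of(ivs, which="G4-II"):
    empty = IntervalSet("e", [])
    sets = {"G4-I": empty, "G4-II": empty, "G4-III": empty}
    sets[which] = IntervalSet(which, ivs)
    return EvidenceGroups(g4_I=sets["G4-I"], g4_II=sets["G4-II"], g4_III=sets["G4-III"])


class TestFeatureMap:
    def test_hand_layout_plus_gene(self):
        fmap = build_feature_map([one_gene("+")], CHROMS)
        spans = {
            k: [(iv.start, iv.end) for iv in s.intervals]
            for k, s in fmap.classes.items()
        }
        assert spans["upstream10kb"] == [(10_000, 20_000)]
        assert spans["downstream2kb"] == [(30_000, 32_000)]
        assert spans["utr5"] == [(20_000, 21_000)]
        assert spans["utr3"] == [(29_000, 30_000)]
        assert spans["exon"] == [(21_000, 29_000)]  # UTR bases claimed first
        assert spans["intron"] == []
        assert spans["intergenic"] == [(0, 10_000), (32_000, 100_000)]

    def test_minus_gene_mirror(self):
        fmap = build_feature_map([one_gene("-")], CHROMS)
        spans = {
            k: [(iv.start, iv.end) for iv in s.intervals]
            for k, s in fmap.classes.items()
        }
        assert spans["upstream10kb"] == [(30_000, 40_000)]
        assert spans["downstream2kb"] == [(18_000, 20_000)]
        assert spans["utr5"] == [(29_000, 30_000)]
        assert spans["utr3"] == [(20_000, 21_000)]

    def test_partition_invariant(self):
        fmap = build_feature_map([one_gene()], CHROMS)
        assert sum(fmap.lengths.values()) == CHROMS["chr1"]

    def test_precedence_via_per_base_oracle(self):
        # second gene's exon lies inside the first gene's upstream window
        g2 = GeneModel("g2", "chr1", "+", 12_000, 14_000, 12_300, 13_700,
                       exons=((12_000, 14_000),))
        genes = [one_gene(), g2]
        fmap = build_feature_map(genes, CHROMS)
        # per-base oracle: paint classes in precedence order, first claim wins
        paint = np.full(CHROMS["chr1"], -1, dtype=int)
        raw = {
            "upstream10kb": [(10_000, 20_000), (2_000, 12_000)],
            "utr5": [(20_000, 21_000), (12_000, 12_300)],
            "utr3": [(29_000, 30_000), (13_700, 14_000)],
            "exon": [(20_000, 30_000), (12_000, 14_000)],
            "intron": [],
            "downstream2kb": [(30_000, 32_000), (14_000, 16_000)],
        }
        for rank, cls in enumerate(FEATURE_CLASSES[:-1]):
            for s, e in raw[cls]:
                sel = paint[s:e] == -1
                paint[s:e][sel] = rank
        for rank, cls in enumerate(FEATURE_CLASSES[:-1]):
            want = int((paint == rank).sum())
            assert fmap.lengths[cls] == want, cls
        assert fmap.lengths["intergenic"] == int((paint == -1).sum())
        assert sum(fmap.lengths.values()) == CHROMS["chr1"]

    def test_gene_beyond_bounds_rejected(self):
        bad = GeneModel("g", "chr1", "+", 99_000, 101_000)
        with pytest.raises(FormatError, match="beyond chromosome end"):
            build_feature_map([bad], CHROMS)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(FormatError, match="unknown chromosome"):
            build_feature_map([one_gene()], {"chrX": 1000})


class TestAssignRegion:
    def test_midpoint_rule_at_boundary(self):
        fmap = build_feature_map([one_gene()], CHROMS)
        # [19990, 20010) has midpoint 20000, the first utr5 base
        assert assign_region(GenomicInterval("chr1", 19_990, 20_010), fmap) == "utr5"

    def test_intergenic(self):
        fmap = build_feature_map([one_gene()], CHROMS)
        assert assign_region(GenomicInterval("chr1", 500, 600), fmap) == "intergenic"

    def test_fractions_sum_to_one(self):
        fmap = build_feature_map([one_gene()], CHROMS)
        rng = np.random.default_rng(0)
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 20)
            for s in rng.integers(0, 99_000, size=50)
        ]
        fracs = region_fractions(groups_of(ivs), fmap)
        per_group = fracs.groupby("group")["fraction"].sum()
        assert per_group["G4-II"] == pytest.approx(1.0)


class TestDensity:
    def test_arithmetic(self):
        # class of 4000 bp with two 100-bp overlaps -> 50 BPKB
        gene = GeneModel("g", "chr1", "+", 20_000, 24_000, exons=((20_000, 24_000),))
        fmap = build_feature_map([gene], {"chr1": 100_000})
        ivs = [GenomicInterval("chr1", 20_100, 20_200), GenomicInterval("chr1", 23_000, 23_100)]
        t = density_table(groups_of(ivs), fmap).set_index(["group", "class"])
        assert t.loc[("G4-II", "exon"), "bpkb"] == pytest.approx(50.0)

    def test_boundary_spanning_g4_contributes_overlap(self):
        fmap = FeatureMap(
            classes={
                "upstream10kb": IntervalSet("u", []),
                "utr5": IntervalSet("u5", []),
                "utr3": IntervalSet("u3", []),
                "exon": IntervalSet("e", [GenomicInterval("chr1", 0, 1000)]),
                "intron": IntervalSet("i", []),
                "downstream2kb": IntervalSet("d", []),
                "intergenic": IntervalSet("ig", [GenomicInterval("chr1", 1000, 2000)]),
            },
            chrom_lengths={"chr1": 2000},
        )
        ivs = [GenomicInterval("chr1", 950, 1050)]
        t = density_table(groups_of(ivs), fmap).set_index(["group", "class"])
        assert t.loc[("G4-II", "exon"), "overlap_bp"] == 50
        assert t.loc[("G4-II", "intergenic"), "overlap_bp"] == 50

    def test_empty_class_is_nan_not_zero(self):
        fmap = build_feature_map([one_gene()], CHROMS)  # intron length 0
        t = density_table(groups_of([]), fmap).set_index(["group", "class"])
        assert np.isnan(t.loc[("G4-II", "intron"), "bpkb"])
        assert t.loc[("G4-II", "exon"), "bpkb"] == 0.0

    def test_against_per_base_oracle_toy_genome(self):
        gene = GeneModel("g", "toy", "+", 2000, 6000, 2500, 5500,
                         exons=((2000, 3000), (4000, 6000)))
        chroms = {"toy": 10_000}
        fmap = build_feature_map([gene], chroms)
        rng = np.random.default_rng(8)
        ivs = [
            GenomicInterval("toy", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 9_900, 30), rng.integers(5, 90, 30))
        ]
        t = density_table(groups_of(ivs), fmap).set_index(["group", "class"])
        # oracle: label every base, accumulate per-G4 overlap per class
        paint = np.empty(10_000, dtype=object)
        for cls in FEATURE_CLASSES:
            for iv in fmap.classes[cls].intervals:
                paint[iv.start : iv.end] = cls
        for cls in FEATURE_CLASSES:
            want = sum(int((paint[iv.start : iv.end] == cls).sum()) for iv in ivs)
            assert t.loc[("G4-II", cls), "overlap_bp"] == want


class TestTssProfile:
    def test_midpoint_at_plus_tss(self):
        genes = [one_gene("+")]
        ivs = [GenomicInterval("chr1", 19_995, 20_005)]  # midpoint 20000 = TSS
        prof = tss_profile(groups_of(ivs), genes, bin_size=500)
        hit = prof[(prof.group == "G4-II") & (prof["count"] > 0)]
        assert len(hit) == 1
        assert hit.iloc[0].bin_start <= 0 <= hit.iloc[0].bin_end

    def test_minus_gene_sign_convention(self):
        genes = [one_gene("-")]  # TSS at 30000, 5' side is the right
        ivs = [GenomicInterval("chr1", 30_495, 30_505)]  # 500 bp 5' of TSS
        prof = tss_profile(groups_of(ivs), genes, bin_size=500)
        hit = prof[(prof.group == "G4-II") & (prof["count"] > 0)]
        assert len(hit) == 1
        assert hit.iloc[0].bin_start == -500

    def test_conservation(self):
        genes = [one_gene("+")]
        rng = np.random.default_rng(1)
        ivs = [
            GenomicInterval("chr1", int(s), int(s) + 10)
            for s in rng.integers(5_000, 40_000, size=80)
        ]
        prof = tss_profile(groups_of(ivs), genes, bin_size=500)
        in_window = sum(
            1 for iv in ivs if -10_000 <= (iv.midpoint - 20_000) <= 500
        )
        assert prof[prof.group == "G4-II"]["count"].sum() == in_window

    def test_uneven_bin_rejected(self):
        with pytest.raises(ValueError, match="divide the window"):
            tss_profile(groups_of([]), [one_gene()], bin_size=333)


class TestGeneTableIO:
    def test_roundtrip(self, tmp_path):
        genes = [one_gene("+"),
                 GeneModel("g2", "chr1", "-", 50_000, 52_000,
                           exons=((50_000, 50_500), (51_500, 52_000)))]
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        back = read_gene_table(path)
        assert [g.gene_id for g in back] == ["g1", "g2"]
        assert back[0].cds_start == 21_000
        assert back[1].exons == ((50_000, 50_500), (51_500, 52_000))
        assert back[1].cds_start is None
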