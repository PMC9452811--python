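from itertools import product

import numpy as np
import pytest

from g4kit.feet import (
    FootPair,
    cluster_motifs,
    enrichment_test,
    extract_feet,
    filter_significant,
    kmer_presence,
    write_meme_motifs,
)
from g4kit.hunter import G4Prediction, revcomp
from g4kit.intervals import Genome, GenomicInterval


def pred(chrom, start, end, strand="+"):
    return G4Prediction(GenomicInterval(chrom, start, end, strand, 2.0), 2.0)


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), 200))
    return Genome({"c": seq}), seq


class TestExtractFeet:
    def test_plus_strand(self, toy_genome):
        genome, seq = toy_genome
        feet = extract_feet([pred("c", 100, 120)], genome)
        assert feet[0].left == seq[50:100]
        assert feet[0].right == seq[120:170]

    def test_minus_strand_swapped_revcomp(self, toy_genome):
        genome, seq = toy_genome
        feet = extract_feet([pred("c", 100, 120, "-")], genome)
        assert feet[0].left == revcomp(seq[120:170])
        assert feet[0].right == revcomp(seq[50:100])

    def test_edge_clipping(self, toy_genome):
        genome, seq = toy_genome
        feet = extract_feet([pred("c", 20, 40)], genome)
        assert feet[0].left == seq[0:20]
        assert len(feet[0].left) == 20

    def test_feet_exclude_g4_bases(self, toy_genome):
        genome, seq = toy_genome
        feet = extract_feet([pred("c", 100, 120)], genome)
        assert len(feet[0].left) == 50 and len(feet[0].right) == 50
        assert seq[100:120] not in feet[0].left + feet[0].right or len(seq[100:120]) < 6

    def test_outside_genome_rejected(self, toy_genome):
        genome, _ = toy_genome
        with pytest.raises(ValueError, match="outside genome"):
            extract_feet([pred("c", 150, 300)], genome)


class TestKmerPresence:
    def test_half_presence(self):
        feet = [
            FootPair("a", "GCGCGCAAAA", "TTTT"),
            FootPair("b", "AAAA", "TTGCGCGCTT"),
            FootPair("c", "AAAAAAAAAA", "TTTT"),
            FootPair("d", "ACACAC", "TGTGTG"),
        ]
        table = kmer_presence(feet, k=6)
        assert table["GCGCGC"] == pytest.approx(0.5)

    def test_absent_kmer_zero(self):
        table = kmer_presence([FootPair("a", "AAAAAAAA", "AAAA")], k=6)
        assert table["GGGGGG"] == 0.0
        assert table["AAAAAA"] == 1.0

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(3)
        feet = [
            FootPair(
                f"g{i}",
                "".join(rng.choice(list("ACGT"), 30)),
                "".join(rng.choice(list("ACGT"), 30)),
            )
            for i in range(20)
        ]
        table = kmer_presence(feet, k=4)
        for kmer in ("ACGT", "GGGG", "TATA", "CCGG"):
            want = sum(1 for fp in feet if kmer in fp.left or kmer in fp.right) / 20
            assert table[kmer] == pytest.approx(want)

    def test_foot_order_invariance(self):
        a = [FootPair("x", "GCGCGCAA", "TTTTTTTT")]
        b = [FootPair("x", "TTTTTTTT", "GCGCGCAA")]
        assert kmer_presence(a, 6) == kmer_presence(b, 6)

    def test_frequencies_in_unit_interval(self):
        rng = np.random.default_rng(1)
        feet = [FootPair(f"g{i}", "".join(rng.choice(list("ACGT"), 50)), "") for i in range(10)]
        assert all(0.0 <= v <= 1.0 for v in kmer_presence(feet).values())


def oracle_binom_upper(k, n, p):
    """Exhaustive enumeration of all 2^n outcome sequences."""
    total = 0.0
    for outcome in product([0, 1], repeat=n):
        if sum(outcome) >= k:
            prob = 1.0
            for o in outcome:
                prob *= p if o else (1 - p)
            total += prob
    return total


def uniform_tables(k, ft, fb):
    kmers = ["".join(p) for p in product("ACGT", repeat=k)]
    return {m: ft for m in kmers}, {m: fb for m in kmers}


class TestEnrichmentTest:
    def test_closed_form_example(self):
        t, b = uniform_tables(2, 1.0, 0.5)  # 16 2-mers, all observed 10/10
        res = {r.kmer: r for r in enrichment_test(t, b, 10, 100)}
        assert res["AA"].p == pytest.approx(2.0 ** -10)
        assert res["AA"].fe == pytest.approx(2.0)

    def test_observed_zero_p_one(self):
        t, b = uniform_tables(2, 0.0, 0.5)
        res = enrichment_test(t, b, 10, 100)
        assert all(r.p == pytest.approx(1.0) for r in res)

    @pytest.mark.parametrize("n,k,p", [(8, 3, 0.25), (10, 10, 0.5), (12, 1, 0.1), (9, 0, 0.3)])
    def test_matches_bruteforce_enumeration(self, n, k, p):
        t, b = uniform_tables(1, k / n, p)
        res = enrichment_test(t, b, n, 10_000)  # big N_background: no floor
        assert res[0].p == pytest.approx(oracle_binom_upper(k, n, p), abs=1e-12)

    def test_monotone_in_observed_count(self):
        ps = []
        for k in range(0, 11):
            t, b = uniform_tables(1, k / 10, 0.3)
            ps.append(enrichment_test(t, b, 10, 1000)[0].p)
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_fold_enrichment_inversion(self):
        t, b = uniform_tables(1, 0.4, 0.1)
        fwd = enrichment_test(t, b, 100, 100)[0].fe
        rev = enrichment_test(b, t, 100, 100)[0].fe
        assert fwd * rev == pytest.approx(1.0)

    def test_background_floor_applied(self):
        t, b = uniform_tables(1, 0.5, 0.0)
        r = enrichment_test(t, b, 10, 50)[0]
        assert np.isfinite(r.fe)
        assert r.fe == pytest.approx(0.5 / (1 / 100))

    def test_bonferroni_family_is_4_to_k(self):
        t, b = uniform_tables(2, 0.9, 0.05)
        r = enrichment_test(t, b, 40, 400)[0]
        assert r.p_adj == pytest.approx(min(1.0, r.p * 16))

    def test_zero_target_rejected(self):
        t, b = uniform_tables(1, 0.0, 0.1)
        with pytest.raises(ValueError, match="N_target"):
            enrichment_test(t, b, 0, 10)


def enr(kmer="AAAAAA", p_adj=0.01, fe=10.0, freq=0.3):
    from g4kit.feet import KmerEnrichment

    return KmerEnrichment(kmer, freq, freq / fe, int(freq * 100), 100, fe, p_adj / 4096, p_adj)


class TestFilterSignificant:
    def test_boundaries_strict(self):
        assert filter_significant([enr(p_adj=0.05)]) == []
        assert filter_significant([enr(fe=4.0)]) == []
        assert filter_significant([enr(freq=0.02)]) == []

    def test_passing(self):
        assert len(filter_significant([enr(p_adj=0.049, fe=4.01, freq=0.021)])) == 1

    def test_planted_scenario(self):
        rng = np.random.default_rng(0)
        planted = "GCGCGC"

        def random_foot(with_kmer):
            seq = "".join(rng.choice(list("AT"), 44))
            return seq[:20] + planted + seq[20:] if with_kmer else seq + "ATATAT"

        target = [
            FootPair(f"t{i}", random_foot(rng.random() < 0.30), "TTTT")
            for i in range(500)
        ]
        background = [
            FootPair(f"b{i}", random_foot(rng.random() < 0.01), "TTTT")
            for i in range(500)
        ]
        res = enrichment_test(
            kmer_presence(target), kmer_presence(background), 500, 500
        )
        sig = {r.kmer for r in filter_significant(res)}
        assert planted in sig
        assert "GGGGGG" not in sig  # unplanted


class TestClusterMotifs:
    def test_shifted_pair_joins(self):
        clusters = cluster_motifs({"GCGCGC": 0.3, "CGCGCG": 0.2})
        assert len(clusters) == 1
        assert set(clusters[0].members) == {"GCGCGC", "CGCGCG"}

    def test_unrelated_split(self):
        clusters = cluster_motifs({"GCGCGC": 0.3, "TATATC": 0.2})
        assert len(clusters) == 2

    def test_single_kmer_unit_columns(self):
        clusters = cluster_motifs({"ACGTAC": 0.5})
        pfm = clusters[0].pfm
        assert pfm.shape == (4, 6)
        # each column is a unit vector scaled by the weight
        assert np.allclose(pfm.max(axis=0), 0.5)
        assert np.allclose(pfm.sum(axis=0), 0.5)
        assert clusters[0].consensus == "ACGTAC"

    def test_every_kmer_in_exactly_one_cluster(self):
        rng = np.random.default_rng(2)
        kmers = {"".join(rng.choice(list("ACGT"), 6)): float(rng.uniform(0.05, 0.5))
                 for _ in range(30)}
        clusters = cluster_motifs(kmers)
        assigned = [m for c in clusters for m in c.members]
        assert sorted(assigned) == sorted(kmers)

    def test_pfm_columns_sum_to_total_weight(self):
        clusters = cluster_motifs({"GCGCGC": 0.3, "CGCGCG": 0.2, "GCGCGA": 0.1})
        for c in clusters:
            total = sum(c.weights.values())
            assert np.allclose(c.pfm.sum(axis=0), total)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no k-mers"):
            cluster_motifs({})

    def test_meme_output(self, tmp_path):
        clusters = cluster_motifs({"GCGCGC": 0.3, "CGCGCG": 0.2})
        path = tmp_path / "motifs.meme"
        write_meme_motifs(clusters, str(path))
        text = path.read_text()
        assert "MEME version 4" in text
        assert "letter-probability matrix" in text
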