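import numpy as np
import pytest

from helpers import naive_ward_partition, nw_score, partition_key
from telotype.allele_cluster import (
    AlleleCluster,
    cluster_reads,
    flag_blank,
    pairwise_score,
    pairwise_score_matrix,
    refine_cluster,
    score_to_distance,
    subtelomere_distance_matrix,
)
from telotype.simulate import decode_pattern, random_dna
from telotype.telomere_scan import TelomereRead
from telotype.tvr_encode import SymbolString, encode_tel_region


def _member(read_id, subtel, tel_seq, rs):
    read = TelomereRead(read_id, subtel + tel_seq, "telomere_at_end", len(subtel), 10)
    return read, encode_tel_region(tel_seq, rs)


class TestPairwiseScore:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("CCDCC", "CCDCC", 25),  # 5 matches x +5
            ("CD", "CE", 1),  # one match, one mismatch
            ("C", "", -4),  # forced single gap
            ("??", "??", -8),  # unknown never matches, even itself
        ],
    )
    def test_examples(self, rs, a, b, expected):
        assert pairwise_score(a, b, rs) == expected

    def test_agrees_with_dp_oracle(self, rs, rng):
        syms = list(rs.alphabet)
        for _ in range(60):
            a = "".join(rng.choice(syms, size=rng.integers(0, 25)))
            b = "".join(rng.choice(syms, size=rng.integers(0, 25)))
            assert pairwise_score(a, b, rs) == nw_score(a, b)

    def test_banded_matrix_agrees_with_exact_matrix(self, rs, rng):
        # same-allele-like strings: mostly canonical with scattered edits
        strings = []
        base = "".join(rng.choice(list("CCCCCCDEFL"), 300))
        for _ in range(8):
            l = list(base)
            for _ in range(12):
                i = int(rng.integers(0, len(l)))
                op = int(rng.integers(0, 3))
                if op == 0:
                    l[i] = str(rng.choice(list(rs.alphabet)))
                elif op == 1 and len(l) > 1:
                    del l[i]
                else:
                    l.insert(i, str(rng.choice(list(rs.alphabet))))
            strings.append("".join(l))
        fast = pairwise_score_matrix(strings, rs)
        exact = pairwise_score_matrix(strings, rs, band=None)
        np.testing.assert_allclose(fast, exact)


class TestScoreToDistance:
    def test_identical_strings_distance_zero(self):
        S = np.array([[25.0, 25.0], [25.0, 25.0]])
        D, valid = score_to_distance(S)
        assert valid.all()
        assert D[0, 1] == 0.0

    def test_formula(self):
        S = np.array([[25.0, 1.0], [1.0, 25.0]])
        D, _ = score_to_distance(S)
        assert D[0, 1] == pytest.approx(0.96)

    def test_negative_cross_score_clips_to_one(self):
        S = np.array([[25.0, -10.0], [-10.0, 25.0]])
        D, _ = score_to_distance(S)
        assert D[0, 1] == 1.0

    def test_non_positive_self_score_excluded(self):
        S = np.array([[25.0, 1.0, 0.0], [1.0, 25.0, 0.0], [0.0, 0.0, -8.0]])
        D, valid = score_to_distance(S)
        assert list(valid) == [True, True, False]
        assert D.shape == (2, 2)


class TestClusterReads:
    def _two_group_distances(self, n=10, inter=0.9):
        D = np.full((2 * n, 2 * n), inter)
        D[:n, :n] = 0.0
        D[n:, n:] = 0.0
        np.fill_diagonal(D, 0.0)
        return D

    def test_two_clean_groups(self):
        clusters, unassigned = cluster_reads(self._two_group_distances(), cut=0.40)
        assert len(clusters) == 2
        assert not unassigned
        assert sorted(map(len, clusters)) == [10, 10]

    def test_all_identical_one_cluster(self):
        D = np.zeros((8, 8))
        clusters, _ = cluster_reads(D, cut=0.40)
        assert len(clusters) == 1

    def test_three_groups_membership(self):
        n = 6
        D = np.full((3 * n, 3 * n), 0.85)
        for g in range(3):
            D[g * n : (g + 1) * n, g * n : (g + 1) * n] = 0.0
        np.fill_diagonal(D, 0.0)
        clusters, _ = cluster_reads(D, cut=0.40)
        assert partition_key(clusters) == partition_key(
            [list(range(g * n, (g + 1) * n)) for g in range(3)]
        )

    def test_small_groups_unassigned(self):
        D = self._two_group_distances(n=2)
        clusters, unassigned = cluster_reads(D, cut=0.40, min_reads=3)
        assert clusters == []
        assert len(unassigned) == 4

    def test_matches_naive_ward_oracle_on_small_inputs(self, rng):
        for trial in range(20):
            n = int(rng.integers(3, 9))
            pts = rng.normal(size=(n, 3))
            D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
            cut = float(rng.uniform(0.5, 2.5))
            got, un = cluster_reads(D, cut=cut, min_reads=1)
            assert partition_key(got + [[u] for u in un]) == partition_key(
                naive_ward_partition(D, cut)
            )

    def test_permutation_invariance(self, rng):
        D = self._two_group_distances(n=5)
        base, _ = cluster_reads(D, cut=0.40)
        perm = rng.permutation(10)
        Dp = D[np.ix_(perm, perm)]
        permuted, _ = cluster_reads(Dp, cut=0.40)
        remapped = [[int(perm[i]) for i in c] for c in permuted]
        assert partition_key(base) == partition_key(remapped)


class TestRefineCluster:
    def test_shared_prefix_alleles_split(self, rs, rng):
        # two alleles sharing a long identical prefix, diverging distally
        prefix = "C" * 5 + "D" * 12 + "C" * 8 + "E" * 10 + "C" * 5
        pat_a = prefix + "F" * 14 + "C" * 40
        pat_b = prefix + "L" * 6 + "C" * 6 + "K" * 9 + "C" * 40
        sub = random_dna(rng, 1500)
        members = []
        for i in range(6):
            members.append(_member(f"a{i}", sub, decode_pattern(pat_a, rs), rs))
        for i in range(6):
            members.append(_member(f"b{i}", sub, decode_pattern(pat_b, rs), rs))
        refined, unassigned = refine_cluster(members, rs)
        assert len(refined) == 2
        groups = [{r.read_id[0] for r, _ in g} for g in refined]
        assert {"a"} in groups and {"b"} in groups

    def test_identical_tvr_divergent_subtelomere_split(self, rs, rng):
        pattern = "C" * 5 + "D" * 10 + "C" * 8 + "E" * 12 + "C" * 40
        tel = decode_pattern(pattern, rs)
        sub1 = random_dna(rng, 1500)
        sub2 = random_dna(rng, 1500)  # unrelated: far beyond 20% divergence
        members = [_member(f"a{i}", sub1, tel, rs) for i in range(5)]
        members += [_member(f"b{i}", sub2, tel, rs) for i in range(5)]
        refined, _ = refine_cluster(members, rs)
        assert len(refined) == 2
        groups = [{r.read_id[0] for r, _ in g} for g in refined]
        assert {"a"} in groups and {"b"} in groups

    def test_homogeneous_cluster_unchanged(self, rs, rng):
        pattern = "C" * 5 + "D" * 10 + "C" * 30
        tel = decode_pattern(pattern, rs)
        sub = random_dna(rng, 1500)
        members = [_member(f"m{i}", sub, tel, rs) for i in range(6)]
        refined, unassigned = refine_cluster(members, rs)
        assert len(refined) == 1
        assert len(refined[0]) == 6
        assert not unassigned


class TestSubtelomereDistance:
    def test_identical_zero_divergent_large(self, rs, rng):
        sub1 = random_dna(rng, 1500)
        sub2 = random_dna(rng, 1500)
        tel = "TTAGGG" * 100
        reads = [
            TelomereRead("a", sub1 + tel, "telomere_at_end", 1500, 10),
            TelomereRead("b", sub1 + tel, "telomere_at_end", 1500, 10),
            TelomereRead("c", sub2 + tel, "telomere_at_end", 1500, 10),
        ]
        D = subtelomere_distance_matrix(reads)
        assert D[0, 1] == pytest.approx(0.0)
        assert D[0, 2] > 0.5


class TestFlagBlank:
    def _cluster(self, variant_counts, rs):
        members = []
        for i, v in enumerate(variant_counts):
            symbols = "D" * v + "C" * (40 - v)
            ss = SymbolString(symbols, [(6 * j, 6 * j + 6) for j in range(40)])
            read = TelomereRead(f"r{i}", "A" * 1200 + "TTAGGG" * 40, "telomere_at_end", 1200, 40)
            members.append((read, ss))
        return AlleleCluster("c0", members)

    def test_no_variants_blank(self, rs):
        assert flag_blank(self._cluster([0, 0, 0], rs), rs).blank

    def test_many_variants_not_blank(self, rs):
        assert not flag_blank(self._cluster([40, 40, 40], rs), rs).blank

    def test_median_equal_threshold_not_blank(self, rs):
        # strict less-than: median exactly min_variants stays non-blank
        assert not flag_blank(self._cluster([5, 5, 5], rs), rs, min_variants=5).blank
        assert flag_blank(self._cluster([4, 4, 4], rs), rs, min_variants=5).blank
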