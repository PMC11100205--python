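import numpy as np
import pytest

from telotype.repeat_model import reverse_complement
from telotype.simulate import (
    apply_errors,
    decode_pattern,
    delete_distal_variant_block,
    make_alleles,
    random_tvr_pattern,
    simulate_sample,
    simulate_trio,
    write_fastq,
)
from telotype.tvr_encode import encode_tel_region


class TestPatternGeneration:
    def test_patterns_start_canonical_end_variant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = random_tvr_pattern(rng)
            assert p[0] == "C"
            assert p[-1] != "C"

    def test_decode_encode_identity(self, rs):
        for a in make_alleles(15, seed=5):
            dna = decode_pattern(a.tvr_pattern, rs)
            assert encode_tel_region(dna, rs).symbols == a.tvr_pattern


class TestSimulateSample:
    def test_fixed_seed_reproducible(self):
        alleles = make_alleles(3, seed=2)
        r1, t1 = simulate_sample(alleles, coverage=10, seed=9)
        r2, t2 = simulate_sample(alleles, coverage=10, seed=9)
        assert r1 == r2
        assert t1.reads == t2.reads

    def test_read_count_accounting(self):
        alleles = make_alleles(2, seed=3)
        reads, truth = simulate_sample(alleles, coverage=30, error_rate=0.0, seed=3)
        # coverage is diploid: each allele gets round(coverage/2) reads
        assert len(reads) == 2 * round(30 / 2)
        assert len(truth.reads) == len(reads)
        assert {t.allele_id for t in truth.reads} == {a.allele_id for a in alleles}

    def test_error_free_reads_decode_exactly(self, rs):
        alleles = make_alleles(2, seed=4)
        reads, truth = simulate_sample(alleles, coverage=6, error_rate=0.0, seed=4)
        tr = {t.read_id: t for t in truth.reads}
        amap = {a.allele_id: a for a in alleles}
        for read_id, seq in reads:
            t = tr[read_id]
            if t.strand == "-":
                seq = reverse_complement(seq)
            allele = amap[t.allele_id]
            tel_region = seq[t.subtel_len :]
            symbols = encode_tel_region(tel_region, rs).symbols
            assert symbols.startswith(allele.tvr_pattern)
            tail = symbols[len(allele.tvr_pattern) :]
            # pure canonical, except the read's final partial repeat (TL is
            # not a multiple of 6) which encodes as unknown or a T-family cut
            assert set(tail[:-1]) <= {"C"}
            assert tail[-1:] in ("", "C", "?", "T")

    def test_mean_tl_converges(self):
        # law of large numbers on the per-read TL draws
        alleles = make_alleles(1, seed=6, tl_mean_range=(4000, 4000), tl_sd=300)
        _, truth = simulate_sample(alleles, coverage=400, error_rate=0.0, seed=6)
        tls = [t.tl for t in truth.reads]
        assert len(tls) == 200
        assert abs(np.mean(tls) - 4000) <= 2 * 300 / np.sqrt(len(tls))

    def test_coverage_validation(self):
        with pytest.raises(ValueError):
            simulate_sample(make_alleles(1, seed=0), coverage=0)
        with pytest.raises(ValueError):
            simulate_sample(make_alleles(1, seed=0), coverage=10, error_rate=0.2)

    def test_wgs_fragmentation_produces_partial_reads(self):
        alleles = make_alleles(2, seed=8)
        reads, truth = simulate_sample(
            alleles, coverage=40, seed=8, wgs_fragmentation=True,
            read_len_mean=4000, read_len_sd=500,
        )
        spans = [(t.frag_start, t.frag_end) for t in truth.reads]
        assert any(s > 0 for s, _ in spans)


class TestErrorModel:
    def test_zero_rate_identity(self, rng):
        seq = "TTAGGG" * 100
        out, n = apply_errors(seq, rng, 0.0)
        assert out == seq and n == 0

    def test_rate_scale(self, rng):
        seq = "ACGT" * 5000  # no homopolymers: bias path inert
        _, n = apply_errors(seq, rng, 0.01, homopolymer_bias=3.0)
        assert 0.005 * len(seq) < n < 0.02 * len(seq)

    def test_homopolymer_bias_concentrates_indels(self):
        # same nominal rate: the homopolymer-rich sequence accumulates more
        # errors when indels are biased into runs >= 3bp
        rng1, rng2 = np.random.default_rng(1), np.random.default_rng(1)
        hp_rich = "TTAGGG" * 2000  # GGG run in every repeat
        hp_free = "ACGT" * 3000
        _, n_rich = apply_errors(hp_rich, rng1, 0.01, homopolymer_bias=5.0, sub_fraction=0.0)
        _, n_free = apply_errors(hp_free, rng2, 0.01, homopolymer_bias=5.0, sub_fraction=0.0)
        assert n_rich / len(hp_rich) > 1.5 * n_free / len(hp_free)


class TestTrio:
    def _parents(self):
        arms = ["chr1p", "chr1q"]
        return make_alleles(2, seed=11, arms=arms), make_alleles(2, seed=12, arms=arms)

    def test_zero_probability_inherits_exactly(self):
        p1, p2 = self._parents()
        child = simulate_trio(p1, p2, 0.0, seed=1)
        parental = {a.tvr_pattern for a in p1} | {a.tvr_pattern for a in p2}
        assert len(child) == 4  # one per arm per parent
        assert all(c.tvr_pattern in parental for c in child)

    def test_certain_deletion_removes_distal_block(self):
        p1, p2 = self._parents()
        child = simulate_trio(p1, p2, 1.0, seed=1)
        by_id = {a.tvr_pattern: a for a in p1 + p2}
        for c in child:
            assert c.tvr_pattern not in by_id
        # and the rule itself: the last variant block disappears
        assert delete_distal_variant_block("CCDDDCCEEE") == "CCDDDCC"
        assert delete_distal_variant_block("CCDDDCCEEECC") == "CCDDDCCCC"
        assert delete_distal_variant_block("CCCC") == "CCCC"

    def test_seed_reproducible(self):
        p1, p2 = self._parents()
        assert simulate_trio(p1, p2, 0.5, seed=7) == simulate_trio(p1, p2, 0.5, seed=7)

    def test_arm_mismatch_rejected(self):
        p1, _ = self._parents()
        p2 = make_alleles(2, seed=13, arms=["chr2p", "chr2q"])
        with pytest.raises(ValueError):
            simulate_trio(p1, p2, 0.0, seed=0)


def test_fastq_round_trip(tmp_path):
    from telotype.report_io import read_sequences

    alleles = make_alleles(2, seed=14)
    reads, _ = simulate_sample(alleles, coverage=4, seed=14)
    for name in ("reads.fastq", "reads.fastq.gz"):
        path = tmp_path / name
        write_fastq(reads, path)
        assert list(read_sequences(path)) == reads
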