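import pytest

from telotype.consensus_atl import (
    atl_distribution,
    map_boundary_to_member,
    msa_consensus,
    representative_atl,
    tvr_boundary,
)
from telotype.tvr_encode import SymbolString


def _ss(symbols, unit=6):
    return SymbolString(symbols, [(unit * i, unit * i + unit) for i in range(len(symbols))])


class TestMsaConsensus:
    def test_identical_members(self, rs):
        s = "CCDDDCCEEC"
        cons = msa_consensus([_ss(s)] * 5, rs)
        assert cons.symbols == s

    def test_single_corrupted_member_outvoted(self, rs, rng):
        truth = "CCDDDDCCEEEECCFFC" + "C" * 20
        members = [_ss(truth) for _ in range(5)]
        corrupt = list(truth)
        corrupt[4] = "K"  # one random substitution
        members[2] = _ss("".join(corrupt))
        assert msa_consensus(members, rs).symbols == truth

    def test_tie_breaks_toward_canonical(self, rs):
        # two members disagree at one column: canonical preferred
        a = "CCDCC"
        b = "CCECC"  # column 2 tied D vs E vs nothing... with canonical absent
        cons = msa_consensus([_ss(a), _ss("CCCCC")], rs)
        assert cons.symbols == "CCCCC"  # D vs C tie -> canonical

    def test_indel_member_handled(self, rs):
        truth = "CCDDDCCEEEC"
        shifted = "CDDDCCEEEC"  # missing one leading canonical
        cons = msa_consensus([_ss(truth), _ss(truth), _ss(shifted)], rs)
        assert cons.symbols == truth

    def test_empty_membership_rejected(self, rs):
        with pytest.raises(ValueError):
            msa_consensus([], rs)


class TestTvrBoundary:
    def test_cumulative_rule(self, rs):
        # 20 variants then 100 canonical: boundary right after the 19th
        # variant (19/20 = 95%), i.e. 19 symbols / 114bp into the string
        cons = _ss("D" * 20 + "C" * 100)
        tvr = tvr_boundary(cons, rs, q=0.95)
        assert tvr.tvr_boundary_symbol == 19
        assert tvr.tvr_boundary_bp == cons.base_offsets[18][1] == 114

    def test_sporadic_distal_variant_excluded(self, rs):
        cons = _ss("D" * 19 + "C" * 80 + "D" + "C" * 20)
        tvr = tvr_boundary(cons, rs, q=0.95)
        assert tvr.tvr_boundary_symbol == 19  # the lone distal D is outside

    def test_blank_consensus_boundary_zero(self, rs):
        tvr = tvr_boundary(_ss("C" * 50), rs)
        assert tvr.tvr_boundary_symbol == 0
        assert tvr.tvr_boundary_bp == 0

    def test_unknown_symbols_not_variants(self, rs):
        tvr = tvr_boundary(_ss("??CC??"), rs)
        assert tvr.tvr_boundary_bp == 0

    def test_appending_canonical_never_moves_boundary(self, rs, rng):
        for _ in range(20):
            syms = "".join(rng.choice(list("CCCDEF"), size=rng.integers(5, 60)))
            base = tvr_boundary(_ss(syms), rs)
            extended = tvr_boundary(_ss(syms + "C" * 30), rs)
            assert extended.tvr_boundary_symbol == base.tvr_boundary_symbol


class TestBoundaryMapping:
    def test_exact_member_maps_exactly(self, rs):
        cons = _ss("CCDDDCC" + "C" * 10)
        tvr = tvr_boundary(cons, rs)
        b = map_boundary_to_member(cons, cons, rs, tvr.tvr_boundary_symbol)
        assert b == tvr.tvr_boundary_bp

    def test_member_insertion_before_boundary_compensated(self, rs):
        # member has 2 extra canonical symbols inserted before the variant
        # block; its boundary lands 12bp deeper, leaving ATL unchanged
        cons = _ss("CC" + "DDD" + "C" * 30)
        member = _ss("CCCC" + "DDD" + "C" * 30)
        tvr = tvr_boundary(cons, rs)
        b = map_boundary_to_member(member, cons, rs, tvr.tvr_boundary_symbol)
        assert b == tvr.tvr_boundary_bp + 12


class TestAtlDistribution:
    def test_read_ending_at_boundary_gives_zero(self, rs):
        cons_tvr = tvr_boundary(_ss("CCDDD"), rs)
        member = _ss("CCDDD")  # nothing beyond the boundary
        d = atl_distribution([member], cons_tvr, rs)
        assert d.lengths_bp == [0]

    def test_lengths_beyond_boundary(self, rs):
        cons_tvr = tvr_boundary(_ss("CCDDD" + "C" * 100), rs)
        member = _ss("CCDDD" + "C" * 50)
        d = atl_distribution([member], cons_tvr, rs)
        assert d.lengths_bp == [300]  # 50 canonical hexamers

    def test_empty_cluster_rejected(self, rs):
        cons_tvr = tvr_boundary(_ss("CCDDD"), rs)
        with pytest.raises(ValueError):
            atl_distribution([], cons_tvr, rs)


class TestRepresentativeAtl:
    @pytest.mark.parametrize(
        "method,expected",
        [
            ("median", 2500.0),
            ("max", 4000.0),
            ("mean", 2500.0),
            ("p75", 3250.0),  # linear interpolation
            ("p100", 4000.0),
        ],
    )
    def test_examples(self, method, expected):
        assert representative_atl([1000, 2000, 3000, 4000], method) == expected

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            representative_atl([1000], "p7x")
        with pytest.raises(ValueError):
            representative_atl([1000], "mode")


def test_consensus_error_robustness(rs, rng):
    """Majority vote across >=5 members recovers truth despite 5% per-symbol
    errors injected independently in each member."""
    truth = "C" * 4 + "D" * 8 + "C" * 6 + "E" * 10 + "C" * 30
    alphabet = list("CDEFGHIKLM")
    good = 0
    n_trials = 40
    for _ in range(n_trials):
        members = []
        for _ in range(7):
            syms = [
                str(rng.choice(alphabet)) if rng.random() < 0.05 else s for s in truth
            ]
            members.append(_ss("".join(syms)))
        if msa_consensus(members, rs).symbols == truth:
            good += 1
    assert good / n_trials >= 0.95
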