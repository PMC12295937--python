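"""RSCU, preferred-codon sets, and Wright's effective number of codons."""

import collections
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cub import enc, enc_expected, get_code, high_frequency_codons, rscu
from cub.codon_bias import _family_homozygosity
from cub.errors import ComputationError
from cub.seq_io import CodonCounts

from oracles import oracle_enc, oracle_rscu


def counts_of(mapping):
    return CodonCounts(counts=collections.Counter(mapping), scope="test")


def random_counts(code, rng, low=2, high=60):
    """Counts with every family observed (>= 2) so no imputation triggers."""
    c = {}
    for family in code.families.values():
        fam = sorted(family)
        vals = rng.integers(low, high, size=len(fam))
        if vals.sum() < 2:
            vals[0] += 2
        for codon, v in zip(fam, vals):
            c[codon] = int(v)
    return counts_of(c)


class TestRSCU:
    def test_uniform_twofold_family(self, code5):
        table = rscu(counts_of({"AAA": 10, "AAG": 10}), code5)
        assert table.rscu["AAA"] == 1.0
        assert table.rscu["AAG"] == 1.0

    def test_all_mass_on_one_leucine_codon(self, code5):
        table = rscu(counts_of({"TTA": 25}), code5)
        assert table.rscu["TTA"] == 6.0
        for codon in code5.families["L"] - {"TTA"}:
            assert table.rscu[codon] == 0.0

    def test_unobserved_family_is_missing_not_zero(self, code5):
        table = rscu(counts_of({"AAA": 1}), code5)
        assert math.isnan(table.rscu["GGG"])

    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_family_size(self, seed):
        code = get_code(5)
        rng = np.random.default_rng(seed)
        table = rscu(random_counts(code, rng, low=0, high=30), code)
        for aa, family in code.families.items():
            vals = [table.rscu[c] for c in family]
            if any(math.isnan(v) for v in vals):
                assert all(math.isnan(v) for v in vals)
            else:
                assert sum(vals) == pytest.approx(len(family), abs=1e-9)

    def test_matches_bruteforce_oracle(self, code5):
        rng = np.random.default_rng(11)
        counts = random_counts(code5, rng)
        expected = oracle_rscu(dict(counts.counts), [set(f) for f in code5.families.values()])
        table = rscu(counts, code5)
        for codon, v in expected.items():
            assert table.rscu[codon] == pytest.approx(v, abs=1e-12)


class TestHighFrequency:
    def test_uniform_usage_has_no_preferred_codons(self, code5):
        flat = counts_of({c: 5 for c in code5.sense_codons})
        report = high_frequency_codons({"sp": rscu(flat, code5)})
        assert report.shared == frozenset()

    def test_disjoint_preferred_sets_share_nothing(self, code5):
        a = rscu(counts_of({"AAA": 30, "AAG": 1}), code5)
        b = rscu(counts_of({"AAG": 30, "AAA": 1}), code5)
        report = high_frequency_codons({"a": a, "b": b})
        assert report.shared == frozenset()
        assert report.unique["a"] == frozenset({"AAA"})
        assert report.unique["b"] == frozenset({"AAG"})

    def test_threshold_is_strictly_greater_than_one(self, code5):
        table = rscu(counts_of({"AAA": 10, "AAG": 10}), code5)
        assert "AAA" not in table.high_frequency()

    def test_third_base_annotation(self, code5):
        report = high_frequency_codons({"a": rscu(counts_of({"TTA": 30, "TTG": 1}), code5)})
        assert report.third_bases(report.per_species["a"]) == {"A": 1}


class TestEnc:
    def test_family_homozygosity_hand_value(self):
        # 2-fold family with counts (5, 5): F = (10 * 0.5 - 1) / 9 = 4/9
        n, f = _family_homozygosity([5, 5])
        assert n == 10
        assert f == pytest.approx(4 / 9, abs=1e-15)

    def test_extreme_bias_reaches_twenty(self, code5):
        # all usage concentrated on one codon per family -> F = 1 everywhere
        concentrated = counts_of({sorted(f)[0]: 100 for f in code5.families.values()})
        result = enc(concentrated, code5)
        assert result.enc == pytest.approx(20.0, abs=1e-12)
        assert not result.imputed_classes

    def test_matches_bruteforce_oracle(self, code5, code1):
        rng = np.random.default_rng(7)
        for code in (code5, code1):
            for _ in range(25):
                counts = random_counts(code, rng)
                expected = oracle_enc(
                    dict(counts.counts), [set(f) for f in code.families.values()]
                )
                assert enc(counts, code).enc == pytest.approx(expected, abs=1e-9)

    def test_uniform_usage_approaches_sense_codon_count(self, code5, code1):
        rng = np.random.default_rng(3)
        for code, limit in ((code5, 62), (code1, 61)):
            n = 100_000
            codons = sorted(code.sense_codons)
            draws = rng.multinomial(n, [1 / len(codons)] * len(codons))
            counts = counts_of(dict(zip(codons, draws)))
            assert enc(counts, code).enc == pytest.approx(limit, abs=0.5)

    def test_scaling_counts_converges_monotonically(self, code5):
        rng = np.random.default_rng(5)
        base = random_counts(code5, rng)
        encs = [
            enc(counts_of({c: v * m for c, v in base.counts.items()}), code5).enc
            for m in (1, 2, 4, 16, 256, 4096)
        ]
        # F̂ = (nS - 1)/(n - 1) rises toward S as n grows, so the ENC
        # estimate decreases monotonically toward its infinite-n value
        # at rate O(1/n)
        assert all(a >= b - 1e-9 for a, b in zip(encs, encs[1:]))
        assert abs(encs[-1] - encs[-2]) < 0.01

    def test_missing_class_imputed_and_recorded(self, code5):
        # only 2-fold families observed: 4/6/8-fold classes need imputation
        twofold = {sorted(f)[0]: 5 for f in code5.families.values() if len(f) == 2}
        twofold.update({sorted(f)[1]: 5 for f in code5.families.values() if len(f) == 2})
        result = enc(counts_of(twofold), code5)
        assert result.imputed_classes == {4, 6, 8}
        # all classes fall back to F̄2 = 4/9 -> ENC = 20 / (4/9) = 45
        assert result.enc == pytest.approx(45.0, abs=1e-9)

    def test_no_valid_family_is_error(self, code5):
        with pytest.raises(ComputationError):
            enc(counts_of({"AAA": 1}), code5)

    def test_codonw_compat_uses_standard_code_classes(self, code5):
        rng = np.random.default_rng(9)
        counts = random_counts(code5, rng)
        native = enc(counts, code5)
        compat = enc(counts, code5, codonw_compat=True)
        assert native.max_enc == 62
        assert compat.max_enc == 61
        assert native.enc != pytest.approx(compat.enc, abs=1e-6)

    def test_exceeds_max_flag(self, code5):
        rng = np.random.default_rng(13)
        counts = random_counts(code5, rng)
        result = enc(counts, code5)
        assert result.exceeds_max == (result.enc > 62)


class TestEncExpected:
    @pytest.mark.parametrize("gc3s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_curve_values(self, gc3s, expected):
        assert enc_expected(gc3s) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            enc_expected(bad)
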