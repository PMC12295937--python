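"""The mutation-selection CDS generator and its analytic oracles."""

import numpy as np
import pytest
from scipy import stats

from cub import (
    SyntheticSpec,
    build_profiles,
    codon_weights,
    emit_fixture_genome,
    enc,
    expected_composition,
    extract_all_cds,
    get_code,
    neutrality_regression,
    read_genbank,
    rscu,
    sample_gene,
    sample_genome,
)
from cub.seq_io import count_codons, sum_counts
from cub.synthetic import DEFAULT_LIGHT_STRAND, default_preferred_codons


class TestSpec:
    def test_preferred_codons_one_per_family_all_at_ending(self, code5):
        preferred = default_preferred_codons(code5)
        assert set(preferred) == set(code5.families)
        for aa, codon in preferred.items():
            assert codon in code5.families[aa]
            assert codon[2] in "AT"

    @pytest.mark.parametrize("bad", [{"gc_pressure": 0.0}, {"selection_strength": -1.0}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SyntheticSpec(**bad)

    def test_weights_normalized(self, code5):
        w = codon_weights(code5, g=0.3, s=2.0)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
        assert set(w) == set(code5.sense_codons)


class TestSampleGene:
    def test_structure(self, code5):
        spec = SyntheticSpec(seed=1)
        cds = sample_gene(spec, length=100, gene_index=0)
        assert len(cds.nt) == 300
        assert cds.start_codon in code5.start_codons
        aa = code5.translate(cds.nt)
        assert aa.endswith("*") and "*" not in aa[:-1]

    def test_symmetric_weights_give_uniform_codon_usage(self, code5):
        # g = 0.5, s = 0: every sense codon has equal weight
        spec = SyntheticSpec(seed=3, gc_pressure=0.5)
        cds = sample_gene(spec, length=100_001, gene_index=0)
        body = cds.sense_codons[1:]  # drop the forced start codon
        codons = sorted(code5.sense_codons)
        observed = [body.count(c) for c in codons]
        chi = stats.chisquare(observed)
        assert chi.pvalue > 0.001

    def test_strong_selection_drives_rscu_to_family_size(self, code5):
        spec = SyntheticSpec(seed=4, selection_strength=1e6)
        cds = sample_gene(spec, length=5000, gene_index=0)
        counts = count_codons(cds, code5, include_start=False)
        table = rscu(counts, code5)
        preferred = default_preferred_codons(code5)
        for aa, codon in preferred.items():
            if sum(counts[c] for c in code5.families[aa]) == 0:
                continue
            assert table.rscu[codon] == pytest.approx(len(code5.families[aa]), abs=1e-9)

    def test_gc3_tracks_mutation_pressure_monotonically(self, code5):
        # oracle: expected GC3 from enumerating the 62-codon distribution
        gs = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
        measured = []
        for i, g in enumerate(gs):
            spec = SyntheticSpec(seed=5, gc_pressure=g)
            cds = sample_gene(spec, length=4000, gene_index=i)
            profs = build_profiles([cds], code5)
            expected = expected_composition(code5, g)["GC3"]
            assert profs[0].GC3 == pytest.approx(expected, abs=0.03)
            measured.append(profs[0].GC3)
        assert measured == sorted(measured)

    def test_order_independent_draws(self, code5):
        spec = SyntheticSpec(seed=6)
        a = sample_gene(spec, length=50, gene_index=3)
        _ = sample_gene(spec, length=200, gene_index=1)
        b = sample_gene(spec, length=50, gene_index=3)
        assert a.nt == b.nt


class TestRegimes:
    def test_mutation_only_genes_lie_near_expected_curve(self, code5):
        spec = SyntheticSpec(
            seed=8, gc_pressure_per_gene=tuple(np.linspace(0.2, 0.8, 13)),
            codons_per_gene=(300, 300),
        )
        genes, _ = sample_genome(spec)
        profs = build_profiles(genes, code5)
        devs = [p.enc_deviation for p in profs]
        assert abs(float(np.mean(devs))) < 3.0

    def test_selection_genes_fall_below_expected_curve(self, code5):
        spec = SyntheticSpec(seed=9, selection_strength=2.0, codons_per_gene=(300, 300))
        genes, _ = sample_genome(spec)
        profs = build_profiles(genes, code5)
        assert float(np.mean([p.enc_deviation for p in profs])) < 0.0

    def test_enc_decreases_monotonically_with_selection(self, code5):
        means = []
        for s in (0.0, 2.0, 10.0):
            spec = SyntheticSpec(seed=10, selection_strength=s, codons_per_gene=(300, 300))
            genes, _ = sample_genome(spec)
            counts = sum_counts([count_codons(c, code5) for c in genes])
            means.append(enc(counts, code5).enc)
        assert means[0] > means[1] > means[2]

    def test_mutation_regime_slope_strongly_positive(self, code5):
        spec = SyntheticSpec(
            seed=11, gc_pressure_per_gene=tuple(np.linspace(0.2, 0.8, 13)),
            codons_per_gene=(300, 300),
        )
        genes, _ = sample_genome(spec)
        profs = build_profiles(genes, code5)
        reg = neutrality_regression(profs)
        assert reg.slope > 0.7
        assert reg.r_squared > 0.8


class TestFixtureGenome:
    def test_emission_is_byte_stable(self, tmp_path):
        spec = SyntheticSpec(seed=12)
        p1 = emit_fixture_genome(spec, tmp_path / "a.gb")
        p2 = emit_fixture_genome(spec, tmp_path / "b.gb")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        a = emit_fixture_genome(SyntheticSpec(seed=1), tmp_path / "a.gb")
        b = emit_fixture_genome(SyntheticSpec(seed=2), tmp_path / "b.gb")
        assert a.read_bytes() != b.read_bytes()

    def test_packaged_fixture_matches_its_spec(self, fixture_path, fixture_spec, tmp_path):
        regenerated = emit_fixture_genome(fixture_spec, tmp_path / "regen.gb")
        assert regenerated.read_bytes() == fixture_path.read_bytes()

    def test_round_trip_through_extraction(self, tmp_path, code5):
        spec = SyntheticSpec(seed=13)
        path = emit_fixture_genome(spec, tmp_path / "g.gb")
        genome = read_genbank(path)
        cds_list = extract_all_cds(genome, code5)
        assert len(cds_list) == 13
        assert sum(1 for c in cds_list if c.strand == "-") == 4
        assert {c.gene for c in cds_list if c.strand == "-"} == set(DEFAULT_LIGHT_STRAND)
        completed = {c.gene for c in cds_list if c.stop_completed}
        assert completed == set(spec.incomplete_stop_genes)
        # extracted sequences equal the sampled genes exactly
        sampled = {c.gene: c.nt for c in sample_genome(spec)[0]}
        for cds in cds_list:
            assert cds.nt == sampled[cds.gene]
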