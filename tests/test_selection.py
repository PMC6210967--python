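"""Codon-usage entropy and Nei-Gojobori Ka/Ks against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panevo import (
    CodonCounts,
    EvolutionModel,
    codon_align,
    compare_core_vs_chromosome,
    estimate_relative_entropy,
    expected_codon_frequencies,
    family_omega,
    ng_differences,
    ng_kaks,
    ng_site_counts,
    observed_codon_frequencies,
    relative_entropy,
    simulate_codon_pair,
)
from panevo._genetics import SENSE_CODONS, SENSE_INDEX
from panevo.selection import drop_gapped_columns
import oracles


# ---------------------------------------------------------------------------
# codon tallies and entropy


class TestCodonFrequencies:
    def test_direct_tally_with_stop_excluded(self):
        counts = observed_codon_frequencies(["ATGAAATAA"])
        assert counts.total == 2
        assert counts.counts[SENSE_INDEX["ATG"]] == 1
        assert counts.counts[SENSE_INDEX["AAA"]] == 1

    def test_ambiguous_codon_skipped(self):
        a = observed_codon_frequencies(["ATGAAAGGG"])
        b = observed_codon_frequencies(["ATGANAGGG"])
        assert b.total == a.total - 1

    def test_bad_length_names_gene(self):
        with pytest.raises(ValueError, match="gene7"):
            observed_codon_frequencies([("gene7", "ATGAA")])

    def test_matches_independent_tally_on_generator_output(self, small_dataset):
        genome = small_dataset.genome_ids[0]
        cds = [(g.gene_id, g.cds) for g in small_dataset.genes[genome]]
        counts = observed_codon_frequencies(cds)
        naive = {}
        for _, s in cds:
            for i in range(0, len(s), 3):
                naive[s[i : i + 3]] = naive.get(s[i : i + 3], 0) + 1
        for codon, idx in SENSE_INDEX.items():
            assert counts.counts[idx] == naive.get(codon, 0)


class TestExpectedFrequencies:
    def test_uniform_composition_gives_uniform_positional_expectation(self):
        # every sense codon once: positions are *not* uniform because the 3
        # stop codons are excluded, so build a genuinely uniform input
        counts = CodonCounts(np.ones(61, dtype=np.int64))
        expected = expected_codon_frequencies(counts, "positional_nucleotide")
        assert expected.sum() == pytest.approx(1.0, abs=1e-12)
        # brute-force recomputation
        pos = np.zeros((3, 4))
        for c, n in zip(SENSE_CODONS, counts.counts):
            for p in range(3):
                pos[p, "ACGT".index(c[p])] += n
        pos /= pos.sum(axis=1, keepdims=True)
        brute = np.array(
            [pos[0, "ACGT".index(c[0])] * pos[1, "ACGT".index(c[1])] * pos[2, "ACGT".index(c[2])] for c in SENSE_CODONS]
        )
        brute /= brute.sum()
        np.testing.assert_allclose(expected, brute, atol=1e-12)

    def test_uniform_synonymous_two_fold_family(self):
        counts = np.zeros(61, dtype=np.int64)
        counts[SENSE_INDEX["AAA"]] = 5
        counts[SENSE_INDEX["AAG"]] = 5
        expected = expected_codon_frequencies(CodonCounts(counts), "uniform_synonymous")
        assert expected[SENSE_INDEX["AAA"]] == pytest.approx(0.5)
        assert expected[SENSE_INDEX["AAG"]] == pytest.approx(0.5)
        assert expected.sum() == pytest.approx(1.0)

    def test_sums_to_one_on_random_counts(self, rng):
        for _ in range(20):
            counts = CodonCounts(rng.integers(0, 50, size=61).astype(np.int64) + 1)
            for model in ("positional_nucleotide", "uniform_synonymous"):
                assert expected_codon_frequencies(counts, model).sum() == pytest.approx(1.0, abs=1e-12)


class TestRelativeEntropy:
    def test_zero_when_observed_equals_expected(self):
        counts = CodonCounts(np.full(61, 10, dtype=np.int64))
        assert relative_entropy(counts, counts.frequencies) == 0.0

    def test_single_codon_closed_form(self):
        counts = np.zeros(61, dtype=np.int64)
        counts[SENSE_INDEX["GCA"]] = 100
        dkl = relative_entropy(CodonCounts(counts), np.full(61, 1.0 / 61.0))
        assert dkl == pytest.approx(math.log2(61), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_nonnegativity_property(self, seed):
        r = np.random.default_rng(seed)
        counts = CodonCounts(r.integers(0, 100, size=61).astype(np.int64) + 1)
        q = r.random(61) + 1e-3
        q /= q.sum()
        assert relative_entropy(counts, q) >= 0.0

    def test_support_violation_raises(self):
        counts = np.zeros(61, dtype=np.int64)
        counts[0] = 5
        q = np.full(61, 1 / 60.0)
        q[0] = 0.0
        with pytest.raises(ValueError):
            relative_entropy(CodonCounts(counts), q)

    def test_bias_correction_shrinks_small_sample_estimates(self, rng):
        from panevo.simulate import sample_codon_counts

        small = CodonCounts(sample_codon_counts(2000, 0.0, rng))
        plain = relative_entropy(small, expected_codon_frequencies(small))
        corrected = estimate_relative_entropy(small)
        assert corrected < plain


class TestWelchComparison:
    def test_identical_groups(self):
        res = compare_core_vs_chromosome([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.welch_t == pytest.approx(0.0)

    def test_shifted_groups_closed_form(self):
        a = [1.0, 2.0, 3.0]
        b = [11.0, 12.0, 13.0]
        res = compare_core_vs_chromosome(b, a)
        # hand Welch: diff=10, se = sqrt(1/3 + 1/3), t = 10/se
        se = math.sqrt(1.0 / 3.0 + 1.0 / 3.0)
        assert res.welch_t == pytest.approx(10.0 / se)
        assert res.p_two_sided < 0.001
        assert res.p_one_sided_core_greater < 0.001

    def test_zero_variance_equal_means(self):
        res = compare_core_vs_chromosome([2.0, 2.0], [2.0, 2.0])
        assert res.welch_t == 0.0 and res.p_two_sided == 1.0

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            compare_core_vs_chromosome([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# Nei-Gojobori


class TestSiteCounts:
    def test_phe_and_met_closed_forms(self):
        assert ng_site_counts("TTT") == pytest.approx((1 / 3, 8 / 3))
        assert ng_site_counts("ATG") == pytest.approx((0.0, 3.0))

    def test_full_table_matches_enumeration_oracle(self):
        for codon in SENSE_CODONS:
            s, n = ng_site_counts(codon)
            s_o, n_o = oracles.site_counts(codon)
            assert s == pytest.approx(s_o), codon
            assert n == pytest.approx(n_o), codon
            assert s + n == pytest.approx(3.0)

    def test_rejects_stop_and_ambiguous(self):
        with pytest.raises(ValueError):
            ng_site_counts("TAA")
        with pytest.raises(ValueError):
            ng_site_counts("ANA")


class TestDifferences:
    def test_single_synonymous_step(self):
        assert ng_differences("TTT", "TTC") == pytest.approx((1.0, 0.0))

    def test_two_pathway_average(self):
        assert ng_differences("TTT", "GTA") == pytest.approx((0.5, 1.5))

    def test_full_61x61_table_matches_pathway_oracle(self):
        for a, b in itertools.product(SENSE_CODONS, repeat=2):
            s_d, n_d = ng_differences(a, b)
            s_o, n_o = oracles.pathway_differences(a, b)
            assert s_d == pytest.approx(s_o), (a, b)
            assert n_d == pytest.approx(n_o), (a, b)
            hamming = sum(x != y for x, y in zip(a, b))
            assert s_d + n_d == pytest.approx(hamming)


class TestKaKs:
    def test_identical_sequences(self):
        rec = ng_kaks("ATGAAA", "ATGAAA")
        assert rec.Ka == 0.0 and rec.Ks == 0.0
        assert not rec.omega_defined and math.isnan(rec.omega)

    def test_random_pairs_match_column_oracle(self, rng):
        sense = list(SENSE_CODONS)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            a = "".join(rng.choice(sense, size=n))
            b_codons = []
            for i in range(n):
                if rng.random() < 0.7:
                    b_codons.append(a[3 * i : 3 * i + 3])
                else:
                    b_codons.append(sense[int(rng.integers(61))])
            b = "".join(b_codons)
            rec = ng_kaks(a, b)
            ora = oracles.kaks_pair(a, b)
            for key in ("S", "N", "s_d", "n_d", "p_s", "p_n"):
                assert getattr(rec, key) == pytest.approx(ora[key]), key
            if not rec.saturated:
                assert rec.Ka == pytest.approx(ora["Ka"])
                assert rec.Ks == pytest.approx(ora["Ks"])

    def test_symmetry(self, rng):
        sense = list(SENSE_CODONS)
        for _ in range(20):
            a = "".join(rng.choice(sense, size=30))
            b = "".join(rng.choice(sense, size=30))
            r1, r2 = ng_kaks(a, b), ng_kaks(b, a)
            for key in ("S", "N", "s_d", "n_d", "Ka", "Ks"):
                assert getattr(r1, key) == pytest.approx(getattr(r2, key), nan_ok=True)
            assert r1.saturated == r2.saturated

    def test_site_sum_identity(self, rng):
        sense = list(SENSE_CODONS)
        a = "".join(rng.choice(sense, size=50))
        b = "".join(rng.choice(sense, size=50))
        rec = ng_kaks(a, b)
        assert rec.S + rec.N == pytest.approx(3 * rec.n_codons)

    def test_saturated_pair_flagged(self):
        # maximally different codons at every position force p >= 3/4
        a = "TTT" * 40
        b = "GGG" * 40
        rec = ng_kaks(a, b)
        assert rec.saturated


class TestCodonAlign:
    def test_identical_set_passthrough(self):
        cds = [("a", "ATGAAACCC"), ("b", "ATGAAACCC")]
        aligned = codon_align(cds)
        assert aligned == [("a", "ATGAAACCC"), ("b", "ATGAAACCC")]

    def test_single_codon_insertion_excluded(self):
        # second sequence carries one extra codon; exactly one column gapped
        a = "ATGGTTACCGAAGATATTCTGGCACGTAAA"  # 10 codons
        b = a[:15] + "GGG" + a[15:]  # 11 codons
        aligned = codon_align([("a", a), ("b", b)])
        gapped = [s for _, s in aligned]
        assert len(gapped[0]) == len(gapped[1])
        n_gap_columns = sum(
            1
            for i in range(0, len(gapped[0]), 3)
            if any(s[i : i + 3] == "---" for s in gapped)
        )
        assert n_gap_columns == 1
        clean = drop_gapped_columns(aligned)
        assert all(len(s) == 30 for _, s in clean)

    def test_internal_stop_dropped(self, caplog):
        cds = [("ok", "ATGAAACCC"), ("bad", "ATGTAACCC"), ("ok2", "ATGAAACCC")]
        aligned = codon_align(cds)
        assert [g for g, _ in aligned] == ["ok", "ok2"]


class TestFamilyOmega:
    def test_two_sequence_family_equals_pairwise(self, rng):
        evo = EvolutionModel(omega_target=0.3, ks_target=0.4)
        a, b = simulate_codon_pair(100, evo, rng)
        fam = family_omega([("a", a), ("b", b)])
        pair = ng_kaks(a, b)
        assert fam.Ka == pytest.approx(pair.Ka)
        assert fam.Ks == pytest.approx(pair.Ks)

    def test_saturated_pair_excluded_from_aggregate(self):
        good_a = "CCTAAAGTT" * 10
        good_b = "CCCAAAGTT" * 10  # one synonymous change per repeat: p_s ~ 0.43
        bad = "CCGAAGGTA" * 10  # synonymous change in every codon: p_s > 3/4 vs both
        assert ng_kaks(good_a, bad).saturated and ng_kaks(good_b, bad).saturated
        fam = family_omega([("a", good_a), ("b", good_b), ("c", bad)])
        assert fam.excluded_pairs == 2
        pair = ng_kaks(good_a, good_b)
        assert fam.Ks == pytest.approx(pair.Ks)

    def test_no_valid_pair_flagged(self):
        a = "TTT" * 40
        b = "GGG" * 40
        fam = family_omega([("a", a), ("b", b)])
        assert not fam.valid
        assert fam.excluded_pairs == 1

    def test_generator_core_families_under_purifying_selection(self, small_dataset):
        """Every synthetic core family shows omega < 1 at omega_target 0.2."""
        core = set(
            small_dataset.truth_families.query("family_class == 'core'")["family_id"].head(15)
        )
        cds_by_gene = small_dataset.cds_by_gene()
        genes = small_dataset.truth_genes
        omegas = []
        for fam_id in core:
            members = genes[genes["family_id"] == fam_id]["gene_id"]
            aln = codon_align([(g, cds_by_gene[g]) for g in members])
            rec = family_omega(aln)
            if rec.omega_defined:
                omegas.append(rec.omega)
        assert omegas and all(w < 1.0 for w in omegas)


class TestOmegaRecovery:
    @pytest.mark.parametrize("omega_target", [0.1, 0.2, 1.0])
    def test_ng_estimate_unbiased(self, omega_target, rng):
        evo = EvolutionModel(omega_target=omega_target, ks_target=0.5)
        estimates = []
        for _ in range(60):
            a, b = simulate_codon_pair(300, evo, rng)
            rec = ng_kaks(a, b)
            if rec.omega_defined:
                estimates.append(rec.omega)
        mean = np.mean(estimates)
        assert mean == pytest.approx(omega_target, abs=0.1 * max(1.0, omega_target / 0.2))
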