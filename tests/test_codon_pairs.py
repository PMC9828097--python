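"""Codon pair counting, dipeptide bias, Poisson classification, pair bias."""
import math

import numpy as np
import pytest
import scipy.stats

from plastcodon import codon_pairs, codon_stats
from plastcodon.codon_pairs import (
    CodonPairError,
    call_overrepresented,
    call_underrepresented,
    classify_rare_codons,
    count_pairs,
    dipeptide_bias,
    junction_dinucleotides,
    pair_bias,
    poisson_p_le1,
    scan_out_of_frame_stops,
    scan_repeats,
)
from plastcodon.codon_stats import CodonCountTable
from plastcodon.genetics import AA_INDEX, SENSE_CODONS, SENSE_INDEX, STOP_CODONS

from conftest import make_cds


def brute_force_pairs(records):
    """Independent sliding-window enumeration of adjacent sense codons."""
    table = {}
    for rec in records:
        sense = [c for c in rec.codons if c not in STOP_CODONS]
        for a, b in zip(sense, sense[1:]):
            table[(a, b)] = table.get((a, b), 0) + 1
    return table


class TestCountPairs:
    def test_toy_gene(self):
        pc = count_pairs([make_cds(["ATG", "AAA", "TTT"])])
        i = SENSE_INDEX
        assert pc.n_pairs == 2
        assert pc.observed[i["ATG"], i["AAA"]] == 1
        assert pc.observed[i["AAA"], i["TTT"]] == 1

    def test_no_cross_gene_pairs(self):
        pc = count_pairs([make_cds(["AAA"]), make_cds(["TTT"])])
        assert pc.n_pairs == 0 and pc.observed.sum() == 0

    def test_stop_codons_never_pair(self):
        pc = count_pairs([make_cds(["AAA", "TAA", "TTT"])])  # stop breaks? no:
        # stops are removed from the sense run; remaining codons are adjacent
        # in the sense-codon sequence, mirroring how a trailing stop works.
        assert pc.n_pairs == 1

    def test_matches_bruteforce_on_synthetic_set(self, default_genome):
        records = default_genome.cds[:12]
        expected = brute_force_pairs(records)
        pc = count_pairs(records)
        assert pc.observed.sum() == pc.n_pairs == sum(expected.values())
        for (a, b), n in expected.items():
            assert pc.observed[SENSE_INDEX[a], SENSE_INDEX[b]] == n

    def test_palindromic_toy_matches_enumeration(self):
        codons = ["ATG", "GTA", "ATG", "GTA", "ATG"]
        pc = count_pairs([make_cds(codons)])
        expected = brute_force_pairs([make_cds(codons)])
        assert pc.observed[SENSE_INDEX["ATG"], SENSE_INDEX["GTA"]] == expected[("ATG", "GTA")] == 2


class TestDipeptideBias:
    def test_forced_single_dipeptide(self):
        d = dipeptide_bias([make_cds(["AAA"] * 50)])
        k = AA_INDEX["K"]
        assert d.dipb[k, k] == pytest.approx(1.0)

    def test_alternating_dipeptide_toy(self):
        # Ala-Gly alternating: aa frequencies are 1/2 each, so the expected
        # (A,G) count is N_P/4 while nearly half of all windows are (A,G).
        codons = ["GCT", "GGT"] * 20
        d = dipeptide_bias([make_cds(codons)])
        a, g = AA_INDEX["A"], AA_INDEX["G"]
        n_pairs = len(codons) - 1
        p_ag = 20.0  # hand count: (A,G) windows at even offsets
        assert d.observed[a, g] == p_ag
        assert d.dipb[a, g] == pytest.approx(p_ag / (0.25 * n_pairs))

    def test_converges_to_one_on_iid_codons(self):
        from plastcodon.synthetic import chloroplast_like_codon_freqs, iid_codon_records

        records = iid_codon_records(
            chloroplast_like_codon_freqs(), 100_000, n_genes=10, seed=3
        )
        d = dipeptide_bias(records)
        well_sampled = d.expected >= 500
        assert well_sampled.sum() > 20
        assert np.abs(d.dipb[well_sampled] - 1.0).max() < 0.1

    def test_undefined_cells_are_nan(self):
        d = dipeptide_bias([make_cds(["AAA", "AAA"])])
        assert math.isnan(d.dipb[AA_INDEX["W"], AA_INDEX["W"]])


class TestPoisson:
    def test_closed_form_values(self):
        assert poisson_p_le1(0.0) == 1.0
        assert poisson_p_le1(1.0) == pytest.approx(2 / math.e)

    def test_matches_scipy_cdf(self):
        lams = np.linspace(0, 12, 50)
        assert np.allclose(poisson_p_le1(lams), scipy.stats.poisson.cdf(1, lams))

    def test_monotone_decreasing(self):
        values = poisson_p_le1(np.linspace(0, 10, 200))
        assert np.all(np.diff(values) < 0)

    def test_negative_lambda_is_error(self):
        with pytest.raises(CodonPairError):
            poisson_p_le1(-0.1)


class TestClassifyRareCodons:
    def test_absent_codon_is_deterministic(self):
        counts = CodonCountTable({"AAA": 500, "TTT": 400})
        cls = classify_rare_codons(counts)
        assert "GGG" in cls.deterministic
        assert cls.mean_p_le1["GGG"] == pytest.approx(1.0)

    def test_very_common_codon_is_probabilistic(self):
        counts = CodonCountTable({c: 50 for c in SENSE_CODONS} | {"AAA": 1500})
        cls = classify_rare_codons(counts)
        assert "AAA" not in cls.deterministic
        assert cls.mean_p_le1["AAA"] < 0.1

    def test_matches_direct_summation_oracle(self, default_genome):
        """Intermediate codon on a ~3000-codon scope: mean P(X<=1) recomputed
        by explicit per-pair evaluation."""
        counts = codon_stats.count_codons(default_genome.cds[:6])
        total = counts.total_sense
        cls = classify_rare_codons(counts)
        for codon in ("CTC", "AAA", "GGT"):
            c_i = counts.counts[codon]
            probs = []
            for other in SENSE_CODONS:
                lam = c_i * counts.counts[other] / total
                probs.append((1 + lam) * math.exp(-lam))
            assert cls.mean_p_le1[codon] == pytest.approx(sum(probs) / 61)


def _toy_state(records):
    counts = codon_stats.count_codons(records)
    pairs = count_pairs(records)
    dipb = dipeptide_bias(records)
    cls = classify_rare_codons(counts)
    return counts, pairs, dipb, cls


class TestPairBias:
    def test_row_sum_identity(self, default_genome):
        counts, pairs, dipb, cls = _toy_state(default_genome.cds)
        result = pair_bias(pairs, counts, dipb, classification=cls)
        c = np.array([counts.counts[x] for x in SENSE_CODONS], dtype=float)
        assert np.allclose(result.e_raw.sum(axis=1), c)

    def test_mixed_ceiling_and_naive_inflation_contrast(self):
        """e_norm = 0.2 with o = 1: the mixed model sees no bias while the
        naive model reports 4-fold overrepresentation."""
        counts, pairs, dipb, cls = _toy_state([make_cds(["AAA"] * 3)])
        pairs.observed[:] = 0
        i, j = SENSE_INDEX["AAA"], SENSE_INDEX["TTT"]
        pairs.observed[i, j] = 1
        dipb.dipb[:] = 1.0
        # c_i = 1 and F_j = 1/5 give e_norm = 0.2 exactly
        counts_obj = CodonCountTable({"AAA": 1, "TTT": 1, "GGT": 3})
        mixed = pair_bias(pairs, counts_obj, dipb, mode="mixed")
        naive = pair_bias(pairs, counts_obj, dipb, mode="naive")
        assert mixed.e_norm[i, j] == pytest.approx(0.2)
        assert mixed.e_used[i, j] == 1.0 and mixed.bias[i, j] == pytest.approx(0.0)
        assert naive.bias[i, j] == pytest.approx(4.0)

    def test_bias_arithmetic(self):
        counts, pairs, dipb, cls = _toy_state([make_cds(["AAA", "TTT"] * 8)])
        result = pair_bias(pairs, counts, dipb)
        i, j = SENSE_INDEX["AAA"], SENSE_INDEX["TTT"]
        o = result.pair_counts.observed[i, j]
        e_used = result.e_used[i, j]
        assert result.bias[i, j] == pytest.approx((o - e_used) / e_used)

    def test_anti_inflation_invariant_on_random_genomes(self):
        """Mixed mode: a pair with e_norm < 1 observed once is never biased."""
        from plastcodon.synthetic import chloroplast_like_codon_freqs, iid_codon_records

        for seed in range(5):
            records = iid_codon_records(
                chloroplast_like_codon_freqs(), 4000, n_genes=8, seed=seed
            )
            counts, pairs, dipb, cls = _toy_state(records)
            result = pair_bias(pairs, counts, dipb, classification=cls)
            sub = (result.e_norm < 1) & (pairs.observed == 1)
            assert np.all(result.bias[sub & np.isfinite(result.bias)] <= 0)
            finite = np.isfinite(result.bias)
            assert np.all(result.bias[finite] >= -1)

    def test_naive_zero_expectation_is_nan_not_division_error(self):
        counts, pairs, dipb, cls = _toy_state([make_cds(["AAA", "TTT"])])
        result = pair_bias(pairs, counts, dipb, mode="naive")
        i = SENSE_INDEX["GGG"]
        assert math.isnan(result.bias[i, i])

    def test_rare_rows_ceiling_variant(self, default_genome):
        counts, pairs, dipb, cls = _toy_state(default_genome.cds[:8])
        result = pair_bias(
            pairs, counts, dipb, ceiling="rare_rows", classification=cls
        )
        rare_rows = [SENSE_INDEX[c] for c in sorted(cls.deterministic)]
        common = [i for i in range(61) if i not in rare_rows]
        assert np.allclose(
            result.e_used[rare_rows], np.ceil(result.e_norm[rare_rows]), equal_nan=True
        )
        assert np.allclose(
            result.e_used[common], result.e_norm[common], equal_nan=True
        )


class TestCalls:
    def test_zero_bias_genome_has_no_calls(self):
        counts, pairs, dipb, cls = _toy_state([make_cds(["AAA"] * 20)])
        result = pair_bias(pairs, counts, dipb)
        assert call_overrepresented(result) == []

    def test_calls_sorted_descending(self, default_genome):
        counts, pairs, dipb, cls = _toy_state(default_genome.cds)
        result = pair_bias(pairs, counts, dipb, mode="naive")
        calls = call_overrepresented(result, fold=3.0)
        biases = [b for _, _, b in calls]
        assert biases == sorted(biases, reverse=True)
        assert all(b > 3.0 for b in biases)

    def test_underrepresented_reported_separately(self, default_genome):
        counts, pairs, dipb, cls = _toy_state(default_genome.cds)
        result = pair_bias(pairs, counts, dipb, mode="naive")
        under = call_underrepresented(result, fold=3.0)
        assert all(b < 1 / 3 - 1 for _, _, b in under)


class TestJunctionDinucleotides:
    def test_single_pair(self):
        jc = junction_dinucleotides([("AAG", "GCC")])
        assert jc.proportions["GG"] == 1.0
        assert jc.cp3_gc_pct == 100.0

    def test_proportions_sum_to_one(self, default_genome):
        counts, pairs, dipb, cls = _toy_state(default_genome.cds)
        result = pair_bias(pairs, counts, dipb, mode="naive")
        calls = call_overrepresented(result, 3.0)
        jc = junction_dinucleotides(calls)
        assert sum(jc.proportions.values()) == pytest.approx(1.0)

    def test_hand_tallied_toy(self):
        pairs = [("AAA", "TTT"), ("AAA", "TTT"), ("AAG", "GGG"), ("TTT", "AAA")]
        jc = junction_dinucleotides(pairs)
        assert jc.proportions["AT"] == 0.5
        assert jc.proportions["GG"] == 0.25
        assert jc.proportions["TA"] == 0.25
        assert jc.cp3_at_pct == pytest.approx(75.0)

    def test_empty_list_is_error(self):
        with pytest.raises(CodonPairError):
            junction_dinucleotides([])


class TestOutOfFrameStops:
    def test_plus_one_frame_hand_check(self):
        scan = scan_out_of_frame_stops([make_cds(["TTT", "AAA"])])
        assert scan["cP3_cA12"]["TAA"] == 1
        assert scan["n_junctions"] == 1

    def test_clean_gene_has_none(self):
        scan = scan_out_of_frame_stops([make_cds(["GGG", "GGG"])])
        assert scan["cP3_cA12"] == {"TAA": 0, "TGA": 0}
        assert scan["cP23_cA1"] == {"TAA": 0, "TGA": 0}

    def test_matches_shifted_regex_oracle(self, default_genome):
        import re

        records = default_genome.cds[:10]
        plus1 = plus2 = 0
        for rec in records:
            sense = "".join(rec.sense_codons)
            for m in re.finditer("(?=(TAA|TGA))", sense):
                if m.start() % 3 == 2:
                    plus1 += 1
                elif m.start() % 3 == 1:
                    plus2 += 1
        scan = scan_out_of_frame_stops(records)
        assert sum(scan["cP3_cA12"].values()) == plus1
        assert sum(scan["cP23_cA1"].values()) == plus2


class TestRepeats:
    def test_mononucleotide_run(self):
        scan = scan_repeats([make_cds(["AAA", "AAA", "TTT"])])
        assert scan.mono_run_count == 1

    def test_junction_windows_on_toy(self):
        scan = scan_repeats([make_cds(["AAA", "TTT"])], lengths=(4,))
        assert scan.junction_windows[4] == 3
        assert scan.junction_counts[4]["AATT"] == 1
        assert scan.junction_counts[4]["AAAT"] == 1
        assert scan.junction_counts[4]["ATTT"] == 1

    def test_expected_counts_scale_with_base_composition(self):
        scan = scan_repeats([make_cds(["AAA", "AAA", "AAA"])], lengths=(4,))
        # all-A sequence: every window must be AAAA and expectation matches
        assert scan.expected_count("AAAA") == pytest.approx(scan.junction_windows[4])
        assert scan.expected_count("GGGG") == 0.0
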