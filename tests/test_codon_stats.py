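"""Codon usage descriptors: counts, freq/1000, RSCU, W, CAI, demand."""
import math
from collections import Counter

import pytest

from plastcodon import codon_stats
from plastcodon.codon_stats import (
    CodonCountTable,
    CodonStatsError,
    cai,
    classify_codons,
    codon_demand,
    count_codons,
    demand_share_fold,
    fold_difference,
    freq_per_1000,
    build_usage_profile,
    read_usage_table,
    relative_adaptiveness,
    rscu,
    write_usage_table,
)
from plastcodon.genetics import SENSE_CODONS, STOP_CODONS, SYNONYMOUS

from conftest import make_cds


class TestCountCodons:
    def test_stops_tallied_separately(self):
        counts = count_codons([make_cds(["ATG", "AAA", "AAA", "TAA"])])
        assert counts.counts["ATG"] == 1 and counts.counts["AAA"] == 2
        assert counts.stop_counts == {"TAA": 1, "TAG": 0, "TGA": 0}
        assert counts.total_sense == 3

    def test_linearity_two_copies_double_counts(self):
        rec = make_cds(["ATG", "TTT", "GGT", "TAA"])
        single = count_codons([rec]).counts
        double = count_codons([rec, rec]).counts
        assert all(double[c] == 2 * single[c] for c in SENSE_CODONS)

    def test_matches_bruteforce_triplet_scan(self, default_genome):
        records = default_genome.cds[:10]
        expected = Counter()
        for rec in records:
            seq = rec.nt_seq
            for i in range(0, len(seq), 3):
                codon = seq[i : i + 3]
                if codon not in STOP_CODONS:
                    expected[codon] += 1
        counts = count_codons(records)
        assert all(counts.counts[c] == expected.get(c, 0) for c in SENSE_CODONS)

    def test_empty_set_is_error(self):
        with pytest.raises(CodonStatsError):
            count_codons([])


class TestFreqPer1000:
    def test_single_codon_gets_full_mass(self):
        counts = CodonCountTable({"AAA": 1})
        assert freq_per_1000(counts)["AAA"] == 1000.0

    def test_direct_arithmetic(self):
        f = freq_per_1000(CodonCountTable({"AAA": 1, "TTT": 3}))
        assert f["AAA"] == 250.0 and f["TTT"] == 750.0

    def test_normalization_sums_to_1000(self, default_genome):
        f = freq_per_1000(count_codons(default_genome.cds))
        assert math.isclose(sum(f.values()), 1000.0, abs_tol=1e-6)

    def test_zero_total_is_error(self):
        with pytest.raises(CodonStatsError):
            freq_per_1000(CodonCountTable({}))


class TestRscu:
    def test_even_usage_gives_one(self):
        r = rscu(CodonCountTable({"AAA": 10, "AAG": 10}))
        assert r["AAA"] == 1.0 and r["AAG"] == 1.0

    def test_direct_arithmetic(self):
        r = rscu(CodonCountTable({"AAA": 30, "AAG": 10}))
        assert r["AAA"] == 1.5 and r["AAG"] == 0.5

    def test_absent_amino_acid_flagged_missing_not_zero(self):
        counts = CodonCountTable({"AAA": 5})
        r = rscu(counts)
        assert math.isnan(r["TTT"]) and math.isnan(r["TTC"])
        profile = build_usage_profile(counts)
        assert "F" in profile.missing_amino_acids

    def test_family_sums_equal_family_size(self, default_genome):
        counts = count_codons(default_genome.cds)
        r = rscu(counts)
        for aa, codons in SYNONYMOUS.items():
            total = sum(r[c] for c in codons)
            if not math.isnan(total):
                assert math.isclose(total, len(codons), rel_tol=1e-12)


class TestRelativeAdaptiveness:
    def test_most_frequent_codon_has_w_one(self, default_genome):
        w = relative_adaptiveness(count_codons(default_genome.cds))
        for codons in SYNONYMOUS.values():
            assert math.isclose(max(w[c] for c in codons), 1.0)

    def test_direct_arithmetic(self):
        w = relative_adaptiveness(CodonCountTable({"AAA": 30, "AAG": 10}))
        assert math.isclose(w["AAG"], 1 / 3)

    def test_pseudocount_rule_for_reference_absent_codon(self):
        w = relative_adaptiveness(CodonCountTable({"AAA": 30}), pseudocount=0.5)
        assert math.isclose(w["AAG"], 0.5 / 30)


class TestCai:
    def test_all_optimal_gene_scores_one(self):
        reference = CodonCountTable({"AAA": 30, "AAG": 1, "GAA": 20, "GAG": 1})
        w = relative_adaptiveness(reference)
        score = cai(make_cds(["ATG", "AAA", "GAA", "AAA", "TAA"]), w)
        assert score.cai == pytest.approx(1.0)
        assert score.length_codons_used == 3  # ATG excluded, stop excluded

    def test_closed_form_two_codon_gene(self):
        w = dict.fromkeys(SENSE_CODONS, 1.0)
        w["AAG"] = 0.25
        score = cai(make_cds(["AAA", "AAG"]), w)
        assert score.cai == pytest.approx(math.sqrt(0.25))

    def test_concatenation_identity(self, default_genome):
        g1, g2 = default_genome.cds[0], default_genome.cds[1]
        w = relative_adaptiveness(count_codons(default_genome.cds))
        s1, s2 = cai(g1, w), cai(g2, w)
        combined = cai(make_cds(g1.sense_codons + g2.sense_codons), w)
        l1, l2 = s1.length_codons_used, s2.length_codons_used
        expected = math.exp(
            (l1 * math.log(s1.cai) + l2 * math.log(s2.cai)) / (l1 + l2)
        )
        assert combined.cai == pytest.approx(expected, rel=1e-12)

    def test_bounds(self, default_genome):
        w = relative_adaptiveness(count_codons(default_genome.cds))
        for rec in default_genome.cds:
            score = cai(rec, w)
            assert 0.0 < score.cai <= 1.0

    def test_no_codons_after_exclusions_is_error(self):
        w = dict.fromkeys(SENSE_CODONS, 1.0)
        with pytest.raises(CodonStatsError):
            cai(make_cds(["ATG", "TGG", "TAA"]), w)


class TestClassification:
    def test_threshold_rule(self):
        w = dict.fromkeys(SENSE_CODONS, 1.0)
        w["AAG"] = 0.1
        cls = classify_codons(w, 0.5)
        assert "AAA" in cls.optimal and "AAG" in cls.non_optimal

    def test_single_codon_families_always_optimal(self):
        w = dict.fromkeys(SENSE_CODONS, 0.0)
        cls = classify_codons(w, 0.5)
        assert {"ATG", "TGG"} <= cls.optimal

    def test_partition_covers_all_sense_codons(self, default_genome):
        w = relative_adaptiveness(count_codons(default_genome.cds))
        cls = classify_codons(w)
        assert cls.optimal.isdisjoint(cls.non_optimal)
        assert cls.optimal | cls.non_optimal == set(SENSE_CODONS)

    def test_recovers_designed_optimal_set_from_design_vector(self):
        """Classifying the designed W vector itself returns the truth sets."""
        from plastcodon.synthetic import SyntheticSpec, W_HIGH, generate_genome

        truth = generate_genome(SyntheticSpec(n_genes=4, seed=3)).truth
        cls = classify_codons(W_HIGH, truth["w_threshold"])
        assert cls.non_optimal == frozenset(truth["rare_codons"])
        assert cls.optimal == frozenset(truth["optimal_codons"])

    def test_recovers_designed_optimal_set_from_sampled_genome(self):
        """A large single-profile genome reproduces the designed optimal set
        through the full count -> W -> classify route (sampling noise must
        stay well inside the design margins)."""
        from plastcodon.synthetic import GroupSpec, SyntheticSpec, W_HIGH, generate_genome

        spec = SyntheticSpec(
            n_genes=120,
            gene_length_codons=(280, 320),
            groups=(GroupSpec("high", (5e3, 5e4), W_HIGH),),
            seed=4,
        )
        syn = generate_genome(spec)
        w = relative_adaptiveness(count_codons(syn.cds))
        cls = classify_codons(w, syn.truth["w_threshold"])
        assert cls.non_optimal == frozenset(syn.truth["rare_codons"])


class TestDemand:
    def test_zero_fpkm_zero_demand(self):
        counts = {"g": count_codons([make_cds(["AAA", "TTT"])])}
        demand = codon_demand(counts, {"g": 0.0})
        assert all(v == 0.0 for v in demand.demand.values())

    def test_direct_arithmetic(self):
        counts = {"g": count_codons([make_cds(["AAA", "AAA"])])}
        assert codon_demand(counts, {"g": 100.0}).demand["AAA"] == 200.0

    def test_scale_equivariance_in_fpkm(self, default_genome):
        per_gene = {
            r.gene: count_codons([r], scope=r.gene) for r in default_genome.cds[:8]
        }
        fpkm = {r.gene: r.fpkm for r in default_genome.cds[:8]}
        d1 = codon_demand(per_gene, fpkm)
        d2 = codon_demand(per_gene, {g: 2 * v for g, v in fpkm.items()})
        assert all(
            d2.demand[c] == pytest.approx(2 * d1.demand[c]) for c in SENSE_CODONS
        )

    def test_missing_fpkm_lists_genes(self):
        counts = {"g": count_codons([make_cds(["AAA"])])}
        with pytest.raises(CodonStatsError, match="g"):
            codon_demand(counts, {})

    def test_share_fold_is_scale_invariant(self, default_genome):
        half = len(default_genome.cds) // 2
        top = {r.gene: count_codons([r]) for r in default_genome.cds[:half]}
        low = {r.gene: count_codons([r]) for r in default_genome.cds[half:]}
        fpkm = {r.gene: r.fpkm for r in default_genome.cds}
        f1 = demand_share_fold(codon_demand(top, fpkm), codon_demand(low, fpkm))
        fpkm2 = {g: 3 * v for g, v in fpkm.items()}
        f2 = demand_share_fold(codon_demand(top, fpkm2), codon_demand(low, fpkm2))
        for c in SENSE_CODONS:
            if c not in f1.capped and not math.isnan(f1.ratios[c]):
                assert f1.ratios[c] == pytest.approx(f2.ratios[c])


class TestFoldDifference:
    def test_identical_profiles_give_unity(self, default_genome):
        p = build_usage_profile(count_codons(default_genome.cds))
        ratios = fold_difference(p, p).ratios
        assert all(
            math.isclose(r, 1.0) for r in ratios.values() if not math.isnan(r)
        )

    def test_direct_arithmetic(self):
        a = build_usage_profile(CodonCountTable({"AAA": 30, "AAG": 10}))
        b = build_usage_profile(CodonCountTable({"AAA": 10, "AAG": 10}))
        # RSCU 1.5 vs 1.0
        assert fold_difference(a, b).ratios["AAA"] == pytest.approx(1.5)

    def test_absent_codon_caps_at_flagged_sentinel(self):
        a = build_usage_profile(CodonCountTable({"AAA": 10, "AAG": 5}))
        b = build_usage_profile(CodonCountTable({"AAA": 10}))
        fd = fold_difference(a, b)
        assert "AAG" in fd.capped and fd.ratios["AAG"] == fd.cap


class TestUsageTable:
    def test_round_trip(self, tmp_path, default_genome):
        counts = count_codons(default_genome.cds)
        path = tmp_path / "usage.tsv"
        write_usage_table(counts, path)
        back = read_usage_table(path)
        assert back.counts == counts.counts
        assert back.stop_counts == counts.stop_counts

    def test_fractions_match_hand_computation(self, tmp_path):
        import pandas as pd

        counts = CodonCountTable({"AAA": 3, "AAG": 1})
        path = tmp_path / "usage.tsv"
        write_usage_table(counts, path)
        df = pd.read_csv(path, sep="\t").set_index("codon")
        assert df.loc["AAA", "fraction"] == pytest.approx(0.75)
        assert df.loc["AAA", "per_1000"] == pytest.approx(750.0)

    def test_empty_table_is_error(self, tmp_path):
        with pytest.raises(CodonStatsError):
            write_usage_table(CodonCountTable({}), tmp_path / "x.tsv")
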