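"""RSCU, mutation-bias-corrected weights, I_TE and phage-host correlations."""

import math

import numpy as np
import pytest

from phagetir.codon_adapt import (AMINO_ACID, SENSE_CODONS, CodonCounts, HostReference, cai_weights,
                                  codon_counts, family_split, host_weights, ite, r_rscu, rscu,
                                  third_position_freqs)
from phagetir.sd_detect import E_COLI_TAIL

UNIFORM_BG = {nt: 0.25 for nt in "ACGU"}


class TestFamilySplit:
    def test_partition_covers_61_sense_codons_exactly_once(self):
        for method in (1, 2):
            codons = [c for fam in family_split(method) for c in fam]
            assert sorted(codons) == list(SENSE_CODONS)

    def test_method2_splits_the_sixfold_families(self):
        fams = {fam for fam in family_split(2)}
        ser = [f for f in fams if AMINO_ACID[f[0]] == "S"]
        assert sorted(len(f) for f in ser) == [2, 4]
        leu = [f for f in fams if AMINO_ACID[f[0]] == "L"]
        arg = [f for f in fams if AMINO_ACID[f[0]] == "R"]
        assert sorted(len(f) for f in leu) == [2, 4]
        assert sorted(len(f) for f in arg) == [2, 4]

    def test_method1_keeps_ser_as_one_family_of_six(self):
        ser = [f for f in family_split(1) if AMINO_ACID[f[0]] == "S"]
        assert len(ser) == 1 and len(ser[0]) == 6

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            family_split(3)


class TestRSCU:
    def test_uniform_twofold_family(self):
        counts = CodonCounts({"AAA": 10, "AAG": 10})  # Lys
        r = rscu(counts)
        assert r["AAA"] == r["AAG"] == 1.0

    def test_extreme_fourfold_bias(self):
        counts = CodonCounts({"GGU": 8, "GGC": 0, "GGA": 0, "GGG": 0})  # Gly
        r = rscu(counts)
        assert r["GGU"] == 4.0 and r["GGC"] == r["GGA"] == r["GGG"] == 0.0

    def test_random_counts_against_hand_formula(self, rng):
        counts = CodonCounts({c: int(rng.integers(0, 50)) for c in SENSE_CODONS})
        r = rscu(counts)
        for fam in family_split(1):
            if len(fam) == 1:
                continue
            total = sum(counts[c] for c in fam)
            for c in fam:
                if total == 0:
                    assert math.isnan(r[c])
                else:
                    assert r[c] == pytest.approx(counts[c] / (total / len(fam)))

    def test_family_rscu_sums_to_family_size(self, rng):
        counts = CodonCounts({c: int(rng.integers(1, 50)) for c in SENSE_CODONS})
        r = rscu(counts)
        for fam in family_split(1):
            if len(fam) > 1:
                assert sum(r[c] for c in fam) == pytest.approx(len(fam))

    def test_empty_counts_error(self):
        with pytest.raises(ValueError):
            rscu(CodonCounts())


class TestCodonCounts:
    def test_start_codon_excluded_and_stops_separate(self):
        cc = codon_counts("AUG" + "AAA" * 3 + "UAA")
        assert cc.counts == {"AAA": 3}
        assert cc.stop_counts == {"UAA": 1}

    def test_dna_input_accepted(self):
        assert codon_counts("ATGAAAAAATAA").counts == {"AAA": 2}


class TestHostWeights:
    def test_uniform_background_reduces_to_classical_adaptiveness(self, rng):
        heg = CodonCounts({c: int(rng.integers(1, 100)) for c in SENSE_CODONS})
        assert host_weights(heg, UNIFORM_BG) == cai_weights(heg, method=2)

    def test_usage_tracking_mutation_bias_gives_no_selection_signal(self):
        # twofold NNY family: background C=0.3, U=0.2 -> E=(0.6, 0.4);
        # HEG usage 60:40 tracks it exactly, so w = (1, 1)
        heg = CodonCounts({"UUC": 60, "UUU": 40})  # Phe
        bg = {"A": 0.25, "C": 0.3, "G": 0.25, "U": 0.2}
        w = host_weights(heg, bg)
        assert w["UUC"] == pytest.approx(1.0) and w["UUU"] == pytest.approx(1.0)

    def test_max_weight_is_one_per_subfamily(self, rng):
        heg = CodonCounts({c: int(rng.integers(0, 100)) for c in SENSE_CODONS})
        bg = {"A": 0.2, "C": 0.3, "G": 0.3, "U": 0.2}
        w = host_weights(heg, bg)
        for fam in family_split(2):
            vals = [w[c] for c in fam if c in w]
            if vals:
                assert max(vals) == pytest.approx(1.0)
                assert all(0 < v <= 1 for v in vals)

    def test_scaling_heg_counts_leaves_w_unchanged(self, rng):
        heg = {c: int(rng.integers(1, 100)) for c in SENSE_CODONS}
        bg = {"A": 0.2, "C": 0.3, "G": 0.3, "U": 0.2}
        w1 = host_weights(CodonCounts(heg), bg)
        w10 = host_weights(CodonCounts({c: 10 * n for c, n in heg.items()}), bg)
        assert w1 == pytest.approx(w10)

    def test_parameter_recovery_from_weight_generated_usage(self):
        # usage proportional to E_i * w*_i recovers w* exactly
        from phagetir.synthetic_data import default_true_weights

        true_w = default_true_weights()
        bg = {"A": 0.2, "C": 0.3, "G": 0.3, "U": 0.2}
        counts = {}
        for fam in family_split(2):
            if len(fam) == 1:
                continue
            e = np.array([bg[c[2]] for c in fam])
            e = e / e.sum()
            wv = np.array([true_w[c] for c in fam])
            p = e * wv / (e * wv).sum()
            for c, pi in zip(fam, p):
                counts[c] = int(round(1e6 * pi))
        w = host_weights(CodonCounts(counts), bg)
        for c, v in w.items():
            assert v == pytest.approx(true_w[c], abs=1e-3)


class TestITE:
    def test_gene_of_optimal_codons_scores_one(self):
        w = {"AAA": 1.0, "AAG": 0.5}
        assert ite(CodonCounts({"AAA": 20}), w) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        w = {"AAA": 0.25, "GGU": 1.0}
        assert ite(CodonCounts({"AAA": 1, "GGU": 1}), w) == pytest.approx(0.5)

    def test_log_domain_recomputation(self, rng):
        w = {c: float(rng.uniform(0.05, 1.0)) for c in SENSE_CODONS}
        for _ in range(20):
            counts = {c: int(rng.integers(0, 10)) for c in rng.choice(SENSE_CODONS, 20)}
            cc = CodonCounts({c: n for c, n in counts.items() if n})
            if not cc.counts:
                continue
            expected = math.exp(sum(n * math.log(w[c]) for c, n in cc.counts.items())
                                / sum(cc.counts.values()))
            assert ite(cc, w) == pytest.approx(expected, abs=1e-12)

    def test_replacing_low_w_synonym_raises_score(self):
        w = {"GGU": 1.0, "GGC": 0.3, "AAA": 0.8}
        low = ite(CodonCounts({"GGC": 5, "AAA": 5}), w)
        high = ite(CodonCounts({"GGC": 4, "GGU": 1, "AAA": 5}), w)
        assert high > low

    def test_no_scorable_codons_errors(self):
        with pytest.raises(ValueError):
            ite(CodonCounts({"AUG": 3}), {"AAA": 1.0})


class TestRrscu:
    def _host(self, counts: CodonCounts) -> HostReference:
        return HostReference(tail=E_COLI_TAIL, heg_counts=counts, background_freqs=dict(UNIFORM_BG))

    def test_identical_usage_correlates_perfectly(self, rng):
        counts = CodonCounts({c: int(rng.integers(1, 100)) for c in SENSE_CODONS})
        r, test = r_rscu(counts, self._host(counts), variant="heg")
        assert r == pytest.approx(1.0)
        assert test.p_value < 1e-10

    def test_w_based_variant_uses_host_weights(self, rng):
        from scipy.stats import pearsonr

        phage = CodonCounts({c: int(rng.integers(1, 100)) for c in SENSE_CODONS})
        host = self._host(CodonCounts({c: int(rng.integers(1, 100)) for c in SENSE_CODONS}))
        r, _ = r_rscu(phage, host, variant="w_based")
        pr = rscu(phage)
        shared = [c for c in pr if c in host.w and not math.isnan(pr[c])]
        assert r == pytest.approx(pearsonr([pr[c] for c in shared], [host.w[c] for c in shared])[0])

    def test_all_genes_variant_requires_counts(self, rng):
        phage = CodonCounts({c: 5 for c in SENSE_CODONS})
        with pytest.raises(ValueError):
            r_rscu(phage, self._host(phage), variant="all_genes")


def test_third_position_freqs_hand_example():
    # third positions: A, G, A, U -> A 0.5, G 0.25, U 0.25
    freqs = third_position_freqs(["AAAGGGCCAUUU"])
    assert freqs == {"A": 0.5, "C": 0.0, "G": 0.25, "U": 0.25}
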