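"""SD-aSD duplex detection, D_toAUG geometry, and per-genome summaries."""

import numpy as np
import pytest

from conftest import make_gene_record, random_seq
from phagetir.sd_detect import (E_COLI_TAIL, AntiSDTail, SDCallConfig, all_matches, call_sd,
                                dtoaug_histogram, find_matches, genome_sd_summary,
                                tail_participation)
from phagetir.seq_io import revcomp_rna

_COMPL = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_force_matches(upstream: str, tail: str, min_len: int = 4):
    """Exhaustive (i, j, L) enumeration of maximal perfect antiparallel duplexes."""

    def pairs_at(i, j):  # 0-based: upstream[i] against tail[j]
        return 0 <= i < len(upstream) and 0 <= j < len(tail) and _COMPL.get(upstream[i]) == tail[j]

    found = set()
    for i in range(len(upstream)):
        for j in range(len(tail)):
            for L in range(min_len, min(len(upstream) - i, j + 2) + 1):
                dup = all(pairs_at(i + k, j - k) for k in range(L))
                maximal = dup and not pairs_at(i - 1, j + 1) and not pairs_at(i + L, j - L)
                if maximal:
                    found.add((i + 1, i + L, j - L + 2, j + 1))  # 1-based mrna/tail spans
    return found


class TestFindMatches:
    def test_aggagg_with_five_nt_spacer_gives_d13(self, tail):
        # C background cannot pair: C pairs only G, and the tail has no GGGG run
        matches = find_matches("C" * 19 + "AGGAGG" + "CCCCC", tail)
        assert len(matches) == 1
        m = matches[0]
        assert (m.L, m.tail_start, m.tail_end) == (6, 6, 11)
        assert (m.tail_overhang, m.spacer, m.d_toaug) == (2, 5, 13)

    def test_aggag_with_six_nt_spacer_gives_d13(self, tail):
        (m,) = find_matches("C" * 19 + "AGGAG" + "CCCCCC", tail)
        assert (m.L, m.spacer, m.tail_overhang, m.d_toaug) == (5, 6, 2, 13)

    def test_all_c_upstream_has_no_match(self, tail):
        assert find_matches("C" * 30, tail) == []

    def test_maximal_duplex_not_reported_as_subduplexes(self, tail):
        matches = find_matches("C" * 19 + "AGGAGG" + "CCCCC", tail)
        assert [m.L for m in matches] == [6]

    def test_matches_equal_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(200):
            up = random_seq(rng, int(rng.integers(10, 41)))
            t = random_seq(rng, int(rng.integers(4, 14)))
            tail = AntiSDTail(t)
            got = {(m.mrna_start, m.mrna_end, m.tail_start, m.tail_end) for m in find_matches(up, tail)}
            assert got == brute_force_matches(up, t)

    def test_d_toaug_identity_and_min_len_monotonicity(self, rng, tail):
        for _ in range(50):
            up = random_seq(rng, 30)
            by_len = {k: find_matches(up, tail, min_len=k) for k in (3, 4, 5)}
            assert len(by_len[3]) >= len(by_len[4]) >= len(by_len[5])
            for m in by_len[3]:
                assert m.d_toaug == m.L + m.spacer + m.tail_overhang
                assert m.tail_overhang == len(tail) - m.tail_end


class TestCallSD:
    def test_d_below_window_rejected(self, tail):
        # AGGAGG directly abutting the start codon: D = 2 + 6 + 0 = 8 < 10
        matches = find_matches("C" * 24 + "AGGAGG", tail)
        has, best = call_sd(matches, SDCallConfig())
        assert not has and best is None

    def test_longest_match_wins(self, tail):
        # AGGAGG at D = 20 and AGGA at D = 13: both qualify, longest wins
        up = "C" * 12 + "AGGAGG" + "C" + "AGGA" + "C" * 7
        assert len(up) == 30
        matches = find_matches(up, tail)
        assert {4, 6} <= {m.L for m in matches}
        has, best = call_sd(matches, SDCallConfig())
        assert has and best.L == 6

    def test_tie_broken_by_distance_to_13(self, tail):
        # two AGGA duplexes, D_toAUG = 18 and 10: equal L, closer-to-13 wins
        up = "C" * 14 + "AGGA" + "C" * 4 + "AGGA" + "C" * 4
        assert len(up) == 30
        matches = [m for m in find_matches(up, tail) if m.L == 4]
        assert sorted(m.d_toaug for m in matches) == [10, 18]
        has, best = call_sd(matches, SDCallConfig())
        assert has
        assert abs(best.d_toaug - 13) == min(abs(m.d_toaug - 13) for m in matches)

    def test_window_none_accepts_any_position(self, tail):
        matches = find_matches("C" * 24 + "AGGAGG", tail)  # D = 8
        assert call_sd(matches, SDCallConfig(d_window=None))[0]

    def test_widening_window_never_lowers_p_sd(self, rng, tail):
        genes = [make_gene_record(random_seq(rng, 40), "AUG" + random_seq(rng, 96), f"g{i}")
                 for i in range(60)]
        p = []
        for window in [(12, 16), (10, 20), (6, 26), None]:
            cfg = SDCallConfig(d_window=window)
            p.append(genome_sd_summary(genes, tail, cfg).p_sd)
        assert p == sorted(p)


class TestGenomeSummary:
    def test_planted_sd_fraction(self, rng, tail):
        from phagetir.synthetic_data import _clean_upstream, _plant_sd

        genes = []
        for i in range(10):
            up = _clean_upstream(40, 0.45, tail, rng)
            if i < 7:  # retry: a plant is rejected when its flanks extend the duplex
                planted = None
                while planted is None:
                    planted = _plant_sd(_clean_upstream(40, 0.45, tail, rng), 6, 13, tail, rng)
                up = planted
            genes.append(make_gene_record(up, "AUG" + random_seq(rng, 96), f"g{i}"))
        s = genome_sd_summary(genes, tail)
        assert (s.p_sd, s.m_sd, s.n_sd) == (70.0, 6.0, 7)

    def test_all_sd_free(self, rng, tail):
        from phagetir.synthetic_data import _clean_upstream

        genes = [make_gene_record(_clean_upstream(40, 0.45, tail, rng),
                                  "AUG" + random_seq(rng, 96), f"g{i}") for i in range(5)]
        s = genome_sd_summary(genes, tail)
        assert s.p_sd == 0.0 and s.m_sd is None

    def test_m_sd_at_least_min_len_whenever_defined(self, rng, tail):
        genes = [make_gene_record(random_seq(rng, 40), "AUG" + random_seq(rng, 96), f"g{i}")
                 for i in range(80)]
        s = genome_sd_summary(genes, tail)
        if s.m_sd is not None:
            assert s.m_sd >= 4

    def test_empty_gene_list_errors(self, tail):
        with pytest.raises(ValueError):
            genome_sd_summary([], tail)


class TestHistogramAndParticipation:
    def test_histogram_counts_all_matches(self, tail):
        ups = ["C" * 19 + "AGGAGG" + "CCCCC",  # D = 13
               "C" * 17 + "AGGAGG" + "CCCCCCC",  # D = 15
               "C" * 19 + "AGGAGG" + "CCCCC"]
        matches = [m for up in ups for m in find_matches(up, tail)]
        assert dtoaug_histogram(matches) == {13: 2, 15: 1}
        assert sum(dtoaug_histogram(matches).values()) == len(matches)
        assert dtoaug_histogram([]) == {}

    def test_single_match_participation(self, tail):
        (m,) = find_matches("C" * 19 + "AGGAGG" + "CCCCC", tail)
        counts = tail_participation([m])
        assert counts.tolist() == [0] * 5 + [1] * 6 + [0, 0]

    def test_participation_matches_brute_force_sum(self, rng, tail):
        ups = [random_seq(rng, 30) for _ in range(50)]
        matches = [m for up in ups for m in find_matches(up, tail)]
        counts = tail_participation(matches)
        expected = np.zeros(13, int)
        for m in matches:
            for site in range(m.tail_start, m.tail_end + 1):
                expected[site - 1] += 1
        assert counts.tolist() == expected.tolist()
        assert counts.sum() == sum(m.L for m in matches)

    def test_ugau_motif_reaches_second_a_from_tail_3_prime_end(self, tail):
        # UGAU pairs tail AUCA (sites 2..5), touching the A at site 5 -- the
        # second A from the rRNA 3' terminus.
        up = "C" * 20 + "UGAU" + "C" * 6
        matches = find_matches(up, tail)
        assert any(m.tail_start <= 5 <= m.tail_end for m in matches)


class TestAllMatches:
    def test_all_matches_is_position_free(self, rng, tail):
        genes = [make_gene_record(random_seq(rng, 40), "AUG" + random_seq(rng, 96), f"g{i}")
                 for i in range(30)]
        ms = all_matches(genes, tail)
        per_gene = sum(len(find_matches(g.upstream30, tail)) for g in genes)
        assert len(ms) == per_gene
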