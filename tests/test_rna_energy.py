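import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seq2abundance.rna_energy import (
    AlphabetError,
    EnergyModel,
    HybridStructure,
    cofold_duplex,
    exterior_loop_energy,
    fold_mfe,
    structure_statistics,
)

from conftest import CANONICAL_PAIRS, brute_force_mfe

RNG = np.random.default_rng(99)


def random_seq(n, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFold:
    def test_no_complementarity(self, energy_model):
        s = fold_mfe("AAAAAAAA", energy_model)
        assert s.pairs == frozenset()
        assert s.dg == 0.0
        assert s.dot_bracket == "........"

    def test_canonical_hairpin(self, energy_model):
        s = fold_mfe("GGGAAAACCC", energy_model)
        assert s.dot_bracket == "(((....)))"
        assert abs(s.dg - brute_force_mfe("GGGAAAACCC", energy_model)) < 1e-9

    def test_min_hairpin_respected(self, energy_model):
        for _ in range(20):
            s = fold_mfe(random_seq(12), energy_model)
            assert all(j - i >= energy_model.min_hairpin + 1 for i, j in s.pairs)

    def test_matches_enumeration_on_random_sequences(self, energy_model):
        rng = np.random.default_rng(5)
        for _ in range(40):
            seq = random_seq(int(rng.integers(1, 13)), rng)
            s = fold_mfe(seq, energy_model)
            assert s.dg <= 0.0
            assert abs(s.dg - brute_force_mfe(seq, energy_model)) < 1e-9

    def test_pairs_are_nested_and_disjoint(self, energy_model):
        s = fold_mfe(random_seq(40), energy_model)
        seen = set()
        for i, j in s.pairs:
            assert i < j
            assert i not in seen and j not in seen
            seen |= {i, j}
        for (i, j) in s.pairs:
            for (a, b) in s.pairs:
                # no crossing
                assert not (i < a < j < b)

    @given(st.text(alphabet="ACGU", min_size=1, max_size=11))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_t_u_relabeling_invariance(self, seq):
        m = EnergyModel.default()
        assert fold_mfe(seq, m).dg == fold_mfe(seq.replace("U", "T"), m).dg

    def test_invalid_alphabet(self, energy_model):
        with pytest.raises(AlphabetError):
            fold_mfe("ACGX", energy_model)

    def test_dot_bracket_consistent(self, energy_model):
        s = fold_mfe("GGGGAAAACCCCAAA", energy_model)
        assert len(s.dot_bracket) == len(s.sequence)
        assert s.dot_bracket.count("(") == len(s.pairs)


def enumerate_duplexes(t, p, model):
    """Independent oracle: exhaustive enumeration of antiparallel duplex pair
    chains with the model's loop-size cap; returns best
    (dg_duplex + dg_exterior) plus components, or None."""
    nt, np_ = len(t), len(p)

    def pairable(a, b):
        return (a, b) in CANONICAL_PAIRS

    best = [math.inf, None]

    def l_dangle(i, j):
        e = 0.0
        if i > 0:
            e += model.dangle_table[(t[i] + p[j], t[i - 1], "5p")]
        if j < np_ - 1:
            e += model.dangle_table[(p[j] + t[i], p[j + 1], "3p")]
        return e

    def r_dangle(i, j):
        e = 0.0
        if i < nt - 1:
            e += model.dangle_table[(t[i] + p[j], t[i + 1], "3p")]
        if j > 0:
            e += model.dangle_table[(p[j] + t[i], p[j - 1], "5p")]
        return e

    def extend(chain, e_helix):
        i, j = chain[-1]
        total = e_helix + l_dangle(*chain[0]) + r_dangle(i, j)
        if total < best[0]:
            best[0], best[1] = total, (list(chain), e_helix)
        for di in range(1, model.max_loop + 2):
            for dj in range(1, model.max_loop + 2):
                ii, jj = i + di, j - dj
                if ii >= nt or jj < 0 or not pairable(t[ii], p[jj]):
                    continue
                if di == 1 and dj == 1:
                    step = model.stack_table[(t[i] + p[j], t[ii] + p[jj])]
                else:
                    step = model.loop_base + model.loop_per_nt * (di - 1 + dj - 1)
                extend(chain + [(ii, jj)], e_helix + step)

    for i in range(nt):
        for j in range(np_):
            if pairable(t[i], p[j]):
                extend([(i, j)], 0.0)
    if best[1] is None:
        return None
    chain, e_helix = best[1]
    return best[0], e_helix, chain


class TestDuplex:
    def test_perfect_duplex(self, energy_model):
        t = "AAGGAGGT"
        h = cofold_duplex(t, "ACCTCCTT", energy_model)
        assert h.duplex_length == 8
        assert h.dg_exterior == 0.0
        assert abs(h.dg_total - (h.dg_duplex + h.dg_exterior + energy_model.duplex_init)) < 1e-12

    def test_no_complementarity_sentinel(self, energy_model):
        h = cofold_duplex("CCCCCCCC", "CCCCCCCC", energy_model)
        assert h.duplex_length == 0 and h.is_sentinel
        assert math.isnan(h.dg_total)

    def test_antisd_duplex_matches_enumeration(self, energy_model):
        rng = np.random.default_rng(17)
        probe = "GATCACCTCCTTA"[:10]
        hits = 0
        for _ in range(25):
            target = random_seq(9, rng) + "AGGAGG" + random_seq(5, rng)
            h = cofold_duplex(target, probe, energy_model)
            oracle = enumerate_duplexes(target, probe, energy_model)
            if h.is_sentinel:
                assert oracle is None or oracle[0] + energy_model.duplex_init >= 0
                continue
            hits += 1
            assert oracle is not None
            assert abs((h.dg_duplex + h.dg_exterior) - oracle[0]) < 1e-9
        assert hits >= 20  # SD-bearing targets should nearly always hybridize

    def test_energy_decomposition_identity(self, energy_model):
        rng = np.random.default_rng(23)
        for _ in range(20):
            h = cofold_duplex(random_seq(20, rng), random_seq(8, rng), energy_model)
            if h.is_sentinel:
                continue
            assert (
                abs(h.dg_total - (h.dg_duplex + h.dg_exterior + energy_model.duplex_init))
                < 1e-12
            )
            assert abs(h.dg_exterior - exterior_loop_energy(h, energy_model)) < 1e-12

    def test_monotone_pair_chain(self, energy_model):
        h = cofold_duplex("TTAGGAGGTT", "ACCTCCT", energy_model)
        assert not h.is_sentinel
        ti = [i for i, _ in h.duplex_pairs]
        pj = [j for _, j in h.duplex_pairs]
        assert ti == sorted(ti) and len(set(ti)) == len(ti)
        assert pj == sorted(pj, reverse=True) and len(set(pj)) == len(pj)


class TestExteriorLoop:
    def test_single_5prime_dangle_is_table_entry(self, energy_model):
        # A-dangle 5' of a GC closing pair on the target strand only
        h = HybridStructure("AGGG", "CCC", ((1, 2), (2, 1), (3, 0)), 0, 0, 0)
        e = exterior_loop_energy(h, energy_model)
        assert e == energy_model.dangle_table[("GC", "A", "5p")]

    def test_additivity_of_independent_dangles(self, energy_model):
        # dangles on both target ends = sum of single-dangle cases
        both = HybridStructure("AGGGT", "CCC", ((1, 2), (2, 1), (3, 0)), 0, 0, 0)
        left = HybridStructure("AGGG", "CCC", ((1, 2), (2, 1), (3, 0)), 0, 0, 0)
        right = HybridStructure("GGGT", "CCC", ((0, 2), (1, 1), (2, 0)), 0, 0, 0)
        assert abs(
            exterior_loop_energy(both, energy_model)
            - exterior_loop_energy(left, energy_model)
            - exterior_loop_energy(right, energy_model)
        ) < 1e-12

    def test_sentinel_gives_nan(self, energy_model):
        h = HybridStructure("AAAA", "AAAA", (), math.nan, math.nan, math.nan)
        assert math.isnan(exterior_loop_energy(h, energy_model))


class TestStructureStatistics:
    def test_unpaired_structure(self, energy_model):
        s = fold_mfe("AAAAAAAA", energy_model)
        unpaired, acc, dg = structure_statistics(s, (2, 6))
        assert unpaired == 8 and acc == 1.0 and dg == 0.0

    def test_hairpin_loop_accessibility(self, energy_model):
        s = fold_mfe("GGGAAAACCC", energy_model)
        unpaired, acc, _ = structure_statistics(s, (3, 7))
        assert unpaired == 4 and acc == 1.0
        _, acc_stem, _ = structure_statistics(s, (0, 3))
        assert acc_stem == 0.0

    def test_empty_subregion_raises(self, energy_model):
        s = fold_mfe("AAAA", energy_model)
        with pytest.raises(ValueError):
            structure_statistics(s, (2, 2))
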