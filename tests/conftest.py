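import numpy as np
import pytest

from seq2abundance.rna_energy import EnergyModel
from seq2abundance.synthetic_data import generate_bundle

CANONICAL_PAIRS = {
    ("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G"),
}


@pytest.fixture(scope="session")
def energy_model() -> EnergyModel:
    return EnergyModel.default()


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic bundle shared across read-only tests."""
    return generate_bundle(n=120, seed=11)


def enumerate_nested_structures(seq: str, min_hairpin: int = 3):
    """Independent exhaustive enumeration of all nested pair sets (oracle)."""
    s = seq.upper().replace("U", "T")
    n = len(s)

    def rec(i, j):
        if j - i + 1 <= 0:
            yield frozenset()
            return
        yield from rec(i + 1, j)  # i unpaired
        for k in range(i + min_hairpin + 1, j + 1):
            if (s[i], s[k]) in CANONICAL_PAIRS:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield left | right | {(i, k)}

    yield from rec(0, n - 1)


def score_pairs_oracle(seq: str, pairs, model: EnergyModel) -> float:
    """Independent scorer: stacks for adjacent pairs + hairpin penalties for
    pairs enclosing no other pair."""
    s = seq.upper().replace("U", "T")
    e = 0.0
    for i, j in pairs:
        if (i + 1, j - 1) in pairs:
            e += model.stack_table[(s[i] + s[j], s[i + 1] + s[j - 1])]
        if not any(i < a and b < j for a, b in pairs):
            e += model.hairpin_penalty[min(j - i - 1, 30)]
    return e


def brute_force_mfe(seq: str, model: EnergyModel) -> float:
    best = 0.0
    for pairs in enumerate_nested_structures(seq, model.min_hairpin):
        best = min(best, score_pairs_oracle(seq, pairs, model))
    return best


def exact_mw_p(a, b) -> float:
    """Independent exact Mann-Whitney oracle: P(min(Ua, Ub) <= observed)."""
    from itertools import combinations

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, n1 = len(pooled), len(a)

    def min_u(x, y):
        ua = sum(np.sum(v > y) + 0.5 * np.sum(v == y) for v in x)
        return min(ua, len(x) * len(y) - ua)

    u_obs = min_u(a, b)
    count = total = 0
    for comb in combinations(range(n), n1):
        mask = np.zeros(n, bool)
        mask[list(comb)] = True
        total += 1
        if min_u(pooled[mask], pooled[~mask]) <= u_obs + 1e-12:
            count += 1
    return count / total
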