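"""Minimal thermodynamic RNA folding and RNA:RNA hybridization.

Two dynamic programs drive the structure-derived TIR features:

* :func:`fold_mfe` — minimum-free-energy *nested* secondary structure of a
  single strand under a simplified nearest-neighbor model (stacking energies
  for adjacent base pairs, a hairpin-loop length penalty; internal, bulge and
  multibranch loops carry no penalty).
* :func:`cofold_duplex` — minimum-energy intermolecular duplex between a
  target (e.g. a 55-nt TIR) and a probe (e.g. the anti-Shine-Dalgarno 3' tail
  of 16S rRNA): one helix, antiparallel, with small bulges/internal loops,
  no intramolecular pairs.  Its energy decomposes exactly as
  ``dg_total = dg_duplex + dg_exterior + duplex_init``, where the exterior
  term is the sum of dangling-end contributions of unpaired bases flanking
  the duplex on both molecules — the "exterior loop" of the hybridization
  complex.

The built-in parameter set is a documented, versioned simplification shipped
as ``data/energy_params.tsv`` (not the Turner/UNAfold tables); an expert can
substitute any complete table with the same schema.  Watson-Crick and GU
pairs are allowed; ``min_hairpin`` defaults to 3; lonely pairs are allowed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
from numba import njit

NT = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(NT)}
PAIR_NAMES = ("AT", "TA", "GC", "CG", "GT", "TG")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_NAMES)}

INF = 1e18
_HP_MAX = 30


class AlphabetError(ValueError):
    """Sequence contains characters outside A/C/G/T/U."""


def _encode(seq: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    try:
        return np.array([_NT_INDEX[c] for c in s], dtype=np.int8)
    except KeyError as exc:
        raise AlphabetError(f"invalid nucleotide {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor parameter set (kcal/mol)."""

    stack_table: dict[tuple[str, str], float]
    hairpin_penalty: dict[int, float]
    dangle_table: dict[tuple[str, str, str], float]
    duplex_init: float
    min_hairpin: int = 3
    loop_base: float = 3.0       # duplex bulge/internal-loop opening
    loop_per_nt: float = 0.5     # per unpaired nt inside a duplex loop
    max_loop: int = 3            # max unpaired nt per strand in a duplex loop

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnergyModel":
        stack, hairpin, dangle, const = {}, {}, {}, {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("kind\t"):
                    continue
                kind, k1, k2, k3, value = line.split("\t")
                if kind == "stack":
                    stack[(k1, k2)] = float(value)
                elif kind == "hairpin":
                    hairpin[int(k1)] = float(value)
                elif kind == "dangle":
                    dangle[(k1, k2, k3)] = float(value)
                elif kind == "const":
                    const[k1] = float(value)
        return cls(
            stack_table=stack,
            hairpin_penalty=hairpin,
            dangle_table=dangle,
            duplex_init=const["duplex_init"],
            min_hairpin=int(const.get("min_hairpin", 3)),
            loop_base=const.get("loop_base", 3.0),
            loop_per_nt=const.get("loop_per_nt", 0.5),
            max_loop=int(const.get("max_loop", 3)),
        )

    @classmethod
    def default(cls) -> "EnergyModel":
        return _default_model()

    # -- array views for the numba kernels ---------------------------------
    def _pair_matrix(self) -> np.ndarray:
        m = -np.ones((4, 4), dtype=np.int64)
        for p, idx in _PAIR_INDEX.items():
            m[_NT_INDEX[p[0]], _NT_INDEX[p[1]]] = idx
        return m

    def _stack_matrix(self) -> np.ndarray:
        m = np.zeros((6, 6))
        for (p1, p2), v in self.stack_table.items():
            m[_PAIR_INDEX[p1], _PAIR_INDEX[p2]] = v
        return m

    def _hairpin_array(self) -> np.ndarray:
        a = np.full(_HP_MAX + 1, INF)
        for l, v in self.hairpin_penalty.items():
            if l <= _HP_MAX:
                a[l] = v
        return a

    def hairpin(self, loop_len: int) -> float:
        return self.hairpin_penalty[min(loop_len, _HP_MAX)]


@lru_cache(maxsize=1)
def _default_model() -> EnergyModel:
    with resources.as_file(
        resources.files("seq2abundance.data").joinpath("energy_params.tsv")
    ) as p:
        return EnergyModel.from_tsv(p)


@dataclass(frozen=True)
class SecondaryStructure:
    sequence: str
    pairs: frozenset[tuple[int, int]]
    dg: float
    dot_bracket: str


@dataclass(frozen=True)
class HybridStructure:
    target: str
    probe: str
    duplex_pairs: tuple[tuple[int, int], ...]
    dg_total: float
    dg_duplex: float
    dg_exterior: float

    @property
    def duplex_length(self) -> int:
        return len(self.duplex_pairs)

    @property
    def is_sentinel(self) -> bool:
        return self.duplex_length == 0


# ---------------------------------------------------------------------------
# Unimolecular folding
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fold_kernel(s, pairmat, stack, hp, min_hairpin):  # pragma: no cover - numba
    n = s.shape[0]
    W = np.zeros((n, n))          # best (possibly empty) structure on [i, j]
    V = np.full((n, n), INF)      # best structure with (i, j) paired
    N = np.full((n, n), INF)      # best NONempty structure on [i, j]
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            # V[i, j]
            pij = pairmat[s[i], s[j]]
            if pij >= 0 and j - i - 1 >= min_hairpin:
                loop = j - i - 1
                best = hp[min(loop, 30)]
                pin = pairmat[s[i + 1], s[j - 1]]
                if pin >= 0 and (j - 1) - (i + 1) - 1 >= min_hairpin:
                    cand = stack[pij, pin] + V[i + 1, j - 1]
                    if cand < best:
                        best = cand
                # nonempty interior that does NOT pair (i+1, j-1) together
                ii, jj = i + 1, j - 1
                if jj > ii:
                    cand = N[ii + 1, jj]
                    if cand < best:
                        best = cand
                    for k in range(ii + 1, jj):  # k < jj: excludes the (ii, jj) pair
                        if V[ii, k] < INF:
                            w = W[k + 1, jj] if k + 1 <= jj else 0.0
                            cand = V[ii, k] + w
                            if cand < best:
                                best = cand
                V[i, j] = best
            # W and N on [i, j]
            bw = W[i + 1, j] if i + 1 <= j else 0.0
            bn = N[i + 1, j] if i + 1 <= j else INF
            for k in range(i + 1, j + 1):
                if V[i, k] < INF:
                    w = W[k + 1, j] if k + 1 <= j else 0.0
                    cand = V[i, k] + w
                    if cand < bw:
                        bw = cand
                    if cand < bn:
                        bn = cand
            if bw > 0.0:
                bw = 0.0  # the empty structure is always admissible
            W[i, j] = bw
            N[i, j] = bn
    return W, V, N


_EPS = 1e-9


def fold_mfe(seq: str, model: EnergyModel | None = None) -> SecondaryStructure:
    """Minimum-free-energy nested structure by dynamic programming.

    The empty structure (dg = 0) is always admissible, so ``dg <= 0``.
    """
    if model is None:
        model = EnergyModel.default()
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = _encode(seq)
    n = len(s)
    if n < model.min_hairpin + 2:
        return SecondaryStructure(seq, frozenset(), 0.0, "." * n)
    pairmat = model._pair_matrix()
    stack = model._stack_matrix()
    hp = model._hairpin_array()
    W, V, N = _fold_kernel(s, pairmat, stack, hp, model.min_hairpin)
    dg = float(W[0, n - 1])
    pairs: set[tuple[int, int]] = set()
    if dg < -_EPS:
        _traceback_W(0, n - 1, s, pairmat, stack, hp, model.min_hairpin, W, V, N, pairs)
    else:
        dg = 0.0
    db = _dot_bracket(n, pairs)
    return SecondaryStructure(seq, frozenset(pairs), dg, db)


def _w(W, i, j):
    return W[i, j] if i <= j else 0.0


def _traceback_W(i, j, s, pairmat, stack, hp, mh, W, V, N, pairs):
    while i <= j:
        if W[i, j] > -_EPS:
            return  # empty realization is optimal
        if i + 1 <= j and abs(W[i, j] - W[i + 1, j]) < _EPS:
            i += 1
            continue
        for k in range(i + 1, j + 1):
            if V[i, k] < INF and abs(W[i, j] - (V[i, k] + _w(W, k + 1, j))) < _EPS:
                pairs.add((i, k))
                _traceback_V(i, k, s, pairmat, stack, hp, mh, W, V, N, pairs)
                i = k + 1
                break
        else:
            raise AssertionError("traceback failed in W")
        continue


def _traceback_V(i, j, s, pairmat, stack, hp, mh, W, V, N, pairs):
    pij = pairmat[s[i], s[j]]
    loop = j - i - 1
    if abs(V[i, j] - hp[min(loop, 30)]) < _EPS:
        return  # hairpin: empty interior
    pin = pairmat[s[i + 1], s[j - 1]]
    if pin >= 0 and (j - 1) - (i + 1) - 1 >= mh:
        if abs(V[i, j] - (stack[pij, pin] + V[i + 1, j - 1])) < _EPS:
            pairs.add((i + 1, j - 1))
            _traceback_V(i + 1, j - 1, s, pairmat, stack, hp, mh, W, V, N, pairs)
            return
    ii, jj = i + 1, j - 1
    if jj > ii:
        if abs(V[i, j] - N[ii + 1, jj]) < _EPS:
            _traceback_N(ii + 1, jj, s, pairmat, stack, hp, mh, W, V, N, pairs)
            return
        for k in range(ii + 1, jj):
            if V[ii, k] < INF and abs(V[i, j] - (V[ii, k] + _w(W, k + 1, jj))) < _EPS:
                pairs.add((ii, k))
                _traceback_V(ii, k, s, pairmat, stack, hp, mh, W, V, N, pairs)
                _traceback_W(k + 1, jj, s, pairmat, stack, hp, mh, W, V, N, pairs)
                return
    raise AssertionError("traceback failed in V")


def _traceback_N(i, j, s, pairmat, stack, hp, mh, W, V, N, pairs):
    while i <= j:
        if i + 1 <= j and N[i, j] < INF and abs(N[i, j] - N[i + 1, j]) < _EPS:
            i += 1
            continue
        for k in range(i + 1, j + 1):
            if V[i, k] < INF and abs(N[i, j] - (V[i, k] + _w(W, k + 1, j))) < _EPS:
                pairs.add((i, k))
                _traceback_V(i, k, s, pairmat, stack, hp, mh, W, V, N, pairs)
                _traceback_W(k + 1, j, s, pairmat, stack, hp, mh, W, V, N, pairs)
                return
        raise AssertionError("traceback failed in N")


def _dot_bracket(n: int, pairs) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return "".join(db)


def score_structure(seq: str, pairs, model: EnergyModel | None = None) -> float:
    """Energy of an explicit nested pair set under the model (for export/debug)."""
    if model is None:
        model = EnergyModel.default()
    s = seq.upper().replace("U", "T")
    pset = set(map(tuple, pairs))
    e = 0.0
    for i, j in pset:
        if (i + 1, j - 1) in pset:
            e += model.stack_table[(s[i] + s[j], s[i + 1] + s[j - 1])]
        if not any(i < a and b < j for a, b in pset):  # hairpin-closing pair
            e += model.hairpin(j - i - 1)
    return e


# ---------------------------------------------------------------------------
# Bimolecular duplex
# ---------------------------------------------------------------------------

@njit(cache=True)
def _duplex_kernel(t, p, pairmat, stack, dangle5, dangle3, loop_base, loop_per_nt,
                   max_loop):  # pragma: no cover - numba
    nt, npr = t.shape[0], p.shape[0]
    D = np.full((nt, npr), INF)   # best chain ending at pair (i, j), incl. left dangles
    for i in range(nt):
        for j in range(npr):
            pij = pairmat[t[i], p[j]]
            if pij < 0:
                continue
            # open a new duplex here: left-end dangles
            e = 0.0
            if i > 0:
                e += dangle5[pij, t[i - 1]]          # target 5' flank
            if j < npr - 1:
                e += dangle3[_revpair(pij), p[j + 1]]  # probe 3' flank
            best = e
            # extend from a previous pair (i' < i, j' > j)
            for di in range(1, max_loop + 2):
                ii = i - di
                if ii < 0:
                    break
                for dj in range(1, max_loop + 2):
                    jj = j + dj
                    if jj >= npr:
                        break
                    if D[ii, jj] >= INF:
                        continue
                    pprev = pairmat[t[ii], p[jj]]
                    if di == 1 and dj == 1:
                        step = stack[pprev, pij]
                    else:
                        step = loop_base + loop_per_nt * (di - 1 + dj - 1)
                    cand = D[ii, jj] + step
                    if cand < best:
                        best = cand
            D[i, j] = best
    return D


@njit(cache=True)
def _revpair(idx):  # pragma: no cover - numba
    # AT<->TA, GC<->CG, GT<->TG
    if idx == 0:
        return 1
    if idx == 1:
        return 0
    if idx == 2:
        return 3
    if idx == 3:
        return 2
    if idx == 4:
        return 5
    return 4


def _dangle_arrays(model: EnergyModel):
    d5 = np.zeros((6, 4))
    d3 = np.zeros((6, 4))
    for (pair, base, side), v in model.dangle_table.items():
        pi, bi = _PAIR_INDEX[pair], _NT_INDEX[base]
        if side == "5p":
            d5[pi, bi] = v
        else:
            d3[pi, bi] = v
    return d5, d3


def cofold_duplex(target: str, probe: str,
                  model: EnergyModel | None = None) -> HybridStructure:
    """Minimum-energy intermolecular duplex (no intramolecular pairs).

    Returns a sentinel (``duplex_length == 0``, energies NaN) when no duplex
    achieves ``dg_total < 0``.
    """
    if model is None:
        model = EnergyModel.default()
    if not target or not probe:
        raise ValueError("target and probe must be nonempty")
    t, p = _encode(target), _encode(probe)
    pairmat = model._pair_matrix()
    stack = model._stack_matrix()
    d5, d3 = _dangle_arrays(model)
    D = _duplex_kernel(t, p, pairmat, stack, d5, d3,
                       model.loop_base, model.loop_per_nt, model.max_loop)

    nt, npr = len(t), len(p)
    best, bi, bj = INF, -1, -1
    for i in range(nt):
        for j in range(npr):
            if D[i, j] >= INF:
                continue
            pij = pairmat[t[i], p[j]]
            e = D[i, j]
            if i < nt - 1:
                e += d3[pij, t[i + 1]]               # target 3' flank
            if j > 0:
                e += d5[int(_revpair_py(pij)), p[j - 1]]  # probe 5' flank
            if e < best:
                best, bi, bj = e, i, j
    if bi < 0:
        return HybridStructure(target, probe, (), math.nan, math.nan, math.nan)

    # traceback the chain from (bi, bj)
    chain = [(bi, bj)]
    i, j = bi, bj
    while True:
        pij = pairmat[t[i], p[j]]
        e_open = 0.0
        if i > 0:
            e_open += d5[pij, t[i - 1]]
        if j < npr - 1:
            e_open += d3[int(_revpair_py(pij)), p[j + 1]]
        if abs(D[i, j] - e_open) < _EPS:
            break
        found = False
        for di in range(1, model.max_loop + 2):
            ii = i - di
            if ii < 0:
                break
            for dj in range(1, model.max_loop + 2):
                jj = j + dj
                if jj >= npr:
                    break
                if D[ii, jj] >= INF:
                    continue
                pprev = pairmat[t[ii], p[jj]]
                if di == 1 and dj == 1:
                    step = stack[pprev, pij]
                else:
                    step = model.loop_base + model.loop_per_nt * (di - 1 + dj - 1)
                if abs(D[i, j] - (D[ii, jj] + step)) < _EPS:
                    chain.append((ii, jj))
                    i, j = ii, jj
                    found = True
                    break
            if found:
                break
        if not found:
            raise AssertionError("duplex traceback failed")
    chain.reverse()  # ascending target index, descending probe index

    h = HybridStructure(target, probe, tuple(chain), 0.0, 0.0, 0.0)
    dg_ext = exterior_loop_energy(h, model)
    dg_duplex = best - dg_ext
    dg_total = dg_duplex + dg_ext + model.duplex_init
    if dg_total >= 0:
        return HybridStructure(target, probe, (), math.nan, math.nan, math.nan)
    return HybridStructure(target, probe, tuple(chain), dg_total, dg_duplex, dg_ext)


def _revpair_py(idx: int) -> int:
    return {0: 1, 1: 0, 2: 3, 3: 2, 4: 5, 5: 4}[idx]


def exterior_loop_energy(h: HybridStructure, model: EnergyModel | None = None) -> float:
    """Dangling-end sum of unpaired bases flanking the duplex (the exterior loop).

    Returns NaN for the sentinel (no-duplex) hybrid; 0 when the duplex spans
    both molecules completely.
    """
    if model is None:
        model = EnergyModel.default()
    if h.duplex_length == 0:
        return math.nan
    t = h.target.upper().replace("U", "T")
    p = h.probe.upper().replace("U", "T")
    (i0, j0), (i1, j1) = h.duplex_pairs[0], h.duplex_pairs[-1]
    e = 0.0
    pair_left = t[i0] + p[j0]
    pair_right = t[i1] + p[j1]
    # probe-side dangles key the pair with the dangling strand's base first
    if i0 > 0:
        e += model.dangle_table[(pair_left, t[i0 - 1], "5p")]
    if j0 < len(p) - 1:
        e += model.dangle_table[(pair_left[::-1], p[j0 + 1], "3p")]
    if i1 < len(t) - 1:
        e += model.dangle_table[(pair_right, t[i1 + 1], "3p")]
    if j1 > 0:
        e += model.dangle_table[(pair_right[::-1], p[j1 - 1], "5p")]
    return e


def write_structures(
    structures: dict[str, SecondaryStructure], path: str | Path
) -> None:
    """Export structures as FASTA-style records with a dot-bracket line."""
    with open(path, "w") as fh:
        for name, s in structures.items():
            fh.write(f">{name} dg={s.dg:.2f}\n{s.sequence}\n{s.dot_bracket}\n")


def structure_statistics(
    s: SecondaryStructure, subregion: tuple[int, int]
) -> tuple[int, float, float]:
    """(unpaired_count over the full structure, accessibility in subregion, dg).

    ``subregion`` is a 0-based half-open interval.
    """
    a, b = subregion
    n = len(s.sequence)
    if not (0 <= a < b <= n):
        raise ValueError(f"empty or out-of-bounds subregion {subregion} for length {n}")
    paired = {i for ij in s.pairs for i in ij}
    unpaired_count = n - len(paired)
    in_sub = range(a, b)
    acc = sum(1 for i in in_sub if i not in paired) / (b - a)
    return unpaired_count, acc, s.dg
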