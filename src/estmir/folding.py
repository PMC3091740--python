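"""Minimum-free-energy RNA secondary structure prediction and hairpin indices.

A self-contained nearest-neighbor energy model (stacking energies over
adjacent base pairs, length-dependent hairpin/bulge/internal-loop penalties,
affine multiloop cost) minimized by a Zuker-style dynamic program with
deterministic traceback.  The model is deliberately compact — Watson-Crick
plus GU wobble pairs, no dangles, no coaxial stacking, no temperature
dependence — so that the minimum can be verified against exhaustive
enumeration on short sequences.  Structures are nested (no pseudoknots) and
written in dot-bracket notation.

The derived hairpin-quality indices follow the conventions used in plant
pre-miRNA screening::

    AMFE = |dG| * 100 / length          (adjusted MFE per 100 nt)
    MFEI = AMFE / GC%                   (minimal folding free energy index)

Any backend producing a :class:`FoldResult` (same-length dot-bracket plus its
energy) can substitute the bundled engine; downstream analyses only consume
that contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

try:  # optional JIT acceleration; the pure-Python path is identical
    from numba import njit as _njit

    def _jit(fn):
        return _njit(fn)
except Exception:  # pragma: no cover - numba is normally available
    def _jit(fn):
        return fn

INF = 1e9
_RT_COEFF = 1.75 * 0.616  # Jacobson-Stockmayer extrapolation slope, kcal/mol

# base codes: A=0 C=1 G=2 U=3, N=4 (unpairable)
_BASE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
# pair-type index for the stack table
_PAIR_INDEX = {(0, 3): 0, (3, 0): 1, (1, 2): 2, (2, 1): 3, (2, 3): 4, (3, 2): 5}
_PAIR_NAMES = ("AU", "UA", "CG", "GC", "GU", "UG")

# stack energies, kcal/mol: row = outer pair (i,j), col = inner pair (i+1,j-1)
_DEFAULT_STACK = np.array([
    #  AU     UA     CG     GC     GU     UG
    [-0.9, -1.1, -2.1, -2.2, -0.6, -1.4],   # AU
    [-1.3, -0.9, -2.1, -2.4, -1.0, -1.3],   # UA
    [-2.1, -2.1, -2.4, -3.3, -1.4, -2.1],   # CG
    [-2.4, -2.2, -3.3, -3.4, -1.5, -2.5],   # GC
    [-1.3, -1.4, -2.1, -2.5, -0.5, -0.6],   # GU
    [-1.0, -0.6, -1.4, -1.5, -0.3, -0.5],   # UG
])

_HAIRPIN_INIT = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_INIT = {2: 1.7, 3: 2.0, 4: 2.1, 5: 2.3, 6: 2.5}

MAXLOOP = 30  # largest bulge/internal loop the DP enumerates (combined size)


@dataclass
class EnergyModel:
    """Tunable parameters of the nearest-neighbor model (kcal/mol)."""

    stack: np.ndarray = field(default_factory=lambda: _DEFAULT_STACK.copy())
    min_hairpin: int = 3
    allow_gu: bool = True
    multiloop_init: float = 3.4   # closing a multiloop
    multiloop_branch: float = 0.4  # per branch, closing pair included
    multiloop_unpaired: float = 0.1

    def hairpin(self, n: int) -> float:
        if n < self.min_hairpin:
            return INF
        if n in _HAIRPIN_INIT:
            return _HAIRPIN_INIT[n]
        return _HAIRPIN_INIT[9] + _RT_COEFF * math.log(n / 9)

    def bulge(self, n: int) -> float:
        if n in _BULGE_INIT:
            return _BULGE_INIT[n]
        return _BULGE_INIT[6] + _RT_COEFF * math.log(n / 6)

    def internal(self, n1: int, n2: int) -> float:
        n = n1 + n2
        base = _INTERNAL_INIT.get(n)
        if base is None:
            base = _INTERNAL_INIT[6] + _RT_COEFF * math.log(n / 6)
        return base + min(0.5 * abs(n1 - n2), 3.0)

    def pair_index(self, a: int, b: int) -> int:
        idx = _PAIR_INDEX.get((a, b), -1)
        if idx >= 4 and not self.allow_gu:
            return -1
        return idx

    def stack_energy(self, outer: str, inner: str) -> float:
        return float(self.stack[_PAIR_NAMES.index(outer), _PAIR_NAMES.index(inner)])


DEFAULT_MODEL = EnergyModel()
ENGINE_TAG = "estmir-nn-dp/0.1"


@dataclass(frozen=True)
class FoldResult:
    structure: str
    dG: float
    engine: str = ENGINE_TAG

    @property
    def pairs(self) -> list[tuple[int, int]]:
        return pairs_from_dotbracket(self.structure)


class FoldingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dot-bracket helpers

def pairs_from_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise FoldingError(f"unbalanced structure at position {i}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise FoldingError(f"invalid structure character {c!r}")
    if stack:
        raise FoldingError("unbalanced structure: unclosed '('")
    pairs.sort()
    return pairs


def dotbracket_from_pairs(n: int, pairs: list[tuple[int, int]]) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def _encode_rna(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_BASE[c] for c in seq.upper()), dtype=np.int8,
                           count=len(seq))
    except KeyError as exc:
        raise FoldingError(f"non-RNA symbol {exc.args[0]!r} in sequence") from None


# ---------------------------------------------------------------------------
# energy of a given structure (loop decomposition)

def energy(seq: str, structure: str, model: EnergyModel | None = None) -> float:
    """Free energy of ``structure`` on ``seq`` under the model.

    Validates balance, pair chemistry and the minimum hairpin size; raises
    :class:`FoldingError` for clashing input.
    """
    model = model or DEFAULT_MODEL
    enc = _encode_rna(seq)
    if len(structure) != len(seq):
        raise FoldingError("structure and sequence lengths differ")
    pairs = pairs_from_dotbracket(structure)
    partner = {i: j for i, j in pairs} | {j: i for i, j in pairs}
    total = 0.0
    for i, j in pairs:
        pt = model.pair_index(int(enc[i]), int(enc[j]))
        if pt < 0:
            raise FoldingError(
                f"disallowed pair {seq[i]}-{seq[j]} at ({i}, {j})")
        # walk the loop closed by (i, j)
        children: list[tuple[int, int]] = []
        unpaired = 0
        pos = i + 1
        while pos < j:
            if pos in partner:
                q = partner[pos]
                if q < pos or q > j:
                    raise FoldingError("pseudoknotted or clashing structure")
                children.append((pos, q))
                pos = q + 1
            else:
                unpaired += 1
                pos += 1
        if not children:
            if unpaired < model.min_hairpin:
                raise FoldingError(
                    f"hairpin loop shorter than {model.min_hairpin} at ({i}, {j})")
            total += model.hairpin(unpaired)
        elif len(children) == 1:
            k, l = children[0]
            n1, n2 = k - i - 1, j - l - 1
            if n1 == 0 and n2 == 0:
                pt_in = model.pair_index(int(enc[k]), int(enc[l]))
                total += float(model.stack[pt, pt_in])
            elif n1 == 0 or n2 == 0:
                total += model.bulge(max(n1, n2))
            else:
                total += model.internal(n1, n2)
        else:
            total += (model.multiloop_init
                      + model.multiloop_branch * (len(children) + 1)
                      + model.multiloop_unpaired * unpaired)
    return total


# ---------------------------------------------------------------------------
# MFE dynamic program

def _loop_penalty_arrays(model: EnergyModel, n: int):
    hp = np.full(n + 1, INF)
    bu = np.full(MAXLOOP + 1, INF)
    for k in range(model.min_hairpin, n + 1):
        hp[k] = model.hairpin(k)
    for k in range(1, MAXLOOP + 1):
        bu[k] = model.bulge(k)
    # internal loops indexed by (n1, n2), n1+n2 <= MAXLOOP
    internal = np.full((MAXLOOP + 1, MAXLOOP + 1), INF)
    for n1 in range(1, MAXLOOP):
        for n2 in range(1, MAXLOOP + 1 - n1):
            internal[n1, n2] = model.internal(n1, n2)
    return hp, bu, internal


@_jit
def _fill(enc, ptab, stack, hp, bu, internal, ml_a, ml_b, ml_c, min_hp):
    n = enc.shape[0]
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    for d in range(min_hp + 1, n):
        for i in range(0, n - d):
            j = i + d
            pt = ptab[enc[i], enc[j]]
            if pt >= 0:
                best = hp[j - i - 1]
                # stacking / bulge / internal via an interior pair (k, l)
                kmax = min(i + MAXLOOP + 1, j - 1)
                for k in range(i + 1, kmax + 1):
                    n1 = k - i - 1
                    lmin = k + min_hp + 1
                    if lmin > j - 1:
                        break
                    for l in range(j - 1, lmin - 1, -1):
                        n2 = j - l - 1
                        if n1 + n2 > MAXLOOP:
                            break
                        pt2 = ptab[enc[k], enc[l]]
                        if pt2 < 0 or V[k, l] >= INF:
                            continue
                        if n1 == 0 and n2 == 0:
                            e = stack[pt, pt2] + V[k, l]
                        elif n1 == 0 or n2 == 0:
                            e = bu[max(n1, n2)] + V[k, l]
                        else:
                            e = internal[n1, n2] + V[k, l]
                        if e < best:
                            best = e
                # multiloop closure: >= 2 branches inside
                for k in range(i + 1, j - 1):
                    if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF:
                        e = ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: part of a multiloop, >= 1 branch
            best_m = INF
            if pt >= 0 and V[i, j] < INF:
                best_m = V[i, j] + ml_b
            if WM[i + 1, j] + ml_c < best_m:
                best_m = WM[i + 1, j] + ml_c
            if WM[i, j - 1] + ml_c < best_m:
                best_m = WM[i, j - 1] + ml_c
            for k in range(i + 1, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF:
                    e = WM[i, k] + WM[k + 1, j]
                    if e < best_m:
                        best_m = e
            if best_m < WM[i, j]:
                WM[i, j] = best_m
    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]  # j unpaired
        for i in range(0, j):
            if V[i, j] < INF:
                e = W[i] + V[i, j]
                if e < best:
                    best = e
        W[j + 1] = best
    return V, WM, W


def _make_ptab(model: EnergyModel) -> np.ndarray:
    ptab = np.full((5, 5), -1, dtype=np.int8)
    for (a, b), idx in _PAIR_INDEX.items():
        if idx >= 4 and not model.allow_gu:
            continue
        ptab[a, b] = idx
    return ptab


_EPS = 1e-9


def _traceback(enc, V, WM, W, ptab, stack, hp, bu, internal, model):
    n = enc.shape[0]
    ml_a, ml_b, ml_c = (model.multiloop_init, model.multiloop_branch,
                        model.multiloop_unpaired)
    pairs: list[tuple[int, int]] = []
    stack_jobs: list[tuple[str, int, int]] = []

    # external segment: prefer pairing over leaving j unpaired, smaller i first
    j = n - 1
    while j >= 0:
        target = W[j + 1]
        if abs(W[j] - target) < _EPS and not any(
                V[i, j] < INF and abs((W[i] if i else 0.0) + V[i, j] - target) < _EPS
                for i in range(0, j + 1)):
            j -= 1
            continue
        advanced = False
        for i in range(0, j + 1):
            if V[i, j] < INF and abs((W[i] if i else 0.0) + V[i, j] - target) < _EPS:
                stack_jobs.append(("V", i, j))
                j = i - 1
                advanced = True
                break
        if not advanced:
            j -= 1

    while stack_jobs:
        kind, i, j = stack_jobs.pop()
        if kind == "V":
            pairs.append((i, j))
            target = V[i, j]
            pt = ptab[enc[i], enc[j]]
            done = False
            kmax = min(i + MAXLOOP + 1, j - 1)
            for k in range(i + 1, kmax + 1):
                if done:
                    break
                n1 = k - i - 1
                for l in range(j - 1, k + model.min_hairpin, -1):
                    n2 = j - l - 1
                    if n1 + n2 > MAXLOOP:
                        break
                    pt2 = ptab[enc[k], enc[l]]
                    if pt2 < 0 or V[k, l] >= INF:
                        continue
                    if n1 == 0 and n2 == 0:
                        e = stack[pt, pt2] + V[k, l]
                    elif n1 == 0 or n2 == 0:
                        e = bu[max(n1, n2)] + V[k, l]
                    else:
                        e = internal[n1, n2] + V[k, l]
                    if abs(e - target) < _EPS:
                        stack_jobs.append(("V", k, l))
                        done = True
                        break
            if done:
                continue
            for k in range(i + 1, j - 1):
                if WM[i + 1, k] < INF and WM[k + 1, j - 1] < INF and abs(
                        ml_a + ml_b + WM[i + 1, k] + WM[k + 1, j - 1] - target) < _EPS:
                    stack_jobs.append(("M", i + 1, k))
                    stack_jobs.append(("M", k + 1, j - 1))
                    done = True
                    break
            if done:
                continue
            if abs(hp[j - i - 1] - target) >= _EPS:  # pragma: no cover
                raise FoldingError("traceback failed in V")
        else:  # WM segment
            target = WM[i, j]
            pt = ptab[enc[i], enc[j]]
            if pt >= 0 and V[i, j] < INF and abs(V[i, j] + ml_b - target) < _EPS:
                stack_jobs.append(("V", i, j))
                continue
            if i + 1 <= j and abs(WM[i + 1, j] + ml_c - target) < _EPS:
                stack_jobs.append(("M", i + 1, j))
                continue
            if i <= j - 1 and abs(WM[i, j - 1] + ml_c - target) < _EPS:
                stack_jobs.append(("M", i, j - 1))
                continue
            done = False
            for k in range(i + 1, j):
                if WM[i, k] < INF and WM[k + 1, j] < INF and abs(
                        WM[i, k] + WM[k + 1, j] - target) < _EPS:
                    stack_jobs.append(("M", i, k))
                    stack_jobs.append(("M", k + 1, j))
                    done = True
                    break
            if not done:  # pragma: no cover
                raise FoldingError("traceback failed in WM")
    return sorted(pairs)


def fold(seq: str, model: EnergyModel | None = None) -> FoldResult:
    """Minimum-free-energy nested structure of an RNA sequence.

    Deterministic: ties are resolved by preferring a paired/stacked
    interpretation over bifurcation, smaller 5' index first.  ``N`` is
    accepted as an unpairable placeholder; other non-RNA symbols raise.
    """
    model = model or DEFAULT_MODEL
    if len(seq) < 10:
        raise FoldingError("too short to fold")
    if len(seq) > 1000:
        raise FoldingError("sequence longer than 1000 nt")
    enc = _encode_rna(seq)
    ptab = _make_ptab(model)
    hp, bu, internal = _loop_penalty_arrays(model, len(seq))
    V, WM, W = _fill(enc, ptab, model.stack, hp, bu, internal,
                     model.multiloop_init, model.multiloop_branch,
                     model.multiloop_unpaired, model.min_hairpin)
    pairs = _traceback(enc, V, WM, W, ptab, model.stack, hp, bu, internal, model)
    structure = dotbracket_from_pairs(len(seq), pairs)
    dg = energy(seq, structure, model)
    return FoldResult(structure=structure, dG=dg)


# ---------------------------------------------------------------------------
# derived indices

def gc_percent(seq: str) -> float:
    """GC content in percent (N counts toward length, not GC)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def amfe(dG: float, length: int) -> float:
    """Adjusted MFE: |dG| normalized to 100 nt."""
    if length <= 0:
        raise ValueError("length must be positive")
    return abs(dG) * 100.0 / length


def mfei(dG: float, length: int, gc_pct: float) -> float:
    """Minimal folding free energy index, positive convention.

    Returns NaN (flagged sentinel) when GC% is zero, where the index is
    undefined.
    """
    if gc_pct == 0:
        return float("nan")
    return amfe(dG, length) / gc_pct
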