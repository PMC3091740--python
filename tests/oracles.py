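"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results with naive quadratic/enumerative code
paths so the production implementations (vectorized scanner, folding DP) are
checked against something that shares no code with them.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_CAN_PAIR = {"AU", "UA", "CG", "GC", "GU", "UG"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_mismatches(mature_dna: str, window: str) -> int:
    n = 0
    for a, b in zip(mature_dna, window):
        if a != b or a == "N" or b == "N":
            n += 1
    return n


def naive_scan(matures: dict[str, str], ests: dict[str, str], max_mm: int):
    """Quadratic re-implementation of the mismatch-limited scanner.

    Returns a set of (mirna_id, est_id, start, end, orientation, mismatches,
    mismatch_positions) tuples with forward-strand coordinates.
    """
    out = set()
    for mid, mat_rna in matures.items():
        mat = mat_rna.replace("U", "T")
        L = len(mat)
        for eid, est in ests.items():
            for off in range(len(est) - L + 1):
                win = est[off:off + L]
                mm = [i + 1 for i in range(L)
                      if mat[i] != win[i] or mat[i] == "N" or win[i] == "N"]
                if len(mm) <= max_mm:
                    out.add((mid, eid, off, off + L, "sense",
                             len(mm), tuple(mm)))
            rc = naive_revcomp(est)
            for off in range(len(rc) - L + 1):
                win = rc[off:off + L]
                mm = [i + 1 for i in range(L)
                      if mat[i] != win[i] or mat[i] == "N" or win[i] == "N"]
                if len(mm) <= max_mm:
                    out.add((mid, eid, len(est) - off - L, len(est) - off,
                             "antisense", len(mm), tuple(mm)))
    return out


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """All nested structures (as tuples of pairs) over the wobble-extended
    alphabet with the given minimum hairpin loop."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):
        if j - i <= 0:
            return [()]
        out = list(rec(i + 1, j))
        for k in range(i + min_hairpin + 1, j):
            if seq[i] + seq[k] in _CAN_PAIR:
                for s1 in rec(i + 1, k):
                    for s2 in rec(k + 1, j):
                        out.append(((i, k),) + s1 + s2)
        return out

    return rec(0, len(seq))


def brute_force_mfe(seq: str, energy_fn, min_hairpin: int = 3) -> float:
    """Exhaustive-enumeration minimum of ``energy_fn(seq, structure)``."""
    best = 0.0
    n = len(seq)
    for pairs in enumerate_structures(seq, min_hairpin):
        chars = ["."] * n
        for i, j in pairs:
            chars[i], chars[j] = "(", ")"
        e = energy_fn(seq, "".join(chars))
        if e < best:
            best = e
    return best
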