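"""Per-species representation statistics for matched mature miRNAs.

For a species with ``m`` of the ``M`` reference matures (redundant set) and
``k`` of the ``K`` matched matures, the statistic is the exact binomial point
probability of observing exactly ``k`` successes in ``K`` draws at rate
``q = m/M``::

    p = C(K, k) * q**k * (1-q)**(K-k)

with direction "over" when k/K > q and "under" when k/K < q.  The point mass
is what reproduces the published species tables for this kind of survey
(including the closed-form (1-q)**K rows where k=0); it is *not* a calibrated
tail probability, so a ``tail`` mode returning the one-sided tail
(P(X>=k) when over, P(X<=k) when under) is provided for calibration studies.
Evaluation is in log space so the statistic stays finite and positive for
large K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import binom

POINT_MASS = "point_mass"
TAIL = "tail"

DEFAULT_THRESHOLDS = (0.05, 0.01, 0.005, 0.001)


@dataclass
class EnrichmentRow:
    species: str
    m: int
    M: int
    k: int
    K: int
    pct_initial: float
    pct_matched: float
    p_value: float
    direction: str  # over | under | none


@dataclass
class ThresholdSweep:
    thresholds: tuple[float, ...]
    over: dict[float, list[str]] = field(default_factory=dict)
    under: dict[float, list[str]] = field(default_factory=dict)


def percent(x: float, total: float) -> float:
    """100*x/total rounded half-away-from-zero to one decimal."""
    if total == 0:
        raise ValueError("total must be > 0")
    v = 100.0 * x / total
    return math.floor(abs(v) * 10 + 0.5) / 10 * (1 if v >= 0 else -1)


def representation_stat(m: int, M: int, k: int, K: int,
                        mode: str = POINT_MASS) -> tuple[float, str]:
    """(p_value, direction) for one species; see module docstring."""
    if M <= 0 or K <= 0:
        raise ValueError("M and K must be positive")
    if not (0 <= m <= M and 0 <= k <= K):
        raise ValueError("need 0 <= m <= M and 0 <= k <= K")
    q = m / M
    if q == 0.0 and k > 0:
        raise ValueError("species absent from initial set cannot have matches")
    if k / K > q:
        direction = "over"
    elif k / K < q:
        direction = "under"
    else:
        direction = "none"
    if mode == POINT_MASS:
        p = math.exp(binom.logpmf(k, K, q))
        if p == 0.0:  # underflow at extreme K; keep the contract p in (0, 1]
            p = 5e-324
    elif mode == TAIL:
        if direction == "over":
            p = float(binom.sf(k - 1, K, q))
        elif direction == "under":
            p = float(binom.cdf(k, K, q))
        else:
            p = 1.0
        if p == 0.0:
            p = 5e-324
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return min(p, 1.0), direction


def build_table(initial_counts: dict[str, int], matched_counts: dict[str, int],
                mode: str = POINT_MASS) -> list[EnrichmentRow]:
    """One row per species in the initial set, in initial-set order.

    Totals M and K are the sums over the redundant sets (duplicates
    re-included), matching how the matched counts are produced by
    :func:`estmir.scan.matched_redundant_set`.
    """
    M = sum(initial_counts.values())
    K = sum(matched_counts.values())
    if M <= 0:
        raise ValueError("empty initial set")
    rows = []
    for sp, m in initial_counts.items():
        k = matched_counts.get(sp, 0)
        if k > m:
            import warnings
            warnings.warn(f"species {sp}: matched count {k} exceeds initial {m}")
        p, direction = representation_stat(m, M, k, K, mode=mode)
        rows.append(EnrichmentRow(
            species=sp, m=m, M=M, k=k, K=K,
            pct_initial=percent(m, M),
            pct_matched=percent(k, K) if K else 0.0,
            p_value=p, direction=direction,
        ))
    return rows


def threshold_sweep(rows: list[EnrichmentRow],
                    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS) -> ThresholdSweep:
    """Species called over/under at each p-value stringency."""
    for t in thresholds:
        if not (0 < t <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
    sweep = ThresholdSweep(thresholds=tuple(thresholds))
    for t in thresholds:
        sweep.over[t] = [r.species for r in rows
                         if r.p_value <= t and r.direction == "over"]
        sweep.under[t] = [r.species for r in rows
                          if r.p_value <= t and r.direction == "under"]
    return sweep


def format_p(p: float) -> str:
    """Two-significant-digit rendering, scientific below 1e-3."""
    if p == 0:
        return "0"
    if p >= 1e-3:
        exp = math.floor(math.log10(abs(p)))
        return f"{round(p, -exp + 1):g}"
    return f"{p:.1e}"


def table_to_tsv(rows: list[EnrichmentRow]) -> str:
    lines = ["species\tm\tpct_initial\tk\tpct_matched\tp_value\tdirection"]
    for r in rows:
        lines.append(f"{r.species}\t{r.m}\t{r.pct_initial:.1f}\t{r.k}\t"
                     f"{r.pct_matched:.1f}\t{format_p(r.p_value)}\t{r.direction}")
    if rows:
        lines.append(f"Total\t{rows[0].M}\t\t{rows[0].K}\t\t\t")
    return "\n".join(lines) + "\n"


def sweep_to_tsv(sweep: ThresholdSweep) -> str:
    lines = ["threshold\tover_represented\tunder_represented"]
    for t in sweep.thresholds:
        lines.append(f"{t:g}\t{','.join(sweep.over[t])}\t{','.join(sweep.under[t])}")
    return "\n".join(lines) + "\n"
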