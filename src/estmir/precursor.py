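"""Candidate pre-miRNA extraction and hairpin screening.

A genuine plant pre-miRNA carries the mature sequence on one arm of a
stem-loop and a near-complementary passenger (miRNA*) on the opposite arm.
Around each sense hit the consensus is folded in a generous window, the
mature/star duplex is located from the predicted structure, the precursor is
trimmed to the duplex ends plus a short pri-extension flank (13 nt per side),
refolded, and screened on:

* MFEI strictly greater than a threshold (default 0.85),
* at most ``max_star_mm`` unpaired mature positions in the duplex (NM),
* few and small asymmetric bulges (defaults: <= 2 bulges of <= 3 nt).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import Callable, Optional

from Bio import Align, SeqIO

from estmir import folding
from estmir.scan import Hit, SENSE
from estmir.seqs import dna_to_rna

FoldFn = Callable[[str], folding.FoldResult]


@dataclass
class Bulge:
    arm: str          # "mature" | "star"
    offset: int       # 0-based offset within that arm's span
    size: int


@dataclass
class Rejection:
    source_id: str
    reason: str
    hit: Optional[Hit] = None


@dataclass
class PrecursorCandidate:
    source_id: str
    sequence: str            # RNA
    structure: str           # dot-bracket
    dG: float
    gc_pct: float
    mfei: float
    nm: int                  # mature positions unpaired in the duplex
    ml: int                  # mature length
    pl: int                  # precursor length
    arm: str                 # "5'" | "3'"
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    bulges: list[Bulge] = field(default_factory=list)
    accepted: bool = False
    reject_reasons: list[str] = field(default_factory=list)
    hit: Optional[Hit] = None


class NoDuplexError(ValueError):
    pass


def star_and_nm(structure: str, mature_span: tuple[int, int]):
    """Locate the miRNA* span and duplex imperfections from a structure.

    The duplex side is the side of the mature (5' or 3') holding the majority
    of the partners of mature positions; mature positions paired elsewhere
    (to the other side, or within the mature itself) are not part of the
    mature/star duplex and count toward ``nm`` like unpaired positions.

    Returns ``(star_span, nm, bulges)`` where ``star_span`` is the minimal
    interval covering the duplex partners, ``nm`` the number of mature
    positions without a duplex partner, and ``bulges`` the maximal
    non-duplex runs interior to the duplex on either arm.  Raises
    :class:`NoDuplexError` when no mature position pairs outside the mature.
    """
    ms, me = mature_span
    pairs = folding.pairs_from_dotbracket(structure)
    partner: dict[int, int] = {}
    for i, j in pairs:
        partner[i], partner[j] = j, i
    left = {p: partner[p] for p in range(ms, me)
            if p in partner and partner[p] < ms}
    right = {p: partner[p] for p in range(ms, me)
             if p in partner and partner[p] >= me}
    if not left and not right:
        raise NoDuplexError("no duplex: no mature position pairs outside "
                            "the mature")
    duplex = right if len(right) >= len(left) else left
    star_positions = sorted(duplex.values())
    star_span = (star_positions[0], star_positions[-1] + 1)
    duplex_mature = sorted(duplex)
    nm = (me - ms) - len(duplex)

    # bulges: the *asymmetric* surplus of unpaired bases between consecutive
    # duplex pairs.  Symmetric internal loops (equal gaps on both arms) are
    # mismatches, already counted by nm; only one-sided surplus bulges the
    # helix.
    bulges: list[Bulge] = []
    for p1, p2 in zip(duplex_mature, duplex_mature[1:]):
        gap_m = p2 - p1 - 1
        q1, q2 = duplex[p1], duplex[p2]    # antiparallel: q1 > q2
        gap_s = q1 - q2 - 1
        if gap_m > gap_s:
            bulges.append(Bulge("mature", p1 + 1 - ms, gap_m - gap_s))
        elif gap_s > gap_m:
            bulges.append(Bulge("star", q2 + 1 - star_span[0], gap_s - gap_m))
    return star_span, nm, bulges


def validate(candidate: PrecursorCandidate, mfei_min: float = 0.85,
             max_star_mm: int = 4, max_bulges: int = 2,
             max_bulge_size: int = 3) -> tuple[bool, list[str]]:
    """Hairpin-quality screen; MFEI comparison is strict (> mfei_min)."""
    reasons = []
    if not (candidate.mfei > mfei_min):  # NaN MFEI fails here too
        reasons.append(f"MFEI <= {mfei_min}")
    if candidate.nm > max_star_mm:
        reasons.append(f"star mismatches > {max_star_mm}")
    if len(candidate.bulges) > max_bulges:
        reasons.append("too many bulges")
    if any(b.size > max_bulge_size for b in candidate.bulges):
        reasons.append(f"bulge larger than {max_bulge_size} nt")
    return (not reasons), reasons


def extract_candidate(consensus: str, hit: Hit, source_id: str = "",
                      fold_window: int = 250, flank: int = 13,
                      fold_fn: FoldFn = folding.fold,
                      mfei_min: float = 0.85, max_star_mm: int = 4,
                      max_bulges: int = 2, max_bulge_size: int = 3):
    """Extract, trim, refold and screen a precursor candidate around a sense hit.

    Returns a :class:`PrecursorCandidate` (accepted or not) or a
    :class:`Rejection` when no hairpin containing the mature, or no passenger
    on the opposite arm, can be found.
    """
    if hit.orientation != SENSE:
        raise ValueError("precursor candidacy requires a sense-orientation hit")
    source_id = source_id or hit.est_id
    L = len(consensus)
    ws = max(0, hit.start - fold_window)
    we = min(L, hit.end + fold_window)
    window = dna_to_rna(consensus[ws:we].upper())
    m_lo, m_hi = hit.start - ws, hit.end - ws
    try:
        win_fold = fold_fn(window)
        star, _, _ = star_and_nm(win_fold.structure, (m_lo, m_hi))
    except (NoDuplexError, folding.FoldingError):
        return Rejection(source_id, "no hairpin", hit)
    if not (star[1] <= m_lo or star[0] >= m_hi):
        return Rejection(source_id, "no opposite arm", hit)

    # trim to duplex ends + flank, refold, and re-trim until stable (the
    # refolded precursor can realize a slightly different duplex extent than
    # the wide-window fold did)
    lo = max(0, min(m_lo, star[0]) - flank)
    hi = min(len(window), max(m_hi, star[1]) + flank)
    pre_fold = star2 = nm = bulges = None
    for _ in range(4):
        pre_seq = window[lo:hi]
        pm_lo, pm_hi = m_lo - lo, m_hi - lo
        try:
            pre_fold = fold_fn(pre_seq)
            star2, nm, bulges = star_and_nm(pre_fold.structure, (pm_lo, pm_hi))
        except (NoDuplexError, folding.FoldingError):
            return Rejection(source_id, "no hairpin", hit)
        new_lo = max(0, lo + min(pm_lo, star2[0]) - flank)
        new_hi = min(len(window), lo + max(pm_hi, star2[1]) + flank)
        if (new_lo, new_hi) == (lo, hi):
            break
        lo, hi = new_lo, new_hi
    else:
        pre_seq = window[lo:hi]
        pm_lo, pm_hi = m_lo - lo, m_hi - lo
        try:
            pre_fold = fold_fn(pre_seq)
            star2, nm, bulges = star_and_nm(pre_fold.structure, (pm_lo, pm_hi))
        except (NoDuplexError, folding.FoldingError):
            return Rejection(source_id, "no hairpin", hit)
    if not (star2[1] <= pm_lo or star2[0] >= pm_hi):
        return Rejection(source_id, "no opposite arm", hit)

    gc = folding.gc_percent(pre_seq)
    cand = PrecursorCandidate(
        source_id=source_id,
        sequence=pre_seq,
        structure=pre_fold.structure,
        dG=pre_fold.dG,
        gc_pct=gc,
        mfei=folding.mfei(pre_fold.dG, len(pre_seq), gc),
        nm=nm,
        ml=pm_hi - pm_lo,
        pl=len(pre_seq),
        arm="5'" if pm_lo < star2[0] else "3'",
        mature_span=(pm_lo, pm_hi),
        star_span=star2,
        bulges=bulges,
        hit=hit,
    )
    cand.accepted, cand.reject_reasons = validate(
        cand, mfei_min=mfei_min, max_star_mm=max_star_mm,
        max_bulges=max_bulges, max_bulge_size=max_bulge_size)
    return cand


def _local_aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.match_score = 2
    al.mismatch_score = -3
    al.open_gap_score = -5
    al.extend_gap_score = -2
    return al


def assign_family_by_precursor(candidate: PrecursorCandidate,
                               known_hairpins_fasta: str):
    """Best local alignment of the candidate against a hairpin library.

    Returns ``(hairpin_id, score, pct_identity)`` for the top-scoring library
    entry, or ``None`` for an empty library.  Raw scores only; no e-values.
    """
    records = list(SeqIO.parse(StringIO(known_hairpins_fasta), "fasta")) \
        if known_hairpins_fasta.strip() else []
    if not records:
        return None
    aligner = _local_aligner()
    query = dna_to_rna(str(candidate.sequence).upper())
    best = None
    for rec in records:
        subject = dna_to_rna(str(rec.seq).upper())
        alignments = aligner.align(subject, query)
        try:
            aln = alignments[0]
        except IndexError:  # no positive-scoring local alignment at all
            continue
        score = aln.score
        matches = aligned = 0
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            for t, q in zip(range(ts, te), range(qs, qe)):
                aligned += 1
                if subject[t] == query[q]:
                    matches += 1
        identity = 100.0 * matches / aligned if aligned else 0.0
        entry = (float(score), rec.id, identity)
        if best is None or entry[0] > best[0]:
            best = entry
    if best is None:
        return None
    return best[1], best[0], best[2]


def precursors_to_tsv(cands: list[PrecursorCandidate]) -> str:
    lines = ["source_id\tdG\tgc_pct\tMFEI\tNM\tML\tPL\tarm\taccepted\t"
             "reject_reasons\tstructure"]
    for c in cands:
        lines.append("\t".join([
            c.source_id, f"{c.dG:.1f}", f"{c.gc_pct:.1f}", f"{c.mfei:.2f}",
            str(c.nm), str(c.ml), str(c.pl), c.arm, str(c.accepted).lower(),
            ";".join(c.reject_reasons), c.structure,
        ]))
    return "\n".join(lines) + "\n"
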