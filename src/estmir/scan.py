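"""Exhaustive mismatch-limited scan of mature miRNAs against ESTs.

This replaces a heuristic BLASTn step with a deterministic scanner: every
full-length ungapped window of every EST, on both strands, is compared
positionally against every non-redundant mature sequence and reported when the
mismatch count is within the configured maximum (default 3, reading "fewer
than 4 mismatches" strictly).  Sense hits (the EST carries the mature itself)
feed precursor candidacy; antisense hits (the EST carries the complementary,
target-type site) feed target analysis.

Coordinates are 0-based half-open on the EST forward strand in both
orientations; mismatch positions are 1-based from the mature 5' end.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from estmir.reference import ReferenceSet
from estmir.seqs import encode, revcomp_dna, rna_to_dna

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class ESTRecord:
    id: str
    sequence: str
    cluster_id: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())


@dataclass(frozen=True)
class Hit:
    """A full-length match of a mature sequence on an EST.

    ``mirna_nr_id`` names the non-redundant representative that was scanned.
    ``mismatch_positions`` are 1-based from the mature 5' end in both
    orientations.
    """

    mirna_nr_id: str
    est_id: str
    start: int
    end: int
    orientation: str
    mismatches: int
    mismatch_positions: tuple[int, ...] = field(default_factory=tuple)


def count_mismatches(mature: str, window: str) -> int:
    """Positional mismatch count with U≡T; N on either side is a mismatch."""
    if len(mature) != len(window):
        raise ValueError(
            f"length mismatch: mature {len(mature)} nt vs window {len(window)} nt"
        )
    a, b = encode(mature), encode(window)
    return int(((a != b) | (a == 4) | (b == 4)).sum())


def _window_hits(mat: np.ndarray, est: np.ndarray, max_mm: int):
    """Yield (offset, mismatch_position_array) for all admissible windows."""
    L = mat.size
    if est.size < L:
        return
    win = np.lib.stride_tricks.sliding_window_view(est, L)
    mism = (win != mat) | (win == 4) | (mat == 4)
    counts = mism.sum(axis=1)
    for off in np.nonzero(counts <= max_mm)[0]:
        yield int(off), np.nonzero(mism[off])[0]


def scan(ref: ReferenceSet, ests: list[ESTRecord], max_mm: int = 3) -> list[Hit]:
    """All mismatch-limited full-length hits of the non-redundant matures.

    The antisense scan runs the mature against the reverse complement of the
    EST and maps window coordinates back to the forward strand; mismatch
    positions stay in mature coordinates.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    hits: list[Hit] = []
    mats = [(r.id, encode(rna_to_dna(r.sequence))) for r in ref.nr_representatives]
    for est in ests:
        fwd = encode(est.sequence)
        rev = encode(revcomp_dna(est.sequence))
        L_est = fwd.size
        for mid, mat in mats:
            L = mat.size
            for off, mmpos in _window_hits(mat, fwd, max_mm):
                hits.append(Hit(mid, est.id, off, off + L, SENSE,
                                len(mmpos), tuple(int(p) + 1 for p in mmpos)))
            for off, mmpos in _window_hits(mat, rev, max_mm):
                # window [off, off+L) on the reverse strand maps to
                # [L_est-off-L, L_est-off) on the forward strand
                hits.append(Hit(mid, est.id, L_est - off - L, L_est - off,
                                ANTISENSE, len(mmpos),
                                tuple(int(p) + 1 for p in mmpos)))
    hits.sort(key=lambda h: (h.est_id, h.start, h.orientation, h.mirna_nr_id))
    return hits


def matched_redundant_set(hits: list[Hit], ref: ReferenceSet) -> Counter:
    """Per-species counts of matched records over the *redundant* set.

    A record is matched iff its sequence's representative has at least one
    hit; each record counts once no matter how many ESTs it hits.  Records
    without a parseable species prefix are skipped (they cannot enter the
    species table).
    """
    rep_seq = {r.id: r.sequence for r in ref.nr_representatives}
    matched_seqs = {rep_seq[h.mirna_nr_id] for h in hits}
    counts: Counter = Counter()
    for rec in ref.records:
        if rec.species_code is not None and rec.sequence in matched_seqs:
            counts[rec.species_code] += 1
    return counts


def matched_record_ids(hits: list[Hit], ref: ReferenceSet) -> set[str]:
    """IDs of all redundant records whose sequence has at least one hit."""
    rep_seq = {r.id: r.sequence for r in ref.nr_representatives}
    matched_seqs = {rep_seq[h.mirna_nr_id] for h in hits}
    return {r.id for r in ref.records if r.sequence in matched_seqs}


def multi_hit_report(hits: list[Hit], ref: ReferenceSet) -> list[dict]:
    """ESTs carrying more than one site, split by same- vs multi-family.

    A "site" is a distinct (start, end, orientation) span; several matures of
    one family matching the same span count as one site.  Returns one row per
    EST with multiple sites or multiple families.
    """
    fam_of = {r.id: r.family for r in ref.nr_representatives}
    by_est: dict[str, list[Hit]] = defaultdict(list)
    for h in hits:
        by_est[h.est_id].append(h)
    rows = []
    for est_id in sorted(by_est):
        hs = by_est[est_id]
        spans_by_family: dict[str, set] = defaultdict(set)
        for h in hs:
            fam = fam_of.get(h.mirna_nr_id) or "?"
            spans_by_family[fam].add((h.start, h.end, h.orientation))
        n_sites = len({s for spans in spans_by_family.values() for s in spans})
        if n_sites < 2 and len(spans_by_family) < 2:
            continue
        rows.append({
            "est_id": est_id,
            "n_hits": len(hs),
            "n_sites": n_sites,
            "families": sorted(spans_by_family),
            "same_family_multi_site": any(len(s) > 1
                                          for s in spans_by_family.values()),
            "multi_family": len(spans_by_family) > 1,
        })
    return rows


def hits_to_tsv(hits: list[Hit], ref: ReferenceSet,
                ests: Optional[list[ESTRecord]] = None) -> str:
    """Human-readable hit table (1-based inclusive coordinates)."""
    fam_of = {r.id: r.family for r in ref.nr_representatives}
    cluster_of = {e.id: e.cluster_id or "" for e in ests} if ests else {}
    lines = ["mirna_id\tfamily\test_id\tcluster_id\tstart\tend\torientation\t"
             "n_mismatch\tmismatch_positions"]
    for h in hits:
        lines.append("\t".join([
            h.mirna_nr_id, fam_of.get(h.mirna_nr_id) or "",
            h.est_id, cluster_of.get(h.est_id, ""),
            str(h.start + 1), str(h.end), h.orientation, str(h.mismatches),
            ",".join(map(str, h.mismatch_positions)),
        ]))
    return "\n".join(lines) + "\n"
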