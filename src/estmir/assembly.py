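"""Star-alignment assembly of EST clusters into columns and a consensus.

EST clusters (UniGene-style) group single-pass reads from one transcription
locus, so members are near-identical copies of a template and a star
alignment against the longest member is an adequate, fast and verifiable
assembly: each member is aligned pairwise to the backbone with an
end-gap-free alignment (match +1, mismatch -1, gap -2, end gaps free), and
the pairwise alignments are merged column-wise.  The per-column symbol
counts are the substrate for SNP/indel calling; the majority symbol per
column gives the consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

from estmir.scan import ESTRecord

logger = logging.getLogger(__name__)

GAP = "-"
CATEGORIES = ("protein_coding", "transcribed", "unknown")


@dataclass
class Cluster:
    id: str
    members: list[ESTRecord]
    annotation: str = ""
    category: str = "unknown"

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cluster {self.id}: no members")
        if self.category not in CATEGORIES:
            raise ValueError(f"cluster {self.id}: unknown category {self.category!r}")


@dataclass
class Column:
    """One alignment column: symbol counts and contributing members.

    ``key`` orders columns: ``(backbone_index, 0)`` for backbone columns and
    ``(backbone_index, ordinal >= 1)`` for bases inserted after that backbone
    position (``(-1, ordinal)`` for insertions before the backbone start).
    ``consensus_pos`` is filled by :func:`assemble` for columns that survive
    into the consensus.
    """

    key: tuple[int, int]
    counts: dict[str, int] = field(default_factory=dict)
    members: dict[str, list[str]] = field(default_factory=dict)
    consensus_pos: Optional[int] = None
    low_confidence: bool = False

    def add(self, symbol: str, member_id: str) -> None:
        self.counts[symbol] = self.counts.get(symbol, 0) + 1
        self.members.setdefault(symbol, []).append(member_id)

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    def majority(self) -> str:
        """Most frequent symbol; ties prefer a base (lexicographically
        smallest) over the gap and flag the column low-confidence."""
        best = max(self.counts.values())
        tied = sorted(s for s, c in self.counts.items() if c == best)
        if len(tied) > 1:
            self.low_confidence = True
            bases = [s for s in tied if s != GAP]
            return bases[0] if bases else GAP
        return tied[0]


@dataclass
class ClusterAlignment:
    cluster_id: str
    columns: list[Column]
    consensus: str
    member_offsets: dict[str, tuple[int, int]]  # member -> [first, last) column idx
    excluded: list[str] = field(default_factory=list)

    def consensus_columns(self) -> list[int]:
        return [ci for ci, col in enumerate(self.columns)
                if col.consensus_pos is not None]

    def column_for_consensus_pos(self, pos: int) -> int:
        for ci, col in enumerate(self.columns):
            if col.consensus_pos == pos:
                return ci
        raise IndexError(f"no column maps to consensus position {pos}")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    try:
        al.end_insertion_score = 0
        al.end_deletion_score = 0
    except AttributeError:  # older biopython naming
        al.target_end_gap_score = 0
        al.query_end_gap_score = 0
    return al


def _align_member(aligner, backbone: str, member: str):
    """Aligned block ranges of member vs backbone, plus identity over the
    aligned span (end gaps excluded, internal gaps counted)."""
    aln = aligner.align(backbone, member)[0]
    tblocks, qblocks = aln.aligned
    if len(tblocks) == 0:
        return [], [], 0.0
    matches = 0
    aligned_len = 0
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        for t, q in zip(range(ts, te), range(qs, qe)):
            aligned_len += 1
            if backbone[t] == member[q]:
                matches += 1
    # internal gaps widen the span
    span_t = tblocks[-1][1] - tblocks[0][0]
    span_q = qblocks[-1][1] - qblocks[0][0]
    block_t = sum(te - ts for ts, te in tblocks)
    block_q = sum(qe - qs for qs, qe in qblocks)
    aligned_len += (span_t - block_t) + (span_q - block_q)
    identity = matches / aligned_len if aligned_len else 0.0
    return [tuple(map(int, b)) for b in tblocks], [tuple(map(int, b)) for b in qblocks], identity


def assemble(cluster: Cluster, min_identity: float = 0.6) -> ClusterAlignment:
    """Star alignment of cluster members; deterministic given member order.

    Members aligning at below ``min_identity`` over their aligned span are
    excluded with a warning (chimeric-cluster guard).  Gap-majority columns
    are dropped from the consensus string but retained in ``columns`` so
    indels stay callable.
    """
    backbone = max(cluster.members, key=lambda m: len(m.sequence))
    aligner = _aligner()

    cols: dict[tuple[int, int], Column] = {}

    def col(key: tuple[int, int]) -> Column:
        if key not in cols:
            cols[key] = Column(key=key)
        return cols[key]

    # member -> (covered backbone span, insertion events)
    coverage: dict[str, tuple[int, int]] = {}
    insertions: dict[str, list[tuple[int, int, str]]] = {}
    excluded: list[str] = []

    for m in cluster.members:
        if m.id == backbone.id and m.sequence == backbone.sequence:
            coverage[m.id] = (0, len(backbone.sequence))
            for b, base in enumerate(backbone.sequence):
                col((b, 0)).add(base, m.id)
            continue
        tblocks, qblocks, identity = _align_member(
            aligner, backbone.sequence, m.sequence)
        if not tblocks or identity < min_identity:
            logger.warning(
                "cluster %s: member %s aligns at %.0f%% identity; excluded",
                cluster.id, m.id, 100 * identity)
            excluded.append(m.id)
            continue
        cov_start, cov_end = tblocks[0][0], tblocks[-1][1]
        coverage[m.id] = (cov_start, cov_end)
        ins_events: list[tuple[int, int, str]] = []
        prev_t = prev_q = None
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            if prev_t is not None:
                if ts > prev_t:  # deletion in member: gaps at backbone columns
                    for b in range(prev_t, ts):
                        col((b, 0)).add(GAP, m.id)
                if qs > prev_q:  # insertion in member after backbone prev_t-1
                    for ordn, q in enumerate(range(prev_q, qs), start=1):
                        col((ts - 1, ordn)).add(m.sequence[q], m.id)
                    ins_events.append((ts - 1, qs - prev_q, m.id))
            for t, q in zip(range(ts, te), range(qs, qe)):
                col((t, 0)).add(m.sequence[q], m.id)
            prev_t, prev_q = te, qe
        insertions[m.id] = ins_events

    # members covering an insertion junction without inserting carry a gap
    for key in [k for k in cols if k[1] >= 1]:
        b, ordn = key
        column = cols[key]
        carriers = {mid for mids in column.members.values() for mid in mids}
        for mid, (cs, ce) in coverage.items():
            if mid not in carriers and cs <= b and b + 1 < ce:
                column.add(GAP, mid)

    ordered = [cols[k] for k in sorted(cols)]
    consensus_chars: list[str] = []
    pos = 0
    for column in ordered:
        sym = column.majority()
        if sym != GAP:
            column.consensus_pos = pos
            consensus_chars.append(sym)
            pos += 1

    # member -> [first, last) column index
    key_index = {c.key: i for i, c in enumerate(ordered)}
    offsets = {}
    for mid, (cs, ce) in coverage.items():
        offsets[mid] = (key_index[(cs, 0)], key_index[(ce - 1, 0)] + 1)

    return ClusterAlignment(
        cluster_id=cluster.id,
        columns=ordered,
        consensus="".join(consensus_chars),
        member_offsets=offsets,
        excluded=excluded,
    )


def consensus_region(aln: ClusterAlignment, start: int, end: int) -> str:
    """Consensus substring in consensus coordinates (0-based half-open)."""
    if not (0 <= start <= end <= len(aln.consensus)):
        raise IndexError(
            f"region [{start}, {end}) outside consensus of length {len(aln.consensus)}")
    return aln.consensus[start:end]


def alignment_summary_tsv(aln: ClusterAlignment) -> str:
    lines = ["column\tbackbone_pos\tinsertion_ord\tconsensus_pos\tdepth\tcounts"]
    for i, c in enumerate(aln.columns):
        counts = ",".join(f"{s}:{n}" for s, n in sorted(c.counts.items()))
        cp = "" if c.consensus_pos is None else str(c.consensus_pos)
        lines.append(f"{i}\t{c.key[0]}\t{c.key[1]}\t{cp}\t{c.depth}\t{counts}")
    return "\n".join(lines) + "\n"
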