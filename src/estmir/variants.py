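"""SNP/indel calling from cluster alignments and precursor refolding impact.

EST redundancy inside a cluster makes alignment columns with two or more
observed alleles candidate polymorphisms.  Singleton alternative alleles are
indistinguishable from single-pass sequencing errors, so calls are classed
``candidate_true`` only when the alternative allele is carried by at least
``min_support`` (default 2) independent member sequences, and
``low_support`` otherwise; both are reported.

For variants inside a precursor, both alleles are substituted into the
precursor sequence and refolded; the impact is summarized as
``ddG = dG_alt - dG_ref`` (positive = destabilizing relative to the
reference allele; exactly antisymmetric under allele swap) together with both
MFEI values and structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from estmir import folding
from estmir.assembly import GAP, ClusterAlignment
from estmir.precursor import NoDuplexError, PrecursorCandidate, star_and_nm
from estmir.targets import CLEAVAGE_POSITIONS, CRITICAL_POSITIONS
from estmir.seqs import dna_to_rna

SNP = "SNP"
INDEL = "indel"

CANDIDATE_TRUE = "candidate_true"
LOW_SUPPORT = "low_support"

FoldFn = Callable[[str], folding.FoldResult]


@dataclass
class VariantCall:
    cluster_id: str
    column: int                      # alignment column index
    consensus_pos: Optional[int]     # None for insertion-only columns
    anchor_pos: int                  # preceding consensus coordinate
    insertion_ordinal: int           # 0 for substitution/deletion columns
    ref_allele: str
    alt_alleles: dict[str, int]
    ref_count: int
    vtype: str                       # SNP | indel
    support_class: str               # candidate_true | low_support
    context: str = "outside"
    mirna_position: Optional[int] = None
    critical: bool = False
    cleavage_site: bool = False


@dataclass
class VariantImpact:
    dG_ref: float
    dG_alt: float
    ddG: float
    mfei_ref: float
    mfei_alt: float
    structure_ref: str
    structure_alt: str
    structure_lost: bool = False


def _region_context(pos: int, regions) -> Optional[str]:
    for reg in regions:
        start, end = reg[0], reg[1]
        kind = reg[2] if len(reg) > 2 else "region"
        if start <= pos < end:
            return kind
    return None


def call_variants(aln: ClusterAlignment, regions: list, min_support: int = 2,
                  report_all: bool = False) -> list[VariantCall]:
    """Variant calls from alignment columns overlapping the given regions.

    ``regions`` are ``(start, end)`` or ``(start, end, kind)`` spans in
    consensus coordinates; ``kind`` becomes the call's context.  A column is
    called when it shows at least two distinct symbols: base vs base is a SNP,
    base vs gap an indel.  With ``report_all`` set, columns outside every
    region are called too (context "outside").
    """
    calls: list[VariantCall] = []
    last_consensus = -1
    ins_ord = 0
    for ci, col in enumerate(aln.columns):
        if col.consensus_pos is not None:
            last_consensus = col.consensus_pos
            ins_ord = 0
        else:
            ins_ord += 1
        anchor = col.consensus_pos if col.consensus_pos is not None else last_consensus
        context = _region_context(anchor, regions)
        if context is None and not report_all:
            continue
        if len(col.counts) < 2:
            continue
        ordered = sorted(col.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ref, ref_count = ordered[0]
        alts = dict(ordered[1:])
        top_alt_count = max(alts.values())
        calls.append(VariantCall(
            cluster_id=aln.cluster_id,
            column=ci,
            consensus_pos=col.consensus_pos,
            anchor_pos=anchor,
            insertion_ordinal=0 if col.consensus_pos is not None else ins_ord,
            ref_allele=ref,
            alt_alleles=alts,
            ref_count=ref_count,
            vtype=INDEL if ref == GAP or GAP in alts else SNP,
            support_class=CANDIDATE_TRUE if top_alt_count >= min_support
            else LOW_SUPPORT,
            context=context or "outside",
        ))
    return calls


def map_to_mirna_position(call: VariantCall, span: tuple[int, int],
                          kind: str) -> int:
    """Map a call to its 1-based miRNA-coordinate position.

    ``kind`` is ``target_site`` (antisense site: position i pairs consensus
    coordinate end - i) or ``mature_region`` (direct 5'->3' mapping).  Sets
    the call's ``mirna_position``, ``critical`` (positions 2-12) and
    ``cleavage_site`` (10/11) fields, and returns the position.
    """
    pos = call.consensus_pos if call.consensus_pos is not None else call.anchor_pos
    start, end = span
    if not (start <= pos < end):
        raise ValueError(f"call at {pos} outside span {span}")
    if kind == "target_site":
        mirna_pos = end - pos
    elif kind == "mature_region":
        mirna_pos = pos - start + 1
    else:
        raise ValueError(f"unknown span kind {kind!r}")
    call.mirna_position = mirna_pos
    call.critical = mirna_pos in CRITICAL_POSITIONS
    call.cleavage_site = mirna_pos in CLEAVAGE_POSITIONS
    call.context = kind
    return mirna_pos


def _apply_allele(seq: str, pos: int, ref: str, allele: str) -> str:
    """Substitute ``allele`` for ``ref`` at ``pos`` (RNA position)."""
    if ref == GAP:        # insertion relative to consensus: add after anchor
        return seq[:pos + 1] + dna_to_rna(allele) + seq[pos + 1:]
    if allele == GAP:     # deletion
        return seq[:pos] + seq[pos + 1:]
    return seq[:pos] + dna_to_rna(allele) + seq[pos + 1:]


def precursor_variant_impact(candidate: PrecursorCandidate, call: VariantCall,
                             precursor_offset: int = 0,
                             alt: Optional[str] = None,
                             fold_fn: FoldFn = folding.fold) -> VariantImpact:
    """Refolding impact of substituting the call's alleles into a precursor.

    ``precursor_offset`` is the consensus coordinate of the precursor's first
    base.  Exactly two alleles are evaluated: the call's reference allele
    (which the precursor sequence carries) and ``alt`` (default: the
    best-supported alternative).  An indel that destroys the mature/star
    duplex is reported with ``structure_lost`` set rather than raising.
    """
    pos = call.consensus_pos if call.consensus_pos is not None else call.anchor_pos
    ppos = pos - precursor_offset
    if not (0 <= ppos < len(candidate.sequence)):
        raise ValueError("call lies outside the precursor span")
    if alt is None:
        alt = max(call.alt_alleles.items(), key=lambda kv: (kv[1], kv[0]))[0]

    seq_ref = candidate.sequence
    seq_alt = _apply_allele(seq_ref, ppos, call.ref_allele, alt)

    fold_ref = fold_fn(seq_ref)
    fold_alt = fold_fn(seq_alt)

    # mature span on the alt sequence (shifted by indels 5' of the mature)
    ms, me = candidate.mature_span
    shift = 0
    if len(seq_alt) != len(seq_ref):
        delta = len(seq_alt) - len(seq_ref)
        if ppos < ms:
            shift = delta
    structure_lost = False
    try:
        alt_ms, alt_me = ms + shift, me + shift
        if not (0 <= alt_ms < alt_me <= len(seq_alt)):
            raise NoDuplexError("mature span shifted out of precursor")
        star, _, _ = star_and_nm(fold_alt.structure, (alt_ms, alt_me))
        if not (star[1] <= alt_ms or star[0] >= alt_me):
            structure_lost = True
    except (NoDuplexError, folding.FoldingError):
        structure_lost = True

    gc_ref = folding.gc_percent(seq_ref)
    gc_alt = folding.gc_percent(seq_alt)
    return VariantImpact(
        dG_ref=fold_ref.dG,
        dG_alt=fold_alt.dG,
        ddG=fold_alt.dG - fold_ref.dG,
        mfei_ref=folding.mfei(fold_ref.dG, len(seq_ref), gc_ref),
        mfei_alt=folding.mfei(fold_alt.dG, len(seq_alt), gc_alt),
        structure_ref=fold_ref.structure,
        structure_alt=fold_alt.structure,
        structure_lost=structure_lost,
    )


def variants_to_tsv(calls: list[VariantCall]) -> str:
    lines = ["cluster_id\tconsensus_pos\tinsertion_ordinal\tref\talt\t"
             "ref_count\talt_counts\tvtype\tsupport_class\tcontext\t"
             "mirna_position\tcritical"]
    for c in calls:
        cp = "" if c.consensus_pos is None else str(c.consensus_pos + 1)
        alt_str = ",".join(f"{a}:{n}" for a, n in sorted(c.alt_alleles.items()))
        lines.append("\t".join([
            c.cluster_id, cp, str(c.insertion_ordinal), c.ref_allele,
            ",".join(sorted(c.alt_alleles)), str(c.ref_count), alt_str,
            c.vtype, c.support_class, c.context,
            "" if c.mirna_position is None else str(c.mirna_position),
            str(c.critical).lower(),
        ]))
    return "\n".join(lines) + "\n"


def variants_to_vcf(calls: list[VariantCall]) -> str:
    """Minimal VCF-like export; positions are consensus-relative (1-based),
    not genome-relative."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=estmir (coordinates are cluster-consensus-relative)",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        pos = (c.consensus_pos if c.consensus_pos is not None else c.anchor_pos) + 1
        alts = ",".join(a if a != GAP else "<DEL>" for a in sorted(c.alt_alleles))
        ref = c.ref_allele if c.ref_allele != GAP else "<INS>"
        info = (f"VTYPE={c.vtype};SUPPORT={c.support_class};"
                f"CONTEXT={c.context};REFCOUNT={c.ref_count}")
        lines.append(f"{c.cluster_id}\t{pos}\t.\t{ref}\t{alts}\t.\t.\t{info}")
    return "\n".join(lines) + "\n"
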