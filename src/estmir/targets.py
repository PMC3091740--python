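"""Target-site profiling and per-family target summaries.

Plant miRNAs guide cleavage of near-perfectly complementary mRNA sites;
cleavage normally occurs opposite the 10th/11th nucleotide of the mature, and
positions 2-12 of the complementary region are functionally critical.  Sites
are therefore profiled position-by-position in miRNA coordinates (1-based
from the mature 5' end) and flagged when a mismatch falls in the critical
window or at the cleavage positions.

Target candidacy requires an antisense hit on a protein-coding cluster;
sense hits on such clusters are recorded separately as possible
pseudo-targets or precursors.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional

from estmir.reference import ReferenceSet
from estmir.scan import ANTISENSE, ESTRecord, Hit

CRITICAL_POSITIONS = range(2, 13)   # positions 2..12 inclusive
CLEAVAGE_POSITIONS = (10, 11)

MATCH, MISMATCH, GAP = "match", "mismatch", "gap"

DEFAULT_PROTEIN_KEYWORDS = (
    "protein", "kinase", "factor", "binding", "domain", "superfamily",
    "synthase", "synthetase", "hydrolase", "transferase", "dehydrogenase",
    "oxidase", "reductase", "peptidase", "enzyme",
)
DEFAULT_TRANSCRIBED_KEYWORDS = ("transcribed",)


@dataclass
class TargetSite:
    cluster_id: Optional[str]
    families: list[str]
    site_span: tuple[int, int]          # coordinates on the EST/consensus
    per_position: list[str]             # miRNA positions 1..ML
    critical_mismatch: bool
    cleavage_site_mismatch: bool
    est_id: Optional[str] = None
    n_mismatch: int = 0


@dataclass
class FamilyTargetSummary:
    clusters_by_family: dict[str, set[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {f: len(c) for f, c in sorted(self.clusters_by_family.items())}

    @property
    def n_families(self) -> int:
        return len(self.clusters_by_family)

    @property
    def n_clusters(self) -> int:
        return len(set().union(*self.clusters_by_family.values())) \
            if self.clusters_by_family else 0


def classify_cluster(annotation: str,
                     protein_keywords: Iterable[str] = DEFAULT_PROTEIN_KEYWORDS,
                     transcribed_keywords: Iterable[str] = DEFAULT_TRANSCRIBED_KEYWORDS,
                     ) -> str:
    """Keyword classification of a cluster annotation.

    Protein/product descriptors win over "transcribed"-style descriptors;
    anything else is ``unknown``.  Keyword lists are configurable.
    """
    text = annotation.lower()
    if any(kw in text for kw in protein_keywords):
        return "protein_coding"
    if any(kw in text for kw in transcribed_keywords):
        return "transcribed"
    return "unknown"


def mirna_position_to_site_coord(position: int, site_span: tuple[int, int]) -> int:
    """Antisense mapping: miRNA position i pairs consensus coordinate end - i."""
    start, end = site_span
    coord = end - position
    if not (start <= coord < end):
        raise IndexError(f"miRNA position {position} outside site span {site_span}")
    return coord


def site_coord_to_mirna_position(coord: int, site_span: tuple[int, int]) -> int:
    start, end = site_span
    if not (start <= coord < end):
        raise IndexError(f"coordinate {coord} outside site span {site_span}")
    return end - coord


def site_profile(hit: Hit, mature: str) -> TargetSite:
    """Per-position complementarity profile of an antisense (target-type) hit.

    The scanner reports mismatch positions in mature coordinates, so the
    profile is match/mismatch over positions 1..ML (the ungapped scan never
    produces gaps); flags follow the 2-12 critical window and 10/11 cleavage
    positions.
    """
    if hit.orientation != ANTISENSE:
        raise ValueError("not a target-type hit: orientation must be antisense")
    ml = len(mature)
    mm = set(hit.mismatch_positions)
    per_position = [MISMATCH if i in mm else MATCH for i in range(1, ml + 1)]
    return TargetSite(
        cluster_id=None,
        families=[],
        site_span=(hit.start, hit.end),
        per_position=per_position,
        critical_mismatch=any(p in mm for p in CRITICAL_POSITIONS),
        cleavage_site_mismatch=any(p in mm for p in CLEAVAGE_POSITIONS),
        est_id=hit.est_id,
        n_mismatch=hit.mismatches,
    )


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def summarize_targets(hits: list[Hit], ests: list[ESTRecord],
                      categories: dict[str, str], ref: ReferenceSet):
    """Distinct protein-coding target clusters per family, plus combined sites.

    ``categories`` maps cluster_id -> category.  Only antisense hits on
    protein-coding clusters count as targets; a cluster hit by several members
    of one family counts once for that family.  Overlapping antisense sites of
    two or more families are reported as combined, multi-miRNA-control entries
    labelled ``famA+famB``.
    """
    fam_of = {r.id: r.family for r in ref.nr_representatives}
    cluster_of = {e.id: e.cluster_id for e in ests}
    summary = FamilyTargetSummary()
    by_est: dict[str, list[Hit]] = defaultdict(list)
    for h in hits:
        if h.orientation != ANTISENSE:
            continue
        cl = cluster_of.get(h.est_id)
        if cl is None or categories.get(cl) != "protein_coding":
            continue
        fam = fam_of.get(h.mirna_nr_id)
        if fam is None:
            continue
        summary.clusters_by_family.setdefault(fam, set()).add(cl)
        by_est[h.est_id].append(h)

    combined: list[dict] = []
    for est_id in sorted(by_est):
        hs = sorted(by_est[est_id], key=lambda h: (h.start, h.mirna_nr_id))
        used: set[int] = set()
        for i, h in enumerate(hs):
            if i in used:
                continue
            group = [h]
            for j in range(i + 1, len(hs)):
                if j in used:
                    continue
                if any(_overlap((g.start, g.end), (hs[j].start, hs[j].end))
                       for g in group):
                    group.append(hs[j])
                    used.add(j)
            fams = sorted({fam_of[g.mirna_nr_id] for g in group},
                          key=lambda f: (len(f), f))
            if len(fams) > 1:
                combined.append({
                    "est_id": est_id,
                    "cluster_id": cluster_of[est_id],
                    "label": "+".join(fams),
                    "span": (min(g.start for g in group),
                             max(g.end for g in group)),
                })
    return summary, combined


def category_tally(annotations: Iterable[str],
                   category_map: dict[str, str]) -> dict[str, dict]:
    """Plain functional-category tally over target annotations.

    Each annotation is assigned the category of the first map term it
    contains (case-insensitive substring); annotations matching no term count
    as ``unannotated``.  Returns category -> {count, pct}.
    """
    counts: dict[str, int] = defaultdict(int)
    items = list(annotations)
    lowered_map = {term.lower(): cat for term, cat in category_map.items()}
    for ann in items:
        text = ann.lower()
        for term, cat in lowered_map.items():
            if term in text:
                counts[cat] += 1
                break
        else:
            counts["unannotated"] += 1
    total = len(items)
    return {cat: {"count": n, "pct": 100.0 * n / total if total else 0.0}
            for cat, n in sorted(counts.items())}


def targets_to_tsv(sites: list[TargetSite], annotations: dict[str, str]) -> str:
    lines = ["cluster_id\tfamilies\tannotation\tsite_start\tsite_end\t"
             "n_mismatch\tcritical_mismatch\tcleavage_site_mismatch"]
    for s in sites:
        lines.append("\t".join([
            s.cluster_id or "", "+".join(s.families),
            annotations.get(s.cluster_id or "", ""),
            str(s.site_span[0] + 1), str(s.site_span[1]),
            str(s.n_mismatch), str(s.critical_mismatch).lower(),
            str(s.cleavage_site_mismatch).lower(),
        ]))
    return "\n".join(lines) + "\n"
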