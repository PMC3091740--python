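"""End-to-end orchestration of the discovery stages.

The flow mirrors the EST-mining protocol: scan matures against raw ESTs
(species-representation statistics are counted over EST matches), relate ESTs
to clusters, assemble each cluster to a consensus, re-scan the consensi to
define miRNA-relevant regions, then run precursor screening on sense hits in
transcribed clusters, target profiling on antisense hits in protein-coding
clusters, and variant calling over all miRNA-relevant regions with refolding
impact for precursor variants.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional

from estmir import assembly, enrichment, precursor, scan, targets, variants
from estmir.config import PipelineConfig
from estmir.reference import ReferenceSet
from estmir.scan import ESTRecord


@dataclass
class PipelineResult:
    hits_est: list = field(default_factory=list)
    matched_counts: dict = field(default_factory=dict)
    enrichment_rows: list = field(default_factory=list)
    sweep: Optional[enrichment.ThresholdSweep] = None
    multi_hit: list = field(default_factory=list)
    alignments: dict = field(default_factory=dict)        # cluster -> ClusterAlignment
    hits_consensus: list = field(default_factory=list)
    precursors: list = field(default_factory=list)        # PrecursorCandidate
    rejections: list = field(default_factory=list)
    target_sites: list = field(default_factory=list)      # TargetSite
    family_summary: Optional[targets.FamilyTargetSummary] = None
    combined_sites: list = field(default_factory=list)
    variant_calls: list = field(default_factory=list)
    variant_impacts: list = field(default_factory=list)   # (call, VariantImpact)


def group_clusters(ests: list[ESTRecord], annotations: dict[str, str],
                   categories: Optional[dict[str, str]] = None) -> list[assembly.Cluster]:
    """Group ESTs by cluster_id; categories default to the keyword rule."""
    members: dict[str, list[ESTRecord]] = defaultdict(list)
    for e in ests:
        if e.cluster_id:
            members[e.cluster_id].append(e)
    out = []
    for cid in sorted(members):
        ann = annotations.get(cid, "")
        cat = (categories or {}).get(cid) or targets.classify_cluster(ann)
        out.append(assembly.Cluster(id=cid, members=members[cid],
                                    annotation=ann, category=cat))
    return out


def run_pipeline(ref: ReferenceSet, ests: list[ESTRecord],
                 annotations: dict[str, str],
                 categories: Optional[dict[str, str]] = None,
                 cfg: Optional[PipelineConfig] = None) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    res = PipelineResult()

    # stage 1: scan raw ESTs; species representation over the redundant set
    res.hits_est = scan.scan(ref, ests, max_mm=cfg.max_mm)
    res.matched_counts = dict(scan.matched_redundant_set(res.hits_est, ref))
    initial_counts: dict[str, int] = defaultdict(int)
    for rec in ref.records:
        if rec.species_code:
            initial_counts[rec.species_code] += 1
    if res.matched_counts:
        res.enrichment_rows = enrichment.build_table(
            dict(initial_counts), res.matched_counts, mode=cfg.statistic_mode)
        res.sweep = enrichment.threshold_sweep(res.enrichment_rows,
                                               cfg.thresholds)
    res.multi_hit = scan.multi_hit_report(res.hits_est, ref)

    # stage 2: assemble clusters, re-scan consensi
    clusters = group_clusters(ests, annotations, categories)
    cat_of = {c.id: c.category for c in clusters}
    consensi = []
    for cl in clusters:
        aln = assembly.assemble(cl)
        res.alignments[cl.id] = aln
        consensi.append(ESTRecord(id=cl.id, sequence=aln.consensus,
                                  cluster_id=cl.id))
    res.hits_consensus = scan.scan(ref, consensi, max_mm=cfg.max_mm)

    # stage 3: precursors from sense hits on non-protein-coding clusters
    mature_of = {r.id: r.sequence for r in ref.nr_representatives}
    for h in res.hits_consensus:
        if h.orientation == scan.SENSE and cat_of.get(h.est_id) != "protein_coding":
            out = precursor.extract_candidate(
                res.alignments[h.est_id].consensus, h, source_id=h.est_id,
                fold_window=cfg.fold_window, flank=cfg.flank,
                mfei_min=cfg.mfei_min, max_star_mm=cfg.max_star_mm,
                max_bulges=cfg.max_bulges, max_bulge_size=cfg.max_bulge_size)
            if isinstance(out, precursor.Rejection):
                res.rejections.append(out)
            else:
                res.precursors.append(out)

    # stage 4: target sites from antisense hits on protein-coding clusters
    for h in res.hits_consensus:
        if h.orientation == scan.ANTISENSE and cat_of.get(h.est_id) == "protein_coding":
            site = targets.site_profile(h, mature_of[h.mirna_nr_id])
            site.cluster_id = h.est_id
            fam = next((r.family for r in ref.nr_representatives
                        if r.id == h.mirna_nr_id), None)
            site.families = [fam] if fam else []
            res.target_sites.append(site)
    res.family_summary, res.combined_sites = targets.summarize_targets(
        res.hits_consensus, consensi, cat_of, ref)

    # stage 5: variants in miRNA-relevant consensus regions
    regions_by_cluster: dict[str, list] = defaultdict(list)
    for h in res.hits_consensus:
        kind = ("target_site" if h.orientation == scan.ANTISENSE
                else "mature_region")
        regions_by_cluster[h.est_id].append((h.start, h.end, kind))
    pre_by_cluster = {c.source_id: c for c in res.precursors}
    for cid, regions in sorted(regions_by_cluster.items()):
        calls = variants.call_variants(res.alignments[cid], regions,
                                       min_support=cfg.min_support)
        for call in calls:
            span_kind = _containing_region(call, regions)
            if span_kind is not None:
                variants.map_to_mirna_position(call, span_kind[0], span_kind[1])
            cand = pre_by_cluster.get(cid)
            if (span_kind is not None and span_kind[1] == "mature_region"
                    and cand is not None and call.vtype == variants.SNP):
                offset = _precursor_offset(cand, call)
                if offset is not None:
                    impact = variants.precursor_variant_impact(
                        cand, call, precursor_offset=offset)
                    res.variant_impacts.append((call, impact))
            res.variant_calls.append(call)
    return res


def _containing_region(call, regions):
    pos = call.consensus_pos if call.consensus_pos is not None else call.anchor_pos
    for start, end, kind in regions:
        if start <= pos < end:
            return (start, end), kind
    return None


def _precursor_offset(cand, call) -> Optional[int]:
    """Consensus coordinate of the precursor start, from its mature hit."""
    if cand.hit is None:
        return None
    offset = cand.hit.start - cand.mature_span[0]
    pos = call.consensus_pos if call.consensus_pos is not None else call.anchor_pos
    if 0 <= pos - offset < len(cand.sequence):
        return offset
    return None
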