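"""Synthetic reference sets, EST clusters and planted features with ground truth.

The generator emulates the statistical shape of the real inputs this kind of
survey consumes — a multi-species mature-miRNA reference, EST clusters that
are noisy redundant copies of one template, hairpin precursors embedded in
transcribed clusters, near-complementary target sites in protein-coding
clusters, and SNPs/indels with controlled allele support — and emits a
machine-readable manifest of every planted feature with its expected pipeline
verdict, so each stage can be tested end to end without downloads.

Background sequence is i.i.d. at a configurable GC (default 45%,
cereal-EST-like).  Designed hairpins are refolded with the baseline engine and
the *realized* duplex (which may deviate from the design when the engine
refolds a planted mismatch) is what the manifest records.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from typing import Optional

from estmir import folding
from estmir.precursor import NoDuplexError, star_and_nm
from estmir.reference import MatureRecord, ReferenceSet, build_reference_set
from estmir.scan import ESTRecord
from estmir.seqs import revcomp_dna, revcomp_rna, rna_to_dna

_COMPLEMENT_RNA = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class PlantedPrecursor:
    mature_id: Optional[str] = None   # None: generator picks one
    nm_star: int = 0
    loop_len: int = 8
    bulges: tuple = ()                # (offset_in_star, size) insertions
    arm: str = "5p"                   # arm carrying the mature
    annotation: str = "transcribed locus"


@dataclass
class PlantedTarget:
    mature_id: Optional[str] = None
    mismatch_positions: tuple[int, ...] = ()
    category: str = "protein_coding"
    annotation: str = "protein coding (kinase domain)"


@dataclass
class PlantedVariant:
    kind: str               # "target_site" | "mature_region"
    feature_index: int      # index into planted_targets / planted_precursors
    mirna_position: int     # 1-based from the mature 5' end
    alt_allele: str         # base, "-"*n deletion, or "+XX" insertion
    alt_support: int = 2


@dataclass
class SimConfig:
    seed: int = 0
    species_spec: tuple = (("aas", 40), ("bbv", 30), ("ccp", 25), ("ddt", 20),
                           ("eem", 15), ("ffo", 10), ("ggl", 6), ("hhc", 4))
    mature_length_range: tuple[int, int] = (20, 22)
    n_clusters: int = 12
    members_per_cluster: tuple[int, int] = (5, 8)
    planted_precursors: tuple = ()
    planted_targets: tuple = ()
    planted_variants: tuple = ()
    error_rate: float = 0.0
    background_gc: float = 0.45
    est_length: int = 400
    max_end_truncation: int = 30
    n_duplicate_pairs: int = 0
    scan_max_mm: int = 3

    def validate(self) -> None:
        n_planted = len(self.planted_precursors) + len(self.planted_targets)
        if n_planted > self.n_clusters:
            raise ValueError("more planted features than clusters")
        lo, hi = self.members_per_cluster
        for v in self.planted_variants:
            # member 1 stays a pristine full-length template copy (the star
            # backbone), and the reference allele must keep the majority
            if 2 * v.alt_support >= lo:
                raise ValueError(
                    f"variant support {v.alt_support} too high for the "
                    f"smallest cluster ({lo} members)")
            if v.kind == "target_site":
                if v.feature_index >= len(self.planted_targets):
                    raise ValueError("variant references a missing target")
                ml_src = self.planted_targets[v.feature_index]
            elif v.kind == "mature_region":
                if v.feature_index >= len(self.planted_precursors):
                    raise ValueError("variant references a missing precursor")
                ml_src = self.planted_precursors[v.feature_index]
            else:
                raise ValueError(f"unknown variant kind {v.kind!r}")
            del ml_src
            if v.mirna_position < 1 or v.mirna_position > self.mature_length_range[1]:
                raise ValueError("variant position outside mature length range")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SimResult:
    reference: ReferenceSet
    reference_fasta: str
    ests: list[ESTRecord]
    est_fasta: str
    cluster_table: str          # TSV: est_id, cluster_id, annotation, category
    manifest: dict

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=1, default=list)


def random_rna(rng: random.Random, length: int, gc: float = 0.45) -> str:
    bases, weights = "GCAU", (gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2)
    return "".join(rng.choices(bases, weights=weights, k=length))


def random_dna(rng: random.Random, length: int, gc: float = 0.45) -> str:
    return rna_to_dna(random_rna(rng, length, gc))


def simulate_reference(cfg: SimConfig, rng: Optional[random.Random] = None):
    """Random matures with configured per-species counts.

    With ``n_duplicate_pairs`` > 0, that many sequences are copied into the
    next species (new deposit, identical sequence) to exercise the
    redundant/non-redundant bookkeeping.
    """
    rng = rng or random.Random(cfg.seed)
    records: list[MatureRecord] = []
    fam = 100
    species = [s for s, _ in cfg.species_spec]
    for sp, n in cfg.species_spec:
        for _ in range(n):
            L = rng.randint(*cfg.mature_length_range)
            seq = random_rna(rng, L, gc=0.5)
            records.append(MatureRecord(id=f"{sp}-miR{fam}", sequence=seq,
                                        species_code=sp, family=str(fam)))
            fam += 1
    for d in range(cfg.n_duplicate_pairs):
        src = records[d]
        dst_sp = species[(species.index(src.species_code) + 1) % len(species)]
        records.append(MatureRecord(id=f"{dst_sp}-miR{src.family}",
                                    sequence=src.sequence,
                                    species_code=dst_sp, family=src.family))
    ref = build_reference_set(records)
    fasta = "".join(f">{r.id}\n{r.sequence}\n" for r in ref.records)
    return ref, fasta


def _plant_star_mismatches(star: str, mature: str, nm: int,
                           rng: random.Random) -> str:
    """Force ``nm`` mature positions to be non-complementary in the star."""
    ml = len(mature)
    # star[q] pairs mature position p = ml - q (1-based); avoid duplex ends
    positions = rng.sample(range(3, ml - 3), nm) if nm else []
    chars = list(star)
    for p in positions:     # p is 0-based mature index
        q = ml - 1 - p
        comp = _COMPLEMENT_RNA[mature[p]]
        choices = [b for b in "ACGU" if b != comp
                   and not (b == "G" and mature[p] == "U")
                   and not (b == "U" and mature[p] == "G")]
        chars[q] = rng.choice(choices)
    return "".join(chars)


def build_hairpin(mature: str, nm_star: int = 0, loop_len: int = 8,
                  bulges: tuple = (), flank: int = 13, arm: str = "5p",
                  rng: Optional[random.Random] = None,
                  fold_fn=folding.fold, max_retries: int = 50) -> dict:
    """Construct a precursor RNA realizing a designed mature/star duplex.

    The star is the reverse complement of the mature with ``nm_star`` planted
    non-complementary positions (GU wobble excluded so the engine cannot
    re-pair them) and optional inserted star-arm bulges.  The loop is drawn
    from {A, C} so it stays unpaired.  The construct is folded with the
    baseline engine; flanks and loop are resampled (up to ``max_retries``)
    until the realized duplex matches the design, and the *realized* values
    are returned regardless.
    """
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3")
    rng = rng or random.Random(0)
    ml = len(mature)
    last: Optional[dict] = None
    for _ in range(max_retries):
        star = _plant_star_mismatches(revcomp_rna(mature), mature, nm_star, rng)
        for off, size in bulges:
            ins = "".join(rng.choice("AC") for _ in range(size))
            star = star[:off] + ins + star[off:]
        loop = "".join(rng.choice("AC") for _ in range(loop_len))
        f5 = random_rna(rng, flank, gc=0.3)
        f3 = random_rna(rng, flank, gc=0.3)
        if arm == "5p":
            seq = f5 + mature + loop + star + f3
            m_span = (flank, flank + ml)
        else:
            seq = f5 + star + loop + mature + f3
            m_span = (flank + len(star) + loop_len, flank + len(star) + loop_len + ml)
        result = fold_fn(seq)
        try:
            star_span, nm, found_bulges = star_and_nm(result.structure, m_span)
        except NoDuplexError:
            continue
        opposite = star_span[1] <= m_span[0] or star_span[0] >= m_span[1]
        realized = {
            "sequence": seq,
            "structure": result.structure,
            "dG": result.dG,
            "mature_span": m_span,
            "star_span": star_span,
            "designed_nm": nm_star,
            "realized_nm": nm,
            "loop_len": loop_len,
            "arm": "5'" if arm == "5p" else "3'",
            "n_bulges": len(found_bulges),
            "opposite_arm": opposite,
        }
        last = realized
        if opposite and nm == nm_star:
            return realized
    if last is None:
        raise RuntimeError(
            f"hairpin construction infeasible after {max_retries} retries "
            f"(mature={mature}, nm_star={nm_star}, loop={loop_len})")
    return last


def plant_target(mature: str, mismatch_positions: tuple[int, ...],
                 background: str, rng: random.Random) -> tuple[str, tuple[int, int]]:
    """Insert an antisense (target-type) site into a background DNA sequence.

    Mismatches are planted at the given 1-based mature positions (any base
    change is a mismatch under the scanner's exact U≡T comparison).  The site
    is kept at least 40 nt from either EST end so member-end truncation in the
    cluster generator never clips it.  Returns the EST sequence and the site
    span on its forward strand.
    """
    ml = len(mature)
    mutated = list(rna_to_dna(mature))
    for p in mismatch_positions:
        if not (1 <= p <= ml):
            raise ValueError(f"mismatch position {p} outside mature length {ml}")
        orig = mutated[p - 1]
        mutated[p - 1] = rng.choice([b for b in "ACGT" if b != orig])
    site = revcomp_dna("".join(mutated))
    offset = rng.randint(40, max(41, len(background) - ml - 40))
    est = background[:offset] + site + background[offset + ml:]
    return est, (offset, offset + ml)


def _mutate(seq: str, rng: random.Random, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i, c in enumerate(chars):
        if rng.random() < rate and c in "ACGT":
            chars[i] = rng.choice([b for b in "ACGT" if b != c])
    return "".join(chars)


def _apply_variant(template: str, pos: int, alt: str) -> tuple[str, str]:
    """Apply a variant spec at template coordinate ``pos``; returns
    (modified sequence, ref allele string)."""
    if alt.startswith("+"):        # insertion after pos
        return template[:pos + 1] + alt[1:] + template[pos + 1:], template[pos]
    if set(alt) == {"-"}:          # deletion of len(alt) bases
        n = len(alt)
        return template[:pos] + template[pos + n:], template[pos:pos + n]
    return template[:pos] + alt + template[pos + 1:], template[pos]


def generate(cfg: SimConfig) -> SimResult:
    """Full synthetic dataset: reference FASTA, EST FASTA, cluster table and
    ground-truth manifest.  Reproducible from (cfg, seed)."""
    cfg.validate()
    rng = random.Random(cfg.seed)
    ref, ref_fasta = simulate_reference(cfg, rng)
    by_id = ref.by_id

    def resolve(mature_id: Optional[str], fallback_idx: int) -> MatureRecord:
        if mature_id is not None:
            return by_id[mature_id]
        return ref.records[(fallback_idx * 7) % len(ref.records)]

    manifest: dict = {
        "seed": cfg.seed,
        "reference": {
            "n_redundant": len(ref.records),
            "n_nonredundant": len(ref.nr_map),
            "species_counts": {sp: n for sp, n in cfg.species_spec},
        },
        "precursors": [], "targets": [], "variants": [], "clusters": [],
    }

    clusters: list[dict] = []

    for idx, spec in enumerate(cfg.planted_precursors):
        rec = resolve(spec.mature_id, idx)
        hp = build_hairpin(rec.sequence, nm_star=spec.nm_star,
                           loop_len=spec.loop_len, bulges=spec.bulges,
                           arm=spec.arm, rng=rng)
        left = random_dna(rng, 80, cfg.background_gc)
        right = random_dna(rng, 80, cfg.background_gc)
        template = left + rna_to_dna(hp["sequence"]) + right
        m_lo = len(left) + hp["mature_span"][0]
        m_hi = len(left) + hp["mature_span"][1]
        cid = f"Cl.{len(clusters) + 1}"
        clusters.append({"id": cid, "template": template,
                         "annotation": spec.annotation,
                         "category": "transcribed"})
        manifest["precursors"].append({
            "cluster_id": cid, "mature_id": rec.id,
            "precursor_span": [len(left), len(left) + len(hp["sequence"])],
            "mature_span": [m_lo, m_hi],
            "designed_nm": hp["designed_nm"], "realized_nm": hp["realized_nm"],
            "loop_len": hp["loop_len"], "arm": hp["arm"],
            "opposite_arm": hp["opposite_arm"],
            "structure": hp["structure"], "dG": hp["dG"],
        })

    for idx, spec in enumerate(cfg.planted_targets):
        rec = resolve(spec.mature_id, idx + len(cfg.planted_precursors))
        background = random_dna(rng, cfg.est_length, cfg.background_gc)
        template, span = plant_target(rec.sequence, tuple(spec.mismatch_positions),
                                      background, rng)
        cid = f"Cl.{len(clusters) + 1}"
        clusters.append({"id": cid, "template": template,
                         "annotation": spec.annotation,
                         "category": spec.category})
        manifest["targets"].append({
            "cluster_id": cid, "mature_id": rec.id,
            "site_span": list(span),
            "mismatch_positions": list(spec.mismatch_positions),
            "n_mismatch": len(spec.mismatch_positions),
            "expected_found": len(spec.mismatch_positions) <= cfg.scan_max_mm,
        })

    while len(clusters) < cfg.n_clusters:
        cid = f"Cl.{len(clusters) + 1}"
        clusters.append({
            "id": cid,
            "template": random_dna(rng, cfg.est_length, cfg.background_gc),
            "annotation": rng.choice(["transcribed locus", "protein coding",
                                      "", "hypothetical product"]),
            "category": "unknown",
        })

    # resolve variants to template coordinates and carrier members
    template_of = {cl["id"]: cl["template"] for cl in clusters}
    variants_by_cluster: dict[str, list[dict]] = {}
    for v in cfg.planted_variants:
        if v.kind == "target_site":
            feat = manifest["targets"][v.feature_index]
            lo, hi = feat["site_span"]
            pos = hi - v.mirna_position
        else:
            feat = manifest["precursors"][v.feature_index]
            lo, hi = feat["mature_span"]
            pos = lo + v.mirna_position - 1
        cid = feat["cluster_id"]
        alt = v.alt_allele
        if not alt.startswith("+") and set(alt) != {"-"} \
                and template_of[cid][pos] == alt:
            # requested SNP allele equals the template base: pick another so
            # a polymorphism is actually planted
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[alt]
        entry = {"cluster_id": cid, "template_pos": pos, "alt": alt,
                 "alt_support": v.alt_support, "kind": v.kind,
                 "mirna_position": v.mirna_position,
                 "expected_class": "candidate_true" if v.alt_support >= 2
                 else "low_support"}
        variants_by_cluster.setdefault(cid, []).append(entry)
        manifest["variants"].append(entry)

    ests: list[ESTRecord] = []
    rows = ["est_id\tcluster_id\tannotation\tcategory"]
    for cl in clusters:
        cid, template = cl["id"], cl["template"]
        n_members = rng.randint(*cfg.members_per_cluster)
        cl_variants = variants_by_cluster.get(cid, [])
        carriers: dict[int, list[dict]] = {}
        pool = list(range(1, n_members))  # member 0 stays pristine
        for v in cl_variants:
            chosen = rng.sample(pool, v["alt_support"])
            for m in chosen:
                carriers.setdefault(m, []).append(v)
            v["carrier_members"] = [f"{cid}.m{m + 1}" for m in sorted(chosen)]
        member_ids = []
        for m in range(n_members):
            seq = template
            # apply this member's variants right-to-left so coordinates hold
            for v in sorted(carriers.get(m, []),
                            key=lambda d: -d["template_pos"]):
                seq, ref_allele = _apply_variant(seq, v["template_pos"], v["alt"])
                v.setdefault("ref_allele", ref_allele)
            seq = _mutate(seq, rng, cfg.error_rate)
            if m not in carriers and cfg.max_end_truncation > 0 and m > 0:
                seq = seq[rng.randint(0, cfg.max_end_truncation):
                          len(seq) - rng.randint(0, cfg.max_end_truncation)]
            mid = f"{cid}.m{m + 1}"
            member_ids.append(mid)
            ests.append(ESTRecord(id=mid, sequence=seq, cluster_id=cid))
            rows.append(f"{mid}\t{cid}\t{cl['annotation']}\t{cl['category']}")
        manifest["clusters"].append({
            "id": cid, "annotation": cl["annotation"],
            "category": cl["category"], "n_members": n_members,
            "template_length": len(template), "members": member_ids,
        })
        for v in cl_variants:
            v.setdefault("ref_allele", template[v["template_pos"]])

    # expected enrichment bookkeeping: which species' records were planted
    planted_ids = [p["mature_id"] for p in manifest["precursors"]] + \
                  [t["mature_id"] for t in manifest["targets"]
                   if t["expected_found"]]
    planted_seqs = {by_id[i].sequence for i in planted_ids}
    matched = {}
    for rec in ref.records:
        if rec.sequence in planted_seqs and rec.species_code:
            matched[rec.species_code] = matched.get(rec.species_code, 0) + 1
    manifest["expected_matched_species_counts"] = matched

    est_fasta = "".join(f">{e.id}\n{e.sequence}\n" for e in ests)
    return SimResult(reference=ref, reference_fasta=ref_fasta, ests=ests,
                     est_fasta=est_fasta, cluster_table="\n".join(rows) + "\n",
                     manifest=manifest)


def default_config(seed: int = 0, error_rate: float = 0.0) -> SimConfig:
    """A study-shaped scenario: several planted precursors and targets, a
    multi-family EST, and variants at miRNA-relevant positions."""
    return SimConfig(
        seed=seed,
        n_clusters=12,
        planted_precursors=(
            PlantedPrecursor(nm_star=0, loop_len=8, arm="5p"),
            PlantedPrecursor(nm_star=2, loop_len=10, arm="3p"),
            PlantedPrecursor(nm_star=1, loop_len=6, arm="5p"),
        ),
        planted_targets=(
            PlantedTarget(mismatch_positions=()),
            PlantedTarget(mismatch_positions=(11,)),
            PlantedTarget(mismatch_positions=(5, 18)),
            PlantedTarget(mismatch_positions=(2, 9, 15)),
            PlantedTarget(mismatch_positions=(1, 6, 13, 20),  # beyond max_mm
                          annotation="protein coding (SBP domain)"),
            PlantedTarget(mismatch_positions=(3,),
                          annotation="transcribed locus", category="transcribed"),
        ),
        planted_variants=(
            PlantedVariant("target_site", 0, 11, "A", alt_support=2),
            PlantedVariant("target_site", 1, 15, "C", alt_support=1),
            PlantedVariant("mature_region", 0, 12, "G", alt_support=2),
            PlantedVariant("target_site", 2, 10, "--", alt_support=2),
        ),
        error_rate=error_rate,
    )


def null_enrichment_sim(initial_counts: dict[str, int], K: int, reps: int,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Null calibration of the tail-mode statistic.

    Draws the matched set uniformly (without replacement) from the initial
    redundant set ``reps`` times and reports the empirical rate of tail-mode
    p <= alpha over all (rep, species) tests, plus the direction split.
    Discreteness and the without-replacement draw make the test conservative.
    """
    import numpy as np

    from estmir.enrichment import TAIL, representation_stat

    if reps < 100:
        raise ValueError("reps must be >= 100")
    species = list(initial_counts)
    m = np.array([initial_counts[s] for s in species])
    M = int(m.sum())
    if not (0 < K <= M):
        raise ValueError("need 0 < K <= M")
    nprng = np.random.default_rng(seed)
    n_tests = n_hits = n_over = n_under = 0
    pvals = []
    for _ in range(reps):
        ks = nprng.multivariate_hypergeometric(m, K)
        for sp_i, sp in enumerate(species):
            p, direction = representation_stat(
                int(m[sp_i]), M, int(ks[sp_i]), K, mode=TAIL)
            pvals.append(p)
            n_tests += 1
            if p <= alpha:
                n_hits += 1
            if direction == "over":
                n_over += 1
            elif direction == "under":
                n_under += 1
    return {
        "alpha": alpha, "reps": reps, "n_tests": n_tests,
        "empirical_rate": n_hits / n_tests,
        "mc_se": (alpha * (1 - alpha) / n_tests) ** 0.5,
        "n_over": n_over, "n_under": n_under,
        "pvals": pvals,
    }
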