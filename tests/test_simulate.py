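import json
import random

import pytest

from estmir.reference import parse_mature_fasta
from estmir.scan import ANTISENSE, ESTRecord, scan
from estmir.simulate import (PlantedPrecursor, PlantedTarget, PlantedVariant,
                             SimConfig, build_hairpin, default_config,
                             generate, plant_target, simulate_reference)
from estmir.targets import site_profile


class TestSimulateReference:
    def test_seeded_determinism(self):
        cfg = SimConfig(seed=42)
        _, fasta1 = simulate_reference(cfg)
        _, fasta2 = simulate_reference(cfg)
        assert fasta1 == fasta2

    def test_per_species_counts(self):
        cfg = SimConfig(seed=7, species_spec=(("aaa", 12), ("bbb", 3)))
        ref, _ = simulate_reference(cfg)
        counts = {}
        for r in ref.records:
            counts[r.species_code] = counts.get(r.species_code, 0) + 1
        assert counts == {"aaa": 12, "bbb": 3}

    def test_duplicates_collapse_in_nr_map(self):
        cfg = SimConfig(seed=7, species_spec=(("aaa", 10), ("bbb", 5)),
                        n_duplicate_pairs=3)
        ref, _ = simulate_reference(cfg)
        assert len(ref.records) == 18
        assert len(ref.nr_map) == 15


class TestBuildHairpin:
    def test_perfect_duplex_arithmetic(self, rng):
        mature = "".join(rng.choice("ACGU") for _ in range(21))
        hp = build_hairpin(mature, nm_star=0, loop_len=8, rng=rng)
        assert len(hp["sequence"]) == 2 * 21 + 8 + 26
        assert hp["realized_nm"] == 0
        assert hp["opposite_arm"]

    def test_arm_side_honored(self, rng):
        mature = "".join(rng.choice("ACGU") for _ in range(21))
        hp5 = build_hairpin(mature, arm="5p", rng=random.Random(5))
        hp3 = build_hairpin(mature, arm="3p", rng=random.Random(5))
        assert hp5["arm"] == "5'" and hp5["mature_span"][0] == 13
        assert hp3["arm"] == "3'" and hp3["mature_span"][0] > 13

    def test_designed_nm_mostly_realized(self):
        hits = 0
        n = 40
        for seed in range(n):
            rng = random.Random(seed)
            mature = "".join(rng.choice("ACGU") for _ in range(21))
            hp = build_hairpin(mature, nm_star=2, loop_len=8, rng=rng)
            hits += hp["realized_nm"] == 2
        assert hits / n >= 0.95

    def test_short_loop_rejected(self):
        with pytest.raises(ValueError, match="loop_len"):
            build_hairpin("ACGUACGUACGUACGUACGUA", loop_len=2)


class TestPlantTarget:
    def test_zero_mismatch_site_found_by_scanner(self, rng):
        mature = "".join(rng.choice("ACGU") for _ in range(21))
        bg = "".join(rng.choice("ACGT") for _ in range(300))
        est, span = plant_target(mature, (), bg, rng)
        ref = parse_mature_fasta(f">sp-miR5\n{mature}\n")
        hits = [h for h in scan(ref, [ESTRecord("e", est)], max_mm=0)
                if h.orientation == ANTISENSE]
        assert [(h.start, h.end) for h in hits] == [span]

    def test_mismatch_at_11_flags_cleavage_through_chain(self, rng):
        mature = "".join(rng.choice("ACGU") for _ in range(21))
        bg = "".join(rng.choice("ACGT") for _ in range(300))
        est, span = plant_target(mature, (11,), bg, rng)
        ref = parse_mature_fasta(f">sp-miR5\n{mature}\n")
        hits = [h for h in scan(ref, [ESTRecord("e", est)], max_mm=3)
                if h.orientation == ANTISENSE and (h.start, h.end) == span]
        assert hits[0].mismatch_positions == (11,)
        assert site_profile(hits[0], mature).cleavage_site_mismatch

    def test_four_mismatches_not_found_at_default_threshold(self, rng):
        mature = "".join(rng.choice("ACGU") for _ in range(21))
        bg = "".join(rng.choice("ACGT") for _ in range(300))
        est, span = plant_target(mature, (1, 6, 13, 20), bg, rng)
        ref = parse_mature_fasta(f">sp-miR5\n{mature}\n")
        hits = [h for h in scan(ref, [ESTRecord("e", est)], max_mm=3)
                if h.orientation == ANTISENSE and (h.start, h.end) == span]
        assert hits == []


class TestGenerate:
    def test_seeded_determinism(self):
        a = generate(default_config(seed=5))
        b = generate(default_config(seed=5))
        assert a.reference_fasta == b.reference_fasta
        assert a.est_fasta == b.est_fasta
        assert a.cluster_table == b.cluster_table
        assert json.dumps(a.manifest, default=list) == \
            json.dumps(b.manifest, default=list)

    def test_manifest_coordinates_validate_against_fasta(self, sim_result):
        ests = {e.id: e.sequence for e in sim_result.ests}
        by_id = sim_result.reference.by_id
        from estmir.seqs import revcomp_dna, rna_to_dna
        for t in sim_result.manifest["targets"]:
            cid = t["cluster_id"]
            pristine = ests[f"{cid}.m1"]
            lo, hi = t["site_span"]
            site = pristine[lo:hi]
            mature_dna = rna_to_dna(by_id[t["mature_id"]].sequence)
            diffs = sum(a != b for a, b in
                        zip(revcomp_dna(site), mature_dna))
            assert diffs == t["n_mismatch"]
        for p in sim_result.manifest["precursors"]:
            cid = p["cluster_id"]
            pristine = ests[f"{cid}.m1"]
            lo, hi = p["mature_span"]
            assert pristine[lo:hi] == rna_to_dna(by_id[p["mature_id"]].sequence)

    def test_inconsistent_config_rejected_before_output(self):
        cfg = SimConfig(planted_variants=(
            PlantedVariant("target_site", 3, 5, "A"),))  # no targets exist
        with pytest.raises(ValueError, match="missing target"):
            generate(cfg)

    def test_variant_support_bounded_by_members(self):
        cfg = SimConfig(
            members_per_cluster=(5, 6),
            planted_targets=(PlantedTarget(),),
            planted_variants=(PlantedVariant("target_site", 0, 5, "A",
                                             alt_support=4),))
        with pytest.raises(ValueError, match="support"):
            generate(cfg)

    def test_noise_free_run_has_zero_unplanted_calls(self, sim_result,
                                                     pipeline_result):
        planted = {(v["cluster_id"], v["template_pos"])
                   for v in sim_result.manifest["variants"]}
        planted_clusters = {c for c, _ in planted}
        for call in pipeline_result.variant_calls:
            assert call.cluster_id in planted_clusters
        # every planted variant with support >= 2 is recovered candidate_true
        for v in sim_result.manifest["variants"]:
            matching = [c for c in pipeline_result.variant_calls
                        if c.cluster_id == v["cluster_id"]
                        and c.support_class == v["expected_class"]]
            assert matching, v
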