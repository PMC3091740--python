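import random

import pytest

from estmir.assembly import Cluster, assemble
from estmir.scan import ESTRecord, Hit, SENSE
from estmir.seqs import rna_to_dna
from estmir.precursor import extract_candidate
from estmir.simulate import build_hairpin, random_dna
from estmir.variants import (CANDIDATE_TRUE, INDEL, LOW_SUPPORT, SNP,
                             call_variants, map_to_mirna_position,
                             precursor_variant_impact)


def _aln(seqs, cid="Cl.v"):
    return assemble(Cluster(id=cid, members=[
        ESTRecord(f"{cid}.m{i+1}", s) for i, s in enumerate(seqs)]))


class TestCallVariants:
    def test_snp_candidate_true(self, rng):
        template = random_dna(rng, 100)
        alt_base = "G" if template[50] != "G" else "A"
        alt = template[:50] + alt_base + template[51:]
        aln = _aln([template] * 3 + [alt] * 2)
        calls = call_variants(aln, [(40, 60, "target_site")])
        assert len(calls) == 1
        c = calls[0]
        assert (c.vtype, c.support_class) == (SNP, CANDIDATE_TRUE)
        assert c.ref_allele == template[50]
        assert c.alt_alleles == {alt_base: 2}
        assert c.consensus_pos == 50

    def test_singleton_low_support(self, rng):
        template = random_dna(rng, 100)
        alt_base = "G" if template[50] != "G" else "A"
        alt = template[:50] + alt_base + template[51:]
        calls = call_variants(_aln([template] * 4 + [alt]), [(40, 60)])
        assert calls[0].support_class == LOW_SUPPORT

    def test_columns_outside_regions_skipped(self, rng):
        template = random_dna(rng, 100)
        alt = template[:80] + ("C" if template[80] != "C" else "T") + template[81:]
        aln = _aln([template] * 3 + [alt] * 2)
        assert call_variants(aln, [(10, 40)]) == []
        assert len(call_variants(aln, [(10, 40)], report_all=True)) == 1

    def test_planted_deletion_called_as_indel(self, rng):
        template = random_dna(rng, 120)
        deleted = template[:60] + template[62:]
        aln = _aln([template] * 4 + [deleted] * 2)
        calls = call_variants(aln, [(55, 70, "target_site")])
        assert len(calls) == 2
        for c in calls:
            assert c.vtype == INDEL
            assert c.support_class == CANDIDATE_TRUE
            assert c.alt_alleles == {"-": 2}
            # gap placement may shift within a repeat run of the template
            assert 55 <= c.consensus_pos < 70

    def test_allele_counts_conserve_depth(self, rng):
        template = random_dna(rng, 80)
        alt = template[:30] + ("A" if template[30] != "A" else "C") + template[31:]
        aln = _aln([template] * 4 + [alt] * 2)
        for c in call_variants(aln, [(0, 80)]):
            col = aln.columns[c.column]
            assert c.ref_count + sum(c.alt_alleles.values()) == col.depth

    def test_noise_free_cluster_has_no_calls(self, rng):
        template = random_dna(rng, 150)
        aln = _aln([template] * 6)
        assert call_variants(aln, [(0, 150)]) == []


class TestMirnaPositionMapping:
    def _call(self, pos):
        from estmir.variants import VariantCall
        return VariantCall(cluster_id="c", column=0, consensus_pos=pos,
                           anchor_pos=pos, insertion_ordinal=0,
                           ref_allele="A", alt_alleles={"G": 2}, ref_count=3,
                           vtype=SNP, support_class=CANDIDATE_TRUE)

    def test_target_site_position_12_critical(self):
        # site span [100, 121): miRNA position 12 pairs coordinate 109
        c = self._call(109)
        assert map_to_mirna_position(c, (100, 121), "target_site") == 12
        assert c.critical and not c.cleavage_site

    def test_position_15_not_critical(self):
        c = self._call(106)
        assert map_to_mirna_position(c, (100, 121), "target_site") == 15
        assert not c.critical

    def test_cleavage_positions(self):
        for mirna_pos in (10, 11):
            c = self._call(121 - mirna_pos)
            map_to_mirna_position(c, (100, 121), "target_site")
            assert c.cleavage_site and c.critical

    def test_mature_region_direct_mapping(self):
        c = self._call(104)
        assert map_to_mirna_position(c, (100, 121), "mature_region") == 5

    def test_exhaustive_round_trip_20nt(self):
        span = (200, 220)
        for coord in range(*span):
            c = self._call(coord)
            pos = map_to_mirna_position(c, span, "target_site")
            assert span[1] - pos == coord
            assert 1 <= pos <= 20

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            map_to_mirna_position(self._call(99), (100, 121), "target_site")


class TestPrecursorVariantImpact:
    def _accepted_candidate(self, seed=0):
        rng = random.Random(seed)
        mature = "".join(rng.choice("ACGU") for _ in range(21))
        hp = build_hairpin(mature, nm_star=0, loop_len=8, rng=rng)
        left = random_dna(rng, 50)
        est = left + rna_to_dna(hp["sequence"]) + random_dna(rng, 50)
        m_lo = len(left) + hp["mature_span"][0]
        hit = Hit("sp-miR1", "e", m_lo, m_lo + 21, SENSE, 0, ())
        cand = extract_candidate(est, hit)
        offset = hit.start - cand.mature_span[0]
        return cand, offset

    def _call_at(self, pos, ref, alt, n_alt=2):
        from estmir.variants import VariantCall
        return VariantCall(cluster_id="c", column=0, consensus_pos=pos,
                           anchor_pos=pos, insertion_ordinal=0,
                           ref_allele=ref, alt_alleles={alt: n_alt},
                           ref_count=4, vtype=SNP,
                           support_class=CANDIDATE_TRUE)

    def test_identical_alleles_zero_ddg(self):
        cand, offset = self._accepted_candidate()
        pos = offset + 5
        ref = cand.sequence[5]
        impact = precursor_variant_impact(
            cand, self._call_at(pos, rna_to_dna(ref), rna_to_dna(ref)),
            precursor_offset=offset)
        assert impact.ddG == 0.0
        assert impact.structure_ref == impact.structure_alt

    def test_allele_swap_flips_sign_exactly(self):
        """Recomputing the impact from the alt-substituted precursor with the
        alleles exchanged gives exactly -ddG."""
        cand, offset = self._accepted_candidate()
        ms = cand.mature_span[0]
        pos = offset + ms + 11          # inside the mature: stem-disrupting
        ref_base = cand.sequence[ms + 11]
        alt_base = "C" if ref_base != "C" else "G"
        fwd = precursor_variant_impact(
            cand, self._call_at(pos, rna_to_dna(ref_base), alt_base),
            precursor_offset=offset)
        alt_seq = cand.sequence[:ms + 11] + alt_base + cand.sequence[ms + 12:]
        swapped = type(cand)(**{**vars(cand), "sequence": alt_seq})
        back = precursor_variant_impact(
            swapped, self._call_at(pos, alt_base, rna_to_dna(ref_base)),
            precursor_offset=offset)
        assert back.ddG == -fwd.ddG
        assert fwd.dG_alt == back.dG_ref

    def test_stem_breaking_substitution_destabilizes(self):
        cand, offset = self._accepted_candidate(seed=4)
        ms = cand.mature_span[0]
        # break a GC pair mid-mature if possible, else any paired position
        pos_rel = next(i for i in range(ms + 4, ms + 18)
                       if cand.structure[i] in "()")
        ref_base = cand.sequence[pos_rel]
        alt_base = {"G": "C", "C": "G", "A": "C", "U": "G"}[ref_base]
        impact = precursor_variant_impact(
            cand, self._call_at(offset + pos_rel, ref_base, alt_base),
            precursor_offset=offset)
        assert impact.ddG > 0

    def test_call_outside_precursor_rejected(self):
        cand, offset = self._accepted_candidate()
        with pytest.raises(ValueError, match="outside"):
            precursor_variant_impact(cand, self._call_at(offset - 5, "A", "G"),
                                     precursor_offset=offset)
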