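"""Protospacer enumeration, RFLP-site attachment, ranking, digest prediction."""

import pytest

from crisprflp import (
    MotifHit,
    RestrictionEnzyme,
    attach_rflp_sites,
    design_guides,
    enumerate_protospacers,
    predict_digest,
    rank_candidates,
)

from conftest import random_dna, revcomp


def brute_force_candidates(seq):
    """Oracle: scan every position for GG / CC dinucleotides directly."""
    out = set()
    for i in range(len(seq) - 1):
        if seq[i : i + 2] == "GG" and i >= 21 and i + 2 <= len(seq):
            s = i - 21  # PAM = [s+20, s+23) with GG at its last two bases
            out.add(("+", s, s + 20, s + 17))
        if seq[i : i + 2] == "CC" and i + 23 <= len(seq):
            out.add(("-", i + 3, i + 23, i + 6))
    return out


class TestEnumerateProtospacers:
    def test_single_plus_strand_candidate(self):
        seq = "A" * 20 + "TGG"
        (cand,) = enumerate_protospacers(seq)
        assert (cand.strand, cand.start, cand.end) == ("+", 0, 20)
        assert cand.pam == "TGG"
        assert cand.cut_boundary == 17
        assert cand.protospacer == "A" * 20

    def test_both_strand_enumeration(self):
        seq = "CCG" + "A" * 20 + "AGG"  # 26 nt
        cands = enumerate_protospacers(seq)
        assert len(cands) == 2
        plus = next(c for c in cands if c.strand == "+")
        minus = next(c for c in cands if c.strand == "-")
        assert (plus.start, plus.end, plus.cut_boundary) == (3, 23, 20)
        assert (minus.start, minus.end, minus.cut_boundary) == (3, 23, 6)
        # guide-oriented protospacer of the minus candidate is the revcomp
        assert minus.protospacer == revcomp(seq[3:23])
        assert minus.pam == revcomp(seq[0:3])

    def test_sequence_without_g_or_c_yields_nothing(self):
        assert enumerate_protospacers("AT" * 30) == []

    def test_short_sequence_yields_empty_list(self):
        assert enumerate_protospacers("ACGTACGT") == []

    def test_agrees_with_dinucleotide_brute_force_on_random_1kb(self, rng):
        seq = random_dna(rng, 1000)
        got = {
            (c.strand, c.start, c.end, c.cut_boundary)
            for c in enumerate_protospacers(seq)
        }
        assert got == brute_force_candidates(seq)

    def test_reverse_complement_mirrors_candidate_set(self, rng):
        seq = random_dna(rng, 400)
        L = len(seq)
        fwd = enumerate_protospacers(seq)
        rev = enumerate_protospacers(revcomp(seq))
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (flip[c.strand], L - c.end, L - c.start, c.protospacer, c.pam)
            for c in rev
        }
        assert {
            (c.strand, c.start, c.end, c.protospacer, c.pam) for c in fwd
        } == mirrored


class TestAttachRflpSites:
    def _cand(self, seq="A" * 20 + "TGG"):
        (c,) = enumerate_protospacers(seq)
        return c  # cut boundary 17

    def test_motif_strictly_crossing_cut_is_attached(self):
        # XcmI-style: 15-nt motif whose final TGG serves as the PAM.
        # Guide at [x-8, x+12), cut c = x+9, motif [x, x+15): x = 8.
        seq = "T" * 8 + "CCA" + "T" * 9 + "TGG" + "T" * 8
        enz = RestrictionEnzyme("XcmI", "CCANNNNNNNNNTGG", 8)
        cands = design_guides(seq, [enz])
        plus = [c for c in cands if c.strand == "+" and c.is_rflp_compatible]
        assert any(
            c.start == 0 and c.cut_boundary == 17 and "XcmI" in c.enzyme_names
            for c in plus
        )

    @pytest.mark.parametrize("interval", [(17, 23), (11, 17)])
    def test_motif_abutting_cut_boundary_not_attached(self, interval):
        cand = self._cand()
        hit = MotifHit("E", interval[0], interval[1], "+")
        (out,) = attach_rflp_sites([cand], [hit])
        assert out.rflp_hits == ()
        assert not out.is_rflp_compatible

    def test_motif_spanning_cut_attached_and_multiple_enzymes_kept(self):
        cand = self._cand()
        hits = [MotifHit("E1", 12, 22, "+"), MotifHit("E2", 16, 20, "+"),
                MotifHit("E3", 30, 40, "+")]
        (out,) = attach_rflp_sites([cand], hits)
        assert out.enzyme_names == ("E1", "E2")


class TestRankCandidates:
    def _mk(self, start, rflp, dist, strand="+"):
        from crisprflp import GuideCandidate

        hits = ((("E", MotifHit("E", start + 10, start + 20, "+")),)
                if rflp else ())
        return GuideCandidate(
            record="r", protospacer="A" * 20, strand=strand,
            start=start, end=start + 20, pam="AGG",
            cut_boundary=start + 17, rflp_hits=hits,
            distance_from_cds_start=dist,
        )

    def test_nearer_cds_start_ranks_first(self):
        a = self._mk(300, True, 300)
        b = self._mk(12, True, 12)
        assert rank_candidates([a, b])[0].distance_from_cds_start == 12

    def test_rflp_compatibility_dominates_distance(self):
        near_no_rflp = self._mk(5, False, 5)
        far_rflp = self._mk(500, True, 500)
        assert rank_candidates([near_no_rflp, far_rflp])[0].is_rflp_compatible

    def test_domain_overlap_beats_distance_among_rflp(self):
        near = self._mk(12, True, 12)
        far = self._mk(300, True, 300)
        ranked = rank_candidates([near, far], domain_intervals=[(295, 330)])
        assert ranked[0].distance_from_cds_start == 300
        assert ranked[0].domain_overlap

    def test_malformed_domain_interval_is_error(self):
        with pytest.raises(ValueError, match="malformed"):
            rank_candidates([self._mk(0, True, 0)], domain_intervals=[(10, 10)])

    def test_tie_break_is_deterministic(self):
        a = self._mk(50, True, 50, strand="-")
        b = self._mk(50, True, 50, strand="+")
        ranked = rank_candidates([a, b])
        assert [c.strand for c in ranked] == ["+", "-"]


class TestPredictDigest:
    ECO = RestrictionEnzyme("TestEnz", "GAATTC", 1)

    def test_no_hits_returns_whole_amplicon(self):
        frags, unique = predict_digest("AT" * 100, self.ECO)
        assert frags == [200]
        assert unique is False

    def test_single_cut_fragments_and_uniqueness(self):
        # implant so the cut (site start + 1) falls at 120 of a 300-mer
        seq = list("AT" * 150)
        seq[119:125] = "GAATTC"
        frags, unique = predict_digest("".join(seq), self.ECO)
        assert frags == [180, 120]
        assert unique is True

    def test_two_cuts_three_fragments(self):
        seq = list("AT" * 150)
        seq[99:105] = "GAATTC"
        seq[199:205] = "GAATTC"
        frags, unique = predict_digest("".join(seq), self.ECO)
        assert frags == [100, 100, 100]
        assert unique is False

    def test_cut_outside_amplicon_reported_uncut_with_warning(self):
        enz = RestrictionEnzyme("BsrI", "ACTGG", 6)
        seq = "AT" * 20 + "ACTGG"  # cut position would be 46 = len, outside
        with pytest.warns(UserWarning, match="uncut"):
            frags, unique = predict_digest(seq, enz)
        assert frags == [45]

    def test_fragments_sum_to_amplicon_length_on_random_sequences(
        self, catalog, rng
    ):
        for _ in range(20):
            seq = random_dna(rng, 500, gc=0.6)
            for enz in catalog:
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    frags, _ = predict_digest(seq, enz)
                assert sum(frags) == 500
                assert sorted(frags, reverse=True) == frags
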