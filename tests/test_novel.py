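"""Hairpin evaluation and the novel-miRNA filter stack."""

import numpy as np
import pytest

from pollenmir.mapping import GenomeHit, MappedTag
from pollenmir.novel import (evaluate_hairpin, predict_novel_mirnas,
                             repeat_similar)
from pollenmir.seqs import random_seq, revcomp
from pollenmir.synthetic import _make_hairpin


def _planted(seed=0, arm="5p"):
    rng = np.random.default_rng(seed)
    hp = _make_hairpin(rng, 21, arm)
    left, right = random_seq(rng, 200), random_seq(rng, 200)
    genome = {"c": left + hp["locus"] + right}
    m0 = len(left) + hp["mature_off"]
    return genome, hp, m0


class TestEvaluateHairpin:
    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_planted_hairpin_accepted_with_correct_arm(self, arm):
        genome, hp, m0 = _planted(3, arm)
        ev = evaluate_hairpin(genome, "c", m0, m0 + 21, "+")
        assert ev.accepted
        assert ev.candidate.arm == arm
        assert ev.candidate.mature_seq == hp["mature"]
        assert ev.candidate.n_paired >= 16

    def test_minus_strand_locus(self):
        genome, hp, m0 = _planted(4, "5p")
        flipped = {"c": revcomp(genome["c"])}
        n = len(genome["c"])
        s0 = n - (m0 + 21)
        ev = evaluate_hairpin(flipped, "c", s0, s0 + 21, "-")
        assert ev.accepted and ev.candidate.mature_seq == hp["mature"]

    def test_star_matches_plant(self):
        genome, hp, m0 = _planted(5, "5p")
        ev = evaluate_hairpin(genome, "c", m0, m0 + 21, "+")
        # predicted star (2-nt 3' overhang geometry) overlaps the planted
        # star arm almost exactly
        assert ev.accepted
        star = ev.candidate.star_seq
        assert len(star) in range(19, 24)
        assert star in hp["locus"] or hp["star"] in star or star in hp["star"]

    def test_unstructured_sequence_rejected(self):
        rng = np.random.default_rng(12)
        # A/C-only sequence cannot pair with itself at all
        genome = {"c": "".join(rng.choice(list("AC"), size=500))}
        ev = evaluate_hairpin(genome, "c", 240, 261, "+")
        assert not ev.accepted

    def test_tag_spanning_loop_rejected(self):
        genome, hp, m0 = _planted(6, "5p")
        # shift the window so the "mature" covers the end of the arm and
        # the terminal loop
        ev = evaluate_hairpin(genome, "c", m0 + 15, m0 + 36, "+")
        assert not ev.accepted

    def test_contig_edge_rejected(self):
        rng = np.random.default_rng(7)
        hp = _make_hairpin(rng, 21, "5p")
        genome = {"c": hp["locus"][hp["mature_off"]:]}   # no upstream flank
        ev = evaluate_hairpin({"c": genome["c"][:25]}, "c", 0, 21, "+")
        assert not ev.accepted and ev.reason == "edge"


class TestRepeatScreen:
    def test_diverged_copy_detected(self):
        rng = np.random.default_rng(8)
        consensus = random_seq(rng, 72)
        copy = list(consensus)
        for p in (10, 30, 50):
            copy[p] = "A" if copy[p] != "A" else "C"
        assert repeat_similar("".join(copy)[3:27], {"r": consensus})

    def test_reverse_orientation_detected(self):
        rng = np.random.default_rng(9)
        consensus = random_seq(rng, 72)
        assert repeat_similar(revcomp(consensus[10:34]), {"r": consensus})

    def test_unrelated_sequence_passes(self):
        rng = np.random.default_rng(10)
        assert not repeat_similar(random_seq(rng, 24),
                                  {"r": random_seq(rng, 72)})


def _mk_tag(seq, hits, counts):
    return MappedTag(seq, counts, sum(counts.values()),
                     [GenomeHit(*h) for h in hits])


class TestFilterStack:
    def _setup(self, seed=20):
        genome, hp, m0 = _planted(seed, "5p")
        mature = hp["mature"]
        star = hp["star"]
        s0 = genome["c"].find(star)
        return genome, mature, star, m0, s0

    def test_multi_locus_rejected_at_f1(self):
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+"),
                               ("c", 500, 521, "+")], {"UNM": 9, "BCP": 2})
        novel, flags = predict_novel_mirnas([tag], genome, [tag])
        assert novel == []
        assert flags.iloc[0]["reason"] == "multiple_loci"

    def test_low_abundance_rejected_at_f2(self):
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+")],
                      {"UNM": 2, "BCP": 2})          # total 4 < 5
        novel, flags = predict_novel_mirnas([tag], genome, [tag])
        assert novel == []
        assert flags.iloc[0]["reason"] == "low_abundance"
        assert flags.iloc[0]["f1_single_locus"] is True \
            or flags.iloc[0]["f1_single_locus"] == True  # noqa: E712

    def test_total_exactly_five_kept(self):
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+")],
                      {"UNM": 3, "BCP": 2})
        novel, _ = predict_novel_mirnas([tag], genome, [tag])
        assert len(novel) == 1

    def test_antisense_coverage_rejected_at_f3(self):
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+")], {"UNM": 9, "BCP": 3})
        anti = _mk_tag(revcomp(mature), [("c", m0, m0 + 21, "-")], {"UNM": 1})
        novel, flags = predict_novel_mirnas([tag, anti], genome, [tag, anti])
        row = flags[flags["sequence"] == mature].iloc[0]
        assert row["reason"] == "both_strands"
        assert all(nm.hairpin.mature_seq != mature for nm in novel)

    def test_single_library_with_star_passes_f7(self):
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+")], {"UNM": 30, "BCP": 0})
        star_tag = _mk_tag(star, [("c", s0, s0 + 21, "+")], {"UNM": 5, "BCP": 0})
        novel, _ = predict_novel_mirnas([tag, star_tag], genome,
                                        [tag, star_tag])
        assert len(novel) == 1           # mature + star collapse to one locus
        assert novel[0].star_detected
        assert novel[0].hairpin.mature_seq == mature

    def test_single_library_without_star_rejected(self):
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+")], {"UNM": 30, "BCP": 0})
        novel, flags = predict_novel_mirnas([tag], genome, [tag])
        assert novel == []
        assert flags.iloc[0]["reason"] == "single_library_no_star"

    def test_repeat_homology_rejected_at_f5(self):
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+")], {"UNM": 9, "BCP": 3})
        library = {"rep": genome["c"][m0 - 20: m0 + 60]}
        novel, flags = predict_novel_mirnas([tag], genome, [tag],
                                            repeat_library=library)
        assert novel == []
        assert flags.iloc[0]["reason"] == "repeat_homology"

    def test_target_requirement_f8(self):
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+")], {"UNM": 9, "BCP": 3})
        novel, flags = predict_novel_mirnas([tag], genome, [tag],
                                            target_checker=lambda s: False)
        assert novel == []
        assert flags.iloc[0]["reason"] == "no_target"
        novel, _ = predict_novel_mirnas([tag], genome, [tag],
                                        target_checker=lambda s: True)
        assert len(novel) == 1

    def test_relaxing_min_count_grows_survivors(self):
        """Filter monotonicity: a looser abundance cutoff never loses
        survivors."""
        genome, mature, star, m0, s0 = self._setup()
        tag = _mk_tag(mature, [("c", m0, m0 + 21, "+")], {"UNM": 2, "BCP": 2})
        strict, _ = predict_novel_mirnas([tag], genome, [tag], min_count=5)
        loose, _ = predict_novel_mirnas([tag], genome, [tag], min_count=3)
        assert {n.hairpin.mature_seq for n in strict} <= \
            {n.hairpin.mature_seq for n in loose}
        assert len(loose) == 1

    def test_ids_follow_genomic_order(self):
        g1, hp1, m1 = _planted(21, "5p")
        rng = np.random.default_rng(99)
        hp2 = _make_hairpin(rng, 21, "5p")
        genome = {"c": g1["c"] + random_seq(rng, 100) + hp2["locus"]
                  + random_seq(rng, 200)}
        m2 = len(g1["c"]) + 100 + hp2["mature_off"]
        t1 = _mk_tag(hp1["mature"], [("c", m1, m1 + 21, "+")],
                     {"UNM": 9, "BCP": 3})
        t2 = _mk_tag(hp2["mature"], [("c", m2, m2 + 21, "+")],
                     {"UNM": 90, "BCP": 30})
        novel, _ = predict_novel_mirnas([t2, t1], genome, [t1, t2])
        assert [n.mirna_id for n in novel] == ["miR-N1", "miR-N2"]
        assert novel[0].hairpin.start < novel[1].hairpin.start
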