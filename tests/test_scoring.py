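"""Scoring system: admission, window widths, intron ratings, partial and
global scores, the filter cascade, and best-match selection."""

import pytest

from exhom.alignment import AlignmentStats, inject_intron_markers
from exhom.scoring import (DEFAULT_CONFIGS, DistanceConfig, ExonMatchCandidate,
                           Orthopair, admit_isoform_pair, apply_bonafide,
                           apply_filters, global_score, mark_reciprocal,
                           score_intron_conservation, select_best_match,
                           window_width)


def stats(sim_q, sim_t):
    return AlignmentStats(identity_pct_q=0, identity_pct_t=0,
                          similarity_pct_q=sim_q, similarity_pct_t=sim_t,
                          gaps_pct_q=0, gaps_pct_t=0)


class TestAdmission:
    cfg = DEFAULT_CONFIGS["short"]  # prot_sim 0.25

    @pytest.mark.parametrize("sim_q,sim_t,expected", [
        (30, 26, True),    # both above cut-off
        (55, 10, True),    # one above twice the cut-off
        (10, 55, True),
        (30, 20, False),   # one side below, neither doubled
        (25, 25, True),    # boundary inclusive
        (49.9, 10, False),
    ])
    def test_cutoff_a(self, sim_q, sim_t, expected):
        assert admit_isoform_pair(stats(sim_q, sim_t), self.cfg) is expected


class TestWindowWidth:
    @pytest.mark.parametrize("sim,gaps,expected", [
        (30, 0, 10), (30.1, 0, 8),
        (49.9, 0, 8), (50, 0, 6),
        (69.9, 0, 6), (70, 0, 4),
        (79.9, 0, 4), (80, 0, 3),
        (85, 5, 3),
        (89.9, 0, 3), (90, 0, 2),
        (95, 35, 10),           # gap clause dominates
        (95, 29.9, 2),
        (10, 0, 10),
    ])
    def test_printed_table(self, sim, gaps, expected):
        assert window_width(sim, gaps) == expected

    def test_gap_context_bonus_rounds_half_up(self):
        # base 4, gaps 4 left / 2 right -> mean 3.0 -> width 7
        assert window_width(75, 0, gaps_left=4, gaps_right=2) == 7
        # mean 2.5 rounds up to 3
        assert window_width(75, 0, gaps_left=3, gaps_right=2) == 7


class TestIntronConservation:
    def _ipa(self, gq, gt, introns_q, introns_t):
        return inject_intron_markers(gq, gt, introns_q, introns_t)

    def test_same_column_same_phase_rates_ten(self):
        ipa = self._ipa("A" * 40, "A" * 40, [(20, 1)], [(20, 1)])
        ic = score_intron_conservation(ipa, 0)
        assert ic.value == 10.0 and ic.matched_target_intron == 0

    def test_offset_subtracted_within_window(self):
        # dissimilar local context (A vs D) -> width 10, so offset 3 matches
        ipa = self._ipa("A" * 40, "D" * 40, [(20, 2)], [(17, 2)])
        ic = score_intron_conservation(ipa, 0)
        assert ic.value == 7.0 and ic.column_offset == 3

    def test_no_marker_in_window_rates_zero(self):
        # identical context -> width 2; nearest target intron is 5 away
        ipa = self._ipa("A" * 40, "A" * 40, [(20, 0)], [(25, 0)])
        ic = score_intron_conservation(ipa, 0)
        assert ic.value == 0.0 and ic.matched_target_intron is None

    def test_phase_mismatch_rates_minus_ten(self):
        ipa = self._ipa("A" * 40, "A" * 40, [(20, 0)], [(20, 1)])
        assert score_intron_conservation(ipa, 0).value == -10.0

    def test_tie_prefers_smaller_offset_then_upstream(self):
        ipa = self._ipa("D" * 40, "A" * 40, [(20, 0)], [(18, 0), (22, 0)])
        ic = score_intron_conservation(ipa, 0)
        assert ic.matched_target_intron == 0 and ic.value == 8.0


class TestGlobalScore:
    def test_internal_maximum_is_one(self):
        assert global_score(0.25, 0.25, 0.2, 0.15, 0.15, "internal") == 1.0

    def test_first_exon_rescaled_by_0_6(self):
        assert global_score(None, 0.25, 0.2, None, 0.15, "first") == 1.0
        assert global_score(None, 0.13, 0.1, None, 0.05, "first") == \
            pytest.approx((0.13 + 0.1 + 0.05) / 0.6)

    def test_last_exon_rescaled_by_0_6(self):
        assert global_score(0.25, None, 0.2, 0.15, None, "last") == 1.0

    def test_all_zero(self):
        assert global_score(0.0, 0.0, 0.0, 0.0, 0.0, "internal") == 0.0

    def test_negative_intron_scores_clamped_at_zero(self):
        assert global_score(-0.25, -0.25, 0.0, 0.0, 0.0, "internal") == 0.0

    def test_single_exon_scored_on_sequence_alone(self):
        assert global_score(None, None, 0.1, None, None, "single") == 0.5


def make_candidate(s1=0.25, s2=0.25, s3=0.2, s4=0.15, s5=0.15,
                   position_class="internal", qlen=60, tlen=60,
                   query_exon="q1", target_exon="t1", target_gene="gT"):
    return ExonMatchCandidate(
        query_exon=query_exon, query_gene="gQ", query_species="A",
        target_exon=target_exon, target_gene=target_gene, target_species="B",
        query_isoform="qi", target_isoform="ti", position_class=position_class,
        s1=s1, s2=s2, s3=s3, s4=s4, s5=s5,
        global_score=global_score(s1, s2, s3, s4, s5, position_class),
        query_len_nt=qlen, target_len_nt=tlen)


class TestFilters:
    medium = DEFAULT_CONFIGS["medium"]  # ex_seq 0.3 -> thresholds 0.06 / 0.045

    def test_thresholds_follow_printed_multipliers(self):
        c = make_candidate(s3=0.06, s4=0.045, s5=0.045)
        assert apply_filters(c, self.medium)["ex_seq"] is True
        c2 = make_candidate(s3=0.0599, s4=0.045, s5=0.045)
        assert apply_filters(c2, self.medium)["ex_seq"] is False
        c3 = make_candidate(s3=0.06, s4=0.0449)
        assert apply_filters(c3, self.medium)["neighbor_seq"] is False

    def test_intron_filter_requires_both_sides_positive(self):
        c = make_candidate(s1=0.25, s2=-0.1)
        assert apply_filters(c, self.medium)["intron"] is False
        cfg1 = DistanceConfig("x", 0.2, 1, 0.3, 0.6)
        assert apply_filters(make_candidate(s1=0.25, s2=-0.1), cfg1)["intron"] is True
        cfg0 = DistanceConfig("x", 0.2, 0, 0.3, 0.6)
        assert apply_filters(make_candidate(s1=-0.2, s2=-0.1), cfg0)["intron"] is True

    def test_terminal_exons_evaluate_existing_side_only(self):
        first = make_candidate(s1=None, s4=None, position_class="first")
        v = apply_filters(first, self.medium)
        assert v["intron"] is True and v["neighbor_seq"] is True

    def test_length_ratio(self):
        c = make_candidate(qlen=30, tlen=60)  # ratio 0.5 < 0.6
        assert apply_filters(c, DEFAULT_CONFIGS["short"])["ex_len"] is False
        assert apply_filters(c, DEFAULT_CONFIGS["long"])["ex_len"] is True


class TestBestMatch:
    def test_passing_candidate_beats_higher_scoring_failure(self):
        good = make_candidate(target_exon="tGood", s3=0.08)
        good.global_score = 0.5
        apply_filters(good, DEFAULT_CONFIGS["long"])
        bad = make_candidate(target_exon="tBad", s3=0.01)
        bad.global_score = 0.9
        apply_filters(bad, DEFAULT_CONFIGS["long"])
        assert good.passes and not bad.passes
        records = select_best_match([bad, good])
        assert len(records) == 1
        assert records[0].target_exon == "tGood" and records[0].status == "orthopair"

    def test_highest_score_among_passing(self):
        a = make_candidate(target_exon="tA")
        a.global_score = 0.91
        b = make_candidate(target_exon="tB")
        b.global_score = 0.84
        for c in (a, b):
            apply_filters(c, DEFAULT_CONFIGS["long"])
        assert select_best_match([b, a])[0].target_exon == "tA"

    def test_no_passing_candidate_becomes_best_hit(self):
        c = make_candidate(s3=0.0, s4=0.0, s5=0.0)
        apply_filters(c, DEFAULT_CONFIGS["short"])
        rec = select_best_match([c])[0]
        assert rec.status == "best_hit"
        assert "ex_seq" in rec.fail_reasons

    def test_tie_broken_by_s3_then_lexicographic(self):
        a = make_candidate(target_exon="tB", s3=0.2)
        b = make_candidate(target_exon="tA", s3=0.18, s4=0.17)  # same global? no
        a.global_score = b.global_score = 0.7
        for c in (a, b):
            apply_filters(c, DEFAULT_CONFIGS["long"])
        assert select_best_match([a, b])[0].target_exon == "tB"  # higher s3
        c1 = make_candidate(target_exon="tB")
        c2 = make_candidate(target_exon="tA")
        for c in (c1, c2):
            apply_filters(c, DEFAULT_CONFIGS["long"])
        assert select_best_match([c1, c2])[0].target_exon == "tA"  # lexicographic

    def test_one_record_per_query_exon_and_target_gene(self):
        cands = [make_candidate(target_exon=f"t{i}", target_gene=g)
                 for g in ("g1", "g2") for i in range(3)]
        for c in cands:
            apply_filters(c, DEFAULT_CONFIGS["long"])
        records = select_best_match(cands)
        assert len(records) == 2
        assert {r.target_gene for r in records} == {"g1", "g2"}


class TestBonafide:
    def _models(self):
        from exhom.annotation import CodingExon, GeneModel

        models = {}
        for sp, gene_id, exon in (("A", "gA", "chr1:1-30:+"), ("B", "gB", "chr2:1-30:+")):
            g = GeneModel(gene_id=gene_id, species=sp)
            g.exons[exon] = CodingExon(exon_id=exon, chrom="c", start=0, end=30,
                                       strand="+", cds_start=0, cds_end=30, gene_id=gene_id)
            models[sp] = {gene_id: g}
        return models

    def test_bonafide_overrides_inferred(self):
        inferred = select_best_match([make_candidate()])
        inferred[0].query_exon = "chr1:1-30:+"
        inferred[0].query_gene = "gA"
        inferred[0].target_gene = "gB"
        merged, warnings = apply_bonafide(
            inferred, [("A", "chr1:1-30:+", "B", "chr2:1-30:+")], self._models())
        assert warnings == []
        mine = [r for r in merged if r.query_species == "A"]
        assert len(mine) == 1 and mine[0].source == "bonafide"
        assert mine[0].target_exon == "chr2:1-30:+"
        # reverse direction added too
        assert any(r.query_species == "B" and r.source == "bonafide" for r in merged)

    def test_unknown_exon_skipped_with_warning(self):
        merged, warnings = apply_bonafide([], [("A", "chr9:1-5:+", "B", "chr2:1-30:+")],
                                          self._models())
        assert merged == [] and len(warnings) == 1

    def test_empty_bonafide_is_identity(self):
        records = select_best_match([make_candidate()])
        merged, warnings = apply_bonafide(list(records), [], self._models())
        assert [r.query_exon for r in merged] == [r.query_exon for r in records]


def test_reciprocal_marking():
    fwd = Orthopair("A", "e1", "g1", "B", "e2", "g2", 0.25, 0.25, 0.2, 0.15, 0.15,
                    1.0, "orthopair", "internal")
    rev = Orthopair("B", "e2", "g2", "A", "e1", "g1", 0.25, 0.25, 0.2, 0.15, 0.15,
                    1.0, "orthopair", "internal")
    lone = Orthopair("A", "e9", "g1", "B", "e8", "g2", None, None, 0.2, None, None,
                     1.0, "orthopair", "single")
    mark_reciprocal([fwd, rev, lone])
    assert fwd.reciprocal and rev.reciprocal and not lone.reciprocal
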