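"""Target-site scoring, slice-position arithmetic, t-plot categories,
degradome mapping and target calling."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from paumir.annotation import revcomp
from paumir.degradome import (
    ScoringParams,
    SignatureProfile,
    TargetAlignment,
    alignment_text,
    call_targets,
    categorize_event,
    map_degradome_tags,
    predict_slice_position,
    scan_sites,
    score_gapped_alignment,
    score_site,
    t_plot_series,
)

MIRNA = "ACGTGACTGATCGTAGCTAGC"  # 21 nt
SITE = revcomp(MIRNA)


def _brute_force_scan(mirna, transcript, params=ScoringParams()):
    out = []
    for i in range(len(transcript) - len(mirna) + 1):
        scored = score_site(mirna, transcript[i : i + len(mirna)], params)
        if scored is not None:
            out.append((i + 1, scored[0], scored[1]))
    return out


class TestScoreSite:
    def test_perfect_complement_scores_zero(self):
        score, pairing = score_site(MIRNA, SITE)
        assert score == 0.0
        assert pairing == "|" * 21

    def test_single_gu_wobble_adds_half_a_point(self):
        # miRNA position 5 is G; replace the paired site C by T -> G:U
        assert MIRNA[4] == "G"
        site = list(SITE)
        site[21 - 5] = "T"
        score, pairing = score_site(MIRNA, "".join(site))
        assert score == 0.5
        assert pairing[4] == "o"
        assert pairing.count("|") == 20

    def test_mismatch_at_position_ten_rejects_regardless_of_score(self):
        site = list(SITE)
        site[21 - 10] = "A" if SITE[21 - 10] != "A" else "C"  # break the pair
        assert score_site(MIRNA, "".join(site)) is None

    def test_gu_at_the_cleavage_site_also_rejects(self):
        # position 11 of the miRNA is T; a site G there makes a U:G wobble,
        # which does not count as a pair at the cleavage site
        assert MIRNA[10] == "T"
        site = list(SITE)
        site[21 - 11] = "G"
        assert score_site(MIRNA, "".join(site)) is None

    def test_score_above_four_rejects(self):
        site = list(SITE)
        for i in (0, 1, 2, 3, 4):  # five mismatches far from the slice site
            site[20 - i] = "A" if site[20 - i] != "A" else "C"
        assert score_site(MIRNA, "".join(site)) is None

    def test_invalid_characters_are_an_error(self):
        with pytest.raises(ValueError):
            score_site(MIRNA, "N" * 21)

    def test_gapped_alignment_charges_two_per_gap(self):
        mg = MIRNA[:15] + "-" + MIRNA[15:]
        sg = SITE[::-1][:15] + "G" + SITE[::-1][15:]
        scored = score_gapped_alignment(mg, sg)
        assert scored is not None
        assert scored[0] == 2.0

    def test_gap_opposite_the_cleavage_site_rejects(self):
        # site-side gap in the column facing miRNA position 10
        sg = SITE[::-1][:9] + "-" + SITE[::-1][10:]
        assert score_gapped_alignment(MIRNA, sg) is None


class TestSlicePosition:
    def test_21mer_site_at_101(self):
        aln = TargetAlignment("m", MIRNA, "t", 101, 121, 0.0, "|" * 21)
        assert predict_slice_position(aln) == 112

    def test_20mer_site_at_1(self):
        aln = TargetAlignment("m", MIRNA[:20], "t", 1, 20, 0.0, "|" * 20)
        assert predict_slice_position(aln) == 11

    def test_gapped_alignment_matches_the_pairing_walk(self):
        # site carries one extra (bulged) base between miRNA positions 15/16
        mg = MIRNA[:15] + "-" + MIRNA[15:]
        sg = revcomp(MIRNA)[::-1][:15] + "G" + revcomp(MIRNA)[::-1][15:]
        aln = TargetAlignment(
            "m", MIRNA, "t", 101, 122, 2.0,
            "|" * 15 + "-" + "|" * 6, mirna_aln=mg, site_aln=sg,
        )
        # walk oracle: from the site 3' end (transcript 122), consume one
        # site base per non-gap column until miRNA position 10 is reached
        pos, mpos = 122, 0
        for mb, sb in zip(mg, sg):
            if mb != "-":
                mpos += 1
            if mpos == 10 and mb != "-":
                expected = pos
                break
            if sb != "-":
                pos -= 1
        assert predict_slice_position(aln) == expected == 113

    def test_ungapped_slice_sits_inside_the_site(self):
        aln = TargetAlignment("m", MIRNA, "t", 50, 70, 0.0, "|" * 21)
        assert 50 <= predict_slice_position(aln) <= 70


class TestCategories:
    def test_single_peak_is_category_one(self):
        prof = SignatureProfile("t", {10: 50})
        assert categorize_event(10, prof) == "I"

    def test_three_position_profile_declared_rule(self):
        # median over {5, 10, 1} is 5; 5 is not above it -> III
        prof = SignatureProfile("t", {3: 5, 7: 10, 11: 1})
        assert categorize_event(3, prof) == "III"
        assert categorize_event(7, prof) == "I"

    def test_between_median_and_maximum_is_category_two(self):
        prof = SignatureProfile("t", {1: 1, 2: 2, 3: 8, 4: 20})
        assert categorize_event(3, prof) == "II"

    def test_no_signal_means_no_event(self):
        prof = SignatureProfile("t", {10: 5})
        assert categorize_event(11, prof) is None

    def test_categories_stable_under_uniform_scaling(self):
        base = {1: 1, 2: 2, 3: 8, 4: 20, 9: 3}
        for k in (1, 3, 17):
            prof = SignatureProfile("t", {p: c * k for p, c in base.items()})
            assert categorize_event(3, prof) == "II"
            assert categorize_event(4, prof) == "I"
            assert categorize_event(1, prof) == "III"


class TestMapDegradomeTags:
    def test_single_tag_contributes_at_its_five_prime_end(self):
        t = "G" * 100 + SITE[:20] + "C" * 80
        profiles = map_degradome_tags({SITE[:20]: 7}, {"t1": t})
        assert profiles["t1"].abundance == {101: 7}

    def test_unmapped_tag_contributes_nothing(self):
        assert map_degradome_tags({"A" * 20: 5}, {"t1": "G" * 200}) == {}

    def test_multimapping_tag_counted_everywhere_and_flagged(self):
        t1 = "G" * 50 + SITE[:20] + "C" * 30
        t2 = "A" * 10 + SITE[:20] + "T" * 70
        profiles = map_degradome_tags({SITE[:20]: 4}, {"t1": t1, "t2": t2})
        assert profiles["t1"].abundance == {51: 4}
        assert profiles["t2"].abundance == {11: 4}
        assert 51 in profiles["t1"].multimapped
        assert 11 in profiles["t2"].multimapped


class TestScanSites:
    def test_planted_perfect_site_found(self):
        t = "G" * 100 + SITE + "C" * 100
        found = scan_sites(MIRNA, t)
        assert (101, 0.0, "|" * 21) in found

    @given(st.text(alphabet="ACGT", min_size=60, max_size=400), st.data())
    @settings(max_examples=25, deadline=None)
    def test_agrees_with_brute_force_window_scorer(self, transcript, data):
        insert_at = data.draw(st.integers(0, len(transcript) - 1))
        t = transcript[:insert_at] + SITE + transcript[insert_at:]
        assert scan_sites(MIRNA, t) == _brute_force_scan(MIRNA, t)

    def test_short_transcript_yields_nothing(self):
        assert scan_sites(MIRNA, "ACGT") == []


class TestCallTargets:
    def _setup(self, n_noise=0):
        t = "G" * 100 + SITE + "C" * 100
        slice_pos = 101 + 21 - 10
        tags = {t[slice_pos - 1 : slice_pos + 19]: 50}
        for i in range(n_noise):
            tags[t[10 + i * 7 : 30 + i * 7]] = 1
        profiles = map_degradome_tags(tags, {"t1": t})
        return {"t1": t}, profiles, slice_pos

    def test_planted_event_recovered_with_no_noise(self):
        transcripts, profiles, slice_pos = self._setup()
        events = call_targets({"mir": MIRNA}, transcripts, profiles)
        assert len(events) == 1
        e = events[0]
        assert e.slice_position == slice_pos
        assert e.slice_abundance == 50
        assert e.category == "I"

    def test_no_complementary_window_means_no_events(self):
        transcripts, profiles, _ = self._setup()
        assert call_targets({"m": "T" * 21}, transcripts, profiles) == []

    def test_site_above_score_threshold_not_called(self):
        transcripts, profiles, _ = self._setup()
        strict = ScoringParams(max_score=-1.0)
        assert call_targets({"mir": MIRNA}, transcripts, profiles, params=strict) == []

    def test_events_rescore_to_their_stored_penalties(self, small_study):
        truth = small_study["truth"]
        transcripts = small_study["transcripts"]
        profiles = map_degradome_tags(small_study["degradome"], transcripts)
        exclude = {}
        for h in truth.hairpins:
            exclude.setdefault(h.transcript_id, []).append((h.start, h.end))
        events = call_targets(
            truth.mature_sequences(), transcripts, profiles, exclude_regions=exclude
        )
        assert events
        params = ScoringParams()
        for e in events:
            a = e.alignment
            rescored = score_site(a.mirna_seq, a.site_seq, params)
            assert rescored is not None
            assert rescored[0] == a.score and rescored[1] == a.pairing
            penalty = sum(
                {"|": 0.0, "o": params.gu_penalty, "x": params.mismatch_penalty}[c]
                for c in a.pairing
            )
            assert penalty == a.score

    def test_excluded_regions_suppress_self_hits(self, small_study):
        truth = small_study["truth"]
        transcripts = small_study["transcripts"]
        profiles = map_degradome_tags(small_study["degradome"], transcripts)
        exclude = {}
        for h in truth.hairpins:
            exclude.setdefault(h.transcript_id, []).append((h.start, h.end))
        events = call_targets(
            truth.mature_sequences(), transcripts, profiles, exclude_regions=exclude
        )
        for e in events:
            for s, end in exclude.get(e.alignment.transcript_id, ()):
                assert e.alignment.site_end < s or e.alignment.site_start > end


class TestReporting:
    def test_tplot_series_flags_the_slice(self):
        prof = SignatureProfile("t", {5: 3, 12: 50, 30: 1})
        df = t_plot_series(prof, [12])
        assert list(df["position"]) == [5, 12, 30]
        assert list(df["is_slice"]) == [False, True, False]

    def test_alignment_text_contains_both_strands_and_the_score(self):
        from paumir.degradome import CleavageEvent

        aln = TargetAlignment("mir-x", MIRNA, "t1", 101, 121, 0.0, "|" * 21,
                              site_seq=SITE)
        block = alignment_text(CleavageEvent(aln, 112, 50, "I"))
        assert SITE in block and MIRNA[::-1] in block
        assert "score 0" in block and "category I" in block
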