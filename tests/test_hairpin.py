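"""Folding contract, precursor excision, hairpin criteria, star detection."""

from __future__ import annotations

import pytest

from paumir.annotation import revcomp
from paumir.hairpin import (
    FoldResult,
    MeyersCriteria,
    detect_star,
    discover_mirnas,
    evaluate_candidate,
    excise_precursor_windows,
    fold_rna,
    pair_table,
    summarize_candidates,
)
from paumir.preprocess import TagLibrary

ENGINES = ["vienna", "fallback"]


def _ideal_precursor(mature: str, pad: int = 14, loop: str = "CAAGAAGAAC") -> str:
    stem5 = "GCGGCGGCGGCGGC"[:pad] + mature + "CGGCGCCGCGGCCG"[:pad]
    return stem5 + loop + revcomp(stem5)


MATURE = "ACGTGACTGATCGTAGCTAGC"  # 21 nt


class TestFoldRna:
    @pytest.mark.parametrize("engine", ENGINES)
    def test_homopolymer_cannot_pair(self, engine):
        fold = fold_rna("A" * 20, engine=engine)
        assert fold.structure == "." * 20
        assert fold.mfe == 0.0

    @pytest.mark.parametrize("engine", ENGINES)
    def test_gc_stem_with_tetraloop_is_strongly_paired(self, engine):
        seq = "GC" * 12 + "GAAA" + "GC" * 12
        fold = fold_rna(seq, engine=engine)
        assert fold.mfe < -20.0
        assert fold.structure.count("(") >= 8

    def test_hairpin_reversal_preserves_the_pairing_energy(self):
        """Reversing a stem-loop keeps the same set of pairs; under the
        fallback per-pair energy model the MFE is exactly invariant (a
        stacking model is direction-dependent, so the thermodynamic engine
        agrees only approximately)."""
        stem5 = "GCGCGGCCGC"
        seq = stem5 + "GAAA" + revcomp(stem5)
        a = fold_rna(seq, engine="fallback")
        b = fold_rna(seq[::-1], engine="fallback")
        assert a.mfe == b.mfe
        va = fold_rna(seq, engine="vienna")
        vb = fold_rna(seq[::-1], engine="vienna")
        assert va.mfe == pytest.approx(vb.mfe, abs=3.0)

    def test_invalid_characters_are_rejected(self):
        with pytest.raises(ValueError):
            fold_rna("ACGTNNNACGTACGTACGTACGTACGTACGTACGTACGTZ")

    def test_u_and_t_fold_identically(self):
        seq = "GC" * 10 + "GAAA" + "GC" * 10
        assert fold_rna(seq).mfe == fold_rna(seq.replace("T", "U")).mfe

    def test_structure_invariants_hold(self):
        fold = fold_rna(_ideal_precursor(MATURE))
        assert len(fold.structure) == len(fold.sequence)
        pt = pair_table(fold.structure)
        for i, j in enumerate(pt):
            if j >= 0:
                assert pt[j] == i

    def test_unbalanced_structure_is_rejected(self):
        with pytest.raises(ValueError):
            FoldResult("ACGT", "(((.", -1.0)


class TestExciseWindows:
    TX = {"t1": "G" * 1000}

    def test_flank_arithmetic(self):
        windows = excise_precursor_windows(("t1", 200, "+"), 21, self.TX, flank=150)
        assert windows == [("t1", 200, 370), ("t1", 50, 220)]

    def test_upstream_window_clipped_at_transcript_start(self):
        windows = excise_precursor_windows(("t1", 1, "+"), 21, self.TX, flank=150)
        assert windows[1] == ("t1", 1, 21)

    def test_out_of_bounds_hit_is_an_error(self):
        with pytest.raises(ValueError):
            excise_precursor_windows(("t1", 995, "+"), 21, self.TX)

    def test_planted_duplex_fully_contained_in_one_window(self, small_study):
        """At least one excision window around the mapped mature covers the
        whole miRNA/miRNA* duplex (mature, loop and star arm) — the region
        hairpin evaluation needs."""
        transcripts = small_study["transcripts"]
        for h in small_study["truth"].hairpins:
            tseq = transcripts[h.transcript_id]
            m0 = tseq.find(h.mature) + 1
            s0 = tseq.find(h.star) + 1
            duplex_lo = min(m0, s0)
            duplex_hi = max(m0 + len(h.mature) - 1, s0 + len(h.star) - 1)
            windows = excise_precursor_windows(
                (h.transcript_id, m0, "+"), len(h.mature), transcripts
            )
            assert any(ws <= duplex_lo and we >= duplex_hi for _, ws, we in windows)


class TestEvaluateCandidate:
    def test_ideal_hairpin_passes_every_flag(self):
        fold = fold_rna(_ideal_precursor(MATURE))
        cand = evaluate_candidate(fold, MATURE, {"L1": 25})
        assert cand.passed, cand.flags
        assert cand.duplex_mismatches == 0
        assert cand.bulged_nucleotides == 0

    def test_mature_straddling_the_loop_fails_arm_containment(self):
        precursor = _ideal_precursor(MATURE)
        loop_start = 14 + 21 + 14
        straddler = precursor[loop_start - 8 : loop_start + 13]
        fold = fold_rna(precursor)
        cand = evaluate_candidate(fold, straddler, {})
        assert not cand.flags["single_arm"]
        assert not cand.passed

    def test_weak_stem_fails_the_energy_flag(self):
        # AT-only stem: pairs form but the crude stability threshold fails
        stem5 = "AT" * 7 + MATURE[:0]
        seq = stem5 + "GAAA" + revcomp(stem5)
        fold = fold_rna(seq)
        cand = evaluate_candidate(
            fold, stem5[:14] if len(stem5) >= 14 else stem5, {},
            criteria=MeyersCriteria(mature_length=(10, 23), precursor_length=(30, 300)),
        )
        assert fold.mfe > -18.0
        assert not cand.flags["mfe"]

    def test_mature_absent_from_precursor_is_an_error(self):
        fold = fold_rna(_ideal_precursor(MATURE))
        with pytest.raises(ValueError):
            evaluate_candidate(fold, "TTTTTTTTTTTTTTTTTTTTT", {})

    def test_flag_thresholds_are_configurable(self):
        fold = fold_rna(_ideal_precursor(MATURE))
        strict = evaluate_candidate(
            fold, MATURE, {}, criteria=MeyersCriteria(max_mfe=-1000.0)
        )
        assert not strict.flags["mfe"]


class TestDetectStar:
    def test_planted_star_recovered_with_library_counts(self, small_study):
        truth = small_study["truth"]
        libs = small_study["libs"]
        transcripts = small_study["transcripts"]
        checked = 0
        for h in truth.hairpins:
            prec = transcripts[h.transcript_id][h.start - 1 : h.end]
            fold = fold_rna(prec)
            cand = evaluate_candidate(fold, h.mature, {})
            star = detect_star(cand, libs)
            assert star is not None
            star_seq, counts = star
            assert star_seq == h.star
            expected = {
                name: lib.tags.get(h.star, 0) for name, lib in libs.items()
            }
            assert counts == expected
            checked += 1
        assert checked == len(truth.hairpins)

    def test_absent_star_reports_zero_counts_not_none(self):
        fold = fold_rna(_ideal_precursor(MATURE))
        cand = evaluate_candidate(fold, MATURE, {})
        empty = TagLibrary("empty", {}, clean_total=1)
        star = detect_star(cand, {"empty": empty})
        assert star is not None
        assert star[1] == {"empty": 0}

    def test_unpaired_mature_has_no_star(self):
        seq = "GC" * 12 + "GAAA" + "GC" * 12 + "ATATATATATATATATATATA"
        fold = fold_rna(seq)
        cand = evaluate_candidate(fold, "ATATATATATATATATATATA", {})
        if not any(p != -1 for p in pair_table(fold.structure)[-21:]):
            assert detect_star(cand, {}) is None


class TestDiscovery:
    def test_synthetic_truth_recovered_above_point_nine(self, small_study):
        """Recall (on hairpins sequenced to >= 10 reads) and precision
        against the planted truth table both reach 0.9."""
        from paumir.annotation import map_tags_to_transcripts

        transcripts = small_study["transcripts"]
        libs = small_study["libs"]
        truth = small_study["truth"]
        all_tags = sorted(set(libs["cond1"].tags) | set(libs["cond2"].tags))
        hits = map_tags_to_transcripts(all_tags, transcripts)
        tag_rows = [
            (s, {n: libs[n].tags.get(s, 0) for n in libs}, hits[s])
            for s in all_tags
            if hits[s]
        ]
        cands = discover_mirnas(tag_rows, transcripts, libs)
        expressed = {
            (h.transcript_id, h.mature)
            for h in truth.hairpins
            if sum(lib.tags.get(h.mature, 0) for lib in libs.values()) >= 10
        }
        planted = {(h.transcript_id, h.mature) for h in truth.hairpins}
        found = {(c.transcript_id, c.mature) for c in cands}
        assert len(found & expressed) / len(expressed) >= 0.9
        assert len(found & planted) / max(1, len(found)) >= 0.9

    def test_candidates_refold_to_their_declared_duplex(self, small_study):
        from paumir.annotation import map_tags_to_transcripts

        transcripts = small_study["transcripts"]
        libs = small_study["libs"]
        matures = [h.mature for h in small_study["truth"].hairpins]
        hits = map_tags_to_transcripts(matures, transcripts)
        rows = [(m, {n: libs[n].tags.get(m, 0) for n in libs}, hits[m]) for m in matures]
        for cand in discover_mirnas(rows, transcripts, libs):
            refold = fold_rna(cand.precursor)
            recheck = evaluate_candidate(refold, cand.mature, cand.mature_counts)
            assert recheck.passed
            if cand.star:
                assert detect_star(recheck, libs)[0] == cand.star

    def test_summary_matches_direct_recomputation(self, small_study):
        from paumir.annotation import map_tags_to_transcripts

        transcripts = small_study["transcripts"]
        libs = small_study["libs"]
        matures = [h.mature for h in small_study["truth"].hairpins]
        hits = map_tags_to_transcripts(matures, transcripts)
        rows = [(m, {n: libs[n].tags.get(m, 0) for n in libs}, hits[m]) for m in matures]
        cands = discover_mirnas(rows, transcripts, libs)
        summary = summarize_candidates(cands)
        assert summary["n_candidates"] == len(cands)
        assert summary["mean_precursor_length"] == pytest.approx(
            sum(len(c.precursor) for c in cands) / len(cands)
        )
        assert summary["mean_mfe"] == pytest.approx(
            sum(c.fold.mfe for c in cands) / len(cands)
        )
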