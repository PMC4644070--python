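"""target_scan: pair classes, +5 rule, significance, two-pass prediction."""

from __future__ import annotations

import numpy as np
import pytest

from cdsrna.boxes import Rejection, annotate_cd_srna
from cdsrna.scan import (
    BasePairClass, ScanMode, ScanRules, call_significance, classify_pair,
    classify_productive, pair_guide_window, predict_targets, scan_guide,
)
from cdsrna.seqio import Molecule, RnaSequence, reverse_complement

from conftest import (
    annotate_and_predict, make_guide, predicted_interaction_set,
    truth_interaction_set,
)
from oracles import oracle_scan


class TestClassifyPair:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("A", "U", BasePairClass.WC), ("G", "C", BasePairClass.WC),
            ("U", "G", BasePairClass.GU), ("G", "U", BasePairClass.GU),
            ("C", "U", BasePairClass.MM), ("A", "A", BasePairClass.MM),
        ],
    )
    def test_taxonomy(self, a, b, expected):
        assert classify_pair(a, b) == expected
        assert classify_pair(b, a) == expected  # symmetry

    def test_invalid_residue(self):
        with pytest.raises(ValueError):
            classify_pair("A", "T")


class TestPairGuideWindow:
    GUIDE = "UUAGGACUGAUCC"            # 13 nt, +5 offset 8
    WINDOW = "GGAUCAGUCCUAA"           # exact reverse complement

    def test_perfect_duplex_and_plus5_site(self):
        guide = make_guide(self.GUIDE)
        assert guide.plus5_offset == 8
        d = pair_guide_window(guide, self.WINDOW, target_start=101)
        assert all(c is BasePairClass.WC for c in d.pair_classes)
        assert d.n_mm == d.n_gu == 0
        # +5 partner is window position 6, here rRNA position 106 (an A)
        assert d.site == 106
        assert self.WINDOW[5] == "A"
        assert d.site_class is BasePairClass.WC

    def test_substitution_at_site_partner(self):
        guide = make_guide(self.GUIDE)
        window = self.WINDOW[:5] + "C" + self.WINDOW[6:]  # perturb +5 partner
        d = pair_guide_window(guide, window)
        assert d.n_mm == 1 and d.site_class is BasePairClass.MM
        assert sum(c is BasePairClass.WC for c in d.pair_classes) == 12

    def test_antiparallel_endpoint_identity(self):
        guide = make_guide(self.GUIDE)
        d = pair_guide_window(guide, self.WINDOW)
        # guide position L pairs window position 1 (both are paired WC here)
        assert classify_pair(self.GUIDE[-1], self.WINDOW[0]) is BasePairClass.WC
        assert d.target_end - d.target_start + 1 == len(guide)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair_guide_window(make_guide(self.GUIDE), "ACGU")


class TestSignificance:
    def _duplex(self, guide_seq, window):
        return pair_guide_window(make_guide(guide_seq), window)

    def test_nine_wc_covering_site_is_significant(self):
        g = "UUAGGACUGAUCC"
        d = self._duplex(g, reverse_complement(g))
        assert call_significance(d, ScanRules(), ScanMode.STRICT)
        assert d.wc_run == 13

    def test_eight_wc_run_fails(self):
        g = "AAAAGGACUGAUC"  # 13 nt
        w = list(reverse_complement(g))
        # break pairing at guide positions 1..4 and 13 -> run 5..12 = 8
        for gpos in (1, 2, 3, 4, 13):
            w[len(g) - gpos] = g[gpos - 1]  # X:X mismatch
        d = self._duplex(g, "".join(w))
        assert d.n_mm == 5
        assert not call_significance(d, ScanRules(), ScanMode.STRICT)
        assert d.wc_run == 8

    def test_run_not_covering_site_fails(self):
        g = "UUAGGACUGAUCC"  # +5 offset 8
        w = list(reverse_complement(g))
        w[len(g) - 8] = g[7]  # mismatch exactly at guide position 8 (+5)
        w[len(g) - 7] = g[6]  # and at position 7: left run 1-6, right 9-13
        d = self._duplex(g, "".join(w))
        assert d.site_class is BasePairClass.MM
        # bridged run = positions 8..13 = 6 < 9 despite a 6-WC left run
        assert not call_significance(d, ScanRules(), ScanMode.STRICT)

    def test_site_mismatch_bridges_run(self):
        """A lone mismatch at the +5 site leaves the duplex significant
        (the complex forms) but non-productive (no methyl transfer)."""
        g = "UUAGGACUGAUCC"
        w = list(reverse_complement(g))
        w[len(g) - 8] = g[7]
        d = self._duplex(g, "".join(w))
        assert d.n_mm == 1 and d.site_class is BasePairClass.MM
        assert call_significance(d, ScanRules(), ScanMode.STRICT)
        assert classify_productive(d) is False

    def test_site_gu_flagged_uncertain(self):
        g = "UUAGGACGGAUCC"  # +5 nucleotide G
        w = list(reverse_complement(g))
        assert g[7] == "G" and w[5] == "C"
        w[5] = "U"  # G:U wobble at the site
        d = self._duplex(g, "".join(w))
        assert d.site_class is BasePairClass.GU
        assert call_significance(d, ScanRules(), ScanMode.STRICT)
        assert classify_productive(d) is False
        assert "uncertain_site_GU" in d.flags

    def test_relaxed_mode_lets_gu_extend_run(self):
        g = "UUAGGACUGAUCC"  # guide position 5 is G; +5 column is 8
        w = list(reverse_complement(g))
        w[len(g) - 5] = "U"  # G:U wobble at guide position 5
        d = self._duplex(g, "".join(w))
        assert d.pair_classes[4] is BasePairClass.GU
        # strict: the wobble splits the WC run; the piece covering the +5
        # column spans positions 6..13 = 8 < 9
        assert not call_significance(d, ScanRules(), ScanMode.STRICT)
        assert d.wc_run == 8
        # relaxed: the wobble extends the run across the full duplex
        assert call_significance(d, ScanRules(), ScanMode.RELAXED)
        assert d.wc_run == 13


class TestScanGuide:
    def _random_rrna(self, rng, n=400):
        return RnaSequence("r", "Sp", Molecule.RRNA_16S,
                           "".join(rng.choice(list("ACGU"), size=n)))

    def test_planted_window_recovered(self, rng):
        rrna_res = list(self._random_rrna(rng, 600).residues)
        guide_seq = "UUAGGACUGAUCC"
        window = reverse_complement(guide_seq)
        rrna_res[100:113] = window  # target_start = 101 (1-based)
        rrna = RnaSequence("r", "Sp", Molecule.RRNA_16S, "".join(rrna_res))
        hits = scan_guide(make_guide(guide_seq), rrna)
        assert hits and hits[0].target_start == 101
        assert hits[0].site == 106
        assert hits[0].productive

    def test_no_pairing_no_hits(self):
        guide = make_guide("A" * 12)
        rrna = RnaSequence("r", "Sp", Molecule.RRNA_16S, "A" * 200)
        assert scan_guide(guide, rrna) == []

    @pytest.mark.parametrize("mode", [ScanMode.STRICT, ScanMode.RELAXED])
    def test_matches_bruteforce_oracle(self, mode, rng):
        rules = ScanRules()
        for _ in range(40):
            L = int(rng.integers(10, 13))
            guide = make_guide("".join(rng.choice(list("ACGU"), size=L)))
            rrna = self._random_rrna(rng, 300)
            got = [
                (h.target_start, h.site, h.wc_run, h.n_mm, h.n_gu,
                 h.site_class.value, h.productive)
                for h in sorted(scan_guide(guide, rrna, rules, mode),
                                key=lambda h: h.target_start)
            ]
            want = [
                (o["target_start"], o["site"], o["wc_run"], o["n_mm"],
                 o["n_gu"], o["site_class"], o["productive"])
                for o in oracle_scan(
                    guide.sequence, rrna.residues,
                    relaxed=(mode is ScanMode.RELAXED),
                )
            ]
            assert got == want

    def test_tightening_rules_shrinks_hit_set(self, rng):
        """Monotonicity: stricter rules never add hits."""
        loose = ScanRules(min_consecutive_wc=9, max_mismatch=1, max_gu=2)
        for _ in range(30):
            L = int(rng.integers(10, 13))
            guide = make_guide("".join(rng.choice(list("ACGU"), size=L)))
            rrna = self._random_rrna(rng, 300)
            base = {h.target_start for h in scan_guide(guide, rrna, loose)}
            for tight in (
                ScanRules(min_consecutive_wc=10, max_mismatch=1, max_gu=2),
                ScanRules(min_consecutive_wc=9, max_mismatch=0, max_gu=2),
                ScanRules(min_consecutive_wc=9, max_mismatch=1, max_gu=0),
                ScanRules(min_consecutive_wc=11, max_mismatch=0, max_gu=0),
            ):
                assert tight.tighter_than(loose)
                sub = {h.target_start for h in scan_guide(guide, rrna, tight)}
                assert sub <= base

    def test_reversal_mirrors_pairing_geometry(self, rng):
        """Reversing both strands reverses the per-position pair classes.

        Significance is anchored at the +5 column (a length-derived,
        direction-dependent position), so the mirrored quantity is the
        antiparallel pairing geometry itself.
        """
        for _ in range(20):
            L = int(rng.integers(10, 13))
            g = "".join(rng.choice(list("ACGU"), size=L))
            w = "".join(rng.choice(list("ACGU"), size=L))
            d = pair_guide_window(make_guide(g), w)
            m = pair_guide_window(make_guide(g[::-1]), w[::-1])
            assert m.pair_classes == d.pair_classes[::-1]
            assert (m.n_mm, m.n_gu) == (d.n_mm, d.n_gu)


class TestPredictTargets:
    def test_clean_dataset_all_double_guides(self, clean_dataset):
        results = annotate_and_predict(clean_dataset)
        for sp, res in results.items():
            n = clean_dataset.spec.n_srnas_per_species
            assert res.summary["n_srnas"] == n
            assert res.summary["n_significant"] == 2 * n
            assert res.summary["n_productive"] == 2 * n
            assert res.summary["n_nonproductive"] == 0
            assert res.summary["n_double_guide"] == n
            assert set(res.srna_classes.values()) == {"double_guide"}

    def test_mixed_dataset_matches_realized_truth(self, mixed_dataset):
        results = annotate_and_predict(mixed_dataset)
        assert predicted_interaction_set(results) == \
            truth_interaction_set(mixed_dataset)

    def test_decoys_counted_as_no_target(self, mixed_dataset):
        results = annotate_and_predict(mixed_dataset)
        truth = mixed_dataset.truth_guides
        for sp, res in results.items():
            decoy_ids = set(
                truth[(truth.species == sp) & (truth.cls == "decoy")
                      & ~truth.expect_significant].srna_id
            )
            both_empty = {
                sid for sid in decoy_ids
                if not truth[(truth.srna_id == sid)].expect_significant.any()
            }
            for sid in both_empty:
                assert res.srna_classes[sid] == "no_target"

    def test_accounting_identity(self, mixed_dataset):
        results = annotate_and_predict(mixed_dataset)
        for res in results.values():
            s = res.summary
            assert s["n_significant"] == s["n_productive"] + s["n_nonproductive"]
            assert s["n_guides"] == s["n_significant"] + s["n_empty_guides"]

    def test_relaxed_rescue_within_hundred_nt(self, mixed_dataset):
        """Guides rescued in pass 2 sit within 100 nt of their anchored
        partner on the same molecule."""
        results = annotate_and_predict(mixed_dataset)
        found_relaxed = False
        for res in results.values():
            by_srna = {}
            for p in res.predictions:
                by_srna.setdefault(p.srna_id, []).append(p)
            for p in res.predictions:
                if p.mode is ScanMode.RELAXED:
                    found_relaxed = True
                    partner = [
                        q for q in by_srna[p.srna_id]
                        if q.guide_kind != p.guide_kind
                    ]
                    assert partner
                    assert partner[0].molecule == p.molecule
                    assert abs(partner[0].position - p.position) <= 100
        assert found_relaxed  # fixture plants relaxed_only sRNAs

    def test_multi_target_flag_superset(self, clean_dataset):
        sp = clean_dataset.species[0]
        srnas = [
            r for r in (annotate_cd_srna(s) for s in clean_dataset.srnas[sp])
            if not isinstance(r, Rejection)
        ]
        single = predict_targets(srnas, clean_dataset.rrnas[sp], species=sp)
        multi = predict_targets(srnas, clean_dataset.rrnas[sp], species=sp,
                                multi_target=True)
        assert single.predictions == multi.predictions
        kept_keys = {(p.srna_id, p.guide_kind) for p in multi.predictions}
        # extras only ever accompany a kept best hit for the same guide
        assert all((p.srna_id, p.guide_kind) in kept_keys for p in multi.extra_hits)
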