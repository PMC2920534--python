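"""Matcher correctness: brute-force oracle equivalence, symmetry, scoring."""

import math
import random

import pytest

from mimoscan.io import AMINO_ACIDS, PeptideRecord, ProteinRecord
from mimoscan.search import (
    MatchParams,
    SearchError,
    dedupe_protein_level,
    find_hits,
    search_panel,
    search_records,
)
from mimoscan.io import make_panel


def oracle_exact_windows(pep: str, prot: str, w: int, m: int) -> set:
    """Independent brute force: every (i, j, L) window, maximality by
    direct neighbour inspection."""
    out = set()
    lp, lq = len(pep), len(prot)
    for i in range(lp):
        for j in range(lq):
            t = min(lp - i, lq - j)
            mism = [0] * (t + 1)
            for L in range(1, t + 1):
                mism[L] = mism[L - 1] + (pep[i + L - 1] != prot[j + L - 1])
            for L in range(w, t + 1):
                if mism[L] > m:
                    continue
                left_ext = (
                    i > 0 and j > 0 and mism[L] + (pep[i - 1] != prot[j - 1]) <= m
                )
                right_ext = (
                    i + L < lp
                    and j + L < lq
                    and mism[L] + (pep[i + L] != prot[j + L]) <= m
                )
                if not left_ext and not right_ext:
                    out.add((i, j, L))
    return out


def _hit_windows(hits) -> set:
    return {
        (h.peptide_offset, h.protein_start, len(h.matched_substring)) for h in hits
    }


def _random_seq(rng, length):
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(length))


class TestExactModeExamples:
    PROT = ProteinRecord("P1", "", "MTDAAPWSKVTQ")
    PEP = PeptideRecord("VPWSKPW")

    def test_window_5_finds_no_four_residue_overlap(self):
        params = MatchParams(min_exact_window=5, max_mismatches=0)
        assert find_hits(self.PEP, self.PROT, params) == []

    def test_window_4_reports_pwsk_at_position_5(self):
        params = MatchParams(min_exact_window=4, max_mismatches=0)
        (hit,) = find_hits(self.PEP, self.PROT, params)
        assert hit.matched_substring == "PWSK"
        assert hit.protein_start == 5
        assert hit.peptide_offset == 1

    def test_full_peptide_identity_match(self):
        prot = ProteinRecord("P2", "", "AAKYRWYKDD")
        pep = PeptideRecord("KYRWYK")
        params = MatchParams(min_exact_window=5, max_mismatches=0)
        (hit,) = find_hits(pep, prot, params)
        assert hit.matched_substring == "KYRWYK"

    def test_too_short_peptide_is_an_error(self):
        params = MatchParams(min_exact_window=5)
        with pytest.raises(SearchError):
            find_hits(PeptideRecord("KYRW"), self.PROT, params)


class TestOracleEquivalence:
    @pytest.mark.parametrize("window,mismatches", [(4, 0), (5, 0), (5, 1), (6, 1)])
    def test_find_hits_matches_brute_force(self, window, mismatches):
        rng = random.Random(20260929 + window * 10 + mismatches)
        params = MatchParams(min_exact_window=window, max_mismatches=mismatches)
        alphabet = "ACDE"  # small alphabet provokes many overlapping windows
        for _ in range(150):
            pep = "".join(rng.choice(alphabet) for _ in range(rng.randint(window, 10)))
            prot = "".join(rng.choice(alphabet) for _ in range(rng.randint(10, 80)))
            hits = find_hits(
                PeptideRecord(pep), ProteinRecord("P", "", prot), params
            )
            assert _hit_windows(hits) == oracle_exact_windows(
                pep, prot, window, mismatches
            )

    def test_indexed_panel_search_equals_pairwise_scan(self):
        rng = random.Random(7)
        params = MatchParams(min_exact_window=5, max_mismatches=0)
        proteome = [
            ProteinRecord(f"P{i}", "", _random_seq(rng, rng.randint(50, 300)))
            for i in range(20)
        ]
        peptides = [_random_seq(rng, rng.randint(5, 12)) for _ in range(15)]
        # plant one peptide to guarantee hits exist
        planted = proteome[3].sequence[10:18]
        peptides.append(planted)
        panel = make_panel("A", "IgG", [(p, 1) for p in set(peptides)])
        fast = search_panel(panel, proteome, params)
        slow = []
        for rec in panel.records:
            for prot in proteome:
                slow.extend(find_hits(rec, prot, params))
        assert _hit_windows(fast) == _hit_windows(slow)
        assert any(h.peptide.sequence == planted for h in fast)

    def test_reversal_symmetry(self):
        rng = random.Random(11)
        params = MatchParams(min_exact_window=4, max_mismatches=1)
        for _ in range(50):
            pep = _random_seq(rng, rng.randint(5, 10))
            prot = _random_seq(rng, rng.randint(20, 120))
            fwd = find_hits(
                PeptideRecord(pep), ProteinRecord("P", "", prot), params
            )
            rev = find_hits(
                PeptideRecord(pep[::-1]), ProteinRecord("P", "", prot[::-1]), params
            )
            lp, lq = len(pep), len(prot)
            mapped = {
                (lp - i - L, lq - j - L, L) for i, j, L in _hit_windows(fwd)
            }
            assert mapped == _hit_windows(rev)


class TestSearchPanel:
    def test_single_containing_protein_yields_one_hit(self):
        panel = make_panel("A", "IgG", [("KYRWYK", 1)])
        proteome = [ProteinRecord("P1", "", "AAKYRWYKDD")]
        hits = search_panel(panel, proteome, MatchParams())
        assert len(hits) == 1

    def test_duplicated_protein_under_two_ids_gives_two_hits(self):
        # homolog behavior: near-identical database entries each match
        panel = make_panel("A", "IgG", [("KYRWYK", 1)])
        proteome = [
            ProteinRecord("FUT6", "", "AAKYRWYKDD"),
            ProteinRecord("FUT3", "", "AAKYRWYKDD"),
        ]
        hits = search_panel(panel, proteome, MatchParams())
        assert sorted(h.protein_id for h in hits) == ["FUT3", "FUT6"]

    def test_empty_proteome_is_an_error(self):
        panel = make_panel("A", "IgG", [("KYRWYK", 1)])
        with pytest.raises(SearchError):
            search_panel(panel, [], MatchParams())

    def test_chance_hit_rate_matches_closed_form(self):
        # 7-mer vs 1000-aa protein, window 5: for i.i.d. uniform sequences
        # a hit exists iff one of the 3 peptide 5-mers occurs in the protein
        rng = random.Random(42)
        trials = 100_000
        p_closed = 1.0 - (1.0 - 20.0**-5) ** (3 * 996)
        hits = 0
        checked = 0
        params = MatchParams(min_exact_window=5, max_mismatches=0)
        for t in range(trials):
            pep = _random_seq(rng, 7)
            prot = _random_seq(rng, 1000)
            windows = {pep[o : o + 5] for o in range(3)}
            found = any(w in prot for w in windows)
            hits += found
            if t < 200:  # matcher agrees with the substring surrogate
                got = find_hits(PeptideRecord(pep), ProteinRecord("P", "", prot), params)
                assert bool(got) == found
        p_mc = hits / trials
        se = math.sqrt(p_closed * (1 - p_closed) / trials)
        assert abs(p_mc - p_closed) <= 3 * se


class TestScoredMode:
    PARAMS = MatchParams(mode="scored", word_size=2, min_score=35)

    def test_identity_match_found_and_rescored(self):
        from Bio.Align import substitution_matrices

        matrix = substitution_matrices.load("PAM30")
        rng = random.Random(5)
        found_any = False
        for _ in range(30):
            core = _random_seq(rng, 7)
            pep = PeptideRecord(core)
            prot = ProteinRecord("P", "", _random_seq(rng, 40) + core + _random_seq(rng, 40))
            hits = find_hits(pep, prot, self.PARAMS)
            assert hits, core
            found_any = True
            for h in hits:
                window = pep.sequence[h.peptide_offset : h.peptide_offset + len(h.matched_substring)]
                rescored = int(
                    sum(matrix[a, b] for a, b in zip(window, h.matched_substring))
                )
                assert rescored == h.score
                assert h.score >= self.PARAMS.min_score
        assert found_any

    def test_no_hit_reported_below_min_score(self):
        rng = random.Random(9)
        for _ in range(100):
            pep = PeptideRecord(_random_seq(rng, 8))
            prot = ProteinRecord("P", "", _random_seq(rng, 200))
            for h in find_hits(pep, prot, self.PARAMS):
                assert h.score >= self.PARAMS.min_score


class TestDedupe:
    def test_two_sites_of_one_protein_collapse_to_one_entry(self):
        from mimoscan.search import MatchHit

        pep = PeptideRecord("KYRWYKAYRWY")
        hits = [
            MatchHit(pep, "P1", 10, "KYRWY", 0, 5),
            MatchHit(pep, "P1", 60, "KYRWYK", 0, 6),
        ]
        table = dedupe_protein_level(hits)
        assert len(table) == 1
        assert table[("KYRWYKAYRWY", "P1")].protein_start == 60  # higher score wins

    def test_seven_distinct_peptides_count_seven(self):
        from mimoscan.search import MatchHit

        hits = [
            MatchHit(PeptideRecord(f"KYRWY{aa}"), "MUC16", i * 10, "KYRWY", 0, 5)
            for i, aa in enumerate("ACDEFGH")
        ]
        table = dedupe_protein_level(hits)
        assert len(table) == 7

    def test_empty_hit_list_gives_empty_table(self):
        assert dedupe_protein_level([]) == {}

    def test_tie_break_prefers_leftmost_site(self):
        from mimoscan.search import MatchHit

        pep = PeptideRecord("KYRWYK")
        hits = [
            MatchHit(pep, "P1", 50, "KYRWY", 0, 5),
            MatchHit(pep, "P1", 5, "KYRWY", 1, 5),
        ]
        assert dedupe_protein_level(hits)[("KYRWYK", "P1")].protein_start == 5
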