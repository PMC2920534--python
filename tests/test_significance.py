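"""Collapse rule, exact statistics, ranking, QC and expression check."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from mimoscan.io import PeptideRecord, ProteinRecord, make_panel
from mimoscan.null_model import null_from_counts
from mimoscan.search import MatchHit, MatchParams
from mimoscan.significance import (
    LENGTH_SUSPECT,
    MOTIF_COLLAPSED,
    SignificanceError,
    binomial_tail,
    collapse_motif_redundancy,
    enrichment_qc,
    expression_cross_check,
    fisher_contrast,
    rank_candidates,
)
from mimoscan.simulate import PanelSpec, SimConfig, generate

PARAMS = MatchParams(min_exact_window=5, max_mismatches=0)


def _hit(seq, protein_id, start, substring, panel_id="A/IgG", copies=1, offset=0):
    return MatchHit(
        peptide=PeptideRecord(seq, copies, panel_id=panel_id),
        protein_id=protein_id,
        protein_start=start,
        matched_substring=substring,
        peptide_offset=offset,
        score=len(substring),
    )


class TestCollapse:
    def test_shared_motif_at_one_site_collapses_to_one(self):
        # five distinct peptides, all matching through one PWSK-like site
        hits = [
            _hit(f"{aa}PWSKA{aa}", "GP", 100, "PWSK") for aa in "ACDEF"
        ]
        k_eff, motif = collapse_motif_redundancy(hits)
        assert k_eff == 1
        assert motif == "PWSK"

    def test_disjoint_unrelated_sites_stay_independent(self):
        hits = [
            _hit("AYRWYKAC", "PLXNB3", 10, "AYRWY"),
            _hit("CDEFGHIK", "PLXNB3", 60, "CDEFG"),
            _hit("MNPQRSTV", "PLXNB3", 120, "MNPQR"),
            _hit("WYACDEFG", "PLXNB3", 200, "WYACD"),
        ]
        k_eff, motif = collapse_motif_redundancy(hits)
        assert k_eff == 4
        assert motif is None

    def test_single_match_is_one_group_without_motif(self):
        k_eff, motif = collapse_motif_redundancy([_hit("AYRWYKAC", "P1", 5, "AYRWY")])
        assert (k_eff, motif) == (1, None)

    def test_overlap_without_shared_substring_does_not_collapse(self):
        hits = [
            _hit("AYRWYKAC", "P1", 10, "AYRWY"),
            _hit("CDEFGHIK", "P1", 12, "CDEFG"),
        ]
        assert collapse_motif_redundancy(hits)[0] == 2


class TestBinomialTail:
    def test_jmjd6_example_equals_three_trial_enumeration(self):
        p0 = 0.00806
        # independent oracle: enumerate the 3-trial outcome space
        oracle = 3 * p0**2 * (1 - p0) + p0**3
        assert binomial_tail(3, 2, p0) == pytest.approx(oracle, rel=1e-12)
        assert binomial_tail(3, 2, p0) == pytest.approx(1.93844e-4, rel=1e-5)
        assert binomial_tail(3, 2, p0) < 0.001

    def test_oversized_decoy_matches_are_unsurprising(self):
        # 7 matches observed where 20.3 are expected by chance
        assert binomial_tail(70, 7, 0.29014) > 0.999

    def test_k_zero_is_exactly_one(self):
        assert binomial_tail(10, 0, 0.3) == 1.0

    def test_agrees_with_scipy_survival_function(self):
        rng = random.Random(4)
        for _ in range(50):
            n = rng.randint(1, 80)
            k = rng.randint(0, n)
            p0 = rng.random()
            assert binomial_tail(n, k, p0) == pytest.approx(
                float(binom.sf(k - 1, n, p0)), rel=1e-9, abs=1e-12
            )

    @settings(derandomize=True, max_examples=200)
    @given(
        st.integers(min_value=1, max_value=60),
        st.floats(min_value=0, max_value=1),
        st.data(),
    )
    def test_monotonicity(self, n, p0, data):
        k = data.draw(st.integers(min_value=1, max_value=n))
        assert binomial_tail(n, k, p0) <= binomial_tail(n, max(k - 1, 0), p0) + 1e-12
        p_hi = data.draw(st.floats(min_value=p0, max_value=1))
        assert binomial_tail(n, k, p0) <= binomial_tail(n, k, p_hi) + 1e-12


def oracle_fisher_one_sided(k1, n1, k2, n2):
    """Exhaustive hypergeometric enumeration with fixed margins."""
    N, K = n1 + n2, k1 + k2
    denom = math.comb(N, n1)
    total = 0.0
    for x in range(k1, min(n1, K) + 1):
        if K - x > n2:
            continue
        total += math.comb(K, x) * math.comb(N - K, n1 - x) / denom
    return total


class TestFisherContrast:
    def test_reconstructed_jmjd6_table(self):
        p = fisher_contrast(2, 3, 0, 67)
        assert p == pytest.approx(3 / math.comb(70, 2), rel=1e-9)
        assert p == pytest.approx(1.2422e-3, rel=1e-3)

    def test_reconstructed_plexin_table(self):
        p = fisher_contrast(4, 24, 0, 46)
        assert p == pytest.approx(
            math.comb(24, 4) / math.comb(70, 4), rel=1e-9
        )
        assert p == pytest.approx(1.1589e-2, rel=1e-3)

    def test_no_matches_anywhere_gives_one(self):
        assert fisher_contrast(0, 3, 0, 67) == pytest.approx(1.0)

    def test_equals_enumeration_for_small_margins(self):
        for n1 in range(0, 16):
            for n2 in range(0, 16):
                for k1 in range(n1 + 1):
                    for k2 in range(n2 + 1):
                        got = fisher_contrast(k1, n1, k2, n2)
                        want = oracle_fisher_one_sided(k1, n1, k2, n2)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-12), (
                            k1,
                            n1,
                            k2,
                            n2,
                        )

    def test_invalid_counts_rejected(self):
        with pytest.raises(SignificanceError):
            fisher_contrast(4, 3, 0, 10)


class TestRankCandidates:
    def _fixed_null(self, f_mean, n=70):
        from mimoscan.null_model import NullEstimate, ProteinNullRow

        return NullEstimate(
            f_mean=f_mean,
            f_sd=0.0,
            n_peptides_used=n,
            proteins_used=(ProteinNullRow("CAL", 1, 1000, f_mean),),
            min_matches_threshold=0,
            params=PARAMS,
        )

    def test_oversized_protein_flagged_length_suspect(self):
        # 7 of 70 peptides hit a 14,507-aa protein: expected-by-chance 20.3
        panel = make_panel(
            "A",
            "IgG",
            [(f"AY{aa}RW{bb}K", 1) for aa in "ACDEFGH" for bb in "ACDEFGHIKL"],
        )
        mucin_seq = "".join(
            random.Random(0).choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(14507)
        )
        proteome = [ProteinRecord("MUC16", "", mucin_seq)]
        hits = [
            _hit(panel.records[i].sequence, "MUC16", 500 * i, mucin_seq[500 * i : 500 * i + 5])
            for i in range(7)
        ]
        null = self._fixed_null(0.02)
        (res,) = rank_candidates(hits, [panel], proteome, null, params=PARAMS)
        assert res.k == 7
        assert res.p_binomial > 0.999
        assert LENGTH_SUSPECT in res.flags

    def test_collapse_never_increases_significance(self):
        panel = make_panel(
            "A", "IgG", [(f"{aa}PWSKAYR", 1) for aa in "ACDEF"]
        )
        proteome = [ProteinRecord("GP", "", "W" * 100 + "PWSK" + "W" * 100)]
        hits = [
            _hit(r.sequence, "GP", 100, "PWSK") for r in panel.records
        ]
        null = self._fixed_null(0.02, n=5)
        (res,) = rank_candidates(hits, [panel], proteome, null, params=PARAMS)
        assert res.k == 5
        assert res.k_eff == 1
        assert MOTIF_COLLAPSED in res.flags
        assert res.shared_motif == "PWSK"
        assert res.p_binomial >= binomial_tail(res.n, res.k, 0.02 * 204 / 1000)

    def test_params_mismatch_is_a_hard_error(self):
        panel = make_panel("A", "IgG", [("KYRWYK", 1)])
        proteome = [ProteinRecord("P1", "", "AAKYRWYKDD")]
        null = self._fixed_null(0.02)
        other = MatchParams(min_exact_window=4)
        with pytest.raises(SignificanceError, match="MatchParams"):
            rank_candidates([], [panel], proteome, null, params=other)

    def test_zero_match_panels_produce_no_rows(self):
        panel = make_panel("A", "IgG", [("KYRWYK", 1)])
        proteome = [ProteinRecord("P1", "", "AAKYRWYKDD")]
        assert (
            rank_candidates([], [panel], proteome, self._fixed_null(0.02), params=PARAMS)
            == []
        )

    def test_null_runs_stay_conservative(self):
        # with no planted antigen, the share of (panel, protein) pairs
        # called significant at level alpha stays below 2*alpha
        cfg_panels = (
            PanelSpec(patient_id="A", n_unique=35),
            PanelSpec(patient_id="B", n_unique=35),
        )
        counts = {0.05: 0, 0.01: 0}
        universe = 0
        for seed in range(20):
            cfg = SimConfig(
                seed=seed, n_proteins=300, panels=cfg_panels,
                planted_protein_length=None,
            )
            proteome, panels, _ = generate(cfg)
            from mimoscan.null_model import estimate_null
            from mimoscan.search import search_panels

            hits = search_panels(panels, proteome, PARAMS)
            null = estimate_null(panels, proteome, PARAMS, min_matches_threshold=0)
            results = rank_candidates(hits, panels, proteome, null, params=PARAMS)
            universe += len(panels) * len(proteome)
            for res in results:
                for alpha in counts:
                    counts[alpha] += res.p_binomial < alpha
        for alpha, count in counts.items():
            assert count / universe <= 2 * alpha


class TestEnrichmentQC:
    def test_boundary_ratio_passes(self):
        assert enrichment_qc(200, 100) == (2.0, True)

    def test_below_twofold_fails(self):
        ratio, ok = enrichment_qc(150, 100)
        assert (pytest.approx(1.5), False) == (ratio, ok)

    def test_zero_panel_counts_fail(self):
        assert enrichment_qc(0, 100) == (0.0, False)

    def test_zero_control_is_an_error(self):
        with pytest.raises(SignificanceError):
            enrichment_qc(100, 0)


class TestExpressionCrossCheck:
    def _candidate(self, protein_id="FUT6", panel_id="A/IgG"):
        from mimoscan.significance import CandidateResult

        return CandidateResult(
            panel_id=panel_id,
            protein_id=protein_id,
            length_aa=359,
            n=3,
            k=2,
            k_eff=2,
            shared_motif=None,
            p_binomial=1e-4,
            p_fisher=1e-3,
            other_matches=0,
            other_total=67,
            q_value=None,
            flags=frozenset(),
            rank=1,
        )

    def test_twofold_over_everyone_else_is_supported(self):
        expr = pd.DataFrame({"tumA": [10.0], "s2": [4.0], "s3": [1.0]}, index=["FUT6"])
        (res,) = expression_cross_check(
            [self._candidate()], expr, {"A/IgG": "tumA"}, {"FUT6": "FUT6"}
        )
        assert "EXPRESSION_SUPPORTED" in res.flags

    def test_below_twofold_is_not_supported(self):
        expr = pd.DataFrame({"tumA": [10.0], "s2": [6.0]}, index=["FUT6"])
        (res,) = expression_cross_check(
            [self._candidate()], expr, {"A/IgG": "tumA"}, {"FUT6": "FUT6"}
        )
        assert "EXPRESSION_SUPPORTED" not in res.flags

    def test_fourteen_sample_pattern_unique_to_own_tumor(self):
        rng = np.random.default_rng(0)
        samples = {f"s{i}": rng.uniform(0.5, 2.0, 1) for i in range(13)}
        samples["tumA"] = np.array([9.0])
        expr = pd.DataFrame(samples, index=["FUT6"])
        (res,) = expression_cross_check(
            [self._candidate()], expr, {"A": "tumA"}, {"FUT6": "FUT6"}
        )
        assert "EXPRESSION_SUPPORTED" in res.flags

    def test_unmapped_gene_left_unflagged(self):
        expr = pd.DataFrame({"tumA": [10.0]}, index=["OTHER"])
        (res,) = expression_cross_check(
            [self._candidate()], expr, {"A/IgG": "tumA"}, {}
        )
        assert "EXPRESSION_SUPPORTED" not in res.flags
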