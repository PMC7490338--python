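"""PWM scanning, empirical p-values, conservation filtering, TF targets."""

import itertools

import numpy as np
import pytest

from regnet.io import Motif, Promoter, PromoterSet, PWMSet, reverse_complement
from regnet.tfbs import (
    BindingSite,
    UNIFORM_BG,
    assign_tf_targets,
    build_null,
    conservation_filter,
    empirical_p,
    encode_sequence,
    pwm_log_odds,
    reverse_complement_matrix,
    scan_all,
    scan_promoter,
)


class TestLogOdds:
    def test_uniform_counts_uniform_background_all_zero(self):
        lom = pwm_log_odds(np.full((4, 6), 10.0))
        np.testing.assert_allclose(lom, 0.0, atol=1e-12)

    def test_single_base_columns_approach_two_bits(self):
        """Pure consensus columns under uniform background: max window score
        tends to L * log2(4) = 12 bits for L=6 as the pseudocount vanishes."""
        counts = np.zeros((4, 6))
        counts[0] = 100.0  # all-A motif
        lom = pwm_log_odds(counts, pseudocount_weight=1e-9)
        assert lom[0].sum() == pytest.approx(12.0, abs=1e-6)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            pwm_log_odds(np.full((4, 4), 1.0), np.array([0.5, 0.5, 0.0, 0.0]))

    def test_zero_column_rejected(self):
        counts = np.full((4, 4), 1.0)
        counts[:, 2] = 0.0
        with pytest.raises(ValueError, match="zero column"):
            pwm_log_odds(counts)


def _motif_matrix(consensus, strength=0.85):
    counts = np.full((4, len(consensus)), (1 - strength) / 3 * 100)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = strength * 100
    return pwm_log_odds(counts)


class TestScanPromoter:
    def test_consensus_scores_highest_at_plant_position(self):
        lom = _motif_matrix("ACGTAC")
        promoter = "ACGTAC" + "T" * 14
        hits = scan_promoter(lom, promoter)
        best = max(hits, key=lambda h: h[2])
        assert best[0] == 0 and best[1] == "+"

    def test_brute_force_oracle_on_toy_promoter(self):
        """Exhaustive per-position hand computation on a 20 nt promoter."""
        rng = np.random.default_rng(3)
        promoter = "".join(rng.choice(list("ACGT"), 20))
        lom = _motif_matrix("ACGT")
        hits = {(s, st): sc for s, st, sc in scan_promoter(lom, promoter)}
        for start in range(17):
            window = promoter[start:start + 4]
            fwd = sum(lom["ACGT".index(b), j] for j, b in enumerate(window))
            rc = reverse_complement(window)
            rev = sum(lom["ACGT".index(b), j] for j, b in enumerate(rc))
            assert hits[(start, "+")] == pytest.approx(fwd, abs=1e-12)
            assert hits[(start, "-")] == pytest.approx(rev, abs=1e-12)

    def test_palindromic_motif_symmetric_scores(self):
        lom = _motif_matrix("ACGT")  # ACGT is its own reverse complement
        promoter = "GGACGTCCAT"
        hits = scan_promoter(lom, promoter)
        fwd = {s: sc for s, st, sc in hits if st == "+"}
        rev = {s: sc for s, st, sc in hits if st == "-"}
        for s in fwd:
            assert fwd[s] == pytest.approx(rev[s], abs=1e-12)

    def test_n_windows_skipped(self):
        lom = _motif_matrix("ACGT")
        hits = scan_promoter(lom, "ACGTNACGT")
        starts = {(s, st) for s, st, _ in hits}
        for s in (1, 2, 3, 4):  # windows covering the N at index 4
            assert (s, "+") not in starts and (s, "-") not in starts
        assert (0, "+") in starts and (5, "+") in starts

    def test_promoter_shorter_than_motif(self):
        with pytest.raises(ValueError, match="shorter than motif"):
            scan_promoter(_motif_matrix("ACGTAC"), "ACG")

    def test_invariant_under_joint_reverse_complement(self):
        """Scanning promoter P with motif M equals scanning rc(P) with rc(M)
        up to coordinate mirroring."""
        rng = np.random.default_rng(9)
        promoter = "".join(rng.choice(list("ACGT"), 30))
        lom = _motif_matrix("GATTAC")
        L = 6
        orig = sorted(sc for _, _, sc in scan_promoter(lom, promoter))
        flipped = sorted(sc for _, _, sc in scan_promoter(
            reverse_complement_matrix(lom), reverse_complement(promoter)))
        np.testing.assert_allclose(orig, flipped, atol=1e-12)


class TestNullAndEmpiricalP:
    def test_uniform_matrix_null_all_zero(self):
        null = build_null(np.zeros((4, 5)), n_samples=2000, seed=0)
        np.testing.assert_allclose(null.scores, 0.0)

    def test_same_seed_identical(self):
        lom = _motif_matrix("ACGTA")
        a = build_null(lom, n_samples=5000, seed=3)
        b = build_null(lom, n_samples=5000, seed=3)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_add_one_rule(self):
        null = build_null(np.zeros((4, 4)), n_samples=1000, seed=0)
        # all nulls are exactly 0
        assert empirical_p(1.0, null) == pytest.approx(1 / 1001)
        assert empirical_p(-1.0, null) == pytest.approx(1.0)
        assert empirical_p(0.0, null) == pytest.approx(1.0)  # ties count as >=

    def test_median_score_near_half(self):
        # continuous-valued matrix so the null has essentially no ties
        lom = np.random.default_rng(4).normal(0, 1, (4, 5))
        null = build_null(lom, n_samples=100_000, seed=1)
        med = float(np.median(null.scores))
        assert 0.48 <= empirical_p(med, null) <= 0.52

    def test_monotone_non_increasing_in_score(self):
        lom = _motif_matrix("ACGTA")
        null = build_null(lom, n_samples=10_000, seed=2)
        scores = np.linspace(null.scores.min() - 1, null.scores.max() + 1, 50)
        ps = [empirical_p(s, null) for s in scores]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_tail_matches_exhaustive_enumeration_len4(self):
        """Motif length 4, uniform background: empirical tails from 1e5
        samples agree with exact enumeration over all 256 words within 0.01."""
        lom = _motif_matrix("ACGT", strength=0.7)
        null = build_null(lom, UNIFORM_BG, n_samples=100_000, seed=5)
        word_scores = np.array([
            sum(lom["ACGT".index(b), j] for j, b in enumerate(word))
            for word in ("".join(w) for w in itertools.product("ACGT", repeat=4))
        ])
        for s in np.unique(word_scores):
            exact_tail = np.mean(word_scores >= s - 1e-12)
            assert empirical_p(float(s), null) == pytest.approx(exact_tail, abs=0.01)


def _site(gene, p=1e-5, cons=None, tf="TF1"):
    return BindingSite(gene, "M1", tf, 0, "+", 10.0, p, cons)


class TestConservationFilter:
    def _promoters(self, tracks):
        proms = {g: Promoter(g, "A" * 50, 40) for g in tracks}
        return PromoterSet(proms, {g: t for g, t in tracks.items() if t is not None},
                           40, 10)

    def test_threshold_rules(self):
        ps = self._promoters({"hi": np.full(50, 0.9), "lo": np.full(50, 0.2),
                              "edge": np.full(50, 0.5)})
        sites = [_site("hi", cons=0.9), _site("lo", cons=0.2),
                 _site("edge", cons=0.5)]
        kept = {s.gene_id for s in conservation_filter(sites, ps, 0.5)}
        assert kept == {"hi", "edge"}  # boundary mean == threshold is kept

    def test_untracked_gene_passes_with_warning(self):
        ps = self._promoters({"g": None})
        with pytest.warns(UserWarning, match="no conservation track"):
            kept = conservation_filter([_site("g")], ps, 0.5)
        assert len(kept) == 1


class TestAssignTfTargets:
    def test_report_requires_min_tfs(self):
        sites = [_site("multi", tf=f"TF{i}") for i in range(5)] + [_site("solo")]
        full, report = assign_tf_targets(sites, p_max=1e-4, min_tfs_report=2)
        assert len(full["multi"]) == 5 and "multi" in report
        assert "solo" in full and "solo" not in report

    def test_p_cutoff_is_inclusive_upper_bound(self):
        full, _ = assign_tf_targets([_site("g", p=1e-4), _site("h", p=2e-4)])
        assert "g" in full and "h" not in full

    def test_no_passing_sites_empty_map(self):
        full, report = assign_tf_targets([_site("g", p=0.5)])
        assert full == {} and report == {}


class TestScanAllRecoversPlantedSites(object):
    def test_planted_sites_found_with_high_confidence(self, small_study):
        sites = scan_all(small_study.pwms, small_study.promoters,
                         n_null_samples=20_000, seed=0)
        sites = conservation_filter(sites, small_study.promoters, 0.5)
        found = {(s.gene_id, s.motif_id, s.start)
                 for s in sites if s.empirical_p <= 1e-4}
        planted = {(s["gene_id"], s["motif_id"], s["position"])
                   for s in small_study.truth.planted_sites}
        assert planted <= found
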