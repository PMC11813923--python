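"""Ideotype transform, WAASB, WAASBY, factor model and MTSI ranking."""

import numpy as np
import pandas as pd
import pytest

from megaenv.errors import MegaenvError, ParameterError
from megaenv.mtsi import (STUDY_PRESETS, compute_waasb, factor_model,
                          higher_is_better_after_transform,
                          ideotype_transform, mtsi_rank, rescale,
                          round_half_up, run_mtsi_pipeline,
                          selection_count, waasby)


class TestIdeotypeTransform:
    def test_target_is_a_fixed_point(self):
        x = pd.Series({"a": 9.0, "b": 5.0})
        y = ideotype_transform(x, ideal=9.0, xmin=2.0, xmax=10.0)
        assert y["a"] == pytest.approx(9.0)

    def test_maximum_target_preserves_maximization(self):
        """When the target is the observed maximum (seeds per pod 8.33),
        the target stays put and everything else maps below it."""
        x = pd.Series({"best": 8.33, "mid": 5.0, "low": 2.0})
        y = ideotype_transform(x, ideal=8.33, xmin=2.0, xmax=8.33)
        assert y["best"] == pytest.approx(8.33)
        assert (y.drop("best") < 8.33).all()
        assert higher_is_better_after_transform(8.33, 2.0, 8.33)

    def test_low_target_folds_symmetric_deviations_together(self):
        """Target 10 on range [0, 40] sits below the midpoint: values 4
        and 16 (both 6 away) transform to the same 16."""
        x = pd.Series({"under": 4.0, "over": 16.0})
        y = ideotype_transform(x, ideal=10.0, xmin=0.0, xmax=40.0)
        assert y["under"] == pytest.approx(16.0)
        assert y["over"] == pytest.approx(16.0)
        assert not higher_is_better_after_transform(10.0, 0.0, 40.0)

    def test_nonpositive_result_is_an_error(self):
        # target in the upper half folds downward: a value as far below
        # the target as the target is above zero lands at exactly zero
        x = pd.Series({"g": 0.0, "ok": 5.0})
        with pytest.raises(MegaenvError, match="g"):
            ideotype_transform(x, ideal=6.0, xmin=0.0, xmax=10.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ParameterError):
            ideotype_transform(pd.Series([1.0]), 1.0, 5.0, 5.0)


class TestRescale:
    def test_endpoints(self):
        values = pd.Series([1.0, 3.0, 5.0])
        up = rescale(values, higher_is_better=True)
        assert up.iloc[0] == 0.0 and up.iloc[2] == 100.0
        down = rescale(values, higher_is_better=False)
        assert down.iloc[0] == 100.0 and down.iloc[2] == 0.0

    def test_midpoint_maps_to_fifty(self):
        assert rescale(pd.Series([0.0, 2.0, 4.0]), True).iloc[1] == \
            pytest.approx(50.0)

    def test_constant_column_rejected(self):
        with pytest.raises(ParameterError):
            rescale(pd.Series([2.0, 2.0]), True)


class TestWaasby:
    def test_equal_inputs_pass_through(self):
        assert waasby(42.0, 42.0, 7, 3) == pytest.approx(42.0)

    def test_seventy_thirty_weighting(self):
        assert waasby(100.0, 0.0, 70, 30) == pytest.approx(70.0)

    def test_zero_stability_weight_is_pure_performance(self):
        assert waasby(55.0, 99.0, 70, 0) == pytest.approx(55.0)

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ParameterError):
            waasby(1.0, 1.0, 0, 0)


class TestWaasb:
    def test_zero_interaction_row_is_maximally_stable(self, rng):
        M = pd.DataFrame(rng.normal(size=(6, 4)))
        M.iloc[2] = 0.0
        w = compute_waasb(M)
        assert w.iloc[2] == pytest.approx(0.0, abs=1e-12)
        assert (w.drop(2) > 0).all()

    def test_rank_one_matrix_reduces_to_first_axis_score(self, rng):
        M = pd.DataFrame(np.outer(rng.normal(size=5), rng.normal(size=3)))
        w = compute_waasb(M)
        U, s, _ = np.linalg.svd(M.to_numpy(), full_matrices=False)
        expected = np.abs(U[:, 0] * np.sqrt(s[0]))
        assert w.to_numpy() == pytest.approx(expected, abs=1e-12)

    def test_matches_independent_formula(self, rng):
        """Re-derive the weighted absolute score sum from scratch."""
        M = pd.DataFrame(rng.normal(size=(8, 4)))
        w = compute_waasb(M)
        U, s, Vt = np.linalg.svd(M.to_numpy(), full_matrices=False)
        ep = s**2 / np.sum(s**2)
        scores = U * np.sqrt(s)          # symmetric-scaled scores
        oracle = np.abs(scores) @ ep / ep.sum()
        assert w.to_numpy() == pytest.approx(oracle, abs=1e-12)

    def test_all_zero_matrix_warns(self):
        M = pd.DataFrame(np.zeros((4, 3)))
        with pytest.warns(UserWarning, match="degenerate"):
            w = compute_waasb(M)
        assert (w == 0).all()


class TestFactorModel:
    def test_uncorrelated_traits_keep_separate_factors(self, rng):
        """Exactly orthogonal trait columns: identity correlation, one
        retained factor per trait, loadings a signed permutation of the
        identity."""
        X = rng.normal(size=(60, 3))
        Q, _ = np.linalg.qr(X - X.mean(0))  # centered, exactly orthogonal
        W = pd.DataFrame(50 + 10 * Q, columns=list("abc"))
        fm = factor_model(W)
        assert fm.n_factors == 3
        assert np.allclose(np.sort(fm.eigenvalues), 1.0, atol=1e-8)
        L = fm.loadings.abs().to_numpy()
        perm = L.argmax(axis=0)
        assert sorted(perm) == [0, 1, 2]
        assert np.all(L.max(axis=0) > 0.99)

    def test_two_perfectly_correlated_blocks_give_two_factors(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        W = pd.DataFrame({"a1": a, "a2": 2 * a + 0.01 * rng.normal(size=200),
                          "b1": b, "b2": -b + 0.01 * rng.normal(size=200)})
        fm = factor_model(W)
        assert fm.n_factors == 2
        assert (fm.communalities > 0.99).all()

    def test_communalities_bounded_by_one(self, rng):
        W = pd.DataFrame(rng.normal(size=(60, 5)))
        fm = factor_model(W)
        assert (fm.communalities <= 1 + 1e-8).all()

    def test_all_hundred_row_scores_like_the_ideotype(self, rng):
        W = pd.DataFrame(rng.uniform(0, 100, size=(30, 3)))
        W.iloc[0] = 100.0
        fm = factor_model(W)
        assert fm.scores.iloc[0].to_numpy() == \
            pytest.approx(fm.ideotype_scores.to_numpy(), abs=1e-10)


class TestMTSIRank:
    def test_genotype_at_ideotype_ranks_first_with_zero_index(self, rng):
        scores = pd.DataFrame(rng.normal(size=(10, 2)),
                              index=[f"G{i}" for i in range(10)])
        ideal = scores.iloc[3].copy()
        res = mtsi_rank(scores, ideal, 20.0)
        assert res.ranking.index[0] == "G3"
        assert res.mtsi["G3"] == pytest.approx(0.0)

    @pytest.mark.parametrize("n,expected", [(179, 27), (220, 33)])
    def test_study_selection_counts(self, n, expected):
        assert selection_count(n, 15.0) == expected

    def test_selected_set_size_matches_rounding_table(self, rng):
        """round(SI * n) with half-up rounding for every n up to 500."""
        for n in range(1, 501):
            brute = int(np.floor(0.15 * n + 0.5))
            assert selection_count(n, 15.0) == brute
        scores = pd.DataFrame(rng.normal(size=(37, 2)))
        res = mtsi_rank(scores, scores.iloc[0] * 0, 15.0)
        assert len(res.selected) == round_half_up(0.15 * 37)

    def test_invalid_selection_intensity(self):
        with pytest.raises(ParameterError):
            selection_count(100, 0.0)
        with pytest.raises(ParameterError):
            selection_count(100, 101.0)


def _planted_dataset(rng, n_geno=12, trials=("S1", "S2", "N1", "N2")):
    """Small MET where G001 sits at the ideotype in every environment."""
    from conftest import make_replicated_dataset

    ideotype = {"NOB": 4.9, "HFP": 10.0, "PPN": 4.12, "SPP": 8.33}
    ranges = {"NOB": (1.0, 4.9), "HFP": (8.0, 60.0), "PPN": (0.3, 4.12),
              "SPP": (2.0, 8.33)}
    genotypes = [f"G{i + 1:03d}" for i in range(n_geno)]
    values = {}
    for trait, (lo, hi) in ranges.items():
        base = rng.uniform(lo, hi, size=(n_geno, 1))
        tab = base + rng.normal(0, 0.05 * (hi - lo),
                                size=(n_geno, len(trials)))
        tab = np.clip(tab, lo, hi)
        table = pd.DataFrame(tab, index=genotypes, columns=list(trials))
        table.loc["G001"] = ideotype[trait]
        values[trait] = table
    dataset = make_replicated_dataset(values, list(trials), genotypes,
                                      noise_sd=0.02, noise_rng=rng)
    return dataset, ideotype


class TestPipeline:
    def test_planted_ideotype_genotype_ranks_first(self, rng):
        dataset, ideotype = _planted_dataset(rng)
        res = run_mtsi_pipeline(dataset, list(ideotype), ideotype=ideotype)
        assert res.ranking.index[0] == "G001"
        assert res.mtsi["G001"] < 0.2 * res.mtsi.median()

    def test_ranking_invariant_to_trait_order(self, rng):
        dataset, ideotype = _planted_dataset(rng)
        traits = list(ideotype)
        a = run_mtsi_pipeline(dataset, traits, ideotype=ideotype)
        b = run_mtsi_pipeline(dataset, traits[::-1], ideotype=ideotype)
        assert list(a.ranking.index) == list(b.ranking.index)

    def test_mega_env_restriction_uses_subset_trials(self, rng):
        dataset, ideotype = _planted_dataset(rng)
        mega_map = {"S1": "SE", "S2": "SE", "N1": "NE", "N2": "NE"}
        res = run_mtsi_pipeline(dataset, list(ideotype), ideotype=ideotype,
                                mega_env="SE", mega_env_map=mega_map)
        assert len(res.selected) == selection_count(12, 15.0)

    def test_missing_ideotype_target_rejected(self, rng):
        dataset, ideotype = _planted_dataset(rng)
        with pytest.raises(ParameterError, match="DTF"):
            run_mtsi_pipeline(dataset, ["DTF"], ideotype=ideotype)

    def test_study_presets_cover_the_published_trait_groupings(self):
        assert STUDY_PRESETS["SE"]["traits"] == ("NOB", "HFP", "PPN", "SPP")
        assert STUDY_PRESETS["NE"]["traits"] == ("NOB", "HFP", "PPN", "SPP")
        assert STUDY_PRESETS["single"]["traits"] == ("PH", "PPF", "PL")
        assert STUDY_PRESETS["single"]["mega_env"] is None
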