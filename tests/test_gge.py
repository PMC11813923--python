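"""GGE model, which-won-where geometry and mean-vs-stability view."""

import numpy as np
import pandas as pd
import pytest

from megaenv.errors import DegenerateGeometryError, ParameterError
from megaenv.gge import (TwoWayTable, brute_force_winner, build_two_way,
                         convex_hull, fit_gge, mean_vs_stability,
                         two_way_from_blups, which_won_where)


def _table(values, genotypes=None, envs=None, locations=None):
    values = np.asarray(values, float)
    g, e = values.shape
    genotypes = genotypes or [f"G{i}" for i in range(g)]
    envs = envs or [f"E{j}" for j in range(e)]
    locations = locations or [env[:-1] or env for env in envs]
    frame = pd.DataFrame(values, index=genotypes, columns=envs)
    meta = pd.DataFrame({"env": envs, "location": locations, "year": 2018})
    return TwoWayTable("trait", frame, meta)


def brute_hull(points):
    """O(n^3) hull oracle: a point is a vertex iff some line through it
    keeps all other points strictly on one side."""
    n = len(points)
    vertices = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = points[j] - points[i]
            rel = points - points[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if np.all(cross >= -1e-12):
                vertices.append(i)
                break
    return sorted(set(vertices))


class TestFitGGE:
    def test_identical_columns_collapse_to_zero(self):
        model = fit_gge(_table(np.outer([1, 2, 3.0], [1, 1, 1])))
        assert np.allclose(model.singular_values[1:], 0.0, atol=1e-12)

    def test_two_by_two_hand_svd(self):
        """[[1,-1],[-1,1]] is already centered; lambda = (2, 0) and PC1
        explains everything."""
        table = _table([[1, -1], [-1, 1], [0, 0]])
        model = fit_gge(table)
        assert model.singular_values[0] == pytest.approx(2.0)
        assert model.singular_values[1] == pytest.approx(0.0, abs=1e-12)
        assert model.varexp[0] == pytest.approx(1.0)

    def test_frobenius_identity(self, rng):
        M = rng.normal(size=(10, 4))
        model = fit_gge(_table(M))
        assert np.sum(model.singular_values**2) == \
            pytest.approx(np.sum(model.centered.to_numpy()**2), abs=1e-10)

    def test_symmetric_scaling_reconstructs_rank2(self, rng):
        # build an exactly rank-2 centered table
        M = np.outer(rng.normal(size=8), rng.normal(size=4)) \
            + np.outer(rng.normal(size=8), rng.normal(size=4))
        model = fit_gge(_table(M), f=0.5)
        recon = model.rank2_inner().to_numpy()
        assert np.allclose(recon, model.centered.to_numpy(), atol=1e-10)

    def test_invalid_scaling_exponent(self):
        with pytest.raises(ParameterError):
            fit_gge(_table(np.eye(3)), f=1.5)


class TestBuildTwoWay:
    def test_missing_cell_filled_and_flagged(self):
        vals = pd.DataFrame([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0]],
                            index=list("abc"), columns=["E1", "E2"])
        fill = pd.DataFrame(4.0, index=vals.index, columns=vals.columns)
        meta = pd.DataFrame({"env": ["E1", "E2"], "location": ["E", "E"],
                             "year": [2018, 2019]})
        table = build_two_way(vals, meta, fill=fill)
        assert table.values.loc["b", "E2"] == 4.0
        assert table.predicted_mask.loc["b", "E2"]
        assert table.predicted_mask.to_numpy().sum() == 1

    def test_missing_without_fill_rejected(self):
        vals = pd.DataFrame([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]],
                            columns=["E1", "E2"])
        meta = pd.DataFrame({"env": ["E1", "E2"], "location": "E",
                             "year": 2018})
        with pytest.raises(ParameterError):
            build_two_way(vals, meta)

    def test_too_few_environments_rejected(self):
        with pytest.raises(ParameterError, match="environments"):
            _table(np.ones((3, 1)))

    def test_blup_based_table_is_complete(self, dtf_fit, study_dataset):
        from megaenv.mixed_models import extract_blups
        meta = study_dataset.trial_meta().rename(
            columns={"trial_id": "env"})
        table = two_way_from_blups(extract_blups(dtf_fit), meta)
        assert table.values.shape == (120, 9)
        assert not table.values.isna().any().any()


class TestWhichWonWhere:
    def test_symmetric_two_sector_construction(self):
        """Four corner genotypes, environments hugging the x-axis: the
        right-side environments go to the right vertices, left to left."""
        pts = np.array([[1, 1], [1, -1], [-1, 1], [-1, -1], [0, 0]],
                       float)
        env = np.array([[1, 0.1], [1, -0.1], [-1, 0.1], [-1, -0.1]])
        # craft a model through SVD of a rank-2 table built from scores
        M = pts @ env.T
        model = fit_gge(_table(M, envs=["R1", "R2", "L1", "L2"],
                               locations=["R", "R", "L", "L"]))
        res = which_won_where(model)
        winners = res.env_winner
        right = {"G0", "G1"}  # the two x = +1 corners
        left = {"G2", "G3"}
        assert {winners["R1"], winners["R2"]} <= right
        assert {winners["L1"], winners["L2"]} <= left

    def test_winner_matches_brute_force_argmax(self, rng):
        """On 50 random models, every environment's sector winner equals
        the exhaustive rank-2 argmax over all genotypes."""
        for _ in range(50):
            g = int(rng.integers(5, 20))
            e = int(rng.integers(3, 8))
            model = fit_gge(_table(rng.normal(size=(g, e))))
            res = which_won_where(model)
            assert res.env_winner == brute_force_winner(model)

    def test_hull_matches_cubic_oracle(self, rng):
        for _ in range(20):
            pts = rng.normal(size=(int(rng.integers(5, 50)), 2))
            assert sorted(convex_hull(pts)) == brute_hull(pts)

    def test_brute_force_winner_lies_on_hull(self, rng):
        for _ in range(20):
            model = fit_gge(_table(rng.normal(size=(12, 5))))
            res = which_won_where(model)
            for winner in brute_force_winner(model).values():
                assert winner in res.hull_vertices

    def test_invariant_to_singular_vector_sign_flips(self, rng):
        """Winners are a property of the data, not the SVD sign choice."""
        import copy
        model = fit_gge(_table(rng.normal(size=(10, 5))))
        for axes in ([0], [1], [0, 1]):
            hand = copy.deepcopy(model)
            hand.genotype_scores.iloc[:, axes] *= -1
            hand.env_scores.iloc[:, axes] *= -1
            assert which_won_where(hand).env_winner == \
                which_won_where(model).env_winner

    def test_degenerate_rank_one_refused(self):
        table = _table(np.outer([1, 2, 3, 4.0], [1, -1, 0.5]))
        with pytest.raises(DegenerateGeometryError, match="rank-1"):
            which_won_where(fit_gge(table))

    def test_single_deviant_year_breaks_repeatability(self):
        pts = np.array([[2, 0], [-2, 1], [-2, -1], [0, 0.1]])
        env = np.array([[1, 0.2], [1, -0.2], [-1, 1], [-1, -1]])
        M = pts @ env.T
        model = fit_gge(_table(M, envs=["A1", "A2", "B1", "B2"],
                               locations=["A", "A", "B", "B"]))
        res = which_won_where(model)
        # B's two years land in different sectors -> one mega-environment
        assert not res.repeatable
        assert len(res.mega_environments) == 1


class TestMeanVsStability:
    def test_origin_genotype_has_zero_projection_and_stability(self, rng):
        """A genotype sitting at the column means centers to the origin
        and scores zero mean performance and zero instability."""
        rows = rng.normal(size=(3, 4))
        vals = np.vstack([rows, rows.mean(axis=0)])  # row 3 = mean row
        model = fit_gge(_table(vals))
        g = model.genotype_coords().iloc[3]
        assert np.allclose(g, 0.0, atol=1e-9)
        res = mean_vs_stability(model)
        assert res.mean_performance.iloc[3] == pytest.approx(0, abs=1e-9)
        assert res.stability.iloc[3] == pytest.approx(0, abs=1e-9)

    def test_rank_one_ranking_equals_row_mean_ranking(self, rng):
        row = rng.normal(size=6)
        col = np.abs(rng.normal(size=4)) + 0.1   # positive env loadings
        table = _table(np.outer(row, col))
        model = fit_gge(table)
        res = mean_vs_stability(model)
        row_means = model.centered.mean(axis=1)
        assert list(res.ranking.index) == \
            list(row_means.sort_values(ascending=False).index)

    def test_collinear_ideal_ranking_matches_mean_ranking(self, rng):
        row = rng.normal(size=7)
        table = _table(np.outer(row, [1.0, 1.0, 1.0]))
        model = fit_gge(table)
        res = mean_vs_stability(model)
        assert list(res.ideal_ranking.index) == list(res.ranking.index)

    def test_zero_average_environment_is_an_error(self):
        """Two environments with exactly opposite score vectors leave the
        average-environment axis undefined."""
        pts = np.array([[1.0], [-1.0], [0.3]])
        model = fit_gge(_table(pts @ np.array([[1.0, -1.0]])))
        assert np.allclose(model.env_coords().to_numpy().mean(axis=0), 0,
                           atol=1e-12)
        with pytest.raises(DegenerateGeometryError):
            mean_vs_stability(model)

    def test_stability_nonnegative(self, rng):
        model = fit_gge(_table(rng.normal(size=(15, 6))))
        res = mean_vs_stability(model)
        assert (res.stability >= 0).all()


def test_plots_render(tmp_path, rng):
    from megaenv.gge import plot_mean_stability, plot_which_won_where
    model = fit_gge(_table(rng.normal(size=(10, 4))))
    plot_which_won_where(model, which_won_where(model),
                         tmp_path / "www.png")
    plot_mean_stability(model, mean_vs_stability(model),
                        tmp_path / "aec.png")
    assert (tmp_path / "www.png").stat().st_size > 0
    assert (tmp_path / "aec.png").stat().st_size > 0
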