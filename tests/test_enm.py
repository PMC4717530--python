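import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from phyloniche.core_io import EnvGrid
from phyloniche.enm import (ModelError, NicheModel, auc, binarize,
                            bootstrap_eval, fit_maxent, max_sss_threshold,
                            pno_profile, range_overlap)
from phyloniche.synthetic import NicheSpec, gen_env_grid


@pytest.fixture(scope="module")
def grid40():
    return gen_env_grid(40, seed=2)


@pytest.fixture(scope="module")
def tiny_niche_presences(grid40):
    """Presence records confined to a small (16-cell) patch — a separable
    niche occupying ~1% of the background."""
    spec = NicheSpec("A", np.zeros(20), np.ones(20), (2, 6, 2, 6))
    cells = spec.anchor_cells(grid40)
    rng = np.random.default_rng(0)
    return cells[rng.integers(0, len(cells), 30)]


class TestFitMaxent:
    def test_background_matching_presences_give_uniform_model(self, grid40):
        """Presences distributed exactly like the background → λ = 0."""
        bg = grid40.masked_cells()
        model = fit_maxent(bg, grid40, beta=0.0)
        assert np.allclose(model.lam, 0.0)
        assert np.allclose(model.raw, 1.0 / len(bg))

    def test_raw_sums_to_one(self, grid40, tiny_niche_presences):
        model = fit_maxent(tiny_niche_presences, grid40, beta=1.0)
        assert model.raw.sum() == pytest.approx(1.0, abs=1e-9)
        # logistic lives in [0, 1); exact zeros only where raw underflowed
        assert np.all((model.logistic >= 0) & (model.logistic < 1))
        assert np.all(model.logistic[model.raw > 0] > 0)

    def test_single_feature_matches_golden_section_oracle(self):
        """Two-cell-type grid: the penalized optimum equals a 1-D search."""
        values = np.zeros((4, 6, 20))
        values[:, 3:, 0] = 1.0          # altitude is the only varying feature
        values[..., 1:] = 0.5
        grid = EnvGrid(values, np.ones((4, 6), bool))
        # 6 presences on the alt=1 half, 1 on the alt=0 half
        pres = np.array([[0, 3], [1, 4], [2, 5], [3, 3], [0, 4], [1, 5], [0, 0]])
        beta = 0.5
        model = fit_maxent(pres, grid, beta=beta)
        # The linear and quadratic altitude features are identical 0/1
        # indicators, so the model is 1-D in their total weight l_tot with
        # objective (6/7)·l_tot − log(n0 + n1·e^l_tot) − s·l_tot where the
        # penalty per feature is beta·sd(presence feature)/sqrt(7).
        lam_tot = model.lam.sum()
        n0, n1 = 12.0, 12.0
        s_per_feature = beta * np.std([1, 1, 1, 1, 1, 1, 0]) / np.sqrt(7)

        def neg_obj(l):
            return -((6 / 7) * l - np.log(n0 + n1 * np.exp(l))
                     - s_per_feature * l)

        res = minimize_scalar(neg_obj, bounds=(0.0, 20.0), method="bounded",
                              options={"xatol": 1e-10})
        assert lam_tot == pytest.approx(res.x, abs=1e-5)
        assert neg_obj(lam_tot) == pytest.approx(neg_obj(res.x), abs=1e-10)

    def test_too_few_presences_rejected(self, grid40):
        with pytest.raises(ModelError):
            fit_maxent(grid40.masked_cells()[:3], grid40)

    def test_cumulative_output_monotone_in_raw(self, grid40, tiny_niche_presences):
        model = fit_maxent(tiny_niche_presences, grid40, beta=1.0)
        cum = model.cumulative
        order = np.argsort(model.raw)
        assert np.all(np.diff(cum[order]) >= 0)
        assert cum.max() == pytest.approx(100.0)

    def test_entropy_consistent_with_raw(self, grid40, tiny_niche_presences):
        model = fit_maxent(tiny_niche_presences, grid40, beta=1.0)
        raw = model.raw[model.raw > 0]
        assert model.entropy == pytest.approx(float(-(raw * np.log(raw)).sum()))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2, 0.3]) == 1.0

    def test_identical_scores(self):
        assert auc([0.5, 0.4], [0.5, 0.4]) == 0.5

    def test_matches_pair_counting(self):
        rng = np.random.default_rng(1)
        sp = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], 20)
        sb = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], 20)
        wins = sum((a > b) + 0.5 * (a == b) for a in sp for b in sb)
        assert auc(sp, sb) == pytest.approx(wins / 400)

    def test_antisymmetry_without_ties(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=15), rng.normal(size=12)
        assert auc(a, b) == pytest.approx(1.0 - auc(b, a))


class TestBootstrapEval:
    def test_separable_niche_keeps_model(self, grid40, tiny_niche_presences):
        mean, _, flag, aucs = bootstrap_eval(tiny_niche_presences, grid40,
                                             replicates=20, seed=1)
        assert mean > 0.99
        assert flag == "keep"
        assert len(aucs) == 20

    def test_background_like_presences_flagged_for_removal(self, grid40):
        rng = np.random.default_rng(3)
        bg = grid40.masked_cells()
        pres = bg[rng.integers(0, len(bg), 30)]
        mean, _, flag, _ = bootstrap_eval(pres, grid40, replicates=20, seed=1)
        assert abs(mean - 0.5) < 0.15
        assert flag == "remove"


class TestThresholdAndOverlap:
    def _toy_model(self, logistic):
        logistic = np.asarray(logistic, dtype=float)
        raw = logistic / logistic.sum()
        return NicheModel(np.zeros(40), [], np.zeros(20), np.ones(20), 0.0,
                          1.0, raw, logistic)

    def test_exhaustive_scan_oracle(self, grid40, tiny_niche_presences):
        model = fit_maxent(tiny_niche_presences, grid40, beta=1.0)
        tau = max_sss_threshold(model, tiny_niche_presences, grid40)
        pres = model.score_cells(grid40, tiny_niche_presences)
        bg = model.logistic
        best = max(
            ((pres >= t).mean() + (bg < t).mean(), t)
            for t in np.unique(np.concatenate([pres, bg])))
        assert tau == pytest.approx(best[1])
        got = (pres >= tau).mean() + (bg < tau).mean()
        assert got == pytest.approx(best[0])

    def test_overlap_identical_and_disjoint(self):
        a = np.array([True, True, False, False])
        b = np.array([False, False, True, True])
        assert range_overlap(a, a) == 100.0
        assert range_overlap(a, b) == 0.0

    def test_overlap_arithmetic(self):
        x = np.zeros(30, bool)
        y = np.zeros(30, bool)
        x[:10] = True
        y[5:15] = True
        assert range_overlap(x, y) == pytest.approx(100 * 5 / 15)
        assert range_overlap(x, y, metric="smaller") == pytest.approx(50.0)

    def test_empty_maps_flagged_nan(self):
        z = np.zeros(5, bool)
        assert np.isnan(range_overlap(z, z))

    def test_binarize_threshold(self):
        model = self._toy_model([0.1, 0.5, 0.9])
        np.testing.assert_array_equal(binarize(model, 0.5),
                                      [False, True, True])


class TestPno:
    def test_uniform_suitability_recovers_plain_histogram(self, grid40):
        bg = grid40.masked_cells()
        model = fit_maxent(bg, grid40, beta=0.0)
        profile = pno_profile(model, grid40, "alt", bins=20)
        vals = grid40.masked_env()[:, 0]
        expected, _ = np.histogram(vals, bins=profile.edges)
        np.testing.assert_allclose(profile.weights, expected / expected.sum(),
                                   atol=1e-12)

    def test_weights_sum_to_one(self, grid40, tiny_niche_presences):
        model = fit_maxent(tiny_niche_presences, grid40, beta=1.0)
        for var in ("alt", "bio4", "bio12"):
            assert pno_profile(model, grid40, var).weights.sum() == \
                pytest.approx(1.0, abs=1e-9)

    def test_concentrated_suitability_is_a_point_mass(self, grid40):
        n = grid40.mask.sum()
        raw = np.zeros(n)
        raw[7] = 1.0
        model = NicheModel(np.zeros(40), [], np.zeros(20), np.ones(20), 0.0,
                           0.0, raw, raw)
        profile = pno_profile(model, grid40, "alt")
        assert profile.weights.max() == pytest.approx(1.0)

    def test_unknown_variable_rejected(self, grid40, tiny_niche_presences):
        model = fit_maxent(tiny_niche_presences, grid40, beta=1.0)
        with pytest.raises(ValueError):
            pno_profile(model, grid40, "bio99")

    def test_altitude_profiles_order_highland_above_lowlands(self, mimic):
        """Highland niche C occupies high altitudes; lowland A and B agree."""
        from phyloniche.pipeline import _nearest_cell
        grid, occ, truth = mimic["grid"], mimic["occurrences"], mimic["true_labels"]
        med = {}
        for state in "ABC":
            sel = occ.df[truth == state]
            cells = np.array([_nearest_cell(grid, lon, lat)
                              for lon, lat in zip(sel["lon"], sel["lat"])])
            model = fit_maxent(cells, grid, beta=1.0)
            med[state] = pno_profile(model, grid, "alt").median()
        assert med["C"] > med["A"] + 500
        assert med["C"] > med["B"] + 500
        assert abs(med["A"] - med["B"]) < 300
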