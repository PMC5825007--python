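"""Multi-response MARS fitting, prediction, grouping and AUC."""

import numpy as np
import pytest

from floraplan import synthgeo
from floraplan.sdm_mars import (
    MarsConfig,
    MarsModel,
    SiteSpeciesMatrix,
    build_site_species_matrix,
    compute_auc,
    evaluate_model,
    fit_mars_multiresponse,
    n_groups_for,
    partition_species_groups,
    predict_probabilities,
)
from floraplan.synthgeo import OccurrenceTable


def _occurrences(records):
    """Build an OccurrenceTable from (species_id, row, col) triples."""
    sids = [r[0] for r in records]
    rows = np.array([r[1] for r in records])
    cols = np.array([r[2] for r in records])
    return OccurrenceTable(
        records=np.stack([rows, cols], axis=1),
        species_ids=sids,
        rows=rows,
        cols=cols,
        dropped_species=[],
        survey_sites=np.unique(np.stack([rows, cols], axis=1), axis=0),
    )


def _single_response_matrix(x, y, names=("x",)):
    x = np.atleast_2d(np.asarray(x, dtype=float).T).T
    return SiteSpeciesMatrix(
        sites=np.zeros((x.shape[0], 2), dtype=int),
        predictor_names=tuple(names),
        X=x,
        Y=np.asarray(y, dtype=float).reshape(x.shape[0], -1),
        species_ids=[f"s{j}" for j in range(np.asarray(y).reshape(x.shape[0], -1).shape[1])],
    )


class TestSiteSpeciesMatrix:
    def test_shared_and_private_sites(self, env40):
        occ = _occurrences(
            [
                ("a", 1, 1), ("b", 1, 1), ("c", 1, 1),
                ("a", 2, 2), ("b", 2, 2), ("c", 2, 2),
                ("a", 3, 3), ("b", 4, 4), ("c", 5, 5),
            ]
        )
        # 2 shared sites + 1 private site each (a@3,3 b@4,4 c@5,5) -> 5 rows
        m = build_site_species_matrix(occ, env40)
        assert m.n_sites == 5
        assert m.Y.sum(axis=0).tolist() == [3, 3, 3]

    def test_every_species_everywhere_gives_all_ones(self, env40):
        recs = [(s, r, r) for s in ("a", "b") for r in (1, 2, 3)]
        m = build_site_species_matrix(_occurrences(recs), env40)
        assert np.all(m.Y == 1)

    def test_matches_nested_loop_oracle(self, env40, species12):
        occ = synthgeo.sample_occurrences(species12, env40, seed=5)
        m = build_site_species_matrix(occ, env40)
        # brute-force rebuild
        sites = [tuple(s) for s in m.sites]
        for j, sid in enumerate(m.species_ids):
            recorded = {
                (int(r), int(c))
                for s, r, c in zip(occ.species_ids, occ.rows, occ.cols)
                if s == sid
            }
            for i, site in enumerate(sites):
                assert m.Y[i, j] == (1.0 if site in recorded else 0.0)
        # predictors extracted at the right cells
        for i, (r, c) in enumerate(sites):
            for k, name in enumerate(m.predictor_names):
                assert m.X[i, k] == env40[name][r, c]

    def test_off_grid_records_rejected(self, env40):
        with pytest.raises(ValueError):
            build_site_species_matrix(_occurrences([("a", 99, 1), ("a", 1, 1)]), env40)


class TestPartition:
    def test_national_survey_partition(self):
        ids = [f"sp{i}" for i in range(2297)]
        groups = partition_species_groups(ids, 15, seed=0)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [153] * 14 + [155]

    def test_even_split(self):
        groups = partition_species_groups([str(i) for i in range(10)], 2, seed=1)
        assert sorted(len(g) for g in groups) == [5, 5]

    @pytest.mark.parametrize("seed", range(20))
    def test_partition_is_a_partition(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(5, 80))
        n = int(rng.integers(1, S + 1))
        ids = [f"x{i}" for i in range(S)]
        groups = partition_species_groups(ids, n, seed=seed)
        flat = [s for g in groups for s in g]
        assert len(flat) == S and set(flat) == set(ids)
        assert len(groups) == n

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            partition_species_groups(["a", "b"], 3)

    def test_batch_trigger(self):
        assert n_groups_for(2297, 300) == 8
        assert n_groups_for(60, 300) == 1


class TestMarsFit:
    def test_recovers_noiseless_hinge(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 50)
        y = np.maximum(0, x - 0.5)
        model = fit_mars_multiresponse(_single_response_matrix(x, y))
        pred = model.predict(x[:, None], clamp=False)
        assert float(((pred[:, 0] - y) ** 2).sum()) < 1e-10
        knots = [k for bf in model.basis for _, k, _ in bf.factors]
        assert min(abs(k - 0.5) for k in knots) < 0.05

    def test_first_basis_matches_exhaustive_enumeration(self):
        """The first forward-pass hinge pair equals the (variable, knot)
        minimizing joint RSS over all candidates, found by brute force."""
        rng = np.random.default_rng(3)
        X = rng.uniform(-1, 1, (12, 2))
        Y = np.column_stack(
            [
                0.7 * np.maximum(0, X[:, 1] - 0.2) + 0.1 * X[:, 0],
                -0.4 * np.maximum(0, 0.2 - X[:, 1]) + 0.05,
            ]
        )
        best = (np.inf, None, None)
        for v in range(2):
            for k in np.unique(X[:, v]):
                B = np.column_stack(
                    [
                        np.ones(12),
                        np.maximum(0, X[:, v] - k),
                        np.maximum(0, k - X[:, v]),
                    ]
                )
                coef, _, _, _ = np.linalg.lstsq(B, Y, rcond=None)
                rss = float(((Y - B @ coef) ** 2).sum())
                if rss < best[0] - 1e-12:
                    best = (rss, v, float(k))
        m = SiteSpeciesMatrix(
            sites=np.zeros((12, 2), int), predictor_names=("x0", "x1"),
            X=X, Y=Y, species_ids=["a", "b"],
        )
        model = fit_mars_multiresponse(m, MarsConfig(max_basis=3))
        v_fit = {v for bf in model.basis[1:] for v, _, _ in bf.factors}
        k_fit = {k for bf in model.basis[1:] for _, k, _ in bf.factors}
        assert v_fit == {best[1]}
        assert len(k_fit) == 1 and next(iter(k_fit)) == pytest.approx(best[2])

    def test_huge_gcv_penalty_prunes_to_intercept(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 30)
        y = np.maximum(0, x - 0.4) + 0.01 * rng.standard_normal(30)
        model = fit_mars_multiresponse(
            _single_response_matrix(x, y), MarsConfig(gcv_penalty=1e12)
        )
        assert len(model.basis) == 1 and model.basis[0].degree == 0

    def test_forward_pass_rss_is_monotone(self, env40, species12):
        occ = synthgeo.sample_occurrences(species12, env40, seed=5)
        m = build_site_species_matrix(occ, env40)
        model = fit_mars_multiresponse(m)
        rss = model.forward_rss
        assert all(rss[i + 1] <= rss[i] + 1e-9 for i in range(len(rss) - 1))

    def test_multiresponse_consistency_with_identical_columns(self):
        """S identical response columns give the same basis and identical
        per-species coefficients as the single-response fit."""
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 40)
        y = (
            np.maximum(0, x - 0.3)
            - 0.5 * np.maximum(0, x - 0.7)
            + 0.05 * rng.standard_normal(40)
        )
        single = fit_mars_multiresponse(_single_response_matrix(x, y))
        multi = fit_mars_multiresponse(
            _single_response_matrix(x, np.tile(y[:, None], (1, 4)))
        )
        assert [bf.factors for bf in multi.basis] == [bf.factors for bf in single.basis]
        for j in range(4):
            np.testing.assert_allclose(multi.coef[:, j], single.coef[:, 0], atol=1e-8)

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            fit_mars_multiresponse(_single_response_matrix([1.0], [1.0]))


class TestPrediction:
    def _intercept_model(self, value, env):
        return MarsModel(
            basis=[__import__("floraplan.sdm_mars", fromlist=["BasisFunction"]).BasisFunction(())],
            coef=np.array([[value]]),
            gcv=0.0,
            predictor_names=tuple(env.layers),
            species_ids=["s0"],
        )

    def test_intercept_only_uniform_raster(self, env40):
        rasters = predict_probabilities(self._intercept_model(0.3, env40), env40)
        assert np.all(rasters["s0"] == pytest.approx(0.3))

    @pytest.mark.parametrize("value,expected", [(-0.2, 0.0), (1.4, 1.0)])
    def test_clamping(self, env40, value, expected):
        rasters = predict_probabilities(self._intercept_model(value, env40), env40)
        assert np.all(rasters["s0"] == expected)

    def test_missing_layer_is_named(self, env40):
        import copy

        model = self._intercept_model(0.3, env40)
        broken = copy.copy(env40)
        broken.layers = {k: v for k, v in env40.layers.items() if k != "slope"}
        with pytest.raises(KeyError, match="slope"):
            predict_probabilities(model, broken)

    def test_training_predictions_match_explicit_basis_expansion(self, env40, species12):
        occ = synthgeo.sample_occurrences(species12, env40, seed=5)
        m = build_site_species_matrix(occ, env40)
        model = fit_mars_multiresponse(m)
        B = np.column_stack([bf.evaluate(m.X) for bf in model.basis])
        raw = B @ model.coef
        pred = model.predict(m.X)
        inside = (raw >= 0) & (raw <= 1)
        np.testing.assert_allclose(pred[inside], raw[inside], atol=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_ties(self):
        assert compute_auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_worked_pair_count(self):
        # 3 concordant pairs of 4: (.8,.6) (.8,.2) (.4,.2); discordant (.4,.6)
        assert compute_auc([0.8, 0.4], [0.6, 0.2]) == 0.75

    def test_empty_side_is_nan(self):
        assert np.isnan(compute_auc([], [0.1]))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_pair_count(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(1, 9))
        a = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=rng.integers(1, 9))
        conc = sum((pi > ai) + 0.5 * (pi == ai) for pi in p for ai in a)
        assert compute_auc(p, a) == pytest.approx(conc / (p.size * a.size))


def test_widespread_species_score_lower_fit_auc(default_study):
    """Under inventory pseudo-absences, fit AUC declines with prevalence:
    a widespread species' pseudo-absences largely sit inside its own
    suitable area, so its presences cannot be ranked cleanly above them.
    Narrow specialists separate almost perfectly."""
    evals = default_study.evals
    auc = np.concatenate([e.auc for e in evals])
    ids = [s for e in evals for s in e.species_ids]
    prev = {sp.species_id: sp.prevalence for sp in default_study.world.species}
    p = np.array([prev[s] for s in ids])
    assert np.corrcoef(p, auc)[0, 1] < -0.5
    assert np.nanmean(auc[p < np.median(p)]) > np.nanmean(auc[p >= np.median(p)])
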