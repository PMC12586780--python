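import math

import numpy as np
import pytest

from thermodive import (
    AllometricLine,
    McmcSettings,
    assign_grafen_lengths,
    compute_dic,
    contrast_at_mass,
    fit_phylo_mixed,
    parse_newick,
    phylo_covariance,
    predict_k_at_mass,
    rank_models,
    random_species_tree,
    simulate_comparative_dataset,
    synth,
)
from thermodive.phylo import PosteriorFit, validate_species_table


class TestNewick:
    def test_cherry_plus_outgroup(self):
        t = parse_newick("((A,B),C);")
        assert sorted(t.tip_names) == ["A", "B", "C"]
        assert t.n_internal == 2

    def test_star_tree(self):
        t = parse_newick("(A,B,C);")
        assert t.n_tips == 3
        assert t.n_internal == 1

    def test_round_trip_preserves_topology(self):
        t = parse_newick("((A,B),(C,(D,E)));")
        t2 = parse_newick(t.newick())
        assert sorted(t2.tip_names) == sorted(t.tip_names)
        assert phylo_covariance(assign_grafen_lengths(t2)).loc[
            t.tip_names, t.tip_names
        ].equals(phylo_covariance(assign_grafen_lengths(t)))

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="Newick|malformed"):
            parse_newick("((A,B,C;")


class TestGrafen:
    def test_two_tip_tree_has_unit_branches(self):
        g = assign_grafen_lengths(parse_newick("(A,B);"))
        lengths = [lf.edge.length for lf in g.dendropy_tree.leaf_node_iter()]
        assert lengths == [1.0, 1.0]

    def test_three_tip_heights(self):
        g = assign_grafen_lengths(parse_newick("((A,B),C);"))
        by_tip = {lf.taxon.label: lf.edge.length
                  for lf in g.dendropy_tree.leaf_node_iter()}
        assert by_tip["A"] == by_tip["B"] == pytest.approx(0.5)
        assert by_tip["C"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_random_topologies_are_ultrametric_with_unit_depth(self, seed):
        tree = random_species_tree(2 + 3 * seed + 2, seed=seed)
        g = assign_grafen_lengths(tree)
        t = g.dendropy_tree
        depths = {}
        for node in t.preorder_node_iter():
            parent = node.parent_node
            depths[node] = 0.0 if parent is None else depths[parent] + node.edge.length
        tip_depths = [depths[lf] for lf in t.leaf_node_iter()]
        np.testing.assert_allclose(tip_depths, 1.0, atol=1e-12)


class TestCovariance:
    def test_star_tree_gives_identity(self):
        g = assign_grafen_lengths(parse_newick("(A,B,C,D);"))
        np.testing.assert_allclose(phylo_covariance(g).to_numpy(), np.eye(4))

    def test_shared_path_entries(self):
        g = assign_grafen_lengths(parse_newick("((A,B),C);"))
        cov = phylo_covariance(g)
        assert cov.loc["A", "B"] == pytest.approx(0.5)
        assert cov.loc["A", "C"] == 0.0
        np.testing.assert_allclose(np.diag(cov.to_numpy()), 1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_psd_and_unit_diagonal(self, seed):
        g = assign_grafen_lengths(random_species_tree(10, seed=seed))
        cov = phylo_covariance(g).to_numpy()
        assert np.linalg.eigvalsh(cov).min() >= -1e-10
        np.testing.assert_allclose(np.diag(cov), 1.0)

    def test_missing_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            phylo_covariance(parse_newick("((A,B),C);"))


class TestSpeciesTable:
    def test_missing_column_and_bad_values(self):
        tree = random_species_tree(3, seed=0)
        df = simulate_comparative_dataset(tree, set(),
                                          synth.DEFAULT_COMPARATIVE_LINES, seed=0)
        with pytest.raises(ValueError, match="mass_kg"):
            validate_species_table(df.drop(columns=["mass_kg"]))
        bad = df.copy()
        bad.loc[0, "k_warm"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            validate_species_table(bad)

    def test_species_must_be_on_tree(self):
        tree = random_species_tree(3, seed=0)
        df = simulate_comparative_dataset(tree, set(),
                                          synth.DEFAULT_COMPARATIVE_LINES, seed=0)
        other = random_species_tree(3, seed=0, prefix="x")
        with pytest.raises(ValueError, match="not in tree"):
            validate_species_table(df, other)


QUICK = McmcSettings(iterations=4000, burn_in=400, thin=4)


class TestMixedModel:
    def test_exact_linear_data_concentrates_on_truth(self):
        # no noise at all: the slope posterior collapses onto the
        # generating line
        tree = random_species_tree(10, seed=1)
        lines = {"k_warm": {True: synth.GroupLine(-1.0, -0.3),
                            False: synth.GroupLine(-1.0, -0.3)}}
        df = simulate_comparative_dataset(tree, set(), lines, sd_phylo=0,
                                          sd_species=0, sd_resid=0,
                                          individuals_per_species=2, seed=2)
        fit = fit_phylo_mixed(df, tree, response="k_warm", formula="mass",
                              mcmc=QUICK, seed=0)
        slope = fit.coef_draws("log10_mass")
        assert slope.mean() == pytest.approx(-0.3, abs=1e-2)
        assert slope.std() < 1e-2

    def test_single_group_interaction_design_rejected(self):
        tree = random_species_tree(6, seed=0)
        df = simulate_comparative_dataset(tree, set(),
                                          synth.DEFAULT_COMPARATIVE_LINES, seed=0)
        with pytest.raises(ValueError, match="both groups"):
            fit_phylo_mixed(df, tree, formula="mass*endo", mcmc=QUICK, seed=0)

    def test_deterministic_under_seed(self):
        tree = random_species_tree(6, seed=5)
        df = simulate_comparative_dataset(tree, {tree.tip_names[0],
                                                 tree.tip_names[1]},
                                          synth.DEFAULT_COMPARATIVE_LINES, seed=3)
        a = fit_phylo_mixed(df, tree, response="ratio", formula="mass+endo",
                            mcmc=QUICK, seed=7)
        b = fit_phylo_mixed(df, tree, response="ratio", formula="mass+endo",
                            mcmc=QUICK, seed=7)
        np.testing.assert_array_equal(a.beta, b.beta)
        assert a.dic == b.dic

    def test_retained_draw_count(self):
        tree = random_species_tree(5, seed=0)
        df = simulate_comparative_dataset(tree, set(),
                                          synth.DEFAULT_COMPARATIVE_LINES, seed=0)
        fit = fit_phylo_mixed(df, tree, response="k_cool", formula="mass",
                              mcmc=QUICK, seed=0)
        assert fit.n_retained == QUICK.n_retained == 900
        assert (fit.sigma2_resid > 0).all()


def _point_mass_fit(beta_hat, y, X, sp_idx, q, sigma2=0.04, draws=120):
    return PosteriorFit(
        response="k_warm", formula="mass",
        coef_names=["intercept", "log10_mass"], species=[f"s{i}" for i in range(q)],
        beta=np.tile(beta_hat, (draws, 1)),
        u=np.zeros((draws, q)), s=np.zeros((draws, q)),
        sigma2_phylo=np.full(draws, 1e-4), sigma2_species=np.full(draws, 1e-4),
        sigma2_resid=np.full(draws, sigma2),
        dic=math.nan, settings=QUICK, seed=0,
        y=y, X=X, species_index=sp_idx, data_hash="h",
    )


class TestDic:
    def test_point_mass_posterior_has_zero_effective_parameters(self):
        rng = np.random.default_rng(0)
        n, q = 30, 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta_hat = np.array([0.5, -0.3])
        y = X @ beta_hat + rng.normal(0, 0.2, n)
        fit = _point_mass_fit(beta_hat, y, X, np.arange(n), q)
        dic = compute_dic(fit)
        s2 = 0.04
        d_hat = n * math.log(2 * math.pi * s2) + float(
            ((y - X @ beta_hat) ** 2).sum()) / s2
        assert dic == pytest.approx(d_hat, abs=1e-9)  # pD = 0

    def test_requires_enough_draws(self):
        rng = np.random.default_rng(0)
        X = np.ones((10, 1))
        fit = _point_mass_fit(np.array([0.0]), rng.normal(size=10), X,
                              np.arange(10), 10, draws=50)
        fit.coef_names = ["intercept"]
        with pytest.raises(ValueError, match="100"):
            compute_dic(fit)


class TestRanking:
    def _dummy(self, formula, dic):
        f = _point_mass_fit(np.array([0.0, 0.0]), np.zeros(5), np.ones((5, 2)),
                            np.arange(5), 5)
        f.formula = formula
        f.dic = dic
        return f

    def test_single_fit_has_zero_delta(self):
        tab = rank_models([self._dummy("mass", -10.0)])
        assert tab["delta_dic"].tolist() == [0.0]

    def test_published_ratio_response_deltas(self):
        # DIC triple reported for the warming:cooling ratio response
        fits = [self._dummy("mass*endo", -47.24), self._dummy("mass+endo", -34.78),
                self._dummy("mass", -34.41)]
        tab = rank_models(fits)
        assert tab["formula"].tolist() == ["mass*endo", "mass+endo", "mass"]
        np.testing.assert_allclose(tab["delta_dic"], [0.0, 12.46, 12.83], atol=1e-9)

    def test_input_order_irrelevant(self):
        fits = [self._dummy("mass", -34.41), self._dummy("mass*endo", -47.24),
                self._dummy("mass+endo", -34.78)]
        tab = rank_models(fits)
        assert tab["formula"].tolist() == ["mass*endo", "mass+endo", "mass"]

    def test_mismatched_data_rejected(self):
        a = self._dummy("mass", -10.0)
        b = self._dummy("mass+endo", -12.0)
        b.data_hash = "different"
        with pytest.raises(ValueError, match="different"):
            rank_models([a, b])


class TestAllometry:
    def test_intercept_at_unit_mass(self):
        line = AllometricLine.from_coefficient(0.11, -0.21)
        assert predict_k_at_mass(line, 1.0) == pytest.approx(0.11)

    def test_positive_mass_required(self):
        with pytest.raises(ValueError, match="positive"):
            predict_k_at_mass(AllometricLine(0.0, -0.5), 0.0)

    def test_cooling_contrast_at_140kg(self):
        endo = AllometricLine.from_coefficient(0.11, -0.68)
        ecto = AllometricLine.from_coefficient(0.11, -0.54)
        assert contrast_at_mass(ecto, endo, 140.0) == pytest.approx(2.0, abs=0.05)
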