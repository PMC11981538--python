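import logging
import math

import numpy as np
import pytest

from trophoweb import (
    FluxParameters,
    FoodWebError,
    compute_fluxes,
    flux_matrix_log10,
    flux_summaries,
    metabolic_losses,
    preference_matrix,
    solve_fluxes,
    trophic_levels,
)
from trophoweb.flux import balance_residuals, prepare_flux_web
from trophoweb.synthetic import SyntheticWebSpec, generate_niche_web

from conftest import make_web


def two_node_web():
    return make_web(
        [("plant", "bug")],
        categories={"plant": "producer"},
        biomass={"plant": 1.0, "bug": 1.0},
        body_mass={"bug": 1.0},
    )


class TestMetabolicLosses:
    def test_basal_loss_is_zero(self):
        losses = metabolic_losses(two_node_web())
        assert losses["plant"] == 0.0

    def test_unit_mass_unit_biomass(self):
        # M = 1 g, B = 1 g -> X = a = 0.71
        losses = metabolic_losses(two_node_web())
        assert losses["bug"] == pytest.approx(0.71)

    def test_allometric_scaling(self):
        # M = 16 g (16^-0.25 = 0.5), B = 2 g -> X = 0.71 * 0.5 * 2 = 0.71
        web = make_web(
            [("plant", "crab")],
            categories={"plant": "producer"},
            biomass={"crab": 2.0},
            body_mass={"crab": 16.0},
        )
        assert metabolic_losses(web)["crab"] == pytest.approx(0.71)

    def test_custom_coefficients(self):
        web = two_node_web()
        losses = metabolic_losses(web, FluxParameters(allometric_a=1.5, allometric_b=-0.5))
        assert losses["bug"] == pytest.approx(1.5)


class TestPreferenceMatrix:
    def test_single_prey_gets_full_preference(self):
        web, biomass = prepare_flux_web(two_node_web())
        w = preference_matrix(web, biomass)
        assert w.loc["plant", "bug"] == pytest.approx(1.0)

    def test_biomass_scaled_shares(self):
        web = make_web(
            [("detritus", "wormA"), ("detritus", "wormB"),
             ("wormA", "fish"), ("wormB", "fish")],
            categories={"detritus": "detritus"},
            biomass={"wormA": 3.0, "wormB": 1.0, "fish": 2.0},
            body_mass={"wormA": 0.1, "wormB": 0.1, "fish": 10.0},
        )
        sub, biomass = prepare_flux_web(web)
        w = preference_matrix(sub, biomass)
        assert w.loc["wormA", "fish"] == pytest.approx(0.75)
        assert w.loc["wormB", "fish"] == pytest.approx(0.25)

    def test_basal_placeholder_enters_preference_weighting(self):
        # basal biomass is the placeholder 1 regardless of recorded biomass
        web = make_web(
            [("algae", "fish"), ("detritus", "fish")],
            categories={"algae": "producer", "detritus": "detritus"},
            biomass={"algae": 500.0, "fish": 2.0},
            body_mass={"fish": 10.0},
        )
        sub, biomass = prepare_flux_web(web)
        w = preference_matrix(sub, biomass)
        assert w.loc["algae", "fish"] == pytest.approx(0.5)
        assert w.loc["detritus", "fish"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_columns_sum_to_one_over_prey(self, seed):
        web = generate_niche_web(SyntheticWebSpec(n_nodes=15, seed=seed))
        sub, biomass = prepare_flux_web(web)
        w = preference_matrix(sub, biomass)
        for consumer in sub.nodes:
            if sub.prey_of(consumer):
                assert w[consumer].sum() == pytest.approx(1.0)


class TestSolveFluxes:
    def test_two_node_balance_forces_flux(self):
        """plant -> consumer with X = 0.545 and e_plant = 0.545 gives F = 1."""
        web, biomass = prepare_flux_web(two_node_web())
        w = preference_matrix(web, biomass)
        fluxes = solve_fluxes(web, w, {"plant": 0.0, "bug": 0.545})
        assert fluxes.flux("plant", "bug") == pytest.approx(1.0)

    def test_three_node_chain_matches_hand_solve(self):
        """detritus -> consumer -> predator, against the 2-unknown dense solve."""
        web = make_web(
            [("detritus", "consumer"), ("consumer", "predator")],
            categories={"detritus": "detritus"},
            biomass={"consumer": 2.0, "predator": 1.0},
            body_mass={"consumer": 1.0, "predator": 16.0},
        )
        params = FluxParameters()
        sub, biomass = prepare_flux_web(web, params)
        w = preference_matrix(sub, biomass)
        losses = metabolic_losses(sub, params)
        fluxes = solve_fluxes(sub, w, losses, params)
        # hand solve: e_d * G_c = X_c + G_p ;  e_c * G_p = X_p
        e_d, e_c = 0.158, 0.906
        a = np.array([[e_d, -1.0], [0.0, e_c]])
        b = np.array([losses["consumer"], losses["predator"]])
        g_c, g_p = np.linalg.solve(a, b)
        assert fluxes.flux("detritus", "consumer") == pytest.approx(g_c)
        assert fluxes.flux("consumer", "predator") == pytest.approx(g_p)

    @pytest.mark.parametrize("seed", range(8))
    def test_balance_residual_and_nonnegativity(self, seed):
        web = generate_niche_web(SyntheticWebSpec(n_nodes=20, seed=seed))
        params = FluxParameters()
        sub, biomass = prepare_flux_web(web, params)
        w = preference_matrix(sub, biomass)
        losses = metabolic_losses(sub, params)
        fluxes = solve_fluxes(sub, w, losses, params)
        assert (fluxes.matrix.to_numpy() >= 0).all()
        for node, res in balance_residuals(fluxes, sub, losses, params).items():
            assert abs(res) < 1e-9 * (1.0 + abs(losses[node]))
        # structural zeros: flux only where an edge exists
        for i in sub.nodes:
            for j in sub.nodes:
                if fluxes.matrix.loc[i, j] > 0:
                    assert (i, j) in sub.edges

    def test_losses_scale_fluxes_linearly(self):
        web = generate_niche_web(SyntheticWebSpec(n_nodes=15, seed=4))
        sub, biomass = prepare_flux_web(web)
        w = preference_matrix(sub, biomass)
        losses = metabolic_losses(sub)
        base = solve_fluxes(sub, w, losses)
        scaled = solve_fluxes(sub, w, {k: 3.0 * v for k, v in losses.items()})
        np.testing.assert_allclose(
            scaled.matrix.to_numpy(), 3.0 * base.matrix.to_numpy(), rtol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_tree_web_matches_closed_form_recursion(self, seed):
        """On tree-shaped webs the apex-down recursion is exact."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        names = [f"v{i:02d}" for i in range(n)]
        # each node's energy flows to exactly one predator (node with lower index);
        # node 0 is the apex, leaves are basal producers
        edges = [(names[j], names[int(rng.integers(0, j))]) for j in range(1, n)]
        prey_of = {}
        for prey, pred in edges:
            prey_of.setdefault(pred, []).append(prey)
        basal = [nm for nm in names if nm not in prey_of]
        web = make_web(
            edges,
            categories={nm: "producer" for nm in basal},
            biomass={nm: float(rng.uniform(0.5, 5.0)) for nm in names if nm not in basal},
            body_mass={nm: float(rng.uniform(0.1, 10.0)) for nm in names if nm not in basal},
        )
        params = FluxParameters()
        sub, biomass = prepare_flux_web(web, params)
        w = preference_matrix(sub, biomass)
        losses = metabolic_losses(sub, params)
        fluxes = solve_fluxes(sub, w, losses, params)

        eff = {nm: params.efficiency_of(web.category(nm)) for nm in names}
        consumption = {}

        def recurse(node):  # apex first, then down the tree
            outflow = 0.0
            for pred in sub.predators_of(node):
                if pred not in consumption:
                    recurse(pred)
                outflow += w.loc[node, pred] * consumption[pred]
            gain = sum(w.loc[p, node] * eff[p] for p in sub.prey_of(node))
            consumption[node] = (losses[node] + outflow) / gain

        for node in sub.nodes:
            if node in basal:
                continue
            if node not in consumption:
                recurse(node)
        for prey, pred in sub.edges:
            expected = w.loc[prey, pred] * consumption[pred]
            assert fluxes.flux(prey, pred) == pytest.approx(expected, abs=1e-12)

    def test_negative_demand_is_infeasible(self):
        web, biomass = prepare_flux_web(two_node_web())
        w = preference_matrix(web, biomass)
        with pytest.raises(FoodWebError, match="infeasible"):
            solve_fluxes(web, w, {"plant": 0.0, "bug": -1.0})

    def test_dropped_dataless_node_logged_and_others_unchanged(self, caplog):
        # apex eats only the basal node; dropping it must not move the
        # fluxes along the independent plant -> c -> d chain
        full = make_web(
            [("plant", "apex"), ("plant", "c"), ("c", "d")],
            categories={"plant": "producer"},
            biomass={"c": 1.0, "d": 2.0},
            body_mass={"c": 1.0, "d": 1.0},
        )
        with caplog.at_level(logging.WARNING):
            fluxes_full, sub = compute_fluxes(full)
        assert "apex" not in sub.nodes
        assert any("apex" in rec.message for rec in caplog.records)
        pruned = make_web(
            [("plant", "c"), ("c", "d")],
            categories={"plant": "producer"},
            biomass={"c": 1.0, "d": 2.0},
            body_mass={"c": 1.0, "d": 1.0},
        )
        fluxes_pruned, _ = compute_fluxes(pruned)
        assert fluxes_full.flux("plant", "c") == pytest.approx(
            fluxes_pruned.flux("plant", "c")
        )
        assert fluxes_full.flux("c", "d") == pytest.approx(fluxes_pruned.flux("c", "d"))


class TestDisplayAndSummaries:
    def test_log10_values_and_structural_zeros(self):
        web = make_web(
            [("plant", "bug"), ("bug", "fish")],
            categories={"plant": "producer"},
            biomass={"bug": 1.0, "fish": 1.0},
            body_mass={"bug": 1.0, "fish": 1.0},
        )
        fluxes, sub = compute_fluxes(web)
        display = flux_matrix_log10(fluxes)
        pos = fluxes.matrix.loc["plant", "bug"]
        assert display.loc["plant", "bug"] == pytest.approx(math.log10(pos))
        assert math.isnan(display.loc["bug", "plant"])  # structural zero -> missing

    def test_log10_rows_ordered_by_trophic_level(self):
        web = generate_niche_web(SyntheticWebSpec(n_nodes=12, seed=2))
        fluxes, sub = compute_fluxes(web)
        levels = trophic_levels(sub)
        display = flux_matrix_log10(fluxes, levels)
        tls = [levels[n] for n in display.index]
        assert tls == sorted(tls)

    def test_shannon_diversity_limits(self):
        web, biomass = prepare_flux_web(two_node_web())
        w = preference_matrix(web, biomass)
        single = solve_fluxes(web, w, {"plant": 0.0, "bug": 0.545})
        assert flux_summaries(single)["shannon_diversity"] == pytest.approx(0.0)

    def test_equal_fluxes_give_log_k(self):
        k = 4
        web = make_web(
            [(f"plant{i}", "bug") for i in range(k)],
            categories={f"plant{i}": "producer" for i in range(k)},
            biomass={"bug": 1.0},
            body_mass={"bug": 1.0},
        )
        fluxes, _ = compute_fluxes(web)
        summary = flux_summaries(fluxes)
        assert summary["n_fluxes"] == k
        assert summary["shannon_diversity"] == pytest.approx(math.log(k))

    def test_summaries_match_direct_summation(self):
        web = generate_niche_web(SyntheticWebSpec(n_nodes=10, seed=9))
        fluxes, _ = compute_fluxes(web)
        values = [v for v in fluxes.matrix.to_numpy().ravel() if v > 0]
        total = sum(values)
        h = -sum((v / total) * math.log(v / total) for v in values)
        summary = flux_summaries(fluxes)
        assert summary["total_flux"] == pytest.approx(total)
        assert summary["shannon_diversity"] == pytest.approx(h)
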