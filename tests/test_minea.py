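"""Minimal networks vs brute force; enrichment statistics."""

import math

import pandas as pd
import pytest

from fluxshift.minea import (
    MetabolicTask,
    MinimalNetwork,
    brute_force_minimal,
    derive_tasks_from_biomass,
    minea_enrichment,
    minimal_network,
)
from fluxshift.model import MetabolicModel, Metabolite, Reaction
from fluxshift.synthetic import ToySpec, make_toy_model


def _model(reactions, biomass="DEMAND_HOST"):
    mets = sorted({m for r in reactions for m in r.stoichiometry})
    return MetabolicModel(
        "tiny", [Metabolite(m, compartment=m.rsplit("_", 1)[1]) for m in mets],
        reactions, biomass_reaction_id=biomass,
    )


def chain_task_model():
    """uptake -> A -> B; the task demands B."""
    rxns = [
        Reaction("EX_a", {"a_e": -1.0}, -10.0, 0.0),
        Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, 0.0, 10.0),
        Reaction("CONV", {"a_c": -1.0, "b_c": 1.0}, 0.0, 10.0),
        Reaction("DEMAND_HOST", {"b_c": -1.0}, 0.0, 10.0),
    ]
    return _model(rxns)


def parallel_routes_model(symmetric: bool):
    """Two routes from uptake to the demanded product: 1 step vs 2 (or 1 vs 1)."""
    rxns = [
        Reaction("EX_a", {"a_e": -1.0}, -10.0, 0.0),
        Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, 0.0, 10.0),
        Reaction("SHORT", {"a_c": -1.0, "p_c": 1.0}, 0.0, 10.0),
        Reaction("LONG1", {"a_c": -1.0, "i_c": 1.0}, 0.0, 10.0),
        Reaction("LONG2", {"i_c": -1.0, "p_c": 1.0}, 0.0, 10.0),
        Reaction("DEMAND_HOST", {"p_c": -1.0}, 0.0, 10.0),
    ]
    if symmetric:
        rxns[2] = Reaction("SHORT", {"a_c": -1.0, "q_c": 1.0}, 0.0, 10.0)
        rxns.append(Reaction("SHORT2", {"q_c": -1.0, "p_c": 1.0}, 0.0, 10.0))
    return _model(rxns)


TASK_B = MetabolicTask("taskb", "demand b", {"b_c": -1.0}, min_rate=0.1)
TASK_P = MetabolicTask("taskp", "demand p", {"p_c": -1.0}, min_rate=0.1)


class TestMinimalNetworks:
    def test_chain_minimal_set_is_whole_chain(self):
        model = chain_task_model()
        nets = minimal_network(model, TASK_B)
        assert len(nets) == 1
        assert nets[0].reactions == frozenset({"EX_a", "T_a", "CONV"})
        size, sets = brute_force_minimal(model, TASK_B)
        assert size == 3 and sets == [nets[0].reactions]

    def test_short_route_beats_long_route(self):
        model = parallel_routes_model(symmetric=False)
        nets = minimal_network(model, TASK_P)
        assert len(nets) == 1
        assert nets[0].reactions == frozenset({"EX_a", "T_a", "SHORT"})
        size, sets = brute_force_minimal(model, TASK_P)
        assert size == 3 and set(sets) == {nets[0].reactions}

    def test_symmetric_routes_give_two_alternatives(self):
        model = parallel_routes_model(symmetric=True)
        nets = minimal_network(model, TASK_P)
        assert {n.reactions for n in nets} == {
            frozenset({"EX_a", "T_a", "LONG1", "LONG2"}),
            frozenset({"EX_a", "T_a", "SHORT", "SHORT2"}),
        }
        size, sets = brute_force_minimal(model, TASK_P)
        assert size == 4 and set(sets) == {n.reactions for n in nets}

    def test_witness_carries_demand_within_network(self):
        model = chain_task_model()
        net = minimal_network(model, TASK_B)[0]
        assert net.witness["DM_task_taskb"] >= TASK_B.min_rate - 1e-9
        off = set(model.reaction_ids()) - net.reactions - {"DEMAND_HOST"}
        assert all(abs(net.witness[r]) < 1e-9 for r in off)

    def test_infeasible_task_returns_empty(self):
        model = chain_task_model()
        task = MetabolicTask("ghost", "no such product", {"a_e": 1.0}, min_rate=0.1)
        # demanding net *production* of a_e beyond what the closed EX allows
        closed = model.copy()
        closed.set_reaction(closed.reaction("EX_a").with_bounds(0.0, 0.0))
        assert minimal_network(closed, TASK_B) == []
        size, sets = brute_force_minimal(closed, TASK_B)
        assert math.isinf(size) and sets == []

    def test_smaller_subnetworks_cannot_carry_demand(self):
        model = parallel_routes_model(symmetric=False)
        size, sets = brute_force_minimal(model, TASK_P)
        # definitional: brute force enumerated ascending, so nothing below `size`
        assert size == 3
        for s in sets:
            assert len(s) == 3


class TestTaskDerivation:
    def test_canonical_toy_model_yields_seven_tasks(self, toy_model):
        tasks = derive_tasks_from_biomass(toy_model)
        assert [t.id for t in tasks] == [
            "protein", "lipid", "dna", "rna", "atp", "superoxide", "lipid_droplet"
        ]

    def test_missing_lipid_droplet_yields_six_tasks_with_warning(self):
        model = make_toy_model(ToySpec(seed=1, include_lipid_droplet=False))
        with pytest.warns(UserWarning, match="lipid_droplet"):
            tasks = derive_tasks_from_biomass(model)
        assert len(tasks) == 6

    def test_zero_coefficient_class_excluded(self, toy_model):
        model = toy_model.copy()
        bio = model.reaction(model.biomass_reaction_id)
        stoich = dict(bio.stoichiometry)
        stoich["dna_c"] = 0.0
        model.set_reaction(Reaction(bio.id, stoich, bio.lower_bound, bio.upper_bound,
                                    bio.gpr, bio.subsystem))
        with pytest.warns(UserWarning, match="dna"):
            tasks = derive_tasks_from_biomass(model)
        assert "dna" not in [t.id for t in tasks]


def _networks(union):
    return {"t1": [MinimalNetwork("t1", frozenset(union), len(union), 0, {})]}


class TestEnrichment:
    def test_worked_hypergeometric_example(self):
        # union of 5 with 3 deregulated; background 20 with 5 deregulated
        background = [f"r{i}" for i in range(20)]
        dereg = {r: None for r in ["r0", "r1", "r2", "r10", "r11"]}
        union = ["r0", "r1", "r2", "r3", "r4"]
        res = minea_enrichment(_networks(union), dereg=dereg, background=background)
        assert res[0].p_value == pytest.approx(1126 / 15504, abs=1e-12)

    def test_exact_tail_matches_direct_summation(self):
        background = [f"r{i}" for i in range(20)]
        dereg = {r: None for r in ["r0", "r1", "r2", "r10", "r11"]}
        union = ["r0", "r1", "r2", "r3", "r4"]
        p = minea_enrichment(_networks(union), dereg=dereg, background=background)[0].p_value
        direct = sum(
            math.comb(5, k) * math.comb(15, 5 - k) for k in (3, 4, 5)
        ) / math.comb(20, 5)
        assert p == pytest.approx(direct, abs=1e-12)

    def test_no_deregulation_anywhere_gives_p_one(self):
        res = minea_enrichment(_networks(["r0", "r1"]), dereg={},
                               background=[f"r{i}" for i in range(10)])
        assert res[0].p_value == 1.0

    def test_network_equal_to_background_is_degenerate(self):
        background = [f"r{i}" for i in range(8)]
        dereg = {r: None for r in background[:3]}
        res = minea_enrichment(_networks(background), dereg=dereg, background=background)
        assert res[0].p_value == pytest.approx(1.0)

    def test_bh_adjustment_is_monotone_in_p_rank(self):
        background = [f"r{i}" for i in range(30)]
        dereg = {r: None for r in background[:6]}
        networks = {
            f"t{j}": [MinimalNetwork(f"t{j}", frozenset(background[j: j + 5]), 5, 0, {})]
            for j in range(4)
        }
        res = minea_enrichment(networks, dereg=dereg, background=background)
        by_p = sorted(res, key=lambda r: r.p_value)
        qs = [r.q_value for r in by_p]
        assert qs == sorted(qs)

    def test_flux_mode_permutation_p_close_to_exact_on_tiny_case(self):
        background = ["r0", "r1", "r2", "r3"]
        lfc = pd.Series([2.0, 0.1, -0.1, 0.05], index=background)
        res = minea_enrichment(
            _networks(["r0"]), flux_log2_fc=lfc, background=background,
            n_permutations=20_000, seed=1,
        )[0]
        assert res.mean_log2_fc == pytest.approx(2.0)
        # exact: 1 of 4 singletons has |mean| >= 2 -> p = 1/4 (plus-one corrected)
        exact = 0.25
        se = math.sqrt(exact * (1 - exact) / 20_000)
        assert abs(res.p_value - exact) < 3 * se + 1e-3

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            minea_enrichment(_networks(["r0"]), dereg={}, background=[])
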