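"""Generator determinism, validity, and ground-truth round trips."""

import numpy as np
import pytest

from fluxshift.expression import average_fold_change, classify_deregulations, reaction_fold_change
from fluxshift.model import apply_environment, optimize_biomass, write_model
from fluxshift.readouts import GeneSignature, auc_signature_score
from fluxshift.synthetic import (
    ToySpec,
    default_environment,
    make_toy_model,
    plant_flux_truth,
    synthesize_cell_matrix,
    synthesize_expression,
    synthesize_repertoire,
)


class TestToyModel:
    def test_deterministic_per_seed(self, tmp_path):
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        write_model(make_toy_model(ToySpec(seed=7)), a)
        write_model(make_toy_model(ToySpec(seed=7)), b)
        assert a.read_bytes() == b.read_bytes()

    def test_size_and_subsystem_coverage(self):
        model = make_toy_model(ToySpec(seed=0))
        assert 30 <= len(model.reactions) <= 80
        assert len({r.subsystem for r in model.reactions}) >= 7

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_biomass_producible_under_default_medium(self, seed):
        model = apply_environment(make_toy_model(ToySpec(seed=seed)), default_environment())
        opt, _ = optimize_biomass(model)
        assert opt > 0

    def test_isozyme_duplication_grows_named_subsystem(self):
        base = make_toy_model(ToySpec(seed=0))
        big = make_toy_model(ToySpec(seed=0, subsystem_extra={"glycolysis": 3}))
        assert len(big.reactions) == len(base.reactions) + 3
        assert sum(r.subsystem == "glycolysis" for r in big.reactions) == \
            sum(r.subsystem == "glycolysis" for r in base.reactions) + 3

    def test_gpr_patterns_mix_complexes_and_isozymes(self):
        model = make_toy_model(ToySpec(seed=0))
        rules = [str(r.gpr) for r in model.reactions if r.gpr is not None]
        assert any(" and " in g for g in rules)
        assert any(" or " in g for g in rules)


@pytest.fixture(scope="module")
def case():
    model = apply_environment(make_toy_model(ToySpec(seed=4)), default_environment())
    truth = plant_flux_truth(model, seed=4, n_up=3, n_down=2, n_contradictory=2)
    return model, truth


class TestPlantedTruth:

    def test_truth_vectors_are_steady_states_within_bounds(self, case):
        model, truth = case
        S = model.stoichiometric_matrix()
        lb, ub = model.bounds_arrays()
        for v in (truth.v_a, truth.v_b):
            vec = np.array([v[r] for r in model.reaction_ids()])
            assert np.abs(S @ vec).max() < 1e-6
            assert (vec >= lb - 1e-7).all() and (vec <= ub + 1e-7).all()

    def test_planted_ratios_hold_exactly_on_truth(self, case):
        model, truth = case
        for rid, call in truth.planted.items():
            assert truth.v_b[rid] == pytest.approx(call.ratio * truth.v_a[rid], abs=1e-6)
            assert abs(truth.v_a[rid]) >= 0.05 - 1e-9

    def test_contradictory_pair_is_lp_infeasible(self, case):
        from fluxshift.remi import brute_force_consistency

        model, truth = case
        m_max, _ = brute_force_consistency(model, truth.contradictory)
        assert m_max == 1  # only one side of the coupled pair can hold

    def test_brute_force_m_max_matches_construction(self, case):
        from fluxshift.remi import brute_force_consistency

        model, truth = case
        m_max, _ = brute_force_consistency(model, truth.dereg)
        assert m_max == len(truth.planted) + len(truth.contradictory) // 2

    def test_odd_contradiction_count_rejected(self, case):
        model, _ = case
        with pytest.raises(ValueError, match="even"):
            plant_flux_truth(model, n_contradictory=1)


class TestExpressionSynthesis:
    def test_noise_free_classification_recovers_planted_directions(self):
        model = apply_environment(make_toy_model(ToySpec(seed=6)), default_environment())
        truth = plant_flux_truth(model, seed=6, n_up=3, n_down=2, n_contradictory=0)
        expr, _ = synthesize_expression(truth, model, noise_sd=0.0, seed=0)
        fc = average_fold_change(expr, "control", "treated", delta=0.0)
        dereg = classify_deregulations(reaction_fold_change(model, fc))
        for rid, call in truth.planted.items():
            assert dereg[rid].direction == call.direction
            assert dereg[rid].ratio == pytest.approx(call.ratio, rel=1e-9)
        assert set(dereg) == set(truth.planted)

    def test_tables_deterministic_per_seed(self):
        model = apply_environment(make_toy_model(ToySpec(seed=6)), default_environment())
        truth = plant_flux_truth(model, seed=6, n_up=2, n_down=1)
        e1, _ = synthesize_expression(truth, model, noise_sd=0.3, seed=5)
        e2, _ = synthesize_expression(truth, model, noise_sd=0.3, seed=5)
        assert e1.values.equals(e2.values)

    def test_recovery_degrades_with_noise(self):
        """Mean recall of planted calls is non-increasing in noise (averaged over seeds)."""
        model = apply_environment(make_toy_model(ToySpec(seed=8)), default_environment())
        recalls = []
        for noise in (0.0, 0.3, 1.0):
            hits, total = 0, 0
            for seed in range(8):
                truth = plant_flux_truth(model, seed=seed, n_up=3, n_down=2)
                expr, _ = synthesize_expression(truth, model, noise_sd=noise, seed=seed)
                fc = average_fold_change(expr, "control", "treated", delta=0.0)
                dereg = classify_deregulations(reaction_fold_change(model, fc))
                for rid, call in truth.planted.items():
                    total += 1
                    hits += int(dereg.get(rid) is not None
                                and dereg[rid].direction == call.direction)
            recalls.append(hits / total)
        assert recalls[0] == 1.0
        assert recalls[0] >= recalls[1] >= recalls[2] - 0.05


class TestCellMatrix:
    def test_null_effect_gives_equal_means(self, rng):
        sig = GeneSignature("s", tuple(f"sg{i}" for i in range(15)))
        ranks, labels = synthesize_cell_matrix(300, 300, sig, effect=0.0, seed=3)
        scores = auc_signature_score(ranks, sig)
        pos = scores[[c for c in scores.index if labels[c] == "pos"]]
        neg = scores[[c for c in scores.index if labels[c] == "neg"]]
        se = np.sqrt(pos.var() / len(pos) + neg.var() / len(neg))
        assert abs(pos.mean() - neg.mean()) < 3 * se + 1e-3

    def test_strong_effect_separates_groups_across_seeds(self):
        sig = GeneSignature("s", tuple(f"sg{i}" for i in range(15)))
        wins = 0
        for seed in range(20):
            ranks, labels = synthesize_cell_matrix(60, 300, sig, effect=2.5, seed=seed)
            scores = auc_signature_score(ranks, sig)
            pos = scores[[c for c in scores.index if labels[c] == "pos"]].mean()
            neg = scores[[c for c in scores.index if labels[c] == "neg"]].mean()
            wins += int(pos > neg)
        assert wins >= 19

    def test_rank_matrix_is_a_permutation_per_cell(self):
        sig = GeneSignature("s", ("sg0",))
        ranks, _ = synthesize_cell_matrix(5, 50, sig, effect=1.0, seed=0)
        for col in ranks.columns:
            assert sorted(ranks[col]) == list(range(1, 51))


class TestRepertoireSynthesis:
    def test_deterministic_per_seed(self):
        a = synthesize_repertoire(40, 1.0, 4000, seed=9)
        b = synthesize_repertoire(40, 1.0, 4000, seed=9)
        assert a.equals(b)

    def test_flat_exponent_approaches_even_repertoire(self):
        from fluxshift.readouts import preprocess_repertoire, repertoire_metrics

        even = []
        for seed in range(5):
            raw = synthesize_repertoire(50, 0.0, 100_000, seed=seed,
                                        out_of_frame_fraction=0.0, singleton_count=0)
            even.append(repertoire_metrics(preprocess_repertoire(raw)).pielou_evenness)
        assert np.mean(even) > 0.98

    def test_all_singletons_preprocess_to_empty(self):
        import pandas as pd
        from fluxshift.readouts import preprocess_repertoire, repertoire_metrics

        raw = pd.DataFrame({
            "nt_seq": ["ATGGCT", "TGGAAA", "GCTGCT"],
            "frame": ["in", "in", "in"],
            "count": [1, 1, 1],
        })
        table = preprocess_repertoire(raw)
        assert table.empty
        with pytest.raises(ValueError):
            repertoire_metrics(table)

    def test_contains_preprocessing_bait(self):
        raw = synthesize_repertoire(40, 1.0, 4000, seed=2)
        assert (raw["frame"] == "out").any()
        assert (raw["count"] == 1).any()
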