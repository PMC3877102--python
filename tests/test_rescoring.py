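"""Re-scoring system A: training table, forest contracts, pose ranking."""

import numpy as np
import pytest

from dockscreen.contacts import ContactVector, N_CONTACT_TYPES
from dockscreen.descriptors import N_DESCRIPTORS
from dockscreen.errors import DegenerateLabelsError, SchemaMismatchError
from dockscreen.rescoring import (
    INACTIVE_PKD,
    build_training_table,
    rank_poses,
    rescore_pose,
    train_rescorer,
)
from dockscreen.structures import MolecularStructure, Pose
from dockscreen.synthetic import FixtureRecipe, fixture_descriptors, make_training_set


def _contact(seed):
    rng = np.random.default_rng(seed)
    return ContactVector(counts=rng.poisson(8, N_CONTACT_TYPES))


def _desc(i=0):
    return fixture_descriptors(i)


class TestTrainingTable:
    def test_inactives_pinned_to_pkd_one(self):
        actives = [(_contact(1), _desc(0), 6.3), (_contact(2), _desc(1), 8.1)]
        inactives = [(_contact(i), _desc(i)) for i in range(3, 6)]
        table = build_training_table(actives, inactives)
        assert len(table) == 5
        assert [ex.label_pkd for ex in table] == [6.3, 8.1, 1.0, 1.0, 1.0]
        assert [ex.active for ex in table] == [True, True, False, False, False]
        assert INACTIVE_PKD == 1.0

    def test_without_inactives(self):
        table = build_training_table([(_contact(1), _desc(0), 5.0)])
        assert len(table) == 1 and table[0].active

    def test_generator_round_trip(self):
        recipe = FixtureRecipe(n_complexes=1000, fraction_inactive=0.3)
        examples, truth = make_training_set(recipe, seed=11)
        assert len(examples) == 1000
        assert [ex.label_pkd for ex in examples] == truth.labels
        inactive = [ex for ex in examples if not ex.active]
        assert len(inactive) == 300
        assert all(ex.label_pkd == INACTIVE_PKD for ex in inactive)

    def test_malformed_entry_named(self):
        with pytest.raises(SchemaMismatchError, match="entry 0"):
            build_training_table([(_contact(1), 6.3)])  # missing descriptors


class TestTrainRescorer:
    def test_requires_enough_examples(self):
        table = build_training_table([(_contact(i), _desc(i), float(i)) for i in range(5)])
        with pytest.raises(DegenerateLabelsError):
            train_rescorer(table, seed=0)

    def test_requires_label_diversity(self):
        table = build_training_table([(_contact(i), _desc(i), 5.0) for i in range(25)])
        with pytest.raises(DegenerateLabelsError):
            train_rescorer(table, seed=0)

    def test_two_distinct_labels_is_the_degenerate_floor(self):
        table = build_training_table(
            [(_contact(i), _desc(i), 5.0) for i in range(24)]
            + [(_contact(99), _desc(24), 9.0)]
        )
        model = train_rescorer(table, seed=0, n_estimators=10)
        assert model.label_range == (5.0, 9.0)

    def test_same_seed_same_predictions(self, small_training_set):
        examples, _ = small_training_set
        probes = np.vstack([ex.features for ex in examples[:20]])
        m1 = train_rescorer(examples, seed=4, n_estimators=30)
        m2 = train_rescorer(examples, seed=4, n_estimators=30)
        np.testing.assert_array_equal(m1.predict(probes), m2.predict(probes))

    def test_noiseless_parameter_recovery(self, small_training_set, model_a):
        examples, _ = small_training_set
        recipe = FixtureRecipe(n_complexes=120, noise_sigma=0.0)
        holdout, truth = make_training_set(recipe, seed=99)
        pred = model_a.predict(np.vstack([ex.features for ex in holdout]))
        from dockscreen.pipeline import pearson_r

        assert pearson_r(pred, truth.labels) >= 0.85


class TestRescorePose:
    def test_single_fully_grown_tree_memorizes(self, small_training_set):
        examples, _ = small_training_set
        model = train_rescorer(
            examples[:50], seed=0, n_estimators=1, bootstrap=False, max_features=1.0
        )
        ex = examples[7]
        assert rescore_pose(model, ex.contact, ex.descriptors) == pytest.approx(
            ex.label_pkd, abs=1e-12
        )

    def test_prediction_bounded_by_training_labels(self, model_a, small_training_set):
        examples, _ = small_training_set
        lo, hi = model_a.label_range
        rng = np.random.default_rng(5)
        for seed in range(50):
            probe = ContactVector(counts=rng.poisson(20, N_CONTACT_TYPES))
            pred = rescore_pose(model_a, probe, _desc(seed))
            assert lo - 1e-9 <= pred <= hi + 1e-9

    def test_schema_mismatch_rejected(self, model_a):
        with pytest.raises(SchemaMismatchError):
            model_a.predict(np.zeros((1, 50)))

    def test_matches_independent_tree_traversal(self, model_a, small_training_set):
        """Forest prediction equals a hand-coded traversal of the serialized trees."""
        examples, _ = small_training_set
        X = np.vstack([ex.features for ex in examples[:100]])

        def traverse(tree, x):
            # the fitted trees compare in single precision, as at fit time
            x = x.astype(np.float32)
            node = 0
            while tree.children_left[node] != -1:
                if x[tree.feature[node]] <= tree.threshold[node]:
                    node = tree.children_left[node]
                else:
                    node = tree.children_right[node]
            return tree.value[node][0][0]

        expected = np.array(
            [
                np.mean([traverse(est.tree_, x) for est in model_a.forest.estimators_])
                for x in X
            ]
        )
        np.testing.assert_allclose(model_a.predict(X), expected, atol=1e-9)

    def test_save_load_round_trip(self, model_a, small_training_set, tmp_path):
        from dockscreen.rescoring import RescoringModel

        examples, _ = small_training_set
        probes = np.vstack([ex.features for ex in examples[:10]])
        path = tmp_path / "model_a.joblib"
        model_a.save(path)
        loaded = RescoringModel.load(path)
        np.testing.assert_array_equal(loaded.predict(probes), model_a.predict(probes))


class TestRankPoses:
    def _pose(self, rank):
        lig = MolecularStructure(id=f"l{rank}", elements=["C"], coords=[[0.0, 0.0, 0.0]])
        return Pose(ligand=lig, tool="any", rank_in_tool=rank)

    def test_one_candidate_retained_per_tool(self, model_a):
        rng = np.random.default_rng(3)
        tool_poses = {
            tool: [(self._pose(r), _contact(10 * t + r)) for r in range(1, 6)]
            for t, tool in enumerate(["eHiTS", "GOLD", "VINA"])
        }
        ranked, top = rank_poses(model_a, tool_poses, _desc(0))
        assert set(top) == {"eHiTS", "GOLD", "VINA"}
        for tool, scored in ranked.items():
            scores = [s.rescore for s in scored]
            assert scores == sorted(scores, reverse=True)
            assert top[tool].rescore == scores[0]

    def test_single_tool_degraded_mode(self, model_a):
        tool_poses = {"GOLD": [(self._pose(1), _contact(1))]}
        _, top = rank_poses(model_a, tool_poses, _desc(0))
        assert list(top) == ["GOLD"]

    def test_score_tie_breaks_to_lower_native_rank(self, model_a):
        shared = _contact(42)  # identical features -> identical re-score
        tool_poses = {"VINA": [(self._pose(3), shared), (self._pose(1), shared)]}
        _, top = rank_poses(model_a, tool_poses, _desc(0))
        assert top["VINA"].pose.rank_in_tool == 1

    def test_no_poses_anywhere_rejected(self, model_a):
        with pytest.raises(ValueError):
            rank_poses(model_a, {"GOLD": []}, _desc(0))
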