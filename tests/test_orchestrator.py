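"""Decentralized training schedules: ledgers, reductions, privacy audits."""

import numpy as np
import pytest

from daita.distillation import DistillationConfig
from daita.evaluation import compute_metrics
from daita.orchestrator import (
    DataAccessLog,
    TrainPlan,
    average_weights,
    closing_pass,
    cluster_train,
    daita_train,
    derive_seed,
    privacy_guard,
    train_locally,
    train_specialists,
)
from daita.synthetic_data import NodeDataset, make_synthetic_dataset, partition_nodes
from daita.topology import TransferLedger, build_clustered, build_ring, decentralized_transfer_count


def make_nodes(n_nodes, n_per_class=60, seed=0):
    pool = make_synthetic_dataset(n_per_class, "gaussian_blobs", 3.0, seed)
    return partition_nodes(pool, "even", n_nodes, seed + 1)


@pytest.fixture
def validation():
    return make_synthetic_dataset(40, "gaussian_blobs", 3.0, 999)


class TestSpecialists:
    def test_one_teacher_per_node_no_transfers(self, linear_factory):
        nodes = make_nodes(5)
        ledger = TransferLedger()
        log = DataAccessLog(ledger)
        teachers = train_specialists(nodes, linear_factory, 2, 0, access_log=log)
        assert set(teachers) == {n.node_id for n in nodes}
        assert len(ledger) == 0
        assert all(e["data_node"] == e["exec_node"] for e in log.entries)

    def test_identical_data_and_seed_give_identical_teachers(self, linear_factory):
        data = make_synthetic_dataset(30, "gaussian_blobs", 3.0, 5)
        nodes = [NodeDataset("nodeX", data), NodeDataset("nodeX", data)]
        t1 = train_specialists([nodes[0]], linear_factory, 3, 7)
        t2 = train_specialists([nodes[1]], linear_factory, 3, 7)
        np.testing.assert_array_equal(
            t1["nodeX"].export_weights(), t2["nodeX"].export_weights()
        )

    def test_missing_class_warns(self, linear_factory):
        data = make_synthetic_dataset(20, "gaussian_blobs", 3.0, 5)
        one_class = data.subset(np.flatnonzero(data.labels == 0))
        with pytest.warns(UserWarning, match="missing a class"):
            train_specialists([NodeDataset("n1", one_class)], linear_factory, 1, 0)


class TestDaitaTrain:
    @pytest.mark.parametrize("n_nodes,rounds", [(n, r) for n in (1, 2, 3, 4, 5, 6) for r in (1, 3, 5)])
    def test_ledger_matches_closed_form_sweep(self, n_nodes, rounds, linear_factory, validation):
        nodes = make_nodes(n_nodes, n_per_class=3 * n_nodes)
        topo = build_ring([n.node_id for n in nodes])
        plan = TrainPlan(epochs_per_node=1, rounds=rounds, seed=1)
        teachers = train_specialists(nodes, linear_factory, 1, 1, plan)
        res = daita_train(
            topo, nodes, teachers, plan, DistillationConfig(), validation, linear_factory
        )
        assert res.ledger.count("train") == decentralized_transfer_count(
            n_nodes, rounds, len(teachers)
        )

    def test_single_node_alpha_one_reduces_to_direct_training(self, linear_factory):
        data = make_synthetic_dataset(80, "gaussian_blobs", 3.0, 3)
        node = NodeDataset("node1", data)
        topo = build_ring(["node1"])
        plan = TrainPlan(epochs_per_node=2, rounds=3, seed=5, class_weighting="uniform")
        res = daita_train(
            topo, [node], {}, plan, DistillationConfig(alpha=1.0), data, linear_factory
        )
        direct = train_locally(data, linear_factory, 6, 5, plan=plan)
        np.testing.assert_array_equal(
            res.students[0].export_weights(), direct.export_weights()
        )

    def test_tiny_run_matches_brute_force_schedule(self, linear_factory, validation):
        # independent reference loop implementing the same traversal schedule
        from daita.distillation import combine_teachers, soften
        from daita.distillation import inverse_frequency_class_weights

        nodes = make_nodes(2, n_per_class=12)
        topo = build_ring([n.node_id for n in nodes])
        plan = TrainPlan(epochs_per_node=1, rounds=2, seed=9)
        cfg = DistillationConfig(temperature=2.0, alpha=0.5)
        teachers = train_specialists(nodes, linear_factory, 1, 9, plan)
        res = daita_train(topo, nodes, teachers, plan, cfg, validation, linear_factory)

        ref = linear_factory(derive_seed(9, "student", "init"))
        rng = np.random.default_rng(derive_seed(9, "student", "batches"))
        for _ in range(2):
            for nd in nodes:
                softs = [
                    soften(t.predict_logits(nd.data.samples), 2.0)
                    for t in teachers.values()
                ]
                combined = combine_teachers(softs)
                node_cfg = DistillationConfig(
                    temperature=2.0,
                    alpha=0.5,
                    class_weights=inverse_frequency_class_weights(nd.data.labels),
                )
                ref.train_epochs(
                    nd.data.samples, nd.data.labels, 1, node_cfg,
                    teacher_soft=combined, rng=rng,
                )
        np.testing.assert_allclose(
            res.students[0].export_weights(), ref.export_weights(), rtol=1e-12
        )

    def test_checkpoint_selection_restores_best_round(self, linear_factory, validation):
        nodes = make_nodes(3, n_per_class=30)
        topo = build_ring([n.node_id for n in nodes])
        plan = TrainPlan(epochs_per_node=1, rounds=4, seed=2)
        teachers = train_specialists(nodes, linear_factory, 1, 2, plan)
        res = daita_train(
            topo, nodes, teachers, plan, DistillationConfig(), validation, linear_factory
        )
        best = res.selection["checkpoint"]
        np.testing.assert_array_equal(
            res.final_model.export_weights(), res.checkpoints[best][0]
        )
        values = [m.balanced_accuracy for _, m in res.checkpoints]
        assert values[best] == max(values)


class TestClosingPass:
    def test_single_node_is_local_epochs_only(self, linear_factory, validation):
        data = make_synthetic_dataset(30, "gaussian_blobs", 3.0, 3)
        node = NodeDataset("node1", data)
        model = linear_factory(0)
        res = closing_pass(
            [model], build_ring(["node1"]), [node], 2, DistillationConfig(), validation
        )
        assert res.ledger.count("train") == 0  # already resident, nothing moves

    def test_five_node_ledger_counts_movements_only(self, linear_factory, validation):
        nodes = make_nodes(5, n_per_class=30)
        topo = build_ring([n.node_id for n in nodes])
        students = [linear_factory(s) for s in range(5)]
        res = closing_pass(students, topo, nodes, 1, DistillationConfig(), validation)
        # 5 visits × 5 models = 25, minus the one model already home at the start
        assert res.ledger.count("train") == 24

    def test_identical_students_stay_identical(self, linear_factory, validation):
        nodes = make_nodes(3, n_per_class=30)
        topo = build_ring([n.node_id for n in nodes])
        students = [linear_factory(1) for _ in range(3)]
        plan = TrainPlan(seed=4)
        res = closing_pass(
            students, topo, nodes, 1, DistillationConfig(), validation, plan
        )
        w = [s.export_weights() for s in res.students]
        np.testing.assert_allclose(w[0], w[1])
        np.testing.assert_allclose(w[1], w[2])

    def test_more_than_one_traversal_rejected(self, linear_factory, validation):
        nodes = make_nodes(2, n_per_class=10)
        topo = build_ring([n.node_id for n in nodes])
        with pytest.raises(ValueError, match="one traversal"):
            closing_pass(
                [linear_factory(0), linear_factory(1)], topo, nodes, 1,
                DistillationConfig(), validation, rounds=2,
            )


class TestClusterTrain:
    def test_three_by_five_circuit_ledger(self, linear_factory, validation):
        nodes = make_nodes(15, n_per_class=75)
        ids = [n.node_id for n in nodes]
        topo = build_clustered([ids[:5], ids[5:10], ids[10:]])
        plan = TrainPlan(epochs_per_node=1, rounds=1, seed=0)
        res = cluster_train(
            topo, nodes, plan, DistillationConfig(), validation, linear_factory
        )
        assert res.ledger.count("train") == 84
        assert not privacy_guard(res.ledger, res.access_log)

    def test_single_cluster_delegates_to_flat_traversal(self, linear_factory, validation):
        nodes = make_nodes(3, n_per_class=15)
        ids = [n.node_id for n in nodes]
        topo = build_clustered([ids])
        plan = TrainPlan(epochs_per_node=1, rounds=2, seed=0)
        res = cluster_train(
            topo, nodes, plan, DistillationConfig(), validation, linear_factory
        )
        assert res.ledger.count("train") == decentralized_transfer_count(3, 2, 3)

    def test_mixed_architectures_rejected(self, validation):
        from daita.models import SoftmaxRegression, TinyMLP

        nodes = make_nodes(4, n_per_class=8)
        ids = [n.node_id for n in nodes]
        topo = build_clustered([ids[:2], ids[2:]])
        calls = iter([SoftmaxRegression(2, 2), TinyMLP(2, 2), SoftmaxRegression(2, 2), TinyMLP(2, 2)])

        def mixed_factory(seed):
            return next(calls)

        with pytest.raises(ValueError, match="architecture"):
            cluster_train(
                topo, nodes, TrainPlan(epochs_per_node=1, rounds=1),
                DistillationConfig(), validation, mixed_factory,
            )


class TestAverageWeights:
    def test_identity_and_symmetry(self, linear_factory):
        m = linear_factory(0)
        np.testing.assert_array_equal(average_weights([m, m]), m.export_weights())
        w = m.export_weights()
        np.testing.assert_allclose(average_weights([w, -w]), 0.0, atol=1e-15)

    def test_mean_of_three_vectors(self):
        vs = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 0.0])]
        np.testing.assert_allclose(average_weights(vs), (vs[0] + vs[1] + vs[2]) / 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            average_weights([np.zeros(3), np.zeros(4)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_weights([])


class TestPrivacyGuard:
    def test_standard_run_passes(self, linear_factory, validation):
        nodes = make_nodes(3, n_per_class=15)
        topo = build_ring([n.node_id for n in nodes])
        plan = TrainPlan(epochs_per_node=1, rounds=1, seed=0)
        teachers = train_specialists(nodes, linear_factory, 1, 0, plan)
        res = daita_train(
            topo, nodes, teachers, plan, DistillationConfig(), validation, linear_factory
        )
        assert privacy_guard(res.ledger, res.access_log) == []

    def test_injected_raw_data_movement_flagged(self):
        ledger = TransferLedger()
        log = DataAccessLog(ledger)
        log.record("student", "node1", "node2", "train", detail="sample_0042")
        violations = privacy_guard(ledger, log)
        assert len(violations) == 1
        v = violations[0]
        assert v["check"] == "raw_data_movement"
        assert (v["data_node"], v["exec_node"]) == ("node1", "node2")
        assert v["detail"] == "sample_0042"

    def test_centralized_mode_is_informational(self):
        ledger = TransferLedger()
        log = DataAccessLog(ledger)
        log.record("baseline", "node1", "central", "train")
        violations = privacy_guard(ledger, log, mode="centralized")
        assert all(v.get("informational") for v in violations)

    def test_remote_evaluation_flagged(self):
        ledger = TransferLedger()
        ledger.record("student", "node1", "node2")
        log = DataAccessLog(ledger)
        log.record("student", "node3", "node3", "train")  # model resides at node2
        violations = privacy_guard(ledger, log)
        assert any(v["check"] == "remote_evaluation" for v in violations)


class TestLearningDynamics:
    def test_overfitting_with_long_node_residence(self, linear_factory):
        """Very long per-node residence never beats the best short schedule."""
        test = make_synthetic_dataset(150, "gaussian_blobs", 3.0, 777)

        def run(k, seed):
            from daita.synthetic_data import inject_asymmetric_noise, make_synthetic_dataset, partition_nodes

            pool = make_synthetic_dataset(250, "gaussian_blobs", 3.0, derive_seed(seed, "p"))
            nodes = partition_nodes(pool, "even", 5, derive_seed(seed, "q"))
            for nd in nodes:
                nd.data = inject_asymmetric_noise(nd.data, {0: 0.5, 1: 0.1}, derive_seed(seed, nd.node_id))
            topo = build_ring([n.node_id for n in nodes])
            plan = TrainPlan(epochs_per_node=k, rounds=1, seed=seed)
            teachers = train_specialists(nodes, linear_factory, 2, seed, plan)
            val = make_synthetic_dataset(40, "gaussian_blobs", 3.0, derive_seed(seed, "v"))
            res = daita_train(topo, nodes, teachers, plan, DistillationConfig(), val, linear_factory)
            # score the raw traversing student: selection would mask overfitting
            report = compute_metrics(res.students[0].predict_proba(test.samples), test.true_labels)
            return report.balanced_accuracy

        gaps = []
        for seed in (1, 2, 3):
            short = max(run(k, seed) for k in (1, 2, 5))
            long = run(20, seed)
            gaps.append(long - short)
        assert np.median(gaps) <= 0
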