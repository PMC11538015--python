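"""Mask sampling, the three training stages, and end-to-end selection."""

import itertools

import numpy as np
import pytest

import gosel._autodiff as ad
from gosel.model import LossConfig, init_classifier, init_selector, selector_forward
from gosel.training import (
    DualNetworkClassifier,
    SelectorTrainer,
    TrainConfig,
    TrainRecord,
    _SplitView,
    sample_mask,
    stage1_epoch,
    stage2_epoch,
    stage3_train,
)


class TestSampleMask:
    def test_popcount_bounds_over_many_draws(self, rng):
        for _ in range(2000):
            m = sample_mask(8, 5, rng)
            assert 1 <= m.sum() <= 5

    def test_full_support_small_space(self, rng):
        seen = {tuple(sample_mask(2, 2, rng)) for _ in range(500)}
        assert seen == {(1, 0), (0, 1), (1, 1)}

    def test_admissible_count_matches_enumeration(self):
        total = sum(
            1
            for r in range(1, 6)
            for _ in itertools.combinations(range(8), r)
        )
        assert total == 218  # C(8,1)+...+C(8,5)


def _toy_problem(rng, n=60, n_mats=4, d=6, k=3):
    arrays = [rng.normal(size=(n, d)) for _ in range(n_mats)]
    y = (rng.random((n, k)) < 0.3).astype(np.int8)
    splits = {
        "train": np.arange(0, 36),
        "val": np.arange(36, 48),
        "test": np.arange(48, 60),
    }

    class L:
        pass

    labels = L()
    labels.y = {s: y[v] for s, v in splits.items()}
    labels.terms = tuple(f"GO:{i}" for i in range(k))
    labels.splits = splits
    return arrays, _SplitView(labels)


def _models(arrays, n_terms, seed=0, lr=1e-2):
    clf = init_classifier([a.shape[1] for a in arrays], n_terms, d_c=8, seed=seed)
    sel = init_selector(len(arrays), hidden=8, seed=seed + 1)
    clf_opt = ad.Adam(clf.parameters(), lr=lr)
    trainer = SelectorTrainer(sel, refit_steps=5)
    return clf, clf_opt, sel, trainer


class TestStage1:
    def test_record_grows_one_entry_per_epoch(self, rng):
        arrays, view = _toy_problem(rng)
        clf, clf_opt, sel, trainer = _models(arrays, 3)
        cfg, lc = TrainConfig(e1=7, seed=0), LossConfig()
        record = TrainRecord()
        g = np.random.default_rng(0)
        for ep in range(7):
            stage1_epoch(arrays, view, clf, clf_opt, trainer, cfg, lc, g, record, ep)
        assert len(record.entries) == 7
        assert all(e["stage"] == "stage1" for e in record.entries)

    def test_seeded_determinism(self, rng):
        losses = []
        for _ in range(2):
            arrays, view = _toy_problem(np.random.default_rng(5))
            clf, clf_opt, sel, trainer = _models(arrays, 3, seed=4)
            cfg, lc = TrainConfig(e1=5, seed=0), LossConfig()
            record = TrainRecord()
            g = np.random.default_rng(9)
            for ep in range(5):
                stage1_epoch(arrays, view, clf, clf_opt, trainer, cfg, lc, g, record, ep)
            losses.append([(e["mask"], e["loss"]) for e in record.entries])
        assert losses[0] == losses[1]

    def test_selector_heldout_mse_decreases_with_frozen_classifier(self, rng):
        arrays, view = _toy_problem(rng)
        clf, _, sel, trainer = _models(arrays, 3)
        clf_opt = ad.Adam(clf.parameters(), lr=0.0)  # frozen Classifier
        cfg, lc = TrainConfig(e1=60, seed=0), LossConfig()
        record = TrainRecord()
        g = np.random.default_rng(1)

        from gosel.model import classifier_forward, asl_loss

        probe_rng = np.random.default_rng(2)
        probes = [sample_mask(4, 2, probe_rng) for _ in range(12)]
        truth = [
            asl_loss(
                classifier_forward(arrays, m, clf, rows=view.splits_local["val"]),
                view.y["val"], lc,
            )
            for m in probes
        ]

        def heldout_mse():
            return float(np.mean([
                (selector_forward(m.astype(float), sel) - t) ** 2
                for m, t in zip(probes, truth)
            ]))

        before = heldout_mse()
        for ep in range(60):
            stage1_epoch(arrays, view, clf, clf_opt, trainer, cfg, lc, g, record, ep)
        assert heldout_mse() < before


class TestStage2:
    def test_top_k_narrowing_and_tie_break(self):
        imp = np.array([0.1, 0.9, 0.3, 0.8, 0.05, 0.2, 0.4, 0.6])
        order = np.argsort(-imp, kind="stable")
        assert sorted(order[:3].tolist()) == [1, 3, 7]
        tie = np.array([0.5, 0.5, 0.1])
        assert np.argsort(-tie, kind="stable")[0] == 0  # lower index wins

    def test_candidate_subsets_exhaustive_for_small_nf(self, rng):
        from gosel.training import _candidate_subsets

        cands = list(_candidate_subsets([2, 5], 20, rng))
        assert cands == [(2,), (5,), (2, 5)]

    def test_epoch_records_candidates_and_best(self, rng):
        arrays, view = _toy_problem(rng)
        clf, clf_opt, sel, trainer = _models(arrays, 3)
        cfg, lc = TrainConfig(e1=1, n_f=2, seed=0), LossConfig()
        record = TrainRecord()
        g = np.random.default_rng(3)
        m2, l_c, _ = stage2_epoch(arrays, view, clf, clf_opt, trainer, cfg, lc, g, record, 0)
        cand = [e for e in record.entries if e["stage"] == "stage2-candidate"]
        assert len(cand) == 3  # 2^2 - 1 subsets of the narrowed space
        best_candidate = min(cand, key=lambda e: e["loss"])
        assert tuple(m2) == best_candidate["mask"]
        assert 1 <= sum(m2) <= 2


class TestStage3:
    def test_unselected_branches_bit_identical(self, rng):
        arrays, view = _toy_problem(rng)
        clf, clf_opt, sel, trainer = _models(arrays, 3)
        m_star = np.array([0, 1, 0, 1])
        frozen_before = [
            (clf.branches[i][0].data.copy(), clf.branches[i][1].data.copy())
            for i in (0, 2)
        ]
        stage3_train(arrays, view, clf, clf_opt, m_star, e3=8, patience=10,
                     loss_cfg=LossConfig())
        for (w0, b0), i in zip(frozen_before, (0, 2)):
            assert np.array_equal(clf.branches[i][0].data, w0)
            assert np.array_equal(clf.branches[i][1].data, b0)

    def test_e3_zero_returns_current_model(self, rng):
        arrays, view = _toy_problem(rng)
        clf, clf_opt, sel, trainer = _models(arrays, 3)
        state = clf.state_arrays()
        best_f, best_epoch, trace = stage3_train(
            arrays, view, clf, clf_opt, np.array([1, 1, 0, 0]), e3=0, patience=5,
            loss_cfg=LossConfig(),
        )
        assert best_epoch == -1 and len(trace) == 1
        for a, b in zip(state, clf.state_arrays()):
            assert np.array_equal(a, b)

    def test_checkpoint_epoch_is_argmax_of_trace(self, rng):
        arrays, view = _toy_problem(rng)
        clf, clf_opt, sel, trainer = _models(arrays, 3, lr=5e-2)
        best_f, best_epoch, trace = stage3_train(
            arrays, view, clf, clf_opt, np.array([1, 0, 1, 0]), e3=12, patience=100,
            loss_cfg=LossConfig(),
        )
        assert best_f == max(trace)
        # trace[0] is the pre-refinement model (epoch -1)
        assert trace[best_epoch + 1] == best_f


class TestRecord:
    def test_best_is_argmin_earliest_on_ties(self):
        r = TrainRecord()
        r.append([1, 0], 0.5, "stage1", 0)
        r.append([0, 1], 0.3, "stage1", 1)
        r.append([1, 1], 0.3, "stage2", 0)
        assert r.best() == ((0, 1), 0.3)
        assert r.best(scope="stage2") == ((1, 1), 0.3)


class TestEndToEnd:
    def test_mask_popcount_within_bounds_and_record_size(self, tiny_dataset):
        space, labels, planted = tiny_dataset
        est = DualNetworkClassifier(e1=15, e2=5, e3=5, random_state=0)
        est.fit(space, labels)
        assert 1 <= est.mask_.sum() <= est.n_f
        assert len(est.record_.entries) >= 15 + 5
        assert set(est.eval_result_.as_dict()) == {
            "fmax", "tau_star", "m_aupr", "M_aupr", "macro_f1", "f1", "accuracy"
        }

    def test_same_seed_identical_run(self, tiny_dataset):
        space, labels, _ = tiny_dataset
        runs = []
        for _ in range(2):
            est = DualNetworkClassifier(e1=10, e2=4, e3=4, random_state=7)
            est.fit(space, labels)
            runs.append((tuple(est.mask_), est.eval_result_.fmax,
                         tuple(e["loss"] for e in est.record_.entries)))
        assert runs[0] == runs[1]

    def test_fixed_mask_skips_selection(self, tiny_dataset):
        space, labels, _ = tiny_dataset
        est = DualNetworkClassifier(e1=5, e2=2, e3=3, random_state=0)
        est.fit(space, labels, fixed_mask=np.ones(len(space), dtype=int))
        assert est.mask_.sum() == len(space)
        assert len(est.record_.entries) == 0

    def test_predict_proba_and_predict_shapes(self, tiny_dataset):
        space, labels, _ = tiny_dataset
        est = DualNetworkClassifier(e1=5, e2=2, e3=2, random_state=0)
        est.fit(space, labels)
        p = est.predict_proba(space, rows=labels.splits["test"])
        assert p.shape == (len(labels.splits["test"]), len(labels.terms))
        pred = est.predict(space, rows=labels.splits["test"])
        assert set(np.unique(pred)) <= {0, 1}

    def test_too_few_matrices_rejected(self, tiny_dataset):
        _, labels, _ = tiny_dataset
        est = DualNetworkClassifier()
        with pytest.raises(ValueError):
            est.fit([np.zeros((labels.splits["test"].max() + 1, 3))], labels)
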