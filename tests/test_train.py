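"""Training protocol: fold planning, online ADAM learning, early stopping,
checkpoint behaviour and held-out integrity."""

import numpy as np
import pytest

from satpose.nn import Adam, ArchitectureSpec
from satpose.nn.layers import Dense
from satpose.nn.network import Network
from satpose.synth import SynthConfig, synthesize_subject
from satpose.train import (
    KeypointRegression,
    TrainingConfig,
    make_folds,
)


class TestMakeFolds:
    def test_twelve_subjects_twelve_folds(self):
        subjects = [f"s{i:02d}" for i in range(12)]
        trials = {s: [f"{s}-t{j}" for j in range(3)] for s in subjects}
        plan = make_folds(subjects, trials, seed=0)
        assert len(plan.folds) == 12
        held = [f.held_out_subject for f in plan.folds]
        assert sorted(held) == sorted(subjects)
        for f in plan.folds:
            assert len(f.train_subjects) == 11
            assert f.held_out_subject not in f.train_subjects

    def test_trials_partition_between_test_sets(self):
        subjects = ["a", "b"]
        trials = {"a": ["a1", "a2"], "b": ["b1", "b2"]}
        plan = make_folds(subjects, trials, seed=1)
        for f in plan.folds:
            t1 = {t for t, _ in f.test_set_1}
            t2 = {t for t, _ in f.test_set_2}
            assert t1 | t2 == set(trials[f.held_out_subject])
            assert not (t1 & t2)

    def test_odd_trial_count_extra_goes_to_set_1(self):
        plan = make_folds(["a", "b"], {"a": ["t1", "t2", "t3"], "b": ["u1", "u2"]},
                          seed=0)
        fold_a = next(f for f in plan.folds if f.held_out_subject == "a")
        assert len(fold_a.test_set_1) == 2
        assert len(fold_a.test_set_2) == 1

    def test_deterministic_given_seed(self):
        subjects = [f"s{i}" for i in range(5)]
        trials = {s: [f"{s}-{j}" for j in range(4)] for s in subjects}
        p1 = make_folds(subjects, trials, seed=9)
        p2 = make_folds(subjects, trials, seed=9)
        for f1, f2 in zip(p1.folds, p2.folds):
            assert f1 == f2

    def test_single_trial_subject_split_by_frames(self):
        with pytest.warns(UserWarning, match="single trial"):
            plan = make_folds(["a", "b"], {"a": ["only"], "b": ["b1", "b2"]}, seed=0)
        fold_a = next(f for f in plan.folds if f.held_out_subject == "a")
        assert fold_a.test_set_1 == [("only", "first_half")]
        assert fold_a.test_set_2 == [("only", "second_half")]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a"], {"a": ["t"]}, seed=0)


def test_toy_regression_learns_linear_targets():
    """Online ADAM with sign (MAE) gradients drives a trivially learnable
    linear problem (2 inputs -> 26 outputs, exactly realizable) below 1e-3
    training MAE within 5000 iterations."""
    rng = np.random.default_rng(0)
    A = rng.normal(size=(2, 26)).astype(np.float32) * 0.3
    c = rng.uniform(0, 0.5, 26).astype(np.float32)
    X = rng.normal(size=(8, 2)).astype(np.float32)
    Y = X @ A + c
    net = Network([Dense(2, 26, name="out")])
    b = np.sqrt(3.0 / 2)
    net.layers[0].weight[...] = rng.uniform(-b, b, (2, 26)).astype(np.float32)
    opt = Adam(net.parameters(), alpha=1e-3)
    maes = []
    for _ in range(5000):
        i = int(rng.integers(8))
        y = net.forward(X[i : i + 1])
        diff = y[0] - Y[i]
        maes.append(float(np.abs(diff).mean()))
        net.backward((np.sign(diff) / 26.0)[None])
        opt.step(net.gradients())
    trailing = np.convolve(maes, np.ones(100) / 100, mode="valid")
    assert trailing.min() < 1e-3


@pytest.fixture(scope="module")
def tiny_fit():
    """A very short real fit on synthetic frames, shared across tests."""
    imgs, coords, _ = synthesize_subject(SynthConfig(n_frames=120, seed=21))
    timgs, tcoords, _ = synthesize_subject(SynthConfig(n_frames=40, seed=22))
    arch = ArchitectureSpec.small()
    cfg = TrainingConfig(max_iterations=240, eval_every=60, patience=32, seed=3)
    model = KeypointRegression(imgs, coords, arch, config=cfg)
    res = model.fit(
        (timgs[:20], tcoords[:20]), (timgs[20:], tcoords[20:]), net_seed=5
    )
    return model, res


class TestFit:
    def test_history_schema_and_checkpoints(self, tiny_fit):
        _, res = tiny_fit
        assert list(res.history.columns) == [
            "iteration", "train_mae", "test1_mae", "test2_mae",
            "best1_mae", "best2_mae",
        ]
        assert res.checkpoint_set1 is not None
        assert res.checkpoint_set2 is not None
        assert res.iterations_run == 240

    def test_best_checkpoint_mae_non_increasing(self, tiny_fit):
        _, res = tiny_fit
        assert (np.diff(res.history["best1_mae"]) <= 0).all()
        assert (np.diff(res.history["best2_mae"]) <= 0).all()
        assert res.checkpoint_set1.mae == res.history["best1_mae"].iloc[-1]

    def test_reproducible_given_seeds(self, tiny_fit):
        model, res = tiny_fit
        res2 = KeypointRegression(
            model.images, model.targets, model.arch,
            preproc=model.preproc, config=model.config,
        ).fit((model.images[:10], model.targets[:10]),
              (model.images[10:20], model.targets[10:20]), net_seed=5)
        # same data+seeds elsewhere in this module differ in test sets; here
        # just assert the training loop itself is deterministic
        res3 = KeypointRegression(
            model.images, model.targets, model.arch,
            preproc=model.preproc, config=model.config,
        ).fit((model.images[:10], model.targets[:10]),
              (model.images[10:20], model.targets[10:20]), net_seed=5)
        assert res2.history.equals(res3.history)

    def test_predict_shape_and_summary(self, tiny_fit):
        model, res = tiny_fit
        preds = res.predict(model.images[:8], which="best1")
        assert preds.shape == (8, 13, 2)
        assert np.all(np.isfinite(preds))
        text = res.summary()
        assert "best MAE" in text and "held-out" in text

    def test_held_out_integrity_enforced(self, tiny_fit):
        model, _ = tiny_fit
        m = KeypointRegression(
            model.images, model.targets, model.arch, config=model.config,
            subject_ids=np.repeat("childX", model.n_train),
        )
        with pytest.raises(ValueError, match="integrity"):
            m.fit(
                (model.images[:10], model.targets[:10]),
                (model.images[10:20], model.targets[10:20]),
                test_subject_ids=["childX"],
            )


def test_mean_pool_outputs_vary_smoothly_under_shift(tiny_fit):
    """Qualitative: a briefly trained mean-pooling model's predictions move
    by a bounded, small amount under a 1-px input shift (no hard bound —
    this documents the localization-friendly behaviour of mean pooling)."""
    model, res = tiny_fit
    img = model.images[0].astype(np.float32)
    shifted = np.empty_like(img)
    shifted[:, 1:] = img[:, :-1]
    shifted[:, 0] = img[:, 0]
    p0 = res.predict(img[None], which="best1")[0]
    p1 = res.predict(shifted[None], which="best1")[0]
    delta = np.abs(p1 - p0)
    assert np.all(np.isfinite(delta))
    assert delta.mean() < 5.0  # a 1-px shift does not cause jumps


def test_early_stopping_fires_after_exact_patience():
    """With an update step far below float32 resolution, evaluation MAE can
    never improve after the first; patience=1 stops after exactly 2
    evaluations, patience=3 after 4."""
    imgs, coords, _ = synthesize_subject(SynthConfig(n_frames=24, seed=31))
    arch = ArchitectureSpec.small()
    for patience, expect_evals in ((1, 2), (3, 4)):
        cfg = TrainingConfig(
            alpha=1e-30, max_iterations=10_000, eval_every=6,
            patience=patience, seed=0,
        )
        model = KeypointRegression(imgs, coords, arch, config=cfg)
        res = model.fit((imgs[:8], coords[:8]), (imgs[8:16], coords[8:16]),
                        net_seed=1)
        assert len(res.history) == expect_evals
        assert res.iterations_run == expect_evals * 6
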