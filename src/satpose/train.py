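"""Training harness: online ADAM with MAE loss, subject-wise cross-validation,
quarter-pass evaluation, best-checkpoint saving and swapped two-test-set
model selection.

The modelling surface is a :class:`KeypointRegression` object built from
data whose :meth:`~KeypointRegression.fit` returns a
:class:`KeypointRegressionResults` carrying loss history, the per-test-set
best checkpoints and a ``summary()`` table.  ``make_folds`` /
``train_fold`` / ``predict_sequence`` wrap it for the cross-validation
protocol: each fold holds out every frame of one subject, the held-out
subject's trials split ~50/50 into two test sets, and final results for each
test set come from the checkpoint that was best on the *other* one —
genuinely held-out model selection.

Training is online (batch size 1): every iteration draws one training frame
uniformly at random, applies a fresh random translation to image and labels,
local-contrast-normalizes, and takes one ADAM step on the mean absolute
error over the 26 outputs.  Evaluation every quarter pass uses untranslated,
LCN'd inputs.  Training stops once neither test set has improved for
``patience`` consecutive evaluations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmarks import KeypointSet
from .nn import Adam, ArchitectureSpec, Network, build_network
from .nn.network import count_parameters
from .preproc import (
    PreprocConfig,
    crop_and_resize,
    local_contrast_normalize,
    random_translate,
)

__all__ = [
    "TrainingConfig",
    "FoldSpec",
    "FoldPlan",
    "make_folds",
    "Checkpoint",
    "TrainingDiverged",
    "KeypointRegression",
    "KeypointRegressionResults",
    "train_fold",
    "predict_sequence",
]


@dataclass
class TrainingConfig:
    """Online-ADAM training parameters (published defaults)."""

    alpha: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 1
    eval_every: int | None = None  # default: floor(n_train / 4), a quarter pass
    patience: int = 32  # consecutive non-improving evaluations before stopping
    max_iterations: int = 500_000
    seed: int = 0
    standardize_targets: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class FoldSpec:
    train_subjects: list
    held_out_subject: str
    #: lists of (trial_id, part) with part in {"all", "first_half", "second_half"}
    test_set_1: list
    test_set_2: list


@dataclass
class FoldPlan:
    folds: list


def make_folds(subjects: list, trials: dict, seed: int = 0) -> FoldPlan:
    """Leave-one-subject-out plan with a per-subject 50/50 trial split.

    ``trials`` maps subject -> list of trial identifiers.  For each fold the
    held-out subject's trials are shuffled (deterministically from ``seed``)
    and split in half; an odd trial goes to test set 1.  A subject with a
    single trial is split by frames instead (warned).
    """
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for cross-validation")
    rng = np.random.default_rng(seed)
    folds = []
    for held in subjects:
        others = [s for s in subjects if s != held]
        tlist = list(trials[held])
        if len(tlist) < 2:
            warnings.warn(
                f"subject {held!r} has a single trial; splitting it by frames",
                stacklevel=2,
            )
            t = tlist[0]
            ts1 = [(t, "first_half")]
            ts2 = [(t, "second_half")]
        else:
            order = list(rng.permutation(len(tlist)))
            shuffled = [tlist[i] for i in order]
            cut = (len(shuffled) + 1) // 2  # odd count: extra trial to set 1
            ts1 = [(t, "all") for t in shuffled[:cut]]
            ts2 = [(t, "all") for t in shuffled[cut:]]
        folds.append(
            FoldSpec(
                train_subjects=others,
                held_out_subject=held,
                test_set_1=ts1,
                test_set_2=ts2,
            )
        )
    return FoldPlan(folds=folds)


@dataclass
class Checkpoint:
    """Best-so-far parameters for one test set."""

    params: list
    spec: ArchitectureSpec
    seed: int
    mae: float
    iteration: int

    def to_network(self) -> Network:
        net = build_network(self.spec, seed=self.seed)
        net.set_parameters(self.params)
        return net


class TrainingDiverged(RuntimeError):
    def __init__(self, iteration: int, last_good: Checkpoint | None) -> None:
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration
        self.last_good = last_good


def _prepare_inputs(images: np.ndarray, pp: PreprocConfig) -> np.ndarray:
    """LCN a stack of (N, H, W, 3) images -> (N, 3, H, W) float32."""
    out = np.empty(
        (images.shape[0], 3, images.shape[1], images.shape[2]), dtype=np.float32
    )
    for i in range(images.shape[0]):
        out[i] = local_contrast_normalize(
            images[i].astype(np.float32), pp.lcn_window, pp.lcn_epsilon
        ).transpose(2, 0, 1)
    return out


class KeypointRegression:
    """Keypoint-regression model over a fixed training array.

    Parameters
    ----------
    images
        Training frames, uint8/float (N, H, W, 3), already at the network
        resolution (use :func:`satpose.preproc.crop_and_resize` upstream).
    targets
        Keypoint coordinates (N, 13, 2) in the same pixel space.
    arch
        Architecture preset; ``ArchitectureSpec.small()`` for desk scale.
    preproc, config
        Preprocessing and training configuration.
    subject_ids
        Optional per-frame subject labels, used to assert held-out
        integrity against test sets.
    """

    def __init__(
        self,
        images: np.ndarray,
        targets: np.ndarray,
        arch: ArchitectureSpec,
        preproc: PreprocConfig | None = None,
        config: TrainingConfig | None = None,
        subject_ids=None,
    ) -> None:
        if images.shape[0] != targets.shape[0]:
            raise ValueError("images and targets must align")
        if images.shape[1] != arch.input_size or images.shape[2] != arch.input_size:
            raise ValueError(
                f"images are {images.shape[1:3]}, architecture expects "
                f"{arch.input_size}x{arch.input_size}"
            )
        self.images = images
        self.targets = np.asarray(targets, dtype=np.float32)
        self.arch = arch
        self.preproc = preproc or PreprocConfig(
            target_size=arch.input_size,
            translation_range=16.0 * arch.input_size / 256.0,
        )
        self.config = config or TrainingConfig()
        self.subject_ids = (
            np.asarray(subject_ids) if subject_ids is not None else None
        )

    @property
    def n_train(self) -> int:
        return self.images.shape[0]

    def _check_integrity(self, test_subject_ids) -> None:
        if self.subject_ids is None or test_subject_ids is None:
            return
        overlap = set(np.unique(self.subject_ids)) & set(
            np.unique(np.asarray(test_subject_ids))
        )
        if overlap:
            raise ValueError(
                f"held-out integrity violated: subjects {sorted(overlap)} "
                "appear in both training and test data"
            )

    def fit(
        self,
        test_set_1: tuple,
        test_set_2: tuple,
        net_seed: int = 0,
        test_subject_ids=None,
        eval_batch: int = 64,
        verbose: bool = False,
    ) -> "KeypointRegressionResults":
        """Run online training with two-test-set early stopping.

        ``test_set_1`` / ``test_set_2`` are ``(images, targets)`` pairs in
        the same format as the training data.
        """
        cfg = self.config
        pp = self.preproc
        self._check_integrity(test_subject_ids)

        net = build_network(self.arch, seed=net_seed)
        opt = Adam(
            net.parameters(), alpha=cfg.alpha, beta1=cfg.beta1, beta2=cfg.beta2
        )
        rng = np.random.default_rng(cfg.seed)
        eval_every = cfg.eval_every or max(1, self.n_train // 4)

        if cfg.standardize_targets:
            mu = self.targets.reshape(self.n_train, -1).mean(axis=0)
            sd = self.targets.reshape(self.n_train, -1).std(axis=0) + 1e-6
        else:
            mu = np.zeros(26, np.float32)
            sd = np.ones(26, np.float32)
        self._mu, self._sd = mu.astype(np.float32), sd.astype(np.float32)

        tests = []
        for imgs, tgts in (test_set_1, test_set_2):
            x = _prepare_inputs(np.asarray(imgs), pp)
            t = (np.asarray(tgts, np.float32).reshape(len(x), -1) - mu) / sd
            tests.append((x, t))

        def eval_mae(params: list | None = None) -> list:
            if params is not None:
                saved = net.copy_parameters()
                net.set_parameters(params)
            maes = []
            for x, t in tests:
                tot, cnt = 0.0, 0
                for s in range(0, len(x), eval_batch):
                    y = net.forward(x[s : s + eval_batch], check_finite=False)
                    tot += float(np.abs(y - t[s : s + eval_batch]).sum())
                    cnt += y.size
                maes.append(tot / cnt)
            if params is not None:
                net.set_parameters(saved)
            return maes

        best = [np.inf, np.inf]
        ckpts: list = [None, None]
        strikes = 0
        history = []
        run_loss, run_n = 0.0, 0
        it = 0
        while it < cfg.max_iterations:
            it += 1
            i = int(rng.integers(self.n_train))
            img = self.images[i].astype(np.float32)
            kp = KeypointSet(self.targets[i], frame_index=i)
            img, kp = random_translate(img, kp, pp.translation_range, rng)
            x = local_contrast_normalize(img, pp.lcn_window, pp.lcn_epsilon)
            x = x.transpose(2, 0, 1)[None]
            t = (kp.as_vector().astype(np.float32) - mu) / sd
            y = net.forward(x)
            diff = y[0] - t
            loss = float(np.abs(diff).mean())
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    it, ckpts[0] if ckpts[0] is not None else ckpts[1]
                )
            run_loss += loss
            run_n += 1
            dy = (np.sign(diff, dtype=np.float32) / diff.size)[None]
            net.backward(dy)
            opt.step(net.gradients())

            if it % eval_every == 0:
                maes = eval_mae()
                improved = False
                for k in (0, 1):
                    if maes[k] < best[k]:
                        best[k] = maes[k]
                        ckpts[k] = Checkpoint(
                            params=net.copy_parameters(),
                            spec=self.arch,
                            seed=net_seed,
                            mae=maes[k],
                            iteration=it,
                        )
                        improved = True
                history.append(
                    {
                        "iteration": it,
                        "train_mae": run_loss / max(run_n, 1),
                        "test1_mae": maes[0],
                        "test2_mae": maes[1],
                        "best1_mae": best[0],
                        "best2_mae": best[1],
                    }
                )
                run_loss, run_n = 0.0, 0
                strikes = 0 if improved else strikes + 1
                if verbose:
                    print(
                        f"iter {it}: test1 {maes[0]:.4f} test2 {maes[1]:.4f} "
                        f"(strikes {strikes})"
                    )
                if strikes >= cfg.patience:
                    break

        return KeypointRegressionResults(
            model=self,
            net=net,
            checkpoint_set1=ckpts[0],
            checkpoint_set2=ckpts[1],
            history=pd.DataFrame(history),
            iterations_run=it,
            target_mean=mu,
            target_sd=sd,
            _tests=tests,
            _eval_batch=eval_batch,
        )


@dataclass
class KeypointRegressionResults:
    """Fit outcome: checkpoints, history and held-out evaluation."""

    model: KeypointRegression
    net: Network
    checkpoint_set1: Checkpoint | None
    checkpoint_set2: Checkpoint | None
    history: pd.DataFrame
    iterations_run: int
    target_mean: np.ndarray
    target_sd: np.ndarray
    _tests: list = field(repr=False, default=None)
    _eval_batch: int = 64

    def _net_for(self, ckpt: Checkpoint) -> Network:
        net = build_network(ckpt.spec, seed=ckpt.seed)
        net.set_parameters(ckpt.params)
        return net

    def held_out_mae(self) -> dict:
        """Swapped model selection: test set 2 scored with the checkpoint
        best on set 1, and vice versa (both in loss space)."""
        out = {}
        for label, ckpt, idx in (
            ("test1", self.checkpoint_set2, 0),
            ("test2", self.checkpoint_set1, 1),
        ):
            if ckpt is None:
                out[label] = np.nan
                continue
            net = self._net_for(ckpt)
            x, t = self._tests[idx]
            tot, cnt = 0.0, 0
            for s in range(0, len(x), self._eval_batch):
                y = net.forward(x[s : s + self._eval_batch], check_finite=False)
                tot += float(np.abs(y - t[s : s + self._eval_batch]).sum())
                cnt += y.size
            out[label] = tot / cnt
        return out

    def predict(self, images: np.ndarray, which: str = "cross1") -> np.ndarray:
        """Predict keypoints (N, 13, 2) in network-pixel space.

        ``which`` selects the parameters: ``"best1"``/``"best2"`` (best on
        that test set), ``"cross1"``/``"cross2"`` (the swapped checkpoint
        appropriate for evaluating on set 1 / set 2) or ``"final"``.
        """
        pick = {
            "best1": self.checkpoint_set1,
            "best2": self.checkpoint_set2,
            "cross1": self.checkpoint_set2,
            "cross2": self.checkpoint_set1,
        }
        if which == "final":
            net = self.net
        else:
            ckpt = pick[which]
            if ckpt is None:
                raise ValueError(f"no checkpoint available for {which!r}")
            net = self._net_for(ckpt)
        x = _prepare_inputs(np.asarray(images), self.model.preproc)
        outs = []
        for s in range(0, len(x), self._eval_batch):
            y = net.forward(x[s : s + self._eval_batch], check_finite=False)
            outs.append(y * self.target_sd + self.target_mean)
        return np.concatenate(outs).reshape(-1, 13, 2)

    def summary(self) -> str:
        cfg = self.model.config
        held = self.held_out_mae()
        lines = [
            "Keypoint regression fit",
            "=" * 52,
            f"architecture        : {self.model.arch.pool}-pooling, "
            f"input {self.model.arch.input_size}px",
            f"trainable parameters: {count_parameters(self.net):,}",
            f"training frames     : {self.model.n_train}",
            f"iterations run      : {self.iterations_run}"
            f" (max {cfg.max_iterations}, patience {cfg.patience})",
            f"ADAM                : alpha={cfg.alpha}, beta1={cfg.beta1}, "
            f"beta2={cfg.beta2}, batch=1",
            f"best MAE, test set 1: {self.checkpoint_set1.mae:.4f}"
            f" @ iter {self.checkpoint_set1.iteration}"
            if self.checkpoint_set1
            else "best MAE, test set 1: n/a",
            f"best MAE, test set 2: {self.checkpoint_set2.mae:.4f}"
            f" @ iter {self.checkpoint_set2.iteration}"
            if self.checkpoint_set2
            else "best MAE, test set 2: n/a",
            f"held-out MAE (swapped selection): "
            f"test1={held['test1']:.4f}, test2={held['test2']:.4f}",
        ]
        return "\n".join(lines)


def train_fold(
    fold: FoldSpec,
    data: dict,
    net_seed: int,
    cfg: TrainingConfig,
    arch: ArchitectureSpec,
    preproc: PreprocConfig | None = None,
    verbose: bool = False,
):
    """Train one cross-validation fold.

    ``data`` maps subject -> trial -> (images, targets).  Returns
    ``(checkpoint_set1_best, checkpoint_set2_best, history)`` plus the full
    results object: ``(ckpt1, ckpt2, history, results)``.
    """

    def gather(subject, spec_list):
        imgs, tgts = [], []
        for trial, part in spec_list:
            im, tg = data[subject][trial]
            n = len(im)
            if part == "first_half":
                sl = slice(0, n // 2)
            elif part == "second_half":
                sl = slice(n // 2, n)
            else:
                sl = slice(None)
            imgs.append(np.asarray(im)[sl])
            tgts.append(np.asarray(tg)[sl])
        return np.concatenate(imgs), np.concatenate(tgts)

    train_imgs, train_tgts, train_subj = [], [], []
    for s in fold.train_subjects:
        for trial, (im, tg) in data[s].items():
            train_imgs.append(np.asarray(im))
            train_tgts.append(np.asarray(tg))
            train_subj.append(np.repeat(s, len(im)))
    model = KeypointRegression(
        np.concatenate(train_imgs),
        np.concatenate(train_tgts),
        arch=arch,
        preproc=preproc,
        config=cfg,
        subject_ids=np.concatenate(train_subj),
    )
    ts1 = gather(fold.held_out_subject, fold.test_set_1)
    ts2 = gather(fold.held_out_subject, fold.test_set_2)
    res = model.fit(
        ts1,
        ts2,
        net_seed=net_seed,
        test_subject_ids=[fold.held_out_subject],
        verbose=verbose,
    )
    return res.checkpoint_set1, res.checkpoint_set2, res.history, res


def predict_sequence(
    checkpoint: Checkpoint,
    seq,
    preproc: PreprocConfig | None = None,
) -> list:
    """Per-frame independent inference over a frame sequence.

    Each frame is cropped to the sequence ROI, resized to the network
    resolution, LCN'd and passed through the network; predictions are
    mapped back to original-image pixels via the crop's scale map.  No
    tracking, no initialization.
    """
    import logging
    import time

    from .data_io import read_frame

    net = checkpoint.to_network()
    size = checkpoint.spec.input_size
    pp = preproc or PreprocConfig(target_size=size)
    preds = []
    t0 = time.perf_counter()
    for i, path in enumerate(seq.frame_paths):
        frame = read_frame(path)
        roi = seq.roi or (0, 0, frame.shape[1], frame.shape[0])
        img, smap = crop_and_resize(frame, roi, size)
        x = local_contrast_normalize(img, pp.lcn_window, pp.lcn_epsilon)
        y = net.forward(x.transpose(2, 0, 1)[None], check_finite=True)
        coords = smap.to_original(np.asarray(y[0], float).reshape(13, 2))
        preds.append(KeypointSet(coords, frame_index=i, source="predicted"))
    dt = time.perf_counter() - t0
    logging.getLogger("satpose").info(
        "predicted %d frames in %.2fs (%.1f frames/s)",
        len(preds), dt, len(preds) / max(dt, 1e-9),
    )
    return preds
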