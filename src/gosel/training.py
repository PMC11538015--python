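"""Three-stage alternating training of the Classifier and the Selector.

Stage 1 (exploration): each epoch samples a random mask m1 with at most N_f
selected matrices, takes one Classifier training step under it, measures the
validation ASL L_c, and fits the Selector on (m1, L_c).

Stage 2 (exploitation): each epoch reads the Selector's input gradient at
the all-0.5 probe mask, keeps the top-N_f most important matrices as the
narrowed space M_f, evaluates candidate subsets of M_f on the validation
set (forward only), records them, and uses the best candidate m2 for one
Classifier training step and one Selector fit step.

Stage 3 (refinement): the mask m* with the lowest recorded validation loss
is frozen; only its branches and the prediction head keep training, with
early stopping and checkpointing on validation Fmax.  Test-set scores come
from the best-validation-Fmax checkpoint.

The Classifier therefore trains for E1+E2+E3 epochs (less early stopping)
and the Selector for E1+E2.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import _autodiff as ad
from . import metrics as _metrics
from .data_io import LabelMatrix
from .embeddings import FeatureMatrixSpace
from .model import (
    ClassifierParams,
    LossConfig,
    SelectorParams,
    asl_loss,
    asl_loss_t,
    classifier_forward,
    classifier_forward_t,
    gradient_importance,
    init_classifier,
    init_selector,
    selector_fit_step,
)

__all__ = [
    "TrainConfig",
    "TrainRecord",
    "sample_mask",
    "stage1_epoch",
    "stage2_epoch",
    "stage3_train",
    "run_dual_training",
    "DualNetworkClassifier",
]


@dataclass
class TrainConfig:
    """Epoch budget, mask-size cap and candidate budget for the three stages.

    By default E2 + E3 = 100 with N_f between 2 and 5.  ``c_candidates``
    bounds Stage-2 subset evaluation when exhaustive enumeration of the
    narrowed space would exceed 31 subsets.
    """

    e1: int = 100
    e2: int = 50
    e3: int = 50
    n_f: int = 2
    c_candidates: int = 20
    patience: int = 10
    seed: int = 0
    record_scope: str = "all"  # or "stage2"
    selector_refit_steps: int = 20

    def __post_init__(self):
        if self.e1 < 1:
            raise ValueError("E1 must be >= 1")
        if self.n_f < 1:
            raise ValueError("N_f must be >= 1")
        if self.c_candidates < 1:
            raise ValueError("c_candidates must be >= 1")
        if self.record_scope not in ("all", "stage2"):
            raise ValueError("record_scope must be 'all' or 'stage2'")


@dataclass
class TrainRecord:
    """Log of (mask, validation loss) pairs; m* is its running argmin."""

    entries: list[dict] = field(default_factory=list)

    def append(self, mask, loss: float, stage: str, epoch: int) -> None:
        self.entries.append(
            {"mask": tuple(int(b) for b in mask), "loss": float(loss),
             "stage": stage, "epoch": int(epoch)}
        )

    def best(self, scope: str = "all") -> tuple[tuple[int, ...], float]:
        """Lowest-loss entry (earliest on ties), optionally Stage-2 only."""
        pool = [
            e for e in self.entries
            if scope == "all" or e["stage"].startswith("stage2")
        ]
        if not pool:
            raise ValueError("empty training record")
        best = pool[0]
        for e in pool[1:]:
            if e["loss"] < best["loss"]:
                best = e
        return best["mask"], best["loss"]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for e in self.entries:
                fh.write(json.dumps({**e, "mask": list(e["mask"])}) + "\n")


def sample_mask(size: int, n_f: int, rng: np.random.Generator) -> np.ndarray:
    """Random 0/1 mask with 1 <= popcount <= N_f.

    The subset size is uniform on 1..N_f and the members uniform without
    replacement, so every admissible mask has positive probability.
    """
    if n_f < 1:
        raise ValueError("N_f must be >= 1")
    k = int(rng.integers(1, min(n_f, size) + 1))
    idx = rng.choice(size, size=k, replace=False)
    mask = np.zeros(size, dtype=np.int8)
    mask[idx] = 1
    return mask


def _classifier_step(arrays, labels, mask, clf, clf_opt, loss_cfg) -> float:
    """One full-batch training step on the train split; returns train loss."""
    clf_opt.zero_grad()
    p = classifier_forward_t(arrays, mask, clf, rows=labels.splits_local["train"])
    loss = asl_loss_t(p, labels.y["train"], loss_cfg)
    val = float(loss.data)
    if not np.isfinite(val):
        raise FloatingPointError("non-finite training loss; check inputs/lr")
    loss.backward()
    clf_opt.step()
    return val


def _val_loss(arrays, labels, mask, clf, loss_cfg) -> float:
    p = classifier_forward(arrays, mask, clf, rows=labels.splits_local["val"])
    val = asl_loss(p, labels.y["val"], loss_cfg)
    if not np.isfinite(val):
        raise FloatingPointError("non-finite validation loss")
    return val


class _SplitView:
    """Labels plus row positions of each split within the feature matrices."""

    def __init__(self, labels: LabelMatrix):
        self.y = labels.y
        self.terms = labels.terms
        self.splits_local = {k: np.asarray(v, dtype=int) for k, v in labels.splits.items()}


class SelectorTrainer:
    """Keeps the Selector fitted to the whole (mask, loss) history.

    A single online gradient step per observation cannot fit the surrogate
    well enough for its input gradient at the 0.5 probe to rank matrices
    (the probe lies outside the training mask distribution), so each new
    pair triggers one online step plus ``refit_steps`` full-batch steps over
    the accumulated record.  Weight decay keeps the fit close to linear
    where the data do not constrain it, which is what makes gradient
    extrapolation at the probe reliable.
    """

    def __init__(self, params: SelectorParams, lr_online: float = 1e-2,
                 refit_steps: int = 20, refit_lr: float = 1e-2,
                 weight_decay: float = 1e-3):
        self.params = params
        self.online_opt = ad.Adam(params.parameters(), lr=lr_online)
        self.refit_opt = ad.Adam(params.parameters(), lr=refit_lr,
                                 weight_decay=weight_decay)
        self.refit_steps = refit_steps
        self._masks: list[np.ndarray] = []
        self._losses: list[float] = []

    def observe(self, mask, loss: float) -> float:
        """One online fit step on the new pair, then refit on the history.

        Returns the pre-step squared error of the new pair (L_s).
        """
        mse = selector_fit_step(mask, loss, self.params, self.online_opt)
        self._masks.append(np.asarray(mask, dtype=np.float64))
        self._losses.append(float(loss))
        if self.refit_steps:
            m = ad.Tensor(np.stack(self._masks))
            target = ad.Tensor(np.asarray(self._losses))
            p = self.params
            for _ in range(self.refit_steps):
                self.refit_opt.zero_grad()
                pred = (ad.relu(m @ p.w1 + p.b1) @ p.w2 + p.b2).reshape(-1)
                resid = pred - target
                (resid * resid).mean().backward()
                self.refit_opt.step()
        return mse


def stage1_epoch(arrays, labels, clf, clf_opt, sel_trainer, cfg, loss_cfg, rng,
                 record: TrainRecord, epoch: int):
    """Exploration: random mask, Classifier step, Selector fit on (m1, L_c)."""
    m1 = sample_mask(len(arrays), cfg.n_f, rng)
    _classifier_step(arrays, labels, m1, clf, clf_opt, loss_cfg)
    l_c = _val_loss(arrays, labels, m1, clf, loss_cfg)
    mse = sel_trainer.observe(m1, l_c)
    record.append(m1, l_c, "stage1", epoch)
    return m1, l_c, mse


def _candidate_subsets(m_f, c_candidates: int, rng: np.random.Generator):
    """Nonempty subsets of the narrowed space, exhaustive when cheap.

    All 2^|M_f| − 1 subsets are enumerated (by size, then lexicographically)
    when there are at most 31; otherwise ``c_candidates`` subsets are drawn
    uniformly at random.
    """
    m_f = sorted(m_f)
    total = 2 ** len(m_f) - 1
    if total <= 31:
        for r in range(1, len(m_f) + 1):
            yield from itertools.combinations(m_f, r)
        return
    for _ in range(c_candidates):
        k = int(rng.integers(1, len(m_f) + 1))
        yield tuple(sorted(rng.choice(m_f, size=k, replace=False)))


def stage2_epoch(arrays, labels, clf, clf_opt, sel_trainer, cfg, loss_cfg, rng,
                 record: TrainRecord, epoch: int):
    """Exploitation: gradient-ranked narrowing, candidate scan, best-mask step."""
    size = len(arrays)
    imp = gradient_importance(sel_trainer.params)
    # top-N_f by importance; ties resolved toward the lower index
    order = np.argsort(-imp, kind="stable")
    m_f = sorted(int(i) for i in order[: cfg.n_f])

    best_mask, best_loss = None, np.inf
    for subset in _candidate_subsets(m_f, cfg.c_candidates, rng):
        cand = np.zeros(size, dtype=np.int8)
        cand[list(subset)] = 1
        loss = _val_loss(arrays, labels, cand, clf, loss_cfg)
        record.append(cand, loss, "stage2-candidate", epoch)
        if loss < best_loss:
            best_mask, best_loss = cand, loss
    m2 = best_mask

    _classifier_step(arrays, labels, m2, clf, clf_opt, loss_cfg)
    l_c = _val_loss(arrays, labels, m2, clf, loss_cfg)
    mse = sel_trainer.observe(m2, l_c)
    record.append(m2, l_c, "stage2", epoch)
    return m2, l_c, mse


def stage3_train(arrays, labels, clf, clf_opt, m_star, e3: int, patience: int,
                 loss_cfg, threshold_grid=None):
    """Refine under the frozen mask; checkpoint at best validation Fmax.

    Unselected branches receive no gradient (they are absent from the
    forward graph), so their parameters are bit-identical before and after.
    Returns (best validation Fmax, its epoch, the Fmax trace); the classifier
    is left loaded with the best checkpoint.
    """
    grid = _metrics.DEFAULT_GRID if threshold_grid is None else threshold_grid
    val_rows = labels.splits_local["val"]

    def val_fmax() -> float:
        p = classifier_forward(arrays, m_star, clf, rows=val_rows)
        return _metrics.fmax(p, labels.y["val"], grid)[0]

    best_state = clf.state_arrays()
    best_f = val_fmax()
    best_epoch = -1  # pre-refinement model
    trace = [best_f]
    stall = 0
    for epoch in range(e3):
        _classifier_step(arrays, labels, m_star, clf, clf_opt, loss_cfg)
        f = val_fmax()
        trace.append(f)
        if f > best_f:
            best_f, best_epoch, best_state = f, epoch, clf.state_arrays()
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    clf.load_state_arrays(best_state)
    return best_f, best_epoch, trace


def run_dual_training(
    space,
    labels: LabelMatrix,
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    d_c: int = 64,
    head_hidden: int | None = None,
    selector_hidden: int = 32,
    lr_classifier: float = 1e-3,
    lr_selector: float = 1e-2,
    weight_decay: float = 0.0,
    activation: str = "sigmoid",
):
    """Full three-stage run; returns (m*, classifier, EvalResult, record).

    Thin functional wrapper over :class:`DualNetworkClassifier`.
    """
    est = DualNetworkClassifier(
        n_f=(cfg or TrainConfig()).n_f,
        e1=(cfg or TrainConfig()).e1,
        e2=(cfg or TrainConfig()).e2,
        e3=(cfg or TrainConfig()).e3,
        c_candidates=(cfg or TrainConfig()).c_candidates,
        patience=(cfg or TrainConfig()).patience,
        record_scope=(cfg or TrainConfig()).record_scope,
        random_state=(cfg or TrainConfig()).seed,
        d_c=d_c,
        head_hidden=head_hidden,
        selector_hidden=selector_hidden,
        lr_classifier=lr_classifier,
        lr_selector=lr_selector,
        weight_decay=weight_decay,
        gamma_pos=(loss_cfg or LossConfig()).gamma_pos,
        gamma_neg=(loss_cfg or LossConfig()).gamma_neg,
        activation=activation,
    )
    est.fit(space, labels)
    return est.mask_, est.classifier_, est.eval_result_, est.record_


class DualNetworkClassifier(BaseEstimator):
    """Multi-label GO-term classifier with embedded feature-matrix selection.

    Parameters
    ----------
    n_f : int
        Maximum number of feature matrices a mask may select (2..5 typical).
    e1, e2, e3 : int
        Epochs for exploration, exploitation and refinement; e2 + e3 = 100
        by default.
    c_candidates : int
        Stage-2 subset-evaluation budget when exhaustive enumeration of the
        narrowed space is too large.
    gamma_pos, gamma_neg : float
        ASL focusing exponents (0 and 2 by default).
    activation : str
        ``"sigmoid"`` per-term probabilities (default) or ``"softmax"``.
    record_scope : str
        Which entries m* is the argmin of: ``"all"`` (both stages) or
        ``"stage2"``.

    Attributes
    ----------
    mask_ : ndarray
        The selected binary mask m* over the feature space.
    classifier_ : ClassifierParams
        Trained classifier parameters (best-validation-Fmax checkpoint).
    selector_ : SelectorParams
        Trained selector surrogate.
    record_ : TrainRecord
        Full (mask, validation loss) log across stages.
    eval_result_ : metrics.EvalResult
        Test-split metric bundle at the validation-selected threshold.
    """

    def __init__(self, n_f=2, e1=100, e2=50, e3=50, c_candidates=20, patience=10,
                 d_c=64, head_hidden=None, selector_hidden=32,
                 selector_refit_steps=20,
                 lr_classifier=3e-3, lr_selector=1e-2, weight_decay=0.0,
                 gamma_pos=0.0, gamma_neg=2.0, activation="sigmoid",
                 record_scope="all", random_state=0, skip_stage1=False):
        self.n_f = n_f
        self.e1 = e1
        self.e2 = e2
        self.e3 = e3
        self.c_candidates = c_candidates
        self.patience = patience
        self.d_c = d_c
        self.head_hidden = head_hidden
        self.selector_hidden = selector_hidden
        self.selector_refit_steps = selector_refit_steps
        self.lr_classifier = lr_classifier
        self.lr_selector = lr_selector
        self.weight_decay = weight_decay
        self.gamma_pos = gamma_pos
        self.gamma_neg = gamma_neg
        self.activation = activation
        self.record_scope = record_scope
        self.random_state = random_state
        self.skip_stage1 = skip_stage1

    def _arrays(self, space):
        if isinstance(space, FeatureMatrixSpace):
            return space.arrays()
        return [np.asarray(a, dtype=np.float64) for a in space]

    def fit(self, space, labels: LabelMatrix, fixed_mask=None):
        """Run the three-stage procedure on a feature space and split labels.

        ``fixed_mask`` skips Stages 1–2 and refines under the given mask
        (used e.g. to train with all matrices always selected).
        """
        cfg = TrainConfig(
            e1=self.e1, e2=self.e2, e3=self.e3, n_f=self.n_f,
            c_candidates=self.c_candidates, patience=self.patience,
            seed=self.random_state, record_scope=self.record_scope,
            selector_refit_steps=self.selector_refit_steps,
        )
        loss_cfg = LossConfig(gamma_pos=self.gamma_pos, gamma_neg=self.gamma_neg)
        arrays = self._arrays(space)
        if len(arrays) < 2 and fixed_mask is None:
            raise ValueError("feature space must contain at least 2 matrices")
        view = _SplitView(labels)
        for split in ("train", "val", "test"):
            if split not in labels.y:
                raise ValueError(f"labels lack the {split!r} split")
        rng = np.random.default_rng(cfg.seed)
        clf = init_classifier(
            [a.shape[1] for a in arrays], len(labels.terms), d_c=self.d_c,
            head_hidden=self.head_hidden, activation=self.activation,
            seed=cfg.seed,
        )
        sel = init_selector(len(arrays), hidden=self.selector_hidden, seed=cfg.seed + 1)
        clf_opt = ad.Adam(clf.parameters(), lr=self.lr_classifier,
                          weight_decay=self.weight_decay)
        sel_trainer = SelectorTrainer(
            sel, lr_online=self.lr_selector,
            refit_steps=cfg.selector_refit_steps, refit_lr=self.lr_selector,
        )
        record = TrainRecord()

        if fixed_mask is not None:
            m_star = np.asarray(fixed_mask, dtype=np.int8)
        else:
            if not self.skip_stage1:  # ablation: untrained Selector at Stage 2
                for epoch in range(cfg.e1):
                    stage1_epoch(arrays, view, clf, clf_opt, sel_trainer, cfg,
                                 loss_cfg, rng, record, epoch)
            for epoch in range(cfg.e2):
                stage2_epoch(arrays, view, clf, clf_opt, sel_trainer, cfg,
                             loss_cfg, rng, record, epoch)
            m_star = np.asarray(record.best(cfg.record_scope)[0], dtype=np.int8)

        best_f, best_epoch, trace = stage3_train(
            arrays, view, clf, clf_opt, m_star, cfg.e3, cfg.patience, loss_cfg
        )

        p_val = classifier_forward(arrays, m_star, clf, rows=view.splits_local["val"])
        p_test = classifier_forward(arrays, m_star, clf, rows=view.splits_local["test"])
        self.eval_result_ = _metrics.evaluate(
            p_val, labels.y["val"], p_test, labels.y["test"]
        )
        self.mask_ = m_star
        self.classifier_ = clf
        self.selector_ = sel
        self.record_ = record
        self.stage3_trace_ = trace
        self.stage3_best_epoch_ = best_epoch
        self.n_features_in_ = len(arrays)
        return self

    def predict_proba(self, space, rows=None, mask=None):
        """Per-term scores for all (or ``rows``) proteins under m*."""
        arrays = self._arrays(space)
        m = self.mask_ if mask is None else mask
        return classifier_forward(arrays, m, self.classifier_, rows=rows)

    def predict(self, space, rows=None, tau=None):
        """Thresholded 0/1 predictions at the validation-selected threshold."""
        tau = self.eval_result_.tau_star if tau is None else tau
        return (self.predict_proba(space, rows) > tau).astype(np.int8)

    def save_checkpoint(self, path) -> None:
        """Single-file checkpoint: parameters, config, seed, space ordering."""
        params = self.classifier_.parameters() + self.selector_.parameters()
        meta = {
            "config": self.get_params(),
            "mask": [int(b) for b in self.mask_],
            "activation": self.classifier_.activation,
        }
        np.savez(
            path,
            *[p.data for p in params],
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )
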