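"""The dual networks: a multi-label Classifier and a loss-surrogate Selector.

The Classifier keeps one single-layer ReLU projection per matrix in the
feature space; the branches named by a binary mask are applied to their
matrices, averaged, and passed through a two-layer prediction head that
scores every GO term.  Training minimizes the asymmetric loss (ASL), a
focal-style binary loss with separate focusing exponents for positives
(γ+) and negatives (γ−); at γ+ = γ− = 0 it is exactly mean binary
cross-entropy.  Defaults γ+ = 0, γ− = 2 down-weight easy negatives, which
dominate sparse GO label matrices.

The Selector is a two-layer MLP from the |M|-length mask to one scalar that
approximates the Classifier's validation ASL for that mask (fit by squared
error).  Because its input is a vector, feature-matrix importance can be
read off as the absolute input gradient at the all-0.5 probe mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor

__all__ = [
    "LossConfig",
    "ClassifierParams",
    "SelectorParams",
    "init_classifier",
    "init_selector",
    "classifier_forward",
    "asl_loss",
    "selector_forward",
    "selector_fit_step",
    "gradient_importance",
]


@dataclass
class LossConfig:
    """Focusing exponents and the clipping epsilon for the asymmetric loss."""

    gamma_pos: float = 0.0
    gamma_neg: float = 2.0
    eps: float = 1e-7

    def __post_init__(self):
        if self.gamma_pos < 0 or self.gamma_neg < 0:
            raise ValueError("focusing parameters must be non-negative")
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must lie in (0, 0.5)")


@dataclass
class ClassifierParams:
    """One projection branch per feature matrix plus the shared head.

    ``branches[i] = (W, b)`` maps ``d_f(i) -> d_c``; the head is
    ``d_c -> hidden -> K``.  ``activation`` is ``"sigmoid"`` (default;
    per-term probabilities, consistent with ASL) or ``"softmax"``.
    """

    branches: list[tuple[Tensor, Tensor]]
    head: tuple[Tensor, Tensor, Tensor, Tensor]
    activation: str = "sigmoid"

    def parameters(self) -> list[Tensor]:
        out = []
        for w, b in self.branches:
            out += [w, b]
        return out + list(self.head)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        for p, a in zip(self.parameters(), arrays):
            p.data = a.copy()


@dataclass
class SelectorParams:
    """Two-layer MLP mask -> scalar predicted validation loss."""

    w1: Tensor
    b1: Tensor
    w2: Tensor
    b2: Tensor

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]


def init_classifier(
    dims,
    n_terms: int,
    d_c: int = 64,
    head_hidden: int | None = None,
    activation: str = "sigmoid",
    seed: int = 0,
) -> ClassifierParams:
    """He-initialized branches and head, deterministic per seed."""
    if activation not in ("sigmoid", "softmax"):
        raise ValueError("activation must be 'sigmoid' or 'softmax'")
    head_hidden = head_hidden or d_c
    rng = np.random.default_rng(seed)
    branches = []
    for d_f in dims:
        w = Tensor(rng.normal(0, np.sqrt(2.0 / d_f), (d_f, d_c)), True)
        b = Tensor(np.zeros(d_c), True)
        branches.append((w, b))
    w1 = Tensor(rng.normal(0, np.sqrt(2.0 / d_c), (d_c, head_hidden)), True)
    b1 = Tensor(np.zeros(head_hidden), True)
    w2 = Tensor(rng.normal(0, np.sqrt(1.0 / head_hidden), (head_hidden, n_terms)), True)
    b2 = Tensor(np.zeros(n_terms), True)
    return ClassifierParams(branches=branches, head=(w1, b1, w2, b2), activation=activation)


def init_selector(n_matrices: int, hidden: int = 32, seed: int = 0) -> SelectorParams:
    rng = np.random.default_rng(seed)
    return SelectorParams(
        w1=Tensor(rng.normal(0, np.sqrt(2.0 / n_matrices), (n_matrices, hidden)), True),
        b1=Tensor(np.zeros(hidden), True),
        w2=Tensor(rng.normal(0, np.sqrt(1.0 / hidden), (hidden, 1)), True),
        b2=Tensor(np.zeros(1), True),
    )


def _as_mask_indices(mask) -> list[int]:
    bits = np.asarray(mask).astype(int)
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("mask entries must be 0/1")
    idx = [int(i) for i in np.flatnonzero(bits)]
    if not idx:
        raise ValueError("mask selects no feature matrix")
    return idx


def classifier_forward_t(
    arrays, mask, params: ClassifierParams, rows: np.ndarray | None = None
) -> Tensor:
    """Differentiable forward pass; ``rows`` restricts to a protein subset.

    Only the matrices with mask bit 1 enter the computation: their branch
    outputs are averaged (unweighted) before the head, so the result is
    invariant to anything stored in unselected matrices and to the
    processing order of the selected ones.
    """
    idx = _as_mask_indices(mask)
    if len(params.branches) != len(arrays):
        raise ValueError("one branch per feature matrix required")
    hs = []
    for i in idx:
        x = arrays[i] if rows is None else arrays[i][rows]
        w, b = params.branches[i]
        hs.append(ad.relu(Tensor(x) @ w + b))
    avg = hs[0]
    for h in hs[1:]:
        avg = avg + h
    avg = avg * (1.0 / len(hs))
    w1, b1, w2, b2 = params.head
    z = ad.relu(avg @ w1 + b1) @ w2 + b2
    if params.activation == "softmax":
        return ad.softmax(z, axis=-1)
    return ad.sigmoid(z)


def classifier_forward(
    arrays, mask, params: ClassifierParams, rows: np.ndarray | None = None
) -> np.ndarray:
    """Per-term scores in [0, 1] for the proteins in ``rows`` (default all)."""
    return classifier_forward_t(arrays, mask, params, rows).data


def asl_loss_t(p: Tensor, y: np.ndarray, cfg: LossConfig) -> Tensor:
    yt = Tensor(np.asarray(y, dtype=np.float64))
    pc = ad.clip(p, cfg.eps, 1.0 - cfg.eps)
    pos = yt * ((1.0 - pc) ** cfg.gamma_pos) * ad.log(pc)
    neg = (1.0 - yt) * (pc ** cfg.gamma_neg) * ad.log(1.0 - pc)
    return -(pos + neg).mean()


def asl_loss(scores: np.ndarray, labels: np.ndarray, cfg: LossConfig | None = None) -> float:
    """Asymmetric loss averaged over all (protein, term) entries.

    ``(1/(N K)) Σ_i Σ_k [ −y_ik (1−p_ik)^{γ+} log p_ik
    − (1−y_ik) p_ik^{γ−} log(1−p_ik) ]``, with scores clipped to
    ``[eps, 1−eps]`` before the logarithms.
    """
    cfg = cfg or LossConfig()
    p = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: scores {p.shape} vs labels {y.shape}")
    p = np.clip(p, cfg.eps, 1.0 - cfg.eps)
    pos = y * (1.0 - p) ** cfg.gamma_pos * np.log(p)
    neg = (1.0 - y) * p ** cfg.gamma_neg * np.log(1.0 - p)
    return float(-(pos + neg).mean())


def selector_forward_t(vec: Tensor, params: SelectorParams) -> Tensor:
    h = ad.relu(vec.reshape(1, -1) @ params.w1 + params.b1)
    return (h @ params.w2 + params.b2).reshape(())


def selector_forward(mask_like, params: SelectorParams) -> float:
    """Predicted Classifier validation loss for a (possibly soft) mask."""
    v = np.asarray(mask_like, dtype=np.float64)
    if v.ndim != 1 or v.shape[0] != params.w1.shape[0]:
        raise ValueError(
            f"selector input must be a vector of length {params.w1.shape[0]}"
        )
    if not np.isfinite(v).all():
        raise ValueError("selector input must be finite")
    return float(selector_forward_t(Tensor(v), params).data)


def selector_fit_step(mask, true_loss: float, params: SelectorParams, opt: ad.Adam) -> float:
    """One squared-error gradient step; returns the pre-step squared error."""
    if not np.isfinite(true_loss):
        raise ValueError("true loss must be finite")
    v = Tensor(np.asarray(mask, dtype=np.float64))
    opt.zero_grad()
    pred = selector_forward_t(v, params)
    residual = pred - float(true_loss)
    loss = residual * residual
    mse = float(loss.data)
    loss.backward()
    opt.step()
    return mse


def gradient_importance(params: SelectorParams, probe=None) -> np.ndarray:
    """|∂ selector / ∂ probe_j| at the all-0.5 probe mask (by default)."""
    size = params.w1.shape[0]
    v = np.full(size, 0.5) if probe is None else np.asarray(probe, dtype=np.float64)
    vt = Tensor(v, requires_grad=True)
    out = selector_forward_t(vt, params)
    out.backward()
    grad = vt.grad if vt.grad is not None else np.zeros(size)
    return np.abs(grad)
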