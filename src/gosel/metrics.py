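"""Protein-centric and term-centric evaluation for multi-label GO prediction.

Fmax is the CAFA headline metric: the maximum over a threshold grid of the
protein-centric F-measure, where precision at τ averages only over the s(τ)
proteins with at least one score strictly above τ and recall averages over
all proteins.  AUPR comes in a micro flavour (flattened protein–term pairs)
and a macro flavour (unweighted mean over GO terms with at least one
positive).  Accuracy is exact-match subset accuracy at the threshold that
maximizes Fmax on the validation split.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import average_precision_score, f1_score

__all__ = [
    "DEFAULT_GRID",
    "EvalResult",
    "precision_recall_at_tau",
    "fmax",
    "aupr_micro",
    "aupr_macro",
    "subset_accuracy",
    "naive_predict",
    "evaluate",
]

#: CAFA-conventional threshold grid 0.01, 0.02, ..., 0.99.
DEFAULT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)


@dataclass
class EvalResult:
    """Metric bundle reported on the test split."""

    fmax: float
    tau_star: float
    m_aupr: float
    M_aupr: float
    macro_f1: float
    f1: float
    accuracy: float

    def as_dict(self) -> dict:
        return asdict(self)


def _check(p, y):
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: scores {p.shape} vs labels {y.shape}")
    return p, y


def precision_recall_at_tau(p, y, tau: float):
    """Protein-centric precision and recall at threshold τ (strict p > τ).

    Precision averages per-protein precision over the s(τ) proteins with at
    least one predicted term; recall averages per-protein recall over all
    proteins (a protein without true terms contributes 0).  Returns
    (precision, recall, s_tau); precision is 0 when s(τ) = 0.
    """
    p, y = _check(p, y)
    pred = p > tau
    n = p.shape[0]
    tp = (pred & (y == 1)).sum(axis=1)
    npred = pred.sum(axis=1)
    ntrue = (y == 1).sum(axis=1)
    covered = npred > 0
    s_tau = int(covered.sum())
    precision = float((tp[covered] / npred[covered]).mean()) if s_tau else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        rec_terms = np.where(ntrue > 0, tp / np.maximum(ntrue, 1), 0.0)
    recall = float(rec_terms.sum() / n) if n else 0.0
    return precision, recall, s_tau


def fmax(p, y, grid=None) -> tuple[float, float]:
    """Maximum F-measure over the threshold grid; ties keep the smallest τ.

    F(τ) = 2 P R / (P + R), defined as 0 when P + R = 0.  Returns
    (Fmax, τ*).
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=np.float64)
    best_f, best_tau = 0.0, float(grid[0])
    for tau in grid:
        prec, rec, _ = precision_recall_at_tau(p, y, tau)
        f = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        if f > best_f:
            best_f, best_tau = f, float(tau)
    return best_f, best_tau


def aupr_micro(p, y) -> float:
    """AUPR on flattened (protein, term) pairs (step-interpolated)."""
    p, y = _check(p, y)
    if (y == 1).sum() == 0:
        raise ValueError("micro AUPR undefined: no positive labels")
    return float(average_precision_score(y.ravel(), p.ravel()))


def aupr_macro(p, y, return_skipped: bool = False):
    """Unweighted mean of per-term AUPRs over terms with >= 1 positive."""
    p, y = _check(p, y)
    vals, skipped = [], 0
    for k in range(y.shape[1]):
        if (y[:, k] == 1).sum() == 0:
            skipped += 1
            continue
        vals.append(average_precision_score(y[:, k], p[:, k]))
    if not vals:
        raise ValueError("macro AUPR undefined: no term has a positive label")
    out = float(np.mean(vals))
    return (out, skipped) if return_skipped else out


def subset_accuracy(p, y, tau: float) -> float:
    """Fraction of proteins whose thresholded prediction set matches exactly."""
    p, y = _check(p, y)
    pred = (p > tau).astype(np.int8)
    return float((pred == y).all(axis=1).mean())


def naive_predict(train_labels: np.ndarray, n_test: int) -> np.ndarray:
    """Frequency baseline: every test protein scores term k at its training
    relative frequency."""
    yt = np.asarray(train_labels)
    if yt.shape[0] < 1:
        raise ValueError("need at least one training protein")
    freq = yt.mean(axis=0)
    return np.tile(freq, (n_test, 1))


def evaluate(p_val, y_val, p_test, y_test, grid=None) -> EvalResult:
    """Full metric bundle on the test split.

    The operating threshold τ* is chosen to maximize Fmax on the validation
    split; Fmax itself is re-maximized over the grid on the test split (the
    CAFA convention), while F1 (micro), Macro-F1 and subset accuracy use τ*.
    """
    grid = DEFAULT_GRID if grid is None else grid
    _, tau_star = fmax(p_val, y_val, grid)
    f_test, _ = fmax(p_test, y_test, grid)
    pred = (np.asarray(p_test) > tau_star).astype(np.int8)
    y_test = np.asarray(y_test)
    return EvalResult(
        fmax=f_test,
        tau_star=tau_star,
        m_aupr=aupr_micro(p_test, y_test),
        M_aupr=aupr_macro(p_test, y_test),
        macro_f1=float(f1_score(y_test, pred, average="macro", zero_division=0)),
        f1=float(f1_score(y_test.ravel(), pred.ravel(), zero_division=0)),
        accuracy=subset_accuracy(p_test, y_test, tau_star),
    )
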