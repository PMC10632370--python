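"""PU loss with dilution/amplification, training loop, CV method selection.

Positive-unlabeled training treats every unlabeled gene as class 0 but
corrects the asymmetry two ways: *dilution* resamples, fresh every epoch, a
small multiset of unlabeled genes (``|P_train| * d`` of them, uniformly with
replacement) so unlabeled genes resembling positives are not hammered every
step and class imbalance disappears; *amplification* multiplies the positive
term of the binary cross entropy by ``a`` so false negatives cost ``a`` times
more than false positives.  Defaults d=10, a=2.

Early stopping monitors an F-measure combining precision on the training
universe with recall on a positives-only holdout, binarized at score > 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .autodiff import Adam, Tensor
from .data import GeneGraph
from .nn import ArchitectureSpec, classifier_inputs, make_classifier

SCORE_THRESHOLD = 0.7
CLAMP = 1e-7


@dataclass(frozen=True)
class LossConfig:
    dilution: int = 10
    amplification: float = 2.0

    def __post_init__(self):
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")
        if self.amplification <= 0:
            raise ValueError("amplification must be > 0")


@dataclass
class TrainingState:
    """Bookkeeping of one training run."""

    epoch: int = 0
    best_f1: float = -np.inf
    best_epoch: int = -1
    stopped_early: bool = False
    history: list[float] = field(default_factory=list)


def sample_diluted_unlabeled(
    unlabeled: np.ndarray, p_train_size: int, d: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform-with-replacement sample of size ``p_train_size * d``."""
    unlabeled = np.asarray(unlabeled)
    if len(unlabeled) == 0:
        raise ValueError("unlabeled set is empty")
    return rng.choice(unlabeled, size=p_train_size * d, replace=True)


def pu_loss(pos_scores, sampled_unlabeled_scores, cfg: LossConfig):
    """Diluted/amplified binary cross entropy.

    ``L = sum_u BCE(0, s_u) / d + a * sum_p BCE(1, s_p)``.  Accepts plain
    arrays (returns a float) or autodiff Tensors (returns a Tensor).  Scores
    are clamped to [1e-7, 1 - 1e-7] to keep the BCE finite.
    """
    tensor_in = isinstance(pos_scores, Tensor) or isinstance(sampled_unlabeled_scores, Tensor)
    pos = pos_scores if isinstance(pos_scores, Tensor) else Tensor(np.asarray(pos_scores))
    unl = (sampled_unlabeled_scores if isinstance(sampled_unlabeled_scores, Tensor)
           else Tensor(np.asarray(sampled_unlabeled_scores)))
    if pos.data.size == 0:
        raise ValueError("positive set is empty")
    pos_c = pos.clamp(CLAMP, 1.0 - CLAMP)
    unl_c = unl.clamp(CLAMP, 1.0 - CLAMP)
    loss = (-(1.0 - unl_c).log()).sum() * (1.0 / cfg.dilution) \
        + cfg.amplification * (-(pos_c.log())).sum()
    return loss if tensor_in else float(loss.data)


def binarize_predictions(scores: np.ndarray, threshold: float = SCORE_THRESHOLD) -> np.ndarray:
    """Binary call per gene: 1 iff score strictly exceeds the threshold."""
    return (np.asarray(scores) > threshold).astype(np.int64)


def _monitor_f1(calls: np.ndarray, train_positives: np.ndarray,
                train_unlabeled: np.ndarray, holdout_positives: np.ndarray) -> float:
    """F1 from training precision and holdout recall (binarized calls).

    Precision is computed over train positives plus all training "negatives"
    (the unlabeled pool); recall over the positives-only holdout.
    """
    tp = calls[train_positives].sum()
    fp = calls[train_unlabeled].sum()
    pr = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    rec = calls[holdout_positives].mean() if len(holdout_positives) else 0.0
    if pr + rec == 0:
        return 0.0
    return 2.0 * pr * rec / (pr + rec)


def fit_model(
    model,
    X: np.ndarray,
    train_positives: np.ndarray,
    holdout_positives: np.ndarray,
    unlabeled: np.ndarray,
    cfg: LossConfig | None = None,
    seed: int = 0,
    max_epochs: int = 1000,
    patience: int = 100,
    lr: float = 1e-3,
) -> TrainingState:
    """Full-batch Adam training with early stopping on the F1 monitor.

    ``unlabeled`` is the training negative pool; under the conservative
    holdout scheme it includes the outer fold's held-out test positives,
    relabeled as negatives.  The model is left holding the weights of the
    epoch that maximized the monitor.  Deterministic under seed.
    """
    cfg = cfg or LossConfig()
    train_positives = np.asarray(sorted(train_positives), dtype=np.int64)
    holdout_positives = np.asarray(sorted(holdout_positives), dtype=np.int64)
    unlabeled = np.asarray(sorted(unlabeled), dtype=np.int64)
    if len(train_positives) == 0:
        raise ValueError("no training positives")
    if np.intersect1d(train_positives, holdout_positives).size:
        raise ValueError("holdout positives overlap training positives")
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=lr)
    state = TrainingState()
    best_weights = model.get_weights()
    since_best = 0
    for epoch in range(max_epochs):
        state.epoch = epoch
        scores = model.forward(Tensor(X))
        sampled = sample_diluted_unlabeled(unlabeled, len(train_positives),
                                           cfg.dilution, rng)
        loss = pu_loss(scores.gather_rows(train_positives),
                       scores.gather_rows(sampled), cfg)
        extra = model.l1_penalty()
        if extra is not None:
            loss = loss + extra
        if not np.isfinite(loss.data):
            raise RuntimeError(f"loss diverged (non-finite) at epoch {epoch}")
        opt.zero_grad()
        loss.backward()
        opt.step()

        calls = binarize_predictions(scores.data)
        f1 = _monitor_f1(calls, train_positives, unlabeled, holdout_positives)
        state.history.append(f1)
        if f1 > state.best_f1:
            state.best_f1 = f1
            state.best_epoch = epoch
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                state.stopped_early = True
                break
    model.set_weights(best_weights)
    return state


def crossval_auroc(
    name: str,
    graph: GeneGraph,
    X: np.ndarray,
    positives: set[int],
    spec: ArchitectureSpec | None = None,
    folds: int = 4,
    repeats: int = 4,
    seed: int = 0,
    embedding: np.ndarray | None = None,
    loss_cfg: LossConfig | None = None,
    max_epochs: int = 1000,
) -> tuple[float, list[dict]]:
    """Method-selection cross validation: mean AUROC over folds x repeats.

    Each fold holds out 25% (1/folds) of positives and of unlabeled genes;
    unlabeled genes are treated as negatives when scoring the holdout.  A
    quarter of the training positives is carved out as the early-stopping
    recall set.  Returns (mean AUROC, tidy per-model records).
    """
    n = X.shape[0]
    pos = np.asarray(sorted(positives), dtype=np.int64)
    unl = np.asarray(sorted(set(range(n)) - set(positives)), dtype=np.int64)
    inputs = classifier_inputs(name, X, embedding)
    records: list[dict] = []
    for rep in range(repeats):
        rng = np.random.default_rng(seed + 10007 * rep)
        pos_perm = rng.permutation(pos)
        unl_perm = rng.permutation(unl)
        pos_folds = np.array_split(pos_perm, folds)
        unl_folds = np.array_split(unl_perm, folds)
        for k in range(folds):
            hold_pos = pos_folds[k]
            hold_unl = unl_folds[k]
            train_pos = np.concatenate([pos_folds[i] for i in range(folds) if i != k])
            train_unl = np.concatenate([unl_folds[i] for i in range(folds) if i != k])
            n_val = max(1, len(train_pos) // 4)
            val_pos, fit_pos = train_pos[:n_val], train_pos[n_val:]
            if len(fit_pos) == 0:
                fit_pos, val_pos = train_pos, train_pos[:1]
            model_seed = seed + 1000 * rep + k
            model = make_classifier(name, X.shape[1], graph, spec=spec,
                                    seed=model_seed, embedding=embedding)
            fit_model(model, inputs, fit_pos, val_pos, train_unl,
                      cfg=loss_cfg, seed=model_seed, max_epochs=max_epochs)
            scores = model.scores(inputs)
            y_true = np.concatenate([np.ones(len(hold_pos)), np.zeros(len(hold_unl))])
            y_score = np.concatenate([scores[hold_pos], scores[hold_unl]])
            auroc = roc_auc_score(y_true, y_score)
            records.append({"method": name, "repeat": rep, "fold": k, "auroc": auroc})
    mean_auroc = float(np.mean([r["auroc"] for r in records]))
    return mean_auroc, records
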