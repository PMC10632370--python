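"""Nested cross-validation ensemble, inner-threshold statistic, consensus.

The ensemble is an m x n nested cross validation over the positive labels:
each of the m outer folds holds out one m-th of the positives as a test set
(relabeled as negatives during training — the conservative holdout scheme),
and splits the remaining positives into n inner validation sets, one per
model, used only for early stopping.  After training, the n models' binary
calls (score > 0.7) are aggregated into a per-gene concordance count
``c_j(g)``.  Within each fold the minimal concordance at which the models'
agreement on the held-out test positives beats a simulated random background
(B = 1000 draws of matched-size random classifiers; one-sided one-sample
t-test, Benjamini-Hochberg FDR < 0.05 across the n bins, or a background mean
below 0.1) becomes the *inner threshold*; unlabeled genes at or above it are
the fold's candidates.  The per-gene consensus score CS in {0..m} counts the
outer folds that selected the gene.  Known positives never receive a CS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import GeneGraph
from .nn import ArchitectureSpec, classifier_inputs, make_classifier
from .train import LossConfig, binarize_predictions, fit_model

logger = logging.getLogger("corelearn")


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Outer/inner split assignments of the positive genes."""

    m: int
    n: int
    seed: int
    test_sets: list[np.ndarray]            # per outer fold j
    val_sets: list[list[np.ndarray]]       # per fold j, per inner model i
    train_sets: list[list[np.ndarray]]     # per fold j, per inner model i


def plan_nested_folds(positives: set[int], m: int = 11, n: int = 10,
                      seed: int = 0) -> FoldPlan:
    """Deterministic balanced partition: positives into m test sets, and each
    fold's remaining positives into n validation sets (sizes within +-1)."""
    pos = np.asarray(sorted(positives), dtype=np.int64)
    if len(pos) < m:
        raise ValueError(f"need at least m={m} positives, got {len(pos)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pos)
    test_sets = [np.sort(a) for a in np.array_split(perm, m)]
    val_sets, train_sets = [], []
    for j in range(m):
        rest = np.setdiff1d(pos, test_sets[j])
        if len(rest) < n:
            raise ValueError(
                f"fold {j}: only {len(rest)} positives left for {n} inner models")
        inner_perm = rng.permutation(rest)
        vals = [np.sort(a) for a in np.array_split(inner_perm, n)]
        trains = [np.setdiff1d(rest, v) for v in vals]
        val_sets.append(vals)
        train_sets.append(trains)
    return FoldPlan(m=m, n=n, seed=seed, test_sets=test_sets,
                    val_sets=val_sets, train_sets=train_sets)


# ---------------------------------------------------------------------------
# Concordance and the random background
# ---------------------------------------------------------------------------

def concordance(call_vectors: np.ndarray) -> np.ndarray:
    """Per-gene count of concordant positive calls over the n models."""
    calls = np.asarray(call_vectors)
    if calls.ndim != 2:
        raise ValueError("expected an (n_models, n_genes) call matrix")
    return calls.sum(axis=0)


def observed_overlap_bins(concord: np.ndarray, test_mask: np.ndarray,
                          n_models: int) -> np.ndarray:
    """C_j per bin c* in 1..n: test positives with concordance exactly c*."""
    vals = concord[test_mask]
    return np.bincount(vals, minlength=n_models + 1)[1:]


def background_concordance(
    call_counts: np.ndarray,
    scored_universe_size: int,
    test_positive_count: int,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """B x n table of random-classifier overlaps with the test positives.

    Each repetition sets up n random classifiers that mark ``call_counts[i]``
    genes uniformly without replacement in the scored universe; the overlap of
    test positives with concordance exactly c* is binned for c* in 1..n.  Only
    the marks landing inside the test set matter, so the simulation draws, per
    classifier, the hypergeometric number of marks falling among the test
    positives and places them uniformly — exactly the marginal distribution of
    full-universe marking restricted to the test set (the dense sampler in the
    test suite is the oracle for this equivalence).
    """
    counts = np.asarray(call_counts, dtype=np.int64)
    n = len(counts)
    N, T = scored_universe_size, test_positive_count
    if np.any(counts > N):
        raise ValueError("call count exceeds scored universe size")
    rng = np.random.default_rng(seed)
    # marks in test set per (rep, classifier)
    x = np.empty((B, n), dtype=np.int64)
    for i, k in enumerate(counts):
        x[:, i] = rng.hypergeometric(T, N - T, k, size=B) if 0 < k else 0
    # place x marks uniformly among the T test positives
    u = rng.random((B, n, T))
    ranks = u.argsort(axis=2).argsort(axis=2)
    marks = ranks < x[:, :, None]
    concord = marks.sum(axis=1)  # (B, T) in 0..n
    table = np.zeros((B, n + 1), dtype=np.int64)
    rows = np.repeat(np.arange(B), T)
    np.add.at(table, (rows, concord.ravel()), 1)
    return table[:, 1:]


def background_concordance_dense(
    call_counts: np.ndarray,
    scored_universe_size: int,
    test_positive_count: int,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Reference sampler: marks the full universe without replacement."""
    counts = np.asarray(call_counts, dtype=np.int64)
    n = len(counts)
    N, T = scored_universe_size, test_positive_count
    rng = np.random.default_rng(seed)
    table = np.zeros((B, n + 1), dtype=np.int64)
    for b in range(B):
        concord = np.zeros(N, dtype=np.int64)
        for k in counts:
            marked = rng.permutation(N)[:k]
            concord[marked] += 1
        vals = concord[:T]  # test positives are exchangeable: take the first T
        table[b] += np.bincount(vals, minlength=n + 1)
    return table[:, 1:]


# ---------------------------------------------------------------------------
# Threshold selection
# ---------------------------------------------------------------------------

@dataclass
class ThresholdDiagnostics:
    """Per-bin evidence behind one fold's inner-threshold decision."""

    observed: np.ndarray        # C_j per bin 1..n
    background_mean: np.ndarray
    background_sd: np.ndarray
    p_values: np.ndarray
    fdr: np.ndarray
    chosen: int | None          # inner threshold c*, or None
    branch: str | None          # "significance" | "low-background" | None


def select_inner_threshold(
    observed: np.ndarray,
    background: np.ndarray,
    fdr_level: float = 0.05,
    low_background_mean: float = 0.1,
) -> ThresholdDiagnostics:
    """Minimal c* whose observed overlap beats the random background.

    Per bin, the observed overlap is referenced against the empirical
    background distribution with a one-sided t statistic
    ``t = (C_j - mean(background)) / sd(background)`` on B - 1 degrees of
    freedom.  The observed overlap is itself a single draw, so it is compared
    with the background *spread*, not the standard error of the background
    mean — the latter shrinks with B and would flag negligible differences as
    significant, destroying the false-discovery calibration of the machinery.
    BH-FDR is applied across the n bins.  The threshold is the minimal bin
    with FDR < ``fdr_level``, or the minimal bin whose background mean is
    below ``low_background_mean`` provided at least one test positive was
    observed there — whichever is smaller.  None if neither condition holds
    anywhere.  Zero-variance background: p = 0 if the observed overlap
    exceeds the background value, else 1.
    """
    observed = np.asarray(observed, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    n = len(observed)
    B = background.shape[0]
    if background.shape[1] != n:
        raise ValueError("background table width must equal the number of bins")
    bg_mean = background.mean(axis=0)
    bg_sd = background.std(axis=0, ddof=1)
    p = np.ones(n)
    for c in range(n):
        if bg_sd[c] == 0:
            p[c] = 0.0 if observed[c] > bg_mean[c] else 1.0
        else:
            t = (observed[c] - bg_mean[c]) / bg_sd[c]
            p[c] = stats.t.sf(t, df=B - 1)
    fdr = multipletests(p, method="fdr_bh")[1]
    sig_bins = np.nonzero(fdr < fdr_level)[0]
    low_bins = np.nonzero((bg_mean < low_background_mean) & (observed >= 1))[0]
    chosen, branch = None, None
    cand = []
    # on a tie the low-background label wins: a near-empty background makes
    # the t-test degenerate, so the mean criterion is the operative one
    if len(low_bins):
        cand.append((low_bins[0], "low-background"))
    if len(sig_bins):
        cand.append((sig_bins[0], "significance"))
    if cand:
        bin_idx, branch = min(cand, key=lambda t: t[0])
        chosen = int(bin_idx) + 1  # bins are 1-based concordance values
    return ThresholdDiagnostics(
        observed=observed, background_mean=bg_mean, background_sd=bg_sd,
        p_values=p, fdr=fdr, chosen=chosen, branch=branch,
    )


def fold_candidates(concord: np.ndarray, chosen: int | None,
                    known_positives: set[int]) -> set[int]:
    """Unlabeled genes at or above the inner threshold (positives excluded)."""
    if chosen is None:
        return set()
    hits = set(int(g) for g in np.nonzero(concord >= chosen)[0])
    return hits - set(known_positives)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Per-gene consensus score with per-fold candidate sets."""

    cs: np.ndarray                    # float; NaN for known positives
    flags: list[str]                  # positive-label | candidate | non-candidate
    candidate_sets: list[set[int]]
    m: int


def consensus_score(candidate_sets: list[set[int]], n_genes: int,
                    known_positives: set[int]) -> ConsensusResult:
    """CS(g) = number of outer folds selecting g; positives get no CS."""
    m = len(candidate_sets)
    cs = np.zeros(n_genes, dtype=np.float64)
    for cands in candidate_sets:
        for g in cands:
            cs[g] += 1
    flags = []
    for g in range(n_genes):
        if g in known_positives:
            flags.append("positive-label")
        elif cs[g] > 0:
            flags.append("candidate")
        else:
            flags.append("non-candidate")
    cs[sorted(known_positives)] = np.nan
    return ConsensusResult(cs=cs, flags=flags, candidate_sets=candidate_sets, m=m)


# ---------------------------------------------------------------------------
# Full nested run
# ---------------------------------------------------------------------------

@dataclass
class EnsembleRun:
    consensus: ConsensusResult
    fold_diagnostics: list[ThresholdDiagnostics]
    plan: FoldPlan
    model_weights: list[list[list[np.ndarray]]] | None = None  # [fold][model]


def run_nested_ensemble(
    name: str,
    graph: GeneGraph,
    X: np.ndarray,
    positives: set[int],
    m: int = 11,
    n: int = 10,
    B: int = 1000,
    fdr_level: float = 0.05,
    spec: ArchitectureSpec | None = None,
    loss_cfg: LossConfig | None = None,
    seed: int = 0,
    max_epochs: int = 1000,
    embedding: np.ndarray | None = None,
    keep_models: bool = False,
) -> EnsembleRun:
    """Train the m x n ensemble and aggregate per-gene consensus scores."""
    n_genes = X.shape[0]
    plan = plan_nested_folds(positives, m=m, n=n, seed=seed)
    inputs = classifier_inputs(name, X, embedding)
    all_genes = np.arange(n_genes)
    unlabeled = np.setdiff1d(all_genes, np.asarray(sorted(positives)))
    candidate_sets: list[set[int]] = []
    diagnostics: list[ThresholdDiagnostics] = []
    kept: list[list[list[np.ndarray]]] | None = [] if keep_models else None
    for j in range(m):
        test_j = plan.test_sets[j]
        # conservative holdout: test positives are relabeled as negatives
        train_neg_pool = np.sort(np.concatenate([unlabeled, test_j]))
        scored = train_neg_pool  # unlabeled union test_j
        scored_mask = np.zeros(n_genes, dtype=bool)
        scored_mask[scored] = True
        calls = np.zeros((n, n_genes), dtype=np.int64)
        fold_models: list[list[np.ndarray]] = []
        for i in range(n):
            model_seed = seed + 997 * j + i + 1
            model = make_classifier(name, X.shape[1], graph, spec=spec,
                                    seed=model_seed, embedding=embedding)
            fit_model(model, inputs, plan.train_sets[j][i], plan.val_sets[j][i],
                      train_neg_pool, cfg=loss_cfg, seed=model_seed,
                      max_epochs=max_epochs)
            calls[i] = binarize_predictions(model.scores(inputs))
            if keep_models:
                fold_models.append(model.get_weights())
        if kept is not None:
            kept.append(fold_models)
        calls[:, ~scored_mask] = 0  # predictions only count on the scored universe
        concord = concordance(calls)
        test_mask = np.zeros(n_genes, dtype=bool)
        test_mask[test_j] = True
        observed = observed_overlap_bins(concord, test_mask, n)
        call_counts = calls[:, scored_mask].sum(axis=1)
        background = background_concordance(
            call_counts, len(scored), len(test_j), B=B,
            seed=seed + 7919 * (j + 1))
        diag = select_inner_threshold(observed, background, fdr_level=fdr_level)
        diagnostics.append(diag)
        cands = fold_candidates(concord, diag.chosen, positives)
        logger.info("fold %d: inner threshold %s (%s), %d candidates",
                    j, diag.chosen, diag.branch, len(cands))
        candidate_sets.append(cands)
    consensus = consensus_score(candidate_sets, n_genes, positives)
    return EnsembleRun(consensus=consensus, fold_diagnostics=diagnostics,
                       plan=plan, model_weights=kept)
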