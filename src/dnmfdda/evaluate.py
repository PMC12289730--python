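"""Ranking metrics and the two evaluation protocols.

Metrics: AUC in its Mann–Whitney form (probability a random positive outranks
a random negative, ties counted half), AUPR as the area under the
precision–recall step curve with tied scores processed as one block, and
R-precision (precision among the top-P ranked items, P = number of
positives — a threshold-free operating point).

Protocols: 10-fold cross-validation over positive cells (each fold's
positives hidden from training and scored against all originally-unknown
cells) and the cold-start test (every drug with exactly one known association
has it hidden, its whole row scored, and the per-drug lists pooled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from .dnmf_core import Hyperparams
from .io_formats import DatasetBundle, LabeledMatrix
from .pipeline import AblationFlags, predict_ddas

__all__ = [
    "EvalReport",
    "auc_score",
    "aupr_score",
    "precision_at_r",
    "make_cv_folds",
    "run_cv10",
    "run_coldstart",
    "COLDSTART_EXCLUDED_DRUG_SIMS",
]

logger = logging.getLogger(__name__)

# Similarity sources that would not exist yet for a genuinely new drug and are
# therefore dropped in the cold-start protocol when present by name.
COLDSTART_EXCLUDED_DRUG_SIMS = ("ddi", "se")


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given label mix."""


@dataclass
class EvalReport:
    """Aggregate (and optionally per-fold) evaluation metrics."""

    auc: float
    aupr: float
    precision: float
    per_fold: list[tuple[float, float, float]] | None
    n_test_positives: int
    n_candidates: int


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    return s, y


def auc_score(scores, labels) -> float:
    """Mann–Whitney AUC: (#concordant + ½·#tied) / (P·N)."""
    s, y = _as_arrays(scores, labels)
    P = int(y.sum())
    N = len(y) - P
    if P == 0 or N == 0:
        raise UndefinedMetricError("AUC needs at least one positive and one negative")
    ranks = rankdata(s)  # average ranks handle ties as half-concordant
    return float((ranks[y == 1].sum() - P * (P + 1) / 2) / (P * N))


def aupr_score(scores, labels) -> float:
    """Area under the precision–recall step curve, ties processed as blocks."""
    s, y = _as_arrays(scores, labels)
    P = int(y.sum())
    if P == 0:
        raise UndefinedMetricError("AUPR needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tp = np.cumsum(y_sorted)
    n_seen = np.arange(1, len(y_sorted) + 1)
    # keep only the last index of each tied-score block
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    precision = tp[block_end] / n_seen[block_end]
    recall = tp[block_end] / P
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def precision_at_r(scores, labels) -> float:
    """R-precision: fraction of positives among the top-P scored items."""
    s, y = _as_arrays(scores, labels)
    P = int(y.sum())
    if P == 0:
        raise UndefinedMetricError("R-precision needs at least one positive")
    if len(y) < P:
        raise ValueError("fewer items than positives")
    order = np.argsort(-s, kind="stable")  # stable: ties keep input order
    return float(y[order[:P]].sum() / P)


def make_cv_folds(positives: list, n_folds: int, seed: int) -> list[list]:
    """Random partition of the positives into folds of near-equal size."""
    if len(positives) < n_folds:
        raise ValueError(f"{len(positives)} positives cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(positives))
    return [[positives[i] for i in chunk] for chunk in np.array_split(perm, n_folds)]


def _fold_params(params: Hyperparams, seed: int, index: int) -> Hyperparams:
    return replace(params, seed=(seed * 1_000_003 + index) % (2**31))


def _masked_bundle(bundle: DatasetBundle, cells: list[tuple[int, int]]) -> DatasetBundle:
    masked = bundle.association.values.copy()
    for i, j in cells:
        masked[i, j] = 0.0
    return DatasetBundle(
        LabeledMatrix(masked, bundle.association.row_ids, bundle.association.col_ids),
        bundle.drug_sims,
        bundle.disease_sims,
    )


def run_cv10(
    bundle: DatasetBundle,
    params: Hyperparams | None = None,
    flags: AblationFlags | None = None,
    seed: int = 0,
    n_folds: int = 10,
) -> EvalReport:
    """10-fold cross-validation over positive association cells.

    Each fold's positives are zeroed in the training matrix; the fold is then
    scored with label 1 on its cells and label 0 on every cell that is zero
    in the original matrix (training positives are never scored).
    """
    params = params or Hyperparams()
    flags = flags or AblationFlags()
    A = bundle.association.values
    positives = [tuple(int(x) for x in ij) for ij in np.argwhere(A == 1)]
    zero_cells = np.argwhere(A == 0)
    folds = make_cv_folds(positives, n_folds, seed)

    per_fold: list[tuple[float, float, float]] = []
    n_candidates = 0
    for f, fold in enumerate(folds):
        train = _masked_bundle(bundle, fold)
        tv = train.association.values
        assert all(tv[i, j] == 0 for i, j in fold), "leakage: test cell present in training"
        scores = predict_ddas(train, _fold_params(params, seed, f), flags)
        fold_scores = np.r_[
            [scores.values[i, j] for i, j in fold],
            scores.values[zero_cells[:, 0], zero_cells[:, 1]],
        ]
        fold_labels = np.r_[np.ones(len(fold)), np.zeros(len(zero_cells))]
        per_fold.append(
            (
                auc_score(fold_scores, fold_labels),
                aupr_score(fold_scores, fold_labels),
                precision_at_r(fold_scores, fold_labels),
            )
        )
        n_candidates += len(fold_labels)
        logger.info("fold %d/%d: auc=%.4f aupr=%.4f", f + 1, n_folds, *per_fold[-1][:2])

    agg = np.mean(per_fold, axis=0)
    return EvalReport(
        auc=float(agg[0]),
        aupr=float(agg[1]),
        precision=float(agg[2]),
        per_fold=per_fold,
        n_test_positives=len(positives),
        n_candidates=n_candidates,
    )


def _coldstart_flags(bundle: DatasetBundle, flags: AblationFlags) -> AblationFlags:
    """Drop similarity sources a new drug would not have, when present by name."""
    if flags.similarity_subset is not None:
        return flags
    legal = [n for n in bundle.drug_sims if n not in COLDSTART_EXCLUDED_DRUG_SIMS]
    if len(legal) == len(bundle.drug_sims):
        return flags
    return replace(flags, similarity_subset={"drug": legal})


def run_coldstart(
    bundle: DatasetBundle,
    params: Hyperparams | None = None,
    flags: AblationFlags | None = None,
    seed: int = 0,
) -> EvalReport:
    """Cold-start test over drugs with exactly one known association.

    Each target drug's single positive is hidden (its row becomes empty,
    exercising the KNN fill), the model is refitted, and the drug's row is
    scored with label 1 on the hidden disease and 0 on its originally-unknown
    diseases.  Rows are pooled across target drugs before computing metrics.
    """
    params = params or Hyperparams()
    flags = _coldstart_flags(bundle, flags or AblationFlags())
    A = bundle.association.values
    targets = [int(i) for i in np.flatnonzero(A.sum(axis=1) == 1)]
    if not targets:
        raise ValueError("cold-start protocol needs at least one singleton drug")

    pooled_scores: list[float] = []
    pooled_labels: list[float] = []
    for t, row in enumerate(targets):
        j_hidden = int(np.flatnonzero(A[row])[0])
        train = _masked_bundle(bundle, [(row, j_hidden)])
        assert train.association.values[row].sum() == 0, "leakage: target row not empty"
        scores = predict_ddas(train, _fold_params(params, seed, t), flags)
        zero_js = np.flatnonzero(A[row] == 0)
        pooled_scores.append(float(scores.values[row, j_hidden]))
        pooled_labels.append(1.0)
        pooled_scores.extend(float(x) for x in scores.values[row, zero_js])
        pooled_labels.extend(0.0 for _ in zero_js)
        logger.info("cold-start target %d/%d (drug row %d)", t + 1, len(targets), row)

    return EvalReport(
        auc=auc_score(pooled_scores, pooled_labels),
        aupr=aupr_score(pooled_scores, pooled_labels),
        precision=precision_at_r(pooled_scores, pooled_labels),
        per_fold=None,
        n_test_positives=len(targets),
        n_candidates=len(pooled_labels),
    )
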