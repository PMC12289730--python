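"""End-to-end prediction: both entity views, fitted, reconstructed, averaged.

One call runs the whole method: fuse the similarity sources per entity type,
densify empty association rows/columns by the weighted-KNN fill, build the
drug-view and disease-view integrated matrices and their Laplacians, fit the
regularized deep factorization of each view, slice the reconstructed
association blocks back out and average them into the final score matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .dnmf_core import Hyperparams, fit_dnmf, layer_dims, reconstruct
from .io_formats import DatasetBundle, LabeledMatrix
from .preprocess import build_integrated, build_laplacian, fuse_similarities, knn_fill

__all__ = ["ScoreMatrix", "AblationFlags", "extract_association", "predict_ddas", "run_ablation"]

logger = logging.getLogger(__name__)


class ScoreMatrix(LabeledMatrix):
    """Predicted association scores: nonnegative, drugs × diseases."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.values.size and self.values.min() < 0:
            raise ValueError("scores must be nonnegative")


@dataclass
class AblationFlags:
    """Switches for the ablation variants.

    use_knn
        Apply the weighted-KNN fill to empty rows (off: raw associations in
        both views).
    use_pretrain
        Initialize layers by plain NMF pretraining (off: random init).
    similarity_subset
        Optional ``{"drug": [...], "disease": [...]}`` restriction to named
        similarity sources.
    """

    use_knn: bool = True
    use_pretrain: bool = True
    similarity_subset: dict[str, list[str]] | None = None
    label: str = "full"


def _select_sims(
    sims: dict[str, LabeledMatrix], subset: list[str] | None, entity: str
) -> list[LabeledMatrix]:
    if subset is None:
        chosen = list(sims.values())
    else:
        missing = [name for name in subset if name not in sims]
        if missing:
            raise KeyError(f"unknown {entity} similarity names: {missing}")
        chosen = [sims[name] for name in subset]
    if not chosen:
        raise ValueError(f"no {entity} similarity matrices left after subsetting")
    return chosen


def extract_association(X_star: np.ndarray, sim_width: int, view: str) -> np.ndarray:
    """Slice the association block out of a reconstructed integrated matrix.

    The drug view returns the block as-is (m×n); the disease view returns its
    transpose so both views land on drugs × diseases.
    """
    X_star = np.asarray(X_star, dtype=float)
    if not 0 < sim_width < X_star.shape[1]:
        raise ValueError(f"sim_width {sim_width} incompatible with shape {X_star.shape}")
    block = X_star[:, sim_width:]
    return block if view == "drug" else block.T


def predict_ddas(
    bundle: DatasetBundle,
    params: Hyperparams | None = None,
    flags: AblationFlags | None = None,
) -> ScoreMatrix:
    """Predict association scores for every drug–disease pair.

    Deterministic given ``params.seed``; the two views use seeds derived from
    it so their fits are independent but reproducible.
    """
    params = params or Hyperparams()
    flags = flags or AblationFlags()
    subset = flags.similarity_subset or {}
    A = bundle.association
    m, n = A.shape

    R = fuse_similarities(_select_sims(bundle.drug_sims, subset.get("drug"), "drug"), "drug")
    D = fuse_similarities(
        _select_sims(bundle.disease_sims, subset.get("disease"), "disease"), "disease"
    )

    A_T = LabeledMatrix(A.values.T, A.col_ids, A.row_ids)
    if flags.use_knn:
        A_rd1 = knn_fill(A, R, params.k, params.decay)
        A_rd2_T = knn_fill(A_T, D, params.k, params.decay)
    else:
        A_rd1, A_rd2_T = A, A_T

    X_R = build_integrated(R, A_rd1, "drug")
    X_D = build_integrated(D, A_rd2_T, "disease")
    L_R = build_laplacian(R)
    L_D = build_laplacian(D)
    dims = layer_dims(m, n, params.taus)

    params_r = replace(params, seed=(params.seed * 2_654_435_761 + 1) % (2**31))
    params_d = replace(params, seed=(params.seed * 2_654_435_761 + 2) % (2**31))
    logger.info(
        "fitting both views: m=%d n=%d dims=%s knn=%s pretrain=%s",
        m, n, dims, flags.use_knn, flags.use_pretrain,
    )
    stack_r = fit_dnmf(X_R, L_R, params_r, dims=dims, pretrain=flags.use_pretrain)
    stack_d = fit_dnmf(X_D, L_D, params_d, dims=dims, pretrain=flags.use_pretrain)

    A1 = extract_association(reconstruct(stack_r), X_R.sim_width, "drug")
    A2 = extract_association(reconstruct(stack_d), X_D.sim_width, "disease")
    return ScoreMatrix((A1 + A2) / 2.0, A.row_ids, A.col_ids)


def run_ablation(
    bundle: DatasetBundle,
    params: Hyperparams,
    variants: list[AblationFlags],
    protocol: str = "cv10",
    seed: int = 0,
):
    """Run the evaluation protocol for each ablation variant on shared folds.

    ``protocol`` is ``"cv10"`` or ``"coldstart"``.  Returns a pandas
    DataFrame with one row per variant (auc, aupr, precision).
    """
    import pandas as pd

    from .evaluate import run_cv10, run_coldstart

    if not variants:
        raise ValueError("need at least one ablation variant")
    if protocol not in ("cv10", "coldstart"):
        raise ValueError("protocol must be 'cv10' or 'coldstart'")
    rows = []
    for flags in variants:
        runner = run_cv10 if protocol == "cv10" else run_coldstart
        report = runner(bundle, params, flags, seed)
        rows.append(
            {
                "variant": flags.label,
                "auc": report.auc,
                "aupr": report.aupr,
                "precision": report.precision,
            }
        )
    return pd.DataFrame(rows)
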