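"""Synthetic datasets with the structure the factorization model assumes.

Real drug–disease data consist of a very sparse binary association matrix
(about 1% of cells positive) together with similarity matrices in [0, 1] with
unit diagonal.  The generator plants a nonnegative low-rank signal: latent
factors U (drugs) and V (diseases) give a ground-truth score matrix U Vᵀ,
associations are the top-density fraction of those scores, and similarities
are noisy rescalings of U Uᵀ and V Vᵀ — so the similarities genuinely carry
information about the held-out associations, as the model requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import DatasetBundle, LabeledMatrix

__all__ = ["SyntheticConfig", "generate_dataset", "split_known_associations"]


@dataclass
class SyntheticConfig:
    """Generator settings.

    m, n
        Drug and disease counts.
    r
        Latent rank of the planted signal; must not exceed min(m, n).
    density
        Target fraction of positive association cells, in (0, 1).
    noise_sd
        Scale of the symmetric Gaussian noise added to both similarity
        matrices (0 gives exact rescaled Gram matrices).
    n_singleton_drugs
        Number of drug rows thinned to exactly one positive — the cold-start
        target population.
    seed
        Seed for all randomness; identical configs produce identical data.
    """

    m: int = 60
    n: int = 40
    r: int = 5
    density: float = 0.01
    noise_sd: float = 0.1
    n_singleton_drugs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if self.r > min(self.m, self.n):
            raise ValueError("latent rank r must not exceed min(m, n)")
        if self.n_singleton_drugs > self.m:
            raise ValueError("n_singleton_drugs must not exceed m")


def _similarity_from_factors(F: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Rescaled Gram matrix of F with unit diagonal and optional noise."""
    g = F @ F.T
    peak = g.max()
    s = g / peak if peak > 0 else g
    np.fill_diagonal(s, 1.0)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=s.shape)
        s = np.clip(s + noise, 0.0, 1.0)
        s = (s + s.T) / 2.0
        np.fill_diagonal(s, 1.0)
    return s


def generate_dataset(cfg: SyntheticConfig) -> tuple[DatasetBundle, LabeledMatrix]:
    """Generate a dataset bundle and its ground-truth score matrix.

    Returns ``(bundle, ground_truth)`` where ``ground_truth`` is the planted
    U Vᵀ score matrix (same ids as the association matrix).  The association
    matrix holds 1 at the ``ceil(density * m * n)`` largest ground-truth
    entries; afterwards ``n_singleton_drugs`` positive rows are thinned to
    their single largest-scoring positive.
    """
    rng = np.random.default_rng(cfg.seed)
    U = np.abs(rng.standard_normal((cfg.m, cfg.r)))
    V = np.abs(rng.standard_normal((cfg.n, cfg.r)))
    truth = U @ V.T

    n_pos = math.ceil(cfg.density * cfg.m * cfg.n)
    flat = truth.ravel()
    top = np.argpartition(flat, -n_pos)[-n_pos:]
    A = np.zeros(cfg.m * cfg.n)
    A[top] = 1.0
    A = A.reshape(cfg.m, cfg.n)

    if cfg.n_singleton_drugs > 0:
        positive_rows = np.flatnonzero(A.sum(axis=1) >= 1)
        if len(positive_rows) < cfg.n_singleton_drugs:
            raise ValueError(
                f"only {len(positive_rows)} rows have positives; cannot make "
                f"{cfg.n_singleton_drugs} singleton drugs"
            )
        chosen = rng.choice(positive_rows, size=cfg.n_singleton_drugs, replace=False)
        for row in chosen:
            pos = np.flatnonzero(A[row])
            keep = pos[np.argmax(truth[row, pos])]
            A[row] = 0.0
            A[row, keep] = 1.0

    drug_ids = [f"R{i + 1:03d}" for i in range(cfg.m)]
    disease_ids = [f"D{j + 1:03d}" for j in range(cfg.n)]
    drug_sim = _similarity_from_factors(U, cfg.noise_sd, rng)
    disease_sim = _similarity_from_factors(V, cfg.noise_sd, rng)

    bundle = DatasetBundle(
        association=LabeledMatrix(A, drug_ids, disease_ids),
        drug_sims={"latent": LabeledMatrix(drug_sim, drug_ids, drug_ids)},
        disease_sims={"latent": LabeledMatrix(disease_sim, disease_ids, disease_ids)},
    )
    ground_truth = LabeledMatrix(truth, drug_ids, disease_ids)
    return bundle, ground_truth


def split_known_associations(
    A: LabeledMatrix, fraction_hidden: float, seed: int
) -> tuple[LabeledMatrix, list[tuple[int, int]]]:
    """Hide a uniform random fraction of the positive cells.

    Returns the training matrix (hidden positives zeroed) and the list of
    hidden (row, column) index pairs.  ``ceil(fraction_hidden * positives)``
    cells are sampled without replacement; deterministic under ``seed``.
    """
    if not 0 < fraction_hidden < 1:
        raise ValueError("fraction_hidden must be in (0, 1)")
    pos = np.argwhere(A.values == 1)
    if len(pos) == 0:
        raise ValueError("association matrix has no positive cells")
    n_hide = math.ceil(fraction_hidden * len(pos))
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pos), size=n_hide, replace=False)
    hidden = [tuple(int(x) for x in pos[i]) for i in picked]
    train = A.values.copy()
    for i, j in hidden:
        train[i, j] = 0.0
    return LabeledMatrix(train, A.row_ids, A.col_ids), hidden
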