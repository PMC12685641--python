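"""Principal component scoring of the sensitivity matrix.

The m x n score matrix A (species x inputs) is column mean-centered and
decomposed by SVD, the numerically stable route to classical ``princomp``
output (no unit-variance scaling).  Each species receives a single scalar
"PCA score": the variance-weighted L2 norm of its component scores over the
leading components covering >= 90% of the variance, rescaled so the score
distribution has unit median.  On that scale, a selection band such as
[0.8, 1.2] picks out species of typical-to-high leverage on the system and
is meaningful regardless of the model's absolute sensitivity magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List

import numpy as np
import pandas as pd

from .sensitivity import ScoreMatrix

__all__ = ["PcaResult", "run_pca", "select_key_species"]

_VARIANCE_COVERAGE = 0.90


@dataclass
class PcaResult:
    loadings: np.ndarray  # (n inputs, k components), orthonormal columns
    component_scores: np.ndarray  # (m outputs, k components)
    explained_variance_ratio: np.ndarray  # (k,)
    species_score: Dict[str, float]
    outputs: List[str]
    inputs: List[str]

    def scores_frame(self) -> pd.DataFrame:
        return pd.Series(self.species_score, name="pca_score").rename_axis(
            "species"
        ).to_frame()


def run_pca(score_matrix: ScoreMatrix) -> PcaResult:
    """Decompose a sensitivity score matrix into principal components."""
    A = np.asarray(score_matrix.A, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2 or A.shape[1] < 2:
        raise ValueError("score matrix must be at least 2 x 2")
    if not np.all(np.isfinite(A)):
        raise ValueError("score matrix contains non-finite entries")
    X = A - A.mean(axis=0, keepdims=True)
    if np.allclose(X, 0.0):
        raise ValueError("degenerate input: zero variance in every column")

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| element of each component positive
    for k in range(Vt.shape[0]):
        pivot = np.argmax(np.abs(Vt[k]))
        if Vt[k, pivot] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    loadings = Vt.T
    scores = U * s
    var = s**2
    evr = var / var.sum()

    # species score: variance-weighted norm over components covering >= 90%
    k_keep = int(np.searchsorted(np.cumsum(evr), _VARIANCE_COVERAGE) + 1)
    k_keep = min(k_keep, scores.shape[1])
    w = evr[:k_keep]
    raw = np.sqrt((scores[:, :k_keep] ** 2 * w[None, :]).sum(axis=1))
    med = np.median(raw)
    scaled = raw / med if med > 0 else raw
    species_score = dict(zip(score_matrix.outputs, scaled.tolist()))

    return PcaResult(
        loadings=loadings,
        component_scores=scores,
        explained_variance_ratio=evr,
        species_score=species_score,
        outputs=list(score_matrix.outputs),
        inputs=list(score_matrix.inputs),
    )


def select_key_species(
    result: PcaResult, lo: float = 0.8, hi: float = 1.2
) -> List[str]:
    """Species whose PCA score lies in [lo, hi], descending by score.

    Bounds are inclusive; ties broken by species id.
    """
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    picked = [
        (score, sid)
        for sid, score in result.species_score.items()
        if lo <= score <= hi
    ]
    picked.sort(key=lambda t: (-t[0], t[1]))
    return [sid for _, sid in picked]
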