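"""Sign and permutation alignment of latent solutions.

Factor models and VAE latent spaces are identified only up to column
permutation and reflection.  Alignment greedily matches estimated columns
to reference columns by absolute correlation and then flips signs so each
matched correlation is positive.  MAE/RMSE between true and estimated
scores are meaningless without this step.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import orthogonal_procrustes

__all__ = ["align_columns", "align_scores", "procrustes_align"]


def procrustes_align(
    est: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal rotation of ``est`` columns closest to ``reference``.

    Resolves the full rotational indeterminacy of a latent solution (sign
    flips and permutations are special cases).  Returns ``(est @ R, R)``.
    """
    est = np.asarray(est, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if est.shape != reference.shape:
        raise ValueError("shape mismatch")
    r, _ = orthogonal_procrustes(est, reference)
    return est @ r, r


def _similarity_matrix(a: np.ndarray, b: np.ndarray, center: bool) -> np.ndarray:
    if center:
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
    sa = np.linalg.norm(a, axis=0)
    sb = np.linalg.norm(b, axis=0)
    sa[sa == 0] = 1.0
    sb[sb == 0] = 1.0
    return (a / sa).T @ (b / sb)  # (cols_a, cols_b)


def align_columns(
    est: np.ndarray, reference: np.ndarray, center: bool = True
) -> tuple[np.ndarray, list[int], list[int]]:
    """Match columns of ``est`` to ``reference`` greedily on |correlation|.

    With ``center=False`` the similarity is the cosine instead of the
    correlation — appropriate for loading matrices, whose columns may be
    near-constant.  Returns ``(aligned, permutation, signs)`` where
    ``aligned[:, k] = signs[k] * est[:, permutation[k]]``.
    """
    est = np.asarray(est, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if est.shape[1] != reference.shape[1]:
        raise ValueError("column count mismatch")
    corr = _similarity_matrix(est, reference, center)  # est-cols x ref-cols
    q = est.shape[1]
    perm = [-1] * q
    signs = [1] * q
    free = set(range(q))
    # repeatedly take the globally largest remaining |corr|
    order = np.dstack(np.unravel_index(np.argsort(-np.abs(corr), axis=None), corr.shape))[0]
    taken_ref: set[int] = set()
    for i, k in order:
        i, k = int(i), int(k)
        if i in free and k not in taken_ref:
            perm[k] = i
            signs[k] = 1 if corr[i, k] >= 0 else -1
            free.discard(i)
            taken_ref.add(k)
        if not free:
            break
    aligned = est[:, perm] * np.asarray(signs)
    return aligned, perm, signs


def align_scores(est_scores: np.ndarray, reference_scores: np.ndarray) -> np.ndarray:
    """Convenience wrapper returning only the aligned score matrix."""
    aligned, _, _ = align_columns(
        np.atleast_2d(np.asarray(est_scores, dtype=float).T).T,
        np.atleast_2d(np.asarray(reference_scores, dtype=float).T).T,
    )
    return aligned
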