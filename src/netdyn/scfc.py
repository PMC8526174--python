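"""The structure–function correlation statistic.

The central quantity of the package: the Pearson correlation between the
flattened off-diagonal entries of the structural adjacency matrix and a
functional-connectivity matrix.  All ordered off-diagonal pairs (i ≠ j)
enter, so an asymmetric FC matrix (e.g. the SER sequential-activation
counts) contributes both orientations; missing (NaN) FC entries are
excluded pairwise.  Because the Pearson coefficient is invariant under
positive affine rescaling, raw counts and normalized FC give identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SCFCResult", "scfc_correlation", "symmetrize_fc"]


@dataclass
class SCFCResult:
    """Outcome of one SC/FC comparison.

    ``r`` is NaN when the correlation is undefined (fewer than two valid
    pairs, or zero variance in either flattened vector); ``status``
    distinguishes that explicitly from a genuine near-zero correlation.
    """

    r: float
    n_pairs_used: int
    status: str = "ok"  # "ok" | "degenerate"

    def __bool__(self) -> bool:
        return self.status == "ok"


def _offdiag_mask(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def scfc_correlation(A: np.ndarray, F: np.ndarray) -> SCFCResult:
    """Pearson correlation of SC and FC over ordered off-diagonal pairs.

    Parameters
    ----------
    A
        Binary adjacency matrix (structural connectivity).
    F
        Real FC matrix of the same shape; NaN entries are treated as
        missing and excluded (pairwise) together with their SC partners.
    """
    A = np.asarray(A, dtype=float)
    F = np.asarray(F, dtype=float)
    if A.shape != F.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"shape mismatch: SC {A.shape} vs FC {F.shape}")
    mask = _offdiag_mask(A.shape[0]) & np.isfinite(F)
    a = A[mask]
    f = F[mask]
    n_pairs = int(mask.sum())
    if n_pairs < 2:
        return SCFCResult(np.nan, n_pairs, status="degenerate")
    a = a - a.mean()
    f = f - f.mean()
    va = float(a @ a)
    vf = float(f @ f)
    if va <= 0.0 or vf <= 0.0:
        return SCFCResult(np.nan, n_pairs, status="degenerate")
    r = float((a @ f) / np.sqrt(va * vf))
    return SCFCResult(r, n_pairs, status="ok")


def symmetrize_fc(F: np.ndarray) -> np.ndarray:
    """S + Sᵀ, for sensitivity analysis of asymmetric sequential matrices."""
    F = np.asarray(F, dtype=float)
    return F + F.T
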