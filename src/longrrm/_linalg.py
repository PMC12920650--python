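"""Shared small linear-algebra helpers.

The half-vectorization convention used throughout the package is
diagonal-major: the k diagonal entries first (in order), then the strictly
lower-triangular entries row-wise, i.e. (1,0), (2,0), (2,1), (3,0), ...
Sampling covariances of variance parameters follow this ordering.
"""

from __future__ import annotations

import numpy as np

__all__ = ["vech_indices", "vech", "unvech", "is_psd", "nearest_psd"]


def vech_indices(k: int):
    """Row/column index pairs for the diagonal-major vech of a k x k matrix."""
    idx = [(i, i) for i in range(k)]
    idx.extend((i, j) for i in range(k) for j in range(i))
    return idx


def vech(K: np.ndarray) -> np.ndarray:
    """Half-vectorize a symmetric matrix (diagonal entries first)."""
    K = np.asarray(K)
    k = K.shape[0]
    return np.array([K[i, j] for i, j in vech_indices(k)])


def unvech(v, k: int) -> np.ndarray:
    """Rebuild a symmetric k x k matrix from its diagonal-major vech."""
    v = np.asarray(v, dtype=float)
    if v.size != k * (k + 1) // 2:
        raise ValueError("vech length does not match order")
    K = np.zeros((k, k))
    for val, (i, j) in zip(v, vech_indices(k)):
        K[i, j] = val
        K[j, i] = val
    return K


def is_psd(K: np.ndarray, tol: float = 0.0) -> bool:
    if K.size == 0:
        return True
    w = np.linalg.eigvalsh((K + K.T) / 2.0)
    return bool(w.min() >= -abs(tol))


def nearest_psd(K: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone (eigenvalue clipping)."""
    S = (K + K.T) / 2.0
    w, V = np.linalg.eigh(S)
    return (V * np.clip(w, 0.0, None)) @ V.T
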