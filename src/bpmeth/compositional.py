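"""Compositional-data primitives shared by the cell-type and mediation modules.

Cell compositions live on the 6-part simplex and cannot be fed to linear
models directly (sum-to-one singularity, spurious negative correlation).
This module provides the standard Aitchison toolkit: closure, multiplicative
zero replacement, centered log-ratio (clr), and an isometric log-ratio (ilr)
transform built from a fixed sequential binary partition whose *first*
coordinate is proportional to log(Stromal / Syncytiotrophoblast) — the
contrast of primary biological interest (villous stromal cells vs the
syncytial layer).
"""

from __future__ import annotations

import numpy as np

#: Canonical cell-type order used throughout the package.
CELL_TYPES = (
    "Syncytiotrophoblast",
    "Stromal",
    "Endothelial",
    "Trophoblast",
    "Hofbauer",
    "nRBC",
)

N_TYPES = len(CELL_TYPES)


def closure(x: np.ndarray) -> np.ndarray:
    """Rescale rows of ``x`` to sum to one."""
    x = np.asarray(x, dtype=float)
    s = x.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("closure requires rows with positive sum")
    return x / s


def zero_replace(x: np.ndarray, delta: float = 1e-4) -> np.ndarray:
    """Multiplicative zero replacement.

    Zeros become ``delta``; non-zero components are scaled down by the mass
    handed to the zeros, so rows still sum to one. Identity when no zeros.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.any(x < 0):
        raise ValueError("compositions must be non-negative")
    if np.any((x > 0).sum(axis=1) == 0):
        raise ValueError("all-zero composition row")
    x = closure(x)
    zeros = x == 0
    n_zero = zeros.sum(axis=1, keepdims=True)
    out = np.where(zeros, delta, x * (1.0 - n_zero * delta))
    return closure(out)


def _sbp_basis() -> np.ndarray:
    """Orthonormal ilr contrast matrix (5 x 6) from a fixed partition.

    Partition order (columns follow :data:`CELL_TYPES`):

    1. Stromal (+) vs Syncytiotrophoblast (-)          -> sqrt(1/2)·log(S/SCT)
    2. {Stromal, SCT} (+) vs the four minor types (-)
    3. {Endothelial, Trophoblast} (+) vs {Hofbauer, nRBC} (-)
    4. Endothelial (+) vs Trophoblast (-)
    5. Hofbauer (+) vs nRBC (-)
    """
    parts = [
        (["Stromal"], ["Syncytiotrophoblast"]),
        (["Stromal", "Syncytiotrophoblast"],
         ["Endothelial", "Trophoblast", "Hofbauer", "nRBC"]),
        (["Endothelial", "Trophoblast"], ["Hofbauer", "nRBC"]),
        (["Endothelial"], ["Trophoblast"]),
        (["Hofbauer"], ["nRBC"]),
    ]
    idx = {name: j for j, name in enumerate(CELL_TYPES)}
    psi = np.zeros((len(parts), N_TYPES))
    for row, (plus, minus) in enumerate(parts):
        r, s = len(plus), len(minus)
        psi[row, [idx[p] for p in plus]] = np.sqrt(s / (r * (r + s)))
        psi[row, [idx[m] for m in minus]] = -np.sqrt(r / (s * (r + s)))
    return psi


#: 5 x 6 orthonormal basis (rows sum to zero, pairwise orthogonal, unit norm).
ILR_BASIS = _sbp_basis()


def clr(x: np.ndarray) -> np.ndarray:
    """Centered log-ratio transform (rows strictly positive)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("clr requires strictly positive compositions")
    lx = np.log(x)
    return lx - lx.mean(axis=1, keepdims=True)


def ilr(x: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Isometric log-ratio coordinates (n x 5) of compositions (n x 6)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive compositions; "
                         "apply zero_replace first")
    psi = ILR_BASIS if basis is None else np.asarray(basis, dtype=float)
    return np.log(x) @ psi.T


def ilr_inverse(y: np.ndarray, basis: np.ndarray | None = None) -> np.ndarray:
    """Map ilr coordinates back onto the simplex."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    psi = ILR_BASIS if basis is None else np.asarray(basis, dtype=float)
    return closure(np.exp(y @ psi))


def stromal_sct_log_ratio(x: np.ndarray) -> np.ndarray:
    """log(Stromal / Syncytiotrophoblast) per sample (natural log)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    i_s = CELL_TYPES.index("Stromal")
    i_t = CELL_TYPES.index("Syncytiotrophoblast")
    if np.any(x[:, [i_s, i_t]] <= 0):
        raise ValueError("Stromal and Syncytiotrophoblast must be positive; "
                         "apply zero_replace first")
    return np.log(x[:, i_s]) - np.log(x[:, i_t])
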