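"""Elastic-network normal mode analysis of the Cα model.

A plain anisotropic elastic network is built on the (energy-minimized)
bead coordinates: every pair within a distance cutoff is connected by a
Hookean spring acting along the pair axis,

    E = (k/2) Σ_{r0_ij ≤ cutoff} (r_ij − r0_ij)².

Diagonalizing the mass-weighted Hessian yields the normal modes.  For
any non-collinear structure the six lowest modes are rigid-body
translations/rotations (eigenvalue ≈ 0) and are excluded from fitting;
modes 7 and up describe internal motions, ordered from most global
(low frequency) to most local.

The degree-of-collectivity measure κ ∈ (1/N, 1] quantifies how many
atoms participate in a mode: κ = 1 when every atom moves equally,
κ = 1/N when a single atom moves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

logger = logging.getLogger(__name__)

__all__ = ["NormalModeSet", "build_enm_hessian", "compute_modes",
           "collectivity", "write_modes"]


@dataclass
class NormalModeSet:
    """Mass-weighted ENM eigenvectors with frequencies and collectivities.

    ``eigenvectors`` has shape ``(n_modes, 3N)``; rows are orthonormal.
    ``mode_index`` is 1-based in ascending eigenvalue order, so the
    rigid-body subspace occupies indices 1–6 for free, non-collinear
    structures.
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray          # ω² in reduced units
    mode_index: np.ndarray           # 1-based
    collectivity: np.ndarray
    zero_tol: float

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.eigenvectors.shape[1] // 3

    @property
    def frequencies(self) -> np.ndarray:
        return np.sqrt(np.maximum(self.eigenvalues, 0.0))

    @property
    def is_rigid_body(self) -> np.ndarray:
        return self.eigenvalues < self.zero_tol

    @property
    def n_rigid_body(self) -> int:
        return int(np.sum(self.is_rigid_body))

    def select(self, mode_indices) -> np.ndarray:
        """Displacement basis (rows) for the given 1-based mode numbers."""
        mode_indices = np.asarray(mode_indices, dtype=int)
        if np.any(mode_indices < 1) or np.any(mode_indices > self.n_modes):
            raise ValueError(f"mode indices out of range 1..{self.n_modes}")
        return self.eigenvectors[mode_indices - 1]


def build_enm_hessian(
    coords: np.ndarray, cutoff: float = 8.0, spring: float = 1.0
) -> np.ndarray:
    """Hessian (3N×3N) of the pairwise elastic network energy.

    Emits a warning (and returns the zero matrix) when no pair falls
    within the cutoff.
    """
    x = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 atoms")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    hess = np.zeros((3 * n, 3 * n))
    ii, jj = np.triu_indices(n, k=1)
    d = x[jj] - x[ii]
    r = np.linalg.norm(d, axis=1)
    within = r <= cutoff
    if not np.any(within):
        logger.warning("no atom pair within ENM cutoff %.2f Å", cutoff)
        return hess
    for i, j, dv, rv in zip(ii[within], jj[within], d[within], r[within]):
        u = dv / rv
        block = spring * np.outer(u, u)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        hess[si, si] += block
        hess[sj, sj] += block
        hess[si, sj] -= block
        hess[sj, si] -= block
    return hess


def compute_modes(
    hessian: np.ndarray, masses: np.ndarray, n_modes: int
) -> NormalModeSet:
    """Lowest ``n_modes`` solutions of the mass-weighted eigenproblem.

    Eigenvalues within the zero tolerance of 0 (rigid-body subspace)
    are clipped to exactly 0.  Eigenvector sign is fixed so that the
    first component of significant magnitude is positive.
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ValueError("hessian must be square")
    if not np.allclose(hessian, hessian.T, atol=1e-8):
        raise ValueError("hessian is not symmetric within 1e-8")
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    n = hessian.shape[0] // 3
    if len(masses) != n:
        raise ValueError("mass count does not match hessian size")
    n_modes = int(n_modes)
    if not 1 <= n_modes <= 3 * n:
        raise ValueError("n_modes out of range")

    m3 = np.repeat(masses, 3)
    inv_sqrt = 1.0 / np.sqrt(m3)
    mw = hessian * np.outer(inv_sqrt, inv_sqrt)
    mw = 0.5 * (mw + mw.T)  # symmetrize round-off
    evals, evecs = scipy.linalg.eigh(mw)
    zero_tol = 1e-6 * max(float(evals[-1]), 1e-300)
    evals = evals[:n_modes].copy()
    evecs = evecs[:, :n_modes].T.copy()
    evals[np.abs(evals) < zero_tol] = np.maximum(
        evals[np.abs(evals) < zero_tol], 0.0)
    evals[(evals < 0) & (evals > -zero_tol)] = 0.0

    # reproducible sign convention across eigensolvers
    for v in evecs:
        nz = np.flatnonzero(np.abs(v) > 1e-8 * np.max(np.abs(v)))
        if len(nz) and v[nz[0]] < 0:
            v *= -1.0

    kappa = np.array([collectivity(v, n) for v in evecs])
    return NormalModeSet(
        eigenvectors=evecs,
        eigenvalues=evals,
        mode_index=np.arange(1, n_modes + 1),
        collectivity=kappa,
        zero_tol=zero_tol,
    )


def collectivity(mode_vector: np.ndarray, n_atoms: int) -> float:
    """Degree of collectivity κ of a displacement vector.

    κ = (1/N) exp(−Σ_i α d_i² ln(α d_i²)) with α normalizing
    Σ_i α d_i² = 1, where d_i² is atom i's squared displacement.
    """
    v = np.asarray(mode_vector, dtype=float).reshape(n_atoms, 3)
    d2 = np.sum(v * v, axis=1)
    total = d2.sum()
    if total <= 0:
        raise ValueError("zero mode vector")
    p = d2 / total
    nz = p > 0
    entropy = -np.sum(p[nz] * np.log(p[nz]))
    return float(np.exp(entropy) / n_atoms)


def write_modes(modes: NormalModeSet, matrix_path: str | Path,
                summary_path: str | Path) -> None:
    """Write eigenvectors as a plain-text matrix and a per-mode summary."""
    np.savetxt(matrix_path, modes.eigenvectors,
               header="rows: modes (ascending eigenvalue); cols: 3N mass-weighted components")
    with open(summary_path, "w") as fh:
        fh.write("mode\teigenvalue\tfrequency\tcollectivity\trigid_body\n")
        for k in range(modes.n_modes):
            fh.write(
                f"{modes.mode_index[k]}\t{modes.eigenvalues[k]:.8e}\t"
                f"{modes.frequencies[k]:.8e}\t{modes.collectivity[k]:.6f}\t"
                f"{int(modes.is_rigid_body[k])}\n"
            )
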