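"""Essential dynamics: PCA of Cα positional fluctuations.

Frames are superposed to the ensemble mean (same convention as RMSF), the
3N×3N covariance of the flattened coordinates is formed with population
(1/F) normalisation, and its symmetric eigendecomposition yields the
collective modes.  Extreme projections along a mode reconstruct the
conformations at the observed projection limits and interpolate between
them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import mean_structure
from .io import Ensemble

__all__ = ["PCAResult", "covariance_and_modes", "project", "extreme_projections"]


@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # Å², descending, clipped at 0
    eigenvectors: np.ndarray       # (3N, n_modes), orthonormal columns
    fractions: np.ndarray          # explained-variance fractions, sum 1
    mean: np.ndarray               # (N, 3) mean structure
    res_ids: np.ndarray
    trace: float                   # total fluctuation (Å²)


def covariance_and_modes(ensemble: Ensemble, align: bool = True) -> PCAResult:
    """Eigendecomposition of the Cα fluctuation covariance.

    ``align=False`` skips the fit-to-mean superposition for ensembles
    already in a common frame.
    """
    if ensemble.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if align:
        mean, fitted = mean_structure(ensemble)
        dev = fitted.coords - mean[None]
    else:
        mean = ensemble.coords.mean(axis=0)
        dev = ensemble.coords - mean[None]
    f = ensemble.n_frames
    x = dev.reshape(f, -1)                       # (F, 3N)
    cov = x.T @ x / f
    w, v = np.linalg.eigh(cov)
    if w.min() < -1e-8:
        raise ValueError("covariance eigenvalues below tolerance")
    w = np.clip(w[::-1], 0.0, None)
    v = v[:, ::-1]
    total = w.sum()
    fractions = w / total if total > 0 else np.zeros_like(w)
    return PCAResult(w, v, fractions, mean, ensemble.res_ids.copy(),
                     trace=float(np.trace(cov)))


def project(ensemble: Ensemble, pca: PCAResult, component: int = 1,
            align: bool = True) -> np.ndarray:
    """Per-frame projections (Å) onto one mode (1-based component index)."""
    if not 1 <= component <= pca.eigenvectors.shape[1]:
        raise ValueError("component index out of range")
    if align:
        _, fitted = mean_structure(ensemble)
        coords = fitted.coords
    else:
        coords = ensemble.coords
    dev = (coords - pca.mean[None]).reshape(ensemble.n_frames, -1)
    return dev @ pca.eigenvectors[:, component - 1]


def extreme_projections(ensemble: Ensemble, pca: PCAResult,
                        component: int = 1, n_interpolated: int = 10,
                        align: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Conformations spanning a mode's observed projection range.

    Returns ``(structures, t)`` where ``structures`` has shape
    (n_interpolated, N, 3): the mean structure displaced along the mode at
    ``n_interpolated`` evenly spaced projections from the minimum to the
    maximum observed; endpoints are the extreme-projection conformations
    reconstructed on the mode.
    """
    if n_interpolated < 2:
        raise ValueError("need at least 2 interpolated structures")
    lam = pca.eigenvalues[component - 1]
    if lam <= 1e-12:     # Å²; numerically zero fluctuation
        raise ValueError(f"component {component} has zero variance")
    proj = project(ensemble, pca, component, align=align)
    t = np.linspace(proj.min(), proj.max(), n_interpolated)
    vec = pca.eigenvectors[:, component - 1].reshape(-1, 3)
    structures = pca.mean[None] + t[:, None, None] * vec[None]
    return structures, t
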