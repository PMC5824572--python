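"""Similarity and accuracy scores for 3D structures and distance profiles.

dPCC and dSCC are the Pearson and Spearman correlations of two pairwise-
distance vectors; both lie in [-1, 1] and are the standard model-quality
scores for reconstructed chromatin structures.  dRMSE is the root-mean-square
difference of pairwise distances after superposing one structure onto the
other with a full Procrustes similarity transform (translation, orthogonal
rotation — reflections included — and isotropic rescaling), since two
structures can only be compared at a common scale.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr, rankdata

from .model import Structure3D

__all__ = ["dpcc", "dscc", "procrustes_align", "drmse", "structure_dscc"]


def _as_vectors(d, D) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(d, dtype=float).ravel()
    D = np.asarray(D, dtype=float).ravel()
    if d.shape != D.shape:
        raise ValueError(f"length mismatch: {d.shape} vs {D.shape}")
    if d.size < 2:
        raise ValueError("need at least 2 distances")
    return d, D


def dpcc(d, D) -> float:
    """Pearson correlation of two distance vectors."""
    d, D = _as_vectors(d, D)
    if np.ptp(d) == 0 or np.ptp(D) == 0:
        raise ValueError("dPCC undefined: a distance vector has zero variance")
    return float(pearsonr(d, D).statistic)


def dscc(d, D) -> float:
    """Spearman correlation: rank-transform (average ranks for ties), then dPCC."""
    d, D = _as_vectors(d, D)
    if np.ptp(d) == 0 or np.ptp(D) == 0:
        raise ValueError("dSCC undefined: a distance vector has zero variance")
    return dpcc(rankdata(d), rankdata(D))


def _coords(s) -> np.ndarray:
    return s.coords if isinstance(s, Structure3D) else np.asarray(s, dtype=float)


def procrustes_align(
    s_prime, s, proper_rotation: bool = False
) -> Structure3D:
    """Least-squares superposition of ``s_prime`` onto reference ``s``.

    Solves the classical full Procrustes problem over translation, orthogonal
    rotation and isotropic scale.  The orthogonal group includes reflections
    unless ``proper_rotation`` restricts to det = +1.
    """
    x = _coords(s_prime)
    y = _coords(s)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 points to superpose")
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    normx = np.linalg.norm(xc)
    normy = np.linalg.norm(yc)
    if normx == 0 or normy == 0:
        raise ValueError("degenerate structure: all points coincident")
    u, sv, vt = np.linalg.svd(xc.T @ yc)
    if proper_rotation and np.linalg.det(u @ vt) < 0:
        u[:, -1] *= -1
        sv = sv.copy()
        sv[-1] *= -1
    rot = u @ vt
    scale = sv.sum() / normx**2
    aligned = scale * xc @ rot + my
    bin_map = s_prime.bin_map if isinstance(s_prime, Structure3D) else None
    return Structure3D(aligned, bin_map=bin_map)


def drmse(
    s_prime,
    s,
    proper_rotation: bool = False,
    rmsd_coords: bool = False,
) -> float:
    """Root-mean-square distance error after Procrustes superposition.

    Default: align ``s_prime`` onto ``s``, then RMS difference over all
    n(n-1)/2 pairwise distances of the two structures.  ``rmsd_coords``
    computes the coordinate RMSD of the superposed point sets instead.
    """
    aligned = procrustes_align(s_prime, s, proper_rotation=proper_rotation)
    y = _coords(s)
    if rmsd_coords:
        return float(np.sqrt(np.mean(np.sum((aligned.coords - y) ** 2, axis=1))))
    dd = pdist(aligned.coords) - pdist(y)
    return float(np.sqrt(np.mean(dd**2)))


def structure_dscc(a, b) -> float:
    """dSCC between the full pairwise-distance vectors of two structures."""
    return dscc(pdist(_coords(a)), pdist(_coords(b)))
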