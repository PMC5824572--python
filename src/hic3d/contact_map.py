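"""Reading, validation, filtering and normalization of Hi-C contact matrices.

A contact map is an N x N symmetric, non-negative matrix of interaction
frequencies (IF) between equal-size genomic bins of one chromosome.  All
downstream modeling operates on a map whose uninformative (empty) bins have
been removed; :func:`filter_empty_bins` records the surviving original bin
indices so structures can be mapped back to genomic coordinates.

Two matrix-balancing normalizations are provided: iterative correction (ICE)
and sequential component normalization (SCN).  Both remove multiplicative
bin-level biases; neither creates contacts where the input had none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactMap",
    "ContactMapError",
    "read_contact_map",
    "write_contact_map",
    "filter_empty_bins",
    "ice_normalize",
    "scn_normalize",
    "prefilter_low_if",
]


class ContactMapError(ValueError):
    """Raised for malformed or degenerate contact-map input."""


@dataclass
class ContactMap:
    """Square symmetric matrix of interaction frequencies with bin metadata.

    Parameters
    ----------
    matrix : ndarray of shape (n, n)
        Non-negative, finite, symmetric interaction frequencies.
    active_bins : ndarray of int
        Original (pre-filtering) bin index of each current row/column;
        strictly increasing.
    bin_size : int, optional
        Genomic bin width in base pairs, if known.
    chrom_label : str, optional
        Chromosome name, if known.
    balanced : bool
        Whether a normalization converged on this matrix.
    """

    matrix: np.ndarray
    active_bins: np.ndarray = field(default=None)  # type: ignore[assignment]
    bin_size: int | None = None
    chrom_label: str | None = None
    balanced: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ContactMapError(
                f"contact matrix must be square, got shape {self.matrix.shape}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ContactMapError("contact matrix contains non-finite values")
        if np.any(self.matrix < 0):
            raise ContactMapError("contact matrix contains negative values")
        if self.active_bins is None:
            self.active_bins = np.arange(self.n_bins)
        else:
            self.active_bins = np.asarray(self.active_bins, dtype=int)
            if len(self.active_bins) != self.n_bins:
                raise ContactMapError("active_bins length must match matrix size")
            if np.any(np.diff(self.active_bins) <= 0):
                raise ContactMapError("active_bins must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


def _symmetrize(a: np.ndarray) -> np.ndarray:
    return (a + a.T) / 2.0


def read_contact_map(
    path,
    format: str = "dense",
    n_bins: int | None = None,
    one_based: bool = False,
    bin_size: int | None = None,
    chrom_label: str | None = None,
) -> ContactMap:
    """Read a contact map from text.

    ``dense`` expects N whitespace-separated rows of N values; the matrix is
    symmetrized as (A + A.T)/2 on load.  ``coo`` expects three columns
    (bin_i, bin_j, IF); each triple sets both (i, j) and (j, i), duplicate
    triples are summed, absent entries are zero.  Indices are 0-based unless
    ``one_based`` is set.
    """
    if format == "dense":
        try:
            a = np.loadtxt(path, dtype=float, ndmin=2)
        except ValueError as exc:
            raise ContactMapError(f"non-numeric value in {path}: {exc}") from exc
        if a.shape[0] != a.shape[1]:
            raise ContactMapError(
                f"dense matrix in {path} is not square: shape {a.shape}"
            )
        if np.any(a < 0):
            bad = np.argwhere(a < 0)[0]
            raise ContactMapError(
                f"negative IF at row {bad[0] + 1}, column {bad[1] + 1} of {path}"
            )
        return ContactMap(_symmetrize(a), bin_size=bin_size, chrom_label=chrom_label)

    if format == "coo":
        triples = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) != 3:
                    raise ContactMapError(
                        f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                    )
                try:
                    i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError:
                    raise ContactMapError(
                        f"{path}:{lineno}: non-numeric entry {parts!r}"
                    ) from None
                if one_based:
                    i, j = i - 1, j - 1
                if i < 0 or j < 0:
                    raise ContactMapError(f"{path}:{lineno}: negative bin index")
                if v < 0:
                    raise ContactMapError(f"{path}:{lineno}: negative IF {v}")
                triples.append((i, j, v))
        if n_bins is None:
            if not triples:
                raise ContactMapError(f"{path}: empty sparse file and no n_bins given")
            n_bins = max(max(i, j) for i, j, _ in triples) + 1
        a = np.zeros((n_bins, n_bins))
        for k, (i, j, v) in enumerate(triples, start=1):
            if i >= n_bins or j >= n_bins:
                raise ContactMapError(
                    f"{path}: entry {k} has bin index ({i}, {j}) outside "
                    f"declared range 0..{n_bins - 1}"
                )
            a[i, j] += v
        m = a + a.T
        np.fill_diagonal(m, np.diag(a))
        return ContactMap(m, bin_size=bin_size, chrom_label=chrom_label)

    raise ValueError(f"unknown contact map format {format!r}")


def write_contact_map(cmap: ContactMap, path, format: str = "dense") -> None:
    """Write a contact map as text (``dense`` matrix or upper-triangle ``coo``)."""
    m = cmap.matrix

    def fmt(v: float) -> str:
        return str(int(v)) if float(v).is_integer() else f"{v:.6g}"

    with open(path, "w") as fh:
        if format == "dense":
            for row in m:
                fh.write(" ".join(fmt(v) for v in row) + "\n")
        elif format == "coo":
            iu = np.triu_indices(cmap.n_bins)
            for i, j in zip(*iu):
                if m[i, j] != 0:
                    fh.write(f"{i} {j} {fmt(m[i, j])}\n")
        else:
            raise ValueError(f"unknown contact map format {format!r}")


def filter_empty_bins(cmap: ContactMap) -> ContactMap:
    """Drop bins whose off-diagonal contact sum is zero.

    The original indices of surviving bins are recorded in ``active_bins`` so
    output structures can be mapped back onto the unfiltered binning.
    Idempotent.
    """
    off = cmap.matrix.copy()
    np.fill_diagonal(off, 0.0)
    keep = off.sum(axis=1) > 0
    if not np.any(keep):
        raise ContactMapError("no informative bins: every bin has zero contacts")
    if np.all(keep):
        return cmap
    return replace(
        cmap,
        matrix=cmap.matrix[np.ix_(keep, keep)],
        active_bins=cmap.active_bins[keep],
    )


def ice_normalize(
    cmap: ContactMap, max_iters: int = 200, tol: float = 1e-6
) -> ContactMap:
    """Iterative correction (matrix balancing) of a filtered contact map.

    Finds a diagonal bias vector B such that W = B A B has equal row sums,
    iterating until every row sum is within ``tol`` (relative) of the mean,
    then rescales so the mean row sum is 1.  The input must contain no empty
    bins.  Non-convergence returns the best iterate with a warning.
    """
    w = cmap.matrix.astype(float).copy()
    if np.any(w.sum(axis=1) == 0):
        raise ContactMapError("ice_normalize requires a map with no empty bins")
    converged = False
    for _ in range(max_iters):
        s = w.sum(axis=1)
        b = s / s.mean()
        if np.max(np.abs(b - 1.0)) < tol:
            converged = True
            break
        w /= np.outer(b, b)
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iters} iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
    w /= w.sum(axis=1).mean()
    return replace(cmap, matrix=_symmetrize(w), balanced=converged)


def scn_normalize(
    cmap: ContactMap, max_iters: int = 200, tol: float = 1e-6
) -> ContactMap:
    """Sequential component normalization of a filtered contact map.

    Alternately scales each column then each row to unit Euclidean norm until
    the matrix is symmetric within ``tol``; the final step symmetrizes.
    """
    w = cmap.matrix.astype(float).copy()
    if np.any(w.sum(axis=1) == 0):
        raise ContactMapError("scn_normalize requires a map with no empty bins")
    converged = False
    for _ in range(max_iters):
        w /= np.linalg.norm(w, axis=0, keepdims=True)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        if np.max(np.abs(w - w.T)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SCN did not converge in {max_iters} iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
    return replace(cmap, matrix=_symmetrize(w), balanced=converged)


def prefilter_low_if(cmap: ContactMap, quantile: float) -> ContactMap:
    """Zero all IF values strictly below the given quantile of positive entries.

    Pre-processing used by the noisy-input (AdaGrad) pipeline variant to
    suppress weak, noise-dominated contacts.  ``quantile=0`` is the identity.
    """
    if not 0.0 <= quantile <= 1.0:
        raise ValueError(f"quantile must be in [0, 1], got {quantile}")
    if quantile == 0.0:
        return cmap
    pos = cmap.matrix[cmap.matrix > 0]
    if pos.size == 0:
        return cmap
    thr = np.quantile(pos, quantile)
    m = cmap.matrix.copy()
    m[m < thr] = 0.0
    return replace(cmap, matrix=m)
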