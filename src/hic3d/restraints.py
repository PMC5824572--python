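"""Conversion of interaction frequencies to target spatial distances.

The modeling assumption is an inverse power law between contact frequency and
spatial separation: D = 1 / IF**alpha = IF**(-alpha), where alpha is the
conversion factor.  One distance restraint is produced per unordered bin pair
with a positive IF; zero-IF pairs carry no restraint.  By default all target
distances are divided by their maximum so they lie in (0, 1], commensurate
with the random-initialization cube; rank-based model scores are invariant to
this common rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_map import ContactMap

__all__ = ["RestraintSet", "if_to_distance", "build_restraints"]


@dataclass
class RestraintSet:
    """Target distances D for bin pairs (i < j), at a given conversion factor."""

    i: np.ndarray
    j: np.ndarray
    d: np.ndarray
    alpha: float
    n_beads: int
    scale: float = 1.0

    @property
    def n(self) -> int:
        return len(self.d)

    def to_text(self, path) -> None:
        """Dump as 3-column text (i, j, D) for debugging."""
        with open(path, "w") as fh:
            for a, b, dv in zip(self.i, self.j, self.d):
                fh.write(f"{a} {b} {dv:.6g}\n")


def if_to_distance(IF, alpha: float):
    """Target distance for interaction frequency ``IF``: IF**(-alpha).

    ``IF`` must be positive (zero-IF pairs are excluded upstream, never
    converted) and ``alpha`` positive.
    """
    IF = np.asarray(IF, dtype=float)
    if np.any(IF <= 0):
        raise ValueError("if_to_distance requires IF > 0; exclude zero-IF pairs")
    if alpha <= 0:
        raise ValueError(f"conversion factor alpha must be > 0, got {alpha}")
    out = IF ** (-alpha)
    return float(out) if out.ndim == 0 else out


def build_restraints(
    cmap: ContactMap, alpha: float, rescale: str = "max_to_one"
) -> RestraintSet:
    """Assemble the restraint list the likelihood runs over.

    One restraint per unordered pair (i < j) with IF > 0; D = IF**(-alpha).
    With ``rescale='max_to_one'`` all D are divided by max(D) and the divisor
    is recorded in ``scale``; ``rescale='none'`` keeps raw distances.
    """
    if alpha <= 0:
        raise ValueError(f"conversion factor alpha must be > 0, got {alpha}")
    if rescale not in ("max_to_one", "none"):
        raise ValueError(f"unknown rescale mode {rescale!r}")
    n = cmap.n_bins
    iu, ju = np.triu_indices(n, k=1)
    ifs = cmap.matrix[iu, ju]
    mask = ifs > 0
    if not np.any(mask):
        raise ValueError("empty restraint set: no positive off-diagonal IFs")
    iu, ju, ifs = iu[mask], ju[mask], ifs[mask]
    d = ifs ** (-alpha)
    scale = 1.0
    if rescale == "max_to_one":
        scale = float(d.max())
        d = d / scale
    return RestraintSet(i=iu, j=ju, d=d, alpha=alpha, n_beads=n, scale=scale)
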