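"""Structure ensembles, conversion-factor selection and consistency scoring.

For each candidate conversion factor alpha, several independently seeded
optimizations are run; every resulting structure is scored by dSCC between
its model distances and the input-derived target distances over the
restrained pairs.  The structure with the highest dSCC to the input is the
representative model and its alpha is the selected conversion factor (ties
break toward smaller alpha, then smaller seed).  Consistency of the ensemble
at the selected alpha is the mean pairwise dSCC between replicate structures'
full distance vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .contact_map import ContactMap
from .metrics import dscc, structure_dscc
from .model import OptimConfig, OptimTrace, Structure3D, log_likelihood, optimize
from .restraints import RestraintSet, build_restraints

__all__ = [
    "EnsembleEntry",
    "EnsembleResult",
    "run_ensemble",
    "select_representative",
    "ensemble_consistency",
    "score_against_truth",
    "dscc_to_input",
]

# Seed stride between alpha values so every (alpha, replicate) cell of the
# sweep draws an independent, reproducible initialization.
_ALPHA_SEED_STRIDE = 10000


@dataclass
class EnsembleEntry:
    alpha: float
    seed: int
    structure: Structure3D
    dscc_to_input: float
    final_L: float
    iterations: int
    trace: OptimTrace | None = None


@dataclass
class EnsembleResult:
    entries: list[EnsembleEntry]
    representative: EnsembleEntry
    selected_alpha: float
    consistency: float | None


def dscc_to_input(
    structure: Structure3D, r: RestraintSet, all_pairs: bool = False
) -> float:
    """dSCC between model Euclidean distances and target distances.

    By default only restrained pairs (IF > 0) are scored — those are the only
    pairs with a defined target.  With ``all_pairs`` the structure's full
    distance vector is compared against a target vector in which unrestrained
    pairs take the largest restrained target (the weakest-contact distance).
    """
    coords = structure.coords
    diff = coords[r.i] - coords[r.j]
    ds = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    if not all_pairs:
        return dscc(ds, r.d)
    n = r.n_beads
    iu, ju = np.triu_indices(n, k=1)
    full_target = np.full(len(iu), r.d.max())
    pos = {(a, b): v for a, b, v in zip(r.i, r.j, r.d)}
    for k, (a, b) in enumerate(zip(iu, ju)):
        if (a, b) in pos:
            full_target[k] = pos[(a, b)]
    full_ds = structure.pairwise_distances()
    return dscc(full_ds, full_target)


def select_representative(entries: list[EnsembleEntry]) -> EnsembleEntry:
    """Entry with maximal dSCC to the input; ties -> smaller alpha, then seed."""
    if not entries:
        raise ValueError("no ensemble entries")
    return min(entries, key=lambda e: (-e.dscc_to_input, e.alpha, e.seed))


def ensemble_consistency(entries: list[EnsembleEntry]) -> float:
    """Mean pairwise dSCC among the entries' full distance vectors."""
    if len(entries) < 2:
        raise ValueError("consistency needs at least 2 entries")
    scores = [
        structure_dscc(a.structure, b.structure)
        for a, b in combinations(entries, 2)
    ]
    return float(np.mean(scores))


def score_against_truth(entries, truths: list[Structure3D]) -> float:
    """Accuracy of an ensemble against a set of known true structures.

    Each reconstructed structure is compared (dSCC of full distance vectors)
    with every true structure; the reconstruction closest to any truth is
    selected and its best-match dSCC is the ensemble's accuracy.  Structures
    modeled on a subset of bins are compared on their own bins, via
    ``bin_map`` into the truth coordinates.
    """
    if not truths:
        raise ValueError("no true structures given")
    structures = [
        e.structure if isinstance(e, EnsembleEntry) else e for e in entries
    ]
    if not structures:
        raise ValueError("no ensemble structures given")
    best = -np.inf
    for s in structures:
        for t in truths:
            tc = t.coords
            if s.n_beads != t.n_beads:
                if s.bin_map.max() >= t.n_beads:
                    raise ValueError(
                        f"bead count mismatch: model covers bins up to "
                        f"{s.bin_map.max()} but truth has {t.n_beads} beads"
                    )
                tc = tc[s.bin_map]
            best = max(best, structure_dscc(s, Structure3D(tc)))
    return float(best)


def run_ensemble(
    cmap: ContactMap,
    alphas,
    n_structures: int = 5,
    cfg: OptimConfig | None = None,
    base_seed: int = 0,
    rescale: str = "max_to_one",
    score_all_pairs: bool = False,
    keep_traces: bool = False,
) -> EnsembleResult:
    """Sweep conversion factors, optimize replicate structures, pick the best.

    Replicate k at the a-th alpha uses seed ``base_seed + a*10000 + k``.
    Consistency is reported for the entries at the selected alpha when there
    are at least two of them.
    """
    alphas = list(alphas)
    if not alphas:
        raise ValueError("alphas must be non-empty")
    if any(a <= 0 for a in alphas):
        raise ValueError("every alpha must be > 0")
    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    cfg = cfg or OptimConfig()
    entries: list[EnsembleEntry] = []
    for a_idx, alpha in enumerate(alphas):
        r = build_restraints(cmap, alpha, rescale=rescale)
        for k in range(n_structures):
            seed = base_seed + a_idx * _ALPHA_SEED_STRIDE + k
            s, trace = optimize(r, cfg, seed=seed)
            s.bin_map = np.asarray(cmap.active_bins, dtype=int)
            entries.append(
                EnsembleEntry(
                    alpha=alpha,
                    seed=seed,
                    structure=s,
                    dscc_to_input=dscc_to_input(s, r, all_pairs=score_all_pairs),
                    final_L=log_likelihood(s, r),
                    iterations=trace.iterations,
                    trace=trace if keep_traces else None,
                )
            )
    rep = select_representative(entries)
    at_best = [e for e in entries if e.alpha == rep.alpha]
    consistency = ensemble_consistency(at_best) if len(at_best) >= 2 else None
    return EnsembleResult(
        entries=entries,
        representative=rep,
        selected_alpha=rep.alpha,
        consistency=consistency,
    )
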