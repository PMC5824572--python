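"""Scikit-learn style estimator wrapping the full reconstruction pipeline.

``HiCStructure`` plays the role sklearn's MDS plays for precomputed
dissimilarities: ``fit(X)`` takes a square contact matrix, runs empty-bin
filtering, optional normalization and pre-filtering, an ensemble sweep over
candidate conversion factors, and exposes the representative 3D model as
``embedding_``.  It composes with sklearn model selection and cloning.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils import check_array

from .contact_map import (
    ContactMap,
    filter_empty_bins,
    ice_normalize,
    prefilter_low_if,
    scn_normalize,
)
from .ensemble import EnsembleResult, run_ensemble
from .model import OptimConfig

__all__ = ["HiCStructure", "DEFAULT_ALPHA_GRID"]

# Default conversion-factor search grid: 0.1 .. 2.0 in steps of 0.1.
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 2.01, 0.1), 2))


class HiCStructure(BaseEstimator):
    """Maximum-likelihood 3D chromosome structure from a Hi-C contact matrix.

    Parameters
    ----------
    alpha : float or "auto", default="auto"
        Conversion factor for IF -> distance.  "auto" sweeps ``alphas`` and
        keeps the factor whose best structure correlates most with the input.
    alphas : sequence of float, optional
        Candidate grid for the sweep; defaults to 0.1..2.0 step 0.1.
    n_structures : int, default=5
        Replicate structures optimized per candidate alpha.
    optimizer : {"gradient_ascent", "adagrad"}, default="gradient_ascent"
        Plain gradient ascent, or AdaGrad per-coordinate steps (the variant
        intended for noisy input, usually with ``prefilter_quantile`` > 0).
    schedule : {"step_decay", "constant"}, default="step_decay"
        Learning-rate schedule for gradient ascent (step decay halves the
        rate every 70 epochs and is the faster-converging default).
    learning_rate : float, optional
        Base rate; None resolves to 0.01 (step decay / AdaGrad) or 0.0001
        (constant).
    epsilon : float, default=0.0001
        Convergence constant on the change in log-likelihood.
    adagrad_eps : float, default=1e-6
        AdaGrad smoothing term.
    max_iter : int, default=10000
        Iteration cap per optimization.
    normalize : {None, "ice", "scn"}, default=None
        Optional matrix balancing applied after empty-bin filtering.
    prefilter_quantile : float, default=0.0
        Zero IFs below this quantile of the positive entries before modeling.
    rescale_distances : {"max_to_one", "none"}, default="max_to_one"
        Whether target distances are rescaled to max 1.
    score_all_pairs : bool, default=False
        Score structures against all pairs instead of restrained pairs only.
    random_state : int, default=0
        Base seed; replicate k at the a-th alpha uses seed + a*10000 + k.

    Attributes
    ----------
    embedding_ : ndarray of shape (n_active_bins, 3)
        Coordinates of the representative structure.
    structure_ : Structure3D
        The representative structure with its bin mapping.
    alpha_ : float
        Selected conversion factor.
    dscc_ : float
        dSCC of the representative model against the input-derived distances.
    ensemble_ : EnsembleResult
        All entries of the sweep, with scores and traces.
    consistency_ : float or None
        Mean pairwise dSCC among replicates at the selected alpha.
    active_bins_ : ndarray
        Original bin indices retained after filtering.
    """

    def __init__(
        self,
        alpha="auto",
        alphas=None,
        n_structures: int = 5,
        optimizer: str = "gradient_ascent",
        schedule: str = "step_decay",
        learning_rate: float | None = None,
        epsilon: float = 0.0001,
        adagrad_eps: float = 1e-6,
        max_iter: int = 10000,
        normalize: str | None = None,
        prefilter_quantile: float = 0.0,
        rescale_distances: str = "max_to_one",
        score_all_pairs: bool = False,
        random_state: int = 0,
    ):
        self.alpha = alpha
        self.alphas = alphas
        self.n_structures = n_structures
        self.optimizer = optimizer
        self.schedule = schedule
        self.learning_rate = learning_rate
        self.epsilon = epsilon
        self.adagrad_eps = adagrad_eps
        self.max_iter = max_iter
        self.normalize = normalize
        self.prefilter_quantile = prefilter_quantile
        self.rescale_distances = rescale_distances
        self.score_all_pairs = score_all_pairs
        self.random_state = random_state

    def _as_contact_map(self, X) -> ContactMap:
        if isinstance(X, ContactMap):
            return X
        X = check_array(X, ensure_min_samples=2)
        if X.shape[0] != X.shape[1]:
            raise ValueError(
                f"contact matrix must be square, got shape {X.shape}"
            )
        return ContactMap((X + X.T) / 2.0)

    def _optim_config(self) -> OptimConfig:
        return OptimConfig(
            optimizer=self.optimizer,
            schedule=self.schedule,
            lr=self.learning_rate,
            epsilon_conv=self.epsilon,
            adagrad_eps=self.adagrad_eps,
            max_iters=self.max_iter,
        )

    def fit(self, X, y=None):
        """Reconstruct the representative 3D structure from contact matrix X."""
        cmap = filter_empty_bins(self._as_contact_map(X))
        if self.normalize == "ice":
            cmap = ice_normalize(cmap)
        elif self.normalize == "scn":
            cmap = scn_normalize(cmap)
        elif self.normalize is not None:
            raise ValueError(f"unknown normalize option {self.normalize!r}")
        if self.prefilter_quantile:
            cmap = prefilter_low_if(cmap, self.prefilter_quantile)
            cmap = filter_empty_bins(cmap)
        if self.alpha == "auto":
            alphas = list(self.alphas) if self.alphas is not None else list(
                DEFAULT_ALPHA_GRID
            )
        else:
            alphas = [float(self.alpha)]
        result: EnsembleResult = run_ensemble(
            cmap,
            alphas,
            n_structures=self.n_structures,
            cfg=self._optim_config(),
            base_seed=self.random_state,
            rescale=self.rescale_distances,
            score_all_pairs=self.score_all_pairs,
        )
        self.contact_map_ = cmap
        self.ensemble_ = result
        self.structure_ = result.representative.structure
        self.embedding_ = self.structure_.coords
        self.alpha_ = result.selected_alpha
        self.dscc_ = result.representative.dscc_to_input
        self.consistency_ = result.consistency
        self.active_bins_ = np.asarray(cmap.active_bins)
        self.n_features_in_ = np.asarray(X).shape[1] if not isinstance(
            X, ContactMap
        ) else X.n_bins
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the (n_active_bins, 3) coordinate embedding."""
        return self.fit(X).embedding_

    def score(self, X=None, y=None) -> float:
        """dSCC of the representative model against the input distances."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "dscc_")
        return self.dscc_
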