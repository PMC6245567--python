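"""PCA pre-processing and t-SNE embedding of provider compositions.

Composition profiles are first projected onto their top principal components
(50 by default) for computational efficiency, then embedded in 2-D with
t-SNE (perplexity 40, Barnes-Hut angle 0.5 by default).  Because the t-SNE
objective is non-convex, several restarts with distinct derived seeds are
run and the solution with the minimum final KL divergence is kept.  Exact
gradients are used below 2,000 points (the tree approximation only pays off
above that); the angle parameter applies to the Barnes-Hut regime.

Also provides the annotation layers used to read an embedding: 2-D density
histograms and per-provider claim-fraction color values clipped at a cap
(15% by default, the scale used for single-drug overlay panels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .containers import ClaimsMatrix, ProfileMatrix
from .errors import ValidationError


@dataclass
class EmbeddingConfig:
    """Hyperparameters for the PCA + t-SNE stage."""

    pca_dims: int = 50
    perplexity: float = 40.0
    theta: float = 0.5
    max_iters: int = 1000
    n_restarts: int = 5
    seed: int = 0
    exact_below: int = 2000  # use exact gradients for small n

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValidationError("theta must be in [0, 1]")
        if not 300 <= self.max_iters <= 1500:
            raise ValidationError("max_iters must be in [300, 1500]")
        if self.n_restarts < 1:
            raise ValidationError("n_restarts must be >= 1")
        if self.perplexity <= 0:
            raise ValidationError("perplexity must be > 0")

    def validate_for(self, n_points: int) -> None:
        bound = (n_points - 1) / 3.0
        if self.perplexity >= bound:
            raise ValidationError(
                f"perplexity {self.perplexity} infeasible for n={n_points}; "
                f"must be < (n-1)/3 = {bound:.2f}"
            )


@dataclass
class Embedding2D:
    """A selected 2-D embedding plus the per-restart costs."""

    providers: pd.Index
    coords: np.ndarray  # (n, 2)
    costs: list[float]  # final KL divergence per restart
    selected_run: int

    @property
    def cost(self) -> float:
        return self.costs[self.selected_run]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.coords[:, 0], "y": self.coords[:, 1]}, index=self.providers
        )


def pca_reduce(profile: ProfileMatrix | np.ndarray, k: int = 50) -> np.ndarray:
    """Project rows onto the top-k principal components of the centered data.

    If ``k`` exceeds the matrix rank (or min(n, d)), the available
    components are retained with a warning.
    """
    X = profile.values if isinstance(profile, ProfileMatrix) else np.asarray(profile, float)
    max_k = min(X.shape)
    if k > max_k:
        warnings.warn(
            f"k={k} exceeds min(n, d)={max_k}; retaining {max_k} components",
            UserWarning,
        )
        k = max_k
    pca = PCA(n_components=k, svd_solver="full")
    reduced = pca.fit_transform(X)
    # drop numerically-null trailing components beyond the rank
    return reduced


def tsne_embed(
    reduced: np.ndarray,
    config: EmbeddingConfig,
    providers: pd.Index | None = None,
) -> Embedding2D:
    """Embed PCA-reduced rows in 2-D, keeping the minimum-KL restart.

    Each restart uses a distinct seed derived from ``config.seed``; the same
    config therefore yields bit-identical coordinates.  Runs 300-1500
    gradient iterations per restart and returns the restart whose final KL
    divergence is smallest.
    """
    X = np.asarray(reduced, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise ValidationError("t-SNE needs at least 10 points")
    config.validate_for(n)
    if providers is None:
        providers = pd.Index(range(n))

    method = "exact" if n < config.exact_below else "barnes_hut"
    child_seeds = np.random.SeedSequence(config.seed).generate_state(config.n_restarts)
    coords_per_run = []
    costs: list[float] = []
    for run in range(config.n_restarts):
        ts = TSNE(
            n_components=2,
            perplexity=config.perplexity,
            angle=config.theta,
            max_iter=config.max_iters,
            method=method,
            init="random",
            random_state=int(child_seeds[run] % (2**31)),
        )
        coords_per_run.append(ts.fit_transform(X))
        costs.append(float(ts.kl_divergence_))
    selected = int(np.argmin(costs))
    return Embedding2D(
        providers=pd.Index(providers),
        coords=coords_per_run[selected],
        costs=costs,
        selected_run=selected,
    )


def density_map(
    embedding: Embedding2D,
    bins: int | tuple[int, int] = 50,
    subset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of embedded providers; counts sum to the subset size.

    ``subset`` is a boolean mask over providers (None = all).  Bin edges are
    computed on the full embedding so subset maps are comparable panels.
    """
    if isinstance(bins, int):
        if bins < 2:
            raise ValidationError("need >= 2 bins per axis")
    else:
        if min(bins) < 2:
            raise ValidationError("need >= 2 bins per axis")
    x, y = embedding.coords[:, 0], embedding.coords[:, 1]
    xedges = np.histogram_bin_edges(x, bins=bins if isinstance(bins, int) else bins[0])
    yedges = np.histogram_bin_edges(y, bins=bins if isinstance(bins, int) else bins[1])
    if subset is not None:
        subset = np.asarray(subset, dtype=bool)
        if not subset.any():
            warnings.warn("empty subset: density map is all zero", UserWarning)
        x, y = x[subset], y[subset]
    hist, _, _ = np.histogram2d(x, y, bins=[xedges, yedges])
    return hist, xedges, yedges


def annotate_fraction(
    matrix: ClaimsMatrix,
    feature,
    class_map: pd.Series | None = None,
    cap: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percent of each provider's claims going to one drug (or class).

    Returns ``(values, zero_total_flag)``: values are
    ``100 * feature claims / total claims`` clipped at ``cap`` (the overlay
    color scale saturates, by default at 15%); providers with zero total get
    value 0 and a True flag.

    ``feature`` is a (drug_name, generic_name) pair, or a class label when
    ``class_map`` is given.
    """
    totals = matrix.row_totals().astype(float)
    if class_map is not None and feature in set(class_map.to_numpy()):
        cols = np.flatnonzero(class_map.reindex(matrix.drugs).to_numpy() == feature)
    else:
        try:
            cols = np.array([matrix.drugs.get_loc(feature)])
        except KeyError as exc:
            raise ValidationError(f"feature {feature!r} not found in matrix") from exc
    feat = np.asarray(matrix.counts[:, cols].sum(axis=1)).ravel().astype(float)
    zero_flag = totals == 0
    vals = np.zeros_like(totals)
    nz = ~zero_flag
    vals[nz] = np.minimum(100.0 * feat[nz] / totals[nz], cap)
    return vals, zero_flag
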