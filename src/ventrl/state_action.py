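"""Discretization of patient physiology into states and ventilator
settings into actions.

States: k-means clustering of the z-scored patient fingerprint (default
k = 650), with two absorbing terminal states (survival, death) appended
after the physiologic states.  BIC/AIC model selection over candidate k
is available for choosing the cluster count.

Actions: a 3-dimensional grid of 7 treatment levels each — ideal body
weight-adjusted tidal volume (mL/kg), PEEP (cmH2O), and FiO2 (%) —
yielding 343 discrete actions.  Bins are half-open [lower, upper), the
last bin open-ended; extra dimensions may be appended with user-supplied
edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "StateModel",
    "ActionGrid",
    "fit_state_model",
    "select_k",
    "assign_state",
]


@dataclass(frozen=True)
class StateModel:
    """Fitted patient-state discretization.

    ``centroids`` live in z-scored feature space; ``mean``/``scale`` hold
    the frozen training-split scaler.  Total state count is k + 2: the
    survival and death terminal states are indices k and k + 1.
    """

    centroids: np.ndarray  # (k, d)
    mean: np.ndarray  # (d,)
    scale: np.ndarray  # (d,)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if np.any(self.scale <= 0):
            raise ValueError("scaler scale must be positive")

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def n_states(self) -> int:
        return self.k + 2

    @property
    def survival_state(self) -> int:
        return self.k

    @property
    def death_state(self) -> int:
        return self.k + 1

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.scale


def fit_state_model(
    rows: np.ndarray, k: int, seed: int = 0, n_init: int = 3
) -> StateModel:
    """Fit the state discretization on training feature rows.

    Features are z-scored on the training split only; k-means is run with
    ``n_init`` restarts from the given seed, so results are deterministic
    given the seed.
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    n_distinct = len(np.unique(rows, axis=0))
    if n_distinct < k:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows available")
    mean = rows.mean(axis=0)
    scale = rows.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    z = (rows - mean) / scale
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    km.fit(z)
    return StateModel(centroids=km.cluster_centers_, mean=mean, scale=scale)


def _kmeans_information_criteria(z: np.ndarray, centroids: np.ndarray, labels: np.ndarray):
    """BIC and AIC of a k-means solution under a spherical-Gaussian mixture
    with shared variance and free mixing proportions.

    The log-likelihood combines the cluster-size multinomial term
    sum_j n_j log(n_j / n) with the Gaussian fit term; parameters are the
    k*d centroid coordinates, k - 1 proportions, and the variance.
    """
    n, d = z.shape
    k = centroids.shape[0]
    resid = z - centroids[labels]
    wcss = float(np.sum(resid**2))
    sigma2 = max(wcss / (d * max(n - k, 1)), 1e-12)
    n_j = np.bincount(labels, minlength=k).astype(float)
    n_j = n_j[n_j > 0]
    loglik = (
        float(np.sum(n_j * np.log(n_j / n)))
        - 0.5 * n * d * np.log(2 * np.pi * sigma2)
        - 0.5 * d * (n - k)
    )
    n_params = k * d + (k - 1) + 1
    bic = -2 * loglik + n_params * np.log(n)
    aic = -2 * loglik + 2 * n_params
    return bic, aic


def select_k(
    rows: np.ndarray, candidates: list[int], seed: int = 0, n_init: int = 3
) -> tuple[int, dict[int, dict[str, float]]]:
    """Choose the cluster count by BIC (AIC reported alongside).

    Returns the BIC-minimizing k and the per-candidate criterion table
    with within-cluster sum of squares.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    rows = np.asarray(rows, dtype=float)
    mean = rows.mean(axis=0)
    scale = rows.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    z = (rows - mean) / scale
    table: dict[int, dict[str, float]] = {}
    for k in sorted(candidates):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(z)
        bic, aic = _kmeans_information_criteria(z, km.cluster_centers_, km.labels_)
        table[k] = {"bic": bic, "aic": aic, "wcss": float(km.inertia_)}
    best = min(table, key=lambda k: table[k]["bic"])
    return best, table


def assign_state(model: StateModel, x: np.ndarray) -> int | np.ndarray:
    """Nearest-centroid state assignment in scaled space.

    Ties break to the lowest centroid index.  Accepts a single feature
    vector or a matrix of rows.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature values")
    single = x.ndim == 1
    z = model.transform(np.atleast_2d(x))
    # squared distances via the expansion ||z||^2 - 2 z.c + ||c||^2
    d2 = (
        np.sum(z**2, axis=1, keepdims=True)
        - 2 * z @ model.centroids.T
        + np.sum(model.centroids**2, axis=1)
    )
    ids = np.argmin(d2, axis=1)
    return int(ids[0]) if single else ids


# ---------------------------------------------------------------------------
# action grid

DEFAULT_EDGES = {
    "vt_ml_per_kg": (0.0, 2.5, 5.0, 7.5, 10.0, 12.5, 15.0),
    "peep_cmh2o": (0.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0),
    "fio2_pct": (0.0, 30.0, 35.0, 40.0, 45.0, 50.0, 55.0),
}

COARSE_EDGES = {
    "vt_ml_per_kg": (0.0, 7.5),
    "peep_cmh2o": (0.0, 7.0),
    "fio2_pct": (0.0, 40.0),
}


@dataclass(frozen=True)
class ActionGrid:
    """Per-dimension lower bin edges defining the discrete action space.

    Each dimension's bins are half-open [edge_i, edge_{i+1}), the last
    bin open-ended, so the bins partition [0, inf).  The flat index is
    row-major over (vt, peep, fio2, *extras) and bijective with the bin
    tuple.
    """

    edges: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EDGES)
    )

    def __post_init__(self) -> None:
        for dim, e in self.edges.items():
            if len(e) < 1 or any(b <= a for a, b in zip(e, e[1:])):
                raise ValueError(f"edges for {dim} must be strictly increasing")
            if e[0] != 0.0:
                raise ValueError(f"first edge for {dim} must be 0 (bins cover [0, inf))")

    @classmethod
    def default(cls) -> "ActionGrid":
        return cls(dict(DEFAULT_EDGES))

    @classmethod
    def coarse(cls) -> "ActionGrid":
        """Reduced 2x2x2 grid (8 actions), used for small-scale studies."""
        return cls(dict(COARSE_EDGES))

    @property
    def dims(self) -> list[str]:
        return list(self.edges)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(len(e) for e in self.edges.values())

    @property
    def n_actions(self) -> int:
        return int(np.prod(self.shape))

    def bin_of(self, dim: str, value: float) -> int:
        """Bin index of a non-negative value along one dimension."""
        if not np.isfinite(value) or value < 0:
            raise ValueError(f"{dim} value must be finite and non-negative, got {value}")
        e = self.edges[dim]
        return int(np.searchsorted(e, value, side="right") - 1)

    def flatten(self, bins: tuple[int, ...]) -> int:
        return int(np.ravel_multi_index(bins, self.shape))

    def unflatten(self, action: int) -> tuple[int, ...]:
        return tuple(int(i) for i in np.unravel_index(action, self.shape))

    def bin_range(self, dim: str, bin_idx: int) -> tuple[float, float]:
        e = self.edges[dim]
        upper = e[bin_idx + 1] if bin_idx + 1 < len(e) else np.inf
        return (e[bin_idx], upper)

    def with_extra_dimension(self, name: str, edges: tuple[float, ...]) -> "ActionGrid":
        new = dict(self.edges)
        if name in new:
            raise ValueError(f"dimension {name!r} already present")
        new[name] = tuple(edges)
        return ActionGrid(new)

    # -- encoding -----------------------------------------------------------

    def encode(self, vt_per_kg: float, peep: float, fio2: float, *extras: float) -> int:
        """Flat action index of a setting triple (plus any extra dims)."""
        values = (vt_per_kg, peep, fio2) + extras
        if len(values) != len(self.edges):
            raise ValueError(f"expected {len(self.edges)} values, got {len(values)}")
        bins = tuple(self.bin_of(d, v) for d, v in zip(self.edges, values))
        return self.flatten(bins)

    def decode(self, action: int) -> dict[str, tuple[float, float]]:
        """Per-dimension [lower, upper) ranges of a flat action index."""
        bins = self.unflatten(action)
        return {d: self.bin_range(d, b) for d, b in zip(self.edges, bins)}

    def all_actions(self) -> list[tuple[int, ...]]:
        return list(product(*(range(n) for n in self.shape)))


def encode_action(
    vt_set_ml: float, ibw_kg: float, peep: float, fio2: float,
    grid: ActionGrid | None = None,
) -> int:
    """Flat action index from raw ventilator settings.

    Tidal volume is normalized to mL per kg of ideal body weight before
    binning.
    """
    if ibw_kg <= 0:
        raise ValueError("ideal body weight must be positive")
    if vt_set_ml < 0 or peep < 0 or fio2 < 0:
        raise ValueError("ventilator settings must be non-negative")
    grid = grid or ActionGrid.default()
    return grid.encode(vt_set_ml / ibw_kg, peep, fio2)


def decode_action(action: int, grid: ActionGrid | None = None) -> dict[str, tuple[float, float]]:
    grid = grid or ActionGrid.default()
    return grid.decode(action)
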