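"""Consensus k-means clustering with PAC-based k selection.

The number of phenogroups is chosen by subsampled consensus clustering:
for each candidate k the cohort is repeatedly subsampled, k-means is run on
each subsample, and the consensus matrix entry (i, j) is the fraction of
co-samplings in which i and j fell in the same cluster. A stable k makes
consensus entries bimodal at 0/1; the proportion of ambiguous clustering
(PAC) — the CDF mass of off-diagonal entries in (0.1, 0.9) — quantifies the
residual ambiguity.

k selection: a candidate k is *admissible* when PAC(k) <= 0.2 (at least
80% of pair-consensus mass is unambiguous). Among admissible ks, the
largest whose PAC lies within PAC_MARGIN of the best admissible PAC is
chosen — the finest clearly stable partition. A bare PAC minimum
systematically prefers coarse merges when cluster sizes are unequal
(merging the two smallest clusters is itself highly reproducible), whereas
splitting a real cluster beyond the true k sends PAC sharply up, so the
admissibility rule recovers the true k where the minimum rule stalls at
k=2; the margin keeps a marginally-stable over-split from outranking a
clearly stable true k. If no k is admissible (structureless data) the PAC
minimum is reported with ties to the smaller k, and the empty admissible
set flags the absence of stable structure.

The final partition is a full-cohort k-means at the chosen k, with groups
renumbered 1..k by descending size so that "phenogroup 1" is always the
largest group, and centroids retained for out-of-sample assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import feature_set_hash
from .matrix import ProteinMatrix

PAC_LOWER, PAC_UPPER = 0.1, 0.9
#: PAC at or below this marks a k as admissible (stable) for k selection.
PAC_STABLE_THRESHOLD = 0.2
#: A stable k is chosen only if its PAC is within this margin of the best
#: PAC, so a marginally-stable over-split cannot beat a clearly-stable k.
PAC_MARGIN = 0.1


class ClusterError(ValueError):
    pass


@dataclass
class PhenogroupAssignment:
    """Sample -> phenogroup mapping (1-based labels) with provenance."""

    labels: pd.Series  # sample_id -> int in 1..k
    k: int
    provenance: dict = field(default_factory=dict)

    def to_zero_based(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int) - 1

    def group_sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class ConsensusResult:
    """Per-k consensus statistics plus the final partition.

    ``consensus_matrices[k]`` holds NaN for pairs never co-sampled; such
    pairs are excluded from the CDF/PAC computation.
    """

    k_values: list[int]
    consensus_matrices: dict[int, np.ndarray]
    cdf_grids: dict[int, tuple[np.ndarray, np.ndarray]]  # (grid, CDF values)
    pac: dict[int, float]
    delta_area: dict[int, float]
    stable_ks: list[int]
    chosen_k: int
    final_labels: PhenogroupAssignment
    centroids: pd.DataFrame  # k x p, standardized units, index 1..k
    params: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Per-k table of PAC and CDF-area increments, with the chosen k."""
        df = pd.DataFrame(
            {
                "k": self.k_values,
                "pac": [self.pac[k] for k in self.k_values],
                "delta_area": [self.delta_area[k] for k in self.k_values],
            }
        )
        df["stable"] = df["k"].isin(self.stable_ks)
        df["chosen"] = df["k"] == self.chosen_k
        return df


def _values(matrix: ProteinMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ProteinMatrix) else matrix


def _relabel_by_size(labels0: np.ndarray, centers: np.ndarray):
    """Renumber clusters 1..k by descending size (stable tie-break)."""
    uniq, counts = np.unique(labels0, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    old_to_new = {int(uniq[i]): rank + 1 for rank, i in enumerate(order)}
    new_labels = np.array([old_to_new[int(l)] for l in labels0])
    new_centers = centers[[uniq[i] for i in order]]
    return new_labels, new_centers


def final_kmeans(
    matrix: ProteinMatrix | pd.DataFrame,
    k: int,
    seed: int,
    n_init: int = 50,
) -> tuple[PhenogroupAssignment, pd.DataFrame]:
    """Full-cohort k-means (k-means++ init, ``n_init`` restarts, best WCSS).

    Groups are renumbered by descending size; centroids are returned in
    standardized feature units with the same 1..k index.
    """
    if k < 2:
        raise ClusterError(f"k must be >= 2, got {k}")
    vals = _values(matrix)
    if k > len(vals):
        raise ClusterError("k exceeds the number of samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels0 = km.fit_predict(vals.to_numpy())
    if len(np.unique(labels0)) < k:
        raise ClusterError("k-means converged with an empty cluster")
    labels1, centers = _relabel_by_size(labels0, km.cluster_centers_)
    assignment = PhenogroupAssignment(
        labels=pd.Series(labels1, index=vals.index, name="phenogroup"),
        k=k,
        provenance={
            "method": "kmeans",
            "seed": seed,
            "n_init": n_init,
            "inertia": float(km.inertia_),
            "feature_set_hash": feature_set_hash(list(vals.columns)),
        },
    )
    centroids = pd.DataFrame(
        centers, index=pd.RangeIndex(1, k + 1, name="phenogroup"),
        columns=vals.columns,
    )
    return assignment, centroids


def _consensus_for_k(
    x: np.ndarray, k: int, n_resamples: int, m: int, rng: np.random.Generator,
    inner_n_init: int = 10,
) -> np.ndarray:
    n = x.shape[0]
    co_cluster = np.zeros((n, n), dtype=np.float64)
    co_sample = np.zeros((n, n), dtype=np.float64)
    for _ in range(n_resamples):
        idx = rng.choice(n, size=m, replace=False)
        km = KMeans(
            n_clusters=k, n_init=inner_n_init,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lab = km.fit_predict(x[idx])
        co_sample[np.ix_(idx, idx)] += 1.0
        for c in np.unique(lab):
            mem = idx[lab == c]
            co_cluster[np.ix_(mem, mem)] += 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = co_cluster / co_sample
    return consensus


def consensus_cluster(
    matrix: ProteinMatrix | pd.DataFrame,
    k_range: tuple[int, int] = (2, 8),
    n_resamples: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    n_init: int = 50,
    inner_n_init: int = 10,
    pac_threshold: float = PAC_STABLE_THRESHOLD,
) -> ConsensusResult:
    """Run subsampled consensus clustering over ``k_range`` (inclusive).

    For each k, ``n_resamples`` subsamples of ``ceil(fraction * n)``
    samples are clustered by k-means; PAC(k) = F(0.9) - F(0.1) of the
    off-diagonal consensus CDF over co-sampled pairs. chosen_k is the
    largest k that is stable (PAC <= ``pac_threshold``) and whose PAC is
    within :data:`PAC_MARGIN` of the best stable PAC — the finest clearly
    stable partition; if no k is stable, the PAC minimum with ties to the
    smaller k. The final partition is ``final_kmeans`` at chosen_k. Fully
    reproducible for a fixed seed.
    """
    vals = _values(matrix)
    n = len(vals)
    k_lo, k_hi = k_range
    if k_lo < 2 or k_hi < k_lo:
        raise ClusterError(f"invalid k_range {k_range}")
    if k_hi > n // 3:
        raise ClusterError(f"k_range upper bound {k_hi} exceeds n/3 = {n // 3}")
    if not (0 < subsample_fraction < 1):
        raise ClusterError("subsample_fraction must be in (0, 1)")
    m = int(np.ceil(subsample_fraction * n))
    x = vals.to_numpy()
    k_values = list(range(k_lo, k_hi + 1))
    rng = np.random.default_rng(seed)

    consensus_matrices: dict[int, np.ndarray] = {}
    pac: dict[int, float] = {}
    cdf_grids: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    areas: dict[int, float] = {}
    triu = np.triu_indices(n, k=1)
    for k in k_values:
        cons = _consensus_for_k(x, k, n_resamples, m, rng, inner_n_init)
        consensus_matrices[k] = cons
        entries = cons[triu]
        missing = np.isnan(entries)
        if missing.mean() > 0.01:
            warnings.warn(
                f"k={k}: {missing.mean():.1%} of pairs never co-sampled",
                stacklevel=2,
            )
        ent = np.sort(entries[~missing])
        grid = np.linspace(0.0, 1.0, 101)
        cdf = np.searchsorted(ent, grid, side="right") / len(ent)
        cdf_grids[k] = (grid, cdf)
        f = lambda t: np.searchsorted(ent, t, side="right") / len(ent)
        pac[k] = float(f(PAC_UPPER) - f(PAC_LOWER))
        areas[k] = float(np.trapezoid(cdf, grid))

    delta_area: dict[int, float] = {}
    for i, k in enumerate(k_values):
        if i == 0:
            delta_area[k] = areas[k]
        else:
            prev = areas[k_values[i - 1]]
            delta_area[k] = (areas[k] - prev) / prev if prev > 0 else 0.0

    stable_ks = [k for k in k_values if pac[k] <= pac_threshold]
    if stable_ks:
        best_pac = min(pac[k] for k in stable_ks)
        chosen_k = max(k for k in stable_ks if pac[k] <= best_pac + PAC_MARGIN)
    else:
        chosen_k = min(k_values, key=lambda k: (pac[k], k))
    final_labels, centroids = final_kmeans(vals, chosen_k, seed=seed, n_init=n_init)
    final_labels.provenance.update(
        {
            "method": "consensus_kmeans",
            "n_resamples": n_resamples,
            "subsample_fraction": subsample_fraction,
            "consensus_seed": seed,
        }
    )
    return ConsensusResult(
        k_values=k_values,
        consensus_matrices=consensus_matrices,
        cdf_grids=cdf_grids,
        pac=pac,
        delta_area=delta_area,
        stable_ks=stable_ks,
        chosen_k=chosen_k,
        final_labels=final_labels,
        centroids=centroids,
        params={
            "n_resamples": n_resamples,
            "subsample_fraction": subsample_fraction,
            "inner_algorithm": "kmeans",
            "inner_n_init": inner_n_init,
            "pac_threshold": pac_threshold,
            "seed": seed,
            "k_range": [k_lo, k_hi],
        },
    )


class ConsensusClusterModel:
    """Model-style wrapper: configure on construction, ``fit(seed)`` to run.

    Mirrors the fit/results idiom of statistical modelling libraries: the
    model holds the data and settings, ``fit`` returns a
    :class:`ConsensusResult` with a ``summary()`` table.
    """

    def __init__(
        self,
        matrix: ProteinMatrix | pd.DataFrame,
        k_range: tuple[int, int] = (2, 8),
        n_resamples: int = 1000,
        subsample_fraction: float = 0.8,
        n_init: int = 50,
    ):
        self.matrix = matrix
        self.k_range = k_range
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.n_init = n_init

    def fit(self, seed: int = 0) -> ConsensusResult:
        return consensus_cluster(
            self.matrix,
            k_range=self.k_range,
            n_resamples=self.n_resamples,
            subsample_fraction=self.subsample_fraction,
            seed=seed,
            n_init=self.n_init,
        )


def assign_by_centroid(
    matrix: ProteinMatrix | pd.DataFrame, centroids: pd.DataFrame
) -> PhenogroupAssignment:
    """Assign samples (on the frozen training scale) to nearest centroids.

    Euclidean distance; ties break toward the lower group index. The
    feature sets must match exactly and in order.
    """
    vals = _values(matrix)
    if list(vals.columns) != list(centroids.columns):
        missing = set(centroids.columns) - set(vals.columns)
        extra = set(vals.columns) - set(centroids.columns)
        raise ClusterError(
            f"feature mismatch: missing {sorted(missing)[:5]}, "
            f"extra {sorted(extra)[:5]}"
            if missing or extra
            else "feature order mismatch"
        )
    x = vals.to_numpy()
    c = centroids.to_numpy()
    d2 = ((x[:, None, :] - c[None, :, :]) ** 2).sum(axis=2)
    labels = centroids.index.to_numpy()[np.argmin(d2, axis=1)]
    return PhenogroupAssignment(
        labels=pd.Series(labels, index=vals.index, name="phenogroup"),
        k=len(centroids),
        provenance={
            "method": "nearest_centroid",
            "feature_set_hash": feature_set_hash(list(vals.columns)),
        },
    )
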