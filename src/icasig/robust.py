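"""Stability-filtered ICA signatures for a single component number.

ICA is run many times with different random initialisations; the pooled
components are clustered (average linkage on 1 - |Pearson|) into as many
clusters as components requested, and each cluster is scored with the
Icasso stability index

    I(M) = (1/|M|^2) * sum_{i,j in M} s_ij
         - (1/(|M| |M'|)) * sum_{i in M, j in M'} s_ij

where s_ij is the absolute Pearson correlation between component loading
vectors and M' is the complement of cluster M.  The intra-cluster double
sum is unrestricted, so the i = j diagonal terms (s_ii = 1) are included;
a singleton cluster therefore scores 1 minus its mean external similarity.
The index is at most 1 (1 for a perfect cluster) and can be negative for
clusters less coherent than their surroundings.  Clusters whose index
exceeds a threshold (default 0.75) are kept, each represented by its
medoid — the member with the greatest total similarity to the cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import skew
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from icasig.io import ExpressionMatrix

_SEED_MOD = 2**31


class IcaRunFailed(RuntimeError):
    """Raised when FastICA fails to converge after all retries."""


@dataclass(frozen=True)
class ComponentSet:
    """One ICA run: loadings S (genes x n) and mixing A (n x samples).

    The gene-wise centered matrix satisfies ``Xc ~= S @ A + offset`` where
    ``offset`` is the rank-one sample-mean shift removed during whitening;
    ``residual`` records the relative Frobenius reconstruction error.
    Loading columns are scaled to unit variance (the compensating scale is
    folded into the mixing rows).
    """

    n_components: int
    loadings: np.ndarray
    mixing: np.ndarray
    run_seed: int
    residual: float
    converged: bool = True


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric matrix of absolute Pearson correlations between components."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class SignatureCluster:
    """A cluster of pooled components at one parameter value."""

    member_indices: tuple[int, ...]
    parameter_n: int
    medoid_index: int | None = None
    stability: float | None = None


@dataclass(frozen=True)
class RobustSignature:
    """A stability-passing cluster's medoid signature at one parameter value."""

    parameter_n: int
    gene_loadings: np.ndarray
    sample_scores: np.ndarray
    stability: float
    cluster_size: int
    medoid_seed: int


def run_ica_once(
    X: ExpressionMatrix,
    n: int,
    seed: int,
    max_iter: int = 200,
    tol: float = 1e-4,
    max_retries: int = 3,
    nonconvergence: str = "accept",
) -> ComponentSet:
    """One FastICA decomposition of the gene-wise centered matrix.

    Deterministic given ``seed``.  When the fixed-point iteration hits
    ``max_iter`` without reaching ``tol`` the result is, by default, still
    returned with ``converged=False``: above the data's effective source
    count the near-Gaussian directions are rotation-unidentifiable, so the
    iteration cannot settle for *any* seed, and it is exactly the stability
    filter's job to discard the wandering components.  With
    ``nonconvergence='strict'`` such runs are instead retried with derived
    seeds and raise :class:`IcaRunFailed` after ``max_retries`` retries.
    Hard numerical failures always follow the retry-then-fail path.
    """
    if not 2 <= n < min(X.n_genes, X.n_samples):
        raise ValueError(
            f"n must satisfy 2 <= n < min(genes, samples) = "
            f"{min(X.n_genes, X.n_samples)}, got {n}"
        )
    if nonconvergence not in ("accept", "strict"):
        raise ValueError(f"unknown nonconvergence policy {nonconvergence!r}")
    centered = X.values - X.values.mean(axis=1, keepdims=True)
    last_exc: Exception | None = None
    for attempt in range(max_retries + 1):
        attempt_seed = (seed + 40009 * attempt) % _SEED_MOD
        ica = FastICA(
            n_components=n,
            random_state=attempt_seed,
            whiten="unit-variance",
            max_iter=max_iter,
            tol=tol,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            try:
                sources = ica.fit_transform(centered)
            except (ValueError, np.linalg.LinAlgError) as exc:
                last_exc = exc
                continue
        converged = not any(
            issubclass(w.category, ConvergenceWarning) for w in caught
        )
        if not converged and nonconvergence == "strict":
            last_exc = IcaRunFailed(f"no convergence within {max_iter} iterations")
            continue
        loadings = sources  # genes x n
        mixing = ica.mixing_.T  # n x samples
        # scale loading columns to unit variance, compensate in mixing
        scale = loadings.std(axis=0)
        scale[scale == 0] = 1.0
        loadings = loadings / scale
        mixing = mixing * scale[:, None]
        effective = centered - ica.mean_[None, :]
        denom = np.linalg.norm(effective)
        residual = (
            float(np.linalg.norm(effective - loadings @ mixing) / denom)
            if denom > 0
            else 0.0
        )
        return ComponentSet(
            n_components=n,
            loadings=loadings,
            mixing=mixing,
            run_seed=seed,
            residual=residual,
            converged=converged,
        )
    raise IcaRunFailed(
        f"FastICA failed for n={n}, seed={seed} after "
        f"{max_retries + 1} attempts: {last_exc}"
    )


def sign_correct(C: ComponentSet) -> ComponentSet:
    """Orient each component so its loading distribution has positive skew.

    Components are sign-indeterminate; orienting by skewness (the convention
    of the robust-ICA literature) makes repeated runs comparable.  When the
    skewness is numerically zero the component is oriented so its
    largest-absolute loading is positive.  Mixing rows are flipped
    consistently, leaving the product S @ A unchanged.  Idempotent.
    """
    loadings = C.loadings.copy()
    mixing = C.mixing.copy()
    sk = skew(loadings, axis=0)
    for j in range(loadings.shape[1]):
        if abs(sk[j]) < 1e-8:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        else:
            flip = sk[j] < 0
        if flip:
            loadings[:, j] *= -1
            mixing[j, :] *= -1
    return ComponentSet(
        n_components=C.n_components,
        loadings=loadings,
        mixing=mixing,
        run_seed=C.run_seed,
        residual=C.residual,
        converged=C.converged,
    )


def similarity_matrix(components: np.ndarray) -> SimilarityMatrix:
    """Absolute Pearson correlation between component loading vectors.

    ``components`` is a genes x m array with one component per column (a
    list of loading vectors is accepted and stacked).
    """
    comps = np.column_stack(components) if isinstance(components, (list, tuple)) else np.asarray(components, dtype=float)
    if comps.ndim != 2 or comps.shape[1] < 2:
        raise ValueError("need at least 2 component vectors")
    stds = comps.std(axis=0)
    if np.any(stds == 0):
        raise ValueError(
            f"component {int(np.argmax(stds == 0))} is constant; "
            "Pearson correlation undefined"
        )
    sigma = np.abs(np.corrcoef(comps, rowvar=False))
    sigma = np.clip((sigma + sigma.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(sigma, 1.0)
    return SimilarityMatrix(values=sigma)


def cluster_components(
    sim: SimilarityMatrix,
    n_clusters: int,
    parameter_n: int | None = None,
    method: str = "average",
) -> list[SignatureCluster]:
    """Agglomerative clustering on 1 - similarity, cut to ``n_clusters``."""
    m = len(sim)
    if not 1 <= n_clusters <= m:
        raise ValueError(f"n_clusters must be in [1, {m}]")
    if parameter_n is None:
        parameter_n = n_clusters
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    labels = fcluster(linkage(condensed, method=method), t=n_clusters, criterion="maxclust")
    clusters = []
    for lab in np.unique(labels):
        members = tuple(int(i) for i in np.nonzero(labels == lab)[0])
        clusters.append(SignatureCluster(member_indices=members, parameter_n=parameter_n))
    return clusters


def medoid_of(cluster, sim: SimilarityMatrix) -> int:
    """Member maximizing total similarity to the cluster; ties -> lowest index."""
    members = sorted(cluster)
    if not members:
        raise ValueError("cluster is empty")
    sums = sim.values[np.ix_(members, members)].sum(axis=1)
    return members[int(np.argmax(sums))]  # argmax takes first max -> lowest index


def stability_index(cluster, sim: SimilarityMatrix) -> float:
    """Icasso stability index: mean intra-similarity minus mean extra-similarity.

    The intra term averages the full |M| x |M| block including the diagonal;
    the extra term averages similarities from the cluster to its complement
    (0 when the complement is empty).
    """
    members = np.asarray(sorted(cluster), dtype=int)
    if members.size == 0:
        raise ValueError("cluster is empty")
    m = len(sim)
    mask = np.zeros(m, dtype=bool)
    mask[members] = True
    outside = np.nonzero(~mask)[0]
    intra = sim.values[np.ix_(members, members)].sum() / members.size**2
    if outside.size == 0:
        return float(intra)
    extra = sim.values[np.ix_(members, outside)].sum() / (members.size * outside.size)
    return float(intra - extra)


def _pooled_runs(X, n, runs, base_seed, jobs):
    seeds = [(base_seed + i) % _SEED_MOD for i in range(runs)]

    def one(seed):
        try:
            return sign_correct(run_ica_once(X, n, seed))
        except IcaRunFailed:
            return None

    if jobs == 1:
        results = [one(s) for s in seeds]
    else:
        results = Parallel(n_jobs=jobs)(delayed(one)(s) for s in seeds)
    ok = [r for r in results if r is not None]
    return ok, runs - len(ok)


def robust_signatures_for_n(
    X: ExpressionMatrix,
    n: int,
    runs: int = 100,
    threshold: float = 0.75,
    base_seed: int = 0,
    jobs: int = 1,
    linkage_method: str = "average",
) -> list[RobustSignature]:
    """Run ICA ``runs`` times at component number ``n`` and keep stable medoids.

    Per-run seeds are ``base_seed .. base_seed + runs - 1`` so the whole
    procedure is reproducible from one master seed and independent of the
    number of parallel workers.  Components from all converged runs are
    pooled, clustered into ``n`` clusters, and clusters with stability index
    strictly above ``threshold`` are returned as medoid signatures (the
    medoid's loading column and its run's corresponding mixing row).
    """
    component_sets, n_failed = _pooled_runs(X, n, runs, base_seed, jobs)
    if not component_sets:
        raise IcaRunFailed(f"all {runs} ICA runs failed for n={n}")
    if n_failed:
        warnings.warn(
            f"{n_failed}/{runs} ICA runs failed to converge for n={n} and were dropped"
        )
    pooled = np.column_stack([cs.loadings for cs in component_sets])
    origin = [
        (ri, ci)
        for ri, cs in enumerate(component_sets)
        for ci in range(cs.loadings.shape[1])
    ]
    sim = similarity_matrix(pooled)
    clusters = cluster_components(
        sim, n_clusters=min(n, len(sim)), parameter_n=n, method=linkage_method
    )
    signatures = []
    for cl in clusters:
        cl.medoid_index = medoid_of(cl.member_indices, sim)
        cl.stability = stability_index(cl.member_indices, sim)
        if cl.stability > threshold:
            run_idx, col_idx = origin[cl.medoid_index]
            cs = component_sets[run_idx]
            signatures.append(
                RobustSignature(
                    parameter_n=n,
                    gene_loadings=cs.loadings[:, col_idx].copy(),
                    sample_scores=cs.mixing[col_idx, :].copy(),
                    stability=float(cl.stability),
                    cluster_size=len(cl.member_indices),
                    medoid_seed=cs.run_seed,
                )
            )
    if not signatures:
        warnings.warn(f"no cluster passed stability threshold {threshold} at n={n}")
    return signatures
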