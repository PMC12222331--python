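"""Nominating the near-optimal range of ICA component numbers from PCA.

Rather than fixing a single component number, the pipeline tests a range of
consecutive values starting at the elbow of the PCA scree (or the knee of
the cumulative-variance curve), located with the Kneedle algorithm
(Satopaa et al. 2011): min-max normalize the curve, orient it concave
increasing, and take the maximum of the difference to the diagonal chord.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from icasig.io import ExpressionMatrix

#: sentinel returned by :func:`kneedle_point` when the curve has no knee
NO_KNEE = None


@dataclass(frozen=True)
class PCASummary:
    """Standard deviations and cumulative variance proportions by PC rank."""

    stdevs: np.ndarray
    cum_var_prop: np.ndarray
    n_components: int
    n_genes: int
    n_samples: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "stdevs", np.asarray(self.stdevs, dtype=float))
        object.__setattr__(
            self, "cum_var_prop", np.asarray(self.cum_var_prop, dtype=float)
        )
        if np.any(np.diff(self.stdevs) > 1e-9 * self.stdevs[0]):
            raise ValueError("stdevs must be non-increasing")


@dataclass(frozen=True)
class ParameterRange:
    """Consecutive candidate component counts ``n_start .. n_start + k - 1``."""

    n_start: int
    k: int
    method: str

    @property
    def values(self) -> tuple[int, ...]:
        return tuple(range(self.n_start, self.n_start + self.k))

    def __post_init__(self) -> None:
        if self.n_start < 2:
            raise ValueError("n_start must be >= 2")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def compute_pca_summary(X: ExpressionMatrix) -> PCASummary:
    """PCA of samples with genes as features, gene-wise centered.

    Returns the component standard deviations (singular values of the
    centered matrix divided by ``sqrt(n_samples - 1)``) and cumulative
    variance proportions for up to ``min(n_genes, n_samples - 1)``
    components.
    """
    if X.n_samples < 3:
        raise ValueError("PCA summary needs at least 3 samples")
    centered = X.values - X.values.mean(axis=1, keepdims=True)
    # samples x genes orientation; economical SVD
    svals = linalg.svd(centered.T, full_matrices=False, compute_uv=False)
    n_comp = min(X.n_genes, X.n_samples - 1)
    svals = svals[:n_comp]
    var = svals**2 / (X.n_samples - 1)
    total = var.sum()
    if total <= 0:
        raise ValueError("matrix has zero total variance (constant matrix)")
    stdevs = np.sqrt(var)
    return PCASummary(
        stdevs=stdevs,
        cum_var_prop=np.cumsum(var) / total,
        n_components=n_comp,
        n_genes=X.n_genes,
        n_samples=X.n_samples,
    )


def kneedle_point(
    y: np.ndarray,
    shape: str = "convex_decreasing",
    tol: float = 1e-9,
) -> int | None:
    """Locate the knee/elbow of a monotone curve (Kneedle, S=1, offline).

    ``convex_decreasing`` fits a scree of standard deviations (elbow);
    ``concave_increasing`` fits a cumulative-variance curve (knee).  The
    curve is min-max normalized, oriented concave increasing, and the
    1-based rank of the maximum of ``y_norm - x_norm`` is returned.  An
    exactly linear curve has no knee: the sentinel ``None`` is returned and
    the caller must handle it.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("kneedle_point needs a 1-D curve of length >= 3")
    if shape not in ("convex_decreasing", "concave_increasing"):
        raise ValueError(f"unknown shape {shape!r}")
    span = y.max() - y.min()
    if span <= 0:
        return NO_KNEE
    y_norm = (y - y.min()) / span
    if shape == "convex_decreasing":
        y_norm = 1.0 - y_norm  # flip vertically -> concave increasing
    x_norm = np.linspace(0.0, 1.0, len(y))
    diff = y_norm - x_norm
    if diff.max() <= tol:
        return NO_KNEE
    return int(np.argmax(diff)) + 1


def estimate_parameter_range(
    pca: PCASummary,
    method: str = "elbow_sd",
    k: int = 10,
    n_start: int | None = None,
) -> ParameterRange:
    """Nominate the near-optimal component-number range from the PCA summary.

    ``elbow_sd`` locates the elbow of the standard-deviation scree;
    ``knee_cumvar`` the knee of the cumulative-variance curve.  The range is
    the ``k`` consecutive integers starting at that point (``n_start`` may
    be given explicitly to skip detection).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_start is None:
        if method == "elbow_sd":
            knee = kneedle_point(pca.stdevs, "convex_decreasing")
        elif method == "knee_cumvar":
            knee = kneedle_point(pca.cum_var_prop, "concave_increasing")
        else:
            raise ValueError(f"unknown method {method!r}")
        if knee is NO_KNEE:
            raise ValueError(
                "no elbow/knee detected (curve is linear); supply n_start "
                "explicitly"
            )
        n_start = max(int(knee), 2)
        used_method = method
    else:
        used_method = "manual"
    limit = min(pca.n_genes, pca.n_samples)
    if n_start + k - 1 >= limit:
        raise ValueError(
            f"largest candidate {n_start + k - 1} must stay below "
            f"min(n_genes, n_samples) = {limit}; choose a smaller k"
        )
    return ParameterRange(n_start=n_start, k=k, method=used_method)


def plot_scree(pca: PCASummary, path: str, chosen: int | None = None) -> None:
    """Write a scree / cumulative-variance diagnostic plot (optional helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ranks = np.arange(1, pca.n_components + 1)
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].plot(ranks, pca.stdevs, marker="o", ms=3)
    axes[0].set(xlabel="PC rank", ylabel="standard deviation", title="scree")
    axes[1].plot(ranks, pca.cum_var_prop, marker="o", ms=3)
    axes[1].set(
        xlabel="PC rank", ylabel="cumulative variance prop.", title="cumulative"
    )
    if chosen is not None:
        for ax in axes:
            ax.axvline(chosen, color="red", lw=1, ls="--")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
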