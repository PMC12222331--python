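"""Synthetic expression matrices with planted independent sources.

Ground-truth fixtures for every pipeline stage: a continuous linear-mixture
generator (Laplace gene loadings — ICA needs non-Gaussian sources — mixed by
Gaussian sample scores, plus Gaussian noise and a non-negativity baseline),
a negative-binomial count generator with planted per-sample sequencing
depths (exercises the filtering and normalization path), and an optimal
matching of estimated signatures to the planted sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from icasig.io import ExpressionMatrix

_SEED_MOD = 2**31


@dataclass(frozen=True)
class PlantedMixture:
    """A synthetic expression matrix plus the planted ground truth."""

    expression: ExpressionMatrix
    true_loadings: np.ndarray  # genes x r
    true_scores: np.ndarray  # r x samples
    noise_sd: float  # absolute noise standard deviation actually used
    r: int
    seed: int
    baseline: float = 0.0
    depth_factors: np.ndarray | None = None


def _ids(prefix: str, n: int) -> tuple[str, ...]:
    width = len(str(n))
    return tuple(f"{prefix}{i + 1:0{width}d}" for i in range(n))


def _draw_loadings(rng, genes: int, r: int, sparsity: float, max_tries: int = 100):
    """I.i.d. Laplace loadings, sparsified per column, with near-orthogonal
    columns enforced by rejection sampling (pairwise |Pearson| < 0.2)."""
    for _ in range(max_tries):
        loadings = rng.laplace(size=(genes, r))
        if sparsity > 0:
            n_zero = int(round(sparsity * genes))
            for j in range(r):
                loadings[rng.choice(genes, size=n_zero, replace=False), j] = 0.0
        if r == 1:
            return loadings
        corr = np.abs(np.corrcoef(loadings, rowvar=False))
        if corr[np.triu_indices(r, k=1)].max() < 0.2:
            return loadings
    raise RuntimeError("could not draw near-orthogonal loading columns")


def generate_mixture(
    genes: int = 2000,
    samples: int = 60,
    r: int = 5,
    noise_sd: float = 0.2,
    sparsity: float = 0.5,
    seed: int = 0,
    noise_scale: str = "relative",
) -> PlantedMixture:
    """Continuous linear mixture ``X = L @ F + noise + baseline``.

    ``noise_sd`` is a multiple of the noiseless signal's standard deviation
    when ``noise_scale='relative'`` (default: 0.2 x signal sd), or an
    absolute standard deviation with ``'absolute'``.  ``sparsity`` is the
    fraction of loading entries zeroed per source.  A constant baseline
    shifts the empirical minimum to zero, preserving the linear structure
    exactly.  Deterministic given ``seed``.
    """
    if not r < min(genes, samples):
        raise ValueError("need r < min(genes, samples)")
    if genes < 10 * r:
        raise ValueError("need genes >= 10 * r for well-separated sources")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed % _SEED_MOD)
    loadings = _draw_loadings(rng, genes, r, sparsity)
    scores = rng.standard_normal((r, samples))
    signal = loadings @ scores
    if noise_scale == "relative":
        sd = noise_sd * float(signal.std())
    elif noise_scale == "absolute":
        sd = float(noise_sd)
    else:
        raise ValueError(f"unknown noise_scale {noise_scale!r}")
    noisy = signal + (rng.standard_normal(signal.shape) * sd if sd > 0 else 0.0)
    baseline = float(-noisy.min())
    expression = ExpressionMatrix(
        values=noisy + baseline,
        gene_ids=_ids("g", genes),
        sample_ids=_ids("s", samples),
        normalized_flag="external",
    )
    return PlantedMixture(
        expression=expression,
        true_loadings=loadings,
        true_scores=scores,
        noise_sd=sd,
        r=r,
        seed=seed,
        baseline=baseline,
    )


def generate_counts(
    genes: int = 1000,
    samples: int = 40,
    r: int = 4,
    depth_factors: np.ndarray | None = None,
    dispersion: float = 0.1,
    seed: int = 0,
    signal_scale: float = 0.5,
    zero_gene_fraction: float = 0.05,
    sparsity: float = 0.5,
) -> PlantedMixture:
    """Negative-binomial counts with planted depths and low-rank log-signal.

    Gene/sample mean is ``depth_s * base_g * exp(signal_scale * Z_gs)`` with
    ``Z`` the unit-variance planted mixture, ``base_g`` log-normal baseline
    expression and NB dispersion ``alpha`` (var = m + alpha m^2).  The depth
    multipliers are recoverable by median-ratio normalization; a fraction of
    genes is forced to all-zero to exercise the sparsity filter.
    """
    if not r < min(genes, samples):
        raise ValueError("need r < min(genes, samples)")
    rng = np.random.default_rng(seed % _SEED_MOD)
    if depth_factors is None:
        depth_factors = rng.uniform(0.4, 2.5, size=samples)
    depth_factors = np.asarray(depth_factors, dtype=float)
    if depth_factors.shape != (samples,) or np.any(depth_factors <= 0):
        raise ValueError("depth_factors must be positive, one per sample")
    loadings = _draw_loadings(rng, genes, r, sparsity)
    scores = rng.standard_normal((r, samples))
    signal = loadings @ scores
    signal = signal / signal.std()
    base = np.exp(rng.normal(5.0, 1.0, size=genes))  # ~150 counts typical, post-filter bulk scale
    mean = depth_factors[None, :] * base[:, None] * np.exp(signal_scale * signal)
    nb_n = 1.0 / dispersion
    counts = rng.negative_binomial(nb_n, nb_n / (nb_n + mean)).astype(float)
    n_zero_genes = int(round(zero_gene_fraction * genes))
    if n_zero_genes:
        counts[rng.choice(genes, size=n_zero_genes, replace=False), :] = 0.0
    expression = ExpressionMatrix(
        values=counts,
        gene_ids=_ids("g", genes),
        sample_ids=_ids("s", samples),
        normalized_flag="raw",
    )
    return PlantedMixture(
        expression=expression,
        true_loadings=loadings,
        true_scores=scores,
        noise_sd=float(dispersion),
        r=r,
        seed=seed,
        depth_factors=depth_factors,
    )


def match_signatures(estimated: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Optimal one-to-one matching of estimated to true signatures.

    Solves the assignment problem maximizing the total absolute Pearson
    correlation between matched columns; returns one row per matched pair
    with its |Pearson|.
    """
    estimated = np.asarray(estimated, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimated.ndim == 1:
        estimated = estimated[:, None]
    if truth.ndim == 1:
        truth = truth[:, None]
    if estimated.shape[0] != truth.shape[0]:
        raise ValueError("estimated and truth must share the gene dimension")
    m, r = estimated.shape[1], truth.shape[1]
    both = np.corrcoef(estimated, truth, rowvar=False)
    cost = -np.abs(both[:m, m:])
    rows, cols = linear_sum_assignment(cost)
    return pd.DataFrame(
        {
            "estimated": rows,
            "truth": cols,
            "abs_pearson": -cost[rows, cols],
        }
    )
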