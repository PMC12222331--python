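"""End-to-end orchestration: parameter range -> robust ICA -> meta-signatures."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from icasig.io import ExpressionMatrix
from icasig.params import ParameterRange, compute_pca_summary, estimate_parameter_range
from icasig.reproducibility import (
    MetaSignature,
    cluster_across_parameters,
    consolidate,
    rank_and_name,
    select_reproducible,
)
from icasig.robust import RobustSignature, robust_signatures_for_n

_SEED_MOD = 2**31


@dataclass
class PipelineResult:
    """Everything a pipeline run produced.

    ``loadings`` is the genes x signatures matrix of standardized gene
    loadings; ``scores`` the signatures x samples matrix of mixing scores.
    ``diagnostics`` tabulates every within-parameter cluster that passed the
    stability filter.
    """

    parameter_range: ParameterRange
    robust_signatures: list[RobustSignature]
    meta_signatures: list[MetaSignature]
    selected: list[MetaSignature]
    loadings: pd.DataFrame
    scores: pd.DataFrame
    diagnostics: pd.DataFrame
    seed: int


def run_pipeline(
    X: ExpressionMatrix,
    k: int = 10,
    runs: int = 100,
    stability_threshold: float = 0.75,
    merge_distance: float = 0.25,
    mode: str = "from_start",
    method: str = "elbow_sd",
    n_start: int | None = None,
    seed: int = 0,
    jobs: int = 1,
    combiner: str = "mean",
    linkage_method: str = "average",
) -> PipelineResult:
    """Extract reproducible gene-expression signatures from a matrix.

    The matrix should already be normalized (CPM / median-ratio / external)
    and, if desired, prefiltered for sparse genes.  One master ``seed``
    drives every ICA run: run ``i`` of parameter index ``p`` uses seed
    ``seed + p * runs + i``, so results are reproducible and independent of
    the number of parallel ``jobs``.
    """
    if X.normalized_flag == "raw":
        warnings.warn(
            "matrix flagged raw; ICA on unnormalized counts is dominated by "
            "library size — normalize first unless this is intentional"
        )
    pca = compute_pca_summary(X)
    prange = estimate_parameter_range(pca, method=method, k=k, n_start=n_start)

    all_signatures: list[RobustSignature] = []
    for p_idx, n in enumerate(prange.values):
        base_seed = (seed + p_idx * runs) % _SEED_MOD
        all_signatures.extend(
            robust_signatures_for_n(
                X,
                n,
                runs=runs,
                threshold=stability_threshold,
                base_seed=base_seed,
                jobs=jobs,
                linkage_method=linkage_method,
            )
        )
    if not all_signatures:
        raise RuntimeError(
            "no signature passed the stability filter at any parameter value; "
            "lower --stability-threshold or inspect the data"
        )
    metas = cluster_across_parameters(all_signatures, merge_distance=merge_distance)
    selected = select_reproducible(metas, prange.values, mode=mode)
    selected = rank_and_name([consolidate(m, combiner=combiner) for m in selected])

    genes = list(X.gene_ids)
    samples = list(X.sample_ids)
    names = [m.name for m in selected]
    loadings = pd.DataFrame(
        np.column_stack([m.gene_loadings for m in selected]) if selected else np.empty((len(genes), 0)),
        index=genes,
        columns=names,
    )
    scores = pd.DataFrame(
        np.vstack([m.sample_scores for m in selected]) if selected else np.empty((0, len(samples))),
        index=names,
        columns=samples,
    )
    diagnostics = pd.DataFrame(
        [
            {
                "parameter_n": s.parameter_n,
                "stability": s.stability,
                "cluster_size": s.cluster_size,
                "medoid_seed": s.medoid_seed,
            }
            for s in all_signatures
        ]
    )
    return PipelineResult(
        parameter_range=prange,
        robust_signatures=all_signatures,
        meta_signatures=metas,
        selected=selected,
        loadings=loadings,
        scores=scores,
        diagnostics=diagnostics,
        seed=seed,
    )


def reproducibility_report(result: PipelineResult) -> pd.DataFrame:
    """Per-selected-signature support, average distance, origin and stabilities."""
    rows = []
    for m in result.selected:
        rows.append(
            {
                "signature": m.name,
                "support": m.support,
                "avg_distance": m.avg_distance,
                "origin_n": m.origin_n,
                "n_members": len(m.member_signatures),
                "member_stabilities": ";".join(
                    f"{s.stability:.4f}" for s in m.member_signatures
                ),
            }
        )
    return pd.DataFrame(rows)
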