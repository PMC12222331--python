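"""Cross-parameter clustering of stable signatures into meta-signatures.

A signature found at one component number is only trusted if near-identical
signatures recur at other component numbers in the tested range.  Stable
signatures from all parameter values are clustered (average linkage on
1 - |Pearson| of gene loadings, tree cut at a merge distance); each cluster's
*support* is the number of distinct parameter values contributing a member.
Clusters reproducible in more than half of the relevant parameter values are
kept and consolidated into a single meta-signature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from icasig.robust import RobustSignature, similarity_matrix


@dataclass(frozen=True)
class MetaSignature:
    """A cross-parameter cluster of robust signatures.

    ``support`` counts the distinct parameter values contributing at least
    one member; ``avg_distance`` is the mean pairwise ``1 - |Pearson|``
    among members (0 for a single member); ``origin_n`` is the smallest
    contributing parameter value.  ``gene_loadings`` / ``sample_scores``
    are filled by :func:`consolidate`.
    """

    member_signatures: tuple[RobustSignature, ...]
    support: int
    avg_distance: float
    origin_n: int
    gene_loadings: np.ndarray | None = None
    sample_scores: np.ndarray | None = None
    name: str | None = None


def _meta_from_members(members: list[RobustSignature]) -> MetaSignature:
    params = {s.parameter_n for s in members}
    if len(members) == 1:
        avg = 0.0
    else:
        sim = similarity_matrix(np.column_stack([s.gene_loadings for s in members]))
        dist = 1.0 - sim.values
        iu = np.triu_indices(len(members), k=1)
        avg = float(dist[iu].mean())
    return MetaSignature(
        member_signatures=tuple(members),
        support=len(params),
        avg_distance=avg,
        origin_n=min(params),
    )


def cluster_across_parameters(
    signatures: list[RobustSignature],
    merge_distance: float = 0.25,
    method: str = "average",
) -> list[MetaSignature]:
    """Cluster stable signatures from all parameter values into meta-signatures.

    The tree on ``1 - |Pearson|`` of gene loadings is cut at
    ``merge_distance`` (default 0.25, i.e. members correlate at |r| >= 0.75
    on average), mirroring the within-parameter stability threshold.
    """
    if not signatures:
        raise ValueError("no signatures to cluster")
    if not 0 < merge_distance < 1:
        raise ValueError("merge_distance must be in (0, 1)")
    if len(signatures) == 1:
        return [_meta_from_members(list(signatures))]
    sim = similarity_matrix(np.column_stack([s.gene_loadings for s in signatures]))
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(
        linkage(squareform(dist, checks=False), method=method),
        t=merge_distance,
        criterion="distance",
    )
    metas = []
    for lab in np.unique(labels):
        members = [signatures[i] for i in np.nonzero(labels == lab)[0]]
        metas.append(_meta_from_members(members))
    return metas


def select_reproducible(
    metas: list[MetaSignature],
    tested_values,
    mode: str = "from_start",
) -> list[MetaSignature]:
    """Keep meta-signatures reproduced in a strict majority of parameter values.

    ``from_start``: the cluster must originate at the first tested value and
    have support in more than half of all tested values.  ``any_origin``
    additionally keeps clusters originating at a later value when they are
    supported in more than half of the parameter values at or above their
    origin.  ``any_origin`` always keeps a superset of ``from_start``.
    """
    tested = sorted(tested_values)
    if not tested:
        raise ValueError("tested_values is empty")
    n_start = tested[0]
    kept = []
    for meta in metas:
        from_start_keep = meta.origin_n == n_start and meta.support > len(tested) / 2
        if mode == "from_start":
            keep = from_start_keep
        elif mode == "any_origin":
            remaining = [v for v in tested if v >= meta.origin_n]
            keep = from_start_keep or meta.support > len(remaining) / 2
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if keep:
            kept.append(meta)
    return kept


def consolidate(meta: MetaSignature, combiner: str = "mean") -> MetaSignature:
    """Combine a meta-signature's members into one gene/sample vector pair.

    Members are sign-aligned to the most stable member (flipped when their
    Pearson correlation with it is negative).  With ``combiner='mean'`` the
    gene loadings are the element-wise mean of the aligned members,
    standardized to mean 0 and unit variance; sample scores are the
    element-wise mean of the correspondingly aligned member scores.  With
    ``combiner='medoid'`` the most stable member's vectors are used directly
    (loadings still standardized).
    """
    members = meta.member_signatures
    if not members:
        raise ValueError("meta-signature has no members")
    anchor = max(range(len(members)), key=lambda i: members[i].stability)
    ref = members[anchor].gene_loadings
    signs = []
    for s in members:
        r = np.corrcoef(ref, s.gene_loadings)[0, 1]
        signs.append(-1.0 if r < 0 else 1.0)
    if combiner == "mean":
        loadings = np.mean([sg * s.gene_loadings for sg, s in zip(signs, members)], axis=0)
        scores = np.mean([sg * s.sample_scores for sg, s in zip(signs, members)], axis=0)
    elif combiner == "medoid":
        loadings = members[anchor].gene_loadings.copy()
        scores = members[anchor].sample_scores.copy()
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    sd = loadings.std()
    if sd == 0:
        raise ValueError("consolidated loadings are constant")
    loadings = (loadings - loadings.mean()) / sd
    return replace(meta, gene_loadings=loadings, sample_scores=scores)


def rank_and_name(metas: list[MetaSignature]) -> list[MetaSignature]:
    """Order by support (desc) then avg_distance (asc) and assign names."""
    ordered = sorted(metas, key=lambda m: (-m.support, m.avg_distance))
    return [replace(m, name=f"signature_{i + 1}") for i, m in enumerate(ordered)]
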