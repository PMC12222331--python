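"""Exports for downstream interpretation and simple phenotype association.

Gene loadings go out as GSEA-preranked ``.rnk`` lists; signature scores can
be tested for association with sample groups using two-sided Wilcoxon
rank-sum tests with Benjamini-Hochberg correction across all signature x
group-pair combinations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from icasig.pipeline import PipelineResult, reproducibility_report


@dataclass(frozen=True)
class PhenotypeTable:
    """Sample group labels (and optional ordinal time) for association tests."""

    sample_ids: tuple[str, ...]
    group: tuple[str, ...]
    time: tuple | None = None

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in phenotype table")
        if len(self.group) != len(self.sample_ids):
            raise ValueError("group labels must match sample ids")
        if self.time is not None and len(self.time) != len(self.sample_ids):
            raise ValueError("time labels must match sample ids")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhenotypeTable":
        time = tuple(frame["time"]) if "time" in frame.columns else None
        return cls(
            sample_ids=tuple(str(s) for s in frame.index),
            group=tuple(str(g) for g in frame["group"]),
            time=time,
        )


def export_ranked_list(name: str, gene_ids, loadings, path: str | Path) -> Path:
    """Write a two-column GSEA-preranked (.rnk) list, descending by loading.

    Ties in loading are ordered lexicographically by gene id so the file is
    byte-identical across runs.
    """
    frame = pd.DataFrame({"gene": list(gene_ids), "loading": np.asarray(loadings, float)})
    frame = frame.sort_values(["loading", "gene"], ascending=[False, True], kind="mergesort")
    path = Path(path)
    frame.to_csv(path, sep="\t", header=False, index=False, float_format="%.17g")
    return path


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum: W = rank sum of the first group.

    Exact null distribution when the pooled size is <= 20 and there are no
    ties; normal approximation with continuity correction otherwise.
    """
    pooled = np.concatenate([x, y])
    exact = len(pooled) <= 20 and len(np.unique(pooled)) == len(pooled)
    res = mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U -> rank-sum W
    return w, float(res.pvalue)


def associate_groups(scores: pd.DataFrame, pheno: PhenotypeTable) -> pd.DataFrame:
    """Wilcoxon rank-sum tests of each signature between every pair of groups.

    ``scores`` is signatures x samples.  Returns a table with columns
    signature, group1, group2, n1, n2, W, p, p_adj (Benjamini-Hochberg over
    all signature x pair tests).  Pairs where either group has fewer than 2
    samples are skipped with a warning.
    """
    sample_to_group = dict(zip(pheno.sample_ids, pheno.group))
    missing = [s for s in scores.columns if s not in sample_to_group]
    if missing:
        raise ValueError(f"samples without phenotype labels: {missing[:5]}")
    groups: dict[str, list[str]] = {}
    for s in scores.columns:
        groups.setdefault(sample_to_group[s], []).append(s)
    if len(groups) < 2:
        raise ValueError("association test needs at least 2 groups")
    rows = []
    for g1, g2 in combinations(sorted(groups), 2):
        if len(groups[g1]) < 2 or len(groups[g2]) < 2:
            warnings.warn(f"skipping pair ({g1}, {g2}): fewer than 2 samples in a group")
            continue
        for sig in scores.index:
            x = scores.loc[sig, groups[g1]].to_numpy(float)
            y = scores.loc[sig, groups[g2]].to_numpy(float)
            w, p = _wilcoxon_rank_sum(x, y)
            rows.append(
                {
                    "signature": sig,
                    "group1": g1,
                    "group2": g2,
                    "n1": len(x),
                    "n2": len(y),
                    "W": w,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    return table


def scores_long_format(scores: pd.DataFrame, pheno: PhenotypeTable | None = None) -> pd.DataFrame:
    """Tidy long-format (signature, sample[, group, time], score) table."""
    long = scores.reset_index(names="signature").melt(
        id_vars="signature", var_name="sample", value_name="score"
    )
    if pheno is not None:
        meta = pd.DataFrame({"sample": pheno.sample_ids, "group": pheno.group})
        if pheno.time is not None:
            meta["time"] = pheno.time
        long = long.merge(meta, on="sample", how="left")
    return long


def export_results(
    result: PipelineResult,
    outdir: str | Path,
    pheno: PhenotypeTable | None = None,
) -> dict:
    """Write all pipeline artifacts under ``outdir`` and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outdir": str(outdir), "files": {}}

    result.loadings.to_csv(outdir / "gene_loadings.tsv", sep="\t", index_label="gene")
    manifest["files"]["gene_loadings"] = "gene_loadings.tsv"
    result.scores.to_csv(outdir / "signature_scores.tsv", sep="\t", index_label="signature")
    manifest["files"]["signature_scores"] = "signature_scores.tsv"
    reproducibility_report(result).to_csv(
        outdir / "reproducibility_report.tsv", sep="\t", index=False
    )
    manifest["files"]["reproducibility_report"] = "reproducibility_report.tsv"
    result.diagnostics.to_csv(outdir / "stability_diagnostics.tsv", sep="\t", index=False)
    manifest["files"]["stability_diagnostics"] = "stability_diagnostics.tsv"

    rnk_dir = outdir / "rnk"
    rnk_dir.mkdir(exist_ok=True)
    for name in result.loadings.columns:
        export_ranked_list(
            name, result.loadings.index, result.loadings[name].to_numpy(), rnk_dir / f"{name}.rnk"
        )
    manifest["files"]["ranked_lists"] = [f"rnk/{n}.rnk" for n in result.loadings.columns]

    long = scores_long_format(result.scores, pheno)
    long.to_csv(outdir / "scores_long.tsv", sep="\t", index=False)
    manifest["files"]["scores_long"] = "scores_long.tsv"

    if pheno is not None and len(set(pheno.group)) >= 2 and not result.scores.empty:
        assoc = associate_groups(result.scores, pheno)
        assoc.to_csv(outdir / "group_association.tsv", sep="\t", index=False)
        manifest["files"]["group_association"] = "group_association.tsv"

    manifest["parameter_range"] = {
        "n_start": result.parameter_range.n_start,
        "k": result.parameter_range.k,
        "values": list(result.parameter_range.values),
        "method": result.parameter_range.method,
    }
    manifest["seed"] = result.seed
    manifest["n_selected"] = len(result.selected)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
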