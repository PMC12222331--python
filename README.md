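# icasig

Robust, reproducible gene-expression signature extraction from bulk
transcriptome matrices with independent component analysis (ICA).

## The problem

ICA decomposes a genes x samples expression matrix `X` (after gene-wise
centering) into additive *signatures*, `X ≈ S·A`: columns of `S` hold each
gene's positive or negative contribution to a signature, rows of `A` hold
each signature's activity per sample.  Unlike group-comparison methods, this
recovers co-regulated gene programs without using sample labels — useful for
cohorts (TCGA-scale tumor panels, longitudinal infection studies) where
expression reflects many known and unknown variables at once.

Two practical obstacles make naive ICA unreliable: the result depends on the
random initialisation of each run, and it depends strongly on the chosen
number of components `n`, for which there is no ground truth.  `icasig`
addresses both:

1. **Parameter range, not a point estimate.**  PCA is run first; the
   elbow of the standard-deviation scree (or the knee of the cumulative
   variance curve), located by the Kneedle algorithm, gives the start `n` of
   a range of `k` consecutive candidate values (default 10), e.g. 10..19.
2. **Within-parameter stability.**  For every candidate `n`, ICA runs many
   times (default 100); pooled components are clustered on absolute Pearson
   correlation and each cluster `M` is scored with the Icasso stability
   index — mean intra-cluster similarity minus mean similarity to everything
   outside:

       I(M) = (1/|M|²) Σ_{i,j∈M} σ_ij − (1/(|M||M̄|)) Σ_{i∈M, j∈M̄} σ_ij

   Clusters with `I > 0.75` survive, represented by their medoid.
3. **Cross-parameter reproducibility.**  Stable signatures from all
   candidate values are clustered again; only clusters supported by a strict
   majority of the tested parameter values are kept, consolidated into
   *meta-signatures* (standardized gene loadings, mean 0 / unit variance,
   plus per-sample scores).

Outputs are a genes x signatures loading matrix, a signatures x samples
score matrix, GSEA-preranked `.rnk` files per signature, a reproducibility
report, and optional Wilcoxon rank-sum association tests of scores against
sample groups (Benjamini–Hochberg corrected).

## Worked example

The built-in generator plants known independent sources, so recovery can be
verified exactly:

```python
from icasig import simulate, run_pipeline
from icasig.simulate import match_signatures

pm = simulate.generate_mixture(genes=1000, samples=50, r=4,
                               noise_sd=0.2, sparsity=0.5, seed=7)
res = run_pipeline(pm.expression, k=4, runs=20, seed=7, method="knee_cumvar")
print("tested range:", res.parameter_range.values)
print("stable signatures:", len(res.robust_signatures))
for m in res.selected:
    print(f"{m.name}: support {m.support}/{len(res.parameter_range.values)}, "
          f"avg distance {m.avg_distance:.4f}, origin n={m.origin_n}")
print(match_signatures(res.loadings.to_numpy(), pm.true_loadings))
```

prints

```
tested range: (4, 5, 6, 7)
stable signatures: 19
signature_1: support 4/4, avg distance 0.0002, origin n=4
signature_2: support 4/4, avg distance 0.0004, origin n=4
signature_3: support 4/4, avg distance 0.0005, origin n=4
signature_4: support 4/4, avg distance 0.0005, origin n=4
   estimated  truth  abs_pearson
0          0      0     0.998343
1          1      1     0.997083
2          2      3     0.996468
3          3      2     0.998363
```

The cumulative-variance knee lands on 4 (the planted dimension), 19 cluster
medoids pass the stability filter across the range 4..7, and they collapse
into exactly 4 meta-signatures, each present at every tested `n` (support
4/4) and each matching one distinct planted source at |Pearson| ≈ 0.997.
`res.loadings` and `res.scores` hold the two output matrices.

The same pipeline is available from the shell:

```sh
icasig simulate --genes 1000 --samples 50 --sources 4 --seed 7 --outdir sim/
icasig run sim/expression.tsv --normalization none --method knee --k 4 \
    --runs 20 --seed 7 --outdir out/
```

For real count matrices, typical flags are `--filter-fraction 0.25`
(drop genes expressed in fewer than a quarter of samples) and
`--normalization cpm` or `median-ratio`.

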