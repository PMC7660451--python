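# gsmdist

Distance-based characterization of metabolic heterogeneity in sets of
genome-scale metabolic models (GSMMs).

## The problem

Automated reconstruction pipelines now produce large *collections* of
constraint-based metabolic models — hundreds of microbial reconstructions, or
patient-derived models built by mapping gene-expression data onto a template
human network. Two models of the same tissue or of related organisms differ
in three distinguishable ways: in *which reactions they contain*, in the
*topology* of their metabolite–reaction network, and in the *flux
distributions* their constraints admit. `gsmdist` quantifies each aspect with
its own pairwise distance metric and combines them into a single
pattern-recognition workflow:

1. **Jaccard distance** between reaction sets, `J(A,B) = 1 − |A∩B|/|A∪B|`,
   computed on binary presence vectors aligned to a template ("parent")
   model's reaction universe.
2. **Weisfeiler-Lehman subtree (WLS) kernel distance** between bipartite
   metabolite–reaction graphs (currency metabolites such as water, ATP and
   NADH removed), `d = 1 − k(x,y)/√(k(x,x)·k(y,y))`, where `k` counts
   matching node labels over iterated WL label refinement.
3. **Flux-correlation distance** `1 − |Pearson r|` between mean flux vectors,
   each obtained by averaging 1,000 uniform samples of the model's
   steady-state polytope `{v : S·v = 0, lb ≤ v ≤ ub}` and z-scoring each
   reaction across models.

Each distance matrix is clustered with average-linkage hierarchical
clustering; the per-metric label vectors are reconciled by consensus
clustering (CSPA, HGPA, MCLA), keeping the candidate with the highest mean
normalized mutual information against the inputs. Distance matrices are
embedded with kernel PCA (Gower-centered classical MDS) for visualization
and for tracing per-subject *trajectories* between paired conditions;
metrics are compared with the Mantel permutation test; and a per-reaction
Kruskal-Wallis screen of the normalized flux matrix identifies reactions
whose activity differs between clusters, aggregated into per-pathway counts
and ±2.5σ outlier flags.

A synthetic-family generator (`gsmdist.synthetic`) creates small model sets
with a shared core pathway, planted group-specific reaction modules,
inclusion noise, per-model bound jitter, and planted flux-bound differences,
so the entire workflow is testable offline.

## Worked example

```python
from gsmdist import (
    SyntheticSpec, generate_family, template_model, build_universe,
    jaccard_matrix, wls_distance_matrix, build_flux_matrix,
    normalize_flux_matrix, flux_distance_matrix, hierarchical_labels,
    consensus, nmi, mantel, kruskal_wallis_screen,
)

spec = SyntheticSpec(seed=1)                    # 2 groups x 12 models
models, truth = generate_family(spec)
universe = build_universe(template_model(spec))

dj = jaccard_matrix(models, universe)
dw = wls_distance_matrix(models, h=3)
fm = build_flux_matrix(models, universe, n_samples=1000, seed=2)
nfm = normalize_flux_matrix(fm)
df = flux_distance_matrix(nfm)

labelings = [hierarchical_labels(d, k=2) for d in (dj, dw, df)]
result = consensus(labelings, k=2, seed=3)
print(result.selected, round(nmi(result.labeling, truth.labeling), 3))
print(round(mantel(dj, dw, seed=0).r, 3), round(mantel(dj, df, seed=0).r, 3))

screen = kruskal_wallis_screen(nfm, result.labeling)
print(sum(r.significant for r in screen), "significant reactions")
```

Output:

```
CSPA 1.0
0.994 -0.054
45 significant reactions
```

The consensus labeling recovers the planted two-group structure exactly
(NMI = 1.0). The Jaccard and WLS distance matrices are almost perfectly
Mantel-correlated (r ≈ 0.99) — reaction content already captures network
topology — while the flux-correlation metric carries complementary
information (r ≈ −0.05). The screen flags 45 reactions at p < 0.05: all 9
planted differential side-chain reactions, plus group-specific module
reactions (absent reactions are recorded as zero flux, so content
differences also register as activity differences) and core reactions whose
admissible flux genuinely shifts when different group branches draw on the
core pathway.

The same pipeline is scriptable from the shell:

```sh
gsmdist simulate --seed 1 --out-dir family/
gsmdist distances --models-dir family/models --template family/template.json \
    --metric jaccard --out dj.tsv
gsmdist cluster --distance dj.tsv --k 2 --out labels.tsv
gsmdist run --config workflow.yaml     # full pipeline from a config file
```

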