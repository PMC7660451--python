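# Methods

This note documents the models, algorithms and numerical choices behind
`gsmdist`, and what its synthetic validation does and does not demonstrate.

## Models and alignment

A model is a set of reactions with stoichiometry, flux bounds
(mmol·gDW⁻¹·h⁻¹), optional boolean gene–protein–reaction (GPR) rules and
pathway (subsystem) annotations. Exchange reactions are recognized
structurally: a reaction touching exactly one metabolite is a boundary
reaction, with the convention that negative flux is uptake. Model sets are
aligned to a *template* ("parent") model whose ordered reaction id list
defines the universe for presence vectors and flux-matrix columns. Alignment
is strict by default — contextualized models are expected to be subsets of
their template; a lenient mode drops off-universe reactions with a logged
count.

SBML I/O is delegated to cobrapy; subsystem strings and the optional class
label travel through SBML `<notes>` key–value pairs, which cobrapy
round-trips faithfully. A flat JSON dialect (documented in
`gsmdist.io`) carries the same fields and is the cheaper format for
synthetic families.

### Expression-based confidence

Gene intensities are log2-transformed (any base gives the same ranking, so
the choice is inert), duplicate probes per gene are averaged, and the top
30% of genes (ties at the cutoff included) are called high-confidence. Gene
confidence propagates to reactions through the GPR with AND → minimum and
OR → maximum over the ordering high > low > absent — the standard
conservative convention for enzyme complexes (a complex is only as available
as its scarcest subunit) and isoenzymes (any sufficient isoform suffices).
Reactions whose rule names no measured gene are "absent".

## Distance metrics

**Jaccard.** `1 − |A∩B|/|A∪B|` on presence vectors. Two empty reaction sets
have distance 0 (identical sets) with a warning. The matrix computation is
vectorized (bit-matrix products) and is checked in tests against naive set
arithmetic; the metric satisfies the triangle inequality.

**WLS kernel.** Models become undirected bipartite metabolite–reaction
graphs: metabolite nodes labeled with the compartment-stripped base id (so
`nadh_c` and `nadh_m` match across models), reaction nodes labeled with the
reaction id, an edge wherever a coefficient is nonzero. Bipartite encoding
preserves reaction identity and stoichiometric adjacency without committing
to a direction, which reversible reactions make ambiguous. Currency
metabolites — by default water, proton, ATP/ADP/AMP, phosphate,
diphosphate, NAD(P)(H), FAD(H₂), CO₂, O₂ and CoA — are deleted first, with
an optional degree threshold; these cofactors appear in so many reactions
that they would otherwise dominate the topology signal. The kernel counts
matching node labels over `h = 3` Weisfeiler-Lehman refinement rounds
(relabeling each node by its own label plus the sorted multiset of neighbor
labels, via one shared injective dictionary, so hash collisions cannot
occur). Kernel values are exact integer dot products; distance is the
cosine-normalized form `1 − k/√(k_xx·k_yy)`, which removes the dependence of
raw kernel values on graph size and puts the metric on the same [0, 1] scale
as the Jaccard distance. "Distance as one minus normalized similarity" is
used rather than a reciprocal because it is bounded and has a zero diagonal.

**Flux correlation.** Each model's steady-state polytope
`{v : S·v = 0, lb ≤ v ≤ ub}` is sampled (below), the sample mean is the
model's flux vector, vectors are stacked over the universe (reactions a
model lacks contribute 0, with an absence mask retained — the union-of-columns
convention is the only one that keeps vectors of different models
conformable), columns are z-scored across models with the sample (ddof = 1)
standard deviation, zero-variance columns are dropped and reported, and the
distance between two models is `1 − |Pearson r|` of their rows. The absolute
value means perfectly anti-correlated flux profiles count as similar;
Pearson correlation is used because Euclidean distances degenerate in
high-dimensional flux spaces.

## Flux sampling

The sampler is a hit-and-run Markov chain on the null-space parameterization
of the steady-state constraint. A feasible point is found by LP (HiGHS via
scipy) and refined onto the null space by least squares; movement is
restricted to `v0 + null(S)·u`, so every iterate satisfies `‖S·v‖∞ ≤ 1e−6`
by construction. Each step draws an isotropic direction inside the null
space, computes the feasible chord from the bounds, and jumps to a uniform
point on it; the stationary law of this chain is exactly uniform on the
polytope. Defaults: 100·dim warm-up steps, thinning of 15 chain steps per
retained sample, 1,000 retained samples, infinite bounds capped at
±1000 mmol·gDW⁻¹·h⁻¹. Degenerate cases are exact: an empty null space or a
point polytope returns the unique feasible point; zero-length chords (vertex
starts) are skipped. An adaptive artificial-centering direction scheme was
evaluated and rejected: on the small, box-like polytopes of the synthetic
families its direction pool collapses and mixing degrades measurably,
whereas isotropic hit-and-run at thinning 15 estimates segment centroids to
±0.3 on a bound of 10.

Per-model chain seeds are derived from the master seed and a CRC of the
model id, so identical models produce identical rows and results do not
depend on the order of the model list. Infeasible models are detected by one
LP and reported together.

## Clustering and consensus

Per-metric labelings come from average-linkage (UPGMA) agglomerative
clustering on the precomputed distances, cut to exactly k clusters with
`cut_tree` (deterministic; scipy breaks merge ties by pair index). The three
consensus algorithms follow the classic cluster-ensemble formulations, with
two documented simplifications that avoid an external hypergraph
partitioner: CSPA re-clusters the co-association matrix with the same
average-linkage routine instead of METIS, and HGPA is a seeded greedy
balanced hyperedge-cut minimization (part sizes within ±25% of n/k, 20
random restarts, first-best tie-breaking). MCLA clusters the input clusters
by Jaccard distance between indicator vectors and assigns each model to the
meta-cluster with maximal average participation, lowest index on ties. The
selected consensus maximizes mean normalized mutual information against the
inputs; NMI uses arithmetic-mean entropy normalization with the convention
that a single-cluster labeling (zero entropy) scores 0; ties between
algorithms break lexicographically (CSPA < HGPA < MCLA). k is a required
parameter (the workflow default is 2, matching a two-condition design).

## Embedding, Mantel test, screen

Kernel PCA of a distance matrix is realized as classical multidimensional
scaling: Gower double-centering of squared distances,
`B = −½·H·(D∘D)·H`, eigendecomposition, coordinates `v·√λ` for the top
positive eigenvalues with a deterministic sign convention. Explained
variance is relative to the positive spectrum; negative eigenvalues (from
non-Euclidean metrics) are truncated and their total magnitude reported. For
Euclidean inputs this reproduces the generating configuration exactly.
Trajectories are simple coordinate differences between paired models
(e.g., the same subject before and after an intervention) with Euclidean
magnitudes.

The Mantel test correlates the strictly-upper-triangle entries of two
distance matrices and builds the null by jointly permuting rows and columns
of the second matrix (9,999 permutations by default, seeded), with the
two-sided add-one p-value `(1 + #{|r*| ≥ |r|})/(1 + N)`.

The Kruskal-Wallis screen tests each retained flux-matrix column between
model groups using the tie-corrected H statistic and the chi-square tail
with (groups − 1) degrees of freedom; a fully tied column gets H = 0, p = 1.
Significance is raw p < 0.05 by default; a Benjamini–Hochberg option exists
but is off, since the screen is an exploratory ranking. Significant
reactions aggregate into per-subsystem counts, and normalized fluxes beyond
±2.5σ are flagged as individual outliers.

## Synthetic families

`SyntheticSpec` defaults describe the study conditions used throughout the
tests: 2 groups × 12 models (a paired two-condition design), a shared
10-reaction core chain with uptake and sink exchanges, 6 shared side-chain
modules with independent exchanges of which 3 are *differential* (bounds
scaled by 1 ± 0.5 between groups), 3 group-specific branch modules of 4
reactions anchored on core metabolites, 5% inclusion noise on group-module
reactions, and 15% per-model bound jitter. Every reaction keeps
`lb ≤ 0 ≤ ub`, so the zero flux vector is always feasible and generated
models can never fail the LP check. Side-chain modules are stoichiometrically
independent of the core, which keeps the planted flux effect local: the
unscaled side chains are true null columns for calibration, whereas core
columns are *not* nulls — group branches genuinely reshape the core's
admissible flux. The bound jitter exists because patient-derived models
differ individually; without it the only within-group variation in sampled
fluxes would be Monte-Carlo noise, which is not exchangeable across
structurally different models and would invalidate rank tests. Expression
tables are log-normal with the model's own group-module genes shifted
upward, plus duplicate probes for a fraction of genes.

What passing tests show: the workflow recovers planted content structure
(consensus NMI ≥ 0.9), reproduces the characteristic metric-correlation
pattern (content and topology metrics almost perfectly correlated, flux
complementary), and detects planted flux differences with high power at
calibrated type-I error on exchangeable nulls. What they do not show:
behavior on genome-scale networks (10³–10⁴ reactions, where WLS runtime and
flux-sampler mixing are the binding constraints), realistic pathway
topology, biomass objectives, or the robustness of conclusions to
model-extraction choices upstream of this package.

## Determinism and problem sizes

Every stochastic component (sampler, HGPA restarts, Mantel permutations,
generators) flows from explicit integer seeds; the workflow driver fans a
master seed out to per-stage seeds recorded in its manifest, and two runs
with the same config are byte-identical. The test suite and the acceptance
script use families of 24 models with ≤ 60-reaction templates, 1,000 flux
samples per model, 200-column calibration matrices and 200-replicate Mantel
calibrations — sizes at which every quantity is checkable against exact
oracles (set arithmetic, hand-expanded WL refinements, analytic polytope
centroids, exhaustive partition enumeration) while the full pipeline runs in
seconds per family.
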