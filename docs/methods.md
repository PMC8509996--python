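# Methods

## The model

miRNA biogenesis is treated as a two-step causal process: RNA-binding
proteins (RBPs) and their protein–protein-interaction (PPI) partners drive
the processing of a primary transcript (pri-miRNA) into the hairpin
precursor (pre-miRNA), and a second set of RBPs drives maturation of the
hairpin into the mature miRNA. For each miRNA and each step, the package
estimates a linear-Gaussian structural equation model (SEM) over nodes
X₁..X_p — RBPs, PPI genes and the target miRNA node —

    X = BᵀX + E,   E_j ~ N(0, w_j²),

where B is the weighted adjacency matrix of a directed acyclic graph. The
support of B is constrained to a prior whitelist: RBP → miRNA-node edges are
allowed only for RBPs with consensus CLIP binding sites on that miRNA (sites
in the pri flank or hairpin seed the pri→pre step; hairpin sites seed the
pre→mature step), and gene → gene → RBP edges follow PPI chains up to eight
interaction steps from a seed RBP, directed toward the seed. The target node
is always a sink.

## Binding-site consensus

The pri-miRNA region is the annotated hairpin extended by 1 kb on both sides
(clamped at coordinate 0; coordinates are 0-based half-open, BED
convention). A candidate site for (RBP, miRNA) requires at least five
overlapping reads (≥1 bp overlap) in each of at least two CLIP samples of
that RBP; RBPs with a single sample are excluded. The reported site interval
is the densest cluster of overlapping supporting reads (ties broken
leftmost) — using the full read span instead would let a single stray decoy
read stretch the site across the locus and corrupt the region typing. A
site whose cluster midpoint lies inside the hairpin is typed `pre`,
otherwise `pri`. Candidates must additionally overlap (≥1 bp) a peak from at
least one peak caller; when no external peak BEDs are given, a built-in
Poisson caller is used (positions whose coverage exceeds the 1−α quantile of
a Poisson with the region-average coverage as mean, α = 0.05, merged into
maximal runs). The built-in caller is a deliberately simple stand-in;
externally produced peaks take precedence when supplied.

## Structure learning

Columns are standardized (mean 0, unit variance) and the penalized score

    Σ_j (1/2n)‖x_j − X b_j‖² + Σ_(i,j) ρ_{λ̃,γ}(|B_ij|)

is minimized by block coordinate descent under the whitelist and an
acyclicity constraint, with the minimax concave penalty
ρ_{λ̃,γ}(t) = λ̃|t| − t²/(2γ) for |t| ≤ γλ̃, else γλ̃²/2, and γ = 2. The
user-facing penalty grid is λ = 1..10; the effective level is λ̃ = λ/√n,
the conventional scaling under which that grid spans near-dense to
aggressively sparse solutions at typical sample sizes (a raw threshold of
λ ≥ 1 would zero every correlation-scale coefficient outright). Edges are
swept grouped by unordered node pair; when both directions are allowed the
direction with the larger coordinate estimate wins the sweep and the
reverse is zeroed, with the incumbent direction retained on near-ties to
prevent oscillation. An update that would close a directed cycle is
rejected. Sweeps stop when the largest parameter change falls below 1e-4
(200 sweeps maximum; non-converged path points are flagged and skipped by
model selection). Solutions are warm-started along the increasing λ path,
which also makes the nonzero-edge count non-increasing in λ in practice.

The optimal λ minimizes BIC = Σ_j n·log(RSS_j/n) + k·log n, where the
residuals come from a per-node least-squares refit of each support (the MCP
shrinkage near the sparse end of the path would otherwise understate the
fit of true edges) and k is the number of edges; ties go to the sparser
model. The per-node sum is the Gaussian log-likelihood of the SEM — pooling
all residuals into a single n·log(RSS_total/n) term dilutes per-node
evidence roughly p-fold and measurably destroys recall, which is why the
pooled form was not used.

Note that Markov-equivalent DAGs (e.g. the two orientations of a chain)
have identical Gaussian scores on standardized data; where the score ties,
the reported orientation follows the whitelist and the sweep's
deterministic tie-breaks. Tests against exhaustive enumeration therefore
accept any score-optimal support.

## SEM fit and parameter selection

Given the selected support, each node is regressed on its parents by least
squares on centered, unstandardized data (so edge weights are on the
expression scale and comparable to planted simulation weights). The
conditional variance est(W_j)² is the residual variance RSS/(n−k_j−1); Ω is
their diagonal; the implied covariance is Σ = (I−B)⁻ᵀ Ω (I−B)⁻¹. Each edge
gets a Wald standard error and two-sided t p-value from its node-wise
regression (no multiple-testing correction; the selection rule is a raw
α = 0.05), and a relative precision 1 − se/|estimate| floored at 0 — the
parameter-"accuracy" notion used for selection, with the 85% default floor.
An edge is reported as a signed association iff p < 0.05 and precision
≥ 0.85.

## Screening

Associations whose target is the miRNA node are screened against expression
correlations at |r| ≥ 0.6 with step-specific sign rules: a positively
associated processing RBP must satisfy r(RBP, pre) ≥ +0.6; a positively
associated maturation RBP must satisfy r(RBP, mature) ≥ +0.6 and
r(RBP, pre) ≤ −0.6; rules are mirrored for negative associations. The
signed form (rather than |r| ≥ 0.6 with post-hoc sign checks) is
implemented. Cross-tissue validation re-applies the same rule per tissue
and histograms each combination by the number of tissues where it holds.
Randomization tests draw random miRNA:RBP pairs uniformly without
replacement from the universe cross-product minus observed pairs, apply the
identical evaluation, and compare by Fisher's exact test on the 2×2
presence table (default dichotomy: present in ≥1 tissue) plus a per-combo
one-sided binomial test against the background per-tissue presence rate (a
zero background with observed successes is reported as the exact point
mass, avoiding division by zero).

miRNA clustering uses average-linkage hierarchical clustering on
correlation distance (1 − r). A dendrogram node qualifies when the
intersection-over-union of its members' RBP sets is ≥ 0.8
(intersection-over-union is the chosen reading of "80% of RBPs shared";
the denominator is otherwise ambiguous); maximal qualifying nodes with ≥2
members are reported, which is equivalent to collecting qualifying clusters
over every cut height and keeping the set-maximal ones. Cell-state
separation runs k-means (k = 2, 10 restarts, seeded) on samples over a
chosen feature subset and scores the best label-permutation agreement.

## Prediction models

Per miRNA, the feature set is its selected causal-net genes: the RBPs with
a significant edge into the miRNA target plus their back-chain ancestors in
the selected-edge graph, over both biogenesis steps. The target is mature
miRNA expression restricted to samples with expression evidence (value
> 0); a miRNA needs at least `min_samples` such samples (default 600,
reflecting a biobank-scale model-admission rule — synthetic runs with a few
hundred samples pass a lower floor explicitly). Models are XGBoost
regression ensembles (squared-error loss, `tree_method="hist"`, single
thread, seeded). The default grid is trees ∈ {100, 300} × depth ∈ {3, 6} ×
learning rate ∈ {0.05, 0.1} with λ_reg = 1, γ = 0, selected by mean 10-fold
CV RMSE inside a seeded 70/30 train/test split; the winner is retrained on
the full training portion. Performance is RMSE, RMAPE = mean(|obs −
pred|/obs)×100 over samples with obs ≠ 0 (zero-observed samples are
excluded from the RMAPE sum and counted), and Accuracy = 100 − RMAPE.

Negative controls reuse the identical split/CV protocol: the swap control
assigns every miRNA another miRNA's feature matrix through a seeded
derangement (no fixed points, so every miRNA truly receives a foreign
net), aligned by sample id; the superset control replaces the causal
features with the full pre-selection candidate network (all reachable PPI
partners and RBPs). Both are compared to the causal models by paired
t-test on test accuracy. For desk-scale runs the control experiments use a
single boosting configuration (300 trees, depth 3, lr 0.1) and 3-fold CV in
both arms — the comparison needs identical protocols, not an exhaustive
grid.

## The synthetic generator

The generator emulates the full input stack so every stage is testable
without external data. The ground truth is a layered signed DAG: PPI genes
(roots, N(0,1)) → RBPs → pre-miRNA → mature miRNA. PPI→RBP edges appear
with probability `edge_density` (default 0.3) and weights uniform on
±[0.5, 1.0], rescaled per RBP to unit summed squared weight so every RBP
has a comparable dynamic range regardless of in-degree; RBPs add intrinsic
noise sd 1.0 (regulator expression is far from fully determined by its
partners). Each miRNA gets one processing RBP (positive weight into its
pre node) and a distinct maturation RBP (positive weight into the mature
node, negative into the pre node — the sign convention the screen tests);
magnitudes are drawn from the weight range. The pre→mature coupling is
deliberately weak (+U(0.1, 0.2)): a strong coupling would cancel the
maturation RBP's direct effect (net effect w_mature − w_pre→mat·|w_pre|)
and make the planted signal unidentifiable — biologically, the mature pool
is dominated by the processing machinery rather than precursor abundance
alone. miRNA-node noise sd defaults to 0.25. When there are at least twice
as many RBPs as miRNAs, the two roles are assigned from disjoint RBPs per
miRNA ("private regulators"), which is what makes the swapped-net control
meaningful; otherwise roles rotate round-robin and distinct miRNAs share
regulators, as the default 5-RBP/10-miRNA condition does.

Expression is sampled ancestrally; batch offsets (3.0 per batch index) are
added per sample block; each row is then shifted so its minimum equals
0.25 — a constant shift keeps the linear-Gaussian SEM assumptions exactly
satisfiable, unlike exponentiation, while producing a non-negative
expression-like scale whose relative errors (RMAPE) are meaningfully large
for bad models. CLIP reads are Poisson stacks at fixed per-pair binding
positions (hairpin centre for maturation, 400 bp upstream of the hairpin
for processing; ±3 bp start jitter; read length 30) plus uniform decoys at
`decoy_rate` per kb (default 0.2). The default reads-per-site rate is 15:
at rate 10 a Poisson draw falls below the five-read rule in ~3% of samples,
so ~6% of planted pairs would fail the two-sample rule by chance alone,
whereas at 15 the failure rate is ~0.03% and planted sites are recovered
essentially surely.

What the generator does *not* emulate: heavy-tailed/log-normal expression,
count noise, unequal library sizes, correlated decoy binding, shared latent
tissue factors, or train/test distribution shift. Passing tests therefore
demonstrate correctness of the machinery and recoverability under the
stated linear-Gaussian conditions, not performance on real sequencing data.

## Study conditions used by the tests and the acceptance script

- Default pipeline: 5 RBPs, 10 PPI genes, 10 miRNAs, 300 samples, 2 CLIP
  samples per RBP. Planted RBP→miRNA edge recall and sign agreement are
  checked here.
- Structure-learning oracles: 3-node exhaustive enumeration (n = 300, 20
  seeds; ties in the penalized score accepted as equivalent optima) and a
  15-node recovery study (n = 500, 10 seeds; whitelist = true edges + 20
  decoys excluding exact reversals, since binding priors carry direction).
- Control study: 20 RBPs (private regulators), 60 PPI genes, 10 miRNAs,
  300 samples, 10 seeds — the PPI universe is made much larger than the
  causal nets (superset ≈ 80 features vs ≈ 2–8 causal) to emulate the
  static-PPI-superset contrast; the swapped/superset comparisons are
  directional at this scale, far smaller than the collapse observed at
  biobank scale.
- End-to-end smoke and held-out prediction: models trained at
  `min_samples` 150 on the 300-sample default condition; held-out samples
  are a fresh 120–150-sample draw from the same truth.

Problem sizes were chosen so the whole suite runs comfortably on a single
CPU; they are stated here as the package's reference conditions.

## Known limitations

- The precision (parameter accuracy) definition 1 − se/|estimate| is one
  reasonable reading of an under-specified notion; it is monotone in the
  Wald t statistic, so selection behaves like a coupled effect-size/
  significance filter.
- Markov-equivalence makes some edge orientations unidentifiable from
  observational Gaussian data; orientation is then determined by the
  binding/PPI priors.
- The two-way batch model is additive (no batch×condition interaction) and
  errors out on aliased designs rather than attempting partial recovery.
- `pre_to_mature` candidate networks do not include the precursor as a
  node; the maturation RBP's reported weight is the marginal effect with
  the precursor path absorbed.
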