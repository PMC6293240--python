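# Methods

## Problem setting

The package organizes a corpus of patient-forum boards. Its unit of
analysis is the *forum document*: all posts of one board concatenated into
a single text, carrying the board's thread and post counts as metadata.
Corpora iterate in lexicographic forum-id order so that every derived
matrix has a stable, reproducible axis.

## Preprocessing

Tokens are lowercased maximal runs of letters/digits with intra-word
apostrophes preserved (curly apostrophes are normalized to `'` first);
leading/trailing apostrophes are stripped, tokens shorter than two
characters and stopwords are dropped. Contractions such as `don't` and
`i'm` are deliberately kept as single tokens — in patient-generated text
they carry affective signal and routinely surface among topic keywords.
The stopword list is a fixed English list shipped with the package
(`data/stopwords_en.txt`); it is frozen for reproducibility, and any
user-supplied list can be substituted. There is no stemming or
lemmatization: inflected surface forms ("swollen", "waiting") are
themselves informative keywords. The vocabulary keeps every token that
appears in at least `min_df` documents (default 1), ordered
lexicographically; the bag-of-words form preserves token multiplicity
because the sampler operates on token instances.

## Topic model and estimation

Standard LDA: document d draws a topic mixture θ_d ~ Dir(α), topic k draws
a word distribution φ_k ~ Dir(β·1_V), each token draws a topic then a
word. Inference is collapsed Gibbs sampling — θ and φ are integrated out
and token t in document d is resampled from

    p(z_t = k | z_−t, w) ∝ (n_dk^−t + α_k) · (n_wk^−t + β) / (n_·k^−t + V·β).

Sweeps visit documents in corpus order and tokens in document order. The
inner loop is numba-compiled; all randomness flows through numba's seeded
generator, so a given (corpus, configuration, seed) yields bit-identical
assignments across runs and platforms. Count matrices are maintained
incrementally and are exactly consistent with the assignments after every
sweep (asserted in tests by full recounts).

Hyperparameters and defaults:

- `K` — number of topics; no default, chosen per run (the pipeline runs a
  user-supplied ladder such as 15/20/30 and emits a full artifact set per
  K; judging when extra topics stop being "new" is left to the analyst).
- `α` — initial symmetric 50/K; re-estimated as an *asymmetric* vector by
  Minka's fixed point on the Dirichlet-multinomial likelihood every 50
  sweeps after a 100-sweep burn-in (cadence configurable;
  `optimize_alpha_every = 0` keeps α fixed). Components of unused topics
  are floored at 1e-6 to keep the prior proper. The fitted α_k is reported
  as the topic's *strength* — a dominance measure that can exceed 1,
  unlike a proportion.
- `β` — symmetric topic-word smoothing, default 0.01.
- iterations — default 1000 sweeps; the analysis drivers use 300–500,
  which suffices at their corpus sizes (the collapsed log-likelihood
  plateaus within ~200 sweeps there; the drivers print the trace).

Derived outputs: topic keys (top 20 words by smoothed within-topic
probability `(n_wk + β)/(n_·k + Vβ)`, ties broken lexicographically) and
the file-feature set, row_d = `(n_dk + α)/(len_d + Σα)`. Rows sum to 1 by
construction — an empty document degrades gracefully to the normalized
prior α/Σα — and no entry can reach 1 exactly unless a document is a
single topic with no smoothing. Topic ids are 1-based in every external
report; internal arrays are 0-based.

The collapsed joint log-likelihood log p(w, z | α, β) (sum of
Dirichlet-multinomial terms over documents and topics) is exposed for
convergence monitoring.

## Similarity and clustering

Each file's feature-set row is a point on the (K−1)-simplex. For files i,
j the Euclidean distance over all K topic weights is mapped to a
similarity by the affine transform `s = 1 − d/√2`, which fixes both
endpoints on probability vectors: identical rows score 1 and
disjoint-support rows (distance √2) score 0. The transform is the simplest
map consistent with similarity scores reported in [0, 1] with unit
self-similarity; since other bounded maps are defensible, it is injectable
(`1/(1+d)` ships as an alternative) and the pipeline manifest records
which was in force. Topic-topic similarity reuses the same machinery on
renormalized feature-set columns (a topic's profile across files; an
all-zero column falls back to uniform).

Clusters at a cutoff t (default 0.80) are the connected components of the
graph with edges `s_ij ≥ t`, computed via scipy's csgraph. Components are
the weakest — least assumption-laden — grouping consistent with "clusters
are sets of items with pairwise similarity above a cutoff": any such set is
contained in one component. Partitions refine monotonically as t grows;
singletons are retained.

## Topic regression

Each file gets an outcome y_i; the default is log10(post_count + 1), a
forum-engagement measure. This outcome is the module's largest
interpretive decision — the modeled response is not dictated by the
pipeline itself — so it is injectable and every report names the outcome
used. Two modes:

- **single-topic screen** (default): one OLS fit `y ~ 1 + topic_k` per
  topic, ranked by AIC ascending, ties broken by topic id.
- **forward stepwise**: greedy growth of a joint model by best AIC
  improvement until no topic improves it; candidates whose entry would
  make the design rank-deficient are skipped (feature rows sum to 1, so
  at most one column is ever dropped this way).

AIC is fixed as `n·ln(2π·RSS/n) + n + 2(p + 2)` — the Gaussian
−2·max-log-likelihood plus 2 per estimated parameter, counting the
intercept and the error variance. Conventions differ across software by
additive constants; any fixed convention preserves the ranking, which is
the quantity of interest. A perfect fit (RSS = 0) is rejected rather than
reported as −∞. A zero-variance outcome yields a warning and an
uninformative ranking rather than an error.

## Category statistics

Given a human forum→category assignment, popularity is the per-category
sum of post counts (threads optional); unassigned forums are pooled in an
explicit bucket so totals are conserved. The rank-frequency check sorts
the popularity counts descending and regresses ln(count) on rank 1..n: a
log-linearly decaying popularity profile gives a straight line (negative
slope, R² near 1). Constant counts make R² undefined; the fit is then
flagged degenerate and reported as 0. The site summary table reports exact
integer totals and per-site post shares rounded to one decimal.

## Synthetic corpora and what they show

The generator draws topics φ_k ~ Dir(β_true·1_V) (default β_true = 0.05,
V = 500: sparse, largely non-overlapping word profiles), assigns the D
forums round-robin to `n_groups` groups, and gives group g a profile that
interpolates between the uniform mixture and the "corner" uniform over the
block of topics the group owns: mixing weight 1/(1 + group_separation),
with separation = ∞ implemented exactly as the corner (disjoint topic
support across groups). Document mixtures are θ_d ~ Dir(κ·profile_g)
with κ = Σα_true (default 50), document lengths Poisson (default mean
200), tokens topic-then-word. Post counts follow the planted engagement
model `posts = round(exp(β₀ + Σ_j effect_j·θ_dj + N(0, σ)))`, floored at
1 so the log outcome is always defined. Defaults — 80 forums, 4 groups,
8 topics, 2 predictive topics with effects 2.0 and −1.5 against σ = 0.1 —
mirror the desk-scale structure the pipeline is meant to recover: a
manageable board count, a handful of thematic groups, and a strong
engagement signal.

Everything needed to score recovery is returned: φ, θ, token-level topic
labels, group labels and outcome coefficients. Estimated topics are
matched one-to-one to planted ones by linear-sum assignment on total
variation distance; recovery is summarized as matched TV distances,
adjusted Rand index between threshold clusters and planted groups, and the
fraction of planted predictive topics inside the top ranks of the AIC
screen.

Known identifiability caveat: with κ = 50 and multiple topics per group,
same-group topics co-occur in nearly fixed proportions in every document,
so they are individually non-identifiable (LDA recovers rotations of the
pair) even though group-level clustering is unaffected — the default-run
driver prints correspondingly large matched TV distances while cluster
recovery is perfect. Topic-recovery evaluations therefore use
one-topic-per-group configurations, where matched TV ≤ 0.15 and token
purity ≥ 0.95 are achieved. What the generator does *not* emulate: real
language (burstiness, syntax, misspellings), user-level posting behavior,
or topic drift over time; passing recovery tests shows the estimation and
clustering machinery is correct under the model's own assumptions, not
that the model fits any particular real site.

## Pipeline and reproducibility

`run_pipeline` executes preprocess → fit (per K in the ladder) →
similarity/clusters → regression (→ categories if an assignment file is
given), writing per-K artifact directories and a manifest with the
configuration, the similarity transform and AIC convention in force,
per-stage wall times and SHA-256 hashes of every artifact. A rerun with
identical configuration and seed reproduces identical hashes. One global
seed fans out to stages by a fixed documented offset (stage index), and
the per-K sampler seed adds K, so stages are individually rerunnable. On
a stage failure the partial output directory is removed.

Problem sizes in the shipped analysis drivers (80 documents × ~200
tokens, 300–500 sweeps, K = 8) and in the tests (down to 40 × 60) were
chosen as the smallest scales at which the planted structure is clearly
recoverable, keeping the whole study runnable on a laptop in well under a
minute.
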