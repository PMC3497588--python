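# Methods

## Dictionary construction

MeSH headings are multiword controlled-vocabulary terms; the engine needs
a flat word vocabulary. Every heading is NFKD-normalized (diacritics
stripped — MeSH exports are ASCII-mostly, and normalization prevents
near-duplicate words), lowercased, and split on any non-alphanumeric
character, so hyphens, commas and slashes all delimit. This is the
simplest reproducible reading of "reduced to single words" and makes the
canonical five-word example heading hold. Filtering then removes
duplicates, stop words and words shorter than three characters
(`min_length=3`, counted after lowercasing), and sorts lexicographically,
so the dictionary is byte-identical across runs for the same input.

Choices worth noting:

- Alphanumeric tokens like `b12` are kept when ≥ 3 characters: vitamin
  names in the reference factor list depend on them.
- The stop-word list is a fixed, versioned English list shipped with the
  package (`data/stopwords_en.txt`); any list can be supplied by path.
- Only preferred headings are used, not MeSH entry terms (synonyms); the
  descriptor-export reader attaches tree numbers but the hierarchy is not
  otherwise used.

## Corpus model

The document unit is one citation (title and abstract joined by a single
space), not one sentence and not one per-factor blob: per-citation columns
keep the matrix well-conditioned and let either factor-representation
strategy (below) be built on top. Publication-year filtering is an option
of the reader, not hard-coded. Citations retrieved for several factors are
kept under each factor independently (no cross-factor deduplication).
MEDLINE tagged-format parsing uses Bio.Medline; records lacking both title
and abstract are dropped with a warning.

## Latent semantic engine

**Weighting.** Default is log-entropy, the canonical LSA choice: local
weight `log(1 + c)`, global weight `g_t = 1 + Σ_d p_td log p_td / log n`
with `p_td = c_td / gf_t`. `none` (raw counts) and `tf-idf`
(`log(1+c) · log(n/df)`) are selectable. Terms absent from the corpus get
global weight 1 (their matrix rows are zero anyway; the choice only
affects queries, whose out-of-corpus words project to nothing).

**Decomposition.** Truncated SVD, dense (`numpy.linalg.svd`) when the
smaller matrix dimension is ≤ 1500 — which also makes full-rank requests
possible — and `scipy.sparse.linalg.svds` above that. `k` defaults to the
smallest value capturing 80% of squared singular-value mass, capped at
300; any integer `1 ≤ k ≤ rank` can be forced. Requests above the
numerical rank (tolerance `max(shape)·eps·σ₁`) are rejected with the
achievable maximum.

**Coordinates and fold-in.** Documents are rows of `V_k Σ_k`. A query is
folded in as `q = U_kᵀ w` (projection onto the term basis), chosen over
the `Σ⁻¹U_kᵀw` variant so the two representations agree: folding an
indexed document's own column gives `U_kᵀ(UΣVᵀe_d) = Σ V_kᵀ e_d`, exactly
its stored coordinates. Consequences, both tested: a single-word query is
proportional to that term's basis row, and at `k = rank` with identity
weighting cosine ranking reduces to the raw vector-space model for any
query in the matrix's column span (an out-of-span query component is
annihilated by the projection, rescaling all its cosines by one constant —
order preserved, absolute values not).

**Factor representation.** A factor owns many documents but needs one
vector. Default: the centroid of its documents' coordinates, re-normalized
to unit length — robust to the order-of-magnitude imbalance in per-factor
collection sizes that biases raw score magnitudes. Alternative
`pseudo-doc` mode: fold in the factor's summed weighted counts, which
behaves like one concatenated mega-document and weights long documents
more. Known limitation either way: generic factors with huge, diffuse
collections score systematically low; no normalization correction is
applied.

**Numerics.** Vectors with norm < 1e-12 are zero; cosine against a zero
vector is reported as undefined (an exception), never as 0. Ranking ties
break lexicographically by factor name, so output order is deterministic.

## Tri-modal disease model

The fitted function is exactly
`f(x) = Σᵢ αᵢ exp(−((x−μᵢ)/σᵢ)²)` — no ½ in the exponent and no
normalizing constant, i.e. a curve-fit model whose components have
variance σᵢ²/2 and area αᵢσᵢ√π. It is fitted to histogram *counts* (20
equal-width bins over [−1, 1] by default — 96 scores need coarse bins),
not to a smoothed density.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
TRF) with α ≥ 0, σ ∈ [10⁻³, 4], μ ∈ [−1, 1]. Multimodal objectives need
restarts: initialization takes μ at the histogram's weighted 10th/50th/90th
percentiles, σ from half the inter-percentile gaps, α from the nearest bin
heights, plus 20 seeded random restarts, keeping the best R². Components
are relabeled so μ₁ ≤ μ₂ ≤ μ₃. An all-zero histogram or total failure
raises a diagnostic error carrying the best parameters and residual seen.

**Thresholds.** The cutoff between adjacent components i, i+1 is the x in
(μᵢ, μᵢ₊₁) where `αᵢ exp(−((x−μᵢ)/σᵢ)²) = αᵢ₊₁ exp(−((x−μᵢ₊₁)/σᵢ₊₁)²)`;
taking logs gives a quadratic solved in closed form. When two roots fall
inside the interval, the one where dominance passes from the left to the
right component (log-ratio decreasing) is taken. Equal amplitudes and
widths give the midpoint exactly. No root in the open interval (heavy
overlap, or a zero amplitude) raises an error recommending manual
thresholds. Thresholds can always be supplied manually; two cutoffs give
three bands, three cutoffs enable the four-band variant with a "low" band.

**Band boundaries** are left-open / right-closed: established is strictly
`score > c_top`, each lower band is `(cᵢ, cᵢ₊₁]`, unknown is
`score ≤ c_lowest`. This matches the published band definitions ("highly
associated if greater than" the top cutoff) and places a score exactly at
a cutoff in the band below it. The number of modes is fixed at three; no
model selection is attempted.

## Networks

Two categorized queries over the same factor universe are linked by
Jaccard overlap: `jaccard_assoc` (default) uses established ∪ potential —
hypotheses live in the weakly-positive region, so excluding the potential
band would discard exactly the interesting overlap — and
`jaccard_established` restricts to the top band. An edge with both sets
empty is undefined and omitted (never weight 0); isolated nodes are kept,
since absence of overlap is itself a finding. Export is GraphML and TSV
only; graph analytics belong to downstream tools.

## Synthetic data

The generators exist so every stage is testable without a PubMed
download; they emulate structure, not language.

- `generate_mesh_fixture` emits multiword headings covering the synthetic
  topic and background vocabularies, so the derived dictionary covers the
  whole planted corpus.
- `generate_planted_corpus` draws each token of a factor's documents from
  the factor's topic vocabulary with probability 1 − noise, else from the
  shared background. Defaults (6 topics × 4 factors, 50 documents per
  factor, 40 tokens per document, 30% noise, 20 words per topic, 100
  background words) are the study layout used by the ranking checks:
  large enough for stable spectra, small enough to decompose in seconds.
- `sample_trimodal` draws from the mixture the curve describes: component
  i with probability ∝ αᵢσᵢ (its area), values Normal(μᵢ, σᵢ/√2), clipped
  to [−1, 1]. Clipping rather than rejection is a documented boundary-mass
  artifact, negligible for the parameter ranges used. The reference
  mixture for recovery checks is α = (5, 10, 5), μ = (−0.4, 0.05, 0.45),
  σ = (0.1, 0.12, 0.1) at n = 500 — three well-separated modes with the
  middle (potential) mode dominant.

What passing these tests does **not** show: real abstracts have Zipfian
vocabularies, named entities, citation-size imbalances of three orders of
magnitude and topical overlap between factors; synthetic topics are
disjoint by construction. The planted-corpus checks validate the
machinery (weighting, decomposition, fold-in, ranking), not retrieval
quality on real literature.

## Pipeline and reproducibility

`run_pipeline` executes dictionary → index → model → per-query
ranking/fit/bands → network (skipped below two queries), writing every
intermediate artifact plus a manifest with settings, SHA-256 input
checksums, per-stage timings and the seed. The seed feeds every random
element (fit restarts); identical configuration + seed reproduces
byte-identical rankings and fits. Model bundles store arrays in `.npy`
and factor vectors as TSV.

## Known limitations

- Generic-factor underestimation (collection-size bias) is flagged but
  not corrected.
- No incremental updates: corpus changes require a full rebuild.
- No live PubMed retrieval; users supply downloaded MEDLINE files or the
  synthetic generator.
- The MeSH hierarchy is parsed but unused (factor sets are curated, not
  generated from the tree).
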