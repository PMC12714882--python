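# Methods

This note documents the models and procedures `fluencynet` implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Data model and preprocessing

A fluency dataset is one ordered token list per participant with a group
label.  Cleaning applies three deterministic rules, in order, per token:

1. **Variant standardization.** Surface forms are mapped to roots through
   a one-to-one variant map (*dogs* → *dog*, common misspellings), before
   any other decision, so a plural repeat of an earlier singular is
   recognized as the same root.
2. **Category filtering.** Tokens whose root is not in the category
   lexicon are removed as non-category intrusions.
3. **Perseveration removal.** Any later occurrence of an already-retained
   root is removed, regardless of adjacency — the standard fluency scoring
   convention; nothing in the data motivates restricting to adjacent
   repeats.

Cleaning is idempotent and conserves tokens: per participant,
`raw = retained + perseverations + non-category`.  The packaged animal
lexicon (172 roots, 186 variants) is a replaceable default, not a
normative standard; analyses of real data should supply the scoring
dictionary actually used, and shared-node counts can shift by a few words
under a different dictionary.

The binary response matrix marks which participant produced which root.
Words are ordered lexicographically (case-folded) everywhere, which fixes
every downstream tie-break.  Producer filtering (≥ 2 producers, per group)
runs **before** cross-group node equating, and columns are not re-filtered
after intersection; exclusion counts therefore refer to each group's own
filtered lexicon, keeping them interpretable.

Response-count contrasts use OLS of count on a group indicator plus
covariates (typically age and education), with listwise deletion of
missing covariates (logged).  The reference level is the run's first
group, so the coefficient reads "impaired minus control" in the standard
configuration.

## Network estimation

Edge weights are cosine similarities of occurrence columns; for binary
data `sim(i, j) = n_ij / √(n_i n_j)` with a zeroed diagonal.  Values lie
in [0, 1]; 0 means two words were never co-produced.

TMFG sparsification is the pure greedy construction:

- **Seed**: the 4-clique with maximum total edge weight, found
  exhaustively (a numba-compiled scan; a pure-numpy implementation of the
  same search is kept as a fallback and verified equal on random inputs).
- **Insertion**: repeatedly add the unused node with the largest summed
  similarity to a current triangular face, connect it to that face's three
  vertices, and split the face.  No edge-swap refinement is applied.
- **Tie-breaks**: lowest node index (i.e., lexicographically earliest
  word), then earliest-created face — determinism across runs and
  platforms.

The result always has `3n − 6` edges, is planar and connected.  A retained
similarity can be exactly zero; such edges are structural edges of the
backbone, so the network object carries an explicit edge mask rather than
inferring edges from nonzero weights.

## Metrics

Two conventions coexist deliberately, mirroring how these pipelines are
used in practice:

- **Global metrics are unweighted on the TMFG backbone**: ASPL is the mean
  hop-count shortest path over connected pairs; CC is the mean unweighted
  local clustering (degree < 2 contributes 0).  This reproduces the
  magnitude regime typical of fluency TMFGs (CC ≈ 0.7–0.8, ASPL ≈ 2–4).
  Weighted variants (Dijkstra on 1/w distances; mean Zhang CC) are config
  toggles.
- **Local metrics are weighted**: strength (sum of incident weights) and
  Zhang's weighted clustering
  `Σ_{j≠k} ŵ_ij ŵ_jk ŵ_ki / ((Σ_j ŵ_ij)² − Σ_j ŵ_ij²)` with
  `ŵ = w / max(w)`; degenerate denominators yield 0.

Modularity is weighted Louvain at resolution 1, best of 10 seeded
restarts (the community algorithm is unspecified in the source pipelines;
Louvain is the common default and restarts absorb its stochasticity —
verified within 0.02 of the exhaustive-partition optimum on ≥ 95% of
random n ≤ 8 graphs).

**Null model**: 1000 (default) Erdős–Rényi graphs at the matched density
`p = 2m / (n(n−1))`; ASPL on a disconnected replicate averages connected
pairs only, keeping the null distribution defined.  Observed metrics are
z-tested against these distributions.

**Node-wise bootstrap**: each replicate draws one random half (`⌈n/2⌉`) of
the *shared* word set — the same subset for both groups, as "shared node
set" implies a common draw — restricts both response matrices to it,
re-estimates cosine + TMFG, and records ASPL/CC/Q.  Group contrasts use
pooled-variance t-tests (df = 2·reps − 2) and pooled-SD Cohen's d; local
contrasts use paired t over matched words with the paired d
(mean diff / SD diff).  No multiple-testing correction is applied, since
none is conventional in this literature's reporting.

## Spreading activation

Synchronous update per step: node i keeps `r·a_i` and receives
`(1−r)·Σ_j a_j w_ij / s_j` from neighbors (s_j = strength); then decay
`×(1−d)`; then values below the suppression threshold are zeroed.
Defaults: 100 units per seeded node, r = 0.5, d = 0, s = 0, t = 10 steps.
With d = 0, s = 0 and no isolated nodes the column-stochastic diffusion
conserves total activation (asserted to 1e−9 per step) and converges to
the strength-proportional stationary distribution (asserted at t = 500 to
1e−6).

The default mode seeds each word in its own independent run (a sweep; an
all-nodes-at-once mode is also provided).  Three per-word readouts of the
sweep are exposed, because they answer different questions:

- **own** — the word's activation in its own run: how slowly activation
  leaves the seed.  In a *degraded* network mixing is slower, so own-seed
  activation is *higher*, not lower.
- **spread** (default for group contrasts) — `initial − own`: how much of
  the word's activation has been transmitted into the network.  This is
  the transmission-efficiency reading, is lower in degraded networks at
  every step, and gives strong paired contrasts across matched words.
- **received** — mean activation reaching the word from the other seeds'
  runs: lower in degraded networks but with weak word-level pairing.

Group comparisons are paired t-tests at each step 1…t on the chosen
measure.  The structure regression predicts the own-seed final activation
from z-scored strength and Zhang CC; across synthetic groups its signs are
stable (strength positive, clustering negative — activation accumulates at
hubs and is held back inside tight clusters).

## Clique percolation

All k-cliques (default k = 3, the most sensitive choice) are enumerated on
the backbone; a clique's intensity is the geometric mean of its edge
weights — the standard weighted clique-percolation convention.  At each
threshold I in 0.01, 0.02, …, 1.00, cliques below intensity I are dropped;
surviving cliques sharing k − 1 nodes form communities, and the number of
words in any surviving community (equivalently, in any surviving clique)
gives a non-increasing curve.  The percolation integral is the left
Riemann sum (step 0.01); a triangle of weight 0.5 yields 3 × 0.50 = 1.50,
and a full curve yields n × 1.00.

Group comparison repeats the analysis over iterations.  Two iteration
modes exist; the default is **node-subsample** (a common random half of
the shared words per iteration, mirroring the node-wise bootstrap).  The
alternative, resampling participants with replacement, duplicates rows and
thereby inflates cosine similarities — duplicated participants co-occur
with themselves — which distorts clique intensities asymmetrically between
groups of different sizes and list lengths; it is retained as an option
but not the default.

## Synthetic cohorts

The generator produces data with the statistical structure the analysis
assumes, with full ground-truth bookkeeping:

- **Lexicon network**: 150 animal roots, 6 equal blocks (semantic
  subcategories), within-block base weight 0.55, between-block 0.12,
  ±25% multiplicative jitter, all clipped to (0, 1].  A Zipf-like
  popularity factor (rank^−1.5, ranks randomly assigned) scales weights so
  core words act as hubs and the tail is rarely produced — the
  idiosyncratic responses later excluded by producer filtering and node
  equating.  The exponent and vocabulary size were calibrated once, at
  design time, so coverage, hub structure, and the shared-node asymmetry
  sit in the regime reported for real fluency cohorts; they are not
  fitted to any dataset.
- **Group profiles**: cohort sizes (120 control / 127 aphasia; 64 fluent /
  63 nonfluent), walk-length means and SDs (22.47 ± 4.90, 9.63 ± 5.25,
  11.95 ± 5.08, 7.27 ± 4.30), and demographic distributions follow the
  reported study population.  Impairment is operationalized as (a) edge
  degradation — each lexicon edge independently removed at rate 0 / 0.25 /
  0.15 / 0.30, with the maximum-weight spanning tree restored if the
  network disconnects — plus (b) higher teleport probability (0.05–0.15)
  and higher noise rates (perseverations 0.03–0.12, intrusions 0.02–0.08,
  variants 0.05).
- **Production model**: a censored weighted random walk — transitions
  proportional to edge weight, uniform teleport with the profile's jump
  probability, each node emitted on first visit only, stopping after a
  truncated-normal number of emissions.  Noise is injected afterwards with
  exact bookkeeping, so the cleaning log can be verified token for token.

What passing tests show: the pipeline recovers planted differences — with
control vs. degraded profiles, the estimated networks show longer ASPL,
lower CC, higher Q, lower percolation integrals, and lower transmitted
activation for the degraded group in 50/50 seeded runs — and cleaning
recovers injected noise exactly.  What they do not show: real transcripts
have richer error structure (phonological paraphasias, semantically
related intrusions, latency structure) and a far larger effective
vocabulary; absolute metric values on real data will differ from the
synthetic regime even though the contrasts behave the same way.

## Numerical choices

- All stochastic stages take explicit seeds; the pipeline derives a
  labelled 31-bit sub-seed per stage from the master seed, so stages are
  reproducible independently of execution order.
- Word order (lexicographic, case-folded) fixes all tie-breaks; TMFG ties
  go to the lowest node index, then the earliest face.
- ASPL of disconnected graphs averages connected pairs; metrics requiring
  edges raise typed errors on edgeless inputs rather than returning NaN.
- Edge-list/GraphML round-trips preserve float precision
  (`float_precision="round_trip"` on read).
- Default resampling sizes in the analysis drivers and the acceptance
  script (300 bootstrap replicates, 300 random graphs, 150 percolation
  iterations) are the package's single-CPU working sizes; the full-size
  settings (1000/1000/500) are plain configuration values.

## Known limitations

- **Bootstrap effect sizes are not calibrated under the null.**  The
  Cohen's d between two groups' bootstrap distributions divides a
  numerator that retains cohort-level estimation error (co-occurrence
  estimates from ~20-word lists converge slowly, and TMFG responds
  discretely to small similarity changes) by a denominator that reflects
  only node-subsample spread.  Two cohorts drawn from the *same* profile
  therefore show |d| < 0.2 in only ~60% of runs at realistic cohort sizes
  (rising slowly with n).  The test suite asserts the ≥ 85% calibration
  bound and deliberately leaves it failing as documentation of this
  property; inferential users should read the bootstrap t and d as
  descriptive of subsample stability, not as calibrated null-hypothesis
  tests.  The same conflation is why such pipelines report t-statistics in
  the tens on real data.
- The generator's fluent/nonfluent contrast does not reproduce the
  empirical resilience ordering: shorter nonfluent lists concentrate
  co-occurrence on the shared core and slightly *raise* cosine weights, so
  nonfluent percolation integrals come out at or above fluent ones in most
  seeds, while the control-vs-impaired ordering is robust.  Treat the
  fluent/nonfluent synthetic percolation comparison as a demonstration of
  the machinery, not of the phenomenon.
- The spreading simulator's absolute activation summaries depend on the
  chosen readout (own / spread / received); only directions and
  significance patterns are meaningful across parameterizations.
- Modularity values from Louvain are lower bounds on optimal Q; with 10
  restarts the residual gap is negligible at these sizes but grows for
  much larger lexicons.
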