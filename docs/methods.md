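# Methods

## Model and procedure

The classifier treats a protein purely as a string over the 20 standard
amino acids and asks whether short-range residue correlations separate two
classes. The feature family is the g-gap dipeptide composition: for gap
g, the ordered pair (a, b) at positions (i, i + g + 1) is one of 400
types, a sequence of length L contains exactly L − g − 1 such pairs, and
the feature vector is the empirical distribution over pair types,
f_u = n_u / (L − g − 1). The denominator is the pair count, which is the
only normalisation that makes each vector an exact probability vector;
row sums are 1 to 1e-9 by construction and tested to that tolerance.
Dipeptides are indexed lexicographically (AA, AC, …, YY); every module,
TSV export and model archive shares this order.

Feature relevance is the one-way ANOVA F value per column: with group
sizes m₁, m₂ (N = m₁ + m₂, K = 2), SS_B = Σ mᵢ(x̄ᵢ − x̄)², SS_W = Σᵢ Σⱼ
(x_ij − x̄ᵢ)², F = (SS_B/(K−1)) / (SS_W/(N−K)). F is used only to rank
features, never for inference, so no multiple-testing correction is
applied (for K = 2 it equals the squared pooled two-sample t statistic, an
identity the tests check against scipy at 1e-9 relative tolerance).
Degenerate columns get total, deterministic ranks: constant columns F = 0;
perfectly separated columns (SS_W = 0, SS_B > 0) an infinity sentinel that
ranks above all finite values. Ties are broken by ascending dipeptide
index so rankings — and everything downstream of them — are reproducible.

Incremental feature selection sweeps the nested subsets along the ranking
(subset of size ε = top-ε features), scoring each with a cross-validated
RBF-SVM and taking the global accuracy peak over all gaps (default 0–10)
and sizes (default every size 1–400; the `stride` parameter thins the
sweep for quick runs — the exhaustive default visits 11 × 400 = 4,400
points). The two-stage protocol scores the sweep with seeded stratified
10-fold CV and re-scores only the confirmed optimum with the jackknife
(leave-one-out), which is unique for fixed data and hyperparameters.
Selection ties break toward the smaller subset, then the smaller gap.

For feature interpretation, F values are min–max normalised over the 400
features of a gap and signed by the class with the larger mean frequency:
F⁰(u) = sgn(f̄⁺_u − f̄⁻_u)·(F(u) − F_min)/(F_max − F_min) ∈ [−1, 1].
Positive F⁰ means the dipeptide prefers the positive class; |F⁰| > 0.5 is
a conventional shortlist threshold. (One published presentation of this
scheme carries a figure caption whose red/blue legend contradicts its own
body text; this implementation follows the convention that positive scores
mark positive-class enrichment.) When an infinite F is present, separated
features get |F⁰| = 1 and finite features are normalised over the finite
range — a corner reachable only on tiny or degenerate datasets.

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| gap range | 0–10 | correlations beyond ~10 residues are not probed |
| c grid | 2⁻⁵…2¹⁵, ×2 steps | regularisation; standard LibSVM-style grid |
| γ grid | 2⁻¹⁵…2⁻⁵, ×2 steps | RBF width; see the caveat below |
| tuning folds | 10 | stratified, one seeded split shared by the whole grid |
| sweep CV | kfold10 | `jackknife` available; `kfold<k>` parses any k |
| stride | 1 | subset-size step of the sweep |
| short policy | error | `drop` removes sequences with L < g + 2 and reports survivors |

Grid-search ties break toward smaller c, then smaller γ, making tuning
deterministic. Hyperparameters are tuned once per gap on the full
400-feature matrix and reused across subset sizes (per-subset re-tuning is
available via `tune_per_subset` but multiplies cost by the grid size);
tuning each of the 4,400 subsets separately is rarely worth it. No class
weighting is applied despite the default benchmark imbalance.

## Synthetic benchmark generator

The generator emulates the structure of a curated two-class benchmark
(default 178 positives vs 226 negatives — the canonical imbalance of
cancerlectin benchmarks — lengths uniform on [80, 300], uniform residue
background with a natural-composition table available). Negatives are
i.i.d. from the background. Positives multiply the conditional probability
of emitting residue b at position i by ρ whenever residue a sits g* + 1
positions back, for each planted pair (a, b), renormalising the position's
distribution; ρ = 1 is an exchangeable null. The signal therefore lives
exactly in the measured feature family and ρ maps directly to a mean
frequency shift of the planted pairs.

What the generator does **not** emulate: real domain architecture,
homology/redundancy structure, length–composition coupling, and
position-specific motifs. One known side effect of the conditional boost:
it raises the *marginal* frequency of the planted second residues in
positives, so weak class signal leaks into every gap's features (and into
amino-acid composition generally). At realistic lengths the pair-level
signal at the planted gap dominates and gap recovery is reliable; on very
short sequences the leak can let a neighbouring gap win. Passing recovery
tests therefore demonstrates that the pipeline finds dipeptide-level
signal it was pointed at — not that it would reach any particular accuracy
on real proteins.

## Numerical choices and caveats

- **Perfect separation / constant features**: handled by the F sentinel
  rules above so ranking never depends on NaN propagation.
- **Determinism**: every stochastic step (fold shuffling, generation)
  consumes an explicit integer seed; repeated runs are byte-identical at
  the TSV level, and the jackknife is seed-free by construction.
- **Near-constant-kernel regime**: on probability-vector features the
  squared distances between samples are of order 1e-2, so the γ range
  2⁻¹⁵…2⁻⁵ leaves the RBF kernel within ~1e-4 of constant; the SVM then
  relies on large c to act as an effectively linear classifier. On data
  *with* signal this works. On null or near-null data the tuned model can
  degenerate into a training-majority predictor, and leave-one-out CV then
  scores such a model at ~0% on balanced classes (each held-out sample
  makes its own class the training minority — the classic LOO/majority
  inversion) while stratified k-fold, whose training sets stay balanced,
  sees ~50%. Consequences adopted here: the null-calibration study uses
  the benchmark's natural 178:226 imbalance (scaled to 89 vs 113), where a
  majority-like model scores exactly the majority fraction and the
  jackknife lands on the m₂/N baseline; and very small balanced fixtures
  in the unit tests use grids extending to γ = 2³ so tuning can find a
  non-degenerate model at n = 60.
- **Short sequences** (L < g + 2) contain no g-gap pair; encoding them is
  an error by default because silent zero vectors would corrupt the group
  means feeding the F statistic. The drop policy removes them and returns
  the surviving index map so labels stay aligned.
- **Model archives** are joblib payloads with a format version, the
  (c, γ) pair, the gap and the ranked feature-column indices, so a saved
  model re-encodes raw sequences identically at load time.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` runs, from one seed: the analytic baselines (exact
arithmetic); 100 random 40×400 datasets for the F = t² oracle check; 1,000
random sequences (lengths 10–100, gaps 0–5) against the brute-force
counting oracle; a ten-seed recovery study — 100+100 sequences, lengths
80–300, five pairs planted at gap 1 with ρ = 5, IFS over gaps 0–3 at
stride 10 under 5-fold CV, hyperparameters tuned once per gap over
exponent-step-2 grids with 5 folds, jackknife at each selected optimum,
with the ρ = 1 imbalanced null on five of the seeds — and a duplicated
small IFS run compared byte-for-byte. These sizes were chosen as the
smallest at which the stochastic properties are stable across seeds; the
full-scale protocol (gaps 0–10, stride 1, 10-fold + jackknife) is the
library default.

## Known limitations

- The method captures pairwise residue correlations only; physicochemical
  encodings and profile (PSSM) information are out of scope.
- Binary classification only; the ANOVA machinery generalises to K > 2
  but the pipeline, metrics and CLI assume two classes.
- The jackknife, while unique, is expensive (N SVM fits per subset);
  sweeping all 4,400 subsets under jackknife is supported but slow — the
  two-stage default exists precisely to avoid it.
- Redundancy reduction of real datasets (CD-HIT-style clustering) must
  happen upstream; the package assumes an already-curated benchmark.
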