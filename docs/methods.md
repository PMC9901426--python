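# Methods

## Model

A phage genome is an ordered sequence of proteins `0..n-1`. Each protein
is mapped to one observation symbol: the Pfam accession of its best
(smallest-e-value) retained `hmmscan` hit, or `NOHIT` if no hit survives
the inclusion threshold. Ties on e-value break by higher bit score, then
lexicographically smallest accession, so symbol assignment is
deterministic. Retention uses a strict inequality (e-value < 1e-4 by
default; 1e-10 in conservative mode, intended for large uncurated contig
catalogs where annotation noise dominates).

Over these symbols we place a two-state HMM with hidden states
*tail* and *non-tail*:

- initial vector π (ordered tail, non-tail),
- 2×2 row-stochastic transition matrix A,
- per-state categorical emission distributions B over the symbol
  alphabet, `NOHIT` included.

`NOHIT` is a first-class emission symbol. Roughly a third of phage
proteins have no Pfam hit; dropping them would shorten the observation
sequences, distort transition counts, and leave those proteins without a
posterior. Treating no-hit as evidence (it is more common outside tail
modules than inside, given the curated tail-domain vocabulary) lets
every CDS receive a probability.

## Training: frequency counting

Training is fully supervised counting; there is no EM. Given per-genome
`(symbol, state)` sequences:

- `A[s][t]` = (adjacent within-genome pairs s→t) / (pairs starting in
  s). Counting never crosses genome boundaries; each genome is an
  independent observation sequence that restarts from π. Genomes are
  treated as linear even when the source record is circular — no
  wrap-around transition is counted or decoded.
- `B[s][d]` = (symbols d in state s) / (positions in state s), then
  rescaled by (1−ε) to reserve the unseen-symbol mass (below). A
  Laplace option (`alpha` pseudocounts) exists but defaults to 0: pure
  maximum likelihood.
- `π[s]` defaults to the **genome-start state frequency**
  (`pi_mode="start"`). A `pi_mode="global"` option counts every
  position instead (the overall tail fraction of the corpus). The two
  differ materially: the global frequency of a Markov chain converges
  to the stationary distribution of A, which for the default chain is
  ≈ 0.024 tail — an order of magnitude below typical start-frequency
  values. Start counting is the default because it makes the estimator
  consistent with the generative process the model assumes (every
  genome is an independent chain started from π): fitting data
  simulated from a known model then recovers that model's π, which is
  the package's core round-trip test. For decoding, the choice is
  nearly irrelevant — π affects only the first position and the chain
  mixes in ~2 steps.

Degenerate corpora raise: a state with zero positions (one-class
corpus) cannot normalize its emission row, and a corpus consisting only
of single-protein genomes has no transitions to count.

### Labeling and vocabularies

Ground-truth states come from the product annotation: a protein is
tail-state iff its product contains one of ten tail keywords as a
case-insensitive substring. Both "fibre" and "fiber" are matched, since
public annotations use both spellings. "Terms"/"TermL" are matched
literally; an opt-in alias set ("terminase small"/"terminase large") is
provided but off by default, since the literal tokens are what the
labeling scheme defines.

Keyword labels are supplemented by domain evidence in two passes.
First, vocabularies: tail domains are all symbols ever observed on a
keyword-tail protein; non-tail domains are symbols observed only on
non-tail proteins. A symbol seen in both classes counts as tail —
symbol-level disjointness standing in for profile-similarity screening,
which operates in sequence space this package does not model (a hook
accepts an externally computed similarity table when exact screening is
wanted). Second, promotion: a keyword-negative protein carrying a
tail-vocabulary symbol is relabeled tail with domain evidence; the
reverse demotion never happens. `NOHIT` enters neither vocabulary.

## Decoding

Per-protein posteriors are computed by the exact forward–backward
recursion with per-position scaling (the scaling constants double as
the incremental log-likelihood), so genomes of length 10⁴+ cannot
underflow. Posterior (per-position MAP) decoding is the primary output
— the posteriors feed ROC analysis directly — and Viterbi is available
as a secondary decoder for a single most-probable path.

Unseen symbols: each state reserves a smoothing mass ε (default 1e-4)
that any symbol outside the training alphabet emits; observed-symbol
probabilities are rescaled by (1−ε). Novel genomes always carry domains
absent from training, and without this mass their likelihood would be
exactly zero. ε = 0 is accepted for pure count ratios (used where exact
hand-counted values are asserted), at the price of failing on
out-of-alphabet symbols.

Tail calls use posterior ≥ τ, default τ = 0.5. The default is
low-stakes: all threshold-dependent results are also swept into full
ROC curves.

Per-morphology models (myoviruses, siphoviruses, podoviruses) are the
same fit run on a morphology-filtered corpus — a corpus filter, not a
model change.

## Module detection

Predicted tail proteins are points on the gene-index axis; distance is
the difference of ordinals (protein spacing), which is insensitive to
protein length. DBSCAN with eps = 6 and minpts = 4 (defaults) labels
points core (≥ minpts points within eps, **the point itself included**
— the common library convention; at the margin this changes core
status, hence stated prominently), border (non-core but within eps of a
core) or outlier. Clusters are maximal density-connected sets, numbered
left to right. A border point reachable from two clusters joins the
cluster discovered first in the left-to-right scan — a deterministic
resolution of DBSCAN's order-dependence. No wrap-around distance on
circular genomes, consistent with the linear treatment in decoding.

A grid-search helper (`tune_params`, eps ∈ 1..10, minpts ∈ 2..8)
scores parameter pairs by agreement with single-module ground truth
(fraction of genomes collapsing to exactly one cluster, or matching a
supplied single-cluster truth table). The objective is this package's
reconstruction of an iterate-until-convergence tuning procedure whose
original objective is not recorded.

The census table reports genomes by morphology and module count using
mutually exclusive categories 0 / 1 / 2 / 3 / 4+ (zero = tail calls too
sparse to form any cluster), with percentages per morphology summing
to 100.

## Evaluation

Per-genome and pooled confusion metrics (TPR, FPR, precision; precision
is NaN when nothing is predicted positive), ROC by sweeping all
distinct score thresholds with trapezoidal AUC — numerically equal to
the Mann–Whitney concordance probability with ties counted ½ —
plus distribution summaries: median per-genome AUC and the fraction of
genomes with TPR = 1, > 0.8, > 0.6. Genomes whose truth contains no
tail protein are excluded from per-genome TPR summaries (scoring them 0
would silently deflate the distribution) but still pool. Pooled ROC
concatenates all proteins; per-genome AUC medians are reported
alongside since either aggregation is defensible.

The subsampling experiment refits on genome subsamples stratified by
morphology (proportions preserved by rounding per stratum, drift
corrected by random pad/trim), evaluates on a fixed holdout, and
reports the TPR-fraction summaries with the min–max tail-vocabulary
size across replicates. All sampling uses one explicit seed recorded in
the output.

## Synthetic data

The generator draws hidden states from the two-state chain (π at each
genome start, A thereafter) and symbols from per-state alphabets with
uniform default weights, replacing the symbol with `NOHIT` at a
per-state rate. Defaults are the study conditions the rest of the
package is exercised under:

| parameter | default | rationale |
|---|---|---|
| π | (0.2039, 0.7961) | start distribution of the reference chain |
| A | rows (0.1712, 0.8288), (0.0203, 0.9797) | reference chain: short tail runs, one switch per ~50 genes |
| genomes × length | 100 × U(30, 80) | typical phage gene counts |
| alphabets | 30 tail / 90 non-tail symbols, uniform | disjoint by construction |
| `NOHIT` rate | 0.3 per state | ≈ fraction of phage proteins with no Pfam hit |

Tail-state products are drawn from keyword-bearing templates
("tail fibre protein", "tape measure protein", …), non-tail from
keyword-free ones, so the keyword labeler recovers the hidden states
exactly and the full real-data path (GenBank → domtbl → labels → fit)
is testable. Fixture writers emit multi-record GenBank, hmmscan
`domtblout` rows (with occasional weaker secondary hits so the
smallest-e-value rule is exercised) and a truth TSV.

What the generator does **not** emulate: nucleotide sequences are
random; domain alphabets are disjoint between states, whereas real tail
and non-tail proteins share domains; emission weights are uniform
rather than long-tailed; no annotation errors, frameshifts or missing
CDS calls. Passing tests therefore demonstrate algorithmic correctness
and internal consistency — recovery of a known generating process — not
field performance on real genomes, where class-overlapping emissions
will lower separability.

## Numerical choices

- Forward–backward in scaled probability space (not log-space); scaling
  is exact and faster for a 2-state chain.
- Posterior normalization enforced per position; model invariants
  (π and A rows sum to 1 within 1e-12, emissions within 1e-9) are
  revalidated on every model load.
- Posteriors printed with 10 significant digits; prediction TSV
  round-trips to printed precision and identical inputs produce
  byte-identical outputs.
- Problem sizes in tests and the acceptance script: path-enumeration
  checks at n ≤ 8 (exact, 2ⁿ paths), parameter recovery at 500 genomes
  × 50 proteins (≈ 1.4 standard errors per ±0.02 on the rarest
  transition row — sampling-error bands in unit tests are therefore
  stated as 4·SE), clustering oracles at n ≤ 200 points.

## Limitations

- Keyword-derived truth is itself imperfect on real data (mislabeled
  hypothetical proteins depress apparent precision); evaluation
  measures agreement with that labeling, not with structural biology.
- One symbol per protein discards multi-domain architecture.
- Strand is recorded but unused; tail modules on opposite strands are
  treated as one neighborhood.
- The two-state chain has geometric run lengths; real tail modules have
  more regular sizes than a geometric distribution implies, which a
  semi-Markov model would capture but this package deliberately does
  not (pure counting training is the point).
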