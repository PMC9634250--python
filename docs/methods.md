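# Methods

This note documents the models, procedures and design choices behind
`tcrbench`, in the order the pipeline runs.

## Data model

A sample is one (peptide, CDR3β[, CDR3α][, MHC][, V/(D)/J alleles]) tuple
with a binary binding label and a provenance tag. A *setting* declares which
fields define tuple identity; the two standard settings are (peptide, cdr3b)
and (peptide, cdr3b, cdr3a, mhc). Sequences are restricted to the 20
standard residues, uppercase; ambiguity codes (B, J, Z, X), O, U and
stop/gap characters are rejected outright, because one bad residue would
otherwise surface later as an encoding error far from its origin. Tables are
pandas-backed with a canonical column set; missing optional values are empty
strings; extra columns (e.g. a source quality score) pass through and can
drive a generic numeric column filter. An optional, default-off
`cdr3_transform` hook on the reader supports CDR3 homogenisation conventions
(e.g. trimming conserved C…F flanks) without asserting any particular rule.

## Dataset assembly

Order: concatenate positives with assay negatives (NA) → length filter →
per-setting deduplication → RN generation from the surviving positives →
final deduplication. The length filter keeps peptides shorter than 16 and
CDR3α/β within 7–21 and 9–23 respectively (α bounds apply only where the
field is populated). Deduplication keys on (identity fields, label), keeps
first occurrences, and treats identity keys seen with *both* labels as
source contradictions; the default policy drops both sides (alternatives:
keep-positive, keep-first). No policy is canonical in the literature;
drop-both is the conservative choice because a contradicted tuple supports
neither label.

**Randomized negatives (RN).** Each negative pairs the peptide block
(peptide + MHC, preserving the pMHC complex) of one positive row with the
TCR block (CDR3α, CDR3β and gene alleles) of another positive. Sampling is
with replacement, rejection-filtered against (a) sharing (peptide, cdr3b)
with any positive — that pair might genuinely bind — and (b) duplicates
under the table's setting; the draw budget is capped at 50× the target
before a shortfall is declared, and the target is round(ratio × positives)
with ratio defaulting to 2. Two deliberate choices:

- *Pairing.* Default `joint` keeps the whole TCR block from a single donor,
  preserving real α/β chain pairing; `independent` (chains from separate
  donors) is provided because the construction is described ambiguously
  across sources.
- *Donor weighting.* The peptide block is drawn uniformly over positive
  *rows*, so frequent epitopes receive proportionally many negatives. The
  TCR block is drawn uniformly over unique TCR *clonotypes*, not rows: a
  clonotype is one receptor however many database entries it has. This also
  has a statistical consequence we verified empirically: row-weighted TCR
  donors make a CDR3's appearance rate among negatives proportional to its
  positive count, which turns CDR3-identity memorization into a strongly
  *anti*-predictive signal on hard-split test sets (memorization-oracle
  AUROC ≈ 0.24 in our pilot) and pushes trained models visibly below chance
  on unseen peptides. Clonotype-uniform donors keep negative appearance
  rates independent of positive counts, and near-chance behaviour means
  chance.

RN negatives are *presumed* non-binding; a small false-negative rate is
inherent to the construction and is part of what the benchmark measures.

## Splits

**Random split (RS).** round(test_frac × n) rows drawn uniformly without
replacement (default 20%).

**Hard split (HS).** Let P_{l,u} be the peptides occurring in at least l and
at most u rows of the supplied table. Peptides are drawn uniformly without
replacement from P_{l,u}; all rows of each drawn peptide go to the test set;
the loop stops at the first draw where the test set reaches min_test_frac
(default 0.15) of the rows — the budget is a floor, so the achieved fraction
can overshoot. If P_{l,u} exhausts first the result carries an `underfilled`
flag. Reference eligibility bounds: l=500, u=10,000 for (peptide, cdr3b);
l=100, u=5,000 for the paired+MHC setting — l guarantees enough TCR variety
per test peptide, u stops one peptide from saturating the budget. P_{l,u} is
materialised in lexicographic order before seeded shuffling so splits are
platform-independent. The table handed to `hard_split` defines the scope;
for RN-negative experiments the caller passes positives + RN negatives only.
The audit reports shared peptides (must be 0 for HS), shared CDR3α/β counts
(informational — HS deliberately permits TCR overlap), the achieved test
fraction, and per-test-peptide class counts.

## Diagnostics

The class histogram counts positive/negative occurrences per unique sequence
of one field. The disjointness fraction is the share of unique sequences
seen in both classes: 0 on pure-NA data (the memorization regime), positive
on RN data (recombination reuses positive CDR3s). The memorization oracle
scores a test row as (pos_train(seq) + α·π) / (total_train(seq) + α) with
pseudo-count α=1 and π the training positive rate; unseen sequences score
exactly π. Laplace smoothing toward the prior keeps the oracle defined on
unseen sequences and avoids degenerate score ties at 0/1. The oracle never
reads the peptide column, so its AUROC is a pure leakage ceiling to report
next to any model.

## Encoding and baseline

Residues are encoded as their BLOSUM50 substitution-score vectors against
the 20 residues in fixed alphabetical order (matrix via Biopython);
sequences are right-padded with constant rows to per-field maxima (15 / 23 /
21 / 34 for peptide / CDR3β / CDR3α / MHC pseudo-sequence) that mirror the
length-filter bounds, so no post-filter sequence overflows. MHC
pseudo-sequences come from a user-supplied allele→sequence table; class I
and II are treated identically and no convention is asserted.

The baseline is a one-hidden-layer feed-forward network (default width 128,
ReLU, sigmoid output) trained with Adam (lr 10⁻³, batch 256, weight decay
10⁻⁴) on binary cross-entropy, in float32, fully seeded. Its input is the
flattened concatenated encodings (scaled by 1/5) plus the 15×23 peptide ×
CDR3β similarity map — the pairwise inner products of position encodings,
scaled to the same numeric footing (1/4). The two feature families play
distinct roles: flattened encodings let the model memorize sequence
identities and per-peptide rules (the leakage channels under study), while
the similarity map is the standard interaction-prediction inductive bias
that makes *pairing* rules expressible in a way that transfers across
peptides. Without it, a network this small provably prefers per-peptide
lookup and no transferable rule is learnable from ~17 training peptides; the
scale matters because a much smaller similarity signal trains too slowly to
compete with memorization.

Training carves a stratified validation split (default 20%) from the
provided training table; after every epoch the validation AUROC is computed
and the weights of the best epoch are kept (ties → earlier epoch). Early
stopping (patience 20 epochs without a new best) only shortens training —
selection is unaffected. Thresholded metrics use a fixed 0.5 cut.

## Evaluation

AUROC is the Mann–Whitney probability that a random positive outscores a
random negative with ties counted ½; AUPR is the step-wise non-interpolated
integral (both via scikit-learn, cross-checked in the tests against a
brute-force pairwise oracle on exhaustive short vectors). Per-peptide AUROC
is computed within each test peptide's rows; peptides with one class present
are reported as missing and excluded from averages. Aggregation over
repeated splits reports the arithmetic mean and *population* standard
deviation, with k recorded so the sample version is recoverable.

## Synthetic data

The generator reproduces the statistical structure the benchmark's findings
rest on, and nothing else — no V(D)J recombination statistics, positional
amino-acid bias, or MHC allele frequencies. Peptide positive counts follow a
Pareto law (shape 1.5 — heavy-tailed, matching rank-frequency curves of real
epitope data; the exact exponent is not critical and is configurable)
clipped to [count_min, count_max]; sequences are uniform random strings,
unique within their pools; per-peptide CDR3s are drawn without replacement
from a shared pool (reuse across peptides creates the multi-peptide TCRs
real data contains). All randomness derives from one seed; identical configs
produce byte-identical CSVs.

Two ground-truth binding rules:

- **Idiosyncratic** — each peptide gets, via a salted hash of the peptide
  alone, a random CDR3 position and a random 5-of-20 residue set; the pair
  binds iff that position carries an allowed residue (satisfaction rate
  q = 0.25). Within a peptide the rule is deterministic and learnable from a
  few hundred examples; across peptides the predicates are independent, so
  the expected AUROC of *any* scorer on an unseen peptide is 0.5. This makes
  the random-split/hard-split contrast sharp: the baseline reaches ≈0.86
  AUROC under RS (per-peptide rules + memorization) and ≈0.47 under HS.
- **Motif** — the binding CDR3 carries the peptide's own first k residues
  (k=3) at a fixed anchor (position 3): a single global mimicry rule,
  transferable to unseen peptides by construction. `motif_strength` (default
  0.9) is the fraction of positives that actually carry their motif.

Both are *pairing* rules by necessity: under RN negatives, any rule
depending on the CDR3 alone is information-free, because recombined
negatives reuse the positive rows' CDR3s and therefore contain any CDR3-only
motif at the same rate as the positives. What recombination destroys — and
what a detectable rule must therefore use — is peptide/CDR3 consistency.

Negative modes: `RN_style` calls the production RN generator (the generator
doubles as an integration test of the builder); `NA_style` draws negatives
from a CDR3 pool disjoint from the positives', giving disjointness 0 by
construction.

## Study conditions and problem sizes

- *Generalization-failure / sensitivity experiments* (defaults): 20
  peptides, positive counts in [300, 1200], CDR3 pool 6000, RN ratio 2 —
  ≈27–43k rows; hard splits at min_test_frac 0.15 with l=100, u=5000 (the
  paired-setting bounds, appropriate for per-peptide totals of ≈900–3600);
  5 splits with seeds 0–4; baseline capped at 200 epochs with patience 20.
  Measured: idiosyncratic mean test AUROC ≈ 0.47 (per-seed 0.45–0.50), motif
  (strength 0.9) mean ≈ 0.88 — the harness separates absent from present
  transfer by a wide margin.
- *Memorization experiment*: NA-style, 20 peptides, counts [100, 400], CDR3
  pool 800 (≈9–12k rows). The small pool gives each CDR3 a multiplicity of
  ≈4–8, so ≳95% of test CDR3βs are seen in training — the regime in which
  the memorization claim applies; oracle test AUROC ≈ 1.0 under RS 80/20.

These sizes were chosen once as the package's reference conditions: large
enough that every peptide is hard-split eligible and AUROC estimates are
stable to a few points, small enough to run on a single CPU in minutes.

## What passing tests do and do not show

The synthetic generators demonstrate mechanisms, not biology: passing tests
show that the pipeline's guarantees hold (no peptide leakage under HS, RN
contract, metric definitions) and that the leakage phenomena are real
consequences of benchmark *structure* — they do not show that any particular
real model memorizes, nor how much transferable signal real TCR data
contains. Real CDR3s are not uniform random strings, real binding rules are
neither perfectly idiosyncratic nor single-motif, and real negatives mix
assay artefacts the generator does not model.

## Known limitations

- The baseline is a deliberately small probe, not a competitive predictor;
  its absolute scores matter only relative to the oracle and to chance.
- RN generation at scale uses rejection sampling; for pathological inputs
  (near-complete positive bipartite graphs) it declares shortfall rather
  than enumerating the exact feasible set.
- The hard split groups by peptide only; TCR-wise or MHC-wise grouping is
  out of scope, and test TCRs may be seen in training by design.
- Contradictory-label handling, RN pairing mode and the CDR3 homogenisation
  hook are configurable because no canonical convention exists; defaults are
  stated above.
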