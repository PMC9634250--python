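# tcrbench

Benchmark construction and leakage diagnosis for TCR–peptide/-pMHC binding
prediction.

## The problem

T-cell receptors (TCRs) recognise peptides presented by MHC molecules,
primarily through the CDR3 loops of their α and β chains. Supervised models
that predict whether a (peptide, CDR3β[, CDR3α, MHC]) tuple binds routinely
report excellent test AUROC — and routinely owe it to how their benchmarks
are built rather than to learned binding rules. Two failure modes dominate:

1. **Class-disjoint CDR3 pools.** When negatives come from assays (the *NA*
   set), each CDR3 sequence occurs in only one class. A model can then
   classify test tuples by memorizing CDR3 identities, ignoring the peptide
   entirely.
2. **Peptide leakage under random splits.** A random split keeps test
   *tuples* unseen, but test *peptides* almost always occur in training
   paired with other TCRs. Performance on such test sets says nothing about
   unseen peptides — the case that matters for neoantigen applications.

`tcrbench` packages the machinery to build such benchmarks honestly and to
measure both failure modes:

- **Dataset assembly** — sequence validation, length filtration (peptide
  < 16, CDR3α 7–21, CDR3β 9–23), per-setting deduplication, and *randomized
  negative* (RN) generation: negatives are recombinations of positive tuples
  (a peptide/pMHC from one binding tuple, a TCR clonotype from another), at
  2× the positive count, never colliding with a known positive
  (peptide, CDR3β).
- **Splits** — the random split (RS) and the **hard split** (HS): sample
  peptides without replacement from P<sub>l,u</sub> = {peptides observed in
  between *l* and *u* tuples}, move *all* of each sampled peptide's rows to
  the test set, stop once a minimum test fraction (default 15%) is reached.
  Test peptides are then provably unseen at training time; an audit verifies
  the guarantee and quantifies the CDR3 overlap that HS deliberately allows.
- **Diagnostics** — per-sequence class histograms, a class-disjointness
  fraction, and a **memorization oracle**: score(row) =
  (pos<sub>train</sub>(cdr3) + απ) / (total<sub>train</sub>(cdr3) + α), the
  executable ceiling for peptide-blind classification.
- **Encoding + baseline** — BLOSUM50 encodings (right-padded, fixed
  alphabetical residue order), optional MHC pseudo-sequence attachment, and a
  small feed-forward scorer on flattened encodings plus a peptide × CDR3β
  similarity map, trained with per-epoch validation-AUROC model selection.
- **Evaluation** — AUROC (Mann–Whitney, ties ½), AUPR (step integral), F1,
  precision, recall, accuracy at a 0.5 threshold, per-peptide AUROC, and
  mean ± population-std aggregation over repeated splits.
- **Synthetic data** — seeded generators reproducing the structures above
  (heavy-tailed peptide counts, NA- or RN-style negatives, binding rules that
  are either peptide-idiosyncratic or globally transferable), so every claim
  is testable without downloads.

## Worked example

`python examples/04_generalization_gap.py` trains the baseline on a
synthetic RN-negative dataset whose binding rules are peptide-idiosyncratic
(an independent random predicate per peptide — nothing transfers), then
evaluates under both splits:

```
dataset: 34236 rows (11412 pos / 22824 RN neg)

random 80/20: test AUROC 0.8569, AUPR 0.6893

hard (unseen peptides): test AUROC 0.4972, AUPR 0.3317
  per-test-peptide AUROC (n=3): mean 0.5021
```

The 0.86 → 0.50 collapse is the leakage gap: under the random split the
model exploits peptide familiarity; on genuinely unseen peptides it has
nothing left. `examples/03_memorization_oracle.py` shows the complementary
phenomenon — on NA-style (class-disjoint) data the peptide-blind oracle
alone reaches test AUROC 1.00 under a random 80/20 split. The other examples
demonstrate dataset assembly and split audits; each prints a short
interpretation of its numbers.

A thin CLI mirrors the library (`tcrbench build / split / diagnose /
diagnose-oracle / simulate / train-baseline / score / evaluate /
aggregate`); run any subcommand with `--help`.

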