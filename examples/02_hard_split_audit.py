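"""Random vs hard train/test splits, with leakage audits.

Generates a synthetic dataset with heavy-tailed peptide counts, applies both
split strategies, and prints their audits. The random split shares most
peptides across train and test (the leakage channel); the hard split shares
none, by construction, while still allowing TCR overlap.
"""

from tcrbench import (
    HardSplitConfig,
    SynthConfig,
    audit_split,
    eligible_test_peptides,
    generate_dataset,
    hard_split,
    random_split,
)

table, _ = generate_dataset(
    SynthConfig(n_peptides=12, count_min=60, count_max=400, n_cdr3_pool=2000, seed=0)
)
print(f"dataset: {len(table)} rows, {table.n_pos} positive / {table.n_neg} negative")

eligible = eligible_test_peptides(table, l=100, u=2000)
print(f"eligible test peptides (100 <= count <= 2000): {len(eligible)}")

rs = random_split(table, test_frac=0.2, seed=0)
rs_audit = audit_split(table, rs)
print(
    f"\nrandom split   : test fraction {rs_audit.test_fraction:.3f}, "
    f"{rs_audit.n_shared_peptides} peptides and "
    f"{rs_audit.n_shared_cdr3b} CDR3β shared across train/test"
)

hs = hard_split(table, HardSplitConfig(min_test_frac=0.15, l=100, u=2000, seed=0))
hs_audit = audit_split(table, hs)
print(
    f"hard split     : test fraction {hs_audit.test_fraction:.3f}, "
    f"{hs_audit.n_shared_peptides} peptides and "
    f"{hs_audit.n_shared_cdr3b} CDR3β shared across train/test"
)
print(f"held-out test peptides: {hs.test_peptides}")
print("\nper-test-peptide composition:")
print(hs_audit.per_test_peptide.to_string(index=False))
print(
    "\nThe hard split guarantees zero peptide sharing (its whole point); "
    "CDR3 sharing remains\nallowed, so only peptide novelty is tested."
)
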