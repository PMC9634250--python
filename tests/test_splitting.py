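"""Random split, hard split, and the no-shared-peptide guarantee."""

import numpy as np
import pandas as pd
import pytest

from tcrbench import PEP_CDR3B, SampleTable
from tcrbench.exceptions import ConfigError, NoEligiblePeptidesError
from tcrbench.splitting import (
    HardSplitConfig,
    audit_split,
    eligible_test_peptides,
    hard_split,
    random_split,
)

from conftest import random_table


def _counted_table(counts: dict[str, int]) -> SampleTable:
    """One row per count, globally unique CDR3s, alternating labels."""
    aas = "ACDEFGHIKLMNPQRSTVWY"
    rows = []
    j = 0
    for pep, n in counts.items():
        for _ in range(n):
            lab = j % 2
            rows.append(
                {
                    "peptide": pep,
                    "cdr3b": f"CA{aas[j % 20]}{aas[(j // 20) % 20]}SSF" + "A" * (j % 7 + 3),
                    "label": lab,
                    "negative_origin": "" if lab else "NA",
                }
            )
            j += 1
    return SampleTable(pd.DataFrame(rows), PEP_CDR3B)


class TestRandomSplit:
    def test_sizes_and_determinism(self):
        rng = np.random.default_rng(0)
        t = random_table(rng, n_peptides=10, max_count=15)
        n = len(t)
        a = random_split(t, 0.2, seed=3)
        b = random_split(t, 0.2, seed=3)
        c = random_split(t, 0.2, seed=4)
        assert len(a.test_indices) == round(0.2 * n)
        assert np.array_equal(a.test_indices, b.test_indices)
        assert not np.array_equal(a.test_indices, c.test_indices)
        assert a.method == "RS" and a.test_peptides == []

    def test_partition(self):
        rng = np.random.default_rng(1)
        t = random_table(rng)
        s = random_split(t, 0.3, seed=0)
        merged = np.sort(np.concatenate([s.train_indices, s.test_indices]))
        assert np.array_equal(merged, np.arange(len(t)))

    @pytest.mark.parametrize("frac", [0.0, 1.0])
    def test_degenerate_fraction_rejected(self, frac):
        rng = np.random.default_rng(2)
        t = random_table(rng)
        with pytest.raises(ValueError):
            random_split(t, frac, seed=0)


class TestEligiblePeptides:
    def test_window(self):
        t = _counted_table({"AAAAAAAAA": 3, "CCCCCCCCC": 5, "DDDDDDDDD": 12})
        assert eligible_test_peptides(t, 4, 10) == {"CCCCCCCCC"}

    def test_unbounded_u_includes_all(self):
        t = _counted_table({"AAAAAAAAA": 3, "CCCCCCCCC": 5})
        assert eligible_test_peptides(t, 1, np.inf) == {"AAAAAAAAA", "CCCCCCCCC"}

    def test_empty_table(self):
        assert eligible_test_peptides(SampleTable.empty(), 1, 10) == set()


class TestHardSplit:
    def test_toy_budget_met_by_first_peptide(self):
        t = _counted_table({"AAAAAAAAA": 10, "CCCCCCCCC": 10, "DDDDDDDDD": 10})
        res = hard_split(t, HardSplitConfig(min_test_frac=0.15, l=5, u=15, seed=0))
        # budget is 4.5 rows; any single sampled peptide contributes 10
        assert len(res.test_peptides) == 1
        assert len(res.test_indices) == 10
        assert len(res.train_indices) == 20
        assert not res.underfilled

    def test_minimum_budget_may_be_exceeded(self):
        t = _counted_table({"AAAAAAAAA": 10, "CCCCCCCCC": 10})
        res = hard_split(t, HardSplitConfig(min_test_frac=0.05, l=1, u=100, seed=0))
        assert len(res.test_indices) == 10  # one whole peptide, 50% > 5%

    def test_no_eligible_peptides(self):
        t = _counted_table({"AAAAAAAAA": 3})
        with pytest.raises(NoEligiblePeptidesError):
            hard_split(t, HardSplitConfig(min_test_frac=0.15, l=5, u=10, seed=0))

    def test_underfill_flag(self):
        t = _counted_table({"AAAAAAAAA": 2, "CCCCCCCCC": 50})
        res = hard_split(t, HardSplitConfig(min_test_frac=0.5, l=1, u=10, seed=0))
        assert res.underfilled
        assert res.test_peptides == ["AAAAAAAAA"]

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            HardSplitConfig(min_test_frac=0.15, l=5, u=4)

    def test_guarantee_and_membership_over_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            t = random_table(rng, n_peptides=int(rng.integers(3, 10)))
            counts = t.df["peptide"].value_counts()
            l, u = 1, int(counts.max())
            res = hard_split(
                t, HardSplitConfig(min_test_frac=0.2, l=l, u=u, seed=int(rng.integers(1e6)))
            )
            train_peps = set(t.df.iloc[res.train_indices]["peptide"])
            test_peps = set(t.df.iloc[res.test_indices]["peptide"])
            assert not (train_peps & test_peps)
            assert test_peps == set(res.test_peptides)
            eligible = eligible_test_peptides(t, l, u)
            assert set(res.test_peptides) <= eligible
            if not res.underfilled:
                assert res.test_fraction >= 0.2

    def test_distinct_seeds_give_distinct_test_sets(self):
        rng = np.random.default_rng(7)
        t = random_table(rng, n_peptides=40, max_count=6)
        lists = [
            tuple(sorted(hard_split(t, HardSplitConfig(0.1, 1, 50, seed=s)).test_peptides))
            for s in range(5)
        ]
        assert len(set(lists)) == 5


class TestAudit:
    def test_hard_split_audit_reports_zero_shared(self):
        rng = np.random.default_rng(8)
        t = random_table(rng, n_peptides=6)
        res = hard_split(t, HardSplitConfig(0.2, 1, 1000, seed=0))
        audit = audit_split(t, res)
        assert audit.n_shared_peptides == 0
        assert audit.test_fraction == res.test_fraction
        assert set(audit.per_test_peptide["peptide"]) == set(res.test_peptides)

    def test_random_split_usually_shares_peptides(self):
        # every peptide occurs many times, so a 40% test set almost surely
        # splits some peptide across both sides
        t = _counted_table({"AAAAAAAAA": 20, "CCCCCCCCC": 20, "DDDDDDDDD": 20})
        shared = 0
        for seed in range(100):
            res = random_split(t, 0.4, seed=seed)
            shared += audit_split(t, res).n_shared_peptides > 0
        assert shared >= 95

    def test_informational_cdr3_overlap_allowed_for_hs(self):
        # same CDR3 paired with two peptides: HS keeps peptides disjoint but
        # may share the TCR across sides (by design)
        df = pd.DataFrame(
            {
                "peptide": ["AAAAAAAAA"] * 2 + ["CCCCCCCCC"] * 2,
                "cdr3b": ["CASSSHAREDF", "CASSOTHERWF"] * 2,
                "label": [1, 0, 1, 0],
                "negative_origin": ["", "RN"] * 2,
            }
        )
        t = SampleTable(df, PEP_CDR3B)
        res = hard_split(t, HardSplitConfig(0.3, 1, 10, seed=0))
        audit = audit_split(t, res)
        assert audit.n_shared_peptides == 0
        assert audit.n_shared_cdr3b == 2

    def test_invalid_indices_raise(self, tiny_table):
        res = random_split(tiny_table, 1 / 3, seed=0)
        res.test_indices = np.array([5])
        with pytest.raises(IndexError):
            audit_split(tiny_table, res)
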