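"""Length filtration, deduplication and RN negative generation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tcrbench import PEP_CDR3B, SampleTable
from tcrbench.builder import (
    LengthFilterConfig,
    RNConfig,
    assemble_dataset,
    deduplicate,
    filter_by_column,
    filter_by_length,
    generate_rn_negatives,
)
from tcrbench.exceptions import ConfigError, EmptyPositivesError

from conftest import random_table


def _table(rows):
    return SampleTable(pd.DataFrame(rows), PEP_CDR3B)


def _pos(pep, cdr3b, **kw):
    return {"peptide": pep, "cdr3b": cdr3b, "label": 1, **kw}


class TestLengthFilter:
    def test_boundaries_enumerated(self):
        # peptide lengths {9, 15, 16} x cdr3b lengths {8, 9, 23, 24}:
        # keep iff len(pep) < 16 and 9 <= len(cdr3b) <= 23
        peps = {n: "A" * n for n in (9, 15, 16)}
        cdrs = {n: "C" * n for n in (8, 9, 23, 24)}
        rows = [_pos(peps[p], cdrs[c]) for p, c in itertools.product(peps, cdrs)]
        out = filter_by_length(_table(rows))
        expected = {(p, c) for p, c in itertools.product((9, 15), (9, 23))}
        got = {(len(r["peptide"]), len(r["cdr3b"])) for _, r in out.df.iterrows()}
        assert got == expected
        assert len(out) == 4

    def test_cdr3a_bounds_only_when_present(self):
        rows = [
            _pos("A" * 9, "C" * 12, cdr3a=""),  # absent alpha: kept
            _pos("A" * 9, "C" * 12, cdr3a="D" * 6),  # too short: dropped
            _pos("A" * 9, "C" * 12, cdr3a="D" * 21),  # at bound: kept
        ]
        out = filter_by_length(_table(rows))
        assert list(out.df["cdr3a"]) == ["", "D" * 21]

    def test_empty_table(self):
        assert len(filter_by_length(SampleTable.empty())) == 0

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(0)
        t = random_table(rng)
        once = filter_by_length(t)
        twice = filter_by_length(once)
        assert once == twice
        # order preserved: surviving rows appear in original relative order
        orig = list(t.df["cdr3b"])
        kept = list(once.df["cdr3b"])
        it = iter(orig)
        assert all(any(x == k for x in it) for k in kept)

    def test_invalid_bounds(self):
        with pytest.raises(ConfigError):
            LengthFilterConfig(cdr3b_min=10, cdr3b_max=9)


class TestDeduplicate:
    def test_cross_source_duplicates_collapse(self):
        rows = [
            _pos("AAAAAAAAA", "CCCCCCCCCC", source="vdjdb"),
            _pos("AAAAAAAAA", "CCCCCCCCCC", source="iedb"),
        ]
        out, report = deduplicate(_table(rows))
        assert len(out) == 1
        assert out.df["source"].iloc[0] == "vdjdb"  # first occurrence kept
        assert report.n_duplicates_removed == 1

    def test_conflict_drop_policy(self):
        rows = [
            _pos("AAAAAAAAA", "CCCCCCCCCC"),
            {"peptide": "AAAAAAAAA", "cdr3b": "CCCCCCCCCC", "label": 0, "negative_origin": "NA"},
            _pos("DDDDDDDDD", "EEEEEEEEEE"),
        ]
        out, report = deduplicate(_table(rows), conflict_policy="drop")
        assert report.n_conflict_keys == 1
        assert len(out) == 1 and out.df["peptide"].iloc[0] == "DDDDDDDDD"

    @pytest.mark.parametrize(
        "policy,expected_labels", [("keep_positive", [1]), ("keep_first", [1])]
    )
    def test_conflict_alternatives(self, policy, expected_labels):
        rows = [
            _pos("AAAAAAAAA", "CCCCCCCCCC"),
            {"peptide": "AAAAAAAAA", "cdr3b": "CCCCCCCCCC", "label": 0, "negative_origin": "NA"},
        ]
        out, _ = deduplicate(_table(rows), conflict_policy=policy)
        assert list(out.df["label"]) == expected_labels

    def test_empty_and_idempotent(self):
        out, _ = deduplicate(SampleTable.empty())
        assert len(out) == 0
        rng = np.random.default_rng(1)
        t = random_table(rng)
        once, _ = deduplicate(t)
        twice, rep = deduplicate(once)
        assert once == twice and rep.n_duplicates_removed == 0


class TestRNNegatives:
    def test_target_count_and_no_collisions(self):
        rng = np.random.default_rng(2)
        peps = ["".join(rng.choice(list("ACDEFGHIK"), size=9)) for _ in range(10)]
        rows = [
            _pos(p, "".join(rng.choice(list("LMNPQRSTV"), size=12)))
            for p in peps
            for _ in range(10)
        ]
        positives = _table(rows)
        negs, report = generate_rn_negatives(positives, RNConfig(ratio=2, seed=0))
        assert report.target == 200
        assert len(negs) == 200 and not report.shortfall
        pos_pairs = set(zip(positives.df["peptide"], positives.df["cdr3b"]))
        neg_pairs = set(zip(negs.df["peptide"], negs.df["cdr3b"]))
        assert not (pos_pairs & neg_pairs)
        assert len(neg_pairs) == 200  # unique under the setting
        assert (negs.df["label"] == 0).all()
        assert (negs.df["negative_origin"] == "RN").all()

    def test_two_positive_exhaustive_case(self):
        # brute force: of the 4 peptide x CDR3 combinations, only the two
        # mismatches are feasible
        positives = _table([_pos("AAAAAAAAA", "C" * 10), _pos("DDDDDDDDD", "E" * 10)])
        negs, report = generate_rn_negatives(positives, RNConfig(ratio=2, seed=7))
        assert report.target == 4 and report.shortfall
        got = set(zip(negs.df["peptide"], negs.df["cdr3b"]))
        assert got == {("AAAAAAAAA", "E" * 10), ("DDDDDDDDD", "C" * 10)}

    def test_single_positive_no_mismatch_exists(self):
        positives = _table([_pos("AAAAAAAAA", "C" * 10)])
        negs, report = generate_rn_negatives(positives, RNConfig(ratio=2, seed=0))
        assert len(negs) == 0 and report.shortfall

    def test_empty_positives(self):
        with pytest.raises(EmptyPositivesError):
            generate_rn_negatives(SampleTable.empty(), RNConfig())

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        positives, _ = deduplicate(random_table(rng, p_pos=1.0))
        a, _ = generate_rn_negatives(positives, RNConfig(ratio=1.5, seed=11))
        b, _ = generate_rn_negatives(positives, RNConfig(ratio=1.5, seed=11))
        c, _ = generate_rn_negatives(positives, RNConfig(ratio=1.5, seed=12))
        assert a == b
        assert a != c

    def test_recombination_never_invents_sequences(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            positives, _ = deduplicate(random_table(rng, n_peptides=4, p_pos=1.0))
            negs, _ = generate_rn_negatives(positives, RNConfig(ratio=2, seed=seed))
            assert set(negs.df["cdr3b"]) <= set(positives.df["cdr3b"])
            assert set(negs.df["peptide"]) <= set(positives.df["peptide"])


class TestAssemble:
    def test_rn_target_uses_post_filter_positives(self):
        # one positive is removed by the length filter; RN target = 2 x survivors
        keep = [_pos("A" * 9, f"{'C' * 11}{aa}") for aa in "DEFGHIKLMN"]
        dropped = _pos("A" * 16, "C" * 12)
        table, report = assemble_dataset(
            _table(keep + [dropped]), rn_cfg=RNConfig(ratio=2, seed=0)
        )
        assert report.n_after_length_filter == 10
        assert report.rn.target == 20
        assert table.n_pos == 10

    def test_na_annotation_and_union(self):
        pos = _table([_pos("A" * 9, "C" * 12)])
        na = _table(
            [{"peptide": "A" * 9, "cdr3b": "D" * 12, "label": 0}]
        )
        table, report = assemble_dataset(pos, na_negatives=na)
        assert len(table) == 2
        assert set(table.negatives().df["negative_origin"]) == {"NA"}
        assert table.negative_scope() == "NA"

    def test_negative_subsets_recoverable(self):
        rng = np.random.default_rng(4)
        pos, _ = deduplicate(random_table(rng, p_pos=1.0))
        na = _table(
            [
                {"peptide": p, "cdr3b": "W" * 13, "label": 0}
                for p in pos.df["peptide"].unique()
            ]
        )
        table, report = assemble_dataset(pos, na_negatives=na, rn_cfg=RNConfig(ratio=1, seed=0))
        assert len(table.negatives("RN")) == report.rn.n_generated
        assert len(table.negatives("NA")) == len(na)
        assert table.negative_scope() == "RN+NA"


class TestColumnFilter:
    def test_quality_score_threshold(self):
        df = pd.DataFrame(
            {
                "peptide": ["A" * 9] * 3,
                "cdr3b": ["C" * 12, "D" * 12, "E" * 12],
                "label": [1, 1, 1],
                "score": ["2", "0", ""],
            }
        )
        out = filter_by_column(SampleTable(df, PEP_CDR3B), "score", 1)
        assert list(out.df["cdr3b"]) == ["C" * 12]
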