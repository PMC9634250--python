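import numpy as np
import pandas as pd
import pytest

from tcrbench import PEP_CDR3B, SampleTable


@pytest.fixture
def tiny_table() -> SampleTable:
    """Three valid rows, two peptides, both classes."""
    return SampleTable(
        pd.DataFrame(
            {
                "peptide": ["NLVPMVATV", "NLVPMVATV", "GILGFVFTL"],
                "cdr3b": ["CASSIRSSYEQYF", "CASSLAPGATNEKLFF", "CASSIRSSYEQYF"],
                "label": [1, 0, 1],
                "negative_origin": ["", "NA", ""],
            }
        ),
        PEP_CDR3B,
    )


def random_table(rng, n_peptides=8, max_count=12, p_pos=0.5) -> SampleTable:
    """Small random but valid table for property checks."""
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    peptides = [
        "".join(rng.choice(aas, size=rng.integers(8, 12))) for _ in range(n_peptides)
    ]
    rows = []
    for pep in peptides:
        for _ in range(int(rng.integers(1, max_count + 1))):
            cdr3 = "".join(rng.choice(aas, size=rng.integers(10, 16)))
            lab = int(rng.random() < p_pos)
            rows.append(
                {
                    "peptide": pep,
                    "cdr3b": cdr3,
                    "label": lab,
                    "negative_origin": "" if lab else "NA",
                }
            )
    return SampleTable(pd.DataFrame(rows), PEP_CDR3B)
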