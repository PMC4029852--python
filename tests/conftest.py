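import numpy as np
import pandas as pd
import pytest

from co2prof import ExpressionMatrix


def matrix_from_groups(gene_values: dict[str, list[list[float]]],
                       conditions=("T0", "T1", "T2")) -> ExpressionMatrix:
    """Build an ExpressionMatrix from per-gene lists of per-condition log2
    replicate values (signals are 2**value, so the analysis log2 recovers
    the inputs exactly)."""
    n_reps = len(next(iter(gene_values.values()))[0])
    sample_ids = [f"{c}_r{r + 1}" for c in conditions for r in range(n_reps)]
    rows = {
        g: [2.0 ** v for group in groups for v in group]
        for g, groups in gene_values.items()
    }
    signals = pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)
    return ExpressionMatrix(
        signals=signals,
        condition_of_sample={s: s.split("_")[0] for s in sample_ids},
        condition_order=list(conditions),
        replicate_of_sample={s: int(s.rsplit("_r", 1)[1]) for s in sample_ids},
    )


@pytest.fixture
def hand_matrix() -> ExpressionMatrix:
    """One gene with log2 replicate groups {1,2,3}, {2,3,4}, {3,4,5}
    (pooled s2 = 1, m = 6, MS_between = 3) plus a flat companion gene."""
    return matrix_from_groups(
        {
            "gene_a": [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]],
            "gene_b": [[5.0, 5.5, 6.0], [5.0, 5.5, 6.0], [5.0, 5.5, 6.0]],
        }
    )


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """2 probes x 6 samples over 3 conditions with 2 replicates each."""
    return matrix_from_groups(
        {
            "p1": [[1.0, 1.5], [2.0, 2.5], [3.0, 3.5]],
            "p2": [[4.0, 4.2], [4.1, 4.3], [4.0, 4.4]],
        }
    )


def random_matrix(rng: np.random.Generator, n_genes: int = 20,
                  conditions=("T0", "T1", "T2"), n_reps: int = 3) -> ExpressionMatrix:
    sample_ids = [f"{c}_r{r + 1}" for c in conditions for r in range(n_reps)]
    signals = pd.DataFrame(
        2.0 ** rng.normal(8.0, 2.0, size=(n_genes, len(sample_ids))),
        index=[f"g{i}" for i in range(n_genes)],
        columns=sample_ids,
    )
    return ExpressionMatrix(
        signals=signals,
        condition_of_sample={s: s.split("_")[0] for s in sample_ids},
        condition_order=list(conditions),
        replicate_of_sample={s: int(s.rsplit("_r", 1)[1]) for s in sample_ids},
    )
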