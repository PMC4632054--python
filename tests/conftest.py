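import numpy as np
import pandas as pd
import pytest

from rilmap import simpop


@pytest.fixture(scope="session")
def small_population():
    """Three 100-cM chromosomes, 30 markers each, 60 F7 RILs."""
    genome = simpop.GenomeModel((100.0, 100.0, 100.0))
    design = simpop.CrossDesign(n_rils=60, final_generation=7)
    truth_df, truth = simpop.simulate_population(
        genome, design, seed=101, markers_per_chrom=30)
    return truth_df, truth


@pytest.fixture(scope="session")
def small_calls(small_population):
    truth_df, truth = small_population
    matrix, support = simpop.emit_call_matrix(
        truth_df, seed=102, return_support=True)
    return matrix, support, truth


def make_matrix(rows: dict[str, str], rils: list[str] | None = None) -> pd.DataFrame:
    """Small marker matrix from call strings, e.g. {"m1": "AABB-"}."""
    n = len(next(iter(rows.values())))
    if rils is None:
        rils = [f"R{i+1:02d}" for i in range(n)]
    data = {m: list(s) for m, s in rows.items()}
    return pd.DataFrame.from_dict(data, orient="index", columns=rils)
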