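import numpy as np
import pandas as pd
import pytest

import bcellsig as b


@pytest.fixture()
def tiny():
    return b.tiny_fixture()


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study shared by read-only tests."""
    cfg = b.SimulationConfig(n_genes=4000, seed=11)
    matrix, annotation, truth = b.simulate_study(cfg)
    compendium, homolog, truth = b.simulate_ligand_compendium(cfg, truth)
    return cfg, matrix, annotation, truth, compendium, homolog


@pytest.fixture(scope="session")
def small_expressed(small_study):
    cfg, matrix, annotation, truth, compendium, homolog = small_study
    return b.filter_expressed(matrix, annotation).matrix


def two_group_annotation(a_ids, b_ids):
    return b.SampleAnnotation.from_groups(
        {**{s: "patient" for s in a_ids}, **{s: "control" for s in b_ids}}
    )


def matrix_from_array(values, prefix="g", symbols=None):
    values = np.asarray(values, float)
    probes = [f"{prefix}{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    sym = pd.Series(symbols, index=probes) if symbols is not None else None
    return b.ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), sym)
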