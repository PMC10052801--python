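"""Shared fixtures. Heavy trained models are session-scoped so that the
unit tests and the acceptance tests measure the same single run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def fixture_smiles_500():
    from ligandgen.experiments import AE_BENCH_SCAFFOLDS
    from ligandgen.synthetic import make_toy_smiles_family
    out = []
    for i, sc in enumerate(AE_BENCH_SCAFFOLDS):
        out += make_toy_smiles_family(sc, 100, 100 + i)
    return out


@pytest.fixture(scope="session")
def small_corpus():
    from ligandgen.synthetic import make_synthetic_corpus
    return make_synthetic_corpus(3, 50, 4, 3.0, 2)


@pytest.fixture(scope="session")
def curation_fixture_table():
    """Six raw rows engineered to leave exactly two survivors.

    Targets A, B, C each hold two rows with activities 1 and 2: the
    activity-1 row sits at the per-target median (label 0, dropped), the
    activity-2 row exceeds it (label 1, kept). C's surviving row carries a
    silicon atom and falls to the uncommon-atom rule.
    """
    return pd.DataFrame({
        "target_id": ["A", "A", "B", "B", "C", "C"],
        "smiles": ["CCO", "CCN", "c1ccccc1", "CCc1ccccc1",
                   "CC(C)O", "C[Si](C)C"],
        "sequence": ["MKTAY", "MKTAY", "GAVLI", "GAVLI", "WFPQS", "WFPQS"],
        "activity": [1.0, 2.0, 1.0, 2.0, 1.0, 2.0],
    })


@pytest.fixture(scope="session")
def masked_lm_run():
    from ligandgen.experiments import masked_lm_benchmark
    return masked_lm_benchmark(seed=0)


@pytest.fixture(scope="session")
def trained_autoencoder(fixture_smiles_500):
    from ligandgen.experiments import autoencoder_benchmark
    return autoencoder_benchmark(seed=0)


@pytest.fixture(scope="session")
def conditional_recovery_run():
    from ligandgen.experiments import conditional_recovery
    return conditional_recovery(seed=0)


@pytest.fixture(scope="session")
def supcon_ablation_run():
    from ligandgen.experiments import supcon_ablation
    return supcon_ablation(seed=0)


@pytest.fixture(scope="session")
def e2e_pipeline(tmp_path_factory):
    from ligandgen.pipeline import RunConfig, run_pipeline
    out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(profile="test", seed=1, out_dir=str(out))
    return run_pipeline(cfg)
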