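"""Shared fixtures: small synthetic cases generated at test time."""

import numpy as np
import pytest

import motifdep as md


@pytest.fixture(scope="session")
def small_case():
    """Width-8 motif, 30 sites, 20 kb genome, one planted (2,5) pair."""
    profile = [1.9, 0.0, 1.9, 0.7, 0.0, 1.9, 0.7, 1.9]
    return md.generate_synthetic_case(
        width=8,
        n_sites=30,
        genome_len=20_000,
        dependency_spec=[md.paired_dependency(2, 5)],
        info_content_target=profile,
        seed=11,
        tf_name="smallTF",
    )


@pytest.fixture(scope="session")
def quick_fit_config():
    return md.FitConfig(n_lambda=10, lambda_min_ratio=0.01, cv_folds=5)


@pytest.fixture(scope="session")
def small_trained(small_case, quick_fit_config):
    genome, sites, truth = small_case
    return md.train_model(sites, genome, fit_config=quick_fit_config, seed=5)


@pytest.fixture
def worked_db():
    """The four-transaction database over positions 2 and 5; every other
    position carries a transaction-unique base so it stays infrequent at
    support 0.5.  Pair structure: (A2,C5), (A2,C5), (A2,G5), (T2,C5)."""
    return md.itemize(["AAACC", "CACGC", "GAGTG", "TTTAC"])
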