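import warnings

import numpy as np
import pandas as pd
import pytest

from castesvm.pipeline import classify_samples, train_caste_classifier
from castesvm.simulate import (SimulationConfig, simulate_dataset,
                               simulate_phenotypes)

SCENARIO_SEEDS = (1, 2, 3, 4, 5)


def toy_counts_samples():
    """2-group toy: 4 genes x 6 samples with all four experimental groups."""
    counts = pd.DataFrame(
        [[10, 12, 0, 1, 5, 6],
         [100, 90, 80, 70, 60, 50],
         [0, 0, 30, 40, 0, 0],
         [1, 2, 3, 4, 5, 6]],
        index=pd.Index([f"g{i}" for i in range(4)], name="gene"),
        columns=["q1", "q2", "w1", "w2", "r1", "r2"],
    )
    samples = pd.DataFrame({
        "sample_id": counts.columns,
        "group": ["queen", "queen", "control_worker", "control_worker",
                  "qr_day3", "qr_day12"],
        "age": [200.0, 210.0, 10.0, 20.0, 15.0, 25.0],
        "ovarian_index": [0.9, 1.0, 0.1, 0.2, 0.4, 0.5],
        "dominance": [1500.0, 1450.0, 1000.0, 1020.0, 1200.0, 1250.0],
        "queenness": [np.nan] * 6,
    }).set_index("sample_id", drop=False)
    return counts, samples


@pytest.fixture
def toy_dataset():
    return toy_counts_samples()


def run_scenario(seed: int, t_age_correlation: float = 0.48) -> dict:
    """The seeded study scenario: 500 genes, 50 planted caste genes at
    |log2FC| = 1.5, 50 disjoint age genes, 26 queens + 12 workers trained,
    10 + 10 fresh holdouts and 58 QR individuals classified."""
    cfg = SimulationConfig(seed=seed, n_queens=36, n_workers=22,
                           t_age_correlation=t_age_correlation)
    ds = simulate_dataset(cfg)
    ds.samples = simulate_phenotypes(ds.truth, noise_sd=0.15, seed=seed,
                                     samples=ds.samples)
    train_ids = [f"Q{i + 1:02d}" for i in range(26)] + \
                [f"W{i + 1:02d}" for i in range(12)]
    hold_q = [f"Q{i + 1:02d}" for i in range(26, 36)]
    hold_w = [f"W{i + 1:02d}" for i in range(12, 22)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trained = train_caste_classifier(
            ds.counts, ds.samples.loc[ds.samples["sample_id"].isin(train_ids)],
            repeats=5, seed=seed)
        qr_report = classify_samples(trained, ds.counts, ds.samples,
                                     subset=["qr_day3", "qr_day12"])
        hold_q_report = classify_samples(trained, ds.counts, ds.samples,
                                         subset=hold_q)
        hold_w_report = classify_samples(trained, ds.counts, ds.samples,
                                         subset=hold_w)
        worker_report = classify_samples(
            trained, ds.counts, ds.samples,
            subset=[f"W{i + 1:02d}" for i in range(12)])
    return {
        "seed": seed,
        "dataset": ds,
        "trained": trained,
        "qr_report": qr_report,
        "holdout_queens": hold_q_report,
        "holdout_workers": hold_w_report,
        "control_workers": worker_report,
    }


@pytest.fixture(scope="session")
def scenario_suite():
    """Fixed 5-seed suite of the study scenario, shared across tests."""
    return [run_scenario(seed) for seed in SCENARIO_SEEDS]


@pytest.fixture(scope="session")
def age_driven_suite():
    """Variant suite where the QR latent state is driven by age alone
    (t-age correlation 0.95, no phenotype effect beyond t)."""
    return [run_scenario(seed, t_age_correlation=0.95)
            for seed in SCENARIO_SEEDS]
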