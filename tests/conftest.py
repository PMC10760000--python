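"""Shared fixtures: one small synthetic cohort reused across test modules.

The cohort is generated at session scope (3,000 probes, 80 reference
samples, 15 replicate pairs, default event rates) so the detection,
reliability and filtering tests all exercise the same realistic data
without re-simulating per test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import semscan as ss

SMALL = dict(n_probes=3000, n_reference=80, n_subjects=15, seed=11)

#: deliberately small tuning grid for tests; the searched knobs are the same
TEST_GRID = {"max_features": ["sqrt"], "max_samples": [0.8], "n_estimators": [150]}


@pytest.fixture(scope="session")
def sim_config() -> ss.SimulationConfig:
    return ss.SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def cohort(sim_config):
    """Reference + stats + replicate pairs + annotation + calls + records."""
    reference, true_class = ss.simulate_reference(sim_config)
    stats = ss.attach_methylation_class(
        ss.compute_reference_stats(reference), seed=sim_config.seed
    )
    sim = ss.simulate_replicate_pairs(sim_config, stats)
    annotation = ss.simulate_annotation(reference.index, seed=sim_config.seed)
    calls_a = ss.detect_sems(sim.betas_a, stats)
    calls_b = ss.detect_sems(sim.betas_b, stats)
    pairs = ss.replicate_pairs(sim.sample_sheet)
    records = ss.classify_records(
        ss.match_replicate_events(
            calls_a, calls_b, sim.betas_a, sim.betas_b, stats, pairs
        )
    )
    return {
        "config": sim_config,
        "reference": reference,
        "true_class": true_class,
        "stats": stats,
        "sim": sim,
        "annotation": annotation,
        "calls_a": calls_a,
        "calls_b": calls_b,
        "pairs": pairs,
        "records": records,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_beta_matrix(rng, n_probes=8, n_samples=5, missing=0.0) -> pd.DataFrame:
    values = rng.random((n_probes, n_samples))
    if missing:
        mask = rng.random(values.shape) < missing
        values = np.where(mask, np.nan, values)
    return pd.DataFrame(
        values,
        index=pd.Index([f"cg{i:05d}" for i in range(n_probes)], name="probe_id"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
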