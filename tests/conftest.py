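import numpy as np
import pytest

from dnadamage import GeneratorConfig, build_conformation
from dnadamage.geometry import ROIParams
from dnadamage.pipeline import RunConfig, run_experiment

LABELS = ("A", "B", "Z")


@pytest.fixture(scope="session")
def roi():
    return ROIParams()


@pytest.fixture(scope="session")
def models(roi):
    return {label: build_conformation(label, roi) for label in LABELS}


@pytest.fixture(scope="session")
def track_runs():
    """Track-mode runs at LET 66.9 keV/um, 100 Gy, 40 replicate seeds x A/B/Z.

    Shared by the clustering-enrichment, DSB-ordering and TSB-ordering tests;
    40 replicates because the per-run site-hit probability is heavy-tailed
    (few primary trajectories per run).
    """
    config = RunConfig(
        conformations=LABELS,
        seeds=tuple(range(40)),
        generator=GeneratorConfig(mode="track", let=66.9, target_dose=100.0),
    )
    return run_experiment(config)


@pytest.fixture(scope="session")
def let_sweep():
    """B-DNA DSB yields across LET {10, 60, 150, 235} keV/um, 10 seeds each."""
    frames = []
    for let in (10.0, 60.0, 150.0, 235.0):
        config = RunConfig(
            conformations=("B",),
            seeds=tuple(range(10)),
            generator=GeneratorConfig(mode="track", let=let, target_dose=100.0),
        )
        frames.append(run_experiment(config))
    import pandas as pd

    return pd.concat(frames, ignore_index=True)


def seed_for(*key) -> int:
    """Deterministic small seed derived from a mixed string/int key."""
    import zlib

    parts = [zlib.crc32(str(k).encode()) for k in key]
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % 2**31)


def rng_for(*key):
    """Deterministic per-test RNG."""
    return np.random.default_rng(seed_for(*key))
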