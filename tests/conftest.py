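import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from polyafrac.data import FractionCountMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def build_matrix(per_library_counts, spikein=None):
    """Assemble a FractionCountMatrix from {library_id: [counts...]}.

    Library ids must look like ``WT_f1_r1`` so condition/fraction/replicate
    can be parsed out.
    """
    counts = pd.DataFrame(per_library_counts)
    n = len(counts)
    counts.index = pd.Index([f"tx{i + 1:03d}" for i in range(n)], name="transcript_id")
    rows = []
    for lib in counts.columns:
        cond, frac, rep = lib.split("_")
        rows.append((cond, int(frac[1:]), int(rep[1:])))
    samples = pd.DataFrame(
        rows,
        index=pd.Index(counts.columns, name="library_id"),
        columns=["condition", "fraction", "replicate"],
    )
    flags = pd.Series(False, index=counts.index)
    if spikein is not None:
        flags.iloc[list(spikein)] = True
    return FractionCountMatrix(counts, samples, flags)


@pytest.fixture(scope="session")
def small_experiment():
    """One modest simulated experiment with targets, shared across tests."""
    from polyafrac.simulate import SimConfig, TailModel, simulate_experiment

    cfg = SimConfig(
        n_transcripts=600,
        target_fraction=0.1,
        seed=42,
        tail_model=TailModel(delta=300.0),
    )
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_results(small_experiment):
    from polyafrac.model import PolyadenylationShiftModel

    return PolyadenylationShiftModel(small_experiment.counts).fit()


def rng(seed=0):
    return np.random.default_rng(seed)
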