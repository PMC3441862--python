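import warnings

import numpy as np
import pandas as pd
import pytest

from cnvintegrate import PipelineConfig, run_pipeline, simulate_cohort
from cnvintegrate.simulate import make_annotation

# small fixtures trip the <100-probe centralization warning by design
warnings.filterwarnings("ignore", message="fewer than 100 probes")

CANONICAL_SEED = 0


@pytest.fixture(scope="session")
def annotation():
    return make_annotation()


@pytest.fixture(scope="session")
def cohort(annotation):
    """Canonical synthetic cohort at study-scale defaults (seed 0)."""
    table, expr, meta, truth = simulate_cohort(seed=CANONICAL_SEED)
    return {"probes": table, "expression": expr, "metadata": meta,
            "truth": truth, "annotation": annotation}


@pytest.fixture(scope="session")
def pipeline_result(cohort):
    """Full pipeline run on the canonical cohort, shared across tests."""
    cfg = PipelineConfig(seed=CANONICAL_SEED)
    return run_pipeline(cohort["probes"], cohort["expression"],
                        cohort["metadata"], cohort["annotation"], cfg)


@pytest.fixture()
def tiny_probe_frame():
    """3-probe, 2-sample probe table frame."""
    return pd.DataFrame({
        "probe_id": ["p1", "p2", "p3"],
        "chromosome": ["1", "1", "2"],
        "start": [100, 200, 100],
        "end": [160, 260, 160],
        "s01": [0.1, 0.2, -0.1],
        "s02": [0.0, 0.05, 0.3],
    })


def random_probe_frame(rng: np.random.Generator, n_probes: int = 50,
                       n_samples: int = 3) -> pd.DataFrame:
    chroms = sorted(rng.choice(["1", "2", "X"], size=n_probes),
                    key=["1", "2", "X"].index)
    starts, counter = [], {}
    for c in chroms:
        counter[c] = counter.get(c, 0) + 1
        starts.append(counter[c] * 1000)
    frame = pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n_probes)],
        "chromosome": chroms,
        "start": starts,
        "end": [s + 60 for s in starts],
    })
    for j in range(n_samples):
        frame[f"s{j:02d}"] = rng.normal(0, 0.3, n_probes)
    return frame
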