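import numpy as np
import pandas as pd
import pytest

from dyadwarp.synthetic_dyads import CouplingSpec, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A 4-dyad study small enough for fast pipeline tests."""
    return simulate_study(
        n_dyads=4, design="exp1", seed=11, spec=CouplingSpec(duration_s=12.0)
    )


@pytest.fixture(scope="session")
def small_sessions(small_study):
    return small_study[0]


@pytest.fixture(scope="session")
def small_session(small_sessions):
    return small_sessions[0]


def make_score_table(
    beta: float,
    sd_dyad: float,
    sd_eps: float,
    n_dyads: int,
    seed: int,
    tasks=("easy_lie", "truth", "difficult_lie", "very_difficult_lie"),
    codes=(1.0, 2.0, 3.0, 4.0),
) -> pd.DataFrame:
    """Score table drawn from the random-intercept generative model."""
    rng = np.random.default_rng(seed)
    rows = []
    for d in range(n_dyads):
        b = rng.normal(scale=sd_dyad)
        for task, code in zip(tasks, codes):
            rows.append(
                {
                    "dyad_id": f"d{d:03d}",
                    "task": task,
                    "aggregate": beta * code + b + rng.normal(scale=sd_eps),
                }
            )
    return pd.DataFrame(rows)
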