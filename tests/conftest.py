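import numpy as np
import pandas as pd
import pytest

from dsindex import TrainingReference, TreeConfig, TreeGroup, simulate_study

# toy reference pinned by the hand-computed oracles:
# controls {1,3,5}, cases {4,6,8}; second variable carries no information
TOY_CONTROLS = [1.0, 3.0, 5.0]
TOY_CASES = [4.0, 6.0, 8.0]


@pytest.fixture
def toy_training() -> TrainingReference:
    return TrainingReference(
        controls=pd.DataFrame({"a": TOY_CONTROLS, "b": [2.0, 2.0, 2.0]}),
        cases=pd.DataFrame({"a": TOY_CASES, "b": [2.0, 2.0, 2.0]}),
    )


@pytest.fixture
def flat_tree() -> TreeConfig:
    return TreeConfig(root=TreeGroup("root", ["a", "b"]))


@pytest.fixture(scope="session")
def default_study():
    """One seeded end-to-end run of the default study design (n = 429)."""
    cohort, model, training = simulate_study(seed=123)
    return cohort, model, training


# ---------------------------------------------------------------------------
# independent brute-force oracles (enumeration; never call the implementation)


def brute_fitness(controls, cases, x: float) -> float:
    """Smoothed error-ratio fitness at cutoff x by direct counting."""
    fn = sum(1 for v in cases if v < x)
    fp = sum(1 for v in controls if v >= x)
    return (fn + 0.5) / (fn + fp + 1.0)


def brute_relevance(controls, cases) -> float:
    """Max Youden index over an exhaustive cutoff scan ("case iff value >= c")."""
    pooled = sorted(set(controls) | set(cases))
    candidates = [pooled[0] - 1.0, pooled[-1] + 1.0]
    candidates += pooled
    candidates += [(a + b) / 2.0 for a, b in zip(pooled, pooled[1:])]
    best = -1.0
    for c in candidates:
        sn = sum(1 for v in cases if v >= c) / len(cases)
        sp = sum(1 for v in controls if v < c) / len(controls)
        best = max(best, sn + sp - 1.0)
    return max(0.0, best)
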