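import numpy as np
import pytest

import fahp


@pytest.fixture(scope="session")
def case():
    """The bundled skidding-system case study."""
    return fahp.case_study()


@pytest.fixture(scope="session")
def goal_judgment(case):
    """Aggregated 3x3 judgment matrix of the goal node."""
    return fahp.aggregate_scores(case.panels["A"])


@pytest.fixture(scope="session")
def goal_consistent(goal_judgment):
    return fahp.to_consistent(goal_judgment)


@pytest.fixture(scope="session")
def random_panels():
    """A batch of random panels across sizes 2..9 (fixed seed)."""
    rng = np.random.default_rng(20260923)
    panels = []
    for _ in range(250):
        n = int(rng.integers(2, 10))
        children = tuple(f"c{k}" for k in range(n))
        config = fahp.FixtureConfig(seed=int(rng.integers(2**31)),
                                    n_experts=int(rng.integers(1, 9)))
        panels.append(fahp.generate_panel("node", children, config,
                                          rng=rng))
    return panels


def all_3x3_judgments():
    """Every complementary 3x3 judgment matrix on the three-scale set."""
    scale = (0.0, 0.5, 1.0)
    out = []
    for a in scale:
        for b in scale:
            for c in scale:
                f = np.array([
                    [0.5, a, b],
                    [1 - a, 0.5, c],
                    [1 - b, 1 - c, 0.5],
                ])
                out.append(fahp.FuzzyJudgmentMatrix(f))
    return out
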