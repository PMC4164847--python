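"""Synthetic fixture generation and the bundled case study.

The generator emulates the data-collection setup the method assumes: a
panel of k experts scoring every unordered child pair of every internal
node on the three-scale {0, 0.5, 1}, over balanced hierarchies of 3-4
levels with 3-9 children per node, plus raw indicator values for a small
set of alternatives.  Scores default to the uniform distribution over the
scale; a consensus skew can be configured to mimic strong-agreement
panels.  Identical seed and config give identical output.

:func:`case_study` returns the bundled forest-harvesting comparison (light
cableway vs. road-cutting skidding) used throughout the documentation and
the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _case_data as _cd
from .errors import ValidationError
from .hierarchy import (
    ExpertPanel,
    Hierarchy,
    IndicatorValueTable,
    build_hierarchy,
)


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic generator.

    ``depth`` counts edges from root to leaf; ``n_children`` bounds the
    per-node child count (inclusive); ``score_probs`` is the expert score
    distribution over (0, 0.5, 1).
    """

    seed: int = 0
    depth: int = 3
    n_children: tuple[int, int] = (3, 9)
    n_experts: int = 7
    n_alternatives: int = 2
    score_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    reverse_fraction: float = 0.1
    graded_fraction: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.n_children
        if not (1 <= lo <= hi):
            raise ValidationError(f"bad child-count range {self.n_children}")
        if self.depth < 1 or self.n_experts < 1 or self.n_alternatives < 2:
            raise ValidationError("depth >= 1, experts >= 1, alternatives >= 2")
        if abs(sum(self.score_probs) - 1.0) > 1e-9:
            raise ValidationError("score_probs must sum to 1")


@dataclass
class FixtureSet:
    """A complete runnable synthetic input set."""

    hierarchy: Hierarchy
    panels: dict[str, ExpertPanel]
    values: IndicatorValueTable
    config: FixtureConfig


def generate_hierarchy(config: FixtureConfig) -> Hierarchy:
    """A balanced random hierarchy with coded node ids (N0, N1, ...)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.n_children
    counter = 0

    def fresh() -> str:
        nonlocal counter
        counter += 1
        return f"N{counter - 1}"

    nodes: dict[str, dict] = {}
    root = fresh()
    frontier = [root]
    for level in range(config.depth):
        next_frontier: list[str] = []
        for nid in frontier:
            k = int(rng.integers(lo, hi + 1))
            children = [fresh() for _ in range(k)]
            nodes[nid] = {"label": f"criterion {nid}", "children": children}
            next_frontier.extend(children)
        frontier = next_frontier
    for nid in frontier:
        u = rng.random()
        if u < config.reverse_fraction:
            direction = "reverse"
        elif u < config.reverse_fraction + config.graded_fraction:
            direction = "graded"
        else:
            direction = "positive"
        nodes[nid] = {"label": f"indicator {nid}", "direction": direction}
    alternatives = tuple(f"alt{i}" for i in range(config.n_alternatives))
    return build_hierarchy(
        {"root": root, "alternatives": list(alternatives), "nodes": nodes}
    )


def generate_panel(
    node_id: str,
    children: tuple[str, ...],
    config: FixtureConfig,
    rng: np.random.Generator | None = None,
) -> ExpertPanel:
    """One random expert panel over the given children."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    scale = np.array([0.0, 0.5, 1.0])
    scores = {
        (a, b): tuple(
            rng.choice(scale, size=config.n_experts, p=config.score_probs)
        )
        for idx, a in enumerate(children)
        for b in children[idx + 1 :]
    }
    return ExpertPanel(node_id=node_id, children=children, scores=scores)


def generate_panels(
    hierarchy: Hierarchy, config: FixtureConfig
) -> dict[str, ExpertPanel]:
    """Random panels covering every internal node (one shared RNG stream)."""
    rng = np.random.default_rng(config.seed)
    return {
        nid: generate_panel(nid, hierarchy[nid].children, config, rng)
        for nid in hierarchy.internal_nodes()
    }


def generate_values(
    hierarchy: Hierarchy, config: FixtureConfig
) -> IndicatorValueTable:
    """Random raw leaf values: graded leaves on [0, 1], others on [0, 100]."""
    rng = np.random.default_rng(config.seed + 1)
    records: dict[tuple[str, str], float] = {}
    for leaf in hierarchy.leaves():
        scale = 1.0 if hierarchy[leaf].direction == "graded" else 100.0
        for alt in hierarchy.alternatives:
            records[(leaf, alt)] = float(rng.random() * scale)
    return IndicatorValueTable.from_records(records)


def generate_fixture(config: FixtureConfig) -> FixtureSet:
    """Hierarchy + panels + raw values, reproducible from the seed."""
    hierarchy = generate_hierarchy(config)
    return FixtureSet(
        hierarchy=hierarchy,
        panels=generate_panels(hierarchy, config),
        values=generate_values(hierarchy, config),
        config=config,
    )


def unanimous_panel(
    node_id: str, children: tuple[str, ...], score: float, n_experts: int = 7
) -> ExpertPanel:
    """A consensus panel where every expert gives every pair ``score``.

    An extreme score (0 or 1) yields the widest possible row-sum spread,
    n - 1; the consistent transform divides spreads by 2n, so even this
    panel keeps every matrix entry strictly inside (0, 1).  Use
    :func:`extreme_consistent_matrix` for a matrix that actually trips the
    degenerate-entry error paths.
    """
    scores = {
        (a, b): (float(score),) * n_experts
        for idx, a in enumerate(children)
        for b in children[idx + 1 :]
    }
    return ExpertPanel(node_id=node_id, children=children, scores=scores)


def extreme_consistent_matrix(n: int = 3):
    """A synthetic complementary matrix with a hard 0/1 entry pair.

    No three-scale panel can produce this through the row-sum transform
    (entries stay within (n-1)/(2n) of 0.5), so it is constructed directly
    to exercise the geometric-mean and reciprocal degeneracy errors.
    """
    from .core import FuzzyConsistentMatrix

    if n < 2:
        raise ValidationError("need n >= 2")
    r = np.full((n, n), 0.5)
    r[0, 1], r[1, 0] = 1.0, 0.0
    return FuzzyConsistentMatrix(r=r, row_sums=r.sum(axis=1))


@dataclass(frozen=True)
class CaseStudy:
    """The bundled skidding-system comparison, verbatim.

    ``hierarchy`` carries the published local weights; ``panels`` holds the
    two comparison matrices published in full (goal node "A" and criterion
    "C11") as single-voice aggregated panels; ``standard_values`` and
    ``integrated_values`` are the published per-leaf columns; ``costs`` the
    per-m3 field cost and labor measurements of the two systems.
    """

    hierarchy: Hierarchy
    panels: dict[str, ExpertPanel]
    standard_values: dict[tuple[str, str], float]
    integrated_values: dict[tuple[str, str], float]
    costs: pd.DataFrame = field(compare=False)

    @property
    def unit_costs(self) -> dict[str, float]:
        return dict(
            zip(self.costs["alternative_id"], self.costs["unit_cost"])
        )

    @property
    def savings_rate(self) -> float:
        """Relative unit-cost saving of cableway over road skidding."""
        uc = self.unit_costs
        return 1.0 - uc["cableway"] / uc["road"]


def case_study() -> CaseStudy:
    """Load the bundled forest-harvesting case."""
    nodes: dict[str, dict] = {}
    for nid, (label, children) in _cd.INTERNAL.items():
        nodes[nid] = {"label": label, "children": list(children)}
    for nid, (label, direction) in _cd.LEAVES.items():
        nodes[nid] = {"label": label, "direction": direction}
    hierarchy = build_hierarchy(
        {"root": "A", "alternatives": list(_cd.ALTERNATIVES), "nodes": nodes}
    )
    for nid, weights in _cd.LOCAL_WEIGHTS.items():
        hierarchy.set_local_weights(nid, weights)

    panels = {
        nid: ExpertPanel(
            node_id=nid,
            children=_cd.INTERNAL[nid][1],
            scores={pair: (score,) for pair, score in judged.items()},
        )
        for nid, judged in _cd.JUDGMENTS.items()
    }

    standard = {
        (leaf, alt): value
        for leaf, pair in _cd.STANDARD_VALUES.items()
        for alt, value in zip(_cd.ALTERNATIVES, pair)
    }
    integrated = {
        (leaf, alt): value
        for leaf, pair in _cd.INTEGRATED_VALUES.items()
        for alt, value in zip(_cd.ALTERNATIVES, pair)
    }
    return CaseStudy(
        hierarchy=hierarchy,
        panels=panels,
        standard_values=standard,
        integrated_values=integrated,
        costs=pd.DataFrame(_cd.COST_ROWS),
    )
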