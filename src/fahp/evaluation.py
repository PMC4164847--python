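"""Standardization, composite weights and the comprehensive score P.

A leaf's *composite* weight is the product of the local weights on the path
from the root down to that leaf; composite weights over all leaves sum to
one.  The comprehensive evaluation of an alternative is the linear form

    P = sum_i x_i * lambda_i + c

where x_i is the standardized value of leaf i in [0, 1], lambda_i its
composite weight, and c a correction term for interference factors not in
the hierarchy (zero by default, assuming positive and negative disturbances
offset).  With c = 0, P itself lies in [0, 1] and alternatives are ranked
by P descending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MissingValueError, ValidationError
from .hierarchy import Hierarchy, IndicatorValueTable


def threshold_standardize(
    values: Mapping[str, float], direction: str = "positive"
) -> dict[str, float]:
    """Min-max standardize one leaf's raw values across alternatives.

    Positive (benefit) leaves map the maximum to 1 and the minimum to 0 via
    y = (x - min) / (max - min).  Reverse (cost) leaves are negated first,
    so the cheapest alternative scores 1.  When all raw values coincide the
    range is degenerate; every alternative then gets the indifference value
    0.5 and a warning is emitted.
    """
    if len(values) < 2:
        raise ValidationError(
            "threshold standardization needs at least two alternatives"
        )
    if direction not in ("positive", "reverse"):
        raise ValidationError(
            f"direction must be 'positive' or 'reverse', got {direction!r}"
        )
    raw = np.asarray(list(values.values()), dtype=float)
    if direction == "reverse":
        raw = -raw
    span = raw.max() - raw.min()
    if span == 0:
        warnings.warn(
            "degenerate range (all raw values equal); standardizing to 0.5",
            stacklevel=2,
        )
        std = np.full_like(raw, 0.5)
    else:
        std = (raw - raw.min()) / span
    return dict(zip(values.keys(), std.tolist()))


def fraction_standardize(percentage: float) -> float:
    """Convert a percentage on [0, 100] to a fraction on [0, 1]."""
    if not 0.0 <= percentage <= 100.0:
        raise ValidationError(f"percentage {percentage} outside [0, 100]")
    return percentage / 100.0


def standardize_table(
    hierarchy: Hierarchy, table: IndicatorValueTable
) -> IndicatorValueTable:
    """Fill the standardized column of an indicator table, leaf by leaf.

    Positive and reverse leaves go through threshold (min-max)
    standardization across the alternatives; graded leaves carry expert
    scores already on [0, 1] and are passed through unchanged.
    """
    df = table.df.copy()
    for leaf in hierarchy.leaves():
        rows = df["leaf_id"] == leaf
        if not rows.any():
            continue
        direction = hierarchy[leaf].direction
        sub = df.loc[rows]
        if direction == "graded":
            bad = sub[(sub["raw_value"] < 0) | (sub["raw_value"] > 1)]
            if not bad.empty:
                raise ValidationError(
                    f"graded leaf {leaf}: values outside [0, 1]"
                )
            df.loc[rows, "standardized_value"] = sub["raw_value"].to_numpy()
        else:
            values = dict(zip(sub["alternative_id"], sub["raw_value"]))
            std = threshold_standardize(values, direction)
            df.loc[rows, "standardized_value"] = [
                std[alt] for alt in sub["alternative_id"]
            ]
    return IndicatorValueTable(df)


def composite_weights(hierarchy: Hierarchy) -> dict[str, float]:
    """Composite (path-product) weight per leaf; sums to one over leaves.

    Requires every non-root node on every root-to-leaf path to carry a
    local weight.
    """
    table: dict[str, float] = {}
    for leaf in hierarchy.leaves():
        weight = 1.0
        for node_id in hierarchy.path_to_root(leaf):
            if node_id == hierarchy.root:
                continue
            lw = hierarchy[node_id].local_weight
            if lw is None:
                raise ValidationError(
                    f"node {node_id} has no local weight; run the weighting "
                    "pass before synthesizing"
                )
            weight *= lw
        table[leaf] = weight
    total = sum(table.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(
            f"composite weights sum to {total!r}; check the local weights"
        )
    return table


@dataclass(frozen=True)
class EvaluationResult:
    """Comprehensive score of one alternative with its per-leaf breakdown."""

    alternative_id: str
    P: float
    per_leaf: dict[str, float] = field(compare=False)
    c: float = 0.0


def evaluate(
    hierarchy: Hierarchy,
    weights: Mapping[str, float],
    standardized: Mapping[tuple[str, str], float] | IndicatorValueTable,
    c: float = 0.0,
) -> list[EvaluationResult]:
    """Score every alternative: P = sum_i x_i * lambda_i + c.

    ``weights`` maps leaf id to composite weight; ``standardized`` supplies
    x in [0, 1] per (leaf, alternative), either as a mapping or as a filled
    :class:`~fahp.hierarchy.IndicatorValueTable`.
    """
    leaves = hierarchy.leaves()
    missing_w = [leaf for leaf in leaves if leaf not in weights]
    if missing_w:
        raise ValidationError(f"no composite weight for leaves {missing_w}")

    def lookup(leaf: str, alt: str) -> float | None:
        if isinstance(standardized, IndicatorValueTable):
            try:
                return standardized.standardized(leaf, alt)
            except MissingValueError:
                return None
        return standardized.get((leaf, alt))

    results = []
    for alt in hierarchy.alternatives:
        per_leaf: dict[str, float] = {}
        absent: list[tuple[str, str]] = []
        for leaf in leaves:
            x = lookup(leaf, alt)
            if x is None:
                absent.append((leaf, alt))
            else:
                per_leaf[leaf] = x * weights[leaf]
        if absent:
            raise MissingValueError(
                f"missing standardized values for pairs {absent}"
            )
        results.append(
            EvaluationResult(
                alternative_id=alt,
                P=sum(per_leaf.values()) + c,
                per_leaf=per_leaf,
                c=c,
            )
        )
    return results


@dataclass(frozen=True)
class Comparison:
    """Alternatives ordered by comprehensive score, best first."""

    ranking: tuple[str, ...]
    scores: dict[str, float] = field(compare=False)
    deltas: tuple[float, ...] = ()

    def __str__(self) -> str:
        parts = [f"{alt} (P={self.scores[alt]:.4f})" for alt in self.ranking]
        return " > ".join(parts)


def compare(results: Sequence[EvaluationResult]) -> Comparison:
    """Rank alternatives by P descending; ties keep input order.

    ``deltas[k]`` is the score gap between ranks k and k+1.
    """
    if len(results) < 2:
        raise ValidationError("need at least two alternatives to compare")
    if len({r.alternative_id for r in results}) != len(results):
        raise ValidationError("duplicate alternative ids in results")
    leaf_sets = {frozenset(r.per_leaf) for r in results}
    if len(leaf_sets) != 1:
        raise ValidationError("results come from mismatched hierarchies")
    ordered = sorted(
        enumerate(results), key=lambda kv: (-kv[1].P, kv[0])
    )
    ranking = tuple(r.alternative_id for _, r in ordered)
    scores = {r.alternative_id: r.P for r in results}
    deltas = tuple(
        ordered[k][1].P - ordered[k + 1][1].P for k in range(len(ordered) - 1)
    )
    return Comparison(ranking=ranking, scores=scores, deltas=deltas)


def report_table(
    hierarchy: Hierarchy,
    weights: Mapping[str, float],
    results: Sequence[EvaluationResult],
) -> pd.DataFrame:
    """Flat report: one row per leaf with ancestry, weights and per-
    alternative standardized and integrated values (rounded to 4 d.p.)."""
    rows = []
    for leaf in hierarchy.leaves():
        path = hierarchy.path_to_root(leaf)[::-1]  # root .. leaf
        row: dict[str, object] = {
            "leaf_id": leaf,
            "label": hierarchy[leaf].label,
            "path": "/".join(path),
            "local_weight": round(hierarchy[leaf].local_weight or float("nan"), 4),
            "composite_weight": round(weights[leaf], 4),
        }
        for res in results:
            integrated = res.per_leaf[leaf]
            x = integrated / weights[leaf] if weights[leaf] else 0.0
            row[f"{res.alternative_id}_standard"] = round(x, 4)
            row[f"{res.alternative_id}_integrated"] = round(integrated, 4)
        rows.append(row)
    return pd.DataFrame(rows)
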