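"""Multi-level indicator hierarchies, expert panels, and indicator tables.

An evaluation system is a rooted tree: a single target node (the overall
goal), one or more layers of criteria, and leaf indicators that carry a
*direction* flag:

``positive``
    larger raw values are better (benefit indicator),
``reverse``
    smaller raw values are better (cost indicator; negated before
    min-max standardization),
``graded``
    qualitative five-grade expert score already expressed on [0, 1],
    used as-is without re-standardization.

Every internal node owns an ordered list of children; after weighting, the
children's local weights sum to one.  All leaves must sit at the same depth
so that composite (path-product) weights are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import (
    CycleError,
    DuplicateIdError,
    MissingDirectionError,
    MissingValueError,
    OrphanNodeError,
    ValidationError,
)

VALID_DIRECTIONS = ("positive", "reverse", "graded")

#: The three admissible pairwise scores: i worse than j, equal, i better.
SCALE = (0.0, 0.5, 1.0)


@dataclass
class CriterionNode:
    """One node of the indicator tree.

    ``local_weight`` is the node's weight among its siblings; it is ``None``
    until a weighting pass fills it in.  ``direction`` is present exactly on
    leaves.
    """

    id: str
    label: str = ""
    children: tuple[str, ...] = ()
    direction: str | None = None
    local_weight: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Hierarchy:
    """A validated indicator tree plus the alternatives under evaluation."""

    root: str
    nodes: dict[str, CriterionNode]
    alternatives: tuple[str, ...] = ()
    _parent: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._parent = {
            child: node.id
            for node in self.nodes.values()
            for child in node.children
        }

    def __getitem__(self, node_id: str) -> CriterionNode:
        return self.nodes[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def parent_of(self, node_id: str) -> str | None:
        return self._parent.get(node_id)

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from ``node_id`` up to (and including) the root."""
        path = [node_id]
        while (up := self._parent.get(path[-1])) is not None:
            path.append(up)
        return path

    def depth_of(self, node_id: str) -> int:
        return len(self.path_to_root(node_id)) - 1

    def preorder(self) -> Iterable[CriterionNode]:
        stack = [self.root]
        while stack:
            node = self.nodes[stack.pop()]
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[str]:
        return [n.id for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[str]:
        return [n.id for n in self.preorder() if not n.is_leaf]

    def set_local_weights(self, node_id: str, weights: Iterable[float]) -> None:
        """Attach local weights to the children of ``node_id`` (in order)."""
        node = self.nodes[node_id]
        weights = list(weights)
        if len(weights) != len(node.children):
            raise ValidationError(
                f"{node_id}: {len(node.children)} children but "
                f"{len(weights)} weights"
            )
        total = sum(weights)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"{node_id}: children's local weights sum to {total!r}, not 1"
            )
        for child, w in zip(node.children, weights):
            self.nodes[child].local_weight = float(w)


def build_hierarchy(spec: Mapping) -> Hierarchy:
    """Build and validate a :class:`Hierarchy` from a nested description.

    ``spec`` maps::

        root: <id>
        alternatives: [<id>, ...]          # optional
        nodes:
          <id>: {label: <str>, children: [<id>, ...]}   # internal node
          <id>: {label: <str>, direction: positive|reverse|graded}  # leaf

    Raises a distinct :class:`~fahp.errors.ValidationError` subclass for a
    cycle, an orphan node, a duplicated child, or a leaf without direction.
    """
    try:
        root = spec["root"]
        raw_nodes = spec["nodes"]
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"hierarchy description missing key {exc}") from exc
    if root not in raw_nodes:
        raise OrphanNodeError(f"root {root!r} is not among the nodes")

    nodes: dict[str, CriterionNode] = {}
    for node_id, entry in raw_nodes.items():
        entry = dict(entry or {})
        children = tuple(entry.get("children") or ())
        if len(set(children)) != len(children):
            raise DuplicateIdError(f"{node_id}: duplicated child ids {children}")
        direction = entry.get("direction")
        if children and direction is not None:
            raise MissingDirectionError(
                f"{node_id}: internal nodes carry no direction flag"
            )
        if not children:
            if direction is None:
                raise MissingDirectionError(f"leaf {node_id}: direction missing")
            if direction not in VALID_DIRECTIONS:
                raise ValidationError(
                    f"leaf {node_id}: direction {direction!r} not in "
                    f"{VALID_DIRECTIONS}"
                )
        nodes[node_id] = CriterionNode(
            id=node_id,
            label=str(entry.get("label", "")),
            children=children,
            direction=direction,
            local_weight=entry.get("local_weight"),
        )

    # each non-root node has exactly one parent
    seen_parent: dict[str, str] = {}
    for node in nodes.values():
        for child in node.children:
            if child not in nodes:
                raise OrphanNodeError(
                    f"{node.id} lists unknown child {child!r}"
                )
            if child in seen_parent:
                raise DuplicateIdError(
                    f"{child} claimed by both {seen_parent[child]} and {node.id}"
                )
            seen_parent[child] = node.id
    if root in seen_parent:
        raise CycleError(f"root {root!r} appears as a child of {seen_parent[root]}")

    # reachability + acyclicity from the root
    reached: set[str] = set()
    stack = [root]
    while stack:
        nid = stack.pop()
        if nid in reached:
            raise CycleError(f"cycle through {nid!r}")
        reached.add(nid)
        stack.extend(nodes[nid].children)
    orphans = set(nodes) - reached
    if orphans:
        raise OrphanNodeError(f"unreachable nodes: {sorted(orphans)}")

    hierarchy = Hierarchy(
        root=root,
        nodes=nodes,
        alternatives=tuple(spec.get("alternatives") or ()),
    )
    depths = {hierarchy.depth_of(leaf) for leaf in hierarchy.leaves()}
    if len(depths) > 1:
        raise ValidationError(
            f"leaves sit at unequal depths {sorted(depths)}; the tree must be "
            "balanced for path-product weights to be comparable"
        )
    return hierarchy


def serialize(hierarchy: Hierarchy) -> dict:
    """Inverse of :func:`build_hierarchy` (round-trips node-for-node)."""
    nodes: dict[str, dict] = {}
    for node in hierarchy.preorder():
        entry: dict = {"label": node.label}
        if node.children:
            entry["children"] = list(node.children)
        else:
            entry["direction"] = node.direction
        if node.local_weight is not None:
            entry["local_weight"] = node.local_weight
        nodes[node.id] = entry
    return {
        "root": hierarchy.root,
        "alternatives": list(hierarchy.alternatives),
        "nodes": nodes,
    }


def load_hierarchy(path: str | Path) -> Hierarchy:
    with open(path, "r", encoding="utf-8") as fh:
        return build_hierarchy(yaml.safe_load(fh))


def dump_hierarchy(hierarchy: Hierarchy, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(serialize(hierarchy), fh, sort_keys=False)


@dataclass
class ExpertPanel:
    """Pairwise three-scale scores from a panel of k experts.

    The panel compares the children of one internal node.  For every ordered
    child pair (i, j) with i before j, ``scores[(i, j)]`` holds one score per
    expert, each in {0, 0.5, 1}: 0 means child i is at a disadvantage to j,
    0.5 equal importance, 1 means i prevails over j.
    """

    node_id: str
    children: tuple[str, ...]
    scores: dict[tuple[str, str], tuple[float, ...]]

    def __post_init__(self) -> None:
        self.children = tuple(self.children)
        self.scores = {
            pair: tuple(float(s) for s in vals)
            for pair, vals in self.scores.items()
        }
        self.validate()

    @property
    def n(self) -> int:
        return len(self.children)

    @property
    def n_experts(self) -> int:
        return len(next(iter(self.scores.values())))

    def validate(self) -> None:
        expected = {
            (a, b)
            for idx, a in enumerate(self.children)
            for b in self.children[idx + 1 :]
        }
        if set(self.scores) != expected:
            missing = expected - set(self.scores)
            extra = set(self.scores) - expected
            raise ValidationError(
                f"panel {self.node_id}: pair mismatch "
                f"(missing {sorted(missing)}, unexpected {sorted(extra)})"
            )
        ks = {len(v) for v in self.scores.values()}
        if not self.scores or ks == {0}:
            raise ValidationError(f"panel {self.node_id}: no scores")
        if len(ks) != 1 or min(ks) < 1:
            raise ValidationError(
                f"panel {self.node_id}: unequal expert counts {sorted(ks)}"
            )
        for pair, vals in self.scores.items():
            bad = [s for s in vals if s not in SCALE]
            if bad:
                raise ValidationError(
                    f"panel {self.node_id} pair {pair}: scores {bad} outside "
                    f"the three-scale set {SCALE}"
                )


def panels_from_table(df: pd.DataFrame) -> dict[str, ExpertPanel]:
    """Group a long score table into one :class:`ExpertPanel` per node.

    Expects columns ``node_id, i_child, j_child, expert_id, score``; child
    order within a panel follows first appearance in the table.
    """
    required = {"node_id", "i_child", "j_child", "expert_id", "score"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"score table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    panels: dict[str, ExpertPanel] = {}
    for node_id, grp in df.groupby("node_id", sort=False):
        children: list[str] = []
        for child in pd.concat([grp["i_child"], grp["j_child"]]):
            if child not in children:
                children.append(child)
        # preserve (i, j) orientation as given
        scores: dict[tuple[str, str], tuple[float, ...]] = {}
        for (i, j), sub in grp.groupby(["i_child", "j_child"], sort=False):
            sub = sub.sort_values("expert_id")
            scores[(i, j)] = tuple(float(s) for s in sub["score"])
        panels[str(node_id)] = ExpertPanel(str(node_id), tuple(children), scores)
    return panels


def read_scores(path: str | Path) -> dict[str, ExpertPanel]:
    """Read a delimited expert-score file (CSV/TSV with a header row)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return panels_from_table(pd.read_csv(path, sep=sep))


@dataclass
class IndicatorValueTable:
    """Raw and standardized leaf values per alternative.

    Backed by a DataFrame with columns ``leaf_id, alternative_id, raw_value,
    standardized_value``; the standardized column starts empty (NaN) and is
    filled by the standardization pass.
    """

    df: pd.DataFrame

    COLUMNS = ("leaf_id", "alternative_id", "raw_value", "standardized_value")

    @classmethod
    def from_records(
        cls, records: Mapping[tuple[str, str], float]
    ) -> "IndicatorValueTable":
        rows = [
            {"leaf_id": leaf, "alternative_id": alt, "raw_value": float(v),
             "standardized_value": float("nan")}
            for (leaf, alt), v in records.items()
        ]
        return cls(pd.DataFrame(rows, columns=list(cls.COLUMNS)))

    @classmethod
    def read_csv(cls, path: str | Path) -> "IndicatorValueTable":
        df = pd.read_csv(path)
        if "standardized_value" not in df.columns:
            df["standardized_value"] = float("nan")
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"value table missing columns {sorted(missing)}")
        return cls(df[list(cls.COLUMNS)].copy())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    def raw(self, leaf_id: str, alternative_id: str) -> float:
        return self._lookup(leaf_id, alternative_id, "raw_value")

    def standardized(self, leaf_id: str, alternative_id: str) -> float:
        value = self._lookup(leaf_id, alternative_id, "standardized_value")
        if pd.isna(value):
            raise MissingValueError(
                f"({leaf_id}, {alternative_id}) has no standardized value yet"
            )
        if not 0.0 <= value <= 1.0:
            raise ValidationError(
                f"({leaf_id}, {alternative_id}): standardized value {value} "
                "outside [0, 1]"
            )
        return value

    def _lookup(self, leaf_id: str, alternative_id: str, column: str) -> float:
        mask = (self.df["leaf_id"] == leaf_id) & (
            self.df["alternative_id"] == alternative_id
        )
        hit = self.df.loc[mask, column]
        if hit.empty:
            raise MissingValueError(f"no row for ({leaf_id}, {alternative_id})")
        return float(hit.iloc[0])
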