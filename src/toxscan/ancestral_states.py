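"""Minimum-cost (Sankoff) ancestral reconstruction of ordinal sensitivity states.

States are the four ordinal sensitivity classes; the default cost of a
change is the absolute rank difference.  The root state may be constrained
(default in the pipeline: ModeratelySensitive).  Branches are annotated UP
when the child outranks the parent and DOWN in the opposite case.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .io_formats import RootedTree, TreeNode
from .sensitivity_rules import SensitivityClass

INF = float("inf")


@dataclass(frozen=True)
class StateModel:
    """Ordered state list plus a symmetric change-cost matrix."""

    states: tuple[str, ...]
    costs: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.states)
        if len(self.costs) != k or any(len(row) != k for row in self.costs):
            raise ValueError("cost matrix must be square over the state list")
        for i in range(k):
            if self.costs[i][i] != 0:
                raise ValueError("cost matrix diagonal must be zero")
            for j in range(k):
                if self.costs[i][j] != self.costs[j][i]:
                    raise ValueError("cost matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.states)

    def rank(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError as exc:
            raise ValueError(
                f"state {state!r} not in model {self.states}"
            ) from exc

    def cost(self, a: str, b: str) -> float:
        return self.costs[self.rank(a)][self.rank(b)]


def default_state_model() -> StateModel:
    states = tuple(
        cls.label for cls in sorted(SensitivityClass, key=int)
    )
    k = len(states)
    costs = tuple(
        tuple(float(abs(i - j)) for j in range(k)) for i in range(k)
    )
    return StateModel(states=states, costs=costs)


class ChangeDirection(enum.Enum):
    UP = "UP"
    DOWN = "DOWN"
    NONE = "NONE"


@dataclass
class AnnotatedTree:
    tree: RootedTree
    states: dict[int, str]          # node index -> state
    total_cost: float
    model: StateModel
    root_constraint: str | None = None

    def state_of(self, node: TreeNode) -> str:
        return self.states[node.index]


@dataclass(frozen=True)
class BranchChange:
    parent_index: int
    child_index: int
    child_label: str | None
    parent_state: str
    child_state: str
    direction: ChangeDirection


def sankoff(tree: RootedTree, tip_states: Mapping[str, str],
            model: StateModel | None = None,
            root_constraint: str | None = None) -> AnnotatedTree:
    """Minimum-cost ancestral state assignment under an arbitrary cost matrix.

    Dynamic programming up the tree, traceback down; handles polytomies
    natively.  Traceback ties prefer the parent's state, then the
    lower-ranked state.  With a ``root_constraint`` the root is pinned and
    the reported cost is the minimum conditional on that state.
    """
    model = model or default_state_model()
    if root_constraint is not None:
        model.rank(root_constraint)  # validates
    k = model.n
    costs = np.array(model.costs, dtype=float)

    nodes = list(tree.preorder())
    table: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip:
            if node.label not in tip_states:
                raise ValueError(f"tip {node.label!r} has no state assigned")
            vec = np.full(k, INF)
            vec[model.rank(tip_states[node.label])] = 0.0
            table[node.index] = vec
        else:
            vec = np.zeros(k)
            for child in node.children:
                child_vec = table[child.index]
                # best over child state t of cost(s, t) + S(child, t)
                vec += (costs + child_vec[None, :]).min(axis=1)
            table[node.index] = vec

    root_vec = table[tree.root.index]
    states: dict[int, str] = {}
    if root_constraint is not None:
        root_rank = model.rank(root_constraint)
        if not np.isfinite(root_vec[root_rank]):
            raise ValueError(
                f"no assignment consistent with root state {root_constraint!r}"
            )
    else:
        root_rank = int(np.argmin(root_vec))  # argmin takes the lowest rank on ties
    total_cost = float(root_vec[root_rank])
    states[tree.root.index] = model.states[root_rank]

    for node in nodes:  # preorder: parents before children
        if node.index not in states:
            continue
        parent_rank = model.rank(states[node.index])
        for child in node.children:
            child_vec = table[child.index]
            options = costs[parent_rank] + child_vec
            best = float(options.min())
            if np.isfinite(options[parent_rank]) and options[parent_rank] == best:
                child_rank = parent_rank  # tie-break: keep the parent's state
            else:
                child_rank = int(np.argmin(options))
            states[child.index] = model.states[child_rank]

    return AnnotatedTree(
        tree=tree,
        states=states,
        total_cost=total_cost,
        model=model,
        root_constraint=root_constraint,
    )


def annotate_changes(annotated: AnnotatedTree) -> list[BranchChange]:
    """Per-branch sensitivity change labels (the up/down arrows)."""
    model = annotated.model
    changes: list[BranchChange] = []
    for node in annotated.tree.preorder():
        for child in node.children:
            parent_state = annotated.states[node.index]
            child_state = annotated.states[child.index]
            delta = model.rank(child_state) - model.rank(parent_state)
            direction = (
                ChangeDirection.UP if delta > 0
                else ChangeDirection.DOWN if delta < 0
                else ChangeDirection.NONE
            )
            changes.append(
                BranchChange(
                    parent_index=node.index,
                    child_index=child.index,
                    child_label=child.label,
                    parent_state=parent_state,
                    child_state=child_state,
                    direction=direction,
                )
            )
    return changes
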