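"""Fitch parsimony and delayed-transformation (DELTRAN) character mapping.

Lesion presence/absence characters (0 = absent, 1 = present, ? = missing)
are optimized on a rooted species tree.  DELTRAN resolves ambiguity by
keeping each node in its parent's state whenever that is compatible with a
minimum-length reconstruction, which pushes changes as far from the root as
possible — appropriate for derived loss characters whose plesiomorphic
state is an intact gene.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import LabeledTimeTree, StructuralError

STATES = frozenset({0, 1})


@dataclass
class FitchResult:
    length: int
    downpass: dict  # id(node) -> frozenset of states


def _tip_state_set(states: dict, label: str) -> frozenset:
    value = states.get(label, "?")
    if value in ("?", None):
        return STATES
    if value in (0, 1, "0", "1"):
        return frozenset({int(value)})
    raise StructuralError(f"bad character state {value!r} for tip {label!r}")


def fitch_optimize(tree: LabeledTimeTree, character: dict) -> FitchResult:
    """Unordered Fitch down-pass: minimal change count and per-node state
    sets.  ``character`` maps tip labels to 0/1/'?'; missing tips are
    treated as '?' (compatible with either state)."""
    downpass: dict = {}
    length = 0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            downpass[id(node)] = _tip_state_set(character, tree.tip_label(node))
            continue
        sets = [downpass[id(ch)] for ch in node.child_nodes()]
        inter = frozenset.intersection(*sets)
        if inter:
            downpass[id(node)] = inter
        else:
            downpass[id(node)] = frozenset.union(*sets)
            length += 1
    return FitchResult(length=length, downpass=downpass)


def deltran_assign(tree: LabeledTimeTree, character: dict) -> dict:
    """DELTRAN final states and change branches.

    Returns ``{"states": {id(node): state}, "changes": [(tipset, parent
    state, child state)], "length": n}``.  Root-state ties break to 0
    (lesion absent), the plesiomorphic condition.
    """
    fitch = fitch_optimize(tree, character)
    states: dict = {}
    changes = []
    for node in tree.tree.preorder_node_iter():
        options = fitch.downpass[id(node)]
        if node.parent_node is None:
            states[id(node)] = 0 if 0 in options else min(options)
            continue
        parent_state = states[id(node.parent_node)]
        if parent_state in options:
            state = parent_state
        else:
            # binary characters: an incompatible set is a singleton
            state = min(options)
        states[id(node)] = state
        if state != parent_state:
            tips = frozenset(
                tree.tip_label(leaf) for leaf in node.leaf_iter()
            )
            changes.append((tips, parent_state, state))
    return {"states": states, "changes": changes, "length": len(changes)}
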