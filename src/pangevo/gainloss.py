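"""Ancestral gene-content reconstruction under asymmetric-cost parsimony.

Two modes share one Sankoff dynamic program over integer states:

* ``sankoff_binary`` — presence/absence states {0,1} with branch transition
  costs c(0->1) = gain_penalty and c(1->0) = loss_penalty;
* ``wagner_abundance`` — copy-number states {0..max_state} with cost
  gain_penalty * max(0, child-parent) + loss_penalty * max(0, parent-child).

The default penalties (gain 1.6, loss 1.0) make losses cheaper than gains, the
standard asymmetry for prokaryotic gene content.  The traceback places changes
as late (close to the leaves) as possible: ties at the root resolve to the
smallest state (absence), and a child keeps its parent's state whenever that
state is among the cost minimisers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Tree

__all__ = ["CostScheme", "AncestralStateTable", "sankoff_binary",
           "wagner_abundance", "summarize_events"]


@dataclass(frozen=True)
class CostScheme:
    gain_penalty: float = 1.6
    loss_penalty: float = 1.0

    def __post_init__(self):
        if self.gain_penalty <= 0 or self.loss_penalty <= 0:
            raise ValueError("penalties must be positive")


@dataclass
class AncestralStateTable:
    """Reconstructed state per (node, cluster) plus per-node event summary."""

    states: pd.DataFrame       # nodes x clusters (leaves included, observed)
    summary: pd.DataFrame      # node -> gains, losses, present
    total_cost: float
    mode: str                  # "binary" | "abundance"


def _check_tree(tree: Tree, taxa) -> None:
    if not tree.root.children:
        raise ValueError("tree must be rooted")
    leaves = tree.leaf_labels()
    if set(leaves) != set(taxa):
        raise ValueError("tree leaf set does not match matrix taxa")
    if len(set(leaves)) != len(leaves):
        raise ValueError("duplicate leaf labels")


def _sankoff(tree: Tree, data: pd.DataFrame, trans: np.ndarray) -> tuple[pd.DataFrame, float]:
    """Vectorised Sankoff DP over all clusters at once.

    ``trans[s_parent, s_child]`` is the branch transition cost; ``data`` holds
    integer leaf states in [0, n_states).
    """
    n_states = trans.shape[0]
    n_clusters = data.shape[1]
    tree.label_internal()
    nodes = list(tree.postorder())
    cost: dict[int, np.ndarray] = {}
    big = np.inf

    for node in nodes:
        if node.is_leaf():
            obs = data.loc[node.label].to_numpy()
            c = np.full((n_states, n_clusters), big)
            c[obs, np.arange(n_clusters)] = 0.0
        else:
            c = np.zeros((n_states, n_clusters))
            for child in node.children:
                # min over child state of trans[s, s'] + cost_child[s']
                c += np.min(trans[:, :, None] + cost[id(child)][None, :, :], axis=1)
        cost[id(node)] = c

    root_cost = cost[id(tree.root)]
    root_state = np.argmin(root_cost, axis=0)          # ties -> smallest state
    total = float(root_cost[root_state, np.arange(n_clusters)].sum())

    assign: dict[int, np.ndarray] = {id(tree.root): root_state}
    for node in tree.preorder():
        if node is tree.root:
            continue
        ps = assign[id(node.parent)]
        totals = trans[ps, :].T + cost[id(node)]       # n_states x n_clusters
        best = totals.min(axis=0)
        # prefer the parent's state among minimisers (defers changes leafward)
        keep = totals[ps, np.arange(n_clusters)] <= best + 1e-12
        child_state = np.argmin(totals, axis=0)
        child_state[keep] = ps[keep]
        assign[id(node)] = child_state

    order = [n.label for n in tree.preorder()]
    states = pd.DataFrame(
        np.vstack([assign[id(n)] for n in tree.preorder()]),
        index=order, columns=data.columns, dtype=int)
    return states, total


def _transition_costs(n_states: int, costs: CostScheme) -> np.ndarray:
    s = np.arange(n_states)
    delta = s[None, :] - s[:, None]                    # child - parent
    return np.where(delta > 0, costs.gain_penalty * delta,
                    -costs.loss_penalty * delta).astype(float)


def sankoff_binary(tree: Tree, matrix: pd.DataFrame,
                   costs: CostScheme = CostScheme()) -> AncestralStateTable:
    """Binary presence/absence reconstruction on a rooted tree.

    ``matrix`` is taxa x clusters with values in {0,1}.
    """
    _check_tree(tree, matrix.index)
    vals = matrix.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("binary matrix must contain only 0/1")
    states, total = _sankoff(tree, matrix.astype(int), _transition_costs(2, costs))
    return AncestralStateTable(states=states,
                               summary=summarize_events_frame(states, tree),
                               total_cost=total, mode="binary")


def wagner_abundance(tree: Tree, pan_matrix: pd.DataFrame,
                     costs: CostScheme = CostScheme(),
                     max_state: int = 9) -> AncestralStateTable:
    """Copy-number reconstruction with per-unit asymmetric gain/loss costs."""
    _check_tree(tree, pan_matrix.index)
    vals = pan_matrix.to_numpy()
    if (vals < 0).any():
        raise ValueError("abundances must be non-negative")
    if vals.max(initial=0) > max_state:
        raise ValueError(
            f"abundance {vals.max()} exceeds max_state={max_state}; "
            "raise max_state")
    states, total = _sankoff(tree, pan_matrix.astype(int),
                             _transition_costs(max_state + 1, costs))
    return AncestralStateTable(states=states,
                               summary=summarize_events_frame(states, tree),
                               total_cost=total, mode="abundance")


def summarize_events_frame(states: pd.DataFrame, tree: Tree) -> pd.DataFrame:
    """Per-node gains (0 -> >=1), losses (>=1 -> 0) and families present.

    Events are counted on the binary (presence) view even in abundance mode;
    copy-number expansions/contractions are reported as separate columns.
    """
    present = states > 0
    rows = []
    for node in tree.preorder():
        p = present.loc[node.label]
        if node is tree.root:
            gains = losses = exp = con = 0
        else:
            pp = present.loc[node.parent.label]
            gains = int((~pp & p).sum())
            losses = int((pp & ~p).sum())
            delta = states.loc[node.label] - states.loc[node.parent.label]
            both = pp & p
            exp = int((delta[both] > 0).sum())
            con = int((delta[both] < 0).sum())
        rows.append({"node": node.label, "gains": gains, "losses": losses,
                     "present": int(p.sum()), "expansions": exp,
                     "contractions": con})
    return pd.DataFrame(rows).set_index("node")


def summarize_events(states: AncestralStateTable, tree: Tree) -> pd.DataFrame:
    """Recompute the per-node gain/loss/present table from a reconstruction."""
    return summarize_events_frame(states.states, tree)
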