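"""Interpretable axis-aligned policy trees.

A policy tree maps a patient's covariates to one prescribed treatment arm by
descending binary threshold splits: rows with ``feature < threshold`` go
left, rows with ``feature >= threshold`` go right. Trees are fit to minimize
the mean doubly-robust estimated mortality score of the prescribed arm,
penalized by ``cp`` per split, subject to a maximum depth and a minimum
number of training rows per leaf.

The optimizer is a randomized local search: a greedy top-down grow pass
followed by coordinate-descent refinement of every internal node (re-split
or prune moves, accepted only when the penalized objective strictly
decreases), repeated from ``n_restarts`` randomized starts and keeping the
best tree. An exhaustive enumerator for depth <= 2 serves as an exact
reference on small problems.

Tie-breaking between arms with equal scores prefers the less invasive arm in
the fixed order OBS < AE < SPLENECTOMY.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import ARMS
from .errors import ConfigurationError, SchemaError

__all__ = [
    "PolicyTree",
    "train_policy_tree",
    "exhaustive_policy_tree",
    "tune",
    "prescribe",
]

TREE_SCHEMA = "splenopt-policy-tree-v1"

_ARM_COLOR = {"OBS": "#2ca02c", "AE": "#1f77b4", "SPLENECTOMY": "#d62728"}


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """One tree node. Internal nodes carry a split, leaves a prescription."""

    # internal fields
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["Node"] = None
    right: Optional["Node"] = None
    missing_goes_left: bool = True
    # leaf fields
    treatment: Optional[str] = None
    n_train: int = 0
    strength: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "treatment": self.treatment,
                "n_train": int(self.n_train),
                "strength": float(self.strength),
            }
        return {
            "feature": self.feature,
            "threshold": float(self.threshold),
            "missing_goes_left": bool(self.missing_goes_left),
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "Node":
        if "treatment" in d:
            return Node(treatment=d["treatment"], n_train=d.get("n_train", 0),
                        strength=d.get("strength", 0.0))
        return Node(
            feature=d["feature"], threshold=float(d["threshold"]),
            missing_goes_left=bool(d.get("missing_goes_left", True)),
            left=Node.from_dict(d["left"]), right=Node.from_dict(d["right"]),
        )


@dataclass
class PolicyTree:
    """An axis-aligned prescription tree over named covariates."""

    root: Node
    max_depth: int = 0
    min_leaf: int = 1
    cp: float = 0.0
    objective: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    # -- structure -----------------------------------------------------

    @property
    def depth(self) -> int:
        def d(n: Node) -> int:
            return 0 if n.is_leaf else 1 + max(d(n.left), d(n.right))
        return d(self.root)

    @property
    def n_splits(self) -> int:
        def c(n: Node) -> int:
            return 0 if n.is_leaf else 1 + c(n.left) + c(n.right)
        return c(self.root)

    @property
    def n_leaves(self) -> int:
        return self.n_splits + 1

    def split_features(self) -> list[str]:
        out: list[str] = []

        def walk(n: Node) -> None:
            if not n.is_leaf:
                out.append(n.feature)
                walk(n.left)
                walk(n.right)

        walk(self.root)
        return out

    def leaves(self) -> list[tuple[str, Node]]:
        """(path description, leaf) pairs in left-to-right order."""
        out: list[tuple[str, Node]] = []

        def walk(n: Node, path: list[str]) -> None:
            if n.is_leaf:
                out.append((" & ".join(path) if path else "(root)", n))
            else:
                walk(n.left, path + [f"{n.feature} < {n.threshold:g}"])
                walk(n.right, path + [f"{n.feature} >= {n.threshold:g}"])

        walk(self.root, [])
        return out

    # -- prescription --------------------------------------------------

    def _route(self, rows: pd.DataFrame) -> tuple[np.ndarray, list[Node]]:
        """Positional leaf id per row (left-to-right leaf order) and the leaves."""
        for f in set(self.split_features()):
            if f not in rows.columns:
                raise SchemaError(f"policy tree split feature '{f}' not in rows")
        leaf_list = [leaf for _, leaf in self.leaves()]
        ids = {id(leaf): i for i, leaf in enumerate(leaf_list)}
        cols = {f: rows[f].to_numpy(dtype=float) for f in set(self.split_features())}
        out = np.full(len(rows), -1, dtype=int)

        def walk(n: Node, pos: np.ndarray) -> None:
            if pos.size == 0:
                return
            if n.is_leaf:
                out[pos] = ids[id(n)]
                return
            v = cols[n.feature][pos]
            go_left = v < n.threshold
            nan = np.isnan(v)
            if nan.any():
                # missing value: follow the majority training branch
                go_left = np.where(nan, n.missing_goes_left, go_left)
            walk(n.left, pos[go_left])
            walk(n.right, pos[~go_left])

        walk(self.root, np.arange(len(rows)))
        return out, leaf_list

    def prescribe(self, rows: pd.DataFrame) -> pd.Series:
        """Prescribe one arm per row by threshold descent.

        A missing value at a split node follows the branch taken by the
        majority of training rows at that node.
        """
        leaf_idx, leaf_list = self._route(rows)
        arms = np.asarray([leaf.treatment for leaf in leaf_list], dtype=object)
        return pd.Series(arms[leaf_idx], index=rows.index)

    def leaf_ids(self, rows: pd.DataFrame) -> pd.Series:
        """Route rows and return the index of the leaf (left-to-right order)."""
        leaf_idx, _ = self._route(rows)
        return pd.Series(leaf_idx, index=rows.index)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": TREE_SCHEMA,
            "arms": list(ARMS),
            "max_depth": int(self.max_depth),
            "min_leaf": int(self.min_leaf),
            "cp": float(self.cp),
            "objective": None if self.objective is None else float(self.objective),
            "metadata": self.metadata,
            "root": self.root.to_dict(),
        }

    @staticmethod
    def from_dict(d: dict) -> "PolicyTree":
        return PolicyTree(
            root=Node.from_dict(d["root"]), max_depth=d.get("max_depth", 0),
            min_leaf=d.get("min_leaf", 1), cp=d.get("cp", 0.0),
            objective=d.get("objective"), metadata=d.get("metadata", {}),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    @staticmethod
    def from_json(source: str | Path) -> "PolicyTree":
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        return PolicyTree.from_dict(json.loads(text))

    def to_dot(self, title: str = "") -> str:
        """Graphviz DOT rendering; leaf fill intensity scales with prescription strength."""
        strengths = [leaf.strength for _, leaf in self.leaves()]
        smax = max(strengths) if strengths and max(strengths) > 0 else 1.0
        lines = ["digraph policy_tree {", '  node [shape=box, style="rounded,filled"];']
        if title:
            lines.append(f'  label="{title}"; labelloc=top;')
        counter = [0]

        def walk(n: Node) -> int:
            nid = counter[0]
            counter[0] += 1
            if n.is_leaf:
                alpha = int(55 + 200 * min(1.0, n.strength / smax))
                color = _ARM_COLOR.get(n.treatment, "#999999") + f"{alpha:02x}"
                lines.append(
                    f'  n{nid} [label="Prescribe {n.treatment}\\nN = {n.n_train}\\n'
                    f'strength = {n.strength:.4f}", fillcolor="{color}"];'
                )
                return nid
            lines.append(
                f'  n{nid} [label="{n.feature} < {n.threshold:g} ?", fillcolor="#eeeeee"];'
            )
            lid, rid = walk(n.left), walk(n.right)
            lines.append(f'  n{nid} -> n{lid} [label="yes"];')
            lines.append(f'  n{nid} -> n{rid} [label="no"];')
            return nid

        # re-walk in declaration order so ids are stable
        def ordered(n: Node) -> int:
            return walk(n)

        ordered(self.root)
        lines.append("}")
        return "\n".join(lines)


def prescribe(tree: PolicyTree, rows: pd.DataFrame) -> pd.Series:
    """Functional alias for :meth:`PolicyTree.prescribe`."""
    return tree.prescribe(rows)


# ---------------------------------------------------------------------------
# Shared fitting helpers
# ---------------------------------------------------------------------------

def _as_gamma_features(rewards, features) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Coerce inputs to (gamma n x 3, X n x f, feature names)."""
    gamma = getattr(rewards, "gamma", rewards)
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[1] != len(ARMS):
        raise SchemaError(f"rewards must be n x {len(ARMS)}")
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    if X.shape[0] != gamma.shape[0]:
        raise SchemaError("rewards rows and feature rows are not aligned")
    if np.isnan(X).any():
        raise SchemaError("features contain missing values; impute or drop before fitting")
    if not np.isfinite(gamma).all():
        raise SchemaError("reward matrix contains non-finite entries")
    return gamma, X, names


def _leaf_stats(gamma: np.ndarray, idx: np.ndarray) -> tuple[int, float, float]:
    """Optimal (arm, summed reward, strength) for a leaf holding rows idx."""
    sums = gamma[idx].sum(axis=0)
    arm = int(np.argmin(sums))
    order = np.sort(sums)
    strength = float((order[1] - order[0]) / max(len(idx), 1))
    return arm, float(sums[arm]), strength


class _Optimizer:
    """Local-search policy tree optimizer over numpy arrays.

    All objectives are tracked as summed rewards plus ``cp_sum`` per split,
    where ``cp_sum = cp * n``, so that dividing by n recovers the mean
    penalized objective.
    """

    def __init__(self, gamma, X, names, max_depth, min_leaf, cp,
                 max_candidates=48, max_passes=4):
        self.gamma, self.X, self.names = gamma, X, names
        self.n, self.f = X.shape
        self.max_depth, self.min_leaf, self.cp = max_depth, min_leaf, cp
        self.cp_sum = cp * self.n
        self.max_candidates = max_candidates
        self.max_passes = max_passes
        self._name_idx = {name: j for j, name in enumerate(names)}

    # -- candidate enumeration ------------------------------------------

    def _cuts(self, xs_sorted: np.ndarray, cap: bool = True) -> np.ndarray:
        """Valid cut positions k (left = first k sorted rows) honouring min_leaf.

        Nodes with at most 600 rows keep full threshold resolution; larger
        nodes subsample cut positions evenly down to ``max_candidates``.
        """
        m = xs_sorted.size
        lo, hi = self.min_leaf, m - self.min_leaf
        if hi < lo:
            return np.empty(0, dtype=int)
        ks = np.arange(lo, hi + 1)
        distinct = xs_sorted[ks - 1] < xs_sorted[ks]
        ks = ks[distinct]
        if cap and m > 600 and ks.size > self.max_candidates:
            sel = np.linspace(0, ks.size - 1, self.max_candidates).round().astype(int)
            ks = ks[np.unique(sel)]
        return ks

    def _best_split(self, idx: np.ndarray, feats: Sequence[int], cap: bool = True):
        """Best single split of rows idx into two optimal leaves.

        Returns (sum, j, threshold) or None if no feasible split exists.
        """
        best = None
        g = self.gamma[idx]
        for j in feats:
            xs = self.X[idx, j]
            order = np.argsort(xs, kind="stable")
            xs_s = xs[order]
            ks = self._cuts(xs_s, cap=cap)
            if ks.size == 0:
                continue
            csum = np.cumsum(g[order], axis=0)
            left = csum[ks - 1]
            right = csum[-1] - left
            vals = left.min(axis=1) + right.min(axis=1)
            b = int(np.argmin(vals))
            if best is None or vals[b] < best[0]:
                thr = 0.5 * (xs_s[ks[b] - 1] + xs_s[ks[b]])
                best = (float(vals[b]), j, float(thr))
        return best

    # -- greedy grow -----------------------------------------------------

    def grow(self, idx: np.ndarray, depth_left: int, rng: Optional[np.random.Generator]) -> Node:
        arm, leaf_sum, strength = self._leaf_stats(idx)
        leaf = Node(treatment=ARMS[arm], n_train=len(idx), strength=strength)
        if depth_left == 0 or len(idx) < 2 * self.min_leaf:
            return leaf
        feats = range(self.f)
        if rng is not None and self.f > 1:
            k = max(1, int(math.ceil(0.6 * self.f)))
            feats = rng.choice(self.f, size=k, replace=False)
        if depth_left == 2 and rng is None:
            node = self._grow_lookahead2(idx, leaf, leaf_sum)
            if node is not None:
                return node
        best = self._best_split(idx, feats)
        if best is None or best[0] >= leaf_sum - self.cp_sum:
            return leaf
        _, j, thr = best
        mask = self.X[idx, j] < thr
        node = Node(feature=self.names[j], threshold=thr,
                    missing_goes_left=bool(mask.sum() >= (~mask).sum()))
        node.left = self.grow(idx[mask], depth_left - 1, rng)
        node.right = self.grow(idx[~mask], depth_left - 1, rng)
        return node

    #: two-step lookahead work gate, in units of (candidate x feature) best-
    #: split evaluations; above this the myopic split is used instead.
    LOOKAHEAD_SORT_BUDGET = 20_000

    def _grow_lookahead2(self, idx: np.ndarray, leaf: Node,
                         leaf_sum: float) -> Optional[Node]:
        """Exact-ish depth-2 subtree: enumerate root cuts, optimizing each
        side as the better of a leaf and its best single split.

        Applied only when the estimated work fits the gate; returns None to
        fall back to the myopic grow otherwise. The penalized comparison
        charges cp per split, so with a large enough cp this still collapses
        to a leaf.
        """
        m = len(idx)
        est_cuts = min(max(m - 2 * self.min_leaf + 1, 0),
                       m if m <= 600 else self.max_candidates)
        if est_cuts * self.f * self.f > self.LOOKAHEAD_SORT_BUDGET:
            return None

        def side_best(side_idx: np.ndarray) -> tuple[float, Node]:
            arm, s, strength = self._leaf_stats(side_idx)
            best_s, best_n = s, Node(treatment=ARMS[arm], n_train=len(side_idx),
                                     strength=strength)
            cand = self._best_split(side_idx, range(self.f))
            if cand is not None and cand[0] + self.cp_sum < best_s:
                _, j, thr = cand
                mask = self.X[side_idx, j] < thr
                la, ls_, lst = self._leaf_stats(side_idx[mask])
                ra, rs_, rst = self._leaf_stats(side_idx[~mask])
                best_s = ls_ + rs_ + self.cp_sum
                best_n = Node(
                    feature=self.names[j], threshold=thr,
                    missing_goes_left=bool(mask.sum() >= (~mask).sum()),
                    left=Node(treatment=ARMS[la], n_train=int(mask.sum()), strength=lst),
                    right=Node(treatment=ARMS[ra], n_train=int((~mask).sum()), strength=rst),
                )
            return best_s, best_n

        best_obj, best_node = leaf_sum, None  # None means: keep the leaf
        for j in range(self.f):
            xs = self.X[idx, j]
            order = np.argsort(xs, kind="stable")
            xs_s = xs[order]
            for k in self._cuts(xs_s):
                thr = 0.5 * (xs_s[k - 1] + xs_s[k])
                mask = self.X[idx, j] < thr
                ls_, lnode = side_best(idx[mask])
                rs_, rnode = side_best(idx[~mask])
                total = ls_ + rs_ + self.cp_sum  # root split penalty
                if total < best_obj:
                    best_obj = total
                    best_node = Node(
                        feature=self.names[j], threshold=float(thr),
                        missing_goes_left=bool(mask.sum() >= (~mask).sum()),
                        left=lnode, right=rnode)
        return best_node if best_node is not None else leaf

    def grow_random(self, idx: np.ndarray, depth_left: int,
                    rng: np.random.Generator) -> Node:
        """Fully randomized initial tree: random feature, random valid cut.

        Used to diversify restart basins; refinement then polishes it.
        """
        arm, _, strength = self._leaf_stats(idx)
        leaf = Node(treatment=ARMS[arm], n_train=len(idx), strength=strength)
        if depth_left == 0 or len(idx) < 2 * self.min_leaf:
            return leaf
        for _ in range(self.f):  # a few attempts to find a splittable feature
            j = int(rng.integers(self.f))
            xs = self.X[idx, j]
            order = np.argsort(xs, kind="stable")
            ks = self._cuts(xs[order], cap=False)
            if ks.size:
                k = int(rng.choice(ks))
                thr = 0.5 * (xs[order][k - 1] + xs[order][k])
                mask = self.X[idx, j] < thr
                node = Node(feature=self.names[j], threshold=float(thr),
                            missing_goes_left=bool(mask.sum() >= (~mask).sum()))
                node.left = self.grow_random(idx[mask], depth_left - 1, rng)
                node.right = self.grow_random(idx[~mask], depth_left - 1, rng)
                return node
        return leaf

    def _leaf_stats(self, idx: np.ndarray) -> tuple[int, float, float]:
        return _leaf_stats(self.gamma, idx)

    # -- evaluation ------------------------------------------------------

    def assign(self, node: Node, idx: np.ndarray) -> Optional[float]:
        """Re-optimize leaf arms bottom-up for routing idx; return summed reward.

        Returns None if any leaf would fall below min_leaf (infeasible).
        Also refreshes n_train / strength / missing_goes_left annotations.
        """
        if node.is_leaf:
            if len(idx) < self.min_leaf:
                return None
            arm, s, strength = self._leaf_stats(idx)
            node.treatment, node.n_train, node.strength = ARMS[arm], len(idx), strength
            return s
        j = self._name_idx[node.feature]
        mask = self.X[idx, j] < node.threshold
        node.missing_goes_left = bool(mask.sum() >= (~mask).sum())
        ls = self.assign(node.left, idx[mask])
        if ls is None:
            return None
        rs = self.assign(node.right, idx[~mask])
        if rs is None:
            return None
        return ls + rs

    def penalized(self, node: Node, idx: np.ndarray) -> Optional[float]:
        s = self.assign(node, idx)
        if s is None:
            return None
        return s + self.cp_sum * _count_splits(node)

    def _fixed_values(self, node: Node, idx: np.ndarray) -> np.ndarray:
        """Per-row reward when routed through *node* with its current arms fixed."""
        out = np.empty(len(idx))
        arm_idx = {a: i for i, a in enumerate(ARMS)}

        def walk(n: Node, rows: np.ndarray, pos: np.ndarray) -> None:
            if rows.size == 0:
                return
            if n.is_leaf:
                out[pos] = self.gamma[rows, arm_idx[n.treatment]]
                return
            j = self._name_idx[n.feature]
            mask = self.X[rows, j] < n.threshold
            walk(n.left, rows[mask], pos[mask])
            walk(n.right, rows[~mask], pos[~mask])

        walk(node, idx, np.arange(len(idx)))
        return out

    # -- coordinate-descent refinement ------------------------------------

    #: exact-verification work budget: when (rows at node) x (candidate
    #: count) is below this, every candidate is verified exactly (leaf arms
    #: re-optimized); above it, only the best fixed-arm scan candidate per
    #: feature is verified.
    EXACT_VERIFY_BUDGET = 2_000_000

    def _resplit_candidates(self, node: Node, idx: np.ndarray) -> list[tuple[int, float]]:
        """Ordered (feature, threshold) proposals for re-splitting *node*.

        Candidates are ranked by the objective with the two subtrees' leaf
        arms held fixed; the caller verifies them exactly in this order.
        Within the work budget all candidates are returned, otherwise one
        per feature.
        """
        vl = self._fixed_values(node.left, idx)
        vr = self._fixed_values(node.right, idx)
        delta = vl - vr
        scored: list[tuple[float, int, float]] = []
        n_cands = 0
        for j in range(self.f):
            xs = self.X[idx, j]
            order = np.argsort(xs, kind="stable")
            xs_s = xs[order]
            ks = self._cuts(xs_s, cap=True)
            if ks.size == 0:
                continue
            n_cands += ks.size
            pref = np.cumsum(delta[order])
            vals = pref[ks - 1] + vr.sum()
            thrs = 0.5 * (xs_s[ks - 1] + xs_s[ks])
            scored.append((vals, j, thrs))
        if not scored:
            return []
        exhaustive_ok = len(idx) * n_cands <= self.EXACT_VERIFY_BUDGET
        out: list[tuple[float, int, float]] = []
        for vals, j, thrs in scored:
            if exhaustive_ok:
                out.extend((float(v), j, float(t)) for v, t in zip(vals, thrs))
            else:
                b = int(np.argmin(vals))
                out.append((float(vals[b]), j, float(thrs[b])))
        out.sort(key=lambda c: c[0])
        return [(j, t) for _, j, t in out[:64 if exhaustive_ok else 6]]

    def refine(self, root: Node) -> Node:
        """Coordinate-descent local search over internal nodes.

        Moves are prune (collapse a subtree to its best leaf) and re-split
        (replace a node's feature/threshold, re-optimizing the leaf arms
        below it). A move changes the objective only through the node's own
        subtree, so each candidate is verified exactly on that subtree's
        rows; a move is accepted only when the penalized objective strictly
        decreases, making the objective monotone non-increasing. After every
        accepted move the routing is recomputed, so proposals never act on
        stale row sets.
        """
        all_idx = np.arange(self.n)
        max_moves = min(self.max_passes * (max(_count_splits(root), 1) + 1), 48)
        for _ in range(max_moves):
            made = False
            for node, idx in _internal_nodes(root, self, all_idx):
                old_contrib = self.assign(node, idx)
                if old_contrib is None:  # cannot happen for a feasible tree
                    continue
                # prune move: collapse the subtree to a single leaf
                arm, leaf_sum, strength = self._leaf_stats(idx)
                saved = self.cp_sum * _count_splits(node)
                if leaf_sum < old_contrib + saved:
                    node.feature = node.threshold = node.left = node.right = None
                    node.treatment, node.n_train, node.strength = ARMS[arm], len(idx), strength
                    made = True
                    break
                # re-split move. When both children are leaves the proposal
                # is the exact best two-leaf split (joint over leaf arms);
                # otherwise scan (feature, threshold) candidates with the
                # subtrees' current leaf arms held fixed. Either way a
                # candidate is verified exactly before acceptance.
                if node.left.is_leaf and node.right.is_leaf:
                    cand = self._best_split(idx, range(self.f), cap=True)
                    candidates = [] if cand is None else [(cand[1], cand[2])]
                else:
                    candidates = self._resplit_candidates(node, idx)
                old = (node.feature, node.threshold)
                accepted = False
                for j, thr in candidates:
                    if (self.names[j], thr) == old:
                        continue
                    node.feature, node.threshold = self.names[j], thr
                    new_contrib = self.assign(node, idx)
                    if new_contrib is not None and new_contrib < old_contrib:
                        made = accepted = True
                        break
                    node.feature, node.threshold = old
                if accepted:
                    break
                if candidates:
                    self.assign(node, idx)  # restore annotations
            if not made:
                break
        self.assign(root, all_idx)
        return root


def _count_splits(n: Node) -> int:
    return 0 if n.is_leaf else 1 + _count_splits(n.left) + _count_splits(n.right)


def _internal_nodes(root: Node, opt: _Optimizer, all_idx: np.ndarray):
    """Yield (node, row index array routed to node), top-down."""
    out: list[tuple[Node, np.ndarray]] = []

    def walk(n: Node, idx: np.ndarray) -> None:
        if n.is_leaf:
            return
        out.append((n, idx))
        j = opt._name_idx[n.feature]
        mask = opt.X[idx, j] < n.threshold
        walk(n.left, idx[mask])
        walk(n.right, idx[~mask])

    walk(root, all_idx)
    return out


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------

def train_policy_tree(rewards, features, depth: int = 3, min_leaf: int = 20,
                      cp: float = 0.0, seed: int = 0, n_restarts: int = 5,
                      max_candidates: int = 48) -> PolicyTree:
    """Fit a policy tree minimizing mean prescribed reward + cp * n_splits.

    Randomized greedy grow followed by coordinate-descent split refinement,
    best of ``n_restarts`` starts (the first start is deterministic greedy
    over all features; later starts draw random feature subsets per node).
    The penalized objective never increases across accepted local-search
    moves. If ``min_leaf * 2**depth`` exceeds n, depth is reduced to the
    feasible maximum (with a warning in the returned metadata).

    Parameters mirror the cohort protocol defaults: at least 20 training
    rows per leaf, mortality scores minimized.
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    if min_leaf < 1:
        raise ConfigurationError("min_leaf must be >= 1")
    gamma, X, names = _as_gamma_features(rewards, features)
    n = len(gamma)
    if n < min_leaf:
        raise ConfigurationError(f"cannot fit: n={n} rows is below min_leaf={min_leaf}")
    warnings: list[str] = []
    if n < 2 * min_leaf:
        depth = 0
    elif min_leaf * 2 ** depth > n:
        feasible = int(math.floor(math.log2(max(n // min_leaf, 1))))
        warnings.append(
            f"min_leaf={min_leaf} x 2^depth exceeds n={n}; depth reduced "
            f"{depth} -> {feasible}"
        )
        depth = max(feasible, 1)
    opt = _Optimizer(gamma, X, names, depth, min_leaf, cp, max_candidates=max_candidates)
    all_idx = np.arange(n)
    best_root, best_obj = None, np.inf
    for r in range(max(n_restarts, 1)):
        rng = None if r == 0 else np.random.default_rng([seed & 0x7FFFFFFF, r])
        if r == 0:
            root = opt.grow(all_idx, depth, None)
        elif depth <= 3 and r % 2 == 1:
            # fully random starts are affordable (and useful) only for
            # shallow trees; deep trees restart from feature-subset greedy
            root = opt.grow_random(all_idx, depth, rng)
        else:
            root = opt.grow(all_idx, depth, rng)
        root = opt.refine(root)
        obj = opt.penalized(root, all_idx)
        if obj is not None and obj < best_obj:
            best_obj, best_root = obj, root
    opt.assign(best_root, all_idx)
    tree = PolicyTree(root=best_root, max_depth=depth, min_leaf=min_leaf, cp=cp,
                      objective=best_obj / max(n, 1),
                      metadata={"seed": int(seed), "n_restarts": int(n_restarts),
                                "n_train": int(n), "warnings": warnings})
    return tree


def exhaustive_policy_tree(rewards, features, depth: int = 2,
                           min_leaf: int = 1) -> PolicyTree:
    """Exact optimum over all axis-aligned trees of at most the given depth.

    Enumerates every split pair (thresholds at midpoints of adjacent observed
    values) and every leaf-arm assignment. Guarded to depth <= 2 and
    n <= 2000 rows; this is a test oracle, not a production fitter.
    """
    gamma, X, names = _as_gamma_features(rewards, features)
    n, f = X.shape
    if depth > 2:
        raise ConfigurationError("exhaustive enumeration is guarded to depth <= 2")
    if n > 2000:
        raise ConfigurationError("exhaustive enumeration is guarded to n <= 2000 rows")

    # self-contained enumeration: all midpoint thresholds, no candidate
    # subsampling, independent of the local-search machinery
    def all_cuts(xs_sorted: np.ndarray) -> np.ndarray:
        m = xs_sorted.size
        if m < 2 * min_leaf:
            return np.empty(0, dtype=int)
        ks = np.arange(min_leaf, m - min_leaf + 1)
        return ks[xs_sorted[ks - 1] < xs_sorted[ks]]

    def leaf_node(idx: np.ndarray) -> tuple[float, Node]:
        sums = gamma[idx].sum(axis=0)
        arm = int(np.argmin(sums))
        ordered = np.sort(sums)
        strength = float((ordered[1] - ordered[0]) / max(len(idx), 1))
        return float(sums[arm]), Node(treatment=ARMS[arm], n_train=len(idx),
                                      strength=strength)

    def best_depth1(idx: np.ndarray) -> tuple[float, Node]:
        best_sum, best = leaf_node(idx)
        g = gamma[idx]
        for j in range(f):
            xs = X[idx, j]
            order = np.argsort(xs, kind="stable")
            xs_s = xs[order]
            ks = all_cuts(xs_s)
            if ks.size == 0:
                continue
            csum = np.cumsum(g[order], axis=0)
            left = csum[ks - 1]
            right = csum[-1] - left
            vals = left.min(axis=1) + right.min(axis=1)
            b = int(np.argmin(vals))
            if vals[b] < best_sum:
                thr = float(0.5 * (xs_s[ks[b] - 1] + xs_s[ks[b]]))
                mask = X[idx, j] < thr
                _, lnode = leaf_node(idx[mask])
                _, rnode = leaf_node(idx[~mask])
                best_sum = float(vals[b])
                best = Node(feature=names[j], threshold=thr, left=lnode, right=rnode,
                            missing_goes_left=bool(mask.sum() >= (~mask).sum()))
        return best_sum, best

    all_idx = np.arange(n)
    best_sum, best = leaf_node(all_idx)
    if depth >= 1 and n >= 2 * min_leaf:
        s, node = best_depth1(all_idx)
        if s < best_sum:
            best_sum, best = s, node
    if depth == 2 and n >= 2 * min_leaf:
        for j in range(f):
            xs = X[:, j]
            order = np.argsort(xs, kind="stable")
            xs_s = xs[order]
            for k in all_cuts(xs_s):
                thr = float(0.5 * (xs_s[k - 1] + xs_s[k]))
                mask = xs < thr
                ls, lnode = best_depth1(all_idx[mask])
                rs, rnode = best_depth1(all_idx[~mask])
                if ls + rs < best_sum:
                    best_sum = ls + rs
                    best = Node(feature=names[j], threshold=thr,
                                left=lnode, right=rnode,
                                missing_goes_left=bool(mask.sum() >= (~mask).sum()))
    return PolicyTree(root=best, max_depth=depth, min_leaf=min_leaf, cp=0.0,
                      objective=best_sum / max(n, 1),
                      metadata={"method": "exhaustive"})


def tune(rewards_train, features_train, rewards_val, features_val,
         depth_grid: Sequence[int] = (3, 4, 5, 6, 7, 8),
         cp_grid: Sequence[float] = (0.0, 1e-4, 1e-3, 1e-2),
         min_leaf: int = 20, seed: int = 0, n_restarts: int = 3,
         max_candidates: int = 48) -> tuple[PolicyTree, pd.DataFrame]:
    """Grid search over (max depth, complexity penalty).

    Each cell fits on the training rewards and is scored by the mean reward
    its prescriptions select in the validation reward matrix (unpenalized).
    Selection follows the one-standard-error rule: among cells whose
    validation value is within one standard error of the best cell's, the
    simplest tree wins (fewest splits, then smallest depth, then smallest
    cp) — the doubly-robust scores are heavy-tailed on rare arms, and
    picking the raw minimum systematically rewards noise-chasing deep
    trees. Exact ties break toward the smallest depth then the smallest
    cp. The winning settings are refit on train+validation combined and
    returned with the full grid table.
    """
    if len(list(depth_grid)) == 0 or len(list(cp_grid)) == 0:
        raise ConfigurationError("depth_grid and cp_grid must be non-empty")
    gv, Xv, names_v = _as_gamma_features(rewards_val, features_val)
    rows = []
    fv = features_val if isinstance(features_val, pd.DataFrame) else pd.DataFrame(Xv, columns=names_v)
    for depth in sorted(depth_grid):
        for cp in sorted(cp_grid):
            t = train_policy_tree(rewards_train, features_train, depth=depth,
                                  min_leaf=min_leaf, cp=cp, seed=seed,
                                  n_restarts=n_restarts, max_candidates=max_candidates)
            pres = t.prescribe(fv)
            arm_idx = pres.map({a: i for i, a in enumerate(ARMS)}).to_numpy()
            picked = gv[np.arange(len(gv)), arm_idx]
            val = float(picked.mean())
            val_se = float(picked.std(ddof=1) / math.sqrt(max(len(picked), 2)))
            rows.append({"depth": depth, "cp": cp, "train_objective": t.objective,
                         "val_value": val, "val_se": val_se,
                         "n_splits": t.n_splits})
    table = pd.DataFrame(rows)
    i_best = int(table.val_value.idxmin())
    threshold = table.loc[i_best, "val_value"] + table.loc[i_best, "val_se"]
    eligible = table[table.val_value <= threshold]
    i_win = eligible.sort_values(["n_splits", "depth", "cp"],
                                 kind="stable").index[0]
    best = (float(table.loc[i_win, "val_value"]),
            int(table.loc[i_win, "depth"]), float(table.loc[i_win, "cp"]))
    # refit the winner on train + validation combined
    gt, Xt, names_t = _as_gamma_features(rewards_train, features_train)
    gamma_all = np.vstack([gt, gv])
    X_all = pd.DataFrame(np.vstack([Xt, Xv]), columns=names_t)
    winner = train_policy_tree(gamma_all, X_all, depth=best[1], min_leaf=min_leaf,
                               cp=best[2], seed=seed, n_restarts=n_restarts,
                               max_candidates=max_candidates)
    winner.metadata.update({"tuned_depth": best[1], "tuned_cp": best[2],
                            "val_value": best[0]})
    return winner, table
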