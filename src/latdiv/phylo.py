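"""Phylogeny construction and shape statistics for simulated clades.

The simulator records a budding genealogy: at each speciation event the
parent species persists and a daughter branches off.  :func:`extant_tree`
converts the species table into the reconstructed phylogeny of the species
alive at an observation time — internal nodes are speciation events with at
least two surviving descendant lineages, unary passages through extinct
ancestors are suppressed, and branch lengths are elapsed time steps, so the
tree is ultrametric.

Shape statistics:

* :func:`root_distances` — number of internal nodes between the root and
  each tip (the root counts as one); the regional mean of these, scaled by
  the tree-wide maximum, is the "mean root distance" diagnostic.
* :func:`beta_ml` — maximum-likelihood estimate of the beta-splitting
  imbalance parameter (0 under the Yule model, −2 at the perfectly
  imbalanced caterpillar limit, large and positive for balanced trees).
* :func:`equal_splits_rate` — the inverse equal-splits ("DR") tip-level
  speciation-rate proxy.
* :func:`lineage_event_rate` — the realised per-lineage speciation rate,
  counting actual branching events along a tip's root-to-tip path.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .simulate import ROOT_PARENT

__all__ = [
    "Node",
    "PhyloError",
    "extant_tree",
    "to_newick",
    "from_newick",
    "tips",
    "root_distances",
    "BetaResult",
    "beta_ml",
    "beta_loglik",
    "equal_splits_rate",
    "lineage_event_rate",
    "BETA_LOWER",
    "BETA_UPPER",
]

BETA_LOWER = -2.0
BETA_UPPER = 10.0


class PhyloError(ValueError):
    """Raised for trees too small or degenerate for a statistic."""


@dataclass
class Node:
    """Rooted binary tree node; tips carry species ids as labels."""

    label: int | str | None = None
    length: float | None = None  # branch length to the parent; None at the root
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


def _postorder(root: Node):
    """Iterative post-order traversal (trees can be thousands of tips deep)."""
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            yield node
        else:
            stack.append((node, True))
            for child in reversed(node.children):
                stack.append((child, False))


def tips(root: Node) -> list[Node]:
    return [n for n in _postorder(root) if n.is_tip]


# -- construction from the species table ---------------------------------


def _species_columns(species: pd.DataFrame):
    sid = species["species_id"].to_numpy(dtype=np.int64)
    order = np.argsort(sid)
    return (
        sid[order],
        species["parent_id"].to_numpy(dtype=np.int64)[order],
        species["origin_time"].to_numpy(dtype=np.int64)[order],
        species["extinction_time"].to_numpy(dtype=np.int64)[order],
    )


def extant_mask(species: pd.DataFrame, at_time: int) -> np.ndarray:
    """Boolean mask (in species-id order) of species alive at ``at_time``."""
    _, _, origin, ext = _species_columns(species)
    return (origin <= at_time) & ((ext < 0) | (ext > at_time))


def extant_tree(species: pd.DataFrame, at_time: int) -> Node:
    """Reconstructed phylogeny of the species extant at ``at_time``.

    The stem edge below the first informative split is dropped (the
    returned root is that split).  Simultaneous daughters of one parent are
    attached in species-id order, giving a deterministic binary resolution
    with zero-length internal edges.
    """
    sid, parent, origin, ext = _species_columns(species)
    if not np.array_equal(sid, np.arange(1, len(sid) + 1)):
        raise PhyloError("species_id must be contiguous 1..N in birth order")
    n_total = len(sid)
    alive = (origin <= at_time) & ((ext < 0) | (ext > at_time))
    if alive.sum() < 2:
        raise PhyloError(f"need >= 2 extant species at t={at_time}, found {int(alive.sum())}")

    # keep = species with at least one extant descendant (incl. itself);
    # children have larger ids than parents, so one reverse sweep suffices.
    keep = alive.copy()
    for i in range(n_total - 1, 0, -1):  # species id i+1; root (id 1) has no parent
        if keep[i] and origin[i] <= at_time:
            keep[parent[i] - 1] = True

    children: dict[int, list[int]] = {}
    for i in range(n_total):
        if keep[i] and parent[i] != ROOT_PARENT and origin[i] <= at_time:
            children.setdefault(parent[i], []).append(i + 1)

    # Build each kept species' lineage segment from the youngest branch point
    # backwards; processing ids in descending order guarantees every child's
    # subtree exists before its parent needs it.
    built: dict[int, tuple[Node, int]] = {}  # id -> (top node, node time)
    for i in range(n_total - 1, -1, -1):
        s = i + 1
        if not keep[i]:
            continue
        if alive[i]:
            cur: Node | None = Node(label=int(s))
            cur_time = at_time
        else:
            cur, cur_time = None, -1
        for c in sorted(children.get(s, ()), key=lambda c: (origin[c - 1], c), reverse=True):
            sub, sub_time = built[c]
            t_split = int(origin[c - 1])
            if cur is None:
                cur, cur_time = sub, sub_time
            else:
                cur.length = float(cur_time - t_split)
                sub.length = float(sub_time - t_split)
                cur = Node(children=[cur, sub])
                cur_time = t_split
        built[s] = (cur, cur_time)
        children.pop(s, None)

    root, _ = built[1]
    root.length = None
    return root


# -- Newick serialisation -------------------------------------------------


def _fmt_length(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def to_newick(root: Node) -> str:
    """Standard Newick with branch lengths; tip labels are bare species ids."""
    out = io.StringIO()
    # iterative depth-first writer: tokens are nodes or literal strings
    stack: list[object] = [root]
    while stack:
        item = stack.pop()
        if isinstance(item, str):
            out.write(item)
            continue
        node: Node = item
        suffix = "" if node.label is None else str(node.label)
        if node.length is not None:
            suffix += f":{_fmt_length(node.length)}"
        if node.is_tip:
            out.write(suffix)
        else:
            out.write("(")
            stack.append(")" + suffix)
            for j, child in enumerate(reversed(node.children)):
                if j:
                    stack.append(",")
                stack.append(child)
    return out.getvalue() + ";"


def from_newick(text: str) -> Node:
    """Parse Newick text (via dendropy) into this module's node type."""
    import dendropy

    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> Node:
        stack = [(dnode, None)]
        top = None
        # dendropy nodes can be deep; do an explicit two-pass conversion
        mapping = {}
        for nd in dnode.preorder_iter():
            label = nd.taxon.label if nd.taxon is not None else nd.label
            if label is not None:
                try:
                    label = int(label)
                except (TypeError, ValueError):
                    pass
            node = Node(label=label, length=nd.edge.length)
            mapping[id(nd)] = node
            if nd is dnode:
                top = node
                node.length = nd.edge.length if nd.edge.length else None
            else:
                mapping[id(nd.parent_node)].children.append(node)
        return top

    return convert(dtree.seed_node)


# -- root distances -------------------------------------------------------


def root_distances(root: Node) -> dict:
    """Tip label → number of internal nodes on the root-to-tip path.

    The root counts as one, so a two-tip tree gives 1 for both tips.
    """
    if root.is_tip or sum(1 for _ in _postorder(root)) < 3:
        raise PhyloError("root distances require a tree with >= 2 tips")
    out: dict = {}
    stack = [(root, 0)]
    while stack:
        node, depth = stack.pop()
        if node.is_tip:
            out[node.label] = depth
        else:
            for child in node.children:
                stack.append((child, depth + 1))
    return out


# -- beta-splitting maximum likelihood ------------------------------------


def _split_sizes(root: Node) -> list[tuple[int, int]]:
    """(clade size n, left-daughter size a) for internal nodes with n >= 3."""
    sizes: dict[int, int] = {}
    splits = []
    for node in _postorder(root):
        if node.is_tip:
            sizes[id(node)] = 1
        else:
            a, b = (sizes[id(c)] for c in node.children)
            sizes[id(node)] = a + b
            if a + b >= 3:
                splits.append((a + b, a))
    return splits


def beta_loglik(splits: list[tuple[int, int]], beta):
    """Log-likelihood of the observed splits under the beta-splitting model.

    A clade of ``n`` tips splits into (i, n−i) with probability
    ``q_n(i) ∝ Γ(β+i+1) Γ(β+n−i+1) / (Γ(i+1) Γ(n−i+1))``, normalised over
    i = 1..n−1; two-tip clades are uninformative.  ``beta`` may be a scalar
    or an array (evaluated pointwise).
    """
    beta_arr = np.atleast_1d(np.asarray(beta, dtype=float))
    by_n: dict[int, list[int]] = {}
    for n, a in splits:
        by_n.setdefault(n, []).append(a)
    ll = np.zeros(beta_arr.shape)
    for n, a_list in by_n.items():
        i = np.arange(1, n)
        log_q = (
            gammaln(beta_arr[:, None] + i + 1)
            + gammaln(beta_arr[:, None] + n - i + 1)
            - gammaln(i + 1)
            - gammaln(n - i + 1)
        )
        log_norm = logsumexp(log_q, axis=1)
        for a in a_list:
            ll += log_q[:, a - 1] - log_norm
    return float(ll[0]) if np.isscalar(beta) or np.ndim(beta) == 0 else ll


class BetaResult(NamedTuple):
    beta: float
    loglik: float
    at_boundary: bool

    def __float__(self) -> float:
        return self.beta


_BOUNDARY_EPS = 1e-6  # keep Γ arguments positive at the lower search edge


def beta_ml(tree_or_splits) -> BetaResult:
    """ML estimate of the beta-splitting imbalance parameter on [−2, 10].

    A coarse grid brackets the optimum, which a bounded golden-section /
    parabolic search then refines to 1e−4.  Optima pinned to an edge of the
    search interval are reported as the boundary value with
    ``at_boundary=True`` (the likelihood may be monotone there: a perfect
    caterpillar drives the estimate to −2, a fully balanced tree to +10).
    """
    if isinstance(tree_or_splits, Node):
        splits = _split_sizes(tree_or_splits)
    else:
        splits = list(tree_or_splits)
    if not splits:
        raise PhyloError("beta requires at least one informative split (>= 3 tips)")

    lo = BETA_LOWER + _BOUNDARY_EPS
    hi = BETA_UPPER
    grid = np.linspace(lo, hi, 61)
    vals = beta_loglik(splits, grid)
    j = int(np.argmax(vals))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda x: -beta_loglik(splits, x),
        bounds=(a, b),
        method="bounded",
        options={"xatol": 1e-4},
    )
    best_beta, best_ll = float(res.x), float(-res.fun)
    # the bracket endpoints can beat the interior optimum when monotone
    for cand in (a, b):
        v = beta_loglik(splits, cand)
        if v > best_ll:
            best_beta, best_ll = float(cand), float(v)
    if best_beta <= lo + 1e-3:
        return BetaResult(BETA_LOWER, beta_loglik(splits, lo), True)
    if best_beta >= hi - 1e-3:
        return BetaResult(BETA_UPPER, beta_loglik(splits, hi), True)
    return BetaResult(best_beta, best_ll, False)


# -- tip rate estimators --------------------------------------------------


def equal_splits_rate(root: Node) -> dict:
    """Inverse equal-splits ("DR") speciation-rate proxy per tip.

    For a tip whose root-ward branch lengths are l_1 (pendant) … l_d, the
    equal-splits measure is ES = Σ_j l_j · 2^−(j−1) and the rate is 1/ES.
    """
    if root.is_tip:
        raise PhyloError("equal-splits rates require >= 2 tips")
    out: dict = {}
    stack = [(root, 0.0)]
    while stack:
        node, acc = stack.pop()
        for child in node.children:
            es = acc / 2.0 + (child.length or 0.0)
            if child.is_tip:
                if es <= 0.0:
                    raise PhyloError(f"tip {child.label}: zero total path length")
                out[child.label] = 1.0 / es
            else:
                stack.append((child, es))
    return out


def lineage_event_rate(
    species: pd.DataFrame,
    events: pd.DataFrame | None,
    tip: int,
    at_time: int,
) -> float:
    """Realised speciation rate along one tip's root-to-tip lineage path.

    Counts the speciation events whose parent was the lineage segment
    occupying the path at the event time, divided by the elapsed time from
    the clade root's origin to ``at_time``.  The events may come from the
    run's event log; with ``events=None`` they are reconstructed from the
    species table (each child's origin time is its parent's event).
    """
    rates = lineage_event_rates(species, events, [tip], at_time)
    return rates[tip]


def lineage_event_rates(
    species: pd.DataFrame,
    events: pd.DataFrame | None,
    tip_ids,
    at_time: int,
) -> dict:
    """Vectorised :func:`lineage_event_rate` over many tips."""
    sid, parent, origin, ext = _species_columns(species)
    if events is not None:
        spec_events = events[events["type"] == "speciation"]
        ev_parent = spec_events["species_id"].to_numpy(dtype=np.int64)
        ev_time = spec_events["time"].to_numpy(dtype=np.int64)
    else:
        nonroot = parent != ROOT_PARENT
        ev_parent = parent[nonroot]
        ev_time = origin[nonroot]
    # per-parent sorted event times
    times_by_parent: dict[int, np.ndarray] = {}
    if len(ev_parent):
        order = np.lexsort((ev_time, ev_parent))
        ev_parent, ev_time = ev_parent[order], ev_time[order]
        cuts = np.nonzero(np.diff(ev_parent))[0] + 1
        for pid, chunk in zip(ev_parent[np.r_[0, cuts]], np.split(ev_time, cuts)):
            times_by_parent[int(pid)] = chunk

    root_origin = int(origin[0])
    denom = at_time - root_origin
    if denom <= 0:
        raise PhyloError("zero elapsed time on the lineage path")

    out: dict = {}
    for tip in tip_ids:
        tip = int(tip)
        i = tip - 1
        if not (origin[i] <= at_time and (ext[i] < 0 or ext[i] > at_time)):
            raise PhyloError(f"species {tip} is not extant at t={at_time}")
        # walk to the root collecting (segment species, tenure window)
        count = 0
        child_birth = at_time
        s = tip
        while True:
            j = s - 1
            t = times_by_parent.get(s)
            if t is not None:
                lo = np.searchsorted(t, int(origin[j]), side="right")
                hi = np.searchsorted(t, child_birth, side="right")
                count += int(hi - lo)
            if parent[j] == ROOT_PARENT:
                break
            child_birth = int(origin[j])
            s = int(parent[j])
        out[tip] = count / denom
    return out
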