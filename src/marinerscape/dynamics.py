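"""Amplification dynamics from tree node distributions over time (LTT).

Every internal node of a lineage tree corresponds to a duplicative
transposition. Node ages (substitutions/site before present, a lightweight
clock smoothing: mean node-to-descendant-tip path length) are accumulated
into a lineage-through-time curve and compared against the constant
per-copy transposition rate null N(t) = exp(r t), r = ln(n)/depth. The
shape of the per-bin rate relative to that null classifies the lineage
history: a past burst followed by decay, multiple bursts, an ongoing
burst, or rate constancy.

Trees are built in-house with neighbor joining on Jukes-Cantor distances
(negative branch lengths clamped to zero); externally built newick trees
can be ingested instead for parity runs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .model import LTTCurve

MAX_DISTANCE = 5.0
MIN_OVERLAP = 50


# ---------------------------------------------------------------------------
# alignment plumbing
# ---------------------------------------------------------------------------

def strip_insertions(rows: list[str], consensus_row: str) -> list[str]:
    """Delete alignment columns where the consensus has a gap."""
    keep = [i for i, sym in enumerate(consensus_row) if sym != "-"]
    return ["".join(r[i] for i in keep) for r in rows]


def jc69_distance_matrix(rows: list[str], max_distance: float = MAX_DISTANCE,
                         min_overlap: int = MIN_OVERLAP) -> np.ndarray:
    """Pairwise Jukes-Cantor distances d = -(3/4) ln(1 - (4/3) p).

    p is computed on shared non-gap sites; saturated pairs (p >= 0.75) and
    pairs sharing fewer than ``min_overlap`` sites get ``max_distance``.
    """
    n = len(rows)
    mat = np.frombuffer("".join(rows).encode("ascii"),
                        dtype=np.uint8).reshape(n, -1)
    is_res = mat != ord("-")
    d = np.zeros((n, n))
    for i in range(n):
        shared = is_res[i] & is_res
        overlap = shared.sum(axis=1)
        diff = ((mat[i] != mat) & shared).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(overlap > 0, diff / np.maximum(overlap, 1), 1.0)
            dist = np.where(p < 0.75, -0.75 * np.log(np.maximum(1e-300, 1 - 4 * p / 3)),
                            max_distance)
        dist = np.minimum(dist, max_distance)
        dist[overlap < min_overlap] = max_distance
        d[i] = dist
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'"


def _nj_newick(matrix: np.ndarray, labels: list[str]) -> str:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0."""
    labels = [_quote(lb) for lb in labels]
    n = len(labels)
    if n == 1:
        return f"{labels[0]}:0.0;"
    if n == 2:
        h = max(0.0, matrix[0, 1] / 2)
        return f"({labels[0]}:{h:.10g},{labels[1]}:{h:.10g});"
    D = matrix.astype(float).copy()
    nodes = list(labels)
    while len(nodes) > 2:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        Q = (r - 2) * D - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = D[i, j] / 2 + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        li, lj = max(0.0, li), max(0.0, lj)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dk = (D[i] + D[j] - D[i, j]) / 2
        keep = [k for k in range(r) if k not in (i, j)]
        D_new = np.empty((r - 1, r - 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = dk[keep]
        D_new[:-1, -1] = dk[keep]
        D_new[-1, -1] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [new]
    h = max(0.0, D[0, 1])
    return f"({nodes[0]}:{h / 2:.10g},{nodes[1]}:{h / 2:.10g});"


def nj_tree(matrix: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree as a dendropy Tree (arbitrary initial rooting)."""
    if len(labels) != matrix.shape[0]:
        raise ValueError("matrix/label size mismatch")
    newick = _nj_newick(matrix, labels)
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def root_with_outgroup(tree: dendropy.Tree, outgroup_label: str) -> dendropy.Tree:
    """Root on the outgroup's pendant edge (midpoint), then prune the outgroup."""
    tree = tree.clone(depth=1)
    leaf = None
    for lf in tree.leaf_node_iter():
        if lf.taxon is not None and lf.taxon.label == outgroup_label:
            leaf = lf
            break
    if leaf is None:
        raise KeyError(f"outgroup {outgroup_label!r} not in tree")
    edge = leaf.edge
    elen = edge.length or 0.0
    tree.reroot_at_edge(edge, length1=elen / 2, length2=elen / 2,
                        update_bipartitions=False)
    tree.prune_taxa([leaf.taxon], suppress_unifurcations=True)
    # after pruning, collapse a leftover unifurcate root onto the ingroup MRCA
    seed = tree.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        tree.seed_node = child
        child.parent_node = None
        child.edge.length = None
        seed = child
    return tree


def pairwise_path_lengths(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = [lf.taxon for lf in tree.leaf_node_iter() if lf.taxon is not None]
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1:]:
            out[tuple(sorted((t1.label, t2.label)))] = pdm.distance(t1, t2)
    return out


# ---------------------------------------------------------------------------
# node ages and the LTT curve
# ---------------------------------------------------------------------------

def node_ages(tree: dendropy.Tree, rule: str = "mean") -> list[float]:
    """Ages (time before present) of internal nodes, leaves at age 0.

    "mean": age = mean path length from the node to its descendant leaves
    (a lightweight clock smoothing). "max": maximum path length instead.
    """
    if rule not in {"mean", "max"}:
        raise ValueError(f"unknown node-age rule {rule!r}")
    ages = []
    stats: dict[dendropy.Node, tuple[float, int, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            stats[node] = (0.0, 1, 0.0)
        else:
            total, count, mx = 0.0, 0, 0.0
            for ch in node.child_nodes():
                csum, cn, cmx = stats[ch]
                el = ch.edge.length or 0.0
                total += csum + el * cn
                count += cn
                mx = max(mx, cmx + el)
            stats[node] = (total, count, mx)
            ages.append(total / count if rule == "mean" else mx)
    return ages


def ltt_curve(ages: list[float], n_leaves: int, bins: int = 10) -> LTTCurve:
    """Cumulative transposition events and per-bin per-copy rates.

    Nodes sorted oldest to youngest; the cumulative count climbs by one per
    node (final count n_leaves - 1 for a binary tree). The per-bin rate is
    events / (copy lineages alive x bin width), integrating the lineage
    count exactly between node times.
    """
    if n_leaves < 2 or not ages:
        return LTTCurve([], [], n_leaves, [], [], [], [], 0.0)
    ages_sorted = sorted(ages, reverse=True)
    depth = ages_sorted[0]
    cumulative = list(range(1, len(ages_sorted) + 1))
    if depth <= 0:
        return LTTCurve(ages_sorted, cumulative, n_leaves, [0.0, 0.0],
                        [len(ages_sorted)], [0.0], [float("nan")], 0.0)
    edges = [depth * (1 - b / bins) for b in range(bins + 1)]  # age: depth -> 0
    bin_events = [0] * bins
    for a in ages_sorted:
        b = min(bins - 1, int((depth - a) / depth * bins))
        bin_events[b] += 1
    # integrate N(t) (lineages alive at age t) over each bin
    bin_ct = [0.0] * bins
    # N(t) = 1 + number of nodes with age > t
    breakpoints = ages_sorted  # descending
    for b in range(bins):
        hi, lo = edges[b], edges[b + 1]
        t = hi
        k = sum(1 for a in breakpoints if a > hi)  # lineages - 1 at age hi
        idx = k
        while t > lo:
            nxt = breakpoints[idx] if idx < len(breakpoints) else lo
            seg_lo = max(lo, min(nxt, t))
            bin_ct[b] += (t - seg_lo) * (k + 1)
            if idx < len(breakpoints) and breakpoints[idx] >= seg_lo and seg_lo > lo:
                k += 1
                idx += 1
            t = seg_lo
    rates = [bin_events[b] / bin_ct[b] if bin_ct[b] > 0 else float("nan")
             for b in range(bins)]
    null_rate = math.log(n_leaves) / depth
    return LTTCurve(node_ages=ages_sorted, cumulative=cumulative,
                    n_leaves=n_leaves, bin_edges=edges, bin_events=bin_events,
                    bin_copy_time=bin_ct, rate_per_copy=rates,
                    null_rate=null_rate)


def constant_rate_null(n_leaves: int, total_depth: float):
    """Constant per-copy rate null: r = ln(n)/depth; E[events](t) = e^{rt} - 1.

    Returns (r, expected_cumulative_events) with t measured forward from
    the root.
    """
    if n_leaves < 2 or total_depth <= 0:
        raise ValueError("need n_leaves >= 2 and positive depth")
    r = math.log(n_leaves) / total_depth

    def expected(t: float) -> float:
        return math.exp(r * min(t, total_depth)) - 1.0

    return r, expected


def log_cumulative_linearity(curve: LTTCurve) -> float:
    """R^2 of log cumulative events vs time from the root (exponential check)."""
    if len(curve.node_ages) < 3:
        return float("nan")
    t = np.array([curve.node_ages[0] - a for a in curve.node_ages])
    y = np.log(np.array(curve.cumulative, dtype=float))
    t = t - t.mean()
    y = y - y.mean()
    denom = (t ** 2).sum() * (y ** 2).sum()
    if denom <= 0:
        return float("nan")
    return float((t * y).sum() ** 2 / denom)


# ---------------------------------------------------------------------------
# pattern classification
# ---------------------------------------------------------------------------

PSEUDO_EVENTS = 0.5  # regularizes near-root thirds holding ~0 expected events


def classify_dynamics(curve: LTTCurve, bins: int | None = None) -> str:
    """Label the amplification pattern of an LTT curve.

    Per-copy transposition rates are aggregated over thirds of the tree
    depth (oldest r1, middle r2, newest r3, with a small pseudo-count
    because the near-root era holds well under one expected event) and
    contrasted; per-bin rates are far too Poisson-noisy near the root to
    compare directly against the constant-rate null. Rules, in order:
      - single_burst_then_decay: >= 5 events in the oldest third, whose
        rate dominates (r1 >= 3 r3 and r1 >= 2 r2);
      - multiple_bursts: an old burst (>= 3 events, r1 >= 2 r2), a
        middle lull and a resurgence (r3 >= 2 r2);
      - ongoing_burst: the newest third dominates (r3 >= 2 r1 and
        r3 >= 2 r2);
      - constant otherwise (under a constant rate the three aggregated
        rates are statistically indistinguishable).
    """
    nbins = bins or (len(curve.bin_events) or 10)
    if len(curve.node_ages) < 10:
        return "insufficient"
    events = np.array(curve.bin_events, dtype=float)
    ct = np.array(curve.bin_copy_time, dtype=float)
    if ct.sum() <= 0:
        return "insufficient"
    third = nbins // 3
    seg = [slice(0, third), slice(third, nbins - third),
           slice(nbins - third, nbins)]
    C = [float(events[s].sum()) for s in seg]
    T = [max(float(ct[s].sum()), 1e-12) for s in seg]
    r1, r2, r3 = [(C[i] + PSEUDO_EVENTS) / T[i] for i in range(3)]

    if C[0] >= 5 and r1 >= 3 * r3 and r1 >= 2 * r2:
        return "single_burst_then_decay"
    if r3 >= 2 * r1 and r3 >= 2 * r2:
        return "ongoing_burst"
    # the inter-burst lull of a multiple-burst history is narrower than a
    # fixed middle third (burst tails leak in), so contrast both outer
    # thirds against the QUIETEST two-bin window in the interior
    lull = None
    for b in range(2, nbins - 3):
        cw = float(events[b:b + 2].sum())
        tw = max(float(ct[b:b + 2].sum()), 1e-12)
        rate = (cw + PSEUDO_EVENTS) / tw
        lull = rate if lull is None else min(lull, rate)
    if lull is not None and C[0] >= 3 and r1 >= 3 * lull and r3 >= 3 * lull:
        return "multiple_bursts"
    return "constant"


# ---------------------------------------------------------------------------
# high-level helper
# ---------------------------------------------------------------------------

@dataclass
class DynamicsResult:
    lineage_id: str
    curve: LTTCurve
    label: str
    age_rule: str = "mean"


def lineage_dynamics(profile_rows: list[str], labels: list[str],
                     lineage_id: str,
                     outgroup_row: str | None = None,
                     bins: int = 10, age_rule: str = "mean"
                     ) -> DynamicsResult:
    """Tree, node ages, LTT and pattern label for one (sub)lineage.

    ``profile_rows`` are copy sequences in consensus coordinates
    (insertions already stripped); the optional outgroup row is the
    closest other lineage's consensus expressed in the same coordinates,
    used for rooting and pruned before the LTT.
    """
    rows = list(profile_rows)
    names = list(labels)
    if outgroup_row is not None:
        rows.append(outgroup_row)
        names.append("__outgroup__")
    d = jc69_distance_matrix(rows)
    tree = nj_tree(d, names)
    if outgroup_row is not None and len(names) >= 3:
        tree = root_with_outgroup(tree, "__outgroup__")
    elif len(names) >= 3:
        tree.reroot_at_midpoint(update_bipartitions=False)
    ages = node_ages(tree, rule=age_rule)
    curve = ltt_curve(ages, n_leaves=len(profile_rows), bins=bins)
    label = classify_dynamics(curve, bins)
    curve.label = label
    return DynamicsResult(lineage_id=lineage_id, curve=curve, label=label,
                          age_rule=age_rule)
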