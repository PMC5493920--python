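"""Post-fit group-level summaries of a dynamic network clustering.

These are the tables behind the usual dynSBM reporting: per-block
connectivity (how often edges occur between groups q and l at step t, and at
which intensity), alluvial flows of memberships between consecutive steps
(with the special group 0 for absent entities), per-node stability
statistics, and contingency tables against external node labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmodel import MembershipTrajectories
from .netdata import DynamicNetwork, _atomic_write

__all__ = [
    "ConnectivityTable",
    "AlluvialFlows",
    "connectivity_summary",
    "alluvial_flows",
    "stability_stats",
    "cross_tabulate",
    "plot_connectivity",
    "plot_alluvial",
]


def _as_Z(Z) -> np.ndarray:
    return Z.Z if isinstance(Z, MembershipTrajectories) else np.asarray(Z, dtype=np.int64)


@dataclass
class ConnectivityTable:
    """Per (q, l, t) block cell: number of observable dyads, proportion of
    absent edges, and the category distribution among present edges.

    Cells with no observable dyad have ``n_possible = 0`` and NaN proportions
    (undefined, not zero).  For undirected networks the table is symmetric in
    (q, l) and each unordered dyad is counted once, in the cell with q <= l.
    """

    n_possible: np.ndarray        # (Q, Q, T) ints
    prop_absent: np.ndarray       # (Q, Q, T), NaN where undefined
    prop_category: np.ndarray     # (Q, Q, T, M), NaN where no present edge
    directed: bool

    @property
    def q_groups(self) -> int:
        return self.n_possible.shape[0]

    @property
    def n_steps(self) -> int:
        return self.n_possible.shape[2]

    def to_frame(self) -> pd.DataFrame:
        Q, T = self.q_groups, self.n_steps
        M = self.prop_category.shape[3]
        rows = []
        for q in range(Q):
            for l in range(Q):
                if not self.directed and l < q:
                    continue
                for t in range(T):
                    row = {"q": q + 1, "l": l + 1, "t": t + 1,
                           "n_possible": int(self.n_possible[q, l, t]),
                           "prop_absent": self.prop_absent[q, l, t]}
                    for m in range(M):
                        row[f"prop_cat_{m + 1}"] = self.prop_category[q, l, t, m]
                    rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        _atomic_write(path, self.to_frame().to_csv(index=False))


@dataclass
class AlluvialFlows:
    """Membership flow counts between consecutive steps, groups 0..Q where 0
    gathers absent entities; counts[t, a, b] nodes going a -> b from t to t+1."""

    counts: np.ndarray            # (T-1, Q+1, Q+1) ints

    @property
    def q_groups(self) -> int:
        return self.counts.shape[1] - 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        T1, G, _ = self.counts.shape
        for t in range(T1):
            for a in range(G):
                for b in range(G):
                    c = int(self.counts[t, a, b])
                    if c:
                        rows.append({"t": t + 1, "from": a, "to": b, "count": c})
        return pd.DataFrame(rows, columns=["t", "from", "to", "count"])

    def to_csv(self, path: str) -> None:
        _atomic_write(path, self.to_frame().to_csv(index=False))


def connectivity_summary(net: DynamicNetwork, Z) -> ConnectivityTable:
    """Count observable dyads and edge categories per block cell and step."""
    Zm = _as_Z(Z)
    if not np.array_equal(Zm > 0, net.presence):
        raise ValueError("memberships inconsistent with the presence mask")
    Q = int(Zm.max(initial=1))
    T, M = net.n_steps, net.n_categories
    cnt = np.zeros((Q, Q, T, M + 1), dtype=np.int64)   # m=0 slot filled later
    n_possible = np.zeros((Q, Q, T), dtype=np.int64)
    for t in range(T):
        p = np.flatnonzero(net.presence[:, t])
        g = Zm[p, t] - 1
        sizes = np.bincount(g, minlength=Q)
        if net.directed:
            n_possible[:, :, t] = np.outer(sizes, sizes)
            n_possible[np.arange(Q), np.arange(Q), t] -= sizes
        else:
            pairs = np.outer(sizes, sizes)
            np.fill_diagonal(pairs, sizes * (sizes - 1) // 2)
            n_possible[:, :, t] = pairs
        if net.self_loops:
            n_possible[np.arange(Q), np.arange(Q), t] += sizes
        sub = net.values[t][np.ix_(p, p)]
        n = p.size
        if net.directed:
            ii, jj = np.where(~np.eye(n, dtype=bool))
        else:
            ii, jj = np.triu_indices(n, k=1)
        np.add.at(cnt, (g[ii], g[jj], t, sub[ii, jj]), 1)
        if net.self_loops:
            np.add.at(cnt, (g, g, t, np.diagonal(sub)), 1)
    if not net.directed:
        # each unordered pair was tallied once under (g_i, g_j) with i < j;
        # fold off-diagonal cells so (q, l) and (l, q) carry the full count
        cnt = cnt + np.where(np.eye(Q, dtype=bool)[:, :, None, None], 0,
                             cnt.transpose(1, 0, 2, 3))
    edges = cnt[..., 1:].sum(axis=3)                    # (Q, Q, T) present edges
    with np.errstate(invalid="ignore", divide="ignore"):
        prop_absent = np.where(n_possible > 0,
                               (n_possible - edges) / n_possible, np.nan)
        prop_category = np.where(edges[..., None] > 0,
                                 cnt[..., 1:] / edges[..., None], np.nan)
    return ConnectivityTable(n_possible, prop_absent, prop_category,
                             net.directed)


def alluvial_flows(Z) -> AlluvialFlows:
    """Exact membership transition counts between consecutive snapshots,
    including flows into and out of the absent group 0."""
    Zm = _as_Z(Z)
    Q = int(Zm.max(initial=1))
    N, T = Zm.shape
    counts = np.zeros((max(T - 1, 0), Q + 1, Q + 1), dtype=np.int64)
    for t in range(T - 1):
        np.add.at(counts[t], (Zm[:, t], Zm[:, t + 1]), 1)
    return AlluvialFlows(counts)


def stability_stats(Z) -> tuple[float, pd.DataFrame]:
    """Fraction of nodes whose group never changes over their present steps,
    plus a per-node table (modal group, occupancy fraction, switch count).

    A switch is a change of group between *consecutive present* steps, so
    absence gaps are bridged.  Modal-group ties break toward the lowest group.
    """
    Zm = _as_Z(Z)
    rows = []
    never = []
    for i in range(Zm.shape[0]):
        groups = Zm[i][Zm[i] > 0]
        if groups.size == 0:
            continue
        n_switch = int(np.sum(groups[1:] != groups[:-1]))
        occ = np.bincount(groups)
        modal = int(np.argmax(occ))
        rows.append({
            "node": i,
            "modal_group": modal,
            "occupancy": occ[modal] / groups.size,
            "n_present": int(groups.size),
            "n_switches": n_switch,
            "never_switched": n_switch == 0,
        })
        never.append(n_switch == 0)
    table = pd.DataFrame(rows, columns=["node", "modal_group", "occupancy",
                                        "n_present", "n_switches",
                                        "never_switched"])
    fraction = float(np.mean(never)) if never else float("nan")
    return fraction, table


def cross_tabulate(Z, labels: dict[int, str],
                   min_occupancy_steps: int = 0) -> pd.DataFrame:
    """Contingency table of modal dynSBM group (rows) against an external
    node labelling (columns), restricted to labelled nodes that spend at
    least ``min_occupancy_steps`` present steps in their modal group."""
    _, per_node = stability_stats(Z)
    per_node = per_node.set_index("node")
    rows = []
    for node, lab in labels.items():
        if node not in per_node.index:
            continue
        rec = per_node.loc[node]
        if rec["occupancy"] * rec["n_present"] >= min_occupancy_steps - 1e-9:
            rows.append((int(rec["modal_group"]), lab))
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows, columns=["group", "label"])
    return pd.crosstab(df["group"], df["label"])


def stability_to_csv(Z, path: str) -> None:
    _, table = stability_stats(Z)
    _atomic_write(path, table.to_csv(index=False))


# ---------------------------------------------------------------------------
# optional plotting conveniences (tables above are the tested contract)

def plot_connectivity(table: ConnectivityTable, path: str | None = None):
    """Q x Q grid of stacked-area panels: white = absent edges, shaded bands =
    category shares among present edges, over time."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    Q, T = table.q_groups, table.n_steps
    M = table.prop_category.shape[3]
    fig, axes = plt.subplots(Q, Q, figsize=(2.2 * Q, 2.2 * Q),
                             squeeze=False, sharex=True, sharey=True)
    x = np.arange(1, T + 1)
    shades = [str(0.8 - 0.6 * m / max(M - 1, 1)) for m in range(M)]
    for q in range(Q):
        for l in range(Q):
            ax = axes[q][l]
            present = np.nan_to_num(1.0 - table.prop_absent[q, l], nan=0.0)
            bands = np.nan_to_num(table.prop_category[q, l], nan=0.0) * present[:, None]
            bottom = np.zeros(T)
            for m in range(M):
                ax.fill_between(x, bottom, bottom + bands[:, m],
                                color=shades[m], step="mid")
                bottom += bands[:, m]
            ax.set_ylim(0, 1)
            ax.set_title(f"({q + 1},{l + 1})", fontsize=8)
    fig.suptitle("block connectivity (shaded) by intensity category")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig


def plot_alluvial(flows: AlluvialFlows, path: str | None = None):
    """Minimal alluvial rendering: group occupancies as columns per step,
    line widths proportional to transition counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    counts = flows.counts
    T1, G, _ = counts.shape
    fig, ax = plt.subplots(figsize=(1.5 * (T1 + 1), 4))
    total = counts[0].sum() if T1 else 1
    for t in range(T1):
        for a in range(G):
            for b in range(G):
                c = counts[t, a, b]
                if c:
                    ax.plot([t, t + 1], [a, b], lw=8.0 * c / max(total, 1),
                            color="steelblue", alpha=0.6,
                            solid_capstyle="round")
    ax.set_yticks(range(G))
    ax.set_yticklabels([("absent (0)" if g == 0 else f"group {g}") for g in range(G)])
    ax.set_xlabel("time step")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
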