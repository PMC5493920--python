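"""Dynamic-network containers, plain-text I/O and ordinal weight binning.

A *dynamic network* is a sequence of T snapshots of a network on a common
node set of size N.  Nodes may be absent at some steps (species not sampled,
individuals not yet born...), recorded in an N x T presence mask; a dyad is
*observable* at step t only if both endpoints are present.  Edge values are
either raw non-negative weights (:class:`RawWeightedNetwork`) or ordinal
categories 0..M (:class:`DynamicNetwork`), 0 meaning "no edge".
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DynamicNetwork",
    "RawWeightedNetwork",
    "read_edge_list",
    "write_edge_list",
    "write_presence",
    "bin_weights",
    "write_memberships",
    "read_memberships",
]


class EdgeListError(ValueError):
    """Malformed or inconsistent edge-list / presence input."""


def _check_common(values: np.ndarray, presence: np.ndarray, directed: bool,
                  self_loops: bool) -> None:
    T, N, N2 = values.shape
    if N != N2:
        raise ValueError("snapshot matrices must be square")
    if presence.shape != (N, T):
        raise ValueError(f"presence must have shape (N, T)=({N}, {T})")
    if N < 2 or T < 1:
        raise ValueError("need N >= 2 nodes and T >= 1 steps")
    if not directed:
        if not np.array_equal(values, values.transpose(0, 2, 1)):
            raise ValueError("undirected network must have symmetric snapshots")
    if not self_loops and np.any(values[:, np.arange(N), np.arange(N)] != 0):
        raise ValueError("self-loops present but self_loops=False")
    # value only where both endpoints present
    obs = presence.T  # (T, N)
    both = obs[:, :, None] & obs[:, None, :]
    if np.any(values[~both] != 0):
        raise ValueError("nonzero value on a dyad with an absent endpoint")


@dataclass
class DynamicNetwork:
    """Categorical dynamic network: values in {0, 1, ..., M}; 0 = no edge.

    Attributes
    ----------
    values : (T, N, N) int array
    presence : (N, T) bool array, True where node i is present at step t
    n_categories : M; M = 1 means binary edges
    node_labels, step_labels : display labels (internal indices are 0-based)
    """

    values: np.ndarray
    presence: np.ndarray
    directed: bool
    self_loops: bool
    n_categories: int
    node_labels: list[str] = field(default_factory=list)
    step_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        if self.values.min(initial=0) < 0 or self.values.max(initial=0) > self.n_categories:
            raise ValueError("edge categories must lie in {0, ..., M}")
        _check_common(self.values, self.presence, self.directed, self.self_loops)
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(self.n_nodes)]
        if not self.step_labels:
            self.step_labels = [str(t + 1) for t in range(self.n_steps)]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    def observable_mask(self, t: int) -> np.ndarray:
        """(N, N) bool mask of observable ordered dyads at step t (diagonal
        included only when self-loops are allowed)."""
        p = self.presence[:, t]
        m = p[:, None] & p[None, :]
        if not self.self_loops:
            np.fill_diagonal(m, False)
        return m

    def n_observable_dyads(self) -> int:
        """Total dyad-step observations: ordered pairs if directed, unordered
        otherwise, self-loops counted once when enabled."""
        total = 0
        for t in range(self.n_steps):
            n_t = int(self.presence[:, t].sum())
            pairs = n_t * (n_t - 1)
            if not self.directed:
                pairs //= 2
            if self.self_loops:
                pairs += n_t
            total += pairs
        return total


@dataclass
class RawWeightedNetwork:
    """Same layout as :class:`DynamicNetwork` but with raw real weights >= 0."""

    values: np.ndarray
    presence: np.ndarray
    directed: bool
    self_loops: bool
    node_labels: list[str] = field(default_factory=list)
    step_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        if np.any(self.values < 0):
            raise ValueError("weights must be non-negative")
        _check_common(self.values, self.presence, self.directed, self.self_loops)
        if not self.node_labels:
            self.node_labels = [str(i) for i in range(self.values.shape[1])]
        if not self.step_labels:
            self.step_labels = [str(t + 1) for t in range(self.values.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]


def _parse_rows(path: str) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append([lineno, line.split("\t") if "\t" in line else line.split()])
    return rows


def read_edge_list(path: str, n_steps: int, directed: bool = False,
                   self_loops: bool = False,
                   presence_path: str | None = None) -> RawWeightedNetwork:
    """Read a TSV edge list (t, i, j[, w]) into a :class:`RawWeightedNetwork`.

    Time steps are 1-based in files.  The node set is the union of labels in
    the edge list and the presence file, indexed in first-appearance order.
    Without a presence file every node is present at every step; with one,
    an edge incident to a node not listed as present at that step is an error
    (absence must not be conflated with isolation).
    """
    node_index: dict[str, int] = {}

    def idx(label: str) -> int:
        if label not in node_index:
            node_index[label] = len(node_index)
        return node_index[label]

    edges: list[tuple[int, int, int, float]] = []
    for lineno, parts in _parse_rows(path):
        if len(parts) not in (3, 4):
            raise EdgeListError(f"{path}:{lineno}: expected 3 or 4 columns")
        try:
            t = int(parts[0])
            w = float(parts[3]) if len(parts) == 4 else 1.0
        except ValueError as exc:
            raise EdgeListError(f"{path}:{lineno}: malformed row") from exc
        if not 1 <= t <= n_steps:
            raise EdgeListError(f"{path}:{lineno}: time step {t} outside 1..{n_steps}")
        if w <= 0:
            raise EdgeListError(f"{path}:{lineno}: weight must be > 0")
        i, j = idx(parts[1]), idx(parts[2])
        if i == j and not self_loops:
            raise EdgeListError(f"{path}:{lineno}: self-loop but self_loops=False")
        edges.append((t - 1, i, j, w))

    presence_pairs: list[tuple[int, int]] | None = None
    if presence_path is not None:
        presence_pairs = []
        for lineno, parts in _parse_rows(presence_path):
            if len(parts) != 2:
                raise EdgeListError(f"{presence_path}:{lineno}: expected 2 columns")
            try:
                t = int(parts[1])
            except ValueError as exc:
                raise EdgeListError(f"{presence_path}:{lineno}: malformed row") from exc
            if not 1 <= t <= n_steps:
                raise EdgeListError(
                    f"{presence_path}:{lineno}: time step {t} outside 1..{n_steps}")
            presence_pairs.append((idx(parts[0]), t - 1))

    n = len(node_index)
    if n < 2:
        raise EdgeListError("network needs at least 2 nodes")
    values = np.zeros((n_steps, n, n))
    seen: set[tuple[int, int, int]] = set()
    for t, i, j, w in edges:
        key = (t, i, j)
        if key in seen or (not directed and (t, j, i) in seen):
            raise EdgeListError(f"duplicate edge ({t + 1}, {i}, {j})")
        seen.add(key)
        values[t, i, j] = w
        if not directed:
            values[t, j, i] = w

    if presence_pairs is None:
        presence = np.ones((n, n_steps), dtype=bool)
    else:
        presence = np.zeros((n, n_steps), dtype=bool)
        for i, t in presence_pairs:
            presence[i, t] = True
        for t, i, j, _ in edges:
            for node in (i, j):
                if not presence[node, t]:
                    raise EdgeListError(
                        f"edge at step {t + 1} incident to absent node "
                        f"{list(node_index)[node]!r}")

    labels = list(node_index)
    return RawWeightedNetwork(values, presence, directed, self_loops,
                              node_labels=labels)


def write_edge_list(net: RawWeightedNetwork | DynamicNetwork, path: str) -> None:
    """Write the TSV edge list (t, i, j, w); undirected pairs written once."""
    lines = []
    for t in range(net.n_steps):
        mat = net.values[t]
        ii, jj = np.nonzero(mat)
        for i, j in zip(ii.tolist(), jj.tolist()):
            if not net.directed and j < i:
                continue
            w = mat[i, j]
            w_str = str(int(w)) if float(w).is_integer() else repr(float(w))
            lines.append(f"{t + 1}\t{net.node_labels[i]}\t{net.node_labels[j]}\t{w_str}")
    _atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))


def write_presence(net: RawWeightedNetwork | DynamicNetwork, path: str) -> None:
    lines = []
    for i in range(net.n_nodes):
        for t in range(net.n_steps):
            if net.presence[i, t]:
                lines.append(f"{net.node_labels[i]}\t{t + 1}")
    _atomic_write(path, "\n".join(lines) + ("\n" if lines else ""))


def bin_weights(net: RawWeightedNetwork, m: int) -> DynamicNetwork:
    """Bin raw positive weights into m equal-frequency ordinal categories.

    Quantile thresholds are computed on the positive weights pooled over all
    steps and dyads, so a category means the same interaction intensity at
    every step.  Ties at a threshold go to the lower bin; zeros stay 0; m = 1
    simply binarizes.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    pos = net.values[net.values > 0]
    if m > 1:
        if np.unique(pos).size < m:
            raise ValueError(
                f"cannot form {m} non-empty bins from "
                f"{np.unique(pos).size} distinct positive weights")
        thresholds = np.quantile(pos, np.arange(1, m) / m)
    else:
        thresholds = np.array([])
    cats = np.zeros_like(net.values, dtype=np.int64)
    mask = net.values > 0
    # number of thresholds strictly below w, so w == threshold -> lower bin
    cats[mask] = np.searchsorted(thresholds, net.values[mask], side="left") + 1
    return DynamicNetwork(cats, net.presence, net.directed, net.self_loops, m,
                          node_labels=list(net.node_labels),
                          step_labels=list(net.step_labels))


def write_memberships(memberships: np.ndarray, path: str,
                      node_labels: list[str] | None = None) -> None:
    """Write a (node, t, group) TSV; group 0 marks absent node-steps."""
    Z = np.asarray(memberships)
    n, T = Z.shape
    labels = node_labels or [str(i) for i in range(n)]
    lines = [f"{labels[i]}\t{t + 1}\t{int(Z[i, t])}"
             for i in range(n) for t in range(T)]
    _atomic_write(path, "\n".join(lines) + "\n")


def read_memberships(path: str, n_steps: int) -> tuple[np.ndarray, list[str]]:
    """Inverse of :func:`write_memberships`; returns (Z, node_labels)."""
    node_index: dict[str, int] = {}
    entries = []
    for lineno, parts in _parse_rows(path):
        if len(parts) != 3:
            raise EdgeListError(f"{path}:{lineno}: expected 3 columns")
        label, t, g = parts[0], int(parts[1]), int(parts[2])
        if label not in node_index:
            node_index[label] = len(node_index)
        entries.append((node_index[label], t - 1, g))
    Z = np.zeros((len(node_index), n_steps), dtype=np.int64)
    for i, t, g in entries:
        Z[i, t] = g
    return Z, list(node_index)


def _atomic_write(path: str, text: str) -> None:
    tmp = f"{path}.tmp{os.getpid()}"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)
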