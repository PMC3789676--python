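"""De novo genetic map construction from an A/B marker matrix.

The procedure mirrors the classical MST-based mapping workflow for an
advanced RIL population treated as doubled haploids:

1. *Preprocess*: drop markers with > 20% missing calls, keep a single
   marker per reference contig (least missing, ties by position), drop
   markers whose missing + heterozygous fraction exceeds 10%, and set the
   remaining heterozygous calls to missing (DH treatment — the observed
   two-point fraction is used directly, without the RIL selfing
   correction R = 2r / (1 + 2r)).
2. *Group*: single-linkage clustering of markers whose two-point test of
   independence (chi-square, 1 df) gives p <= 1e-5; connected components
   of this graph are the linkage groups.
3. *Order*: within each group, markers with identical genotype vectors are
   collapsed into bins; a minimum spanning tree of the complete
   recombination-fraction graph seeds an initial order (depth-first
   traversal from one end of the tree's diameter), which is refined by
   2-opt segment reversals minimising the sum of adjacent recombination
   fractions.  Orientation of each group is arbitrary.
4. *Distances*: cumulative Kosambi-transformed adjacent recombination
   fractions, d = 25 * ln((1 + 2r) / (1 - 2r)) cM.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from gbsim.config import ConfigurationError, InputError
from gbsim.tables import CODE_A, CODE_B, CODE_H, CODE_MISSING, MarkerMatrix

R_CAP = 0.4999  # cap for distance transforms; kosambi diverges at 0.5


@dataclass(frozen=True)
class MapBuildParams:
    max_missing_marker: float = 0.20
    missing_threshold: float = 0.10     # missing + het fraction per marker
    cut_off_p: float = 1e-5
    distance_function: str = "kosambi"
    no_map_dist: float = 20.0
    no_map_size: int = 2
    apply_no_map: bool = False          # inert by default
    one_marker_per_contig: bool = True
    max_2opt_sweeps: int = 200

    def __post_init__(self) -> None:
        for p in (self.max_missing_marker, self.missing_threshold):
            if not (0.0 < p < 1.0):
                raise ConfigurationError("thresholds must lie in (0, 1)")
        if not (0.0 < self.cut_off_p < 1.0):
            raise ConfigurationError("cut_off_p must lie in (0, 1)")


@dataclass
class GeneticMap:
    """Ordered markers per linkage group with cM positions."""

    table: pd.DataFrame   # columns: marker_id, group, order_index, cM

    def __post_init__(self) -> None:
        for g, sub in self.table.groupby("group"):
            cm = sub.sort_values("order_index")["cM"].to_numpy()
            if np.any(np.diff(cm) < -1e-9):
                raise ValueError(f"cM not non-decreasing in group {g}")

    @property
    def groups(self) -> list[int]:
        return sorted(self.table["group"].unique())

    def group_sizes(self) -> dict[int, int]:
        return self.table.groupby("group").size().to_dict()


def kosambi(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map function: r -> cM.  Domain [0, 0.5)."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise InputError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi: cM -> recombination fraction."""
    d = np.asarray(d_cM, dtype=float)
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def preprocess_markers(
    matrix: MarkerMatrix, params: MapBuildParams = MapBuildParams(),
    use_contigs: bool | None = None,
) -> MarkerMatrix:
    """Apply the pre-mapping marker filters; hets become missing at the end.

    ``use_contigs`` defaults to the params flag when the matrix carries
    contig annotations, and is ignored otherwise.
    """
    calls = matrix.calls
    n = calls.shape[1]
    missing_frac = (calls == CODE_MISSING).sum(axis=1) / n
    keep = missing_frac <= params.max_missing_marker
    m = matrix.subset(keep)

    if use_contigs is None:
        use_contigs = params.one_marker_per_contig and m.contig is not None
    if use_contigs and m.contig is not None:
        miss = (m.calls == CODE_MISSING).sum(axis=1)
        df = pd.DataFrame({
            "contig": m.contig, "missing": miss,
            "pos": m.pos if m.pos is not None else np.arange(m.n_markers),
            "row": np.arange(m.n_markers)})
        chosen = (df.sort_values(["contig", "missing", "pos"])
                    .groupby("contig", sort=False).head(1)["row"]
                    .to_numpy())
        chosen.sort()
        m = m.subset(chosen)

    bad_frac = ((m.calls == CODE_MISSING) | (m.calls == CODE_H)).sum(axis=1) / n
    m = m.subset(bad_frac <= params.missing_threshold)
    if m.n_markers == 0:
        raise InputError("no markers survive the map pre-filters")
    out = m.calls.copy()
    out[out == CODE_H] = CODE_MISSING
    return MarkerMatrix(m.ids, out, list(m.samples), m.contig, m.pos)


def recombination_fraction(
    marker_x: np.ndarray, marker_y: np.ndarray,
) -> tuple[float, float, int]:
    """Two-point recombination estimate and independence test p-value.

    Over individuals non-missing at both markers, ``r_hat`` is the raw
    fraction of parental-class disagreements (capping at 0.4999 happens
    only at the distance transform) and the p-value comes from a 1-df
    chi-square test on the 2x2 class table.  Returns
    (r_hat, p_value, n_informative); r_hat is NaN when no individual is
    informative.
    """
    ok = (marker_x != CODE_MISSING) & (marker_y != CODE_MISSING)
    x = marker_x[ok]
    y = marker_y[ok]
    n = len(x)
    if n == 0:
        return float("nan"), 1.0, 0
    r_hat = float((x != y).mean())
    table = np.array([
        [np.sum((x == CODE_A) & (y == CODE_A)),
         np.sum((x == CODE_A) & (y == CODE_B))],
        [np.sum((x == CODE_B) & (y == CODE_A)),
         np.sum((x == CODE_B) & (y == CODE_B))],
    ])
    p = _chi2_p(table)
    return r_hat, p, n


def _chi2_p(table: np.ndarray) -> float:
    rs = table.sum(axis=1)
    cs = table.sum(axis=0)
    n = table.sum()
    if n == 0 or (rs == 0).any() or (cs == 0).any():
        return 1.0
    stat = n * (table[0, 0] * table[1, 1] - table[0, 1] * table[1, 0]) ** 2 \
        / (rs[0] * rs[1] * cs[0] * cs[1])
    return float(stats.chi2.sf(stat, 1))


def pairwise_linkage(
    calls: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (r_hat, p_value, n_informative) via matrix products.

    ``calls`` is (n_markers, n_individuals) over {A, B, missing}.  Returns
    square matrices; r_hat is NaN where no individual is informative.
    """
    a = (calls == CODE_A).astype(np.float64)
    b = (calls == CODE_B).astype(np.float64)
    n_aa = a @ a.T
    n_ab = a @ b.T
    n_ba = b @ a.T
    n_bb = b @ b.T
    n = n_aa + n_ab + n_ba + n_bb
    rec = n_ab + n_ba
    with np.errstate(invalid="ignore", divide="ignore"):
        r = rec / n
        rs0 = n_aa + n_ab
        rs1 = n_ba + n_bb
        cs0 = n_aa + n_ba
        cs1 = n_ab + n_bb
        stat = n * (n_aa * n_bb - n_ab * n_ba) ** 2 / (rs0 * rs1 * cs0 * cs1)
    degenerate = (n == 0) | (rs0 == 0) | (rs1 == 0) | (cs0 == 0) | (cs1 == 0)
    stat = np.where(degenerate, 0.0, stat)
    p = stats.chi2.sf(stat, 1)
    p = np.where(degenerate, 1.0, p)
    return r, p, n.astype(np.int64)


def group_markers(
    matrix: MarkerMatrix, params: MapBuildParams = MapBuildParams(),
) -> list[np.ndarray]:
    """Single-linkage clustering at the two-point p-value cutoff.

    Returns index arrays into ``matrix``; groups are sorted by decreasing
    size.
    """
    _r, p, n = pairwise_linkage(matrix.calls)
    g = nx.Graph()
    g.add_nodes_from(range(matrix.n_markers))
    ii, jj = np.nonzero(np.triu((p <= params.cut_off_p) & (n > 0), k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [np.array(sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=len, reverse=True)
    return comps


def _initial_order(r: np.ndarray) -> list[int]:
    """DFS preorder of the MST from one end of its (weighted) diameter."""
    n = r.shape[0]
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            w = r[i, j]
            g.add_edge(i, j, weight=0.5 if np.isnan(w) else w)
    mst = nx.minimum_spanning_tree(g)
    far = dict(nx.single_source_dijkstra_path_length(mst, 0))
    u = max(far, key=far.get)
    far_u = dict(nx.single_source_dijkstra_path_length(mst, u))
    # DFS from the diameter endpoint, visiting nearest children first
    order: list[int] = []
    seen = set()
    stack = [u]
    while stack:
        node = stack.pop()
        if node in seen:
            continue
        seen.add(node)
        order.append(node)
        nbrs = sorted(mst.neighbors(node),
                      key=lambda v: mst[node][v]["weight"], reverse=True)
        stack.extend(v for v in nbrs if v not in seen)
    return order


def _adjacent_sum(order: list[int], r: np.ndarray) -> float:
    w = r[order[:-1], order[1:]]
    return float(np.nansum(np.where(np.isnan(w), 0.5, w)))


def _two_opt(order: list[int], r: np.ndarray, max_sweeps: int) -> list[int]:
    """Local search on the adjacent-r sum: 2-opt reversals plus or-opt moves.

    2-opt reverses a segment; or-opt relocates a short segment (length
    1-3) elsewhere in the order.  Both neighbourhoods optimise the same
    objective and neither move is applied unless it strictly lowers the
    sum, so the refinement is monotone.
    """
    n = len(order)
    rr = np.where(np.isnan(r), 0.5, r)
    order = list(order)
    for _ in range(max_sweeps):
        improved = False
        # 2-opt: reverse order[i..j]
        for i in range(1, n - 1):
            a = order[i - 1]
            c = order[i]
            for j in range(i + 1, n):
                b = order[j]
                delta = rr[a, b] - rr[a, c]
                if j + 1 < n:
                    d = order[j + 1]
                    delta += rr[c, d] - rr[b, d]
                if delta < -1e-12:
                    order[i:j + 1] = reversed(order[i:j + 1])
                    c = order[i]
                    improved = True
        # or-opt: move order[i..i+L-1] to sit after position k
        for seg_len in (1, 2, 3):
            i = 0
            while i + seg_len <= n:
                seg = order[i:i + seg_len]
                rest = order[:i] + order[i + seg_len:]
                base_cut = _join_cost(order, rr, i, seg_len)
                best_gain, best_k, best_rev = 0.0, None, False
                for k in range(len(rest) + 1):
                    if k == i:  # same place
                        continue
                    for rev in (False, True):
                        s = seg[::-1] if rev else seg
                        gain = base_cut - _insert_cost(rest, rr, k, s)
                        if gain > best_gain + 1e-12:
                            best_gain, best_k, best_rev = gain, k, rev
                if best_k is not None:
                    s = seg[::-1] if best_rev else seg
                    order = rest[:best_k] + s + rest[best_k:]
                    improved = True
                else:
                    i += 1
        if not improved:
            break
    return order


def _join_cost(order: list[int], rr: np.ndarray, i: int,
               seg_len: int) -> float:
    """Change in adjacent-r sum from excising order[i:i+seg_len]."""
    n = len(order)
    cost = 0.0
    if i > 0:
        cost += rr[order[i - 1], order[i]]
    if i + seg_len < n:
        cost += rr[order[i + seg_len - 1], order[i + seg_len]]
    if i > 0 and i + seg_len < n:
        cost -= rr[order[i - 1], order[i + seg_len]]
    return cost


def _insert_cost(rest: list[int], rr: np.ndarray, k: int,
                 seg: list[int]) -> float:
    """Change in adjacent-r sum from inserting ``seg`` before rest[k]."""
    cost = 0.0
    if k > 0:
        cost += rr[rest[k - 1], seg[0]]
    if k < len(rest):
        cost += rr[seg[-1], rest[k]]
    if 0 < k < len(rest):
        cost -= rr[rest[k - 1], rest[k]]
    return cost


def order_markers(
    matrix: MarkerMatrix, params: MapBuildParams = MapBuildParams(),
) -> pd.DataFrame:
    """Order one linkage group; returns marker_id, order_index, cM.

    Markers with identical genotype vectors are collapsed into bins that
    share a cM position; bins are ordered by marker id for determinism.
    """
    calls = matrix.calls
    n_markers = matrix.n_markers
    if n_markers == 1:
        return pd.DataFrame({"marker_id": [matrix.ids[0]],
                             "order_index": [0], "cM": [0.0]})
    _uniq, inverse = np.unique(calls, axis=0, return_inverse=True)
    n_bins = _uniq.shape[0]
    bin_members: list[list[int]] = [[] for _ in range(n_bins)]
    for mi, bi in enumerate(inverse):
        bin_members[bi].append(mi)

    r, _p, _n = pairwise_linkage(_uniq)
    np.fill_diagonal(r, 0.0)
    if n_bins == 1:
        order = [0]
    elif n_bins == 2:
        order = [0, 1]
    else:
        order = _initial_order(r)
        order = _two_opt(order, r, params.max_2opt_sweeps)

    adj = np.array([min(R_CAP, r[order[k], order[k + 1]])
                    if not np.isnan(r[order[k], order[k + 1]]) else R_CAP
                    for k in range(len(order) - 1)])
    cm = np.concatenate([[0.0], np.cumsum(kosambi(adj))]) \
        if len(order) > 1 else np.array([0.0])

    rows = []
    oi = 0
    for k, bi in enumerate(order):
        for mi in sorted(bin_members[bi], key=lambda m: str(matrix.ids[m])):
            rows.append((matrix.ids[mi], oi, float(cm[k])))
            oi += 1
    return pd.DataFrame(rows, columns=["marker_id", "order_index", "cM"])


def build_map(
    matrix: MarkerMatrix, params: MapBuildParams = MapBuildParams(),
    preprocess: bool = True,
) -> GeneticMap:
    """Full map construction: preprocess, group, order, and assemble."""
    m = preprocess_markers(matrix, params) if preprocess else matrix
    groups = group_markers(m, params)
    if params.apply_no_map:
        groups = [g for g in groups if len(g) > params.no_map_size]
    frames = []
    for gi, idx in enumerate(groups, start=1):
        sub = m.subset(idx)
        ordered = order_markers(sub, params)
        ordered.insert(1, "group", gi)
        frames.append(ordered)
    table = pd.concat(frames, ignore_index=True)
    return GeneticMap(table)
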