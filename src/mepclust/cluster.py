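"""Hierarchical clustering with multiscale-bootstrap cluster support.

The complexes' similarity profiles (columns of the SI matrix, or of the
distance matrix if configured) are clustered with correlation distance,
d(i, j) = 1 - Pearson(col_i, col_j), and complete linkage.  Cluster
support is assessed by the multiscale bootstrap: for each scale factor
r the rows of the data matrix are resampled with replacement to size
round(r * n), the tree is rebuilt, and BP_r of a reference node is the
fraction of replicates whose tree contains the node's exact leaf set.
The approximately unbiased (AU) p-value of a node is obtained by fitting

    psi(r) = Phi^-1(1 - BP_r) = v sqrt(r) + c / sqrt(r)

by weighted least squares over the scales and setting
AU = 1 - Phi(v - c).  BP at r = 1 is the ordinary bootstrap probability.
Nodes with AU above the significance threshold (default 0.95, strict
inequality, root excluded) are flagged as significantly supported
clusters — the proxy for groups of cross-reactivity candidates.

Determinism: agglomeration ties are broken by the lexicographically
smallest merged leaf-label set, and every (scale, replicate) draws from
its own seed-derived stream, so results are bit-reproducible for a given
(seed, scales, nboot) and unchanged for early replicates when nboot
grows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError, ZeroVarianceError

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 10))


def correlation_distance(data: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None):
    """Pairwise correlation distance between columns: 1 - Pearson r.

    Rows are observations, columns are complexes.  A zero-variance
    column makes Pearson undefined and raises, naming the complex.
    """
    if isinstance(data, pd.DataFrame):
        labels = [str(c) for c in data.columns]
        mat = data.to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        labels = [str(i) for i in range(mat.shape[1])] if labels is None else list(labels)
    if mat.shape[1] < 3:
        raise DataError(f"at least 3 columns required, got {mat.shape[1]}")
    std = mat.std(axis=0)
    dead = np.where(std == 0)[0]
    if dead.size:
        raise ZeroVarianceError(
            "zero-variance similarity profile for: " + ", ".join(labels[i] for i in dead)
        )
    corr = np.corrcoef(mat, rowvar=False)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0), list(labels)


def _corr_dist_bootstrap(mat: np.ndarray) -> np.ndarray:
    """Correlation distance tolerant of degenerate resamples.

    A column that happens to be constant in a bootstrap replicate gets
    correlation 0 (distance 1) with every other column instead of
    failing the replicate.
    """
    std = mat.std(axis=0)
    safe = std > 0
    corr = np.zeros((mat.shape[1], mat.shape[1]))
    if safe.sum() >= 2:
        sub = np.corrcoef(mat[:, safe], rowvar=False)
        corr[np.ix_(safe, safe)] = sub
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


@dataclass
class ClusterTree:
    """A complete-linkage merge tree with per-node AU/BP support.

    Node ids: leaves are 0..n-1 in label order; internal node k (0-based
    merge order) has id n + k.  ``merges[k] = (left_id, right_id,
    height)``.  ``au``/``bp`` align with the merge order; NaN marks AU
    that could not be computed.
    """

    leaves: tuple[str, ...]
    merges: list[tuple[int, int, float]]
    au: np.ndarray | None = None
    bp: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def leafsets(self) -> list[frozenset[str]]:
        """Leaf-label set of each internal node, in merge order."""
        n = self.n_leaves
        sets: list[frozenset[str]] = [frozenset([lab]) for lab in self.leaves]
        out = []
        for left, right, _ in self.merges:
            s = sets[left] | sets[right]
            sets.append(s)
            out.append(s)
        return out

    def heights(self) -> np.ndarray:
        return np.array([h for _, _, h in self.merges])

    def significant_nodes(self, threshold: float = 0.95) -> list[frozenset[str]]:
        """Leaf sets of non-root nodes with AU strictly above ``threshold``."""
        if self.au is None:
            raise DataError("AU values not computed for this tree")
        sets = self.leafsets()
        flagged = []
        for k, s in enumerate(sets):
            if k == len(sets) - 1:
                continue  # root
            if np.isfinite(self.au[k]) and self.au[k] > threshold:
                flagged.append(s)
        return flagged

    def flagged_partition(self, threshold: float = 0.95) -> dict[str, int]:
        """Partition of the leaves induced by the flagged clusters.

        Each leaf is assigned to the *maximal* flagged cluster containing
        it — the pvclust ``pvpick`` convention of reporting the largest
        supported clusters (flagged clusters are nested, so the largest
        one containing a leaf is unique); a leaf in no flagged cluster
        becomes a singleton.
        """
        flagged = sorted(self.significant_nodes(threshold), key=len, reverse=True)
        assignment: dict[str, int] = {}
        next_id = 0
        group_of_set: dict[frozenset[str], int] = {}
        for leaf in self.leaves:
            home = next((s for s in flagged if leaf in s), None)
            if home is None:
                assignment[leaf] = next_id
                next_id += 1
            else:
                if home not in group_of_set:
                    group_of_set[home] = next_id
                    next_id += 1
                assignment[leaf] = group_of_set[home]
        return assignment

    def nodes_frame(self) -> pd.DataFrame:
        """Per-internal-node table: id, leaf set, height, AU, BP."""
        n = self.n_leaves
        sets = self.leafsets()
        rows = []
        for k, (left, right, h) in enumerate(self.merges):
            rows.append(
                {
                    "node": n + k,
                    "leaf_set": ",".join(sorted(sets[k])),
                    "height": h,
                    "au": float(self.au[k]) if self.au is not None else np.nan,
                    "bp": float(self.bp[k]) if self.bp is not None else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        """Newick with AU (scaled 0-100) as internal-node support values."""
        n = self.n_leaves
        heights = [0.0] * n + [h for _, _, h in self.merges]

        def render(node: int, parent_height: float) -> str:
            blen = max(parent_height - heights[node], 0.0)
            if node < n:
                return f"{self.leaves[node]}:{blen:.6g}"
            k = node - n
            left, right, h = self.merges[k]
            inner = f"({render(left, h)},{render(right, h)})"
            support = ""
            if self.au is not None and np.isfinite(self.au[k]):
                support = f"{100.0 * self.au[k]:.2f}"
            return f"{inner}{support}:{blen:.6g}"

        root = n + len(self.merges) - 1
        _, _, root_h = self.merges[-1]
        left, right, _ = self.merges[-1]
        body = f"({render(left, root_h)},{render(right, root_h)})"
        if self.au is not None and np.isfinite(self.au[-1]):
            body += f"{100.0 * self.au[-1]:.2f}"
        return body + ";"


def complete_linkage(
    dist: np.ndarray, labels: Sequence[str] | None = None
) -> ClusterTree:
    """Deterministic complete-linkage agglomeration.

    Inter-cluster distance is the maximum pairwise member distance;
    among equal-distance candidate merges the pair whose merged,
    sorted leaf-label tuple is lexicographically smallest is chosen.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise DataError("distance matrix must be square")
    if np.abs(dist - dist.T).max() > 1e-9:
        raise DataError("distance matrix is not symmetric (tolerance 1e-9)")
    labels = [str(i) for i in range(n)] if labels is None else [str(x) for x in labels]
    if len(labels) != n:
        raise DataError("label count does not match matrix size")

    m = 2 * n - 1
    work = np.full((m, m), np.inf)
    work[:n, :n] = 0.5 * (dist + dist.T)  # exact symmetry for the tie scan
    np.fill_diagonal(work, np.inf)
    active = np.zeros(m, dtype=bool)
    active[:n] = True
    leaf_tuples: list[tuple[str, ...]] = [(lab,) for lab in labels]
    merges: list[tuple[int, int, float]] = []

    for step in range(n - 1):
        idx = np.where(active)[0]
        sub = work[np.ix_(idx, idx)]
        iu = np.triu_indices_from(sub, k=1)
        tri = sub[iu]
        dmin = tri.min()
        hits = np.where(tri == dmin)[0]
        best = None
        for h in hits:
            a, b = iu[0][h], iu[1][h]
            i, j = int(idx[a]), int(idx[b])
            key = tuple(sorted(leaf_tuples[i] + leaf_tuples[j]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        new = n + step
        merged_rows = np.maximum(work[i], work[j])
        work[new, :] = merged_rows
        work[:, new] = merged_rows
        work[new, new] = np.inf
        active[i] = active[j] = False
        active[new] = True
        # deterministic child order: smaller leaf-tuple first
        left, right = (i, j) if leaf_tuples[i] <= leaf_tuples[j] else (j, i)
        merges.append((left, right, float(dmin)))
        leaf_tuples.append(tuple(sorted(leaf_tuples[i] + leaf_tuples[j])))

    return ClusterTree(leaves=tuple(labels), merges=merges)


@dataclass(frozen=True)
class BootstrapTable:
    """Per-node, per-scale bootstrap counts and probabilities."""

    leafsets: tuple[frozenset[str], ...]  # internal nodes, merge order
    scales: tuple[float, ...]
    nboot: int
    counts: np.ndarray  # n_nodes x n_scales
    seed: int

    @property
    def bp(self) -> np.ndarray:
        return self.counts / self.nboot


def _replicate_leafsets(dist: np.ndarray) -> set[frozenset[int]]:
    """Internal-node leaf-index sets of a complete-linkage tree (lean path)."""
    tree = complete_linkage(dist)
    out: set[frozenset[int]] = set()
    n = tree.n_leaves
    sets: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    for left, right, _ in tree.merges:
        s = sets[left] | sets[right]
        sets.append(s)
        out.add(s)
    return out


def multiscale_bootstrap(
    data: pd.DataFrame | np.ndarray,
    scales: Sequence[float] | None = None,
    nboot: int = 1000,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> tuple[BootstrapTable, ClusterTree]:
    """Multiscale row-resampling bootstrap of the cluster tree.

    Returns the bootstrap table and the reference tree (built from the
    full data).  Per-(scale, replicate) random streams are derived from
    the master seed so the table is bit-reproducible and early
    replicates are unchanged when ``nboot`` grows.
    """
    if nboot < 1:
        raise DataError("nboot must be >= 1")
    scales = tuple(DEFAULT_SCALES if scales is None else scales)
    if any(r <= 0 for r in scales):
        raise DataError("all scales must be > 0")
    if isinstance(data, pd.DataFrame):
        labels = [str(c) for c in data.columns]
        mat = data.to_numpy(dtype=float)
    else:
        mat = np.asarray(data, dtype=float)
        labels = [str(i) for i in range(mat.shape[1])] if labels is None else list(labels)
    n_rows = mat.shape[0]

    ref_dist, labels = correlation_distance(mat, labels)
    ref_tree = complete_linkage(ref_dist, labels)
    node_sets_labels = ref_tree.leafsets()
    index_of = {lab: i for i, lab in enumerate(labels)}
    node_sets = [frozenset(index_of[lab] for lab in s) for s in node_sets_labels]

    counts = np.zeros((len(node_sets), len(scales)), dtype=int)
    for si, r in enumerate(scales):
        m_rows = int(round(r * n_rows))
        if m_rows < 2:
            raise DataError(f"scale {r}: resample size {m_rows} < 2 rows")
        for b in range(nboot):
            rng = np.random.Generator(
                np.random.PCG64(np.random.SeedSequence((seed, si, b)))
            )
            rows = rng.integers(0, n_rows, size=m_rows)
            rep_sets = _replicate_leafsets(_corr_dist_bootstrap(mat[rows]))
            for k, s in enumerate(node_sets):
                if s in rep_sets:
                    counts[k, si] += 1

    table = BootstrapTable(
        leafsets=tuple(node_sets_labels),
        scales=scales,
        nboot=nboot,
        counts=counts,
        seed=seed,
    )
    ref_tree.params = {"scales": scales, "nboot": nboot, "seed": seed}
    return table, ref_tree


def au_from_bp(table: BootstrapTable) -> tuple[np.ndarray, np.ndarray]:
    """AU p-values from the multiscale BP curves; also returns plain BP.

    Per node: psi_r = Phi^-1(1 - BP_r) is fitted as v sqrt(r) + c/sqrt(r)
    by WLS (weights nboot * pdf(psi_r)^2 / (BP_r (1 - BP_r)), the
    standard multiscale-bootstrap variance), and AU = 1 - Phi(v - c).
    Degenerate nodes: BP_r = 1 at all scales -> AU = 1; BP_r = 0 at all
    scales -> AU = 0; otherwise scales with BP_r in {0, 1} are excluded
    and fewer than 2 usable scales leaves AU as NaN with a warning.
    The returned plain BP is the column at the scale closest to r = 1.
    """
    scales = np.asarray(table.scales, dtype=float)
    bp_all = table.bp
    n_nodes = bp_all.shape[0]
    au = np.full(n_nodes, np.nan)
    r1 = int(np.argmin(np.abs(scales - 1.0)))
    bp_plain = bp_all[:, r1].astype(float)

    for k in range(n_nodes):
        bp = bp_all[k]
        if np.all(bp >= 1.0):
            au[k] = 1.0
            continue
        if np.all(bp <= 0.0):
            au[k] = 0.0
            continue
        usable = (bp > 0.0) & (bp < 1.0)
        if usable.sum() < 2:
            warnings.warn(
                f"node {k}: fewer than 2 non-degenerate scales; AU not computed",
                stacklevel=2,
            )
            continue
        r = scales[usable]
        p = bp[usable]
        psi = norm.ppf(1.0 - p)
        design = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
        weights = table.nboot * norm.pdf(psi) ** 2 / (p * (1.0 - p))
        wd = design * weights[:, None]
        try:
            beta = np.linalg.solve(design.T @ wd, wd.T @ psi)
        except np.linalg.LinAlgError:
            warnings.warn(f"node {k}: singular AU fit; AU not computed", stacklevel=2)
            continue
        v, c = beta
        au[k] = float(np.clip(1.0 - norm.cdf(v - c), 0.0, 1.0))
    return au, bp_plain


def cluster_with_support(
    data: pd.DataFrame | np.ndarray,
    scales: Sequence[float] | None = None,
    nboot: int = 1000,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> ClusterTree:
    """Reference tree with AU/BP attached: the full clustering stage."""
    table, tree = multiscale_bootstrap(data, scales=scales, nboot=nboot, seed=seed, labels=labels)
    tree.au, tree.bp = au_from_bp(table)
    return tree
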