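"""Hierarchical clustering of specific-IgE profiles with bootstrap support.

Allergen columns of the IgE matrix are clustered by average linkage (UPGMA)
on correlation distance, d(a, b) = 1 - Pearson r over shared non-missing
sera.  Clade confidence comes from resampling sera (rows) with replacement:

- BP, the ordinary bootstrap probability: the fraction of replicate trees
  that contain the clade;
- AU, the approximately unbiased p-value from multiscale bootstrap: BP is
  measured at several resample-size scales r (resample size round(r*n)),
  each BP_r is probit-transformed, z_r = Phi^-1(1 - BP_r), the curve
  z(r) = v*sqrt(r) + c/sqrt(r) is fitted by weighted least squares, and
  AU = 1 - Phi(v - c).  The fitted v is a signed distance and c a curvature
  term of the clade's boundary in resampling space.

Ties in the agglomeration are broken deterministically by the
lexicographically smallest pair of cluster labels, so the tree is invariant
to input column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import AnalysisError

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


# -- distance -------------------------------------------------------------


def correlation_distance(matrix: pd.DataFrame,
                         min_rows: int = 3,
                         undefined: float = 1.0) -> pd.DataFrame:
    """1 - Pearson correlation between allergen columns.

    Correlations use pairwise-complete rows (no value imputation).  Columns
    with zero variance are excluded with a warning; pairs with fewer than
    two complete rows get the *undefined* distance (1.0, i.e. r = 0).
    """
    if len(matrix) < min_rows:
        raise AnalysisError(f"need >= {min_rows} sera rows for correlation distance")
    data = matrix.astype(float)
    variances = data.var(axis=0, skipna=True)
    bad = [c for c in data.columns if not np.isfinite(variances[c]) or variances[c] == 0.0]
    if bad:
        warnings.warn(f"zero-variance columns excluded from clustering: {bad}",
                      stacklevel=2)
        data = data.drop(columns=bad)
    if data.shape[1] < 2:
        raise AnalysisError("fewer than 2 usable columns")
    corr = data.corr(method="pearson", min_periods=2)
    dist = 1.0 - corr
    dist = dist.fillna(undefined)
    np.fill_diagonal(dist.values, 0.0)
    return dist


# -- UPGMA ----------------------------------------------------------------


@dataclass(frozen=True)
class DendroNode:
    """One node of the merge tree; leaves have height 0 and no children."""

    leaves: frozenset[str]
    height: float
    children: tuple["DendroNode", "DendroNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    @property
    def label(self) -> str:
        # representative label: lexicographically first leaf
        return min(self.leaves)


@dataclass
class Dendrogram:
    """Binary UPGMA merge tree over allergen labels."""

    root: DendroNode
    leaf_order: list[str] = field(default_factory=list)

    @property
    def leaves(self) -> frozenset[str]:
        return self.root.leaves

    def internal_nodes(self) -> list[DendroNode]:
        """Internal nodes, root last, excluding trivial single-leaf nodes."""
        out: list[DendroNode] = []

        def walk(node: DendroNode) -> None:
            if node.children is None:
                return
            for ch in node.children:
                walk(ch)
            out.append(node)

        walk(self.root)
        return out

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes (the units that get support values)."""
        return [n.leaves for n in self.internal_nodes()]

    def heights(self) -> dict[frozenset[str], float]:
        return {n.leaves: n.height for n in self.internal_nodes()}


def average_linkage_cluster(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration of a symmetric distance matrix.

    Inter-cluster distance is the size-weighted average of member
    distances (equivalently the mean over all leaf pairs).  The minimum-
    distance pair is chosen with ties broken by the lexicographically
    smallest (sorted) pair of cluster key tuples, making the result
    independent of input order.
    """
    labels = [str(c) for c in distances.columns]
    if len(labels) < 2:
        raise AnalysisError("need >= 2 items to cluster")
    d: dict[tuple[str, ...], dict[tuple[str, ...], float]] = {}
    nodes: dict[tuple[str, ...], DendroNode] = {}
    sizes: dict[tuple[str, ...], int] = {}
    keys: list[tuple[str, ...]] = []
    mat = distances.to_numpy(float)
    for i, a in enumerate(labels):
        key = (a,)
        keys.append(key)
        nodes[key] = DendroNode(leaves=frozenset([a]), height=0.0)
        sizes[key] = 1
        d[key] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                val = float(mat[i, j])
                d[(a,)][(b,)] = val
                d[(b,)][(a,)] = val

    active = sorted(keys)
    while len(active) > 1:
        best: tuple[float, tuple[str, ...], tuple[str, ...]] | None = None
        for i, ka in enumerate(active):
            for kb in active[i + 1:]:
                cand = (d[ka][kb], ka, kb)
                if best is None or cand < best:
                    best = cand
        height, ka, kb = best
        merged_key = tuple(sorted(ka + kb))
        merged = DendroNode(leaves=nodes[ka].leaves | nodes[kb].leaves,
                            height=height,
                            children=(nodes[ka], nodes[kb]))
        nodes[merged_key] = merged
        sizes[merged_key] = sizes[ka] + sizes[kb]
        d[merged_key] = {}
        for kc in active:
            if kc in (ka, kb):
                continue
            val = (sizes[ka] * d[ka][kc] + sizes[kb] * d[kb][kc]) / (sizes[ka] + sizes[kb])
            d[merged_key][kc] = val
            d[kc][merged_key] = val
        active = sorted(k for k in active if k not in (ka, kb)) + [merged_key]
        active.sort()

    root_key = active[0]
    order: list[str] = []

    def collect(node: DendroNode) -> None:
        if node.children is None:
            order.append(next(iter(node.leaves)))
        else:
            for ch in sorted(node.children, key=lambda n: n.label):
                collect(ch)

    root = nodes[root_key]
    collect(root)
    return Dendrogram(root=root, leaf_order=order)


# -- bootstrap support ----------------------------------------------------


@dataclass
class ClusterSupport:
    """Per-clade support values of an observed dendrogram.

    ``table`` is indexed by node id (0..k-1, in :meth:`Dendrogram.clades`
    order) with columns ``leaves`` (sorted tuple), ``bp`` and — after
    multiscale fitting — ``au``, ``v``, ``c`` and ``degenerate``.
    """

    table: pd.DataFrame
    B: int
    scales: tuple[float, ...] = (1.0,)

    def bp_of(self, leaves: frozenset[str]) -> float:
        key = tuple(sorted(leaves))
        match = self.table[self.table["leaves"] == key]
        if not len(match):
            raise KeyError(f"no such clade: {key}")
        return float(match["bp"].iloc[0])

    def au_of(self, leaves: frozenset[str]) -> float:
        key = tuple(sorted(leaves))
        match = self.table[self.table["leaves"] == key]
        if not len(match) or "au" not in match:
            raise KeyError(f"no AU for clade: {key}")
        return float(match["au"].iloc[0])

    def to_csv(self, path, comment: str | None = None):
        from pathlib import Path
        path = Path(path)
        df = self.table.copy()
        df["leaves"] = df["leaves"].map(lambda t: "|".join(t))
        text = df.to_csv(index_label="node", float_format="%.6g")
        if comment:
            text = f"# {comment}\n" + text
        path.write_text(text)
        return path


def _count_clades(matrix: pd.DataFrame,
                  clades: Sequence[frozenset[str]],
                  n_resample: int,
                  B: int,
                  rng: np.random.Generator) -> np.ndarray:
    """How many of B row-resampled trees contain each clade."""
    counts = np.zeros(len(clades), dtype=int)
    n = len(matrix)
    values = matrix.to_numpy(float)
    columns = matrix.columns
    for _ in range(B):
        idx = rng.integers(0, n, size=n_resample)
        boot = pd.DataFrame(values[idx], columns=columns)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dist = correlation_distance(boot, min_rows=2)
            tree = average_linkage_cluster(dist)
        except AnalysisError:
            continue
        present = set(tree.clades())
        for k, clade in enumerate(clades):
            if clade in present:
                counts[k] += 1
    return counts


def bootstrap_support(matrix: pd.DataFrame,
                      B: int = 1000,
                      seed: int = 0,
                      dendrogram: Dendrogram | None = None) -> ClusterSupport:
    """Ordinary bootstrap probabilities (scale 1) for every observed clade.

    Sera (rows) are resampled with replacement B times; BP of a clade is
    the fraction of replicate trees containing exactly that leaf set.
    """
    if B <= 0:
        raise AnalysisError("B must be positive")
    if dendrogram is None:
        dendrogram = average_linkage_cluster(correlation_distance(matrix))
    clades = dendrogram.clades()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    counts = _count_clades(matrix, clades, len(matrix), B, rng)
    table = pd.DataFrame({
        "leaves": [tuple(sorted(c)) for c in clades],
        "bp": counts / B,
    })
    return ClusterSupport(table=table, B=B, scales=(1.0,))


def fit_au_curve(scales: Sequence[float],
                 bp_values: Sequence[float],
                 B: int | Sequence[int]) -> tuple[float, float, float, bool]:
    """Fit the multiscale z-curve and return (v, c, au, degenerate).

    z_r = Phi^-1(1 - BP_r) is regressed on (sqrt(r), 1/sqrt(r)) without
    intercept, weighted by the delta-method precision of z_r,
    w_r = B * phi(z_r)^2 / (BP_r (1 - BP_r)).  BP values are clipped to
    [1/(B+1), B/(B+1)] to keep the probit finite; a clade seen never or
    always at every scale is degenerate and gets AU 0 or 1 directly.
    """
    r = np.asarray(scales, float)
    bp = np.asarray(bp_values, float)
    Bs = np.full(r.shape, B, dtype=float) if np.isscalar(B) else np.asarray(B, float)
    if np.all(bp <= 0.0):
        return np.nan, np.nan, 0.0, True
    if np.all(bp >= 1.0):
        return np.nan, np.nan, 1.0, True
    bp_c = np.clip(bp, 1.0 / (Bs + 1.0), Bs / (Bs + 1.0))
    z = norm.ppf(1.0 - bp_c)
    X = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    w = Bs * norm.pdf(z) ** 2 / (bp_c * (1.0 - bp_c))
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    au = float(1.0 - norm.cdf(v - c))
    return v, c, au, False


def multiscale_au(matrix: pd.DataFrame,
                  scales: Sequence[float] = DEFAULT_SCALES,
                  B: int = 1000,
                  seed: int = 0,
                  dendrogram: Dendrogram | None = None) -> ClusterSupport:
    """AU p-values by multiscale bootstrap; also fills BP at scale 1.

    For each scale r the resample size is round(r * n); every scale must
    keep at least 3 rows.  If scale 1.0 is absent from *scales* it is added
    so that BP is always reported.
    """
    n = len(matrix)
    scales = tuple(sorted(set(float(s) for s in scales) | {1.0}))
    sizes = {s: int(round(s * n)) for s in scales}
    if min(sizes.values()) < 3:
        raise AnalysisError("smallest scaled resample size must be >= 3")
    if dendrogram is None:
        dendrogram = average_linkage_cluster(correlation_distance(matrix))
    clades = dendrogram.clades()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 12]))
    bp_by_scale = np.zeros((len(scales), len(clades)))
    for si, s in enumerate(scales):
        counts = _count_clades(matrix, clades, sizes[s], B, rng)
        bp_by_scale[si] = counts / B

    rows = []
    for k, clade in enumerate(clades):
        v, c, au, degen = fit_au_curve(scales, bp_by_scale[:, k], B)
        rows.append({
            "leaves": tuple(sorted(clade)),
            "bp": float(bp_by_scale[scales.index(1.0), k]),
            "au": au, "v": v, "c": c, "degenerate": degen,
        })
    table = pd.DataFrame(rows)
    return ClusterSupport(table=table, B=B, scales=scales)


# -- Newick export --------------------------------------------------------


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_newick(dendrogram: Dendrogram,
                  support: ClusterSupport | None = None,
                  decimals: int = 6) -> str:
    """Render the tree as Newick with merge-height branch lengths.

    Branch length = parent height - child height (leaves sit at height 0).
    Internal nodes are labelled "AU/BP" when support is given; labels with
    spaces or Newick metacharacters are single-quoted.
    """

    def node_label(node: DendroNode) -> str:
        if support is None:
            return ""
        key = tuple(sorted(node.leaves))
        match = support.table[support.table["leaves"] == key]
        if not len(match):
            return ""
        bp = float(match["bp"].iloc[0])
        if "au" in match.columns and np.isfinite(match["au"].iloc[0]):
            return _quote_label(f"{float(match['au'].iloc[0]):.2f}/{bp:.2f}")
        return _quote_label(f"{bp:.2f}")

    def render(node: DendroNode, parent_height: float | None) -> str:
        if node.children is None:
            body = _quote_label(next(iter(node.leaves)))
        else:
            parts = [render(ch, node.height)
                     for ch in sorted(node.children, key=lambda n: n.label)]
            body = "(" + ",".join(parts) + ")" + node_label(node)
        if parent_height is None:
            return body
        length = parent_height - node.height
        return f"{body}:{length:.{decimals}f}"

    return render(dendrogram.root, None) + ";"
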