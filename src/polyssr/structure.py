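"""Group-structure inference for binary allele panels.

Three complementary views of panel structure:

* an average-linkage (UPGMA) dendrogram on modified Rogers' distances, with
  per-cluster support from multiscale bootstrap resampling of allele
  columns.  Bootstrap probabilities (BP) are measured at several resample
  sizes n' = round(A * r); the signed-distance / curvature model
  ``z_r = v * s_r + c / s_r`` with ``s_r = sqrt(1/r)`` and
  ``z_r = Phi^-1(1 - BP_r)`` is fitted by weighted least squares, and the
  approximately unbiased p-value is AU = 1 - Phi(v - c).  The fit corrects
  the selection bias that makes the naive BP at r = 1 conservative for
  clusters actually present in the data;

* a k-means cascade over a range of cluster numbers, scored by the
  Calinski-Harabasz criterion CH = [B/(k-1)] / [W/(n-k)] and maximised to
  choose k;

* principal component analysis of the column-centred binary matrix (no
  scaling), via singular value decomposition.

All stochastic operations take an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

from .distance import DistanceMatrix, modified_rogers
from .matrix import AlleleMatrix

__all__ = [
    "hclust_average",
    "MultiscaleFit",
    "fit_au",
    "NodeSupport",
    "SupportedDendrogram",
    "multiscale_bootstrap_support",
    "DEFAULT_SCALES",
    "PartitionResult",
    "kmeans_cascade",
    "calinski_harabasz",
    "PCAResult",
    "pca_binary",
]

#: Default resampling ratios n'/n for the multiscale bootstrap.
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


def hclust_average(d: DistanceMatrix, method: str = "average") -> np.ndarray:
    """Agglomerative clustering of a distance matrix; UPGMA by default.

    Returns the merge table in scipy linkage format (one row per merge:
    left id, right id, height, size).  ``method`` may be ``average``,
    ``complete`` or ``ward``.  Deterministic given the input and scipy's
    tie rule (lowest-index pair first).
    """
    if method not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {method!r}")
    if d.n < 2:
        raise ValueError("need at least 2 individuals to cluster")
    return hierarchy.linkage(d.condensed(), method=method)


def _merge_masks(Z: np.ndarray, n: int) -> list[int]:
    """Leaf-set bitmasks of the n-1 internal nodes of a linkage tree."""
    masks = [1 << i for i in range(n)]
    out = []
    for a, b in Z[:, :2].astype(int):
        m = masks[a] | masks[b]
        masks.append(m)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# Multiscale bootstrap / AU p-values
# ---------------------------------------------------------------------------


@dataclass
class MultiscaleFit:
    """Result of the signed-distance / curvature fit for one cluster.

    ``v`` estimates the signed distance of the data from the boundary of the
    region where the cluster holds; ``c`` the boundary curvature.  The
    corrected bootstrap probability at scale 1 is ``1 - Phi(v + c)``; when
    the fitted curvature is zero AU coincides with it.
    """

    scales: np.ndarray
    bp_by_scale: np.ndarray
    B: int
    v: float
    c: float
    au: float
    bp_corrected: float
    residual: float
    degenerate: bool = False


def fit_au(scales, bp_by_scale, B: int) -> MultiscaleFit:
    """Fit the multiscale model and compute the AU p-value for one cluster.

    BP values are clamped to [1/(2B), 1 - 1/(2B)]; scales whose BP sits at a
    clamp bound carry no information about the model and get weight zero.
    If fewer than two informative scales remain, the fit is degenerate and
    AU falls back to 1 (cluster essentially always observed) or 0 (never
    observed).  Weighted least squares uses delta-method binomial weights
    ``B * phi(z)^2 / (BP (1 - BP))``.
    """
    scales = np.asarray(scales, dtype=float)
    bp = np.asarray(bp_by_scale, dtype=float)
    if scales.shape != bp.shape:
        raise ValueError("scales and bp_by_scale must have the same length")
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    if np.unique(scales).size < 2:
        raise ValueError("need at least 2 distinct scales to fit the multiscale model")
    lo, hi = 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)
    clamped = np.clip(bp, lo, hi)
    informative = (bp > lo) & (bp < hi)

    if informative.sum() < 2 or np.unique(scales[informative]).size < 2:
        mean_bp = float(clamped.mean())
        au = 1.0 if mean_bp > 0.5 else 0.0
        return MultiscaleFit(scales, bp, B, np.nan, np.nan, au, au, np.nan, degenerate=True)

    s = np.sqrt(1.0 / scales[informative])
    z = norm.ppf(1.0 - clamped[informative])
    w = B * norm.pdf(z) ** 2 / (clamped[informative] * (1.0 - clamped[informative]))
    # WLS of z on [s, 1/s]
    design = np.column_stack([s, 1.0 / s])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], z * sw, rcond=None)
    v, c = float(coef[0]), float(coef[1])
    resid = float(np.sum(w * (z - design @ coef) ** 2))
    au = float(1.0 - norm.cdf(v - c))
    bp_corr = float(1.0 - norm.cdf(v + c))
    return MultiscaleFit(scales, bp, B, v, c, au, bp_corr, resid)


@dataclass
class NodeSupport:
    """Support values for one internal node (cluster) of the dendrogram."""

    node_id: int  # scipy node index (n .. 2n-2)
    members: tuple[str, ...]
    height: float
    au: float
    bp: float  # naive bootstrap probability at scale closest to 1
    v: float
    c: float
    bp_by_scale: np.ndarray
    degenerate: bool


@dataclass
class SupportedDendrogram:
    """UPGMA tree over individuals annotated with AU/BP cluster support."""

    ids: list[str]
    Z: np.ndarray
    nodes: list[NodeSupport]
    scales: np.ndarray
    B: int
    seed: int | None
    unit: str
    metric: str = "modified_rogers"
    linkage_method: str = "average"

    def support_for(self, members) -> NodeSupport | None:
        """Look up support for a cluster by its member set, if it is a clade."""
        want = frozenset(members)
        for node in self.nodes:
            if frozenset(node.members) == want:
                return node
        return None

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "node": s.node_id,
                "members": ",".join(s.members),
                "au": s.au,
                "bp": s.bp,
                "v": s.v,
                "c": s.c,
                "degenerate": s.degenerate,
            }
            for s in self.nodes
        ]
        return pd.DataFrame(rows).set_index("node")

    def to_newick(self) -> str:
        """Newick string with `[au=..,bp=..]` percentage labels on internal nodes."""
        by_id = {s.node_id: s for s in self.nodes}
        n = len(self.ids)
        tree = hierarchy.to_tree(self.Z)

        def render(node, parent_height):
            blen = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{blen:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            sup = by_id.get(node.id)
            label = f"[au={sup.au * 100:.0f},bp={sup.bp * 100:.0f}]" if sup else ""
            return f"({left},{right}){label}:{blen:.6g}"

        left = render(tree.left, tree.dist)
        right = render(tree.right, tree.dist)
        sup = by_id.get(tree.id)
        label = f"[au={sup.au * 100:.0f},bp={sup.bp * 100:.0f}]" if sup else ""
        return f"({left},{right}){label};"


def multiscale_bootstrap_support(
    m: AlleleMatrix,
    scales=DEFAULT_SCALES,
    B: int = 1000,
    seed: int | None = None,
    unit: str = "allele",
    linkage_method: str = "average",
) -> SupportedDendrogram:
    """UPGMA dendrogram with multiscale-bootstrap AU/BP support per cluster.

    For each resampling ratio r the allele columns (or whole marker blocks,
    ``unit='marker'``) are resampled with replacement to size round(A*r)
    (round(L*r) for markers), the tree is rebuilt from the resampled binary
    data, and BP_r of each original cluster is the fraction of resample
    trees containing it as a leaf set.  :func:`fit_au` then yields the AU
    p-value per cluster.  Resampling multiplicities act as integer column
    weights, which is exactly equivalent to duplicating columns.
    """
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    if np.unique(scales).size < 2:
        raise ValueError("need at least 2 distinct scales for the AU fit")
    if B < 100:
        raise ValueError("B must be at least 100 for usable BP estimates")
    if unit not in ("allele", "marker"):
        raise ValueError(f"unit must be 'allele' or 'marker', got {unit!r}")

    n, A = m.n, m.n_alleles
    rng = np.random.default_rng(seed)
    dw = modified_rogers(m)
    Z = hclust_average(dw, method=linkage_method)
    obs_masks = _merge_masks(Z, n)
    obs_set = set(obs_masks)

    X = m.X.astype(float)
    loci = m.loci
    L = len(loci)
    marker_cols = [js for js in loci.values()]

    counts = {mask: np.zeros(len(scales), dtype=np.int64) for mask in obs_masks}
    for si, r in enumerate(scales):
        if unit == "allele":
            size = int(round(A * r))
        else:
            size = int(round(L * r))
        if size == 0:
            raise ValueError(f"scale {r} resamples zero {unit} units")
        for _ in range(B):
            if unit == "allele":
                w = rng.multinomial(size, np.full(A, 1.0 / A)).astype(float)
            else:
                mcounts = rng.multinomial(size, np.full(L, 1.0 / L))
                w = np.zeros(A)
                for cnt, js in zip(mcounts, marker_cols):
                    if cnt:
                        w[js] = cnt
            # weighted squared Euclidean via the Gram trick (x^2 = x for 0/1 data)
            t = X @ w
            G = (X * w) @ X.T
            D2 = np.maximum(t[:, None] + t[None, :] - 2.0 * G, 0.0)
            np.fill_diagonal(D2, 0.0)
            Zb = hierarchy.linkage(squareform(np.sqrt(D2), checks=False), method=linkage_method)
            seen = set()
            masks = [1 << i for i in range(n)]
            for a, b in Zb[:, :2].astype(int):
                mk = masks[a] | masks[b]
                masks.append(mk)
                if mk in obs_set and mk not in seen:
                    counts[mk][si] += 1
                    seen.add(mk)

    # scale closest to 1 reports the naive BP
    ref = int(np.argmin(np.abs(scales - 1.0)))
    nodes = []
    for i, mask in enumerate(obs_masks):
        bp_by_scale = counts[mask] / B
        fit = fit_au(scales, bp_by_scale, B)
        members = tuple(m.individuals[j] for j in range(n) if mask >> j & 1)
        nodes.append(
            NodeSupport(
                node_id=n + i,
                members=members,
                height=float(Z[i, 2]),
                au=fit.au,
                bp=float(bp_by_scale[ref]),
                v=fit.v,
                c=fit.c,
                bp_by_scale=bp_by_scale,
                degenerate=fit.degenerate,
            )
        )
    return SupportedDendrogram(
        ids=list(m.individuals),
        Z=Z,
        nodes=nodes,
        scales=scales,
        B=B,
        seed=seed,
        unit=unit,
        linkage_method=linkage_method,
    )


# ---------------------------------------------------------------------------
# k-means cascade and Calinski-Harabasz
# ---------------------------------------------------------------------------


def calinski_harabasz(X, labels) -> float:
    """Calinski-Harabasz criterion CH = [B/(k-1)] / [W/(n-k)].

    B is the between-cluster and W the within-cluster sum of squared
    deviations.  Returns ``inf`` when W is zero (perfectly tight clusters);
    raises on k < 2 or an empty cluster.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq = np.unique(labels)
    k = uniq.size
    if k < 2:
        raise ValueError("Calinski-Harabasz requires at least 2 clusters")
    if k >= n:
        raise ValueError("Calinski-Harabasz requires k < n")
    grand = X.mean(axis=0)
    B = W = 0.0
    for g in uniq:
        block = X[labels == g]
        if block.shape[0] == 0:
            raise ValueError(f"empty cluster {g!r}")
        cen = block.mean(axis=0)
        B += block.shape[0] * float(np.sum((cen - grand) ** 2))
        W += float(np.sum((block - cen) ** 2))
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    """One Lloyd run from a random-point init; returns (labels, inertia).

    The within-cluster sum of squares is asserted non-increasing across
    iterations (up to numerical slack).
    """
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    prev_obj = np.inf
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(n), labels].sum())
        assert obj <= prev_obj + 1e-9 * max(1.0, prev_obj), "Lloyd objective increased"
        new_centers = centers.copy()
        for g in range(k):
            members = X[labels == g]
            if members.shape[0]:
                new_centers[g] = members.mean(axis=0)
            else:  # re-seed an emptied cluster at the worst-fit point
                new_centers[g] = X[int(d2.min(axis=1).argmax())]
        if obj == prev_obj and np.allclose(new_centers, centers):
            break
        centers = new_centers
        prev_obj = obj
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(n), labels].sum())
    return labels, inertia


@dataclass
class PartitionResult:
    """k-means cascade output: CH per k, assignments per k, selected k."""

    k_range: list[int]
    ch_by_k: dict[int, float]
    assignments_by_k: dict[int, np.ndarray]  # labels 1..k per individual
    inertia_by_k: dict[int, float]
    best_k: int
    degenerate: bool = False
    seed: int | None = None

    def to_dataframe(self, ids) -> pd.DataFrame:
        df = pd.DataFrame(
            {f"cluster_k{k}": self.assignments_by_k[k] for k in self.k_range},
            index=pd.Index(ids, name="individual_id"),
        )
        return df


def kmeans_cascade(
    m,
    k_min: int = 2,
    k_max: int = 10,
    restarts: int = 10,
    seed: int | None = None,
) -> PartitionResult:
    """Lloyd's k-means over k = k_min..k_max with best-of-restarts, scored
    by the Calinski-Harabasz criterion.

    Operates on the binary data rows; since the modified Rogers' distance is
    a constant rescaling of the Euclidean metric on those rows, partitions
    in D_w geometry and in raw-row geometry coincide.  ``best_k`` is the
    argmax of CH; ties break toward smaller k (parsimony).  A panel of
    identical rows is reported as degenerate rather than scored.
    """
    X = (m.X if isinstance(m, AlleleMatrix) else np.asarray(m)).astype(float)
    n = X.shape[0]
    if not (1 < k_min <= k_max):
        raise ValueError("need 1 < k_min <= k_max")
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than n={n}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    rng = np.random.default_rng(seed)

    if np.all(X == X[0]):
        ks = list(range(k_min, k_max + 1))
        return PartitionResult(
            k_range=ks,
            ch_by_k={k: float("nan") for k in ks},
            assignments_by_k={k: np.ones(n, dtype=int) for k in ks},
            inertia_by_k={k: 0.0 for k in ks},
            best_k=k_min,
            degenerate=True,
            seed=seed,
        )

    ch_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    inertia_by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        best = None
        for _ in range(restarts):
            labels, inertia = _lloyd(X, k, rng)
            if best is None or inertia < best[1]:
                best = (labels, inertia)
        labels, inertia = best
        # relabel to 1..k in order of first appearance
        remap = {g: i + 1 for i, g in enumerate(dict.fromkeys(labels.tolist()))}
        labels_by_k[k] = np.asarray([remap[g] for g in labels], dtype=int)
        inertia_by_k[k] = inertia
        ch_by_k[k] = calinski_harabasz(X, labels) if np.unique(labels).size >= 2 else float("nan")

    def score(k: int) -> float:
        v = ch_by_k[k]
        return float("-inf") if np.isnan(v) else v

    best_k = max(ch_by_k, key=score)
    # ties toward smaller k
    for k in sorted(ch_by_k):
        if score(k) == score(best_k):
            best_k = k
            break
    return PartitionResult(
        k_range=list(range(k_min, k_max + 1)),
        ch_by_k=ch_by_k,
        assignments_by_k=labels_by_k,
        inertia_by_k=inertia_by_k,
        best_k=best_k,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    """Component scores and percent variance from SVD of the centred matrix."""

    ids: list[str]
    scores: np.ndarray  # n x p
    pct_var: np.ndarray  # length p, sums to 100
    loadings: np.ndarray  # A x p

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=pd.Index(self.ids, name="individual_id"), columns=cols)


def pca_binary(m: AlleleMatrix) -> PCAResult:
    """PCA of the raw binary matrix: columns centred, no scaling.

    Scores are U * S from the SVD of the centred matrix; percent variance is
    the normalised squared singular values.  With all components kept the
    scores reproduce the pairwise Euclidean geometry of the centred data
    exactly.
    """
    if m.n < 3:
        raise ValueError("PCA needs at least 3 individuals")
    Xc = m.X.astype(float) - m.X.mean(axis=0, dtype=float)
    if np.allclose(Xc, 0):
        raise ValueError("matrix has zero variance; PCA undefined")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = min(m.n - 1, m.n_alleles)
    U, s, Vt = U[:, :keep], s[:keep], Vt[:keep]
    scores = U * s
    pct = 100.0 * s**2 / np.sum(s**2)
    return PCAResult(list(m.individuals), scores, pct, Vt.T)
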