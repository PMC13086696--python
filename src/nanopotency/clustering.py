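"""Ensemble hierarchical clustering with multiscale-bootstrap cluster support.

Compounds are clustered on their log10 BMC endpoint profiles under 12
linkage x distance configurations (complete/average/single/Ward x
euclidean/manhattan/minkowski). For each configuration, cluster support is
estimated by multiscale bootstrap: endpoint columns are resampled with
replacement at relative sizes 0.4–1.4 of the original feature count, each
resample is re-clustered, and per internal node the fraction of resamples
whose dendrogram contains that exact member set is recorded. Fitting the
normal-quantile-transformed bootstrap probabilities against sqrt(scale) and
1/sqrt(scale) by weighted least squares gives the signed distance ``v`` and
curvature ``c`` of the multiscale model, from which the approximately
unbiased p-value AU = 1 - Phi(v - c) and the plain bootstrap probability
BP = 1 - Phi(v + c) follow. Nodes with AU above 0.95 (root excluded) are the
statistically supported clusters.

Across attempts, compound pairs are tabulated into a co-occurrence matrix
(fraction of attempts sharing a supported cluster) and a pooled-cluster
Jaccard matrix; potency groups are the connected components of the
thresholded co-occurrence graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import norm

from .datasets import child_seed

__all__ = [
    "ClusterConfig",
    "NodeSupport",
    "AttemptResult",
    "CoClusterSummary",
    "DEFAULT_LINKAGES",
    "DEFAULT_DISTANCES",
    "default_configs",
    "hierarchical_cluster",
    "dendrogram_node_sets",
    "multiscale_bootstrap",
    "au_from_counts",
    "extract_supported",
    "run_attempt",
    "run_ensemble",
    "select_best_attempt",
    "co_cluster_summary",
    "derive_groups",
    "attempt_to_newick",
]

DEFAULT_LINKAGES = ("complete", "average", "single", "ward")
DEFAULT_DISTANCES = ("euclidean", "manhattan", "minkowski")
DEFAULT_SCALES = tuple(np.round(np.arange(0.4, 1.41, 0.1), 10))


@dataclass(frozen=True)
class ClusterConfig:
    """One linkage x distance clustering attempt's settings."""

    linkage: str
    distance: str
    minkowski_p: float = 3.0
    scales: tuple = DEFAULT_SCALES
    nboot: int = 1000
    au_threshold: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.linkage not in DEFAULT_LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.distance not in DEFAULT_DISTANCES:
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.nboot < 1:
            raise ValueError("nboot must be >= 1")
        if any(s <= 0 for s in self.scales):
            raise ValueError("scales must be positive")

    @property
    def label(self) -> str:
        return f"{self.linkage}-{self.distance}"


def default_configs(nboot: int = 1000, seed: int = 0, au_threshold: float = 0.95,
                    scales: Sequence[float] = DEFAULT_SCALES,
                    minkowski_p: float = 3.0) -> list[ClusterConfig]:
    """The 12 standard attempts, in documented order (linkage-major)."""
    return [
        ClusterConfig(lk, ds, minkowski_p=minkowski_p, scales=tuple(scales),
                      nboot=nboot, au_threshold=au_threshold,
                      seed=child_seed(seed, lk, ds))
        for lk in DEFAULT_LINKAGES
        for ds in DEFAULT_DISTANCES
    ]


@dataclass
class NodeSupport:
    """Bootstrap support for one internal dendrogram node (a member set)."""

    members: frozenset
    bp_counts: dict = field(default_factory=dict)  # realized scale -> hit count
    nboot: int = 0
    au: float = float("nan")
    bp: float = float("nan")
    v_signed: float = float("nan")
    c_curvature: float = float("nan")
    fit_ok: bool = False


@dataclass
class AttemptResult:
    """One clustering attempt: dendrogram, node supports, supported clusters."""

    config: ClusterConfig
    labels: list
    linkage_matrix: np.ndarray
    node_supports: list
    supported_clusters: list  # list of frozensets, root excluded
    singletons: list

    @property
    def n_supported(self) -> int:
        return len(self.supported_clusters)


@dataclass
class CoClusterSummary:
    """Pairwise co-clustering evidence pooled over attempts."""

    attempts: int
    co_occurrence: pd.DataFrame
    jaccard: pd.DataFrame
    never_clustered: list


# ---------------------------------------------------------------------------
# dendrograms
# ---------------------------------------------------------------------------

def _distances(X: np.ndarray, distance: str, minkowski_p: float) -> np.ndarray:
    if distance == "euclidean":
        return pdist(X, metric="euclidean")
    if distance == "manhattan":
        return pdist(X, metric="cityblock")
    return pdist(X, metric="minkowski", p=minkowski_p)


def hierarchical_cluster(X: np.ndarray, linkage: str, distance: str,
                         minkowski_p: float = 3.0) -> np.ndarray:
    """Agglomerative dendrogram (scipy linkage matrix) over rows of ``X``.

    Ward linkage on non-euclidean dissimilarities applies the usual
    Lance-Williams update to the supplied distances (the common
    ``ward.D2``-on-dissimilarity practice). scipy's deterministic
    lowest-index merge order provides the tie-break.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN cells; impute before clustering")
    d = _distances(X, distance, minkowski_p)
    return hierarchy.linkage(d, method=linkage)


def dendrogram_node_sets(Z: np.ndarray, labels: Sequence) -> list[frozenset]:
    """Member sets of the internal nodes, in merge order (root last)."""
    n = Z.shape[0] + 1
    sets: list[frozenset] = [frozenset([labels[i]]) for i in range(n)]
    out = []
    for i in range(Z.shape[0]):
        left, right = int(Z[i, 0]), int(Z[i, 1])
        merged = sets[left] | sets[right]
        sets.append(merged)
        out.append(merged)
    return out


# ---------------------------------------------------------------------------
# multiscale bootstrap
# ---------------------------------------------------------------------------

def multiscale_bootstrap(X: np.ndarray, labels: Sequence, config: ClusterConfig,
                         rng: np.random.Generator | None = None) -> list[NodeSupport]:
    """Per-node subtree recovery counts across bootstrap scales.

    Features (columns) are resampled with replacement at size
    ``round(r * n_features)`` per scale r; compounds are re-clustered on the
    resampled features and each original internal node is counted when its
    exact member set appears as a subtree. Scales yielding fewer than 2
    features are skipped. The realized scale round(r*n)/n keys the counts.
    """
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    if rng is None:
        rng = np.random.default_rng(config.seed)
    Z0 = hierarchical_cluster(X, config.linkage, config.distance, config.minkowski_p)
    nodes = dendrogram_node_sets(Z0, labels)
    supports = {ns: NodeSupport(members=ns, nboot=config.nboot) for ns in nodes}

    for r in config.scales:
        m = int(round(r * n_feat))
        if m < 2:
            continue
        realized = m / n_feat
        counts = {ns: 0 for ns in nodes}
        for _ in range(config.nboot):
            cols = rng.integers(0, n_feat, size=m)
            Zb = hierarchical_cluster(X[:, cols], config.linkage, config.distance,
                                      config.minkowski_p)
            found = set(dendrogram_node_sets(Zb, labels))
            for ns in nodes:
                if ns in found:
                    counts[ns] += 1
        for ns in nodes:
            supports[ns].bp_counts[realized] = counts[ns]
    return [supports[ns] for ns in nodes]


def au_from_counts(support: NodeSupport) -> NodeSupport:
    """Fill AU/BP by the weighted least-squares multiscale fit.

    Scales with degenerate counts (0 or nboot) carry no information about the
    curvature and are excluded from the fit. On the usable scales,
    BP = count/nboot is clamped to [0.5/nboot, 1 - 0.5/nboot] and
    z = Phi^-1(1 - BP); regressing z on (sqrt(r'), 1/sqrt(r')) with
    binomial-variance weights w = nboot * phi(z)^2 / (BP (1-BP)) yields
    (v, c) and AU = 1 - Phi(v - c), BP_corrected = 1 - Phi(v + c).
    Fully degenerate nodes (all counts 0 or all = nboot) pin AU to 0 or 1.
    The two-parameter regression needs at least 3 usable scales to average
    over anything (with 2 it merely interpolates two binomially noisy points
    and extrapolates wildly); below that, and on a failed fit, AU falls back
    to the raw BP at the scale nearest r = 1 with ``fit_ok=False``.
    """
    nboot = support.nboot
    scales = sorted(support.bp_counts)
    counts = np.array([support.bp_counts[r] for r in scales], dtype=float)
    if len(scales) == 0:
        raise ValueError("no usable bootstrap scales")
    if np.all(counts == 0):
        support.au, support.bp, support.fit_ok = 0.0, 0.0, True
        support.v_signed, support.c_curvature = float("inf"), 0.0
        return support
    if np.all(counts == nboot):
        support.au, support.bp, support.fit_ok = 1.0, 1.0, True
        support.v_signed, support.c_curvature = float("-inf"), 0.0
        return support

    r_all = np.asarray(scales, dtype=float)
    fallback_bp = float(counts[np.argmin(np.abs(r_all - 1.0))] / nboot)
    usable = (counts > 0) & (counts < nboot)
    r = r_all[usable]
    bp = np.clip(counts[usable] / nboot, 0.5 / nboot, 1.0 - 0.5 / nboot)
    z = norm.ppf(1.0 - bp)
    w = nboot * norm.pdf(z) ** 2 / (bp * (1.0 - bp))
    if len(r) < 3:
        support.au, support.bp, support.fit_ok = fallback_bp, fallback_bp, False
        return support
    # WLS of z on (sqrt(r), 1/sqrt(r))
    A = np.column_stack([np.sqrt(r), 1.0 / np.sqrt(r)])
    W = np.diag(w)
    try:
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ A, np.sqrt(w) * z, rcond=None)
        v, c = float(beta[0]), float(beta[1])
    except np.linalg.LinAlgError:
        support.au, support.bp, support.fit_ok = fallback_bp, fallback_bp, False
        return support
    if not (np.isfinite(v) and np.isfinite(c)):
        support.au, support.bp, support.fit_ok = fallback_bp, fallback_bp, False
        return support
    support.v_signed, support.c_curvature = v, c
    support.au = float(1.0 - norm.cdf(v - c))
    support.bp = float(1.0 - norm.cdf(v + c))
    support.fit_ok = True
    return support


# ---------------------------------------------------------------------------
# attempts and the ensemble
# ---------------------------------------------------------------------------

def extract_supported(node_supports: Sequence[NodeSupport], all_members: frozenset,
                      threshold: float = 0.95):
    """Supported member sets (AU > threshold, root excluded) and singletons."""
    supported = [ns.members for ns in node_supports
                 if ns.au > threshold and ns.members != all_members]
    covered: set = set()
    for s in supported:
        covered |= s
    singletons = sorted(all_members - covered)
    return supported, singletons


def run_attempt(matrix: pd.DataFrame, config: ClusterConfig) -> AttemptResult:
    """Cluster, bootstrap, and extract supported clusters for one config."""
    labels = list(matrix.index)
    X = matrix.to_numpy(dtype=float)
    Z = hierarchical_cluster(X, config.linkage, config.distance, config.minkowski_p)
    supports = multiscale_bootstrap(X, labels, config)
    for ns in supports:
        au_from_counts(ns)
    supported, singletons = extract_supported(supports, frozenset(labels),
                                              config.au_threshold)
    return AttemptResult(config, labels, Z, supports, supported, singletons)


def run_ensemble(matrix: pd.DataFrame, nboot: int = 1000, seed: int = 0,
                 au_threshold: float = 0.95,
                 configs: Sequence[ClusterConfig] | None = None) -> list[AttemptResult]:
    """Run all 12 attempts (or the supplied configs) on one BMC matrix."""
    if configs is None:
        configs = default_configs(nboot=nboot, seed=seed, au_threshold=au_threshold)
    return [run_attempt(matrix, cfg) for cfg in configs]


def select_best_attempt(attempts: Sequence[AttemptResult]) -> AttemptResult:
    """Most supported clusters; ties to fewest singletons, then config order."""
    if not attempts:
        raise ValueError("no attempts")
    best = attempts[0]
    for att in attempts[1:]:
        if att.n_supported > best.n_supported:
            best = att
        elif att.n_supported == best.n_supported and len(att.singletons) < len(best.singletons):
            best = att
    return best


def co_cluster_summary(attempts: Sequence[AttemptResult]) -> CoClusterSummary:
    """Pairwise co-occurrence fractions and pooled-cluster Jaccard similarity.

    ``co_occurrence[i, j]`` is the fraction of attempts in which i and j sit
    together in at least one supported cluster; ``jaccard[i, j]`` is
    |clusters containing both| / |clusters containing either| over the pooled
    supported-cluster list. Compounds never in any supported cluster get 0
    rows (flagged in ``never_clustered``); their diagonal stays 0 for
    co-occurrence by the convention that the diagonal marks membership in at
    least one supported cluster.
    """
    if not attempts:
        raise ValueError("no attempts")
    labels = attempts[0].labels
    for att in attempts[1:]:
        if att.labels != labels:
            raise ValueError("attempts disagree on the compound set")
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    together = np.zeros((n, n))
    ever = np.zeros(n, dtype=bool)
    pooled: list[frozenset] = []
    for att in attempts:
        pair_hit = np.zeros((n, n), dtype=bool)
        for cl in att.supported_clusters:
            pooled.append(cl)
            ii = [idx[m] for m in cl]
            ever[ii] = True
            for a in ii:
                for b in ii:
                    pair_hit[a, b] = True
        together += pair_hit
    co = together / len(attempts)
    np.fill_diagonal(co, 0.0)
    for i in range(n):
        if ever[i]:
            co[i, i] = 1.0

    jac = np.zeros((n, n))
    contains = np.zeros((len(pooled), n), dtype=bool)
    for ci, cl in enumerate(pooled):
        for m in cl:
            contains[ci, idx[m]] = True
    for a in range(n):
        for b in range(n):
            both = np.sum(contains[:, a] & contains[:, b])
            either = np.sum(contains[:, a] | contains[:, b])
            jac[a, b] = both / either if either else 0.0

    co_df = pd.DataFrame(co, index=labels, columns=labels)
    jac_df = pd.DataFrame(jac, index=labels, columns=labels)
    never = [labels[i] for i in range(n) if not ever[i]]
    return CoClusterSummary(len(attempts), co_df, jac_df, never)


def derive_groups(summary: CoClusterSummary, threshold: float = 0.5) -> list[list]:
    """Potency groups: connected components of the thresholded co-occurrence graph.

    Components of size >= 2 only; a group is a set of compounds likely to be
    found together within a supported cluster across attempts.
    """
    labels = list(summary.co_occurrence.index)
    co = summary.co_occurrence.to_numpy()
    n = len(labels)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(n):
        for b in range(a + 1, n):
            if co[a, b] >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[int, list] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(labels[i])
    groups = [sorted(v) for v in comps.values() if len(v) >= 2]
    groups.sort(key=lambda g: (-len(g), g[0]))
    return groups


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def attempt_to_newick(attempt: AttemptResult) -> str:
    """Dendrogram as Newick with AU/BP node comments."""
    Z = attempt.linkage_matrix
    labels = attempt.labels
    by_set = {ns.members: ns for ns in attempt.node_supports}
    n = Z.shape[0] + 1
    trees: list[str] = [str(lab).replace(" ", "_") for lab in labels]
    sets: list[frozenset] = [frozenset([lab]) for lab in labels]
    heights: list[float] = [0.0] * n
    for i in range(Z.shape[0]):
        l, r = int(Z[i, 0]), int(Z[i, 1])
        h = float(Z[i, 2])
        merged = sets[l] | sets[r]
        ns = by_set.get(merged)
        comment = f"[&&NHX:au={ns.au:.4f}:bp={ns.bp:.4f}]" if ns is not None and np.isfinite(ns.au) else ""
        bl_l = max(h - heights[l], 0.0)
        bl_r = max(h - heights[r], 0.0)
        trees.append(f"({trees[l]}:{bl_l:.6g},{trees[r]}:{bl_r:.6g}){comment}")
        sets.append(merged)
        heights.append(h)
    return trees[-1] + ";"
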