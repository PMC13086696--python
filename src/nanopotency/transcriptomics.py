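"""Transcriptomic benchmark concentrations and pathway points of departure.

Concentration-responsive genes are identified with a Williams-type trend test
(isotonic/PAVA-amalgamated group means against control, pooled variance,
permutation p-values) combined with a 1.5-fold-change filter. Passing genes
get a model-averaged BMC at SD-based benchmark responses (1.021, 1.349,
1.932, 2.601 residual SDs by default), and pathway-level transcriptional
points of departure (tPODs) are the median gene BMC among
concentration-responsive pathway members, subject to a minimum-gene rule
(plain 3-gene floor, or the NTP rule of at least 3 genes and 5 % of the
pathway).

Gene models are fitted on the log2-ratio scale with normal residuals; the
family ids mirror the usual continuous suite but use additive saturating
forms appropriate for data centred at zero:

* ``linear``: a + b*x
* ``power``:  a + b*x**d
* ``hill``:   a + b * x**d / (c**d + x**d)
* ``exp3``:   a + b * (1 - exp(-x/c))
* ``exp5``:   a + b * (1 - exp(-(x/c)**d))
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datasets import ExpressionDataset, child_seed
from .doseresponse import BmrSpec, DEFAULT_SD_BMRS

__all__ = [
    "GeneBmc",
    "PathwayTpod",
    "GENE_MODEL_FAMILY",
    "pava",
    "williams_trend_test",
    "williams_many",
    "max_fold_change",
    "filter_responsive_genes",
    "fit_gene_family",
    "model_average_bmc",
    "pathway_tpod",
    "read_gmt",
    "analyze_expression",
]

GENE_MODEL_FAMILY = ("linear", "power", "hill", "exp3", "exp5")


@dataclass
class GeneBmc:
    """Model-averaged benchmark concentration for one gene at one BMR."""

    gene: str
    bmc: float | None
    p_trend: float
    max_abs_fc: float
    model_weights: dict = field(default_factory=dict)
    status: str = "ok"  # ok | unreachable | fit_failed


@dataclass
class PathwayTpod:
    """Pathway-median transcriptional point of departure."""

    pathway: str
    n_genes_in_pathway: int
    n_responsive: int
    tpod: float | None
    rule: str  # min3 | ntp_5pct


# ---------------------------------------------------------------------------
# Williams trend test
# ---------------------------------------------------------------------------

def pava(values: Sequence[float], weights: Sequence[float] | None = None,
         increasing: bool = True) -> np.ndarray:
    """Pool-adjacent-violators amalgamation of group means.

    Returns the isotonic (or antitonic) fit; pooled blocks share their
    weighted mean, e.g. means [3, 1, 2] with equal weights amalgamate to
    [2, 2, 2] under a nondecreasing constraint.
    """
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if not increasing:
        return -pava(-v, w, increasing=True)
    # blocks as (mean, weight) with pooling while a violator exists
    means: list[float] = []
    wts: list[float] = []
    sizes: list[int] = []
    for mi, wi in zip(v, w):
        means.append(float(mi))
        wts.append(float(wi))
        sizes.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, s2 = means.pop(), wts.pop(), sizes.pop()
            m1, w1, s1 = means.pop(), wts.pop(), sizes.pop()
            means.append((m1 * w1 + m2 * w2) / (w1 + w2))
            wts.append(w1 + w2)
            sizes.append(s1 + s2)
    return np.repeat(means, sizes)


def _williams_stats(values: np.ndarray, group_sizes: np.ndarray):
    """Williams statistics (both directions) for rows of ``values``.

    ``values`` is (P, N) with samples ordered control-first in blocks of
    ``group_sizes``. The isotonic estimate at the highest dose equals the
    extreme over suffix-weighted means of the treated groups, which is what
    the statistic needs; full PAVA is exposed separately via :func:`pava`.
    """
    counts = np.asarray(group_sizes)
    G = len(counts)
    N = counts.sum()
    edges = np.concatenate([[0], np.cumsum(counts)])
    sums = np.stack([values[:, edges[g]:edges[g + 1]].sum(axis=1) for g in range(G)], axis=1)
    sqs = np.stack([(values[:, edges[g]:edges[g + 1]] ** 2).sum(axis=1) for g in range(G)], axis=1)
    means = sums / counts
    ss_within = (sqs - counts * means**2).sum(axis=1)
    df = N - G
    s2 = np.maximum(ss_within / df, 0.0)

    treated_sums = sums[:, 1:]
    treated_counts = counts[1:]
    suf_sum = np.cumsum(treated_sums[:, ::-1], axis=1)[:, ::-1]
    suf_cnt = np.cumsum(treated_counts[::-1])[::-1]
    suffix_means = suf_sum / suf_cnt
    iso_up = suffix_means.max(axis=1)
    iso_down = suffix_means.min(axis=1)

    se = np.sqrt(s2 * (1.0 / counts[-1] + 1.0 / counts[0]))
    d_up = iso_up - means[:, 0]
    d_down = iso_down - means[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_up = np.where(se > 0, d_up / np.where(se > 0, se, 1.0),
                        np.sign(d_up) * np.inf)
        t_down = np.where(se > 0, d_down / np.where(se > 0, se, 1.0),
                          np.sign(d_down) * np.inf)
    t_up = np.where(np.isnan(t_up), 0.0, t_up)
    t_down = np.where(np.isnan(t_down), 0.0, t_down)
    return t_up, t_down


def williams_trend_test(groups: Sequence[Sequence[float]], n_permutations: int = 1000,
                        seed: int = 0) -> float:
    """Two-sided permutation p-value for a monotone concentration trend.

    ``groups`` are replicate responses ordered by concentration, control
    first. One-sided p-values for the increasing and decreasing Williams
    statistics are combined by Bonferroni doubling, capped at 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 3:
        raise ValueError("need >= 3 concentration groups including control")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("need >= 2 replicates per group")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    values = np.concatenate(arrs)
    if np.all(values == values[0]):
        return 1.0
    sizes = np.array([len(a) for a in arrs])
    rng = np.random.default_rng(seed)
    idx = np.tile(np.arange(values.size), (n_permutations, 1))
    idx = rng.permuted(idx, axis=1)
    stacked = np.vstack([values[None, :], values[idx]])
    t_up, t_down = _williams_stats(stacked, sizes)
    p_up = (1 + np.sum(t_up[1:] >= t_up[0])) / (n_permutations + 1)
    p_down = (1 + np.sum(t_down[1:] <= t_down[0])) / (n_permutations + 1)
    return float(min(1.0, 2.0 * min(p_up, p_down)))


def williams_many(matrix: pd.DataFrame, concentrations: Sequence[float],
                  n_permutations: int = 1000, seed: int = 0) -> pd.Series:
    """Per-gene Williams permutation p-values for a genes x samples matrix.

    ``concentrations`` gives the exposure concentration of each column; the
    columns are regrouped in ascending concentration order. Each gene uses an
    independent permutation stream derived from ``seed``.
    """
    conc = np.asarray(concentrations, dtype=float)
    order = np.argsort(conc, kind="stable")
    levels = np.unique(conc)
    sizes = np.array([(conc == lv).sum() for lv in levels])
    data = matrix.to_numpy()[:, order]
    out = {}
    for gi, gene in enumerate(matrix.index):
        groups = np.split(data[gi], np.cumsum(sizes)[:-1])
        out[gene] = williams_trend_test(groups, n_permutations, seed=child_seed(seed, gene))
    return pd.Series(out, name="p_trend")


# ---------------------------------------------------------------------------
# fold-change filter
# ---------------------------------------------------------------------------

def max_fold_change(log2_values: Sequence[float], concentrations: Sequence[float]) -> float:
    """Largest per-concentration fold change vs control, in either direction.

    Fold change at each concentration is 2**(mean log2 ratio); the magnitude
    max(FC, 1/FC) is maximised over nonzero concentrations, so 0.6-fold down
    and 1.67-fold up are equally extreme.
    """
    y = np.asarray(log2_values, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    fcs = []
    for lv in np.unique(conc):
        if lv == 0:
            continue
        fc = 2.0 ** float(np.mean(y[conc == lv]))
        fcs.append(max(fc, 1.0 / fc))
    return max(fcs) if fcs else 1.0


def filter_responsive_genes(gene_table: pd.DataFrame, p_cutoff: float = 0.05,
                            fc_cutoff: float = 1.5) -> list[str]:
    """Genes with trend p < cutoff AND a >= 1.5-fold change in either direction.

    ``gene_table`` needs columns ``gene``, ``p_trend``, ``max_abs_fc``.
    """
    keep = (gene_table["p_trend"] < p_cutoff) & (gene_table["max_abs_fc"] >= fc_cutoff)
    return list(gene_table.loc[keep, "gene"])


# ---------------------------------------------------------------------------
# gene models and model averaging
# ---------------------------------------------------------------------------

def _gene_mean(model_id: str, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    _d = lambda ld: math.exp(min(max(ld, -4.0), 3.0))  # keep x**d in range
    with np.errstate(over="ignore", invalid="ignore"):
        if model_id == "linear":
            a, b = theta
            return a + b * x
        if model_id == "power":
            a, b, ld = theta
            return a + b * np.power(x, _d(ld))
        if model_id == "hill":
            a, b, lc, ld = theta
            d = _d(ld)
            xd = np.power(x, d)
            return a + b * xd / (math.exp(min(max(lc, -30.0), 30.0)) ** d + xd)
        if model_id == "exp3":
            a, b, lc = theta
            return a + b * (1.0 - np.exp(-x / math.exp(min(max(lc, -30.0), 30.0))))
        if model_id == "exp5":
            a, b, lc, ld = theta
            return a + b * (1.0 - np.exp(-np.power(x / math.exp(min(max(lc, -30.0), 30.0)), _d(ld))))
    raise ValueError(f"unknown gene model {model_id!r}")


def _fit_gene_model(model_id: str, x: np.ndarray, y: np.ndarray, seed: int):
    """Least-squares fit; returns (theta, aic, sigma) or None on failure."""
    xmax = float(np.max(x))
    slope = (np.mean(y[x == xmax]) - np.mean(y[x == 0])) / xmax if xmax > 0 else 0.0
    a0 = float(np.mean(y[x == 0]))
    amp0 = float(np.mean(y[x == xmax]) - a0)
    starts = []
    if model_id == "linear":
        starts.append(np.array([a0, slope]))
    elif model_id == "power":
        for d0 in (0.7, 1.0, 2.0):
            starts.append(np.array([a0, slope if d0 == 1.0 else amp0 / xmax**d0, math.log(d0)]))
    elif model_id == "hill":
        for c0 in (xmax / 4, xmax):
            for d0 in (1.0, 2.0):
                starts.append(np.array([a0, amp0 * 1.2, math.log(c0), math.log(d0)]))
    elif model_id == "exp3":
        for c0 in (xmax / 4, xmax):
            starts.append(np.array([a0, amp0 * 1.2, math.log(c0)]))
    else:  # exp5
        for c0 in (xmax / 4, xmax):
            for d0 in (1.0, 2.0):
                starts.append(np.array([a0, amp0 * 1.2, math.log(c0), math.log(d0)]))
    rng = np.random.default_rng(seed)
    if model_id != "linear":
        jitter = starts[0].copy()
        jitter[1:] = jitter[1:] * rng.uniform(0.5, 2.0, size=len(jitter) - 1)
        starts.append(jitter)

    def resid(theta):
        r = y - _gene_mean(model_id, x, theta)
        return np.where(np.isfinite(r), r, 1e6)

    best = None
    for t0 in starts:
        try:
            sol = optimize.least_squares(resid, t0, xtol=1e-12, ftol=1e-12, max_nfev=1000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return None
    n = len(y)
    sigma2 = max(2 * best.cost / n, 1e-300)
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    k = len(best.x) + 1
    return best.x, 2 * k - 2 * loglik, math.sqrt(sigma2)


def fit_gene_family(concentrations, log2_values, family: Sequence[str] = GENE_MODEL_FAMILY,
                    seed: int = 0):
    """Fit every family member to one gene; return (fits, AIC weights, sigma).

    ``fits`` maps model id -> (theta, aic, sigma); weights are
    exp(-ΔAIC/2) normalised over the converged members; the pooled residual
    SD is their weight-averaged sigma.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(log2_values, dtype=float)
    fits = {}
    for m in family:
        res = _fit_gene_model(m, x, y, seed=child_seed(seed, m))
        if res is not None:
            fits[m] = res
    if not fits:
        return {}, {}, float("nan")
    aics = np.array([fits[m][1] for m in fits])
    w = np.exp(-(aics - aics.min()) / 2.0)
    w = w / w.sum()
    weights = {m: float(wi) for m, wi in zip(fits, w)}
    sigma_pooled = float(sum(weights[m] * fits[m][2] for m in fits))
    return fits, weights, sigma_pooled


def _bmc_from_family(fits, weights, sigma_pooled, xmax: float, k_sd: float):
    """Root of |avg_mean(x) - avg_mean(0)| = k_sd * sigma on [0, xmax]."""

    def avg_mean(xx):
        xx = np.asarray(xx, dtype=float)
        return sum(weights[m] * _gene_mean(m, xx, fits[m][0]) for m in fits)

    m0 = float(avg_mean(np.array([0.0]))[0])
    delta = k_sd * sigma_pooled
    grid = np.linspace(0.0, xmax, 256)
    dev = np.abs(avg_mean(grid) - m0) - delta
    if dev[0] >= 0:
        return 0.0, "ok"  # deviation already exceeds delta at control
    cross = np.nonzero((dev[:-1] < 0) & (dev[1:] >= 0))[0]
    if len(cross) == 0:
        return None, "unreachable"
    i = int(cross[0])
    f = lambda xx: abs(float(avg_mean(np.array([xx]))[0]) - m0) - delta
    bmc = float(optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-10, rtol=1e-10))
    return bmc, "ok"


def model_average_bmc(
    concentrations: Sequence[float],
    log2_values: Sequence[float],
    bmr: BmrSpec,
    family: Sequence[str] = GENE_MODEL_FAMILY,
    seed: int = 0,
    gene: str = "",
    p_trend: float = float("nan"),
) -> GeneBmc:
    """AIC-weight model-averaged BMC for one gene at an SD-based BMR.

    Every family member is fitted by maximum likelihood (normal residuals on
    the log2 scale); weights are exp(-ΔAIC/2) normalised; the BMC solves
    ``|mean(x) - mean(0)| = k * sigma_pooled`` on the weight-averaged mean
    curve by bracketed root-finding over the tested range.
    """
    if bmr.kind != "sd":
        raise ValueError("gene BMCs use SD-based BMRs")
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(log2_values, dtype=float)
    fc = max_fold_change(y, x)
    fits, weights, sigma_pooled = fit_gene_family(x, y, family, seed)
    if not fits:
        return GeneBmc(gene, None, p_trend, fc, {}, status="fit_failed")
    bmc, status = _bmc_from_family(fits, weights, sigma_pooled, float(np.max(x)), bmr.value)
    return GeneBmc(gene, bmc, p_trend, fc, weights, status=status)


# ---------------------------------------------------------------------------
# pathway tPOD
# ---------------------------------------------------------------------------

def pathway_tpod(gene_bmcs: Sequence[GeneBmc], pathway_genes: set[str],
                 rule: str = "min3", pathway: str = "") -> PathwayTpod:
    """Median BMC over concentration-responsive pathway genes.

    ``rule='min3'`` requires at least 3 responsive genes; ``rule='ntp_5pct'``
    requires max(3, ceil(0.05 * pathway size)) — e.g. 10 genes for a 198-gene
    pathway. Even counts take the arithmetic midpoint of the central pair.
    """
    if not pathway_genes:
        raise ValueError("pathway gene set is empty")
    if rule == "min3":
        threshold = 3
    elif rule == "ntp_5pct":
        threshold = max(3, math.ceil(0.05 * len(pathway_genes)))
    else:
        raise ValueError(f"unknown tPOD rule {rule!r}")
    in_path = [g for g in gene_bmcs if g.gene in pathway_genes and g.status == "ok" and g.bmc is not None]
    n_resp = len(in_path)
    tpod = float(np.median([g.bmc for g in in_path])) if n_resp >= threshold else None
    return PathwayTpod(pathway or "pathway", len(pathway_genes), n_resp, tpod, rule)


def read_gmt(path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name <tab> description <tab> genes...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


# ---------------------------------------------------------------------------
# high-level driver
# ---------------------------------------------------------------------------

def analyze_expression(
    dataset: ExpressionDataset,
    bmrs: Sequence[BmrSpec] = DEFAULT_SD_BMRS,
    n_permutations: int = 1000,
    p_cutoff: float = 0.05,
    fc_cutoff: float = 1.5,
    family: Sequence[str] = GENE_MODEL_FAMILY,
    seed: int = 0,
) -> dict[str, list[GeneBmc]]:
    """Trend test + filter + model-averaged BMCs for one expression dataset.

    Returns a mapping BMR label -> GeneBmc list for the responsive genes.
    """
    conc = dataset.samples.set_index("sample").loc[dataset.matrix.columns,
                                                   "concentration_ug_per_ml"].to_numpy()
    pvals = williams_many(dataset.matrix, conc, n_permutations, seed=child_seed(seed, "williams"))
    fcs = {g: max_fold_change(dataset.matrix.loc[g].to_numpy(), conc) for g in dataset.matrix.index}
    table = pd.DataFrame({"gene": pvals.index, "p_trend": pvals.to_numpy(),
                          "max_abs_fc": [fcs[g] for g in pvals.index]})
    responsive = filter_responsive_genes(table, p_cutoff, fc_cutoff)
    out: dict[str, list[GeneBmc]] = {bmr.label(): [] for bmr in bmrs}
    xmax = float(np.max(conc))
    for g in responsive:
        y = dataset.matrix.loc[g].to_numpy()
        fits, weights, sigma_pooled = fit_gene_family(conc, y, family,
                                                      seed=child_seed(seed, "bmc", g))
        for bmr in bmrs:
            if not fits:
                rec = GeneBmc(g, None, float(pvals[g]), fcs[g], {}, status="fit_failed")
            else:
                bmc, status = _bmc_from_family(fits, weights, sigma_pooled, xmax, bmr.value)
                rec = GeneBmc(g, bmc, float(pvals[g]), fcs[g], weights, status=status)
            out[bmr.label()].append(rec)
    return out
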