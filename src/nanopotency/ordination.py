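"""Ordination and association analyses of the BMC potency matrices.

PCA (correlation-matrix convention: columns centred and scaled to unit
variance, unit-norm eigenvector loadings) with the |loading| > 0.4
significance rule on the first two components; Spearman rank correlations
between endpoint potencies on the combined cross-BMR matrix; and Kendall
tau-b between endpoint potencies and ordinal/continuous physicochemical
properties with pairwise deletion of missing property values. Correlation
strength follows the conventional taxonomy (negligible/weak/moderate/
strong/very strong); coefficients falling in the taxonomy's boundary gaps
(e.g. |r| exactly 0.30–0.31) take the lower bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PcaResult",
    "AssociationResult",
    "pca",
    "spearman_matrix",
    "kendall_tau_b",
    "strength_label",
    "property_associations",
]

LOADING_CUTOFF = 0.4
_STRENGTH_BOUNDS = ((0.31, "negligible"), (0.51, "weak"), (0.71, "moderate"),
                    (0.91, "strong"))


@dataclass
class PcaResult:
    """Scores, loadings and variance shares of a scaled PCA."""

    scores: pd.DataFrame           # rows x PCs
    loadings: pd.DataFrame         # endpoints x PCs (unit-norm eigenvectors)
    pct_variance: pd.Series        # per PC, sums to 100 over all PCs
    kept_pcs: int
    significant: dict              # PC name -> endpoints with |loading| > 0.4


@dataclass
class AssociationResult:
    """One correlation with its strength label."""

    pair: tuple
    method: str                    # spearman | kendall_tau_b
    coefficient: float | None
    p_value: float | None
    strength: str | None
    significant: bool
    n: int
    flag: str = ""


def strength_label(coefficient: float) -> str:
    """Bin |r| into negligible/weak/moderate/strong/very strong."""
    ar = abs(float(coefficient))
    if ar > 1.0 + 1e-12:
        raise ValueError("correlation coefficient outside [-1, 1]")
    for bound, name in _STRENGTH_BOUNDS:
        if ar <= bound:
            return name
    return "very strong"


def pca(matrix: pd.DataFrame, scale: bool = True, kept_pcs: int = 2,
        loading_cutoff: float = LOADING_CUTOFF) -> PcaResult:
    """PCA of rows (compounds) over endpoint columns.

    Columns are centred and, with ``scale=True``, divided by their sample SD
    (the correlation-matrix convention). Loadings are unit-norm eigenvectors;
    each PC's sign is fixed so its largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need >= 3 rows for PCA")
    sd = X.std(axis=0, ddof=1)
    if scale:
        zero = np.where(sd == 0)[0]
        if len(zero):
            raise ValueError(f"zero-variance endpoint column: {matrix.columns[zero[0]]!r}")
        Xs = (X - X.mean(axis=0)) / sd
    else:
        Xs = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = s**2 / (X.shape[0] - 1)
    # sign convention: largest |loading| per PC made positive
    V = Vt.T
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    scores = U * s
    pc_names = [f"PC{j + 1}" for j in range(V.shape[1])]
    scores_df = pd.DataFrame(scores, index=matrix.index, columns=pc_names)
    load_df = pd.DataFrame(V, index=matrix.columns, columns=pc_names)
    pct = pd.Series(100.0 * eig / eig.sum(), index=pc_names, name="pct_variance")
    significant = {
        pc: list(load_df.index[np.abs(load_df[pc]) > loading_cutoff])
        for pc in pc_names[:kept_pcs]
    }
    return PcaResult(scores_df, load_df, pct, kept_pcs, significant)


def spearman_matrix(combined: pd.DataFrame, alpha: float = 0.05) -> list[AssociationResult]:
    """Spearman rank correlations for every endpoint pair of the combined matrix.

    Average ranks for ties, two-sided p, pairwise-complete observations; a
    pair with fewer than 4 complete observations is skipped with a flag.
    """
    out = []
    cols = list(combined.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            sub = combined[[a, b]].dropna()
            if len(sub) < 4:
                out.append(AssociationResult((a, b), "spearman", None, None, None,
                                             False, len(sub), flag="too_few_observations"))
                continue
            rho, p = stats.spearmanr(sub[a], sub[b])
            out.append(AssociationResult((a, b), "spearman", float(rho), float(p),
                                         strength_label(rho), p < alpha, len(sub)))
    return out


def kendall_tau_b(x: Sequence[float], y: Sequence[float], pair=("x", "y"),
                  alpha: float = 0.05) -> AssociationResult:
    """Kendall tau-b with tie correction; exact p for small untied samples.

    Rows where either value is missing are dropped pairwise (properties are
    absent for dissolved compounds). An all-tied variable has no defined
    coefficient and is reported absent with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return AssociationResult(pair, "kendall_tau_b", None, None, None, False,
                                 n, flag="too_few_observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return AssociationResult(pair, "kendall_tau_b", None, None, None, False,
                                 n, flag="undefined_all_tied")
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    method = "exact" if (n <= 10 and not has_ties) else "asymptotic"
    tau, p = stats.kendalltau(x, y, variant="b", method=method)
    return AssociationResult(pair, "kendall_tau_b", float(tau), float(p),
                             strength_label(tau), p < alpha, n)


def property_associations(
    combined: pd.DataFrame,
    properties: pd.DataFrame,
    property_cols: Sequence[str] = ("form_code", "pps_nm", "ssa_m2_per_g", "solubility_pct"),
) -> list[AssociationResult]:
    """Kendall tau-b between each endpoint potency and each property.

    Endpoint BMCs are the combined cross-BMR rows (compound, bmr); each
    compound's property value is broadcast across its BMR rows, mirroring the
    pooled Spearman convention.
    """
    comp_index = combined.index.get_level_values("compound")
    out = []
    for prop in property_cols:
        pvals = properties.set_index("compound")[prop]
        prop_vec = pvals.reindex(comp_index).to_numpy(dtype=float)
        for ep in combined.columns:
            out.append(
                kendall_tau_b(combined[ep].to_numpy(dtype=float), prop_vec,
                              pair=(ep, prop))
            )
    return out


def associations_to_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    """Flatten association results to the delimited output schema."""
    return pd.DataFrame(
        {
            "var_a": [r.pair[0] for r in results],
            "var_b": [r.pair[1] for r in results],
            "method": [r.method for r in results],
            "coefficient": [r.coefficient for r in results],
            "p_value": [r.p_value for r in results],
            "strength": [r.strength for r in results],
            "significant": [r.significant for r in results],
            "n": [r.n for r in results],
            "flag": [r.flag for r in results],
        }
    )
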