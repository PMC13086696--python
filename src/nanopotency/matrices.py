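"""Assembly of the compounds x endpoints benchmark-concentration matrices.

One matrix per benchmark response holds the 7 potency endpoints (24/48 h
viability, 2/4 h comet, 40 h micronucleus, 24/48 h transcriptomic tPOD) in µM
constituent metal. Cells without an estimable BMC (no response, unreachable
BMR, failed fit) are imputed with the compound's top tested concentration —
the usual "no observed BMC at or below the top dose" surrogate — then each
endpoint column is winsorized and the whole matrix log10-transformed. The
four per-BMR matrices row-stack into the combined cross-BMR matrix used for
the correlation analyses (18 compounds x 4 BMRs = 72 rows).

Winsorization replaces the ``floor(q * n)`` most extreme values in a column
with the adjacent order statistic (the convention of
``scipy.stats.mstats.winsorize``), which makes the operation idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mstats

__all__ = [
    "BmcMatrix",
    "DEFAULT_ENDPOINT_COLUMNS",
    "assemble_matrix",
    "impute_and_winsorize",
    "log10_transform",
    "combine_across_bmrs",
    "split_combined",
]

DEFAULT_ENDPOINT_COLUMNS = (
    "viability_24h",
    "viability_48h",
    "comet_2h",
    "comet_4h",
    "mn_40h",
    "tpod_24h",
    "tpod_48h",
)


@dataclass
class BmcMatrix:
    """Compounds x endpoints BMC matrix with per-cell provenance flags.

    ``values`` is µM constituent metal (or log10 µM once transformed;
    ``log_scale`` says which). ``flags`` holds 'fitted', 'imputed' or
    'winsorized' per cell ('' for absent cells awaiting imputation).
    """

    bmr_label: str
    values: pd.DataFrame
    flags: pd.DataFrame
    log_scale: bool = False
    warnings: list = field(default_factory=list)

    def copy(self) -> "BmcMatrix":
        return BmcMatrix(self.bmr_label, self.values.copy(), self.flags.copy(),
                         self.log_scale, list(self.warnings))

    def write(self, path) -> None:
        out = self.values.copy()
        out.index.name = "compound"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path, bmr_label: str = "", log_scale: bool = True) -> "BmcMatrix":
        vals = pd.read_csv(path, sep="\t", index_col=0)
        flags = pd.DataFrame("fitted", index=vals.index, columns=vals.columns)
        return cls(bmr_label, vals, flags, log_scale=log_scale)


def assemble_matrix(
    records: pd.DataFrame,
    bmr_label: str,
    compounds: Sequence[str] | None = None,
    endpoints: Sequence[str] = DEFAULT_ENDPOINT_COLUMNS,
) -> BmcMatrix:
    """Raw per-BMR matrix from a BMC record table.

    ``records`` needs columns compound, endpoint, bmr, bmc_uM_metal, status;
    only rows matching ``bmr_label`` are used. Absent or non-ok records leave
    empty cells (flag '') for downstream imputation. Duplicate
    compound x endpoint records are a validation error.
    """
    sub = records[records["bmr"] == bmr_label]
    dup = sub.duplicated(subset=["compound", "endpoint"])
    if dup.any():
        pairs = sub.loc[dup, ["compound", "endpoint"]].values.tolist()
        raise ValueError(f"duplicate compound x endpoint records: {pairs}")
    if compounds is None:
        compounds = sorted(sub["compound"].unique())
    values = pd.DataFrame(np.nan, index=list(compounds), columns=list(endpoints), dtype=float)
    flags = pd.DataFrame("", index=list(compounds), columns=list(endpoints))
    for _, r in sub.iterrows():
        if r["endpoint"] not in values.columns or r["compound"] not in values.index:
            continue
        if r["status"] == "ok" and pd.notna(r["bmc_uM_metal"]):
            values.loc[r["compound"], r["endpoint"]] = float(r["bmc_uM_metal"])
            flags.loc[r["compound"], r["endpoint"]] = "fitted"
    return BmcMatrix(bmr_label, values, flags)


def impute_and_winsorize(
    matrix: BmcMatrix,
    ceiling_uM: Mapping[str, float],
    winsor_quantiles: tuple[float, float] = (0.05, 0.95),
    ceiling_multiplier: float = 1.0,
) -> BmcMatrix:
    """Fill non-responsive cells with the top tested concentration, then winsorize.

    ``ceiling_uM`` maps each compound to its highest tested concentration in
    µM metal. Winsorization is per endpoint column at the given quantile pair
    using order-statistic replacement; fitted values inside the bounds are
    never altered, and re-applying the operation is a no-op.
    """
    q_low, q_high = winsor_quantiles
    if not 0 <= q_low < q_high <= 1:
        raise ValueError("winsor quantiles must satisfy 0 <= low < high <= 1")
    out = matrix.copy()
    drop = [ep for ep in out.values.columns if out.values[ep].isna().all()]
    if drop:
        out.warnings.append(f"dropping all-absent endpoint columns: {drop}")
        out.values = out.values.drop(columns=drop)
        out.flags = out.flags.drop(columns=drop)
    for comp in out.values.index:
        for ep in out.values.columns:
            if np.isnan(out.values.loc[comp, ep]):
                if comp not in ceiling_uM:
                    raise KeyError(f"no top-concentration ceiling for compound {comp!r}")
                out.values.loc[comp, ep] = float(ceiling_uM[comp]) * ceiling_multiplier
                out.flags.loc[comp, ep] = "imputed"
    for ep in out.values.columns:
        col = out.values[ep].to_numpy(dtype=float)
        wz = np.asarray(mstats.winsorize(col, limits=(q_low, 1.0 - q_high)))
        changed = wz != col
        out.values[ep] = wz
        out.flags.loc[changed, ep] = out.flags.loc[changed, ep] + "+winsorized"
    return out


def log10_transform(matrix: BmcMatrix) -> BmcMatrix:
    """Elementwise log10; every value must be positive."""
    if matrix.log_scale:
        raise ValueError("matrix is already log10-transformed")
    bad = matrix.values.stack()[matrix.values.stack() <= 0]
    if len(bad):
        cell = bad.index[0]
        raise ValueError(f"non-positive BMC at compound={cell[0]!r}, endpoint={cell[1]!r}")
    out = matrix.copy()
    out.values = np.log10(matrix.values)
    out.log_scale = True
    return out


def combine_across_bmrs(matrices: Sequence[BmcMatrix]) -> pd.DataFrame:
    """Row-stack per-BMR matrices into the combined (compound, bmr) matrix.

    Rows are compound-major, BMR-minor, giving 18 x 4 = 72 rows for the full
    study design. Endpoint sets must agree across BMRs.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    cols = list(matrices[0].values.columns)
    comps = list(matrices[0].values.index)
    for m in matrices[1:]:
        if list(m.values.columns) != cols:
            raise ValueError("endpoint sets differ across BMR matrices")
        if list(m.values.index) != comps:
            raise ValueError("compound sets differ across BMR matrices")
    frames = {m.bmr_label: m.values for m in matrices}
    rows = []
    keys = []
    for comp in comps:
        for label, vals in frames.items():
            rows.append(vals.loc[comp])
            keys.append((comp, label))
    out = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(keys, names=["compound", "bmr"]))
    out.columns = cols
    return out


def split_combined(combined: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Inverse of :func:`combine_across_bmrs` (per-BMR value frames)."""
    out = {}
    for label in combined.index.get_level_values("bmr").unique():
        sub = combined.xs(label, level="bmr")
        out[label] = sub
    return out
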