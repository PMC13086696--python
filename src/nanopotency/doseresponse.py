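"""Benchmark-concentration modelling of apical endpoints.

Continuous dose-response models in the PROAST family are fitted by maximum
likelihood under lognormal residuals (responses strictly positive), with the
exposure timepoint as an optional covariate: background ``a`` and rate ``b``
are level-specific while shape ``d``, asymptote ``c`` and the residual SD are
shared. The best model per compound x endpoint is the one with the lowest
AIC; exact AIC ties are broken by the lower benchmark concentration. BMCs are
reported at relative-deviation benchmark responses (5/10/25/50 % by default)
and converted to µM of the constituent metal.

Model family (x >= 0 concentration; a, b, c, d per docstrings below):

* ``null``:  m(x) = a
* ``exp3``:  m(x) = a * exp(b * x**d)
* ``exp5``:  m(x) = a * (c - (c - 1) * exp(-b * x**d)),  b > 0
* ``hill3``: m(x) = a * (1 - x**d / (b**d + x**d))
* ``hill5``: m(x) = a * (1 + (c - 1) * x**d / (b**d + x**d)),  b > 0
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .datasets import CompoundSpec, ConcResponseDataset, UnreachableBmrError, child_seed

__all__ = [
    "BmrSpec",
    "FittedModel",
    "BmcRecord",
    "DEFAULT_RELATIVE_BMRS",
    "DEFAULT_SD_BMRS",
    "MODEL_FAMILY",
    "ENDPOINT_DIRECTIONS",
    "load_molar_masses",
    "normalize_to_metal_uM",
    "fit_model",
    "fit_all_models",
    "select_best_model",
    "bmc_from_model",
    "fit_bmc_records",
    "records_to_frame",
]

MODEL_FAMILY = ("null", "exp3", "exp5", "hill3", "hill5")

#: Adverse direction per endpoint family (prefix before the timepoint suffix).
ENDPOINT_DIRECTIONS = {
    "viability": "decrease",
    "comet": "increase",
    "mn": "increase",
    "tpod": "increase",
}

_AIC_TIE_TOL = 1e-6


@dataclass(frozen=True)
class BmrSpec:
    """Benchmark response: relative deviation from control, or k residual SDs."""

    kind: str = "relative"  # relative | sd
    value: float = 0.05
    direction: str = "adverse-auto"  # increase | decrease | adverse-auto

    def __post_init__(self) -> None:
        if self.kind not in ("relative", "sd"):
            raise ValueError("BMR kind must be 'relative' or 'sd'")
        if self.value <= 0:
            raise ValueError("BMR value must be positive")
        if self.kind == "relative" and self.value >= 1:
            raise ValueError("relative BMR must be a fraction < 1")

    def label(self) -> str:
        if self.kind == "relative":
            return f"rel{self.value * 100:g}"
        return f"sd{self.value:g}"


DEFAULT_RELATIVE_BMRS = tuple(BmrSpec("relative", v) for v in (0.05, 0.10, 0.25, 0.50))
DEFAULT_SD_BMRS = tuple(BmrSpec("sd", v) for v in (1.021, 1.349, 1.932, 2.601))


@dataclass
class FittedModel:
    """One maximum-likelihood dose-response fit, possibly with covariate levels.

    ``params`` maps covariate level -> (a, b, c, d); levels are the distinct
    timepoints (a single ``None`` level when no covariate is used). ``sigma``
    is the pooled residual SD on the log scale.
    """

    model_id: str
    params: dict
    sigma: float
    log_likelihood: float
    n_params: int
    aic: float
    covariate_levels: tuple
    status: str = "ok"  # ok | fit_failed

    def mean(self, x, level=None) -> np.ndarray:
        a, b, c, d = self.params[level]
        return _model_mean(self.model_id, np.asarray(x, dtype=float), a, b, c, d)


@dataclass
class BmcRecord:
    """One compound x endpoint x BMR potency estimate."""

    compound: str
    endpoint: str
    timepoint_h: float
    bmr: BmrSpec
    bmc: float | None  # on the fitted concentration axis
    model_id: str
    aic: float
    status: str  # ok | no_response | unreachable | fit_failed
    bmc_uM_metal: float | None = None


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def load_molar_masses() -> pd.DataFrame:
    """Default molar-mass table for the study compounds (editable TSV)."""
    with resources.files("nanopotency.data").joinpath("molar_masses.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _mass_table_dict(table: pd.DataFrame | Mapping[str, float] | None) -> Mapping[str, float]:
    if table is None:
        table = load_molar_masses()
    if isinstance(table, pd.DataFrame):
        return dict(zip(table["chemical_formula"], table["molar_mass_g_per_mol"]))
    return table


def normalize_to_metal_uM(
    mass_conc_ug_per_ml: float,
    compound: CompoundSpec,
    molar_mass_table: pd.DataFrame | Mapping[str, float] | None = None,
) -> float:
    """Convert a mass concentration to µM of the constituent metal.

    µM metal = µg/mL / (g/mol) * 1000 * metal atoms per formula unit. Hydrated
    salts use the hydrate molar mass as listed in the table entry.
    """
    if mass_conc_ug_per_ml < 0:
        raise ValueError("mass concentration must be >= 0")
    masses = _mass_table_dict(molar_mass_table)
    try:
        mw = masses[compound.chemical_formula]
    except KeyError:
        raise KeyError(
            f"no molar mass for formula {compound.chemical_formula!r}"
        ) from None
    return mass_conc_ug_per_ml / mw * 1000.0 * compound.metal_atoms_per_formula


# ---------------------------------------------------------------------------
# model means and likelihood
# ---------------------------------------------------------------------------

def _model_mean(model_id: str, x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    if model_id == "null":
        return np.full_like(x, a)
    with np.errstate(over="ignore", invalid="ignore"):
        xd = np.power(np.maximum(x, 0.0), d)
        if model_id == "exp3":
            return a * np.exp(np.clip(b * xd, -700, 700))
        if model_id == "exp5":
            return a * (c - (c - 1.0) * np.exp(np.clip(-b * xd, -700, 700)))
        frac = xd / (b**d + xd)
        if model_id == "hill3":
            return a * (1.0 - frac)
        if model_id == "hill5":
            return a * (1.0 + (c - 1.0) * frac)
    raise ValueError(f"unknown model {model_id!r}")


def _n_free_params(model_id: str, n_levels: int) -> int:
    # level-specific a and b; shared c, d; pooled sigma
    if model_id == "null":
        return n_levels + 1
    if model_id == "exp3":
        return 2 * n_levels + 1 + 1  # a_l, b_l, d, sigma
    if model_id == "hill3":
        return 2 * n_levels + 1 + 1
    return 2 * n_levels + 2 + 1  # exp5/hill5: + c


def _pack(model_id: str, a: np.ndarray, b: np.ndarray, c: float, d: float) -> np.ndarray:
    la = np.log(a)
    if model_id == "null":
        return la
    if model_id == "exp3":
        return np.concatenate([la, b, [np.log(d)]])
    lb = np.log(b)
    if model_id == "hill3":
        return np.concatenate([la, lb, [np.log(d)]])
    return np.concatenate([la, lb, [np.log(c), np.log(d)]])


def _unpack(model_id: str, theta: np.ndarray, n_levels: int):
    a = np.exp(theta[:n_levels])
    if model_id == "null":
        return a, np.zeros(n_levels), 1.0, 1.0
    # shape exponent kept in a sane range to avoid x**d overflow
    if model_id == "exp3":
        b = theta[n_levels : 2 * n_levels]
        d = math.exp(min(max(theta[-1], -4.0), 3.0))
        return a, b, 1.0, d
    b = np.exp(np.clip(theta[n_levels : 2 * n_levels], -60, 60))
    if model_id == "hill3":
        d = math.exp(min(max(theta[-1], -4.0), 3.0))
        return a, b, 0.0, d
    c = math.exp(min(max(theta[-2], -30.0), 30.0))
    d = math.exp(min(max(theta[-1], -4.0), 3.0))
    return a, b, c, d


def fit_model(
    data: pd.DataFrame,
    model_id: str,
    covariate: str | None = "timepoint_h",
    seed: int = 0,
    n_starts: int = 5,
) -> FittedModel:
    """Maximum-likelihood fit of one model to a compound x endpoint slice.

    ``data`` needs columns ``concentration``, ``response`` and, when
    ``covariate`` is given, that covariate column. Responses must be strictly
    positive (lognormal likelihood). Optimizer failures yield a
    ``fit_failed`` model rather than an exception.
    """
    conc = np.asarray(data["concentration"], dtype=float)
    resp = np.asarray(data["response"], dtype=float)
    if np.any(resp <= 0):
        raise ValueError("responses must be strictly positive for the lognormal likelihood")
    if len(np.unique(conc)) < 3:
        raise ValueError("need >= 3 distinct concentrations including control")
    if covariate is not None and covariate in data.columns:
        lev = np.asarray(data[covariate])
        levels = tuple(sorted(pd.unique(lev)))
    else:
        lev = np.zeros(len(conc))
        levels = (0,)
    lev_idx = np.searchsorted(np.asarray(sorted(set(lev.tolist()))), lev)
    if len(levels) == 1:
        levels = (None,)
        lev_idx = np.zeros(len(conc), dtype=int)

    logy = np.log(resp)
    nlev = len(levels)

    def residuals(theta: np.ndarray) -> np.ndarray:
        a, b, c, d = _unpack(model_id, theta, nlev)
        mu = np.empty_like(logy)
        for li in range(nlev):
            m = lev_idx == li
            mean = _model_mean(model_id, conc[m], a[li], b[li], c, d)
            with np.errstate(invalid="ignore", divide="ignore"):
                mu[m] = np.log(np.maximum(mean, 1e-300))
        r = logy - mu
        return np.where(np.isfinite(r), r, 1e6)

    best = None
    for theta0 in _starting_points(model_id, conc, logy, lev_idx, nlev, seed, n_starts):
        try:
            sol = optimize.least_squares(
                residuals, theta0, method="lm" if len(theta0) < len(logy) else "trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    if best is None:
        return FittedModel(model_id, {}, float("nan"), float("nan"),
                           _n_free_params(model_id, nlev), float("inf"),
                           levels, status="fit_failed")

    a, b, c, d = _unpack(model_id, best.x, nlev)
    n = len(logy)
    rss = float(2 * best.cost)
    sigma2 = max(rss / n, 1e-300)
    # lognormal density of y includes the -sum(log y) Jacobian term
    loglik = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0) - float(np.sum(logy))
    k = _n_free_params(model_id, nlev)
    params = {levels[li]: (float(a[li]), float(b[li]), float(c), float(d)) for li in range(nlev)}
    return FittedModel(
        model_id=model_id,
        params=params,
        sigma=math.sqrt(sigma2),
        log_likelihood=loglik,
        n_params=k,
        aic=2 * k - 2 * loglik,
        covariate_levels=levels,
    )


def _starting_points(model_id, conc, logy, lev_idx, nlev, seed, n_starts):
    """Log-spaced rate grids around the data scale, per DESIGN: >=5 starts."""
    xmax = float(np.max(conc))
    a0 = np.array([np.exp(np.mean(logy[(lev_idx == li) & (conc == 0)])) if np.any((lev_idx == li) & (conc == 0)) else np.exp(np.mean(logy[lev_idx == li])) for li in range(nlev)])
    # observed top/control log-ratio per level, to orient direction + magnitude
    ratios = []
    for li in range(nlev):
        m = lev_idx == li
        sub_c, sub_y = conc[m], logy[m]
        top = sub_c == np.max(sub_c)
        ratios.append(float(np.mean(sub_y[top]) - math.log(a0[li])))
    r = float(np.mean(ratios))
    if model_id == "null":
        yield np.log(a0)
        return
    rng = np.random.default_rng(seed)
    d_grid = (0.7, 1.0, 2.0)
    scale_grid = (0.3, 1.0, 3.0)
    count = 0
    for d0 in d_grid:
        for s in scale_grid:
            if model_id == "exp3":
                b0 = (r if r != 0 else -0.1) / (xmax**d0) * s
                yield _pack(model_id, a0, np.full(nlev, b0), 1.0, d0)
                if count == 0:
                    yield _pack(model_id, a0, np.full(nlev, -b0), 1.0, d0)
            elif model_id == "exp5":
                c0 = max(math.exp(r * 1.2), 1e-3)
                if abs(c0 - 1) < 1e-3:
                    c0 = 1.5 if r >= 0 else 0.5
                b0 = s / (xmax**d0)
                yield _pack(model_id, a0, np.full(nlev, b0), c0, d0)
            elif model_id == "hill3":
                yield _pack(model_id, a0, np.full(nlev, xmax * s), 0.0, d0)
            elif model_id == "hill5":
                c0 = max(math.exp(r * 1.2), 1e-3)
                if abs(c0 - 1) < 1e-3:
                    c0 = 1.5 if r >= 0 else 0.5
                yield _pack(model_id, a0, np.full(nlev, xmax * s), c0, d0)
            count += 1
            if count >= max(n_starts, 5) and model_id != "exp3":
                # jittered extra start to escape local minima
                pass
    # one random jittered start for robustness
    if model_id != "null":
        d0 = float(np.exp(rng.normal(0, 0.3)))
        if model_id == "exp3":
            b0 = (r if r != 0 else -0.1) / (xmax**d0) * float(np.exp(rng.normal(0, 1)))
            yield _pack(model_id, a0, np.full(nlev, b0), 1.0, d0)
        elif model_id in ("hill3", "hill5"):
            c0 = 0.5 if r < 0 else 2.0
            yield _pack(model_id, a0, np.full(nlev, xmax * float(np.exp(rng.normal(0, 1)))), c0, d0)
        else:
            c0 = 0.5 if r < 0 else 2.0
            yield _pack(model_id, a0, np.full(nlev, float(np.exp(rng.normal(0, 1))) / xmax), c0, d0)


def fit_all_models(
    data: pd.DataFrame,
    covariate: str | None = "timepoint_h",
    models: Sequence[str] = MODEL_FAMILY,
    seed: int = 0,
) -> list[FittedModel]:
    """Fit the full family to one data slice."""
    return [fit_model(data, m, covariate=covariate, seed=child_seed(seed, m)) for m in models]


def select_best_model(candidates: Sequence[FittedModel], bmr: BmrSpec) -> FittedModel:
    """Lowest AIC wins; AIC ties (within 1e-6) go to the lowest BMC at ``bmr``."""
    if not candidates:
        raise ValueError("empty candidate list")
    usable = [m for m in candidates if m.status == "ok"]
    if not usable:
        out = candidates[0]
        return out
    best_aic = min(m.aic for m in usable)
    tied = [m for m in usable if m.aic <= best_aic + _AIC_TIE_TOL]
    if len(tied) == 1:
        return tied[0]

    def tiebreak_bmc(m: FittedModel) -> float:
        vals = []
        for level in m.covariate_levels:
            rec = bmc_from_model(m, bmr, covariate_level=level)
            if rec.status == "ok":
                vals.append(rec.bmc)
        return min(vals) if vals else float("inf")

    return min(tied, key=tiebreak_bmc)


# ---------------------------------------------------------------------------
# BMC inversion
# ---------------------------------------------------------------------------

def _invert_ratio(model_id: str, params, target: float) -> float:
    """Concentration where m(x)/m(0) = target; closed form per model."""
    a, b, c, d = params
    if model_id == "null":
        raise UnreachableBmrError("constant model has no BMC")
    if model_id == "exp3":
        u = math.log(target) / b if b != 0 else float("inf")
        if not (u > 0 and math.isfinite(u)):
            raise UnreachableBmrError(f"ratio {target} unreachable for exp3 b={b}")
        return u ** (1.0 / d)
    if model_id == "exp5":
        denom = c - 1.0
        if denom == 0:
            raise UnreachableBmrError("flat exp5 (c=1)")
        s = (c - target) / denom
        if not 0.0 < s < 1.0:
            raise UnreachableBmrError(f"ratio {target} beyond exp5 asymptote c={c}")
        return (-math.log(s) / b) ** (1.0 / d)
    if model_id == "hill3":
        if not 0.0 < target < 1.0:
            raise UnreachableBmrError(f"hill3 only reaches ratios in (0,1), not {target}")
        f = 1.0 - target
        return b * (f / (1.0 - f)) ** (1.0 / d)
    # hill5
    denom = c - 1.0
    if denom == 0:
        raise UnreachableBmrError("flat hill5 (c=1)")
    f = (target - 1.0) / denom
    if not 0.0 < f < 1.0:
        raise UnreachableBmrError(f"ratio {target} beyond hill5 asymptote c={c}")
    return b * (f / (1.0 - f)) ** (1.0 / d)


def _fitted_direction(model: FittedModel, level) -> str:
    a, b, c, d = model.params[level]
    if model.model_id == "exp3":
        return "decrease" if b < 0 else "increase"
    if model.model_id == "hill3":
        return "decrease"
    return "decrease" if c < 1.0 else "increase"


def bmc_from_model(model: FittedModel, bmr: BmrSpec, covariate_level=None,
                   compound: str = "", endpoint: str = "") -> BmcRecord:
    """BMC where the fitted mean deviates from control by the BMR fraction.

    Direction ``adverse-auto`` takes the fitted curve's own direction (sign of
    b, or c versus 1).
    """
    tp = covariate_level if isinstance(covariate_level, (int, float)) else float("nan")
    if model.status != "ok":
        return BmcRecord(compound, endpoint, tp, bmr, None, model.model_id,
                         model.aic, "fit_failed")
    if model.model_id == "null":
        return BmcRecord(compound, endpoint, tp, bmr, None, "null", model.aic, "no_response")
    if bmr.kind != "relative":
        raise ValueError("apical BMCs use relative BMRs")
    level = covariate_level if covariate_level in model.params else model.covariate_levels[0]
    direction = bmr.direction
    if direction == "adverse-auto":
        direction = _fitted_direction(model, level)
    target = 1.0 - bmr.value if direction == "decrease" else 1.0 + bmr.value
    try:
        x = _invert_ratio(model.model_id, model.params[level], target)
    except UnreachableBmrError:
        return BmcRecord(compound, endpoint, tp, bmr, None, model.model_id,
                         model.aic, "unreachable")
    return BmcRecord(compound, endpoint, tp, bmr, float(x), model.model_id, model.aic, "ok")


# ---------------------------------------------------------------------------
# high-level driver
# ---------------------------------------------------------------------------

def _endpoint_family(endpoint: str) -> str:
    return endpoint.rsplit("_", 1)[0]


def fit_bmc_records(
    dataset: ConcResponseDataset,
    bmrs: Sequence[BmrSpec] = DEFAULT_RELATIVE_BMRS,
    compounds: Mapping[str, CompoundSpec] | None = None,
    molar_mass_table=None,
    seed: int = 0,
) -> list[BmcRecord]:
    """Fit every compound x endpoint family and report BMCs at every BMR.

    Endpoint families sharing a prefix (e.g. ``viability_24h``/``viability_48h``)
    are fitted jointly with the timepoint as covariate; the BMC is evaluated at
    each covariate level and reported under the per-timepoint endpoint name.
    When ``compounds`` (and optionally ``molar_mass_table``) are supplied,
    BMCs are additionally converted to µM constituent metal.
    """
    df = dataset.table.copy()
    df["family"] = df["endpoint"].map(_endpoint_family)
    records: list[BmcRecord] = []
    for (comp, fam), sub in df.groupby(["compound", "family"], sort=True):
        slice_df = pd.DataFrame({
            "concentration": sub["concentration_ug_per_ml"],
            "response": sub["response"],
            "timepoint_h": sub["timepoint_h"],
        })
        n_tp = sub["timepoint_h"].nunique()
        covariate = "timepoint_h" if n_tp > 1 else None
        try:
            fits = fit_all_models(slice_df, covariate=covariate, seed=child_seed(seed, comp, fam))
        except ValueError:
            fits = []
        tp_to_endpoint = dict(
            sub[["timepoint_h", "endpoint"]].drop_duplicates().itertuples(index=False, name=None)
        )
        for bmr in bmrs:
            direction = ENDPOINT_DIRECTIONS.get(fam)
            eff_bmr = BmrSpec(bmr.kind, bmr.value, direction or bmr.direction)
            best = select_best_model(fits, eff_bmr) if fits else None
            for tp, ep_name in sorted(tp_to_endpoint.items()):
                if best is None:
                    rec = BmcRecord(comp, ep_name, tp, eff_bmr, None, "none", float("nan"), "fit_failed")
                else:
                    level = tp if tp in best.params else best.covariate_levels[0]
                    rec = bmc_from_model(best, eff_bmr, covariate_level=level,
                                         compound=comp, endpoint=ep_name)
                    rec.timepoint_h = tp
                if rec.status == "ok" and compounds is not None and comp in compounds:
                    rec.bmc_uM_metal = normalize_to_metal_uM(rec.bmc, compounds[comp], molar_mass_table)
                records.append(rec)
    return records


def records_to_frame(records: Sequence[BmcRecord]) -> pd.DataFrame:
    """Flatten BMC records to the delimited output schema."""
    return pd.DataFrame(
        {
            "compound": [r.compound for r in records],
            "endpoint": [r.endpoint for r in records],
            "timepoint_h": [r.timepoint_h for r in records],
            "bmr": [r.bmr.label() for r in records],
            "bmc": [r.bmc for r in records],
            "bmc_uM_metal": [r.bmc_uM_metal for r in records],
            "model": [r.model_id for r in records],
            "aic": [r.aic for r in records],
            "status": [r.status for r in records],
        }
    )
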