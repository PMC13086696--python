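"""Synthetic concentration-response and expression data with known ground truth.

This module generates the two raw data types the potency-grouping pipeline
consumes — replicate-level apical endpoint responses (viability, comet,
micronucleus) across a concentration series, and log2-ratio gene-expression
matrices — from explicit dose-response archetypes, so that every downstream
estimate (benchmark concentrations, trend tests, cluster recovery, hazard
calls) can be checked against a known truth.

Apical responses are drawn as ``mean_curve(x) * exp(N(0, sigma))``
(multiplicative lognormal noise, matching the lognormal likelihood used for
fitting); expression log2 ratios are additive-normal around the archetype's
mean shift from control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundSpec",
    "PotencyArchetype",
    "ExperimentDesign",
    "ConcResponseDataset",
    "ExpressionDataset",
    "UnreachableBmrError",
    "ConfigurationError",
    "mean_response",
    "true_bmc",
    "invert_mean",
    "generate_apical_dataset",
    "generate_expression_dataset",
    "DEFAULT_DESIGN",
    "default_study_compounds",
    "default_archetype_library",
    "default_group_assignment",
    "load_compound_table",
    "child_seed",
]

APICAL_ENDPOINTS = (
    "viability_24h",
    "viability_48h",
    "comet_2h",
    "comet_4h",
    "mn_40h",
)
TPOD_ENDPOINTS = ("tpod_24h", "tpod_48h")
ALL_ENDPOINTS = APICAL_ENDPOINTS + TPOD_ENDPOINTS


class ConfigurationError(ValueError):
    """Raised when a generator request is internally inconsistent."""


class UnreachableBmrError(ValueError):
    """The requested benchmark response lies beyond the curve's asymptote."""


def child_seed(master_seed: int, *tags: object) -> int:
    """Derive a reproducible sub-stream seed (< 2**31) from a master seed.

    Stages and per-compound/per-gene streams each get an independent seed so
    that adding one stage never perturbs another stage's random draws.
    """
    h = master_seed % (2**31 - 1)
    for tag in tags:
        for ch in str(tag):
            h = ((h * 1000003) ^ ord(ch)) & 0xFFFFFFFFFFFFFFFF
    return h % (2**31 - 1)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundSpec:
    """One test article: a dissolved metal salt, nanoparticle or microparticle.

    ``form_code`` is the ordinal 1/2/3 = dissolved/NP/MP convention used for
    ordinal correlation against potency. Particle descriptors (``pps_nm``
    primary particle size, ``ssa_m2_per_g`` specific surface area,
    ``solubility_pct``) are absent (None) for dissolved compounds.
    """

    id: str
    chemical_formula: str
    metal: str
    metal_atoms_per_formula: int = 1
    form_code: int = 2
    pps_nm: float | None = None
    ssa_m2_per_g: float | None = None
    solubility_pct: float | None = None

    def __post_init__(self) -> None:
        if self.form_code not in (1, 2, 3):
            raise ConfigurationError(
                f"{self.id}: form_code must be 1 (dissolved), 2 (NP) or 3 (MP)"
            )
        if self.metal_atoms_per_formula < 1:
            raise ConfigurationError(f"{self.id}: metal_atoms_per_formula >= 1")
        if self.form_code == 1 and (self.pps_nm is not None or self.ssa_m2_per_g is not None):
            raise ConfigurationError(
                f"{self.id}: dissolved compounds carry no particle size/surface area"
            )


@dataclass(frozen=True)
class PotencyArchetype:
    """Ground-truth dose-response curve for one compound x endpoint.

    Models (x = concentration on the design axis, µg/mL; fitted BMCs are
    converted to µM constituent metal downstream):

    * ``exp3``:  m(x) = a * exp(b * x**d)          (b < 0 for a decrease)
    * ``exp5``:  m(x) = a * (c - (c-1) * exp(-b * x**d)),  b > 0
    * ``hill``:  m(x) = a * (1 + (c-1) * x**d / (b**d + x**d)),  b > 0

    ``sigma`` is the lognormal residual SD (log scale) for apical data, or
    the additive normal SD (log2 scale) for expression data.
    """

    model_id: str  # exp3 | exp5 | hill
    a: float
    b: float
    c: float = 1.0
    d: float = 1.0
    sigma: float = 0.1
    direction: str = "decrease"  # increase | decrease

    def __post_init__(self) -> None:
        if self.model_id not in ("exp3", "exp5", "hill"):
            raise ConfigurationError(f"unknown archetype model {self.model_id!r}")
        if self.sigma < 0 or self.d <= 0 or self.a <= 0:
            raise ConfigurationError("archetype requires sigma >= 0, d > 0, a > 0")
        if self.direction not in ("increase", "decrease"):
            raise ConfigurationError("direction must be 'increase' or 'decrease'")


@dataclass(frozen=True)
class ExperimentDesign:
    """Concentration series, replication and timepoints for one experiment."""

    concentrations_ug_per_ml: tuple[float, ...]
    replicates: int = 3
    timepoints_h: tuple[float, ...] = (24.0, 48.0)
    seed: int = 0

    def __post_init__(self) -> None:
        conc = self.concentrations_ug_per_ml
        if len(conc) < 2 or conc[0] != 0:
            raise ConfigurationError("first concentration must be the 0 vehicle control")
        if any(b <= a for a, b in zip(conc, conc[1:])):
            raise ConfigurationError("concentrations must be strictly increasing")
        if self.replicates < 2:
            raise ConfigurationError("need >= 2 replicates")


@dataclass
class ConcResponseDataset:
    """Replicate-level apical responses, long format, with generator truth.

    ``table`` columns: compound, endpoint, timepoint_h, concentration_ug_per_ml,
    replicate, response. ``truth`` maps (compound, endpoint, timepoint) to the
    generating :class:`PotencyArchetype` (empty for user-loaded data).
    """

    table: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ConcResponseDataset":
        return cls(table=pd.read_csv(path, sep="\t"))


@dataclass
class ExpressionDataset:
    """Genes x samples log2-ratio matrix plus per-sample annotation.

    ``samples`` columns: sample, compound, concentration_ug_per_ml,
    timepoint_h, replicate. ``truth`` maps gene id -> PotencyArchetype for the
    responsive genes.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, matrix_path, samples_path) -> None:
        self.matrix.to_csv(matrix_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, matrix_path, samples_path) -> "ExpressionDataset":
        return cls(
            matrix=pd.read_csv(matrix_path, sep="\t", index_col=0),
            samples=pd.read_csv(samples_path, sep="\t"),
        )


# ---------------------------------------------------------------------------
# mean curves and the closed-form BMC oracle
# ---------------------------------------------------------------------------

def mean_response(arch: PotencyArchetype, x) -> np.ndarray:
    """Evaluate the archetype's mean curve at concentration(s) ``x``."""
    x = np.asarray(x, dtype=float)
    if arch.model_id == "exp3":
        return arch.a * np.exp(arch.b * x**arch.d)
    if arch.model_id == "exp5":
        return arch.a * (arch.c - (arch.c - 1.0) * np.exp(-arch.b * x**arch.d))
    # hill
    xd = x**arch.d
    return arch.a * (1.0 + (arch.c - 1.0) * xd / (arch.b**arch.d + xd))


def invert_mean(arch: PotencyArchetype, target_ratio: float) -> float:
    """Concentration at which m(x)/m(0) equals ``target_ratio`` (closed form).

    Raises :class:`UnreachableBmrError` when the asymptote precludes it.
    """
    t = float(target_ratio)
    if t == 1.0:
        return 0.0
    if arch.model_id == "exp3":
        u = np.log(t) / arch.b
        if u <= 0:
            raise UnreachableBmrError(f"ratio {t} not reachable by exp3 with b={arch.b}")
        return float(u ** (1.0 / arch.d))
    if arch.model_id == "exp5":
        denom = arch.c - 1.0
        if denom == 0:
            raise UnreachableBmrError("exp5 with c=1 is flat")
        s = (arch.c - t) / denom
        if not 0.0 < s < 1.0:
            raise UnreachableBmrError(
                f"ratio {t} beyond exp5 asymptote c={arch.c} (unreachable BMR)"
            )
        return float((-np.log(s) / arch.b) ** (1.0 / arch.d))
    # hill
    denom = arch.c - 1.0
    if denom == 0:
        raise UnreachableBmrError("hill with c=1 is flat")
    f = (t - 1.0) / denom
    if not 0.0 < f < 1.0:
        raise UnreachableBmrError(
            f"ratio {t} beyond hill asymptote c={arch.c} (unreachable BMR)"
        )
    return float(arch.b * (f / (1.0 - f)) ** (1.0 / arch.d))


def true_bmc(arch: PotencyArchetype, bmr) -> float:
    """Closed-form benchmark concentration of an archetype at a BMR.

    For a relative BMR of value v the BMC solves ``m(x)/m(0) = 1 ∓ v`` in the
    archetype's adverse direction. For an SD-based BMR (gene expression, where
    the archetype mean is a log2 shift from control) it solves
    ``|m(x) − m(0)| = k·sigma``.
    """
    if bmr.kind == "relative":
        t = 1.0 - bmr.value if arch.direction == "decrease" else 1.0 + bmr.value
        return invert_mean(arch, t)
    # SD-based: additive shift of k*sigma from the control mean
    m0 = float(mean_response(arch, 0.0))
    delta = bmr.value * arch.sigma
    target = m0 - delta if arch.direction == "decrease" else m0 + delta
    return invert_mean(arch, target / m0)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_apical_dataset(
    compounds: Sequence[CompoundSpec],
    archetypes: Mapping[str, Mapping[str, PotencyArchetype]],
    design: ExperimentDesign,
    endpoints: Sequence[str] = APICAL_ENDPOINTS,
) -> ConcResponseDataset:
    """Draw replicate apical responses for every compound x endpoint.

    ``archetypes[compound.id][endpoint]`` must exist for every requested
    endpoint; endpoint names carrying an ``_<hours>h`` suffix are assigned to
    that timepoint, and the archetype applies at that single timepoint.
    """
    rows = []
    truth: dict = {}
    for comp in compounds:
        comp_arch = archetypes.get(comp.id)
        if comp_arch is None:
            raise ConfigurationError(f"no archetypes configured for compound {comp.id!r}")
        for ep in endpoints:
            arch = comp_arch.get(ep)
            if arch is None:
                raise ConfigurationError(
                    f"missing archetype for compound {comp.id!r}, endpoint {ep!r}"
                )
            tp = _endpoint_timepoint(ep)
            rng = np.random.default_rng(child_seed(design.seed, comp.id, ep))
            mu = mean_response(arch, np.asarray(design.concentrations_ug_per_ml))
            for ci, conc in enumerate(design.concentrations_ug_per_ml):
                noise = rng.normal(0.0, arch.sigma, size=design.replicates) if arch.sigma > 0 else np.zeros(design.replicates)
                resp = mu[ci] * np.exp(noise)
                for ri in range(design.replicates):
                    rows.append((comp.id, ep, tp, conc, ri + 1, resp[ri]))
            truth[(comp.id, ep, tp)] = arch
    table = pd.DataFrame(
        rows,
        columns=[
            "compound",
            "endpoint",
            "timepoint_h",
            "concentration_ug_per_ml",
            "replicate",
            "response",
        ],
    )
    return ConcResponseDataset(table=table, truth=truth)


def _endpoint_timepoint(endpoint: str) -> float:
    tail = endpoint.rsplit("_", 1)[-1]
    if tail.endswith("h"):
        try:
            return float(tail[:-1])
        except ValueError:
            pass
    return float("nan")


def generate_expression_dataset(
    compound: CompoundSpec,
    design: ExperimentDesign,
    n_genes: int,
    responsive: Mapping[str, PotencyArchetype],
    timepoint_h: float = 24.0,
    null_sigma: float = 0.2,
) -> ExpressionDataset:
    """Log2-ratio expression matrix: sparse responsive genes on a null background.

    Non-responsive genes are N(0, null_sigma) at every concentration.
    Responsive genes shift by ``mean(x) − mean(0)`` of their archetype (log2
    scale) with additive N(0, arch.sigma) noise.
    """
    if n_genes < len(responsive):
        raise ConfigurationError(
            f"n_genes={n_genes} < {len(responsive)} responsive genes requested"
        )
    gene_ids = [f"gene{str(i).zfill(len(str(n_genes)))}" for i in range(1, n_genes + 1)]
    known = set(gene_ids)
    for g in responsive:
        if g not in known:
            raise ConfigurationError(f"responsive gene {g!r} not among generated gene ids")

    conc = list(design.concentrations_ug_per_ml)
    sample_rows = []
    cols = []
    for ci, c in enumerate(conc):
        for ri in range(design.replicates):
            name = f"{compound.id}_c{ci}_r{ri + 1}_{timepoint_h:g}h"
            cols.append(name)
            sample_rows.append((name, compound.id, c, timepoint_h, ri + 1))
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample", "compound", "concentration_ug_per_ml", "timepoint_h", "replicate"],
    )

    rng = np.random.default_rng(child_seed(design.seed, compound.id, "expr", timepoint_h))
    data = rng.normal(0.0, null_sigma, size=(n_genes, len(cols)))
    conc_per_col = np.repeat(conc, design.replicates)
    for g, arch in responsive.items():
        gi = gene_ids.index(g)
        shift = mean_response(arch, conc_per_col) - mean_response(arch, 0.0)
        noise = rng.normal(0.0, arch.sigma, size=len(cols)) if arch.sigma > 0 else 0.0
        data[gi] = shift + noise
    matrix = pd.DataFrame(data, index=gene_ids, columns=cols)
    return ExpressionDataset(matrix=matrix, samples=samples, truth=dict(responsive))


# ---------------------------------------------------------------------------
# the default emulated study
# ---------------------------------------------------------------------------

#: Default exposure design: 0 + five doses to 100 µg/mL, triplicate, 24/48 h.
DEFAULT_DESIGN = ExperimentDesign(
    concentrations_ug_per_ml=(0.0, 6.25, 12.5, 25.0, 50.0, 100.0),
    replicates=3,
    timepoints_h=(24.0, 48.0),
    seed=0,
)

def load_compound_table() -> pd.DataFrame:
    """Physicochemical property table for the 18 study compounds."""
    with resources.files("nanopotency.data").joinpath("compounds.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def default_study_compounds() -> list[CompoundSpec]:
    """The 18 compounds (4 dissolved salts, 7 NPs, 7 MPs) as CompoundSpecs."""
    df = load_compound_table()
    out = []
    for _, r in df.iterrows():
        out.append(
            CompoundSpec(
                id=r["compound"],
                chemical_formula=r["chemical_formula"],
                metal=r["metal"],
                metal_atoms_per_formula=int(r["metal_atoms_per_formula"]),
                form_code=int(r["form_code"]),
                pps_nm=None if pd.isna(r["pps_nm"]) else float(r["pps_nm"]),
                ssa_m2_per_g=None if pd.isna(r["ssa_m2_per_g"]) else float(r["ssa_m2_per_g"]),
                solubility_pct=None if pd.isna(r["solubility_pct"]) else float(r["solubility_pct"]),
            )
        )
    return out


# Archetype classes encode planted group structure: soluble metals kill cells
# and perturb stress signalling at low µM; genotoxic particles drive comet/MN
# with milder cytotoxicity; inert particles barely respond over the range.
_ARCHETYPE_CLASSES: dict[str, dict[str, PotencyArchetype]] = {
    "soluble_cytotoxic": {
        "viability_24h": PotencyArchetype("exp3", a=100.0, b=-0.010, d=1.0, sigma=0.10, direction="decrease"),
        "viability_48h": PotencyArchetype("exp3", a=100.0, b=-0.015, d=1.0, sigma=0.10, direction="decrease"),
        "comet_2h": PotencyArchetype("exp5", a=4.0, b=0.008, c=4.0, d=1.0, sigma=0.10, direction="increase"),
        "comet_4h": PotencyArchetype("exp5", a=4.0, b=0.012, c=4.5, d=1.0, sigma=0.10, direction="increase"),
        "mn_40h": PotencyArchetype("hill", a=1.0, b=60.0, c=6.0, d=2.0, sigma=0.10, direction="increase"),
    },
    "genotoxic_particle": {
        "viability_24h": PotencyArchetype("exp3", a=100.0, b=-0.0015, d=1.0, sigma=0.10, direction="decrease"),
        "viability_48h": PotencyArchetype("exp3", a=100.0, b=-0.0025, d=1.0, sigma=0.10, direction="decrease"),
        "comet_2h": PotencyArchetype("exp5", a=4.0, b=0.010, c=5.0, d=1.0, sigma=0.10, direction="increase"),
        "comet_4h": PotencyArchetype("exp5", a=4.0, b=0.014, c=6.0, d=1.0, sigma=0.10, direction="increase"),
        "mn_40h": PotencyArchetype("hill", a=1.0, b=120.0, c=5.0, d=2.0, sigma=0.10, direction="increase"),
    },
    "insoluble_inert": {
        "viability_24h": PotencyArchetype("exp3", a=100.0, b=-2e-05, d=1.0, sigma=0.10, direction="decrease"),
        "viability_48h": PotencyArchetype("exp3", a=100.0, b=-4e-05, d=1.0, sigma=0.10, direction="decrease"),
        "comet_2h": PotencyArchetype("exp5", a=4.0, b=5e-05, c=1.3, d=1.0, sigma=0.10, direction="increase"),
        "comet_4h": PotencyArchetype("exp5", a=4.0, b=6e-05, c=1.3, d=1.0, sigma=0.10, direction="increase"),
        "mn_40h": PotencyArchetype("hill", a=1.0, b=5000.0, c=1.4, d=1.0, sigma=0.10, direction="increase"),
    },
}

_DEFAULT_GROUPS = {
    "ZnCl2": "soluble_cytotoxic",
    "ZnO NP": "soluble_cytotoxic",
    "ZnO MP": "soluble_cytotoxic",
    "MnSO4": "soluble_cytotoxic",
    "NiCl2": "soluble_cytotoxic",
    "CuO NP": "genotoxic_particle",
    "NiO NP": "genotoxic_particle",
    "NiO MP": "genotoxic_particle",
    "MnO2 NP": "genotoxic_particle",
    "MnO2 MP": "insoluble_inert",
    "CuO MP": "insoluble_inert",
    "Al2O3 NP": "insoluble_inert",
    "Al2O3 MP": "insoluble_inert",
    "AlCl3": "insoluble_inert",
    "Fe2O3 NP": "insoluble_inert",
    "Fe2O3 MP": "insoluble_inert",
    "TiO2 NP": "insoluble_inert",
    "TiO2 MP": "insoluble_inert",
}


def default_group_assignment() -> dict[str, str]:
    """Planted archetype class per study compound (the generator's truth)."""
    return dict(_DEFAULT_GROUPS)


def default_archetype_library(
    compounds: Iterable[CompoundSpec] | None = None,
    groups: Mapping[str, str] | None = None,
    potency_jitter: float = 0.15,
    seed: int = 0,
) -> dict[str, dict[str, PotencyArchetype]]:
    """Per-compound archetypes drawn from shared class templates.

    Compounds of one class share curve shapes; their rate parameter ``b`` is
    jittered multiplicatively (lognormal, ``potency_jitter`` log-SD) so that
    within-class potencies differ but remain far from other classes.
    """
    compounds = list(compounds) if compounds is not None else default_study_compounds()
    groups = dict(groups) if groups is not None else default_group_assignment()
    out: dict[str, dict[str, PotencyArchetype]] = {}
    for comp in compounds:
        cls = groups.get(comp.id)
        if cls is None:
            raise ConfigurationError(f"no archetype class for compound {comp.id!r}")
        rng = np.random.default_rng(child_seed(seed, "arch", comp.id))
        eps = float(np.exp(rng.normal(0.0, potency_jitter))) if potency_jitter > 0 else 1.0
        # hill's b is an ED50 (divide to raise potency); exp rates multiply
        out[comp.id] = {
            ep: replace(arch, b=arch.b / eps if arch.model_id == "hill" else arch.b * eps)
            for ep, arch in _ARCHETYPE_CLASSES[cls].items()
        }
    return out
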