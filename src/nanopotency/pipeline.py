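"""End-to-end orchestration of the potency-grouping analysis.

Stages run in dependency order over plain delimited-text artifacts, so any
stage can be rerun from files alone and externally supplied matrices (e.g. a
user-exported published BMC matrix) can be injected mid-pipeline:

1. simulate apical + expression data from archetypes (or load user files);
2. fit apical BMCs at the relative BMRs (5/10/25/50 %), µM-metal normalised;
3. trend-test/filter/fit transcriptomic gene BMCs at the SD BMRs and compute
   stress-pathway tPODs per timepoint;
4. assemble per-BMR 7-endpoint matrices, impute, winsorize, log10;
5. ensemble clustering per BMR (12 attempts each), pooled cross-BMR
   co-occurrence, potency groups;
6. PCA per BMR and Spearman / Kendall tau-b association analyses;
7. rule-based hazard calls and the group x hazard table.

Every artifact is stamped into a manifest with the config hash and master
seed; rerunning an identical config reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, hazard, matrices, ordination, transcriptomics
from .datasets import (
    DEFAULT_DESIGN,
    CompoundSpec,
    ConcResponseDataset,
    ExperimentDesign,
    ExpressionDataset,
    PotencyArchetype,
    child_seed,
    default_archetype_library,
    default_group_assignment,
    default_study_compounds,
    generate_apical_dataset,
    generate_expression_dataset,
    load_compound_table,
)
from .doseresponse import (
    DEFAULT_RELATIVE_BMRS,
    DEFAULT_SD_BMRS,
    BmrSpec,
    fit_bmc_records,
    normalize_to_metal_uM,
    records_to_frame,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_study", "load_config"]

#: Matrix labels pairing each relative BMR with its SD-BMR transcriptomic twin.
BMR_LEVELS = (
    ("BMR5", BmrSpec("relative", 0.05), BmrSpec("sd", 1.021)),
    ("BMR10", BmrSpec("relative", 0.10), BmrSpec("sd", 1.349)),
    ("BMR25", BmrSpec("relative", 0.25), BmrSpec("sd", 1.932)),
    ("BMR50", BmrSpec("relative", 0.50), BmrSpec("sd", 2.601)),
)

# expression archetypes per planted class: (n_responsive, archetype template)
_EXPRESSION_CLASSES: dict[str, tuple[int, PotencyArchetype]] = {
    "soluble_cytotoxic": (30, PotencyArchetype("hill", a=1.0, b=30.0, c=3.5, d=1.5,
                                               sigma=0.25, direction="increase")),
    "genotoxic_particle": (6, PotencyArchetype("hill", a=1.0, b=45.0, c=3.0, d=1.5,
                                               sigma=0.25, direction="increase")),
    "insoluble_inert": (2, PotencyArchetype("hill", a=1.0, b=80.0, c=1.9, d=1.5,
                                            sigma=0.25, direction="increase")),
}


@dataclass
class RunConfig:
    """Everything a reproducible run needs; serialisable to YAML."""

    seed: int = 0
    out_dir: str = "run_out"
    compounds: tuple = ()          # empty = all 18 study compounds
    concentrations_ug_per_ml: tuple = DEFAULT_DESIGN.concentrations_ug_per_ml
    replicates: int = 3
    timepoints_h: tuple = (24.0, 48.0)
    n_genes: int = 200
    pathway_size: int = 50
    n_permutations: int = 1000
    nboot: int = 1000
    au_threshold: float = 0.95
    group_threshold: float = 0.5
    minkowski_p: float = 3.0
    winsor_quantiles: tuple = (0.05, 0.95)
    potency_jitter: float = 0.15

    def digest(self) -> str:
        # identity of the computation: everything except where outputs land
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(**raw)
    for name in ("compounds", "concentrations_ug_per_ml", "timepoints_h", "winsor_quantiles"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    return cfg


# ---------------------------------------------------------------------------
# stage 1: simulation
# ---------------------------------------------------------------------------

def simulate_study(config: RunConfig):
    """Generate apical + expression data for the configured compound set.

    Returns (compounds dict, apical ConcResponseDataset, expression datasets
    keyed by (compound, timepoint), stress pathway gene set, responsive-gene
    truth counts).
    """
    all_comps = {c.id: c for c in default_study_compounds()}
    ids = list(config.compounds) if config.compounds else list(all_comps)
    unknown = [i for i in ids if i not in all_comps]
    if unknown:
        raise ValueError(f"unknown compounds: {unknown}")
    comps = {i: all_comps[i] for i in ids}
    groups = default_group_assignment()
    design = ExperimentDesign(
        concentrations_ug_per_ml=tuple(config.concentrations_ug_per_ml),
        replicates=config.replicates,
        timepoints_h=tuple(config.timepoints_h),
        seed=child_seed(config.seed, "sim"),
    )
    archetypes = default_archetype_library(comps.values(), groups,
                                          potency_jitter=config.potency_jitter,
                                          seed=child_seed(config.seed, "arch"))
    apical = generate_apical_dataset(list(comps.values()), archetypes, design)

    n_digits = len(str(config.n_genes))
    gene_ids = [f"gene{str(i).zfill(n_digits)}" for i in range(1, config.n_genes + 1)]
    pathway = set(gene_ids[: config.pathway_size])
    expression: dict[tuple, ExpressionDataset] = {}
    truth_counts: dict[str, int] = {}
    for cid, comp in comps.items():
        n_resp, template = _EXPRESSION_CLASSES[groups[cid]]
        rng = np.random.default_rng(child_seed(config.seed, "exprarch", cid))
        responsive = {}
        for gi in range(n_resp):
            jitter = float(np.exp(rng.normal(0.0, config.potency_jitter)))
            sign_down = gi % 4 == 3  # a quarter of responsive genes go down
            c = 1.0 / template.c if sign_down else template.c
            responsive[gene_ids[gi]] = PotencyArchetype(
                template.model_id, a=template.a, b=template.b / jitter, c=c,
                d=template.d, sigma=template.sigma,
                direction="decrease" if sign_down else "increase",
            )
        truth_counts[cid] = n_resp
        for tp in design.timepoints_h:
            expression[(cid, tp)] = generate_expression_dataset(
                comp, design, config.n_genes, responsive, timepoint_h=tp,
            )
    return comps, apical, expression, pathway, truth_counts


# ---------------------------------------------------------------------------
# stages 2-3: BMC estimation
# ---------------------------------------------------------------------------

def _tpod_records(comps: Mapping[str, CompoundSpec], expression, pathway,
                  config: RunConfig) -> pd.DataFrame:
    rows = []
    stress_counts: dict[tuple, int] = {}
    for (cid, tp), ds in expression.items():
        res = transcriptomics.analyze_expression(
            ds, bmrs=DEFAULT_SD_BMRS, n_permutations=config.n_permutations,
            seed=child_seed(config.seed, "tx", cid, tp),
        )
        endpoint = f"tpod_{tp:g}h"
        for label, gene_bmcs in res.items():
            tpod = transcriptomics.pathway_tpod(gene_bmcs, pathway, rule="min3",
                                                pathway="stress_pathway")
            if label == DEFAULT_SD_BMRS[0].label():
                stress_counts[(cid, tp)] = tpod.n_responsive
            if tpod.tpod is not None:
                uM = normalize_to_metal_uM(tpod.tpod, comps[cid])
                rows.append((cid, endpoint, tp, label, tpod.tpod, uM, "avg", np.nan, "ok"))
            else:
                rows.append((cid, endpoint, tp, label, np.nan, np.nan, "avg", np.nan, "no_response"))
    df = pd.DataFrame(rows, columns=["compound", "endpoint", "timepoint_h", "bmr",
                                     "bmc", "bmc_uM_metal", "model", "aic", "status"])
    return df, stress_counts


# ---------------------------------------------------------------------------
# stage 7: hazard inputs from the raw data
# ---------------------------------------------------------------------------

def _hazard_calls(comps, apical: ConcResponseDataset, stress_counts,
                  thresholds: hazard.HazardThresholds) -> list[hazard.HazardCall]:
    df = apical.table
    calls = []
    for cid in comps:
        flags: list[str] = []

        def mean_by_conc(endpoint):
            sub = df[(df["compound"] == cid) & (df["endpoint"] == endpoint)]
            if sub.empty:
                return None
            return sub.groupby("concentration_ug_per_ml")["response"].mean()

        viab = mean_by_conc("viability_48h")
        if viab is not None and 0.0 in viab.index:
            fractions = viab / viab.loc[0.0]
            top_frac = float(fractions.iloc[-1])
        else:
            fractions, top_frac = None, None
        death, f = hazard.call_cell_death(top_frac)
        if f:
            flags.append(f"cell_death:{f}")

        mn = mean_by_conc("mn_40h")
        if mn is not None and 0.0 in mn.index and fractions is not None:
            folds = (mn / mn.loc[0.0]).drop(index=0.0)
            matched = [float(fractions.get(c, np.nan)) for c in folds.index]
            matched = [None if np.isnan(v) else v for v in matched]
            clast, f = hazard.call_clastogenicity(list(folds), matched)
        else:
            clast, f = False, "insufficient_data"
        if f:
            flags.append(f"clastogenicity:{f}")

        comet = mean_by_conc("comet_4h")
        max_tail = float(comet.max()) if comet is not None else None
        breaks, f = hazard.call_dna_strand_breaks(max_tail)
        if f:
            flags.append(f"dna_strand_breaks:{f}")

        n_genes = stress_counts.get((cid, 48.0), stress_counts.get((cid, 24.0), 0))
        stress, _ = hazard.call_cell_stress(n_genes)

        calls.append(hazard.HazardCall(cid, death, stress, breaks, clast, flags=flags))
    return calls


# ---------------------------------------------------------------------------
# the pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write artifacts under ``config.out_dir``.

    Returns the manifest dictionary (also written as ``manifest.json``).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(json.dumps(asdict(config), default=list)),
                      "config_digest": config.digest(),
                      "seed": config.seed,
                      "artifacts": [], "warnings": []}

    def save(df: pd.DataFrame, name: str, index=False):
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        manifest["artifacts"].append(name)

    # 1. simulate
    comps, apical, expression, pathway, _truth = simulate_study(config)
    apical.write(out / "apical_responses.tsv")
    manifest["artifacts"].append("apical_responses.tsv")
    with open(out / "stress_pathway.gmt", "w") as fh:
        fh.write("stress_pathway\tsynthetic\t" + "\t".join(sorted(pathway)) + "\n")
    manifest["artifacts"].append("stress_pathway.gmt")

    # 2. apical BMCs
    apical_records = fit_bmc_records(apical, DEFAULT_RELATIVE_BMRS, comps,
                                     seed=child_seed(config.seed, "apical"))
    apical_df = records_to_frame(apical_records)
    save(apical_df, "bmc_apical.tsv")

    # 3. transcriptomic tPODs
    tpod_df, stress_counts = _tpod_records(comps, expression, pathway, config)
    save(tpod_df, "bmc_tpod.tsv")

    # 4. matrices per BMR level
    top_conc = max(config.concentrations_ug_per_ml)
    ceiling = {cid: normalize_to_metal_uM(top_conc, comp) for cid, comp in comps.items()}
    per_bmr: dict[str, matrices.BmcMatrix] = {}
    for label, rel_bmr, sd_bmr in BMR_LEVELS:
        rec = pd.concat([
            apical_df[apical_df["bmr"] == rel_bmr.label()],
            tpod_df[tpod_df["bmr"] == sd_bmr.label()],
        ])
        rec = rec.assign(bmr=label)
        raw = matrices.assemble_matrix(rec, label, compounds=list(comps))
        filled = matrices.impute_and_winsorize(raw, ceiling, config.winsor_quantiles)
        manifest["warnings"].extend(filled.warnings)
        logm = matrices.log10_transform(filled)
        per_bmr[label] = logm
        logm.write(out / f"bmc_matrix_{label}.tsv")
        manifest["artifacts"].append(f"bmc_matrix_{label}.tsv")
    combined = matrices.combine_across_bmrs(list(per_bmr.values()))
    combined.to_csv(out / "bmc_matrix_combined.tsv", sep="\t")
    manifest["artifacts"].append("bmc_matrix_combined.tsv")

    # 5. ensemble clustering per BMR + pooled groups
    all_attempts = []
    cluster_report = []
    for label, m in per_bmr.items():
        attempts = clustering.run_ensemble(
            m.values, nboot=config.nboot, au_threshold=config.au_threshold,
            seed=child_seed(config.seed, "boot", label),
            configs=clustering.default_configs(
                nboot=config.nboot, seed=child_seed(config.seed, "boot", label),
                au_threshold=config.au_threshold, minkowski_p=config.minkowski_p),
        )
        all_attempts.extend(attempts)
        best = clustering.select_best_attempt(attempts)
        with open(out / f"dendrogram_{label}_{best.config.label}.nwk", "w") as fh:
            fh.write(clustering.attempt_to_newick(best) + "\n")
        manifest["artifacts"].append(f"dendrogram_{label}_{best.config.label}.nwk")
        for att in attempts:
            cluster_report.append({
                "bmr": label, "attempt": att.config.label,
                "n_supported": att.n_supported, "n_singletons": len(att.singletons),
                "best": att is best,
            })
    save(pd.DataFrame(cluster_report), "cluster_attempts.tsv")
    summary = clustering.co_cluster_summary(all_attempts)
    summary.co_occurrence.to_csv(out / "co_occurrence.tsv", sep="\t")
    summary.jaccard.to_csv(out / "jaccard.tsv", sep="\t")
    manifest["artifacts"] += ["co_occurrence.tsv", "jaccard.tsv"]
    groups = clustering.derive_groups(summary, threshold=config.group_threshold)
    save(pd.DataFrame([{"group": i + 1, "compound": c} for i, g in enumerate(groups) for c in g]),
         "groups.tsv")

    # 6. ordination + associations
    pca_rows = []
    for label, m in per_bmr.items():
        res = ordination.pca(m.values)
        pca_rows.append({
            "bmr": label,
            "pc1_pct": res.pct_variance.iloc[0],
            "pc2_pct": res.pct_variance.iloc[1],
            "pc1_plus_pc2_pct": res.pct_variance.iloc[:2].sum(),
            "pc1_significant": ";".join(res.significant["PC1"]),
            "pc2_significant": ";".join(res.significant["PC2"]),
        })
        res.loadings.to_csv(out / f"pca_loadings_{label}.tsv", sep="\t")
        res.scores.to_csv(out / f"pca_scores_{label}.tsv", sep="\t")
        manifest["artifacts"] += [f"pca_loadings_{label}.tsv", f"pca_scores_{label}.tsv"]
    save(pd.DataFrame(pca_rows), "pca_summary.tsv")
    spearman = ordination.spearman_matrix(combined)
    save(ordination.associations_to_frame(spearman), "spearman_endpoints.tsv")
    props = load_compound_table()
    props = props[props["compound"].isin(list(comps))]
    kendall = ordination.property_associations(combined, props)
    save(ordination.associations_to_frame(kendall), "kendall_properties.tsv")

    # 7. hazard
    calls = _hazard_calls(comps, apical, stress_counts, hazard.HazardThresholds())
    table = hazard.hazard_table(calls, groups)
    save(table, "hazard_calls.tsv")
    with open(out / "hazard_report.txt", "w") as fh:
        fh.write(hazard.render_hazard_report(table) + "\n")
    manifest["artifacts"].append("hazard_report.txt")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
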