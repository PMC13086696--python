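"""Rule-based hazard identification from raw endpoint summaries.

Four boolean calls per compound, using the maximal response at the latest
assessment timepoint for each endpoint:

* cell death — viability at the top concentration ≤ 66 % of control
  (inclusive, i.e. a 1.5-fold decrease);
* clastogenicity/aneugenicity — micronucleus induction ≥ 2-fold at any
  concentration retaining ≥ 40 % viability;
* DNA strand breaks — > 10 % DNA in tail (strict) at the latest comet
  timepoint;
* cell stress signalling — at least 3 concentration-responsive,
  differentially expressed genes in the stress pathway.

Missing inputs yield an explicit negative call with an insufficient-data
flag rather than a missing state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "HazardThresholds",
    "HazardCall",
    "call_cell_death",
    "call_clastogenicity",
    "call_dna_strand_breaks",
    "call_cell_stress",
    "hazard_table",
    "render_hazard_report",
]

HAZARD_COLUMNS = ("cell_death", "cell_stress", "dna_strand_breaks",
                  "clastogenicity_aneugenicity")


@dataclass(frozen=True)
class HazardThresholds:
    """Printed-cutoff boundary semantics: ≤ 0.66, ≥ 2-fold at ≥ 0.40, > 10 %, ≥ 3."""

    viability_max_fraction: float = 0.66
    mn_fold_min: float = 2.0
    mn_viability_floor: float = 0.40
    tail_dna_pct_min: float = 10.0
    min_responsive_genes: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.viability_max_fraction <= 1 and 0 < self.mn_viability_floor <= 1):
            raise ValueError("viability fractions must lie in (0, 1]")
        if self.mn_fold_min <= 0 or self.tail_dna_pct_min <= 0 or self.min_responsive_genes <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class HazardCall:
    """The four boolean calls for one compound."""

    compound: str
    cell_death: bool
    cell_stress: bool
    dna_strand_breaks: bool
    clastogenicity_aneugenicity: bool
    group: str = "ungrouped"
    flags: list = field(default_factory=list)


def call_cell_death(viability_fraction_top_conc: float | None,
                    thresholds: HazardThresholds = HazardThresholds()) -> tuple[bool, str]:
    """True iff top-concentration viability (latest timepoint) ≤ the cutoff."""
    if viability_fraction_top_conc is None:
        return False, "insufficient_data"
    return viability_fraction_top_conc <= thresholds.viability_max_fraction, ""


def call_clastogenicity(mn_fold_changes: Sequence[float],
                        viability_fractions: Sequence[float | None],
                        thresholds: HazardThresholds = HazardThresholds()) -> tuple[bool, str]:
    """True iff any concentration shows ≥ 2-fold MN at ≥ 40 % viability.

    Concentrations with no matched viability measurement are skipped.
    """
    if len(mn_fold_changes) != len(viability_fractions):
        raise ValueError("fold-change and viability vectors must align per concentration")
    flag = ""
    for fold, viab in zip(mn_fold_changes, viability_fractions):
        if viab is None:
            flag = "unmatched_viability_skipped"
            continue
        if fold >= thresholds.mn_fold_min and viab >= thresholds.mn_viability_floor:
            return True, flag
    return False, flag


def call_dna_strand_breaks(max_tail_dna_pct: float | None,
                           thresholds: HazardThresholds = HazardThresholds()) -> tuple[bool, str]:
    """True iff the maximal %DNA-in-tail strictly exceeds 10 %."""
    if max_tail_dna_pct is None:
        return False, "insufficient_data"
    return max_tail_dna_pct > thresholds.tail_dna_pct_min, ""


def call_cell_stress(n_responsive_pathway_genes: int,
                     thresholds: HazardThresholds = HazardThresholds()) -> tuple[bool, str]:
    """True iff at least 3 concentration-responsive pathway genes."""
    return n_responsive_pathway_genes >= thresholds.min_responsive_genes, ""


def hazard_table(calls: Sequence[HazardCall],
                 groups: Sequence[Sequence[str]] | None = None) -> pd.DataFrame:
    """Group-annotated call table, sorted by group then compound.

    ``groups`` are the potency groups from the cluster ensemble (ordered);
    compounds in no group are listed as 'ungrouped'.
    """
    membership: Mapping[str, str] = {}
    if groups:
        for gi, grp in enumerate(groups, start=1):
            for comp in grp:
                membership[comp] = str(gi)
    rows = []
    for call in calls:
        call.group = membership.get(call.compound, "ungrouped")
        rows.append(
            {
                "group": call.group,
                "compound": call.compound,
                "cell_death": call.cell_death,
                "cell_stress": call.cell_stress,
                "dna_strand_breaks": call.dna_strand_breaks,
                "clastogenicity_aneugenicity": call.clastogenicity_aneugenicity,
                "flags": ";".join(call.flags),
            }
        )
    df = pd.DataFrame(rows)
    key = df["group"].map(lambda g: (1, "") if g == "ungrouped" else (0, g.zfill(4)))
    df = df.iloc[sorted(range(len(df)), key=lambda i: (key[i], df["compound"][i]))]
    return df.reset_index(drop=True)


def render_hazard_report(table: pd.DataFrame) -> str:
    """Check-mark style text rendering of the hazard call table."""
    lines = [f"{'group':>9}  {'compound':<12} {'death':>5} {'stress':>6} {'DNAbrk':>6} {'clast':>5}"]
    for _, r in table.iterrows():
        marks = ["x" if r[c] else "." for c in HAZARD_COLUMNS]
        lines.append(f"{r['group']:>9}  {r['compound']:<12} "
                     f"{marks[0]:>5} {marks[1]:>6} {marks[2]:>6} {marks[3]:>5}")
    return "\n".join(lines)
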