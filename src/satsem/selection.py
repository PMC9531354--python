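"""Merging CTT and IRT screening flags into a deletion decision.

An item is deleted when it raises three or more of the eleven applicable
criteria (eight CTT + three IRT); criteria that are not computable for an
item are excluded from its count but the >= 3 threshold stays absolute.
Explicit overrides (e.g. dropping a formal-complaint item with near-zero
information on substantive grounds) are recorded with their reason.
Selection is single-pass: flags are not recomputed after deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .grm import GradedResponseModel, grm_flags, item_information
from .model_spec import ModelDefinition
from .screening import ctt_flag_table, keyed_dataset
from .synthetic import SurveyDataset

__all__ = ["SelectionReport", "aggregate_flags", "apply_overrides",
           "run_screening", "CTT_FLAG_COLUMNS", "IRT_FLAG_COLUMNS"]

CTT_FLAG_COLUMNS = [
    "floor_flag", "ceiling_flag", "ttest_flag", "item_dimension_flag",
    "item_total_flag", "alpha_flag", "stepwise_flag", "efa_flag",
]
IRT_FLAG_COLUMNS = ["a_flag", "b_flag", "info_flag"]


@dataclass
class SelectionReport:
    """Per-item flag counts and keep/delete decisions."""

    table: pd.DataFrame              # items x criteria flags + count + decision
    final_items: list
    notes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def mark_table(self) -> pd.DataFrame:
        """Items-by-criteria table with 'x' marks and '-' for
        not-applicable criteria, mirroring the screening-report layout."""
        cols = CTT_FLAG_COLUMNS + IRT_FLAG_COLUMNS
        out = pd.DataFrame(index=self.table.index, columns=cols, dtype=object)
        for c in cols:
            for it in self.table.index:
                v = self.table.loc[it, c]
                out.loc[it, c] = "-" if v is None or pd.isna(v) \
                    else ("x" if v else "")
        out["flag_count"] = self.table["flag_count"]
        out["decision"] = self.table["decision"]
        return out


def aggregate_flags(ctt: pd.DataFrame, irt: pd.DataFrame,
                    threshold: int = 3) -> SelectionReport:
    """Merge CTT and IRT flag tables and apply the deletion rule.

    Both inputs are indexed by item; items present in only one source
    raise ValueError.  The count includes only applicable (non-None)
    criteria; decision is "delete" at count >= `threshold`, else "keep".
    """
    if set(ctt.index) != set(irt.index):
        only = set(ctt.index) ^ set(irt.index)
        raise ValueError(f"items present in one source only: {sorted(only)}")
    irt = irt.loc[ctt.index]
    merged = ctt.join(irt[[c for c in irt.columns if c not in ctt.columns]])

    counts, flagged = [], []
    for it in merged.index:
        names = []
        for c in CTT_FLAG_COLUMNS + IRT_FLAG_COLUMNS:
            v = merged.loc[it, c] if c in merged.columns else None
            if v is not None and not pd.isna(v) and bool(v):
                names.append(c)
        counts.append(len(names))
        flagged.append(",".join(names))
    merged["flag_count"] = counts
    merged["flagged_criteria"] = flagged
    merged["decision"] = ["delete" if c >= threshold else "keep"
                          for c in counts]
    final = [it for it in merged.index if merged.loc[it, "decision"] == "keep"]
    return SelectionReport(table=merged, final_items=final)


def apply_overrides(report: SelectionReport, overrides) -> SelectionReport:
    """Remove explicitly overridden items (list of (item, reason) pairs),
    recording the reason; overriding an already-deleted item is a no-op
    with a note."""
    table = report.table.copy()
    notes = list(report.notes)
    final = list(report.final_items)
    for item, reason in overrides:
        if item not in table.index:
            raise ValueError(f"unknown item in override: {item!r}")
        if table.loc[item, "decision"] == "delete":
            notes.append(f"{item}: override redundant (already deleted)")
            continue
        table.loc[item, "decision"] = "override-delete"
        notes.append(f"{item}: deleted by override ({reason})")
        final.remove(item)
    return SelectionReport(table=table, final_items=final, notes=notes)


def _grm_blocks(m: ModelDefinition, level: str):
    """Item blocks for GRM calibration.  level="construct" groups items by
    top-level construct (a second-order construct's facets are calibrated
    together on its shared trait, which also identifies single-item
    facets); level="facet" calibrates each first-order block separately;
    level="global" calibrates all items against one satisfaction trait
    (reverse-keyed items flipped first)."""
    if level == "global":
        return [list(m.all_indicators)]
    in_hoc = {c for comps in m.hoc_components.values() for c in comps}
    blocks = []
    for lv in m.latents:
        if lv.order == "second":
            if level == "construct":
                blocks.append(list(m.indicators_of(lv.name)))
        elif lv.name in in_hoc:
            if level == "facet":
                blocks.append(list(lv.indicators))
        else:
            blocks.append(list(lv.indicators))
    return blocks


def run_screening(d: SurveyDataset, m: ModelDefinition,
                  overrides=(), k_items: int = None,
                  alpha_margin: float = 0.01,
                  ttest_na_latents=("PC",),
                  grm_level: str = "construct") -> SelectionReport:
    """Full screening pass: CTT criteria, GRM calibration per construct
    block, IRT criteria, flag aggregation, and overrides.

    `k_items` sets the draft-instrument size for the average-information
    threshold 16/K (default: the model's own item count).
    """
    if k_items is None:
        k_items = len(m.all_indicators)
    ctt = ctt_flag_table(d, m, alpha_margin=alpha_margin,
                         ttest_na_latents=ttest_na_latents)

    params, curves = {}, {}
    grm_data = keyed_dataset(d, m).responses if grm_level == "global" \
        else d.responses
    for block in _grm_blocks(m, grm_level):
        res = GradedResponseModel(grm_data[block]).fit()
        for it, p in res.params.items():
            params[it] = p
            curves[it] = item_information(p, res.model.grid)
    irt = grm_flags(params, curves, k_items=k_items)

    report = aggregate_flags(ctt, irt)
    if overrides:
        report = apply_overrides(report, overrides)
    return report
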