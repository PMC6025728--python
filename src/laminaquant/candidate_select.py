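"""The screen's transcript-selection filter.

A transcript qualifies as a candidate Brn3a target when, in the P3
sorted-RGC quantification, it is (1) expressed above 2 FPKM in Brn3a
wild-type RGCs (strict, "more than"), (2) at least two-fold higher in
Brn3a wild-type than knockout RGCs, and (3) free of Brn3b regulation
(direction-free Brn3b WT/KO fold strictly below two).  Fold ratios use a
floor pseudocount on the denominator only — ``num / max(den, eps)`` — so a
transcript absent in the knockout passes rather than dividing by zero,
while ratios between well-expressed transcripts are untouched (selections
are therefore identical for eps in {0, 0.1} whenever all abundances are
at least 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = (
    "fpkm_brn3a_wt_rgc",
    "fpkm_brn3a_ko_rgc",
    "fpkm_brn3b_wt_rgc",
    "fpkm_brn3b_ko_rgc",
)

ABUNDANCE_PREFIXES = ("fpkm_", "cpm_")


def _validate(table: pd.DataFrame, required) -> None:
    for col in required:
        if col not in table.columns:
            raise ValueError(f"missing column {col}")
    for col in table.columns:
        if col.startswith(ABUNDANCE_PREFIXES):
            vals = table[col].to_numpy(dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative abundance in column {col}")


def fold_ratio(num, den, epsilon: float = 0.1):
    """num / max(den, epsilon); with epsilon=0 a zero denominator gives inf."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    floored = np.maximum(den, epsilon)
    with np.errstate(divide="ignore"):
        return np.where(floored > 0, num / np.where(floored > 0, floored, 1.0), np.inf)


def select_candidates(
    table: pd.DataFrame,
    fpkm_min: float = 2.0,
    fold_min: float = 2.0,
    brn3b_fold_max: float = 2.0,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Apply the three selection criteria; returns a copy of the table with
    per-criterion audit columns and the combined ``selected`` flag."""
    _validate(table, REQUIRED_COLUMNS)
    out = table.copy()
    wt = out["fpkm_brn3a_wt_rgc"].to_numpy(dtype=float)
    ko = out["fpkm_brn3a_ko_rgc"].to_numpy(dtype=float)
    bwt = out["fpkm_brn3b_wt_rgc"].to_numpy(dtype=float)
    bko = out["fpkm_brn3b_ko_rgc"].to_numpy(dtype=float)

    brn3a_fold = fold_ratio(wt, ko, epsilon)
    brn3b_fold = np.maximum(fold_ratio(bwt, bko, epsilon), fold_ratio(bko, bwt, epsilon))

    out["pass_min_expression"] = wt > fpkm_min
    out["brn3a_fold"] = brn3a_fold
    out["pass_brn3a_fold"] = brn3a_fold >= fold_min
    out["brn3b_fold"] = brn3b_fold
    out["pass_brn3b_independence"] = brn3b_fold < brn3b_fold_max
    out["selected"] = (
        out["pass_min_expression"]
        & out["pass_brn3a_fold"]
        & out["pass_brn3b_independence"]
    )
    return out


GENE_CPM_COLUMNS = ("cpm_brn3a_wt_rgc", "cpm_brn3a_ko_rgc", "cpm_retina")


def gene_level_flags(
    table: pd.DataFrame, fold: float = 2.0, epsilon: float = 0.1
) -> pd.DataFrame:
    """Gene-level cross-reference flags from CPM columns: RGC enrichment
    (wild-type RGC at least two-fold over whole retina) and Brn3a dependency
    (wild-type at least two-fold over knockout), same pseudocount rule."""
    _validate(table, GENE_CPM_COLUMNS + ("gene",))
    per_gene = table.drop_duplicates("gene")
    rgc = per_gene["cpm_brn3a_wt_rgc"].to_numpy(dtype=float)
    ko = per_gene["cpm_brn3a_ko_rgc"].to_numpy(dtype=float)
    retina = per_gene["cpm_retina"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "gene": per_gene["gene"].to_numpy(),
            "rgc_enriched": fold_ratio(rgc, retina, epsilon) >= fold,
            "brn3a_dependent": fold_ratio(rgc, ko, epsilon) >= fold,
        }
    )
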