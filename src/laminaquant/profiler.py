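"""Aggregate per-age calls into gene-level developmental summaries.

One gene's evidence across the five postnatal ages (P0, P3, P7, P14, P22)
is condensed into a summary row: was the gene GCL-enriched at P3, was the
enrichment developmentally consistent (at least 4 of the 5 ages), was it
Brn3a-dependent at P3 or at any age, when does GCL expression switch on
(onset), culminate (peak, possibly a plateau spanning adjacent ages) and
disappear (offset), and is the GCL signal carried by sparse intensely
stained somata.  Panel-level counts and percentages summarize a whole
candidate panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .layerstats import CallRecord
from .synthgen import AGES

CONSISTENCY_MIN_AGES = 4  # "at least 4 out of 5 ages"


@dataclass(frozen=True)
class GeneSummaryRow:
    gene: str
    gcl_p3: bool
    gcl_consistent: bool
    brn3a_target_p3: bool
    brn3a_target_any: bool
    onset: str | None
    peak: str | None  # single age or a plateau range such as "P7-P14"
    offset: str | None
    sparse: bool


@dataclass(frozen=True)
class PanelCounts:
    n_genes: int
    n_gcl_p3: int
    n_brn3a_p3: int
    n_brn3a_any: int
    n_consistent_dependency: int | None
    pct_gcl_p3: int
    pct_brn3a_any: int


def _call_flag(record) -> bool:
    if isinstance(record, CallRecord):
        return record.call
    return bool(record)


def _check_ages(mapping: Mapping[str, object], what: str) -> None:
    for age in AGES:
        if age not in mapping:
            raise ValueError(f"missing age {age} in {what}")


def onset_peak_offset(
    gcl_series: Mapping[str, float],
    noise_mad: float,
    plateau_tol: float | None = None,
) -> tuple[str | None, str | None, str | None]:
    """Classify a per-age GCL expression series.

    The detection threshold is 3x the pooled noise MAD (scale-free; a value
    must rise clearly above measurement noise to count as expressed).
    Onset is the earliest age above threshold; the peak is the age of the
    maximum, reported as a range when adjacent ages sit within
    ``plateau_tol`` (default: one noise MAD) of the maximum; offset is the
    earliest post-onset age at which the signal falls back below threshold
    and stays there.
    """
    _check_ages(gcl_series, "expression series")
    values = np.array([float(gcl_series[a]) for a in AGES])
    threshold = 3.0 * float(noise_mad)
    above = values > threshold
    if not above.any():
        return None, None, None
    onset_i = int(np.argmax(above))

    tol = float(noise_mad) if plateau_tol is None else float(plateau_tol)
    peak_i = int(np.argmax(values))
    near = values >= values[peak_i] - tol
    lo = peak_i
    while lo > 0 and near[lo - 1]:
        lo -= 1
    hi = peak_i
    while hi < len(AGES) - 1 and near[hi + 1]:
        hi += 1
    peak = AGES[peak_i] if lo == hi else f"{AGES[lo]}-{AGES[hi]}"

    offset = None
    for i in range(onset_i + 1, len(AGES)):
        if not above[i:].any():
            offset = AGES[i]
            break
    return AGES[onset_i], peak, offset


def summarize_gene(
    gene: str,
    enrichment_calls: Mapping[str, CallRecord | bool],
    dependency_calls: Mapping[str, CallRecord | bool],
    gcl_series: Mapping[str, float],
    noise_mad: float,
    sparse_flags: Mapping[str, bool] | None = None,
) -> GeneSummaryRow:
    """Fold one gene's per-age calls and expression series into a summary
    row.  All five ages must be present in every input."""
    _check_ages(enrichment_calls, "enrichment calls")
    _check_ages(dependency_calls, "dependency calls")
    enriched = {a: _call_flag(enrichment_calls[a]) for a in AGES}
    dependent = {a: _call_flag(dependency_calls[a]) for a in AGES}
    onset, peak, offset = onset_peak_offset(gcl_series, noise_mad)
    sparse = bool(sparse_flags and any(sparse_flags.get(a, False) for a in AGES))
    return GeneSummaryRow(
        gene=gene,
        gcl_p3=enriched["P3"],
        gcl_consistent=sum(enriched.values()) >= CONSISTENCY_MIN_AGES,
        brn3a_target_p3=dependent["P3"],
        brn3a_target_any=any(dependent.values()),
        onset=onset,
        peak=peak,
        offset=offset,
        sparse=sparse,
    )


def consistent_dependency(dependency_calls: Mapping[str, CallRecord | bool]) -> bool:
    """Developmentally consistent regulation: a significant dependent call
    at >= 4 of the 5 ages (mirroring the GCL-consistency convention)."""
    _check_ages(dependency_calls, "dependency calls")
    return sum(_call_flag(dependency_calls[a]) for a in AGES) >= CONSISTENCY_MIN_AGES


def consistent_dependency_genes(matrix: pd.DataFrame) -> list[str]:
    """Genes with consistent dependency in a per-age boolean matrix
    (columns: gene, P0, P3, P7, P14, P22)."""
    out = []
    for _, row in matrix.iterrows():
        if consistent_dependency({a: bool(row[a]) for a in AGES}):
            out.append(row["gene"])
    return out


def panel_counts(
    summary: pd.DataFrame, dependency_matrix: pd.DataFrame | None = None
) -> PanelCounts:
    """Headline counts over a gene-summary table.

    ``summary`` needs boolean columns gcl_p3, brn3a_target_p3 and
    brn3a_target_any; percentages are integer-rounded.  When a per-age
    dependency matrix is supplied, the count of developmentally consistent
    targets is included.
    """
    if len(summary) == 0:
        raise ValueError("empty summary table")
    n = len(summary)
    n_gcl_p3 = int(summary["gcl_p3"].astype(bool).sum())
    n_p3 = int(summary["brn3a_target_p3"].astype(bool).sum())
    n_any = int(summary["brn3a_target_any"].astype(bool).sum())
    n_consistent = (
        len(consistent_dependency_genes(dependency_matrix))
        if dependency_matrix is not None
        else None
    )
    return PanelCounts(
        n_genes=n,
        n_gcl_p3=n_gcl_p3,
        n_brn3a_p3=n_p3,
        n_brn3a_any=n_any,
        n_consistent_dependency=n_consistent,
        pct_gcl_p3=round(100.0 * n_gcl_p3 / n),
        pct_brn3a_any=round(100.0 * n_any / n),
    )


def sparse_gcl_flag(
    gcl_pixels: np.ndarray,
    background: float = 200.0,
    outlier_fraction: float = 0.01,
    background_tol: float = 25.0,
) -> bool:
    """Detect the "highly and sparsely expressed" pattern in a GCL band.

    Flags layers whose mean gray stays near background (the bulk of cells
    unstained) while more than ``outlier_fraction`` of pixels are stained
    outliers, i.e. darker than the robust mean by 3 robust SDs.  The robust
    scale (1.4826 MAD) keeps the stained somata themselves from inflating
    the spread estimate.
    """
    px = np.asarray(gcl_pixels, dtype=float).ravel()
    mu = float(np.median(px))
    sigma = 1.4826 * float(np.median(np.abs(px - mu)))
    sigma = max(sigma, 1.0)
    frac = float(np.mean(px < mu - 3.0 * sigma))
    return frac > outlier_fraction and abs(mu - background) <= background_tol


def summary_to_frame(rows: Iterable[GeneSummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "gcl_p3": r.gcl_p3,
                "gcl_consistent": r.gcl_consistent,
                "brn3a_target_p3": r.brn3a_target_p3,
                "brn3a_target_any": r.brn3a_target_any,
                "onset": r.onset,
                "peak": r.peak,
                "offset": r.offset,
                "sparse": r.sparse,
            }
            for r in rows
        ]
    )
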