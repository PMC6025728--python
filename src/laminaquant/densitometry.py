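"""Layer ROI placement, mean-gray densitometry and IPL-referenced
normalization.

The measurement emulated here: on each bright-field section, a small number
of rectangular regions of interest (default 3) is placed in every resolvable
retinal layer, column-aligned across layers ("registered along the section
plane"), and the mean gray value of each ROI is recorded.  Because absolute
staining intensity varies between sections and runs, every cellular layer is
referenced to the inner plexiform layer (IPL) of the same registration
group: normalized(layer) = raw(IPL) - raw(layer).  The IPL is free of cell
bodies, so under bright-field polarity (darker = more stain) a stained
cellular layer scores positive.  At P0 no IPL exists and raw values are
carried forward unnormalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthgen import AGE_PROFILES, AgeLayerProfile, SectionImage


@dataclass(frozen=True)
class Roi:
    """A rectangular region of interest, 0-based half-open."""

    layer: str
    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if self.row_end <= self.row_start or self.col_end <= self.col_start:
            raise ValueError(f"empty ROI in layer {self.layer}")

    @property
    def area(self) -> int:
        return (self.row_end - self.row_start) * (self.col_end - self.col_start)


@dataclass
class DensitometryRecord:
    """Raw and IPL-normalized mean gray values for one registration group."""

    gene: str
    age: str
    genotype: str
    replicate: int
    roi_group: int
    raw: dict[str, float]
    normalized: dict[str, float]  # empty when no IPL reference exists
    normalization_applied: bool


def place_layer_rois(
    image: SectionImage,
    age_profile: AgeLayerProfile | None = None,
    n_rois: int = 3,
    seed: int = 0,
    margin: int = 1,
) -> list[Roi]:
    """Place ``n_rois`` column-aligned registration groups of layer ROIs.

    Each group spans an identical column range in every layer; ROIs of the
    same layer have identical areas.  Placement is deterministic for a given
    seed: groups are uniformly spaced along the section with a seeded jitter
    inside the free gaps.  Returned group-major (all layers of group 0, then
    group 1, ...).
    """
    if age_profile is None:
        age_profile = AGE_PROFILES[image.age]
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    width = image.pixels.shape[1]
    roi_w = max(4, width // (2 * n_rois))
    free = width - n_rois * roi_w
    if free < 0:
        raise ValueError(f"image too narrow for {n_rois} ROIs")
    gap = free // (n_rois + 1)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x401]))
    jitters = rng.integers(0, max(1, gap // 2 + 1), size=n_rois)

    rows: dict[str, tuple[int, int]] = {}
    for layer in age_profile.layers:
        r0, r1 = image.layer_rows[layer]
        m = margin if (r1 - r0) > 2 * margin else 0
        if r1 - r0 - 2 * m < 1:
            raise ValueError(f"layer {layer} too small for ROI placement")
        rows[layer] = (r0 + m, r1 - m)

    rois: list[Roi] = []
    for g in range(n_rois):
        c0 = gap * (g + 1) + roi_w * g + int(jitters[g])
        c0 = min(c0, width - roi_w)
        for layer in age_profile.layers:
            rois.append(Roi(layer, *rows[layer], c0, c0 + roi_w))
    return rois


def mean_gray(image: SectionImage, roi: Roi) -> float:
    """Arithmetic mean of the pixel gray values inside the ROI."""
    h, w = image.pixels.shape
    if not (0 <= roi.row_start < roi.row_end <= h and 0 <= roi.col_start < roi.col_end <= w):
        raise ValueError(f"ROI {roi} outside image bounds {(h, w)}")
    return float(
        np.mean(image.pixels[roi.row_start : roi.row_end, roi.col_start : roi.col_end])
    )


def normalize_record(
    raw: Mapping[str, float],
    age: str,
    gene: str = "",
    genotype: str = "",
    replicate: int = 0,
    roi_group: int = 0,
) -> DensitometryRecord:
    """Apply the age-specific IPL reference: normalized = raw(IPL) - raw(layer).

    At P0 (no IPL) raw values are carried forward with
    ``normalization_applied=False``.
    """
    profile = AGE_PROFILES[age]  # KeyError -> caller misuse; validate instead
    for layer in profile.layers:
        if layer not in raw:
            raise ValueError(f"missing layer {layer} in raw values for {age}")
    raw = {layer: float(raw[layer]) for layer in profile.layers}
    if not profile.has_ipl_reference:
        return DensitometryRecord(
            gene, age, genotype, replicate, roi_group, raw, {}, False
        )
    ipl = raw["IPL"]
    normalized = {
        layer: ipl - value for layer, value in raw.items() if layer != "IPL"
    }
    return DensitometryRecord(
        gene, age, genotype, replicate, roi_group, raw, normalized, True
    )


def measure_image(
    image: SectionImage, n_rois: int = 3, seed: int = 0
) -> list[DensitometryRecord]:
    """One DensitometryRecord per registration group of the image."""
    profile = AGE_PROFILES[image.age]
    rois = place_layer_rois(image, profile, n_rois=n_rois, seed=seed)
    n_layers = len(profile.layers)
    records = []
    for g in range(n_rois):
        group = rois[g * n_layers : (g + 1) * n_layers]
        raw = {roi.layer: mean_gray(image, roi) for roi in group}
        records.append(
            normalize_record(
                raw,
                image.age,
                gene=image.gene,
                genotype=image.genotype,
                replicate=image.replicate,
                roi_group=g,
            )
        )
    return records


def quantify_images(
    images: Iterable[SectionImage], n_rois: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Long-format table: one row per (image, registration group, layer).

    The ``value`` column holds the stain-oriented quantity entering
    statistics downstream: the IPL-normalized value where a reference
    exists (positive = darker than IPL = stained), and the negated raw mean
    gray at P0, so that "more stain" is always the larger value.  Negation
    changes neither the KS statistic nor its p-value, only the directional
    reading; the raw gray is kept in its own column.
    """
    rows = []
    for image in images:
        for rec in measure_image(image, n_rois=n_rois, seed=seed):
            for layer, rawval in rec.raw.items():
                norm = rec.normalized.get(layer, np.nan)
                rows.append(
                    {
                        "gene": rec.gene,
                        "age": rec.age,
                        "genotype": rec.genotype,
                        "replicate": rec.replicate,
                        "roi_group": rec.roi_group,
                        "layer": layer,
                        "raw": rawval,
                        "normalized": norm,
                        "value": norm if rec.normalization_applied else -rawval,
                        "normalization_applied": rec.normalization_applied,
                    }
                )
    return pd.DataFrame(rows)


def sample_values(
    quant: pd.DataFrame, gene: str, age: str, genotype: str, layer: str
) -> np.ndarray:
    """Pool the per-ROI values of one (gene, age, genotype, layer) into the
    sample a two-sample test consumes (IPL rows carry raw only and have no
    pooled value)."""
    sel = quant[
        (quant["gene"] == gene)
        & (quant["age"] == age)
        & (quant["genotype"] == genotype)
        & (quant["layer"] == layer)
    ]
    vals = sel["value"].to_numpy(dtype=float)
    return vals[~np.isnan(vals)]
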