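"""Synthetic inputs with known ground truth.

Every downstream stage of the package consumes data that, in the original
study design, comes from wet-lab work that cannot be redistributed: stained
retinal sections photographed in bright field, transcript quantification
tables from sorted-cell RNA sequencing, and multi-isoform gene annotations.
This module generates stand-ins for all three with the ground truth planted
and recorded, so recovery can be asserted rather than guessed:

* laminated bright-field section images — horizontal layer bands whose mean
  gray encodes stain amplitude (darker = more transcript), optional sparse
  intensely stained somata, Gaussian pixel noise, and a knockout genotype
  effect applied to the ganglion cell layer;
* transcript FPKM tables with a configurable fraction of planted
  Brn3a-dependent candidates that satisfy the screen's selection criteria
  by construction;
* synthetic isoform panels with alternative first exons (Clcc1-like) or
  cassette/skipped exons (Pnkd-like), with primers planted at known sites.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import json
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

from .isoform_kit import (
    BandObservation,
    PrimerPair,
    TranscriptModel,
    with_spliced,
)

log = logging.getLogger(__name__)

AGES = ("P0", "P3", "P7", "P14", "P22")
GENOTYPES = ("WT", "KO")


@dataclass(frozen=True)
class AgeLayerProfile:
    """Which retinal layers are resolvable at a given postnatal age.

    At birth only the neuroblast layer and the nascent ganglion cell layer
    can be told apart; the inner plexiform layer appears around P3 and the
    full four-layer lamination (ONL/INL/IPL/GCL) from P7 on.  The IPL, being
    free of cell bodies, serves as the normalization reference wherever it
    exists.
    """

    age: str
    layers: tuple[str, ...]  # outer-to-inner anatomical order
    has_ipl_reference: bool

    def __post_init__(self) -> None:
        assert ("IPL" in self.layers) == self.has_ipl_reference


AGE_PROFILES: dict[str, AgeLayerProfile] = {
    "P0": AgeLayerProfile("P0", ("NBL", "GCL"), False),
    "P3": AgeLayerProfile("P3", ("NBL", "IPL", "GCL"), True),
    "P7": AgeLayerProfile("P7", ("ONL", "INL", "IPL", "GCL"), True),
    "P14": AgeLayerProfile("P14", ("ONL", "INL", "IPL", "GCL"), True),
    "P22": AgeLayerProfile("P22", ("ONL", "INL", "IPL", "GCL"), True),
}

#: Per-age layer thickness as a fraction of section height.  The source
#: imagery reports no geometry, so these are plausible radial-section
#: proportions chosen once; ROI logic only needs each band to be a
#: contiguous horizontal stripe.
LAYER_FRACTIONS: dict[str, dict[str, float]] = {
    "P0": {"NBL": 0.75, "GCL": 0.25},
    "P3": {"NBL": 0.60, "IPL": 0.15, "GCL": 0.25},
    "P7": {"ONL": 0.35, "INL": 0.25, "IPL": 0.20, "GCL": 0.20},
    "P14": {"ONL": 0.35, "INL": 0.25, "IPL": 0.20, "GCL": 0.20},
    "P22": {"ONL": 0.35, "INL": 0.25, "IPL": 0.20, "GCL": 0.20},
}

DEFAULT_BACKGROUND = 200.0
DEFAULT_HEIGHT = 200
DEFAULT_WIDTH = 160
SOMA_RADIUS = 3  # px; sparse somata are drawn as disks at desk scale


@dataclass(frozen=True)
class ExpressionScenario:
    """Ground-truth staining program for one gene.

    ``amplitudes`` maps (age, layer) to the diffuse stain amplitude in gray
    levels for the wild type; unlisted combinations mean no stain.  In the
    knockout, the GCL amplitudes (diffuse and sparse) are multiplied by
    ``genotype_effect`` (0 = complete loss, 1 = no regulation).
    ``sparse_fraction`` maps (age, layer) to the expected fraction of the
    band covered by intensely stained somata of amplitude
    ``sparse_amplitude``.
    """

    gene: str
    amplitudes: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sparse_fraction: Mapping[tuple[str, str], float] = field(default_factory=dict)
    sparse_amplitude: float = 0.0
    noise_sd: float = 5.0
    genotype_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sparse_amplitude < 0:
            raise ValueError("sparse_amplitude must be >= 0")
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("stain amplitudes must be >= 0")
        if any(not (0.0 <= f <= 1.0) for f in self.sparse_fraction.values()):
            raise ValueError("sparse_fraction must lie in [0, 1]")

    def amplitude(self, age: str, genotype: str, layer: str) -> float:
        a = float(self.amplitudes.get((age, layer), 0.0))
        if genotype == "KO" and layer == "GCL":
            a *= self.genotype_effect
        return a

    def soma_amplitude(self, age: str, genotype: str, layer: str) -> float:
        a = float(self.sparse_amplitude)
        if genotype == "KO" and layer == "GCL":
            a *= self.genotype_effect
        return a


@dataclass
class SectionImage:
    """One grayscale bright-field section with a per-row layer map.

    Darker pixels (lower gray value) mean more stain.
    """

    pixels: np.ndarray  # uint8, (rows, cols)
    layer_rows: dict[str, tuple[int, int]]  # layer -> (row_start, row_end)
    gene: str
    age: str
    genotype: str
    replicate: int
    seed: int

    @property
    def layers(self) -> tuple[str, ...]:
        return tuple(self.layer_rows)

    def layer_of_row(self, row: int) -> str:
        for layer, (r0, r1) in self.layer_rows.items():
            if r0 <= row < r1:
                return layer
        return "outside"

    def layer_pixels(self, layer: str) -> np.ndarray:
        r0, r1 = self.layer_rows[layer]
        return self.pixels[r0:r1, :]


def layer_bands(age: str, height: int) -> dict[str, tuple[int, int]]:
    """Row ranges of each layer for a section of the given height."""
    if age not in AGE_PROFILES:
        raise ValueError(f"unsupported age {age!r}")
    profile = AGE_PROFILES[age]
    fracs = LAYER_FRACTIONS[age]
    bands: dict[str, tuple[int, int]] = {}
    r = 0
    for i, layer in enumerate(profile.layers):
        r1 = height if i == len(profile.layers) - 1 else r + round(fracs[layer] * height)
        bands[layer] = (r, r1)
        r = r1
    return bands


def _image_rng(scenario: ExpressionScenario, age: str, genotype: str,
               replicate: int, seed: int) -> np.random.Generator:
    # Mix all identity components into the seed sequence so every
    # (scenario, age, genotype, replicate, seed) tuple maps to its own
    # reproducible stream, independent of Python hash randomization.
    tag = zlib.crc32(f"{scenario.gene}|{age}|{genotype}".encode())
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(replicate), tag])
    )


def generate_section_image(
    scenario: ExpressionScenario,
    age: str,
    genotype: str,
    replicate: int = 0,
    seed: int = 0,
    height: int = DEFAULT_HEIGHT,
    width: int = DEFAULT_WIDTH,
    background: float = DEFAULT_BACKGROUND,
) -> SectionImage:
    """Render one synthetic section: horizontal layer bands at
    ``background - amplitude`` gray, sparse stained somata, pixel noise."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    bands = layer_bands(age, height)  # raises on unsupported age
    rng = _image_rng(scenario, age, genotype, replicate, seed)

    img = np.full((height, width), background, dtype=float)
    for layer, (r0, r1) in bands.items():
        amp = scenario.amplitude(age, genotype, layer)
        if amp > background:
            log.warning(
                "%s %s %s %s: amplitude %.1f exceeds background %.1f; clipping",
                scenario.gene, age, genotype, layer, amp, background,
            )
        img[r0:r1, :] = background - amp

    for layer, (r0, r1) in bands.items():
        frac = float(scenario.sparse_fraction.get((age, layer), 0.0))
        if frac <= 0:
            continue
        soma_amp = scenario.soma_amplitude(age, genotype, layer)
        area = (r1 - r0) * width
        disk_area = math.pi * SOMA_RADIUS**2
        n_somata = rng.poisson(frac * area / disk_area)
        for _ in range(n_somata):
            cr = rng.integers(r0, r1)
            cc = rng.integers(0, width)
            rr, cc_ = _disk((cr, cc), SOMA_RADIUS, shape=img.shape)
            keep = (rr >= r0) & (rr < r1)
            img[rr[keep], cc_[keep]] = background - soma_amp

    if scenario.noise_sd > 0:
        img = img + rng.normal(0.0, scenario.noise_sd, size=img.shape)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SectionImage(
        pixels=pixels,
        layer_rows=bands,
        gene=scenario.gene,
        age=age,
        genotype=genotype,
        replicate=replicate,
        seed=seed,
    )


# --- image I/O: TIFF/PNG plus a JSON sidecar --------------------------------


def write_section_image(image: SectionImage, path) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, image.pixels)
    else:
        from PIL import Image

        Image.fromarray(image.pixels, mode="L").save(path)
    sidecar = {
        "gene": image.gene,
        "age": image.age,
        "genotype": image.genotype,
        "replicate": image.replicate,
        "seed": image.seed,
        "layer_rows": {k: list(v) for k, v in image.layer_rows.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_section_image(path) -> SectionImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        pixels = tifffile.imread(path)
    else:
        from PIL import Image

        pixels = np.asarray(Image.open(path).convert("L"))
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SectionImage(
        pixels=pixels.astype(np.uint8),
        layer_rows={k: tuple(v) for k, v in meta["layer_rows"].items()},
        gene=meta["gene"],
        age=meta["age"],
        genotype=meta["genotype"],
        replicate=meta["replicate"],
        seed=meta["seed"],
    )


# ---------------------------------------------------------------------------
# Transcript quantification tables
# ---------------------------------------------------------------------------

QUANT_COLUMNS = (
    "gene",
    "transcript",
    "fpkm_brn3a_wt_rgc",
    "fpkm_brn3a_ko_rgc",
    "fpkm_retina",
    "fpkm_brn3b_wt_rgc",
    "fpkm_brn3b_ko_rgc",
    "planted",
)


def generate_quant_table(
    n_genes: int = 100,
    n_transcripts_per_gene: int = 2,
    planted_fraction: float = 0.1,
    fold: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Transcript FPKM table with planted screen candidates.

    Planted transcripts pass all three selection criteria with margin
    (FPKM above threshold, Brn3a WT/KO fold above ``fold``, Brn3b fold near
    one); the rest fail exactly one criterion with margin.  The ground-truth
    ``planted`` column is always emitted so recovery tests never re-derive
    truth from the selection output.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValueError("planted_fraction must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7AB1E]))
    n = n_genes * n_transcripts_per_gene
    n_planted = int(round(planted_fraction * n))
    planted = np.zeros(n, dtype=bool)
    planted[rng.choice(n, size=n_planted, replace=False)] = True

    wt = np.empty(n)
    ko = np.empty(n)
    retina = np.empty(n)
    bwt = np.empty(n)
    bko = np.empty(n)
    for i in range(n):
        if planted[i]:
            wt[i] = rng.uniform(5.0, 50.0)
            ko[i] = wt[i] / (fold * rng.uniform(1.3, 3.0))
            retina[i] = wt[i] / rng.uniform(2.5, 5.0)
            bwt[i] = rng.uniform(3.0, 30.0)
            bko[i] = bwt[i] * rng.uniform(0.85, 1.15)
        else:
            mode = rng.integers(0, 3)
            if mode == 0:  # too low in RGCs
                wt[i] = rng.uniform(0.0, 1.5)
                ko[i] = wt[i] * rng.uniform(0.5, 1.5)
                bwt[i] = rng.uniform(0.5, 5.0)
                bko[i] = bwt[i] * rng.uniform(0.85, 1.15)
            elif mode == 1:  # no Brn3a differential
                wt[i] = rng.uniform(5.0, 50.0)
                ko[i] = wt[i] * rng.uniform(0.75, 1.3)
                bwt[i] = rng.uniform(3.0, 30.0)
                bko[i] = bwt[i] * rng.uniform(0.85, 1.15)
            else:  # Brn3b-regulated
                wt[i] = rng.uniform(5.0, 50.0)
                ko[i] = wt[i] / (fold * rng.uniform(1.3, 3.0))
                bwt[i] = rng.uniform(5.0, 40.0)
                bko[i] = bwt[i] / rng.uniform(2.8, 5.0)
            retina[i] = wt[i] * rng.uniform(0.5, 2.0)

    genes = [f"gene{g:04d}" for g in range(n_genes) for _ in range(n_transcripts_per_gene)]
    tx = [
        f"gene{g:04d}.t{t + 1}"
        for g in range(n_genes)
        for t in range(n_transcripts_per_gene)
    ]
    return pd.DataFrame(
        {
            "gene": genes,
            "transcript": tx,
            "fpkm_brn3a_wt_rgc": wt,
            "fpkm_brn3a_ko_rgc": ko,
            "fpkm_retina": retina,
            "fpkm_brn3b_wt_rgc": bwt,
            "fpkm_brn3b_ko_rgc": bko,
            "planted": planted,
        }
    )


# ---------------------------------------------------------------------------
# Isoform panels
# ---------------------------------------------------------------------------


def _random_genome(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=length))


def _plant(genome: list[str], pos: int, seq: str) -> None:
    genome[pos : pos + len(seq)] = list(seq)


def _random_primer(rng: np.random.Generator, length: int = 20) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_isoform_panel(kind: str, seed: int = 0):
    """Synthetic multi-isoform gene models on a synthetic genome.

    ``alt_first_exon`` emulates a Clcc1-like locus: several isoforms with
    distinct first exons splicing onto a shared downstream exon chain, one
    of which carries an extra cassette exon (e2).  ``cassette`` emulates a
    Pnkd-like locus: isoforms skipping internal exons.  Returns
    ``(genome, models)`` with spliced sequences attached.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x150F]))
    if kind == "alt_first_exon":
        exons = {
            "e1a": (100, 220),
            "e1b": (300, 430),
            "e1c": (500, 590),
            "e2": (650, 740),
            "e3": (800, 950),
            "e4": (1050, 1200),
            "e5": (1300, 1430),
            "e6": (1550, 1750),
        }
        genome = _random_genome(rng, 1800)
        common = ("e3", "e4", "e5", "e6")
        chains = {
            "iso_a": ("e1a",) + common,
            "iso_b": ("e1b",) + common,
            "iso_c": ("e1c", "e2") + common,
        }
    elif kind == "cassette":
        exons = {
            "e1": (80, 200),
            "e2": (280, 460),
            "e3": (540, 680),
            "e4": (760, 1080),
            "e5": (1160, 1390),
            "e6": (1470, 1670),
        }
        genome = _random_genome(rng, 1750)
        chains = {
            "iso_full": ("e1", "e2", "e3", "e4", "e5", "e6"),
            "iso_skip": ("e1", "e2", "e3", "e5", "e6"),
            "iso_short": ("e2", "e3", "e4"),
        }
    else:
        raise ValueError(f"unknown panel kind {kind!r}")

    genome_str = "".join(genome)
    models = [
        with_spliced(
            TranscriptModel(
                id=name,
                strand="+",
                exons=tuple(exons[e] for e in chain),
                exon_names=chain,
            ),
            genome_str,
        )
        for name, chain in chains.items()
    ]
    return genome_str, models


def pnkd_like_panel(seed: int = 0):
    """Synthetic stand-in for a three-isoform cassette locus with a
    diagnostic primer panel and its band observations.

    The structure mirrors the published Pnkd situation: a ``long`` isoform
    starting at exon 2 and skipping exons 4-5, a ``medium`` isoform starting
    at exon 5, and a ``short`` isoform spanning exons 2-4.  Primer sites are
    planted so pair p1+p2 yields a 246 bp product across the e2_e3 junction,
    p3+p4 a 289 bp product inside e4 (short only), p5+p6 167 bp inside e5
    and p5+p7 282 bp across e5_e6 (medium only).  The band pattern encodes a
    retina-like outcome: every reaction positive except p3+p4, which
    excludes the short isoform.  All sequences are synthetic.

    Returns (genome, models, primer_pairs, observations).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    exons = {
        "e1": (60, 180),
        "e2": (260, 440),   # len 180
        "e3": (520, 660),   # len 140
        "e4": (740, 1060),  # len 320
        "e5": (1140, 1370),  # len 230
        "e6": (1450, 1650),  # len 200
    }
    genome = _random_genome(rng, 1750)
    p1, p3, p5 = (_random_primer(rng) for _ in range(3))
    p2, p4, p6, p7 = (_random_primer(rng) for _ in range(4))
    # forward sites
    _plant(genome, exons["e2"][0] + 64, p1)    # 116 nt of e2 in the product
    _plant(genome, exons["e4"][0] + 10, p3)
    _plant(genome, exons["e5"][0] + 20, p5)
    # reverse sites (planted as the reverse complement on the template)
    _plant(genome, exons["e3"][0] + 110, _revcomp(p2))  # ends 130 into e3: 116+130=246
    _plant(genome, exons["e4"][0] + 279, _revcomp(p4))  # 289 bp within e4
    _plant(genome, exons["e5"][0] + 167, _revcomp(p6))  # 167 bp within e5
    _plant(genome, exons["e6"][0] + 52, _revcomp(p7))   # 210+72=282 across e5_e6
    genome_str = "".join(genome)

    chains = {
        "long": ("e2", "e3", "e6"),
        "medium": ("e5", "e6"),
        "short": ("e2", "e3", "e4"),
    }
    models = [
        with_spliced(
            TranscriptModel(
                id=name,
                exons=tuple(exons[e] for e in chain),
                exon_names=chain,
            ),
            genome_str,
        )
        for name, chain in chains.items()
    ]
    pairs = [
        PrimerPair("p1+p2", p1, p2),
        PrimerPair("p3+p4", p3, p4),
        PrimerPair("p5+p6", p5, p6),
        PrimerPair("p5+p7", p5, p7),
    ]
    observations = [
        BandObservation("p1+p2", (246,)),
        BandObservation("p3+p4", ()),
        BandObservation("p5+p6", (167,)),
        BandObservation("p5+p7", (282,)),
    ]
    return genome_str, models, pairs, observations


def clcc1_like_panel(seed: int = 0):
    """Synthetic stand-in for an alternative-first-exon locus whose band
    pattern requires a novel junction.

    Isoforms a and b splice their first exons directly onto exon 3; isoform
    c is the only annotated carrier of exon 2.  The observations make the
    exon-1c to exon-2 junction test negative (excluding isoform c) while an
    exon-2-anchored pair is positive, so the only explanation is an
    unannotated transcript joining e2 onto e3.  All sequences are synthetic.

    Returns (genome, models, primer_pairs, observations).
    """
    genome_str, models = generate_isoform_panel("alt_first_exon", seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC1CC1]))
    genome = list(genome_str)
    exons = {
        name: span
        for m in models
        for name, span in zip(m.exon_names, m.exons)
    }
    fa, fb, fc, f2 = (_random_primer(rng) for _ in range(4))
    r2, r3 = (_random_primer(rng) for _ in range(2))
    _plant(genome, exons["e1a"][0] + 30, fa)
    _plant(genome, exons["e1b"][0] + 40, fb)
    _plant(genome, exons["e1c"][0] + 10, fc)
    _plant(genome, exons["e2"][0] + 5, f2)
    _plant(genome, exons["e2"][0] + 60, _revcomp(r2))
    _plant(genome, exons["e3"][0] + 80, _revcomp(r3))
    genome_str = "".join(genome)
    models = [
        with_spliced(
            TranscriptModel(
                id=m.id, strand=m.strand, exons=m.exons, exon_names=m.exon_names
            ),
            genome_str,
        )
        for m in models
    ]
    pairs = [
        PrimerPair("fa+r3", fa, r3),
        PrimerPair("fb+r3", fb, r3),
        PrimerPair("fc+r2", fc, r2),
        PrimerPair("f2+r3", f2, r3),
    ]

    # observed sizes: take the true predicted sizes for the positive pairs
    from .isoform_kit import predict_products

    obs = []
    for name, positive_on in (
        ("fa+r3", "iso_a"),
        ("fb+r3", "iso_b"),
        ("fc+r2", None),  # negative: excludes the annotated e2 carrier
    ):
        if positive_on is None:
            obs.append(BandObservation(name, ()))
        else:
            pair = next(p for p in pairs if p.name == name)
            preds = predict_products(pair, models)
            size = next(
                p.product_length for p in preds if p.transcript_id == positive_on
            )
            obs.append(BandObservation(name, (size,)))
    # the e2-anchored pair bands at the size the annotated e2 carrier would
    # give (the novel e2->e3 transcript shares that spliced span)
    pair = next(p for p in pairs if p.name == "f2+r3")
    preds = predict_products(pair, models)
    size = next(p.product_length for p in preds if p.transcript_id == "iso_c")
    obs.append(BandObservation("f2+r3", (size,)))
    return genome_str, models, pairs, obs


# ---------------------------------------------------------------------------
# Demo scenarios
# ---------------------------------------------------------------------------


def tusc5_like_scenario(noise_sd: float = 3.0) -> ExpressionScenario:
    """A gene expressed in sparse, intensely stained GCL somata at every
    age, completely lost in the knockout — the strongest dependency pattern
    the study design can show."""
    return ExpressionScenario(
        gene="tusc5_like",
        amplitudes={(age, "GCL"): 5.0 for age in AGES},
        sparse_fraction={(age, "GCL"): 0.12 for age in AGES},
        sparse_amplitude=150.0,
        noise_sd=noise_sd,
        genotype_effect=0.0,
    )


def flat_scenario(gene: str = "null", noise_sd: float = 5.0) -> ExpressionScenario:
    """No stain anywhere: the null against which calibration is checked."""
    return ExpressionScenario(gene=gene, noise_sd=noise_sd)
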