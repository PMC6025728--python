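# Methods

## What the package models

The workflow validated here is a candidate-gene screen in postnatal mouse
retina.  A prior RNASeq comparison of sorted Brn3a (Pou4f1) wild-type and
knockout retinal ganglion cells (RGCs) nominates candidate target
transcripts; colorimetric in situ hybridization (ISH) on retinal sections
at five postnatal ages (P0, P3, P7, P14, P22) then asks, per gene and age,
whether the signal is enriched in the ganglion cell layer (GCL) and whether
it depends on Brn3a.  Transcript-isoform identity is resolved separately by
RT-PCR band patterns against annotated splice models.  The package
implements every computational stage of that workflow over synthetic data
with known ground truth, plus the published summary tables as packaged
fixtures.

## Synthetic sections

Raw study images are not redistributable, so the generator produces the
simplest laminated image that exercises the measurement code honestly:

* horizontal layer bands in anatomical order, with per-age layer sets
  (P0: NBL/GCL; P3: NBL/IPL/GCL; P7–P22: ONL/INL/IPL/GCL) and fixed
  thickness fractions (defaults in `synthgen.LAYER_FRACTIONS`);
* bright-field polarity: pixel gray = background − stain amplitude, with
  background 200 (leaves headroom for amplitudes up to 200 before
  clipping, which is logged);
* optional sparse somata: disks of radius 3 px placed by Poisson sampling
  so that the expected covered area fraction equals `sparse_fraction`,
  drawn at `sparse_amplitude`;
* i.i.d. Gaussian pixel noise (`noise_sd`, default 5 gray levels), clipped
  to [0, 255] and quantized to 8 bits;
* a knockout effect: GCL amplitudes (diffuse and sparse) multiplied by
  `genotype_effect` in KO sections.

Everything is a pure function of (parameters, seed): seeds are mixed with
the gene/age/genotype/replicate identity through a `SeedSequence`, so
identical calls are bit-identical and replicates are independent.

What the generator does **not** emulate: cell-scale texture, uneven
illumination, section-to-section thickness variation, chromogen
saturation, or layer boundary curvature.  Passing tests therefore
demonstrate that the measurement and inference chain is correct under its
stated noise model, not that it is robust to real histology artifacts.

## Densitometry and normalization

Per image, `n_rois` (default 3, as in the emulated protocol) registration
groups are placed: each group is one column span shared by the ROIs of
every layer ("registered along the section plane"), and same-layer ROIs
have identical areas.  Placement is deterministic given a seed — groups
are uniformly spaced with a seeded jitter inside the free gaps — because a
manual placement cannot be reproduced.

The measured quantity is the arithmetic mean gray of the ROI.  Where an
inner plexiform layer exists (P3 on), each cellular layer is referenced to
the same group's IPL ROI: normalized = raw(IPL) − raw(layer).  The IPL
carries no cell bodies, so under bright-field polarity stained layers
score positive; the differencing also cancels any constant illumination
offset (an exact invariance, tested).  At P0 there is no IPL and raw
values are carried forward, flagged `normalization_applied=False`.

Downstream statistics consume a stain-oriented value: the normalized value
where it exists, the **negated** raw gray at P0.  Negation changes neither
the KS statistic nor its p-value (the test is invariant under a common
monotone transform); it only makes "larger = more stain" hold at every
age, which the directional gates below require.

ROI means from all ROIs and replicate images of one (gene, age, genotype)
pool into one sample per layer — 9 observations from 3 images × 3 ROIs in
the default configuration, matching the 6–9 observation scale of the
emulated protocol.  A documented limitation is inherited deliberately:
sparsely expressed genes can hide in the ROI mean, because averaging
dilutes a few intense somata across mostly unstained tissue.  The package
flags the pattern (below) but does not compensate for it.

## Two-sample KS testing

Comparisons use the two-sided two-sample Kolmogorov–Smirnov test on
empirical CDFs (right-continuous convention for ties).  With 6–9
observations per group the asymptotic distribution is unreliable, so exact
p-values are used wherever affordable:

* full enumeration of all C(n1+n2, n1) splits of the pooled sample
  (the conditional permutation null; exact under ties) for n1+n2 ≤ 16,
  and up to 22 when ties make the lattice method inapplicable;
* the classical lattice-path counting recursion (exact for tie-free
  samples) up to n1+n2 = 64;
* otherwise the asymptotic series p = 2·Σ (−1)^(k−1) exp(−2k²mD²),
  m = n1·n2/(n1+n2), truncated below 1e-12 and clamped to (0, 1].

The two exact routes agree with each other and with an independent
reference implementation to 1e-9 on tie-free samples, and exact and
asymptotic p differ by less than 0.02 at n1=n2=30 (both asserted).

Significance grading follows the conventional star levels with strict
inequalities: p<0.05 `*`, p<0.01 `**`, p<0.001 `***`.  No multiple-testing
correction is applied — stars are per-comparison, mirroring the emulated
analysis; consumers comparing many genes/ages should treat the stars as
descriptive.

Two comparison types are built on this:

* **enrichment** — GCL sample vs the inner reference layer (NBL at P0/P3,
  INL from P7) within one genotype;
* **dependency** — wild-type GCL vs knockout GCL.

Both gate the positive call on direction: a significant difference counts
as enrichment only when the GCL median exceeds the inner-layer median, and
as dependency only when the WT median exceeds the KO median.  Medians are
used because sparse-soma skew makes means fragile.  Direction labels are
comparison-specific (`higher_in_GCL`/`lower_in_GCL`,
`higher_in_WT`/`lower_in_WT`, or `none` on exactly tied medians).

## Developmental profiling

Per-gene summaries over the five ages:

* `gcl_p3`, `brn3a_target_p3`, `brn3a_target_any` from the directional
  calls; `gcl_consistent` uses the at-least-4-of-5-ages rule.  The same
  4-of-5 rule operationalizes "developmentally consistent" Brn3a
  dependency (the convention is stated for enrichment; applying it to
  dependency is this package's choice, and on the packaged per-age
  dependency fixture it selects exactly Mapk10, Tusc5 and Cdh4).
* **onset** = earliest age whose GCL contrast exceeds 3× the pooled noise
  MAD (scale-free; no absolute threshold is defensible across probes);
  **peak** = age of the maximum, reported as a range (e.g. "P7-P14") when
  adjacent ages lie within one noise MAD of it; **offset** = earliest
  post-onset age where the signal falls below threshold and stays below.
  At P0 the contrast series uses GCL − NBL on the stain-oriented scale so
  it is comparable to the IPL-normalized values of later ages.
* **sparse flag**: a GCL band whose robust mean stays within 25 gray of
  background while more than 1% of pixels are darker than the robust mean
  by 3 robust SDs (1.4826·MAD, so the somata themselves do not inflate the
  spread estimate).  This encodes "highly and sparsely expressed" — a few
  intense somata on an otherwise unstained layer.

`panel_counts` reduces a summary table to headline counts with
integer-rounded percentages.

## Candidate selection

A transcript passes the screen when FPKM in Brn3a-WT RGCs exceeds 2
(strict), the Brn3a WT/KO fold is at least 2 (inclusive), and the
direction-free Brn3b WT/KO fold is below 2 (strict).  Fold ratios use a
floor pseudocount on the denominator only, `num / max(den, eps)` with
eps=0.1: a transcript absent in the knockout passes rather than dividing
by zero, while ratios between well-expressed transcripts are untouched —
so selections are identical for eps ∈ {0, 0.1} whenever all abundances are
≥ 1, and the exactly-two-fold boundary behaves the same with or without
the pseudocount.  (An additive pseudocount on both numerator and
denominator would violate both properties.)  Gene-level CPM flags (RGC vs
whole retina, WT vs KO) use the same rule and serve only for
cross-referencing ISH outcomes.

## Isoform diagnostics

In-silico PCR is exact string matching — the primers were designed to
their templates, so mismatch tolerance is out of scope.  Product length is
the span from the forward-site start through the reverse-site end on the
spliced sequence; multiple products per isoform are allowed, and exon
junctions strictly inside the amplicon are reported.  Band-size matching
uses a ±10% tolerance (gel resolution is not better specified).

Band-pattern interpretation treats negative reactions as perfectly
sensitive: a negative pair excludes every isoform it is predicted to
amplify.  The remaining ambiguity is resolved by exhaustive search over
subsets of the surviving isoforms; a subset is consistent when every
observed band is predicted by some member (within tolerance) and every
member's predicted product on a tested pair appears as a band.
Inclusion-minimal consistent subsets are reported; an isoform in every
minimal subset is `supported`, one in no consistent subset `excluded`,
anything else `undetermined`.  A positive band no surviving isoform can
produce triggers a novel-junction search: candidate transcripts join one
exon of the panel onto the downstream exon chain of an annotated isoform,
and a hypothesis is emitted when the candidate reproduces the band size
with the hypothesized join inside the amplicon.  The perfect-sensitivity
assumption is the method's main caveat: a failed reaction (bad primers,
degraded template) reads as biological absence.

Riboprobe QC checks template length (160–900 nt), melting temperature by
the long-duplex approximation Tm = 81.5 + 16.6·log10([Na+]) + 0.41·(%GC)
− 675/N at [Na+] = 0.195 M (a typical hybridization salt; the emulated
protocol states its Tm window but not its formula, and this combination
reproduces that window for realistic probes), a windowed
trinucleotide-entropy screen for low-complexity sequence (minimum window
entropy below 2 bits flags; random sequence scores ≈5), and an internal
repeat flag on any duplicated 15-mer.  `append_t3` prefixes the 26-nt T3
promoter consensus to a reverse primer, so extended product sizes are
template + 26.

## Packaged fixtures

The published primer/probe table, the splice-variant table and the 28-gene
summary table are transcribed to TSV and shipped with the package,
checksum-verified on load, together with a per-age dependency matrix
encoded from the per-age significance levels in the running text (see
`fixtures/NOTES.md` for transcription conventions and known ambiguities in
the primer-column splits).  These fixtures are the inputs to the
panel-count and consistency computations; nothing in the package looks up
their headline numbers directly.

## Problem sizes and numerical choices

Default sections are 200×160 px (statistical-calibration runs use 100×80
to keep replicate counts high); calibration uses 2000 null replicates and
500 power replicates at 9 ROI means per group, the isoform-inference
parity check 100 random panels of up to 5 isoforms, and the selection
oracle 500-transcript tables.  Exact-method cutoffs (enumeration ≤ 16
pooled observations, ≤ 22 under ties; lattice ≤ 64) were chosen so every
comparison the default pipeline produces is evaluated exactly.  Degenerate
inputs fail loudly: empty samples, p-values outside (0, 1], missing
layers or ages, unknown primer pairs, out-of-bounds exons and ROIs all
raise with the offending item named.

## Known limitations

* The synthetic noise model is Gaussian and spatially white; calibration
  results do not transfer to structured noise.
* Onset/peak/offset thresholds are noise-referenced; with very low noise
  the 3·MAD threshold becomes extremely permissive.
* The novel-junction search proposes single joins onto annotated
  downstream chains; multi-join novel transcripts are out of reach.
* Sparse-expression dilution in ROI means is flagged, not corrected.
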