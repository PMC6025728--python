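"""Transcript-model arithmetic and isoform diagnostics.

This module answers the questions raised when a gene has several splice
isoforms and only gel bands from RT-PCR reactions are available to decide
which of them a tissue actually expresses:

* which amplicons does a primer pair yield on each isoform's spliced
  sequence (in-silico PCR), and which exon-exon junctions does each
  amplicon span;
* given a set of positive/negative band observations, which isoforms are
  supported, which are excluded, and do any bands require a previously
  unannotated splice junction to explain;
* is a PCR template suitable as an in situ hybridization riboprobe
  (length, melting temperature, sequence-complexity screens), and what is
  its length once the T3 promoter consensus is appended to the reverse
  primer.

Exon coordinates are 0-based half-open throughout; GFF3 input (1-based
closed) is converted on read.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import gc_fraction

#: T3 RNA polymerase promoter consensus appended to reverse primers so the
#: purified PCR product can serve as a riboprobe transcription template.
T3_PROMOTER = "GGAGCAAATTAACCCTCACTAAAGGG"

_ACGT = frozenset("ACGT")


def _check_acgt(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"empty {what}")
    bad = set(seq) - _ACGT
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """One splice isoform as an ordered list of genomic exon intervals."""

    id: str
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    exon_names: tuple[str, ...] | None = None
    chrom: str = "synth"
    spliced: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"{self.id}: empty exon ({start}, {end})")
            if start < prev_end:
                raise ValueError(f"{self.id}: exons overlap or are unsorted")
            prev_end = end
        if self.exon_names is not None and len(self.exon_names) != len(self.exons):
            raise ValueError(f"{self.id}: exon_names length mismatch")

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)

    def exon_label(self, i: int) -> str:
        """Name of the i-th exon in transcription order."""
        n = len(self.exons)
        j = i if self.strand == "+" else n - 1 - i
        if self.exon_names is not None:
            return self.exon_names[j]
        return f"ex{j + 1}"


def splice(model: TranscriptModel, genome: str) -> str:
    """Concatenate exon substrings; reverse-complement on the minus strand."""
    for start, end in model.exons:
        if start < 0 or end > len(genome):
            raise ValueError(
                f"{model.id}: exon ({start}, {end}) outside genome of length {len(genome)}"
            )
    seq = "".join(genome[start:end] for start, end in model.exons)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def with_spliced(model: TranscriptModel, genome: str) -> TranscriptModel:
    """Return a copy of *model* carrying its spliced sequence."""
    return TranscriptModel(
        id=model.id,
        strand=model.strand,
        exons=model.exons,
        exon_names=model.exon_names,
        chrom=model.chrom,
        spliced=splice(model, genome),
    )


# --- BED12 / GFF3 I/O -------------------------------------------------------


def write_bed12(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start = m.exons[0][0]
            end = m.exons[-1][1]
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - start) for s, e in m.exons)
            fh.write(
                "\t".join(
                    [
                        m.chrom,
                        str(start),
                        str(end),
                        m.id,
                        "0",
                        m.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(m.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


def read_bed12(path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"not a BED12 line: {line[:60]!r}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            models.append(
                TranscriptModel(id=name, strand=strand, exons=exons, chrom=chrom)
            )
    return models


def read_gff3(path) -> list[TranscriptModel]:
    """Read transcript models (mRNA/transcript features with exon children)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for ftype in ("mRNA", "transcript"):
        for t in db.features_of_type(ftype):
            exons = tuple(
                sorted(
                    # GFF3 is 1-based closed; convert to 0-based half-open.
                    (e.start - 1, e.end)
                    for e in db.children(t, featuretype="exon")
                )
            )
            if exons:
                models.append(
                    TranscriptModel(
                        id=t.id, strand=t.strand, exons=exons, chrom=t.seqid
                    )
                )
    return models


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'."""

    name: str
    forward: str
    reverse: str
    t3_appended: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward", _check_acgt(self.forward, "forward primer"))
        object.__setattr__(self, "reverse", _check_acgt(self.reverse, "reverse primer"))


@dataclass(frozen=True)
class PcrPrediction:
    """One amplicon a primer pair yields on one isoform."""

    pair: str
    transcript_id: str
    product_length: int
    junctions: tuple[str, ...] = ()
    t3_appended: bool = False

    @property
    def extended_length(self) -> int:
        """Product length including the T3 promoter extension, if appended."""
        return self.product_length + (len(T3_PROMOTER) if self.t3_appended else 0)


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def predict_products(
    pair: PrimerPair, models: Sequence[TranscriptModel]
) -> list[PcrPrediction]:
    """Exact-match in-silico PCR of *pair* against each isoform.

    The forward primer must match the spliced sequence directly and the
    reverse primer as its reverse complement, in amplifiable orientation
    (forward site fully upstream of the reverse site).  Product length is
    the span from the forward-site start through the reverse-site end.  A
    transcript may yield several products when a primer matches more than
    once.  Junctions strictly inside the amplicon are reported by the names
    of the exons they join.
    """
    rc_rev = str(Seq(pair.reverse).reverse_complement())
    out: list[PcrPrediction] = []
    for m in models:
        if m.spliced is None:
            raise ValueError(f"{m.id}: spliced sequence not available")
        seq = m.spliced
        f_starts = _find_all(seq, pair.forward)
        r_ends = [i + len(rc_rev) for i in _find_all(seq, rc_rev)]
        # exon boundaries in spliced coordinates
        bounds = list(itertools.accumulate(e - s for s, e in m.exons))[:-1]
        for fs in f_starts:
            for re_ in r_ends:
                if fs + len(pair.forward) > re_ - len(rc_rev):
                    continue  # sites overlap or wrong order
                spanned = tuple(
                    f"{m.exon_label(i)}_{m.exon_label(i + 1)}"
                    for i, b in enumerate(bounds)
                    if fs < b < re_
                )
                out.append(
                    PcrPrediction(
                        pair=pair.name,
                        transcript_id=m.id,
                        product_length=re_ - fs,
                        junctions=spanned,
                        t3_appended=pair.t3_appended,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Band-pattern interpretation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BandObservation:
    """Gel outcome of one RT-PCR reaction: band sizes in bp, or negative."""

    pair: str
    sizes: tuple[int, ...] = ()

    @property
    def positive(self) -> bool:
        return len(self.sizes) > 0


@dataclass(frozen=True)
class NovelJunctionHypothesis:
    """A band explainable only by joining two exons not spliced together
    in any annotated isoform."""

    pair: str
    size: int
    junction: str | None


@dataclass
class SupportResult:
    status: dict[str, str]  # transcript id -> supported|excluded|undetermined
    minimal_subsets: list[frozenset[str]]
    novel_junctions: list[NovelJunctionHypothesis]


def _size_match(observed: int, predicted: int, tol: float) -> bool:
    return abs(observed - predicted) <= tol * predicted


def _subset_consistent(
    subset: frozenset[str],
    observations: Sequence[BandObservation],
    by_pair: Mapping[str, Sequence[PcrPrediction]],
    explained: set[tuple[str, int]],
    tol: float,
) -> bool:
    """Perfect-sensitivity consistency: a present transcript's predicted
    product must band, and every band must come from a present transcript
    (or an accepted novel-junction hypothesis)."""
    for obs in observations:
        preds = [p for p in by_pair[obs.pair] if p.transcript_id in subset]
        if not obs.positive:
            if preds:
                return False
            continue
        for size in obs.sizes:
            if (obs.pair, size) in explained:
                continue
            if not any(_size_match(size, p.product_length, tol) for p in preds):
                return False
        for p in preds:
            if not any(_size_match(size, p.product_length, tol) for size in obs.sizes):
                return False
    return True


def _novel_junction_search(
    pair: PrimerPair,
    size: int,
    models: Sequence[TranscriptModel],
    genome: str,
    tol: float,
) -> str | None:
    """Look for an unannotated exon join explaining an orphan band.

    Chimeric candidates join one exon of the panel onto the downstream exon
    chain of an annotated isoform, skipping whatever lies between; the first
    junction whose predicted product matches the band size (and which no
    annotated isoform already contains) is reported.
    """
    # union of named exons across the panel, plus annotated exon chains
    exon_by_name: dict[str, tuple[int, int]] = {}
    annotated_chains: set[tuple[tuple[int, int], ...]] = set()
    for m in models:
        for i in range(len(m.exons)):
            exon_by_name[m.exon_label(i)] = m.exons[i]
        annotated_chains.add(m.exons)
    for a_name, b_name in itertools.product(exon_by_name, repeat=2):
        if a_name == b_name:
            continue
        a = exon_by_name[a_name]
        b = exon_by_name[b_name]
        if a[1] > b[0]:
            continue
        for m in models:
            labels = [m.exon_label(i) for i in range(len(m.exons))]
            if b_name not in labels:
                continue
            k = labels.index(b_name)
            chain = (a,) + m.exons[k:]
            if chain in annotated_chains:
                continue  # identical to an annotated isoform: not novel
            names = (a_name,) + tuple(labels[k:])
            try:
                cand = with_spliced(
                    TranscriptModel(
                        id="novel", strand=m.strand, exons=chain, exon_names=names
                    ),
                    genome,
                )
            except ValueError:
                continue
            junction = f"{a_name}_{b_name}"
            for p in predict_products(pair, [cand]):
                # the amplicon must actually span the hypothesized join
                if _size_match(size, p.product_length, tol) and junction in p.junctions:
                    return junction
    return None


def infer_transcript_support(
    predictions: Sequence[PcrPrediction],
    observations: Sequence[BandObservation],
    transcripts: Sequence[str] | None = None,
    primer_pairs: Sequence[PrimerPair] | None = None,
    models: Sequence[TranscriptModel] | None = None,
    genome: str | None = None,
    tolerance: float = 0.10,
) -> SupportResult:
    """Decide which isoforms the band pattern supports, excludes or leaves
    open, and flag bands that require a novel splice junction.

    Negative evidence is treated as perfectly sensitive: a negative reaction
    excludes every transcript on which its pair predicts a product.  The
    remaining ambiguity is resolved by exhaustive search over subsets of the
    surviving transcripts, reporting the inclusion-minimal subsets
    consistent with all observations.  A transcript present in every minimal
    subset is ``supported``; one present in none of the consistent subsets is
    ``excluded``; anything else is ``undetermined``.
    """
    by_pair: dict[str, list[PcrPrediction]] = {
        pp.name: [] for pp in primer_pairs or []
    }
    for p in predictions:
        by_pair.setdefault(p.pair, []).append(p)
    for obs in observations:
        if obs.pair not in by_pair:
            raise ValueError(f"observation references unknown primer pair {obs.pair!r}")

    universe = list(
        dict.fromkeys(
            transcripts
            if transcripts is not None
            else [p.transcript_id for p in predictions]
        )
    )

    # hard exclusions from negative reactions
    hard_excluded = {
        p.transcript_id
        for obs in observations
        if not obs.positive
        for p in by_pair[obs.pair]
    }
    surviving = [t for t in universe if t not in hard_excluded]

    # bands no surviving transcript can produce -> novel-junction hypotheses
    novel: list[NovelJunctionHypothesis] = []
    explained: set[tuple[str, int]] = set()
    pair_lookup = {pp.name: pp for pp in primer_pairs or []}
    for obs in observations:
        if not obs.positive:
            continue
        for size in obs.sizes:
            if any(
                p.transcript_id in surviving
                and _size_match(size, p.product_length, tolerance)
                for p in by_pair[obs.pair]
            ):
                continue
            junction = None
            if models is not None and genome is not None and obs.pair in pair_lookup:
                junction = _novel_junction_search(
                    pair_lookup[obs.pair], size, models, genome, tolerance
                )
            novel.append(NovelJunctionHypothesis(obs.pair, size, junction))
            explained.add((obs.pair, size))

    consistent = [
        frozenset(s)
        for r in range(len(surviving) + 1)
        for s in itertools.combinations(surviving, r)
        if _subset_consistent(frozenset(s), observations, by_pair, explained, tolerance)
    ]
    minimal = [
        s for s in consistent if not any(t < s for t in consistent)
    ]

    status = {}
    in_some = set().union(*consistent) if consistent else set()
    in_all_minimal = (
        set.intersection(*(set(s) for s in minimal)) if minimal else set()
    )
    for t in universe:
        if t in hard_excluded or t not in in_some:
            status[t] = "excluded"
        elif t in in_all_minimal:
            status[t] = "supported"
        else:
            status[t] = "undetermined"
    return SupportResult(status=status, minimal_subsets=minimal, novel_junctions=novel)


# ---------------------------------------------------------------------------
# Riboprobe QC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCReport:
    length: int
    tm: float
    gc: float
    low_complexity: bool
    repeat_flag: bool
    passed: bool
    reasons: tuple[str, ...] = ()


#: Monovalent-cation concentration (molar) assumed by the long-duplex Tm
#: approximation; typical of 1x hybridization salt.
DEFAULT_NA_MOLAR = 0.195

MIN_PROBE_LENGTH = 160
MAX_PROBE_LENGTH = 900
MIN_PROBE_TM = 77.0
MAX_PROBE_TM = 94.0


def probe_tm(sequence: str, na_molar: float = DEFAULT_NA_MOLAR) -> float:
    """Melting temperature of a long duplex:
    Tm = 81.5 + 16.6 log10([Na+]) + 0.41 (%GC) - 675/N."""
    sequence = _check_acgt(sequence, "probe")
    gc = gc_fraction(sequence)
    return 81.5 + 16.6 * math.log10(na_molar) + 0.41 * (100.0 * gc) - 675.0 / len(sequence)


def _windowed_triplet_entropy(seq: str, window: int = 48, step: int = 16) -> float:
    """Minimum Shannon entropy (bits) of overlapping-trinucleotide counts
    over sliding windows; homopolymers and simple repeats score near zero."""
    if len(seq) < 3:
        return 0.0
    starts = range(0, max(1, len(seq) - window + 1), step)
    best = math.inf
    for s in starts:
        chunk = seq[s : s + window]
        counts = Counter(chunk[i : i + 3] for i in range(len(chunk) - 2))
        total = sum(counts.values())
        h = -sum((c / total) * math.log2(c / total) for c in counts.values())
        best = min(best, h)
    return best


def _has_repeated_kmer(seq: str, k: int = 15) -> bool:
    seen: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in seen:
            return True
        seen.add(kmer)
    return False


LOW_COMPLEXITY_ENTROPY = 2.0  # bits; random sequence scores ~5


def probe_qc(sequence: str, na_molar: float = DEFAULT_NA_MOLAR) -> QCReport:
    """Screen a riboprobe template: 160-900 bp, Tm 77-94 degC, and free of
    low-complexity or internally repeated sequence."""
    sequence = _check_acgt(sequence, "probe")
    n = len(sequence)
    tm = probe_tm(sequence, na_molar)
    low = _windowed_triplet_entropy(sequence) < LOW_COMPLEXITY_ENTROPY
    rep = _has_repeated_kmer(sequence)
    reasons = []
    if not (MIN_PROBE_LENGTH <= n <= MAX_PROBE_LENGTH):
        reasons.append("length")
    if not (MIN_PROBE_TM <= tm <= MAX_PROBE_TM):
        reasons.append("tm")
    if low:
        reasons.append("low_complexity")
    if rep:
        reasons.append("repeat")
    return QCReport(
        length=n,
        tm=tm,
        gc=gc_fraction(sequence),
        low_complexity=low,
        repeat_flag=rep,
        passed=not reasons,
        reasons=tuple(reasons),
    )


def append_t3(reverse_primer: str) -> str:
    """Prefix the T3 promoter consensus onto a reverse primer (adds 26 nt)."""
    return T3_PROMOTER + _check_acgt(reverse_primer, "reverse primer")
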