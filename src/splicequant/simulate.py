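"""Spliced-read simulator with an exact expected-PSI oracle.

The simulator emulates a poly(A) RNA-seq library over a toy two-exon locus
expressing a three-isoform mixture:

* ``canonical`` — exon 1 spliced to exon 2 (reads crossing the junction get
  an N skip spanning the whole intron);
* ``misspliced`` — exon 1 joined to a pseudo-exon inside intron 1, the
  *FMR1-217*-type product (junction-crossing reads get a short N skip from
  the donor to the pseudo-exon start; reads inside the pseudo-exon are
  genuine intronic reads);
* ``retained`` — unspliced pre-mRNA (pure M alignments; reads fully inside
  the intron are intron-retention evidence).

Reads are error-free with perfect alignments: the simulator exercises
counting logic, not an aligner.  Paired-end fragments draw an integer length
from a discretised truncated normal restricted to fit the transcript and a
uniform placement, and emit one record per mate.  All randomness flows from
one seed through a fixed stream order (isoform draws, then per-isoform
fragment lengths, then placements), so outputs are reproducible bit for bit.

:func:`expected_psi` computes category probabilities by exhaustive
enumeration of every (isoform, fragment length, placement) combination,
classifying each template read with the production classifier — the analytic
ground truth against which pipeline estimates are tested.  Per-read truth
labels written by :func:`simulate_reads`, in contrast, come from independent
coordinate arithmetic on the transcript, so classifier and simulator can
check each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from scipy.special import ndtr

from .alignments import (
    FLAG_MATE_REVERSE,
    FLAG_PAIRED,
    FLAG_PROPER_PAIR,
    FLAG_READ1,
    FLAG_READ2,
    FLAG_REVERSE,
    AlignmentRecord,
    Cigar,
    cigar_to_string,
)
from .classify import Category, ClassifierConfig, classify_read
from .errors import ContractError
from .locus import Interval, LocusConfig, NormalizedLocus, normalize_locus

__all__ = [
    "ToyLocus",
    "SimulationParams",
    "ReadTruth",
    "SimulationTruth",
    "ISOFORMS",
    "build_toy_locus",
    "isoform_blocks",
    "template_record",
    "expected_psi",
    "simulate_reads",
    "write_sam",
    "write_reference_fasta",
    "write_truth_tsv",
]

ISOFORMS = ("canonical", "misspliced", "retained")


@dataclass(frozen=True)
class ToyLocus:
    """Synthetic two-exon locus with a pseudo-exon inside the intron.

    ``pseudo_exon`` is a half-open offset interval relative to the donor
    (first intronic base); the default (100, 400) places a 300-bp pseudo-exon
    100 bp into a 2-kb intron.  ``origin`` is the 1-based genomic start of
    exon 1.
    """

    chromosome: str = "chrT"
    exon1_len: int = 500
    intron_len: int = 2000
    exon2_len: int = 500
    pseudo_exon: Tuple[int, int] = (100, 400)
    origin: int = 1001
    flank: int = 200

    def __post_init__(self):
        if min(self.exon1_len, self.intron_len, self.exon2_len) < 1:
            raise ContractError("exon/intron lengths must be positive")
        ps, pe = self.pseudo_exon
        if not (1 <= ps < pe <= self.intron_len):
            raise ContractError(
                f"pseudo_exon {self.pseudo_exon} must lie strictly inside "
                f"(0, intron_len={self.intron_len}]"
            )
        if self.origin < 1 or self.flank < 0:
            raise ContractError("origin must be >= 1 and flank >= 0")

    @property
    def total_len(self) -> int:
        return self.exon1_len + self.intron_len + self.exon2_len


@dataclass(frozen=True)
class SimulationParams:
    """Isoform mixture and library design of one simulated sample.

    ``mis_fraction`` (f) and ``retained_fraction`` (r) are the transcript
    proportions of the mis-spliced and intron-retained isoforms; canonical
    transcripts make up 1-f-r.  Defaults mirror a paired-end 150-bp short-read
    library; ``n_reads`` counts emitted alignment records (two per fragment
    when paired).
    """

    mis_fraction: float = 0.0
    retained_fraction: float = 0.0
    read_len: int = 150
    n_reads: int = 20_000
    paired: bool = True
    fragment_len_mean: float = 300.0
    fragment_len_sd: float = 50.0
    seed: int = 0

    def __post_init__(self):
        f, r = self.mis_fraction, self.retained_fraction
        if not (0.0 <= f <= 1.0 and 0.0 <= r <= 1.0 and f + r <= 1.0 + 1e-12):
            raise ContractError(
                f"invalid mixture: mis_fraction={f}, retained_fraction={r} "
                "(require both in [0,1] with sum <= 1)"
            )
        if self.read_len < 1 or self.n_reads < 0:
            raise ContractError("read_len must be >= 1 and n_reads >= 0")
        if self.fragment_len_mean <= 0 or self.fragment_len_sd <= 0:
            raise ContractError("fragment length mean and sd must be positive")

    @property
    def mixture(self) -> Tuple[float, float, float]:
        f, r = self.mis_fraction, self.retained_fraction
        return (max(0.0, 1.0 - f - r), f, r)


@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated record."""

    name: str
    mate: int  # 0 single-end, 1 or 2 for paired
    isoform: str
    transcript_start: int
    expected_category: Category


@dataclass(frozen=True)
class SimulationTruth:
    """Per-read labels plus analytically expected per-record category rates."""

    reads: Tuple[ReadTruth, ...]
    expected_junction_rate: float
    expected_intron_rate: float
    expected_cryptic_rate: float
    expected_unclassified_rate: float
    expected_psi: Optional[float]


# ---------------------------------------------------------------------------
# Locus construction and isoform geometry
# ---------------------------------------------------------------------------

def build_toy_locus(t: ToyLocus, seed: int = 0) -> Tuple[str, LocusConfig]:
    """Deterministic pseudo-random reference sequence and matching config."""
    rng = np.random.default_rng(seed)
    ref_len = (t.origin - 1) + t.total_len + t.flank
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=ref_len)])
    e1_start = t.origin
    e1_end = t.origin + t.exon1_len - 1
    in_start, in_end = e1_end + 1, e1_end + t.intron_len
    e2_start, e2_end = in_end + 1, in_end + t.exon2_len
    cfg = LocusConfig(
        locus_name="toy_locus",
        chromosome=t.chromosome,
        exon1=(e1_start, e1_end),
        intron1=(in_start, in_end),
        exon2=(e2_start, e2_end),
        window_bp=50,
        transcript_region=(e1_start, in_start + t.pseudo_exon[1] - 1),
    )
    return seq, cfg


def isoform_blocks(t: ToyLocus) -> Dict[str, List[Interval]]:
    """Genomic (0-based half-open) exon blocks of each isoform's mature transcript."""
    o = t.origin - 1
    donor = o + t.exon1_len
    acceptor = donor + t.intron_len
    ps, pe = t.pseudo_exon
    return {
        "canonical": [Interval(o, donor), Interval(acceptor, acceptor + t.exon2_len)],
        "misspliced": [Interval(o, donor), Interval(donor + ps, donor + pe)],
        "retained": [Interval(o, acceptor + t.exon2_len)],
    }


def transcript_length(blocks: Sequence[Interval]) -> int:
    return sum(b.length for b in blocks)


def _project(blocks: Sequence[Interval], start: int, length: int
             ) -> Tuple[int, Cigar]:
    """Project transcript interval [start, start+length) to genomic M/N CIGAR."""
    remaining = length
    toff = 0
    pos: Optional[int] = None
    ops: List[Tuple[str, int]] = []
    prev_end: Optional[int] = None
    for b in blocks:
        blen = b.length
        if start >= toff + blen:
            toff += blen
            continue
        lo = b.start + max(0, start - toff)
        take = min(remaining, b.end - lo)
        if pos is None:
            pos = lo
        else:
            gap = lo - prev_end
            if gap > 0:
                ops.append(("N", gap))
        ops.append(("M", take))
        prev_end = lo + take
        remaining -= take
        toff += blen
        if remaining == 0:
            break
    if remaining != 0 or pos is None:
        raise ContractError("read extends past the transcript end")
    # merge adjacent M ops (possible when blocks are genomically adjacent)
    merged: List[Tuple[str, int]] = []
    for op, ln in ops:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return pos, tuple(merged)


def template_record(t: ToyLocus, isoform: str, start: int, read_len: int,
                    name: str = "template", flags: int = 0) -> AlignmentRecord:
    """The error-free alignment a read from (isoform, start) would produce."""
    blocks = isoform_blocks(t)[isoform]
    pos, cig = _project(blocks, start, read_len)
    return AlignmentRecord(query_name=name, reference_name=t.chromosome,
                          position=pos, cigar=cig, flags=flags,
                          mapping_quality=255)


# ---------------------------------------------------------------------------
# Independent analytic labels (coordinate arithmetic, no classifier code)
# ---------------------------------------------------------------------------

def _analytic_label(t: ToyLocus, isoform: str, start: int, read_len: int,
                    window: int, overhang: int) -> Category:
    e1 = t.exon1_len
    ps, pe = t.pseudo_exon
    end = start + read_len  # transcript half-open end
    crosses = start <= e1 - overhang and end >= e1 + overhang
    if isoform == "canonical":
        if crosses:
            # skip == intron exactly -> within any window of donor/acceptor
            return Category.CANONICAL_JUNCTION
        return Category.UNCLASSIFIED
    if isoform == "misspliced":
        if crosses:
            # skip [donor, donor+ps): canonical only if ps within window of
            # the acceptor, i.e. intron_len - ps <= window
            if t.intron_len - ps <= window:
                return Category.CANONICAL_JUNCTION
            if ps < t.intron_len - window:
                return Category.CRYPTIC_JUNCTION
            return Category.UNCLASSIFIED
        if start >= e1:
            return Category.INTRON_CONTAINED  # wholly inside the pseudo-exon
        return Category.UNCLASSIFIED
    if isoform == "retained":
        if start >= e1 and end <= e1 + t.intron_len:
            return Category.INTRON_CONTAINED
        return Category.UNCLASSIFIED
    raise ContractError(f"unknown isoform {isoform!r}")


# ---------------------------------------------------------------------------
# Exact expectation by exhaustive enumeration
# ---------------------------------------------------------------------------

def _fragment_length_weights(L: int, p: SimulationParams) -> Tuple[np.ndarray, np.ndarray]:
    """Discretised truncated-normal fragment lengths on [read_len, L]."""
    lengths = np.arange(p.read_len, L + 1)
    z_hi = (lengths + 0.5 - p.fragment_len_mean) / p.fragment_len_sd
    z_lo = (lengths - 0.5 - p.fragment_len_mean) / p.fragment_len_sd
    w = ndtr(z_hi) - ndtr(z_lo)
    total = w.sum()
    if total <= 0:
        raise ContractError(
            "fragment length distribution has no mass on "
            f"[{p.read_len}, {L}] (mean={p.fragment_len_mean}, sd={p.fragment_len_sd})"
        )
    return lengths, w / total


def _label_codes(t: ToyLocus, locus: NormalizedLocus, ccfg: ClassifierConfig,
                 isoform: str, read_len: int) -> np.ndarray:
    """Production-classifier category per transcript start position."""
    blocks = isoform_blocks(t)[isoform]
    L = transcript_length(blocks)
    cats = list(Category)
    codes = np.empty(L - read_len + 1, dtype=np.int8)
    for s in range(L - read_len + 1):
        rec = template_record(t, isoform, s, read_len)
        codes[s] = cats.index(classify_read(rec, locus, ccfg))
    return codes


def expected_psi(t: ToyLocus, p: SimulationParams,
                 ccfg: ClassifierConfig = ClassifierConfig()) -> SimulationTruth:
    """Exact per-record category rates under the simulator's sampling model.

    Every (isoform, fragment length, placement) combination is enumerated;
    each template read is classified with the production classifier and
    weighted by the mixture, the fragment-length mass and the uniform
    placement probability.  For single-end runs the enumeration is simply
    uniform over read starts.  ``expected_psi`` is then
    intron_rate / (junction_rate + intron_rate).
    """
    _, cfg = build_toy_locus(t)
    locus = normalize_locus(cfg)
    blocks = isoform_blocks(t)
    shortest = min(transcript_length(b) for b in blocks.values())
    if p.read_len > shortest:
        raise ContractError(
            f"read_len {p.read_len} exceeds shortest transcript ({shortest})"
        )
    mixture = p.mixture
    cats = list(Category)
    rates = np.zeros(len(cats))
    for iso, pi in zip(ISOFORMS, mixture):
        if pi == 0.0:
            continue
        L = transcript_length(blocks[iso])
        codes = _label_codes(t, locus, ccfg, iso, p.read_len)
        ind = np.stack([(codes == k).astype(float) for k in range(len(cats))])
        if not p.paired:
            rates += pi * ind.mean(axis=1)
            continue
        csum = np.concatenate([np.zeros((len(cats), 1)), np.cumsum(ind, axis=1)],
                              axis=1)
        lengths, w = _fragment_length_weights(L, p)
        for fl, wl in zip(lengths, w):
            if wl == 0.0:
                continue
            n_pos = L - fl + 1
            # mate 1 starts: uniform on [0, L-fl]; mate 2 starts: shifted window
            m1 = (csum[:, n_pos] - csum[:, 0]) / n_pos
            lo2 = fl - p.read_len
            m2 = (csum[:, lo2 + n_pos] - csum[:, lo2]) / n_pos
            rates += pi * wl * 0.5 * (m1 + m2)
    j = float(rates[cats.index(Category.CANONICAL_JUNCTION)])
    i = float(rates[cats.index(Category.INTRON_CONTAINED)])
    c = float(rates[cats.index(Category.CRYPTIC_JUNCTION)])
    u = float(rates[cats.index(Category.UNCLASSIFIED)])
    psi = None if j + i == 0 else i / (j + i)
    return SimulationTruth(reads=(), expected_junction_rate=j,
                           expected_intron_rate=i, expected_cryptic_rate=c,
                           expected_unclassified_rate=u, expected_psi=psi)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

_MATE1_FLAGS = FLAG_PAIRED | FLAG_PROPER_PAIR | FLAG_MATE_REVERSE | FLAG_READ1
_MATE2_FLAGS = FLAG_PAIRED | FLAG_PROPER_PAIR | FLAG_REVERSE | FLAG_READ2


def simulate_reads(t: ToyLocus, p: SimulationParams
                   ) -> Tuple[List[AlignmentRecord], SimulationTruth]:
    """Draw reads from the isoform mixture; return records sorted by position.

    Paired runs emit ``n_reads // 2`` fragments (two records each).  Truth
    labels come from :func:`_analytic_label` (independent arithmetic), and
    expected rates from :func:`expected_psi` (exhaustive enumeration with the
    production classifier).
    """
    truth_rates = expected_psi(t, p)
    blocks = isoform_blocks(t)
    rng = np.random.default_rng(p.seed)
    window = 50  # toy locus default window; labels use the same default config
    overhang = 1

    n_units = p.n_reads // 2 if p.paired else p.n_reads
    iso_idx = rng.choice(3, size=n_units,
                         p=np.asarray(p.mixture) / sum(p.mixture))
    entries: List[Tuple[AlignmentRecord, ReadTruth]] = []
    unit = 0
    for k, iso in enumerate(ISOFORMS):
        sel = np.nonzero(iso_idx == k)[0]
        if len(sel) == 0:
            continue
        L = transcript_length(blocks[iso])
        if p.read_len > L:
            raise ContractError(
                f"read_len {p.read_len} exceeds {iso} transcript length {L}"
            )
        if p.paired:
            lengths, w = _fragment_length_weights(L, p)
            fls = rng.choice(lengths, size=len(sel), p=w)
            starts = rng.integers(0, L - fls + 1)
        else:
            fls = np.full(len(sel), p.read_len)
            starts = rng.integers(0, L - p.read_len + 1, size=len(sel))
        for fl, s in zip(fls.tolist(), starts.tolist()):
            name = f"frag{unit:07d}"
            unit += 1
            if p.paired:
                s2 = s + fl - p.read_len
                pos1, cig1 = _project(blocks[iso], s, p.read_len)
                pos2, cig2 = _project(blocks[iso], s2, p.read_len)
                rec1 = AlignmentRecord(name, t.chromosome, pos1, cig1,
                                       flags=_MATE1_FLAGS, mapping_quality=255,
                                       next_reference_start=pos2,
                                       template_length=0)
                rec2 = AlignmentRecord(name, t.chromosome, pos2, cig2,
                                       flags=_MATE2_FLAGS, mapping_quality=255,
                                       next_reference_start=pos1,
                                       template_length=0)
                span_lo = min(pos1, pos2)
                span_hi = max(rec1.reference_end, rec2.reference_end)
                tlen = span_hi - span_lo
                rec1 = AlignmentRecord(name, t.chromosome, pos1, cig1,
                                       flags=_MATE1_FLAGS, mapping_quality=255,
                                       next_reference_start=pos2,
                                       template_length=tlen if pos1 <= pos2 else -tlen)
                rec2 = AlignmentRecord(name, t.chromosome, pos2, cig2,
                                       flags=_MATE2_FLAGS, mapping_quality=255,
                                       next_reference_start=pos1,
                                       template_length=-tlen if pos1 <= pos2 else tlen)
                entries.append((rec1, ReadTruth(name, 1, iso, s,
                                                _analytic_label(t, iso, s, p.read_len,
                                                                window, overhang))))
                entries.append((rec2, ReadTruth(name, 2, iso, s2,
                                                _analytic_label(t, iso, s2, p.read_len,
                                                                window, overhang))))
            else:
                pos1, cig1 = _project(blocks[iso], s, p.read_len)
                rec = AlignmentRecord(name, t.chromosome, pos1, cig1,
                                      flags=0, mapping_quality=255)
                entries.append((rec, ReadTruth(name, 0, iso, s,
                                               _analytic_label(t, iso, s, p.read_len,
                                                               window, overhang))))
    entries.sort(key=lambda e: (e[0].position, e[0].query_name, e[0].flags))
    records = [e[0] for e in entries]
    truth = SimulationTruth(
        reads=tuple(e[1] for e in entries),
        expected_junction_rate=truth_rates.expected_junction_rate,
        expected_intron_rate=truth_rates.expected_intron_rate,
        expected_cryptic_rate=truth_rates.expected_cryptic_rate,
        expected_unclassified_rate=truth_rates.expected_unclassified_rate,
        expected_psi=truth_rates.expected_psi,
    )
    return records, truth


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------

def _record_seq(rec: AlignmentRecord, reference: str) -> str:
    """SEQ field: reference bases under M/=/X; N placeholders for S/I bases."""
    parts: List[str] = []
    pos = rec.position
    for op, length in rec.cigar:
        if op in ("M", "=", "X"):
            parts.append(reference[pos:pos + length])
            pos += length
        elif op in ("D", "N"):
            pos += length
        elif op in ("S", "I"):
            parts.append("N" * length)
    return "".join(parts)


def write_sam(records: Sequence[AlignmentRecord], reference: str, path,
              chromosome: str, make_bam: bool = False) -> None:
    """Write a header-complete coordinate-sorted SAM (optionally BAM + index).

    Input must already be position-sorted; reading the file back through
    :func:`splicequant.alignments.read_alignments` reproduces the records.
    """
    positions = [r.position for r in records]
    if positions != sorted(positions):
        raise ContractError("write_sam requires records sorted by position")
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": chromosome, "LN": len(reference)}],
    })
    path = Path(path)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.query_name
            seg.flag = rec.flags
            seg.reference_id = 0
            seg.reference_start = rec.position
            seg.mapping_quality = rec.mapping_quality
            seg.cigarstring = cigar_to_string(rec.cigar)
            seq = _record_seq(rec, reference)
            seg.query_sequence = seq
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if rec.next_reference_start is not None:
                seg.next_reference_id = 0
                seg.next_reference_start = rec.next_reference_start
                seg.template_length = rec.template_length
            else:
                seg.next_reference_id = -1
            out.write(seg)
    if make_bam:
        bam_path = str(path.with_suffix(".bam"))
        pysam.sort("-o", bam_path, str(path))
        pysam.index(bam_path)


def write_reference_fasta(reference: str, chromosome: str, path,
                          width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chromosome}\n")
        for k in range(0, len(reference), width):
            fh.write(reference[k:k + width] + "\n")


def write_truth_tsv(truth: SimulationTruth, path) -> None:
    df = pd.DataFrame(
        [{"read_name": r.name, "mate": r.mate, "isoform": r.isoform,
          "transcript_start": r.transcript_start,
          "expected_category": r.expected_category.value}
         for r in truth.reads],
        columns=["read_name", "mate", "isoform", "transcript_start",
                 "expected_category"],
    )
    df.to_csv(path, sep="\t", index=False)
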