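"""Alignment record I/O, CIGAR arithmetic, and record-level filters.

SAM/BAM files are read through pysam; records are converted to the
lightweight :class:`AlignmentRecord` used throughout the package so that the
classifier, coverage and simulator operate on one plain container that can
also be constructed directly in code (the simulator does exactly that).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import pysam

from .errors import AlignmentInputError, CigarParseError, ContractError
from .locus import Interval, NormalizedLocus, chromosomes_match

__all__ = [
    "AlignmentRecord",
    "FilterConfig",
    "parse_cigar",
    "cigar_to_string",
    "aligned_blocks",
    "base_aligned_runs",
    "reference_span",
    "passes_filters",
    "read_alignments",
]

# SAM flag bits
FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_READ1 = 0x40
FLAG_READ2 = 0x80
FLAG_SECONDARY = 0x100
FLAG_QCFAIL = 0x200
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800

CIGAR_OPS = "MIDNSHP=X"
_REF_CONSUMING = frozenset("MDN=X")
_BASE_ALIGNED = frozenset("M=X")
# pysam integer op codes -> characters
_PYSAM_OPS = "MIDNSHP=XB"

Cigar = Tuple[Tuple[str, int], ...]

_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def parse_cigar(text: str) -> Cigar:
    """Parse a CIGAR string into an ordered ``((op, length), ...)`` tuple.

    ``"*"`` (unmapped convention) parses to the empty tuple.  Malformed input
    raises :class:`CigarParseError` carrying the offset of the bad token.
    """
    if text == "*":
        return ()
    ops: List[Tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _CIGAR_TOKEN.match(text, pos)
        if not m:
            raise CigarParseError(
                f"malformed CIGAR {text!r} at offset {pos}", offset=pos
            )
        length = int(m.group(1))
        if length < 1:
            raise CigarParseError(
                f"zero-length CIGAR operation in {text!r} at offset {pos}", offset=pos
            )
        ops.append((m.group(2), length))
        pos = m.end()
    if not ops:
        raise CigarParseError(f"empty CIGAR {text!r}", offset=0)
    return tuple(ops)


def cigar_to_string(cigar: Cigar) -> str:
    if not cigar:
        return "*"
    return "".join(f"{length}{op}" for op, length in cigar)


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment line: position, CIGAR, flags, mapping quality.

    ``position`` is the 0-based leftmost aligned reference coordinate.
    ``next_reference_start`` / ``template_length`` carry mate placement for
    SAM output and are optional.
    """

    query_name: str
    reference_name: str
    position: int
    cigar: Cigar
    flags: int = 0
    mapping_quality: int = 60
    next_reference_start: Optional[int] = None
    template_length: int = 0

    def __post_init__(self):
        if self.position < 0:
            raise ContractError(f"negative position {self.position}")
        if not (0 <= self.mapping_quality <= 255):
            raise ContractError(f"mapping quality {self.mapping_quality} outside 0-255")
        if not self.is_unmapped and not any(op in _REF_CONSUMING for op, _ in self.cigar):
            raise ContractError(
                f"mapped record {self.query_name!r} has a CIGAR consuming no reference bases"
            )

    # flag accessors --------------------------------------------------------
    @property
    def is_paired(self) -> bool:
        return bool(self.flags & FLAG_PAIRED)

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & FLAG_UNMAPPED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & FLAG_SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & FLAG_DUPLICATE)

    @property
    def is_qcfail(self) -> bool:
        return bool(self.flags & FLAG_QCFAIL)

    @property
    def reference_end(self) -> int:
        """One past the last reference base consumed by the alignment."""
        return self.position + sum(
            length for op, length in self.cigar if op in _REF_CONSUMING
        )


@dataclass(frozen=True)
class FilterConfig:
    """Record-level filters applied before classification and coverage.

    Defaults are deliberately permissive (no MAPQ threshold, duplicates kept):
    the counting rules themselves define the analysis, and any read the
    aligner reported as primary is eligible.
    """

    min_mapping_quality: int = 0
    include_duplicates: bool = True
    include_secondary: bool = False
    include_supplementary: bool = False
    count_mode: str = "per_record"  # or "per_fragment"

    def __post_init__(self):
        if not (0 <= self.min_mapping_quality <= 255):
            raise ContractError(
                f"min_mapping_quality {self.min_mapping_quality} outside 0-255"
            )
        if self.count_mode not in ("per_record", "per_fragment"):
            raise ContractError(f"unknown count_mode {self.count_mode!r}")


def aligned_blocks(rec: AlignmentRecord) -> List[Interval]:
    """Maximal reference intervals of base-aligned ops (M/=/X), D merged, N split.

    Soft/hard clips and insertions consume no reference and are ignored.
    """
    if rec.is_unmapped:
        raise ContractError("aligned_blocks requires a mapped record")
    blocks: List[Interval] = []
    pos = rec.position
    block_start: Optional[int] = None
    for op, length in rec.cigar:
        if op in _BASE_ALIGNED:
            if block_start is None:
                block_start = pos
            pos += length
        elif op == "D":
            # deletion: reference consumed inside the enclosing block
            if block_start is None:
                block_start = pos
            pos += length
        elif op == "N":
            if block_start is not None:
                blocks.append(Interval(block_start, pos))
                block_start = None
            pos += length
        # I, S, H, P consume no reference
    if block_start is not None:
        blocks.append(Interval(block_start, pos))
    return blocks


def base_aligned_runs(rec: AlignmentRecord) -> List[Interval]:
    """Reference intervals of M/=/X bases only (D and N excluded) — coverage units."""
    if rec.is_unmapped:
        raise ContractError("base_aligned_runs requires a mapped record")
    runs: List[Interval] = []
    pos = rec.position
    run_start: Optional[int] = None
    for op, length in rec.cigar:
        if op in _BASE_ALIGNED:
            if run_start is None:
                run_start = pos
            pos += length
        else:
            if run_start is not None:
                runs.append(Interval(run_start, pos))
                run_start = None
            if op in ("D", "N"):
                pos += length
    if run_start is not None:
        runs.append(Interval(run_start, pos))
    return runs


def reference_span(rec: AlignmentRecord) -> Interval:
    """Full reference span including N skips — the overlap unit of region queries."""
    return Interval(rec.position, rec.reference_end)


def passes_filters(rec: AlignmentRecord, f: FilterConfig) -> bool:
    """True iff the record survives the configured record-level filters."""
    if rec.is_unmapped or rec.is_qcfail:
        return False
    if rec.is_secondary and not f.include_secondary:
        return False
    if rec.is_supplementary and not f.include_supplementary:
        return False
    if rec.is_duplicate and not f.include_duplicates:
        return False
    return rec.mapping_quality >= f.min_mapping_quality


def _from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cig: Cigar = ()
    if seg.cigartuples:
        cig = tuple((_PYSAM_OPS[op], length) for op, length in seg.cigartuples)
    return AlignmentRecord(
        query_name=seg.query_name or "",
        reference_name=seg.reference_name or "",
        position=max(0, seg.reference_start if seg.reference_start is not None else 0),
        cigar=cig,
        flags=seg.flag,
        mapping_quality=seg.mapping_quality,
        next_reference_start=(
            seg.next_reference_start if seg.next_reference_start is not None
            and seg.next_reference_start >= 0 else None
        ),
        template_length=seg.template_length or 0,
    )


def _resolve_chromosome(references: Sequence[str], chromosome: str,
                        strict: bool = False) -> str:
    for name in references:
        if chromosomes_match(name, chromosome, strict=strict):
            return name
    raise AlignmentInputError(
        f"chromosome {chromosome!r} not found in alignment file; "
        f"available: {', '.join(references) or '(none)'}"
    )


def read_alignments(path, region: Optional[NormalizedLocus] = None,
                    strict_chrom: bool = False) -> Iterator[AlignmentRecord]:
    """Yield mapped records whose reference span overlaps ``region.analysis_region``.

    ``region=None`` yields every mapped record in the file (used for
    round-trip checks).  BAM input uses the index for the region query and
    raises a helpful error when the index is missing; SAM input is scanned
    linearly.  Overlap is judged on the full reference span, so a read whose
    only overlap with the region is via an N skip is still yielded.
    """
    p = Path(path)
    if not p.exists():
        raise AlignmentInputError(f"alignment file not found: {p}")
    is_sam = p.suffix.lower() == ".sam"
    mode = "r" if is_sam else "rb"
    with pysam.AlignmentFile(str(p), mode) as af:
        if region is None:
            for seg in af.fetch(until_eof=True):
                if not seg.is_unmapped:
                    yield _from_pysam(seg)
            return
        chrom = _resolve_chromosome(list(af.references), region.chromosome,
                                    strict=strict_chrom)
        start, end = region.analysis_region.start, region.analysis_region.end
        if is_sam:
            for seg in af.fetch(until_eof=True):
                if seg.is_unmapped or seg.reference_name != chrom:
                    continue
                if seg.reference_start < end and seg.reference_end > start:
                    yield _from_pysam(seg)
        else:
            try:
                iterator = af.fetch(chrom, start, end)
            except ValueError as exc:
                raise AlignmentInputError(
                    f"{p}: region query failed — is the file coordinate-sorted and "
                    f"indexed? (run 'samtools index {p}')"
                ) from exc
            for seg in iterator:
                if not seg.is_unmapped:
                    yield _from_pysam(seg)
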