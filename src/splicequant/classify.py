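"""Read classification at a two-exon splicing event.

Each filtered alignment overlapping the locus is assigned exactly one
category by the first matching rule, evaluated in order:

1. ``canonical_junction`` — some N skip matches the intron.  In ``windowed``
   mode (default) both skip edges must fall within ``window_bp`` of the donor
   and acceptor sites respectively; in ``exact`` mode the skip must equal the
   intron interval.  At least ``min_overhang_bp`` aligned bases are required
   on each side of the matching skip.
2. ``cryptic_junction`` — some N skip starts within ``window_bp`` of the
   donor but ends strictly inside the intron, beyond the acceptor window:
   the split-read signature of an exon1→pseudo-exon junction (the
   *FMR1-217*-type event), with the same overhang requirement.
3. ``intron_contained`` — no N operation, and every aligned block lies fully
   within the intron: an intron-retention read.
4. ``unclassified`` — anything else (e.g. a read straddling the exon/intron
   boundary without a skip, or a read confined to an exon).

Junction categories are checked before containment, so a spliced read can
never count as intron-contained, keeping the two informative read
definitions disjoint.  Percent-spliced-in uses only categories 1 and 3;
cryptic-junction reads are reported separately (see
:mod:`splicequant.metrics`).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .alignments import (
    AlignmentRecord,
    FilterConfig,
    aligned_blocks,
    passes_filters,
)
from .errors import ContractError
from .locus import Interval, NormalizedLocus

__all__ = [
    "Category",
    "ClassifierConfig",
    "ReadClassCounts",
    "skipped_intervals",
    "skips_with_overhangs",
    "classify_read",
    "count_reads",
    "counts_to_frame",
    "write_counts_tsv",
    "read_counts_tsv",
]

_BASE_ALIGNED = frozenset("M=X")


class Category(str, Enum):
    CANONICAL_JUNCTION = "canonical_junction"
    CRYPTIC_JUNCTION = "cryptic_junction"
    INTRON_CONTAINED = "intron_contained"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassifierConfig:
    """Junction matching mode, window and overhang for classification.

    ``window_bp=None`` inherits the window from the locus configuration.
    """

    junction_match: str = "windowed"  # or "exact"
    min_overhang_bp: int = 1
    window_bp: Optional[int] = None

    def __post_init__(self):
        if self.junction_match not in ("windowed", "exact"):
            raise ContractError(f"unknown junction_match {self.junction_match!r}")
        if self.min_overhang_bp < 1:
            raise ContractError("min_overhang_bp must be >= 1")
        if self.window_bp is not None and self.window_bp < 0:
            raise ContractError("window_bp must be >= 0")


@dataclass(frozen=True)
class ReadClassCounts:
    """Per-sample category tallies; the conservation invariant is enforced."""

    sample_id: str
    canonical_junction: int = 0
    cryptic_junction: int = 0
    intron_contained: int = 0
    unclassified: int = 0

    def __post_init__(self):
        for name in ("canonical_junction", "cryptic_junction",
                     "intron_contained", "unclassified"):
            if getattr(self, name) < 0:
                raise ContractError(f"negative count for {name}")

    @property
    def total(self) -> int:
        return (self.canonical_junction + self.cryptic_junction
                + self.intron_contained + self.unclassified)

    def __add__(self, other: "ReadClassCounts") -> "ReadClassCounts":
        return ReadClassCounts(
            sample_id=self.sample_id,
            canonical_junction=self.canonical_junction + other.canonical_junction,
            cryptic_junction=self.cryptic_junction + other.cryptic_junction,
            intron_contained=self.intron_contained + other.intron_contained,
            unclassified=self.unclassified + other.unclassified,
        )


def skipped_intervals(rec: AlignmentRecord) -> List[Interval]:
    """Reference intervals skipped by N operations, in genomic order."""
    if rec.is_unmapped:
        raise ContractError("skipped_intervals requires a mapped record")
    out: List[Interval] = []
    pos = rec.position
    for op, length in rec.cigar:
        if op == "N":
            out.append(Interval(pos, pos + length))
            pos += length
        elif op in _BASE_ALIGNED or op == "D":
            pos += length
    return out


def skips_with_overhangs(rec: AlignmentRecord) -> List[Tuple[Interval, int, int]]:
    """Each N skip with the number of aligned (M/=/X) bases before and after it."""
    if rec.is_unmapped:
        raise ContractError("skips_with_overhangs requires a mapped record")
    aligned_len = [0]
    skips: List[Tuple[Interval, int]] = []  # (interval, aligned bases before)
    pos = rec.position
    for op, length in rec.cigar:
        if op in _BASE_ALIGNED:
            aligned_len[0] += length
            pos += length
        elif op == "D":
            pos += length
        elif op == "N":
            skips.append((Interval(pos, pos + length), aligned_len[0]))
            pos += length
    total = aligned_len[0]
    return [(iv, before, total - before) for iv, before in skips]


def _window_bp(locus: NormalizedLocus, cfg: ClassifierConfig) -> int:
    return locus.window_bp if cfg.window_bp is None else cfg.window_bp


def classify_read(rec: AlignmentRecord, locus: NormalizedLocus,
                  cfg: ClassifierConfig = ClassifierConfig()) -> Category:
    """Assign one category to a mapped record overlapping the locus.

    Pure function of ``(record, locus, config)``; see module docstring for
    the rule order.
    """
    if rec.is_unmapped:
        raise ContractError("classify_read requires a mapped record")
    donor = locus.donor_site
    acceptor = locus.acceptor_site
    w = _window_bp(locus, cfg)
    oh = cfg.min_overhang_bp
    skips = skips_with_overhangs(rec)

    # rule 1: canonical junction
    for iv, before, after in skips:
        if before < oh or after < oh:
            continue
        if cfg.junction_match == "exact":
            if iv.start == donor and iv.end == acceptor:
                return Category.CANONICAL_JUNCTION
        else:
            if abs(iv.start - donor) <= w and abs(iv.end - acceptor) <= w:
                return Category.CANONICAL_JUNCTION

    # rule 2: cryptic junction (exon1 donor -> acceptor inside the intron)
    for iv, before, after in skips:
        if before < oh or after < oh:
            continue
        if abs(iv.start - donor) <= w and donor < iv.end < acceptor - w:
            return Category.CRYPTIC_JUNCTION

    # rule 3: intron containment (no skip at all)
    if not skips:
        blocks = aligned_blocks(rec)
        if blocks and all(locus.intron.contains_interval(b) for b in blocks):
            return Category.INTRON_CONTAINED

    return Category.UNCLASSIFIED


def _fragment_category(labels: Sequence[Category]) -> Category:
    """Collapse mate labels to one fragment label.

    Consensus over informative (non-unclassified) mate labels; conflicting
    informative labels resolve to unclassified.
    """
    informative = {c for c in labels if c is not Category.UNCLASSIFIED}
    if not informative:
        return Category.UNCLASSIFIED
    if len(informative) == 1:
        return next(iter(informative))
    return Category.UNCLASSIFIED


def count_reads(records: Iterable[AlignmentRecord], locus: NormalizedLocus,
                fcfg: FilterConfig = FilterConfig(),
                ccfg: ClassifierConfig = ClassifierConfig(),
                sample_id: str = "") -> ReadClassCounts:
    """Tally categories over a record stream (filters applied here).

    ``per_record`` mode counts every passing record; ``per_fragment`` mode
    counts each query name once, collapsing mate labels by informative
    consensus.  Records failing filters contribute nothing, including to the
    total.  An empty stream yields all-zero counts (the silenced-locus case).
    """
    tally: Dict[Category, int] = {c: 0 for c in Category}
    if fcfg.count_mode == "per_record":
        for rec in records:
            if not passes_filters(rec, fcfg):
                continue
            tally[classify_read(rec, locus, ccfg)] += 1
    else:
        by_name: Dict[str, List[Category]] = {}
        for rec in records:
            if not passes_filters(rec, fcfg):
                continue
            by_name.setdefault(rec.query_name, []).append(
                classify_read(rec, locus, ccfg)
            )
        for labels in by_name.values():
            tally[_fragment_category(labels)] += 1
    return ReadClassCounts(
        sample_id=sample_id,
        canonical_junction=tally[Category.CANONICAL_JUNCTION],
        cryptic_junction=tally[Category.CRYPTIC_JUNCTION],
        intron_contained=tally[Category.INTRON_CONTAINED],
        unclassified=tally[Category.UNCLASSIFIED],
    )


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["sample_id", "canonical_junction", "cryptic_junction",
                  "intron_contained", "unclassified", "total"]


def counts_to_frame(counts: Sequence[ReadClassCounts]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "canonical_junction": c.canonical_junction,
            "cryptic_junction": c.cryptic_junction,
            "intron_contained": c.intron_contained,
            "unclassified": c.unclassified,
            "total": c.total,
        }
        for c in counts
    ]
    return pd.DataFrame(rows, columns=_COUNT_COLUMNS)


def write_counts_tsv(counts: Sequence[ReadClassCounts], path) -> None:
    counts_to_frame(counts).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> List[ReadClassCounts]:
    df = pd.read_csv(path, sep="\t")
    return [
        ReadClassCounts(
            sample_id=str(row["sample_id"]),
            canonical_junction=int(row["canonical_junction"]),
            cryptic_junction=int(row["cryptic_junction"]),
            intron_contained=int(row["intron_contained"]),
            unclassified=int(row["unclassified"]),
        )
        for _, row in df.iterrows()
    ]
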