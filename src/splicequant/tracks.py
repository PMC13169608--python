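"""Per-base coverage tracks and sashimi-style junction count tables.

Coverage counts base-aligned CIGAR operations only (M/=/X): N-skipped,
deleted, and clipped bases contribute no depth.  Tracks can be scaled as a
pair by the single pair-wide maximum raw depth, the presentation used for
side-by-side condition panels.  Junction tables aggregate every N-derived
skip into (donor, acceptor, count) rows labelled canonical / cryptic / other
by the same window rules the classifier applies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .alignments import (
    AlignmentRecord,
    FilterConfig,
    base_aligned_runs,
    passes_filters,
)
from .classify import ClassifierConfig
from .errors import ContractError
from .locus import Interval, NormalizedLocus

__all__ = [
    "CoverageTrack",
    "JunctionRow",
    "JunctionTable",
    "compute_coverage",
    "scale_pair",
    "junction_counts",
    "write_bedgraph",
    "junctions_to_frame",
    "write_junction_tsv",
    "write_junction_bed",
]


@dataclass(frozen=True)
class CoverageTrack:
    """Per-base depth over a region; ``scaled`` tracks hold values in [0, 1]."""

    sample_id: str
    chromosome: str
    region: Interval
    depth: np.ndarray
    scaled: bool = False
    scale_factor: Optional[float] = None

    def __post_init__(self):
        if len(self.depth) != self.region.length:
            raise ContractError(
                f"depth length {len(self.depth)} != region length {self.region.length}"
            )

    @property
    def max_depth(self) -> float:
        return float(self.depth.max()) if len(self.depth) else 0.0


def compute_coverage(records: Iterable[AlignmentRecord], region: Interval,
                     fcfg: FilterConfig = FilterConfig(),
                     sample_id: str = "", chromosome: str = "") -> CoverageTrack:
    """Depth[x] = number of filtered records with an aligned base at x."""
    depth = np.zeros(region.length, dtype=np.int64)
    r0, r1 = region.start, region.end
    for rec in records:
        if not passes_filters(rec, fcfg):
            continue
        for run in base_aligned_runs(rec):
            lo, hi = max(run.start, r0), min(run.end, r1)
            if lo < hi:
                depth[lo - r0:hi - r0] += 1
    return CoverageTrack(sample_id=sample_id, chromosome=chromosome,
                         region=region, depth=depth)


def scale_pair(a: CoverageTrack, b: CoverageTrack) -> Tuple[CoverageTrack, CoverageTrack]:
    """Scale both tracks by the single pair-wide maximum raw depth.

    If the pair maximum is 0 (both tracks empty) the tracks are returned
    unscaled with ``scaled=False`` so the degenerate case stays visible.
    """
    if a.region != b.region:
        raise ContractError(
            f"scale_pair requires matching regions, got "
            f"[{a.region.start},{a.region.end}) and [{b.region.start},{b.region.end})"
        )
    pair_max = max(a.max_depth, b.max_depth)
    if pair_max == 0:
        return (replace(a, scaled=False, scale_factor=None),
                replace(b, scaled=False, scale_factor=None))
    return (
        replace(a, depth=a.depth / pair_max, scaled=True, scale_factor=pair_max),
        replace(b, depth=b.depth / pair_max, scaled=True, scale_factor=pair_max),
    )


@dataclass(frozen=True)
class JunctionRow:
    donor: int      # 0-based first skipped base
    acceptor: int   # 0-based one past the last skipped base
    read_count: int
    label: str      # canonical | cryptic | other


@dataclass(frozen=True)
class JunctionTable:
    sample_id: str
    chromosome: str
    rows: Tuple[JunctionRow, ...]

    @property
    def total_count(self) -> int:
        return sum(r.read_count for r in self.rows)


def _skip_label(start: int, end: int, locus: NormalizedLocus, window: int) -> str:
    donor, acceptor = locus.donor_site, locus.acceptor_site
    if abs(start - donor) <= window and abs(end - acceptor) <= window:
        return "canonical"
    if abs(start - donor) <= window and donor < end < acceptor - window:
        return "cryptic"
    return "other"


def junction_counts(records: Iterable[AlignmentRecord], locus: NormalizedLocus,
                    fcfg: FilterConfig = FilterConfig(),
                    ccfg: ClassifierConfig = ClassifierConfig(),
                    sample_id: str = "") -> JunctionTable:
    """Aggregate every N skip of every filtered record into labelled rows."""
    from .classify import skipped_intervals  # local to avoid cycle at import time

    window = locus.window_bp if ccfg.window_bp is None else ccfg.window_bp
    tally: dict = {}
    for rec in records:
        if not passes_filters(rec, fcfg):
            continue
        for iv in skipped_intervals(rec):
            tally[(iv.start, iv.end)] = tally.get((iv.start, iv.end), 0) + 1
    rows = tuple(
        JunctionRow(donor=s, acceptor=e, read_count=c,
                    label=_skip_label(s, e, locus, window))
        for (s, e), c in sorted(tally.items())
    )
    return JunctionTable(sample_id=sample_id, chromosome=locus.chromosome, rows=rows)


# ---------------------------------------------------------------------------
# Writers (genome-browser-ready text formats)
# ---------------------------------------------------------------------------

def _format_depth(v) -> str:
    f = float(v)
    if f == int(f):
        return str(int(f))
    return f"{f:.6g}"


def write_bedgraph(track: CoverageTrack, path, track_name: Optional[str] = None) -> None:
    """Run-length merged bedGraph (0-based half-open); zero-depth runs omitted."""
    lines: List[str] = []
    name = track_name or track.sample_id or "coverage"
    lines.append(f'track type=bedGraph name="{name}"')
    depth = np.asarray(track.depth)
    if len(depth):
        change = np.nonzero(np.diff(depth))[0] + 1
        bounds = np.concatenate(([0], change, [len(depth)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            v = depth[lo]
            if v == 0:
                continue
            lines.append(
                f"{track.chromosome}\t{track.region.start + lo}"
                f"\t{track.region.start + hi}\t{_format_depth(v)}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def junctions_to_frame(table: JunctionTable) -> pd.DataFrame:
    rows = [
        {"chrom": table.chromosome, "donor": r.donor, "acceptor": r.acceptor,
         "count": r.read_count, "label": r.label}
        for r in table.rows
    ]
    return pd.DataFrame(rows, columns=["chrom", "donor", "acceptor", "count", "label"])


def write_junction_tsv(table: JunctionTable, path) -> None:
    junctions_to_frame(table).to_csv(path, sep="\t", index=False)


def write_junction_bed(table: JunctionTable, path, anchor: int = 1) -> None:
    """BED12 rows with two ``anchor``-bp blocks flanking each junction.

    The convention mirrors aligner junction BED output: the feature spans
    from one base before the donor to one base after the acceptor, the score
    is the supporting read count.
    """
    lines = []
    for idx, r in enumerate(table.rows):
        start, end = r.donor - anchor, r.acceptor + anchor
        if start < 0:
            continue
        block_sizes = f"{anchor},{anchor}"
        block_starts = f"0,{r.acceptor - start}"
        lines.append("\t".join(map(str, [
            table.chromosome, start, end, f"{r.label}_{idx}", r.read_count, ".",
            start, end, "0,0,0", 2, block_sizes, block_starts,
        ])))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
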