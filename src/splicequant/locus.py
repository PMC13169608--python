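"""Locus model: the genomic coordinates of a two-exon splicing event.

A locus is configured in 1-based inclusive coordinates, the convention of SAM
headers, genome browsers, and printed genomic intervals, so published
coordinates can be pasted directly into a config file.  All internal
arithmetic uses 0-based half-open intervals, which make overlap and length
computations uniform.  :func:`normalize_locus` performs the conversion;
:func:`denormalize_locus` inverts it exactly.

The canonical use case is intron 1 of human *FMR1* (GRCh38
chrX:147,912,230-147,921,932), whose retention and internal pseudo-exon give
rise to the truncated *FMR1-217* isoform, but any exon-intron-exon triplet can
be configured.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

from .errors import ConfigError, LocusValidationError

__all__ = [
    "Interval",
    "LocusConfig",
    "NormalizedLocus",
    "load_locus_config",
    "parse_locus_config",
    "normalize_locus",
    "denormalize_locus",
    "chromosomes_match",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise LocusValidationError(
                f"invalid interval [{self.start}, {self.end}): "
                "require 0 <= start <= end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


#: 1-based inclusive interval as it appears in configs: (start, end).
Interval1 = Tuple[int, int]


def _check_interval1(name: str, iv: Interval1) -> None:
    start, end = iv
    if start < 1 or end < start:
        raise LocusValidationError(
            f"{name}: invalid 1-based interval {start}-{end} (require 1 <= start <= end)"
        )


@dataclass(frozen=True)
class LocusConfig:
    """A validated two-exon splicing event in 1-based inclusive coordinates.

    ``exon1``, ``intron1`` and ``exon2`` must be contiguous:
    ``exon1.end + 1 == intron1.start`` and ``intron1.end + 1 == exon2.start``.
    ``window_bp`` is the half-width of the window around each splice site
    within which a spliced read's skip edge is accepted as matching that site.
    """

    locus_name: str
    chromosome: str
    exon1: Interval1
    intron1: Interval1
    exon2: Interval1
    window_bp: int = 50
    transcript_region: Optional[Interval1] = None
    strand: Optional[str] = None  # recorded, not used by the counting rules

    def __post_init__(self):
        for name, iv in (("exon1", self.exon1), ("intron1", self.intron1),
                         ("exon2", self.exon2)):
            _check_interval1(name, iv)
        if self.window_bp < 1:
            raise LocusValidationError(
                f"window_bp must be >= 1, got {self.window_bp}"
            )
        if self.exon1[1] + 1 != self.intron1[0]:
            raise LocusValidationError(
                "exon1 and intron1 are not contiguous: "
                f"exon1 ends at {self.exon1[1]} but intron1 starts at {self.intron1[0]}"
            )
        if self.intron1[1] + 1 != self.exon2[0]:
            raise LocusValidationError(
                "intron1 and exon2 are not contiguous: "
                f"intron1 ends at {self.intron1[1]} but exon2 starts at {self.exon2[0]}"
            )
        if self.strand not in (None, "+", "-"):
            raise LocusValidationError(f"strand must be '+', '-' or absent, got {self.strand!r}")
        if self.transcript_region is not None:
            _check_interval1("transcript_region", self.transcript_region)
            tr = self.transcript_region
            for name, iv in (("exon1", self.exon1), ("intron1", self.intron1)):
                if tr[1] < iv[0] or iv[1] < tr[0]:
                    raise LocusValidationError(
                        f"transcript_region {tr[0]}-{tr[1]} does not overlap {name} "
                        f"{iv[0]}-{iv[1]}"
                    )

    @property
    def intron_length(self) -> int:
        return self.intron1[1] - self.intron1[0] + 1


@dataclass(frozen=True)
class NormalizedLocus:
    """Internal 0-based half-open view of a :class:`LocusConfig`.

    ``donor_site`` is the coordinate of the first intronic base and
    ``acceptor_site`` one past the last intronic base, so that
    ``acceptor_site - donor_site`` equals the intron length and a canonical
    spliced read carries an N skip exactly equal to ``intron``.
    ``analysis_region`` is the exon1..exon2 span padded by ``window_bp`` on
    each side; reads outside it are irrelevant to the event.
    """

    chromosome: str
    exon1: Interval
    intron: Interval
    exon2: Interval
    window_bp: int
    analysis_region: Interval
    transcript_region: Optional[Interval] = None
    strand: Optional[str] = None
    locus_name: str = ""

    @property
    def donor_site(self) -> int:
        return self.intron.start

    @property
    def acceptor_site(self) -> int:
        return self.intron.end


def _to0(iv: Interval1) -> Interval:
    return Interval(iv[0] - 1, iv[1])


def _to1(iv: Interval) -> Interval1:
    return (iv.start + 1, iv.end)


def normalize_locus(cfg: LocusConfig) -> NormalizedLocus:
    """Convert a validated config to 0-based half-open internal coordinates."""
    exon1, intron, exon2 = _to0(cfg.exon1), _to0(cfg.intron1), _to0(cfg.exon2)
    pad = cfg.window_bp
    analysis = Interval(max(0, exon1.start - pad), exon2.end + pad)
    return NormalizedLocus(
        chromosome=cfg.chromosome,
        exon1=exon1,
        intron=intron,
        exon2=exon2,
        window_bp=cfg.window_bp,
        analysis_region=analysis,
        transcript_region=None if cfg.transcript_region is None else _to0(cfg.transcript_region),
        strand=cfg.strand,
        locus_name=cfg.locus_name,
    )


def denormalize_locus(locus: NormalizedLocus) -> LocusConfig:
    """Exact inverse of :func:`normalize_locus` (round-trip guaranteed)."""
    return LocusConfig(
        locus_name=locus.locus_name,
        chromosome=locus.chromosome,
        exon1=_to1(locus.exon1),
        intron1=_to1(locus.intron),
        exon2=_to1(locus.exon2),
        window_bp=locus.window_bp,
        transcript_region=None if locus.transcript_region is None else _to1(locus.transcript_region),
        strand=locus.strand,
    )


def chromosomes_match(a: str, b: str, strict: bool = False) -> bool:
    """Compare chromosome names across reference dialects.

    GRCh38 references circulate both with and without the ``chr`` prefix;
    unless ``strict``, the prefix is stripped before comparison.
    """
    if strict:
        return a == b
    return a.removeprefix("chr") == b.removeprefix("chr")


# ---------------------------------------------------------------------------
# Config file parsing.  Dialect: flat "key = value" lines, '#' comments,
# intervals written "start-end" in 1-based inclusive coordinates (commas in
# numbers are tolerated so printed coordinates paste cleanly).
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("locus_name", "chromosome", "exon1", "intron1", "exon2")
_KNOWN_KEYS = _REQUIRED_KEYS + ("window_bp", "transcript_region", "strand")

_INTERVAL_RE = re.compile(r"^(\d+)\s*-\s*(\d+)$")


def _parse_interval(key: str, raw: str) -> Interval1:
    m = _INTERVAL_RE.match(raw.replace(",", "").strip())
    if not m:
        raise ConfigError(f"{key}: expected an interval 'start-end', got {raw!r}")
    return (int(m.group(1)), int(m.group(2)))


def parse_locus_config(text: str, source: str = "<string>") -> LocusConfig:
    """Parse the flat key-value locus config dialect (see module docstring)."""
    values = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{source}:{lineno}: expected 'key = value', got {line!r}")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"{source}:{lineno}: unknown key {key!r}")
        values[key] = raw
    for key in _REQUIRED_KEYS:
        if key not in values:
            raise ConfigError(f"{source}: missing required field {key!r}")
    kwargs = {
        "locus_name": values["locus_name"],
        "chromosome": values["chromosome"],
        "exon1": _parse_interval("exon1", values["exon1"]),
        "intron1": _parse_interval("intron1", values["intron1"]),
        "exon2": _parse_interval("exon2", values["exon2"]),
    }
    if "window_bp" in values:
        try:
            kwargs["window_bp"] = int(values["window_bp"])
        except ValueError as exc:
            raise ConfigError(f"{source}: window_bp must be an integer") from exc
    if "transcript_region" in values:
        kwargs["transcript_region"] = _parse_interval(
            "transcript_region", values["transcript_region"]
        )
    if "strand" in values:
        kwargs["strand"] = values["strand"]
    return LocusConfig(**kwargs)


def load_locus_config(path) -> LocusConfig:
    """Read and validate a locus config file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"locus config not found: {p}")
    return parse_locus_config(p.read_text(), source=str(p))


def with_window(cfg: LocusConfig, window_bp: int) -> LocusConfig:
    """Return a copy of ``cfg`` with a different junction window."""
    return replace(cfg, window_bp=window_bp)
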