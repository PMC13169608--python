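"""Shared fixtures: toy locus, hand-labelled reads, independent oracles."""

import re

import pytest
from hypothesis import HealthCheck, settings

from splicequant.alignments import AlignmentRecord, parse_cigar
from splicequant.classify import Category
from splicequant.locus import normalize_locus
from splicequant.simulate import ToyLocus, build_toy_locus

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy():
    """Default toy locus: exon1 500, intron 2000, exon2 500, pseudo-exon [100,400)."""
    return ToyLocus()


@pytest.fixture(scope="session")
def toy_cfg(toy):
    _, cfg = build_toy_locus(toy)
    return cfg


@pytest.fixture(scope="session")
def toy_ref(toy):
    ref, _ = build_toy_locus(toy)
    return ref


@pytest.fixture(scope="session")
def toy_locus(toy_cfg):
    # 0-based: exon1 [1000,1500), intron [1500,3500), exon2 [3500,4000)
    return normalize_locus(toy_cfg)


def make_record(pos, cigar, name="r", flags=0, mapq=60, chrom="chrT"):
    return AlignmentRecord(query_name=name, reference_name=chrom, position=pos,
                           cigar=parse_cigar(cigar), flags=flags,
                           mapping_quality=mapq)


# ---------------------------------------------------------------------------
# Independent brute-force classifier: rasterize aligned/skipped bases from the
# CIGAR text itself and apply the category rules by set arithmetic.  Shares no
# code with the production classifier.
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def brute_force_classify(pos, cigar_text, donor, acceptor, window, overhang=1,
                         exact=False):
    block_bases = set()   # M/=/X/D positions (containment unit)
    skips = []            # (start, end, aligned-before, aligned-after)
    aligned_so_far = 0
    cursor = pos
    raw = [(int(m.group(1)), m.group(2)) for m in _TOKEN.finditer(cigar_text)]
    for length, op in raw:
        if op in "M=X":
            block_bases.update(range(cursor, cursor + length))
            aligned_so_far += length
            cursor += length
        elif op == "D":
            block_bases.update(range(cursor, cursor + length))
            cursor += length
        elif op == "N":
            skips.append([cursor, cursor + length, aligned_so_far, None])
            cursor += length
    total_aligned = aligned_so_far
    for s in skips:
        s[3] = total_aligned - s[2]

    def edge_ok(s, e):
        if exact:
            return s == donor and e == acceptor
        return abs(s - donor) <= window and abs(e - acceptor) <= window

    for s, e, before, after in skips:
        if before >= overhang and after >= overhang and edge_ok(s, e):
            return Category.CANONICAL_JUNCTION
    for s, e, before, after in skips:
        if (before >= overhang and after >= overhang
                and abs(s - donor) <= window and donor < e < acceptor - window):
            return Category.CRYPTIC_JUNCTION
    if not skips and block_bases and all(
            donor <= x < acceptor for x in block_bases):
        return Category.INTRON_CONTAINED
    return Category.UNCLASSIFIED


# ---------------------------------------------------------------------------
# Hand-labelled 50-record truth table over the toy locus
# (donor = 1500, acceptor = 3500, window = 50, min overhang = 1).
# Labels were assigned by hand from the category rules; the acceptance test
# additionally re-derives every label with brute_force_classify.
# ---------------------------------------------------------------------------

CANON = Category.CANONICAL_JUNCTION
CRYPT = Category.CRYPTIC_JUNCTION
INTRON = Category.INTRON_CONTAINED
OTHER = Category.UNCLASSIFIED

HAND_LABELLED = [
    # canonical junction: skip matches the intron within the window
    (1450, "50M2000N50M", CANON),       # exact intron skip
    (1499, "1M2000N149M", CANON),       # one-base overhang on the exon1 side
    (1351, "149M2000N1M", CANON),       # one-base overhang on the exon2 side
    (1400, "50M2050N100M", CANON),      # skip start at donor-50 (window edge)
    (1450, "100M1950N50M", CANON),      # skip start at donor+50 (window edge)
    (1400, "100M1950N50M", CANON),      # skip end at acceptor-50 (window edge)
    (1400, "100M2050N50M", CANON),      # skip end at acceptor+50 (window edge)
    (1300, "50M100N50M2000N50M", CANON),  # multi-N: second skip is the intron
    (1460, "40M2000N110M", CANON),      # asymmetric overhangs
    (1470, "30M2000N30M10I80M", CANON),  # insertion downstream of the skip
    (1450, "20S50M2000N50M30S", CANON),  # soft-clipped ends
    (1445, "55M1995N95M", CANON),       # 5-bp jitter on the acceptor edge
    # cryptic junction: donor-anchored skip ending inside the intron
    (1450, "50M100N50M", CRYPT),        # donor -> pseudo-exon start (offset 100)
    (1499, "1M100N149M", CRYPT),        # one-base overhang cryptic
    (1400, "100M200N50M", CRYPT),       # deeper acceptor (offset 200)
    (1450, "50M1949N50M", CRYPT),       # skip end at acceptor-51: just past window
    (1460, "40M110N110M", CRYPT),
    (1455, "50M95N105M", CRYPT),        # skip start at donor+5
    (1445, "50M110N100M", CRYPT),       # skip start at donor-5
    (1300, "100M50N50M100N50M", CRYPT),  # multi-N: only the second is cryptic
    # intron-contained: no skip, all aligned bases inside the intron
    (1500, "150M", INTRON),             # starts exactly at the donor
    (3350, "150M", INTRON),             # ends exactly at the acceptor
    (2000, "150M", INTRON),
    (2000, "70M10D70M", INTRON),        # deletion merges into the block
    (2500, "10S140M", INTRON),          # soft clip consumes no reference
    (1700, "50M", INTRON),
    (3400, "100M", INTRON),
    (1600, "30M5I115M", INTRON),        # insertion consumes no reference
    (2200, "150M", INTRON),
    (3000, "150M", INTRON),
    # unclassified: everything else
    (1499, "150M", OTHER),              # one base in exon 1, no skip
    (3351, "150M", OTHER),              # last base beyond the acceptor
    (1420, "150M", OTHER),              # straddles the donor without a skip
    (1350, "150M", OTHER),              # ends exactly at the donor (all exon 1)
    (3500, "150M", OTHER),              # starts exactly at the acceptor (all exon 2)
    (960, "150M", OTHER),               # flank/exon1, inside the analysis window
    (1501, "50M100N50M", OTHER),        # skip start at donor+51: off-by-one outside
    (1399, "50M100N50M", OTHER),        # skip start at donor-51: off-by-one outside
    (1400, "100M2051N50M", OTHER),      # skip end at acceptor+51: off-by-one outside
    (1349, "100M2051N50M", OTHER),      # donor edge off by 51, acceptor edge exact
    (2000, "50M50N50M", OTHER),         # intronic read with an internal skip
    (3550, "50M100N50M", OTHER),        # skip entirely within exon 2 territory
    (1000, "100M", OTHER),              # exon 1 only
    (1440, "60M", OTHER),               # exon 1 read ending at the donor
    (3450, "100M", OTHER),              # spans the acceptor without a skip
    (2900, "100M700N100M", OTHER),      # intron -> exon 2 skip (acceptor side only)
    (1200, "100M200N100M", OTHER),      # exon-1-internal skip ending at the donor
    (950, "50M", OTHER),                # entirely in the padded flank
    (2485, "15M1000N15M", OTHER),       # acceptor-anchored skip, donor edge off
    (4000, "50M", OTHER),               # distal exon 2
]


@pytest.fixture(scope="session")
def hand_labelled_records():
    return [
        (make_record(pos, cig, name=f"hand{i:02d}"), label)
        for i, (pos, cig, label) in enumerate(HAND_LABELLED)
    ]
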