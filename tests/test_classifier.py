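"""Read classification rules, counting, and oracle equivalence."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from splicequant.alignments import FLAG_QCFAIL, FLAG_SECONDARY, FilterConfig
from splicequant.classify import (
    Category,
    ClassifierConfig,
    ReadClassCounts,
    classify_read,
    count_reads,
    skipped_intervals,
)
from splicequant.errors import ContractError

from conftest import brute_force_classify, make_record


# --- skipped_intervals -----------------------------------------------------

@pytest.mark.parametrize("pos,cigar,expected", [
    (100, "50M1000N50M", [(150, 1150)]),
    (100, "100M", []),
    (0, "10M5N10M5N10M", [(10, 15), (25, 30)]),
])
def test_skipped_intervals(pos, cigar, expected):
    rec = make_record(pos, cigar)
    assert [(s.start, s.end) for s in skipped_intervals(rec)] == expected


# --- classify_read rule examples ------------------------------------------
# toy locus: donor = 1500, acceptor = 3500, intron length 2000, window 50

@pytest.mark.parametrize("pos,cigar,expected", [
    (1450, "50M2000N50M", Category.CANONICAL_JUNCTION),   # full intron skip
    (2000, "150M", Category.INTRON_CONTAINED),            # all bases intronic
    (1470, "30M120N120M", Category.CRYPTIC_JUNCTION),     # skip ends 120 bp in
    (1420, "150M", Category.UNCLASSIFIED),                # boundary, no skip
    (3600, "100M", Category.UNCLASSIFIED),                # exon 2 only
])
def test_classify_rule_examples(toy_locus, pos, cigar, expected):
    assert classify_read(make_record(pos, cigar), toy_locus) == expected


def test_hand_labelled_truth_table(toy_locus, hand_labelled_records):
    mismatches = [
        (rec.position, rec.cigar, expected.value, got.value)
        for rec, expected in hand_labelled_records
        if (got := classify_read(rec, toy_locus)) != expected
    ]
    assert mismatches == []


def test_unmapped_record_violates_contract(toy_locus):
    from splicequant.alignments import FLAG_UNMAPPED, AlignmentRecord
    rec = AlignmentRecord("u", "chrT", 0, (), flags=FLAG_UNMAPPED)
    with pytest.raises(ContractError):
        classify_read(rec, toy_locus)


def test_exact_mode_requires_exact_skip(toy_locus):
    jittered = make_record(1445, "55M1995N95M")   # 5 bp off the acceptor
    exact = ClassifierConfig(junction_match="exact")
    assert classify_read(jittered, toy_locus, exact) == Category.UNCLASSIFIED
    assert classify_read(jittered, toy_locus) == Category.CANONICAL_JUNCTION


def test_overhang_requirement(toy_locus):
    rec = make_record(1499, "1M2000N149M")
    assert classify_read(rec, toy_locus) == Category.CANONICAL_JUNCTION
    strict = ClassifierConfig(min_overhang_bp=5)
    assert classify_read(rec, toy_locus, strict) == Category.UNCLASSIFIED


# --- random-record oracle equivalence --------------------------------------

_segment = st.tuples(st.sampled_from(["N", "D", "I"]), st.integers(1, 2600))


@st.composite
def random_cigars(draw):
    """Alternating M blocks and N/D/I separators; optional soft clips."""
    parts = []
    if draw(st.booleans()):
        parts.append(("S", draw(st.integers(1, 30))))
    parts.append(("M", draw(st.integers(1, 200))))
    for _ in range(draw(st.integers(0, 3))):
        parts.append(draw(_segment))
        parts.append(("M", draw(st.integers(1, 200))))
    if draw(st.booleans()):
        parts.append(("S", draw(st.integers(1, 30))))
    return tuple(parts)


@given(pos=st.integers(950, 4050), cigar=random_cigars(),
       window=st.sampled_from([0, 10, 50]), overhang=st.integers(1, 10),
       exact=st.booleans())
def test_classifier_matches_base_set_oracle(toy_locus, pos, cigar, window,
                                            overhang, exact):
    """classify_read agrees with an independent rasterizing classifier."""
    from splicequant.alignments import cigar_to_string
    text = cigar_to_string(cigar)
    rec = make_record(pos, text)
    cfg = ClassifierConfig(junction_match="exact" if exact else "windowed",
                           min_overhang_bp=overhang, window_bp=window)
    got = classify_read(rec, toy_locus, cfg)
    expected = brute_force_classify(pos, text, toy_locus.donor_site,
                                    toy_locus.acceptor_site, window,
                                    overhang=overhang, exact=exact)
    if exact:
        # exact mode changes only the canonical rule; cryptic still windowed
        assert got == expected
    else:
        assert got == expected


@given(pos=st.integers(950, 4050), cigar=random_cigars(),
       window=st.integers(0, 80))
def test_exact_canonical_implies_windowed_canonical(toy_locus, pos, cigar, window):
    from splicequant.alignments import cigar_to_string
    rec = make_record(pos, cigar_to_string(cigar))
    exact = ClassifierConfig(junction_match="exact")
    windowed = ClassifierConfig(junction_match="windowed", window_bp=window)
    if classify_read(rec, toy_locus, exact) == Category.CANONICAL_JUNCTION:
        assert classify_read(rec, toy_locus, windowed) == Category.CANONICAL_JUNCTION


# --- counting --------------------------------------------------------------

def test_count_reads_tallies_and_conserves(toy_locus):
    recs = ([make_record(1450, "50M2000N50M", name=f"j{i}") for i in range(90)]
            + [make_record(2000, "150M", name=f"i{i}") for i in range(10)])
    counts = count_reads(recs, toy_locus, sample_id="s1")
    assert (counts.canonical_junction, counts.cryptic_junction,
            counts.intron_contained, counts.unclassified) == (90, 0, 10, 0)
    assert counts.total == 100


def test_empty_stream_gives_all_zero_counts(toy_locus):
    counts = count_reads([], toy_locus, sample_id="silenced")
    assert counts.total == 0
    assert counts == ReadClassCounts(sample_id="silenced")


def test_filtered_records_are_excluded_from_total(toy_locus):
    recs = [
        make_record(2000, "150M", name="keep"),
        make_record(2000, "150M", name="secondary", flags=FLAG_SECONDARY),
        make_record(2000, "150M", name="qcfail", flags=FLAG_QCFAIL),
        make_record(2000, "150M", name="lowmapq", mapq=2),
    ]
    counts = count_reads(recs, toy_locus,
                         FilterConfig(min_mapping_quality=10), sample_id="s")
    assert counts.intron_contained == 1
    assert counts.total == 1


def test_count_matches_hand_labels(toy_locus, hand_labelled_records):
    recs = [rec for rec, _ in hand_labelled_records]
    labels = [lab for _, lab in hand_labelled_records]
    counts = count_reads(recs, toy_locus, sample_id="fixture")
    assert counts.canonical_junction == labels.count(Category.CANONICAL_JUNCTION)
    assert counts.cryptic_junction == labels.count(Category.CRYPTIC_JUNCTION)
    assert counts.intron_contained == labels.count(Category.INTRON_CONTAINED)
    assert counts.unclassified == labels.count(Category.UNCLASSIFIED)
    assert counts.total == len(recs)


def test_per_fragment_mode_collapses_mates(toy_locus):
    from splicequant.alignments import FLAG_PAIRED, FLAG_READ1, FLAG_READ2
    f1, f2 = FLAG_PAIRED | FLAG_READ1, FLAG_PAIRED | FLAG_READ2
    recs = [
        # fragment a: junction mate + exonic mate -> canonical
        make_record(1450, "50M2000N50M", name="a", flags=f1),
        make_record(1300, "150M", name="a", flags=f2),
        # fragment b: both unclassified -> unclassified
        make_record(1300, "150M", name="b", flags=f1),
        make_record(1200, "150M", name="b", flags=f2),
        # fragment c: conflicting informative labels -> unclassified
        make_record(1450, "50M2000N50M", name="c", flags=f1),
        make_record(2000, "150M", name="c", flags=f2),
    ]
    fcfg = FilterConfig(count_mode="per_fragment")
    counts = count_reads(recs, toy_locus, fcfg, sample_id="s")
    assert counts.total == 3
    assert counts.canonical_junction == 1
    assert counts.unclassified == 2


def test_classification_is_deterministic(toy_locus, hand_labelled_records):
    once = [classify_read(r, toy_locus) for r, _ in hand_labelled_records]
    twice = [classify_read(r, toy_locus) for r, _ in hand_labelled_records]
    assert once == twice
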