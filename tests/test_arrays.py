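"""Unit tests for array detection and the orientation cascade."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rtcrispr.arrays import (
    CrisprArray,
    RepeatDB,
    detect_arrays,
    resolve_orientation,
    revcomp,
    score_orientation,
)
from rtcrispr.synth import ArraySpec, mutate_dna, random_dna

from .conftest import matching_array, planted_array_contig

REPEAT = "GTTTCAGACGAACCCTTGTAGGGTTGAAGC"  # 30 bp
dna = st.text(alphabet="ACGT", min_size=0, max_size=60)


@given(dna)
def test_revcomp_is_an_involution(seq):
    assert revcomp(revcomp(seq)) == seq


# --- detection -------------------------------------------------------------


def test_random_sequence_has_no_arrays():
    contig = random_dna(np.random.default_rng(0), 10_000)
    assert detect_arrays(contig) == []


def test_planted_array_detected_within_one_unit():
    spec = ArraySpec(repeat_seq=REPEAT, n_repeats=6, spacer_len_range=(35, 36))
    contig, start, end = planted_array_contig(spec, seed=1)
    arrays = detect_arrays(contig, "c")
    assert len(arrays) == 1
    assert matching_array(arrays, start, end) is not None
    assert arrays[0].n_repeats >= 5


def test_two_arrays_2kb_apart_are_not_merged():
    rng = np.random.default_rng(2)
    spec = ArraySpec(repeat_seq=REPEAT, n_repeats=5)
    c1, s1, e1 = planted_array_contig(spec, seed=3)
    gap = random_dna(rng, 2_000)
    c2, s2, e2 = planted_array_contig(spec, seed=4)
    contig = c1 + gap + c2
    offset = len(c1) + len(gap)
    arrays = detect_arrays(contig, "c")
    assert len(arrays) == 2
    assert matching_array(arrays, s1, e1) is not None
    assert matching_array(arrays, offset + s2, offset + e2) is not None


def test_detection_mirrors_under_reverse_complement():
    spec = ArraySpec(repeat_seq=REPEAT, n_repeats=6)
    contig, _s, _e = planted_array_contig(spec, seed=5)
    fwd = detect_arrays(contig, "c")
    rev = detect_arrays(revcomp(contig), "c")
    n = len(contig)
    mirrored = sorted((n - a.end + 1, n - a.start + 1) for a in rev)
    assert sorted((a.start, a.end) for a in fwd) == mirrored


def test_array_invariants_enforced():
    rep = ((1, 30), REPEAT)
    with pytest.raises(ValueError):
        CrisprArray("c", 1, 60, [rep, rep], [((31, 40), "A" * 10)], REPEAT)


# --- orientation scoring (criterion i) ------------------------------------


def test_strong_forward_signal_scores_h_band():
    spec = ArraySpec(
        repeat_seq=REPEAT, leader_at_enrichment=0.25, terminal_repeat_mutations=3
    )
    contig, s, e = planted_array_contig(spec, seed=6)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    orientation, band, score = score_orientation(arr, contig)
    assert (orientation, band) == ("forward", "H")
    assert score > 0


def test_strong_reverse_signal_scores_h_band():
    spec = ArraySpec(
        repeat_seq=REPEAT,
        orientation="reverse",
        leader_at_enrichment=0.25,
        terminal_repeat_mutations=3,
    )
    contig, s, e = planted_array_contig(spec, seed=7)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    orientation, band, _score = score_orientation(arr, contig)
    assert (orientation, band) == ("reverse", "H")


def test_short_flank_gives_na_band():
    spec = ArraySpec(repeat_seq=REPEAT, leader_at_enrichment=0.25)
    contig, s, e = planted_array_contig(spec, seed=8, left_pad=0, trim_leader=150)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    _o, band, _s2 = score_orientation(arr, contig)
    assert band == "NA"


def test_symmetric_array_never_scores_h():
    spec = ArraySpec(
        repeat_seq=REPEAT, leader_at_enrichment=0.0, terminal_repeat_mutations=0
    )
    contig, s, e = planted_array_contig(spec, seed=9)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    _o, band, _s2 = score_orientation(arr, contig)
    assert band in ("L", "M", "NA")


def test_score_orientation_rejects_out_of_bounds():
    spec = ArraySpec(repeat_seq=REPEAT)
    contig, s, e = planted_array_contig(spec, seed=10)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    with pytest.raises(ValueError):
        score_orientation(arr, contig[: arr.end - 10])


# --- the cascade (criteria i-iii) ------------------------------------------


def test_criterion_i_call_is_kept_and_not_downgraded(repeat_db):
    spec = ArraySpec(repeat_seq=REPEAT)
    contig, s, e = planted_array_contig(spec, seed=11)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    out = resolve_orientation(arr, contig, repeat_db, [])
    assert (out.orientation, out.criterion) == ("forward", "i")
    assert out.band in ("H", "M")
    again = resolve_orientation(out, contig, repeat_db, [])
    assert again == out


def test_criterion_ii_db_match_resolves_na_array(repeat_db):
    db_repeat = sorted(repeat_db.sequences())[0]
    # plant the reverse complement of a known repeat with no intrinsic signal
    spec = ArraySpec(
        repeat_seq=revcomp(db_repeat),
        leader_at_enrichment=0.0,
        terminal_repeat_mutations=0,
    )
    contig, s, e = planted_array_contig(spec, seed=12, left_pad=0, trim_leader=150)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    out = resolve_orientation(arr, contig, repeat_db, [])
    assert (out.orientation, out.criterion) == ("reverse", "ii")


def test_criterion_iii_inherits_from_group_member(repeat_db):
    # an oriented group member with a near-identical repeat
    member_spec = ArraySpec(repeat_seq=REPEAT)
    m_contig, ms, me = planted_array_contig(member_spec, seed=13)
    member = resolve_orientation(
        matching_array(detect_arrays(m_contig, "m"), ms, me), m_contig, repeat_db, []
    )
    assert member.criterion == "i"

    query_spec = ArraySpec(
        repeat_seq=mutate_dna(np.random.default_rng(14), REPEAT, 2),
        leader_at_enrichment=0.0,
        terminal_repeat_mutations=0,
    )
    contig, s, e = planted_array_contig(query_spec, seed=15, left_pad=0, trim_leader=150)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    out = resolve_orientation(arr, contig, repeat_db, [member])
    assert (out.orientation, out.criterion) == ("forward", "iii")


def test_cascade_exhaustion_leaves_undetermined(repeat_db):
    spec = ArraySpec(
        repeat_seq=REPEAT, leader_at_enrichment=0.0, terminal_repeat_mutations=0
    )
    contig, s, e = planted_array_contig(spec, seed=16, left_pad=0, trim_leader=150)
    arr = matching_array(detect_arrays(contig, "c"), s, e)
    out = resolve_orientation(arr, contig, repeat_db, [])
    assert (out.orientation, out.criterion) == ("undetermined", "none")


# --- RepeatDB --------------------------------------------------------------


def test_repeat_db_rejects_duplicates_and_bad_dna():
    with pytest.raises(ValueError):
        RepeatDB([("ACGT" * 6, "forward", "f1"), ("ACGT" * 6, "forward", "f2")])
    with pytest.raises(ValueError):
        RepeatDB([("acgtacgtacgtacgtacgt", "forward", "f1")])


def test_repeat_db_tsv_roundtrip(tmp_path, repeat_db):
    path = tmp_path / "db.tsv"
    lines = ["repeat\torientation\tfamily"] + [
        f"{s}\t{o}\t{f}" for s, o, f in repeat_db.entries
    ]
    path.write_text("\n".join(lines) + "\n")
    assert RepeatDB.from_tsv(path).entries == repeat_db.entries
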