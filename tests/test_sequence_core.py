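"""Sequence I/O, IUPAC algebra, alignment and site-calling behaviour."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faw_haplotyper.iupac import IUPAC_TO_STATES, decode, encode, merge_letters
from faw_haplotyper.sequence_core import (
    DEFAULT_SCORING,
    Alignment,
    AlignmentScoring,
    FastaParseError,
    MarkerSite,
    ReferenceAmplicon,
    SangerRead,
    SequenceValidationError,
    call_site,
    global_align,
    orient_read,
    read_fasta,
    read_reference,
    write_fasta,
    write_reference,
)

# ---------------------------------------------------------------------------
# IUPAC algebra
# ---------------------------------------------------------------------------

LETTERS = sorted(IUPAC_TO_STATES)


@given(st.sampled_from(LETTERS), st.sampled_from(LETTERS))
@settings(derandomize=True)
def test_merge_letters_is_state_set_union(a, b):
    assert decode(merge_letters(a, b)) == decode(a) | decode(b)
    assert merge_letters(a, b) == merge_letters(b, a)


def test_encode_decode_roundtrip():
    for letter, states in IUPAC_TO_STATES.items():
        assert encode(states) == letter
    with pytest.raises(ValueError):
        decode("X")
    with pytest.raises(ValueError):
        encode(set())


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------


def test_read_fasta_basic(tmp_path):
    p = tmp_path / "r.fa"
    p.write_text(">s1 some description\nACGT\n")
    reads = read_fasta(p)
    assert len(reads) == 1
    assert reads[0].id == "s1"
    assert reads[0].seq == "ACGT"


def test_read_fasta_non_iupac_names_record_and_position(tmp_path):
    p = tmp_path / "r.fa"
    p.write_text(">bad\nACGX\n")
    with pytest.raises(SequenceValidationError, match=r"bad.*position 4"):
        read_fasta(p)


def test_read_fasta_malformed_names_line(tmp_path):
    p = tmp_path / "r.fa"
    p.write_text("ACGT\n>late\nACGT\n")
    with pytest.raises(FastaParseError, match="line 1"):
        read_fasta(p)


@given(
    st.lists(
        st.text(alphabet=sorted("ACGTRYSWKMBDHVN"), min_size=1, max_size=80),
        min_size=1,
        max_size=5,
    )
)
@settings(derandomize=True, max_examples=25)
def test_fasta_write_read_roundtrip(tmp_path_factory, seqs):
    reads = [SangerRead(f"r{i}", s, "COI") for i, s in enumerate(seqs)]
    path = tmp_path_factory.mktemp("fa") / "round.fa"
    write_fasta(reads, path)
    assert read_fasta(path) == reads


def test_sangerread_rejects_empty_and_bad_alphabet():
    with pytest.raises(ValueError):
        SangerRead("x", "", "COI")
    with pytest.raises(SequenceValidationError, match="position 3"):
        SangerRead("x", "AC-T", "COI")


# ---------------------------------------------------------------------------
# reference amplicons
# ---------------------------------------------------------------------------


def test_site_outside_amplicon_rejected():
    site = MarkerSite("s", "COI", 200, frozenset("A"), "consistency-check")
    with pytest.raises(ValueError, match="outside"):
        ReferenceAmplicon(gene="COI", sequence="ACGTACGT", coordinate_offset=100, sites=[site])


def test_non_gt_splice_donor_warns():
    with pytest.warns(UserWarning, match="splice donor"):
        ref = ReferenceAmplicon(
            gene="Tpi",
            sequence="ACGTACGTAC",
            coordinate_offset=1,
            intron_boundary=5,
            intron_length=4,
        )
    assert ref.warnings


def test_reference_tsv_roundtrip(tmp_path, tpi_ref):
    write_reference(tpi_ref, tmp_path / "ref.fa", tmp_path / "ref.tsv")
    loaded = read_reference(tmp_path / "ref.fa", tmp_path / "ref.tsv")
    assert loaded.sequence == tpi_ref.sequence
    assert loaded.coordinate_offset == tpi_ref.coordinate_offset
    assert loaded.intron_boundary == tpi_ref.intron_boundary
    assert loaded.intron_length == tpi_ref.intron_length
    assert {s.name for s in loaded.sites} == {s.name for s in tpi_ref.sites}
    for s in tpi_ref.sites:
        t = loaded.site_by_name(s.name)
        assert (t.ref_position, t.allowed_states, t.role) == (
            s.ref_position,
            s.allowed_states,
            s.role,
        )


# ---------------------------------------------------------------------------
# global alignment
# ---------------------------------------------------------------------------


def brute_force_best_score(a: str, b: str, scoring: AlignmentScoring) -> float:
    """Exhaustive enumeration of all global alignments (oracle, tiny inputs)."""

    def column_score(cols):
        score = 0.0
        prev_gap_a = prev_gap_b = False
        for ca, cb in cols:
            if ca == "-":
                score += scoring.gap_extend if prev_gap_a else scoring.gap_open
                prev_gap_a, prev_gap_b = True, False
            elif cb == "-":
                score += scoring.gap_extend if prev_gap_b else scoring.gap_open
                prev_gap_b, prev_gap_a = True, False
            else:
                hit = decode(ca) & decode(cb)
                score += scoring.match if hit else scoring.mismatch
                prev_gap_a = prev_gap_b = False
        return score

    best = -float("inf")
    stack = [(0, 0, ())]
    while stack:
        i, j, cols = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, column_score(cols))
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, cols + ((a[i], b[j]),)))
        if i < len(a):
            stack.append((i + 1, j, cols + ((a[i], "-"),)))
        if j < len(b):
            stack.append((i, j + 1, cols + (("-", b[j]),)))
    return best


def test_identity_alignment_scores_full_match(coib_ref):
    read = SangerRead("r", coib_ref.sequence, "COI")
    aln = global_align(read, coib_ref)
    assert aln.aligned_read == aln.aligned_ref == coib_ref.sequence
    assert aln.score == pytest.approx(len(coib_ref.sequence) * DEFAULT_SCORING.match)


def test_single_deletion_yields_one_gap_column():
    aln = global_align("ACGT", "ACGGT")
    assert aln.aligned_read.count("-") == 1
    assert aln.aligned_ref.count("-") == 0
    assert aln.read == "ACGT" and aln.ref == "ACGGT"


def test_alignment_score_matches_exhaustive_oracle():
    rng = np.random.default_rng(7)
    bases = list("ACGT")
    for _ in range(40):
        a = "".join(rng.choice(bases, size=rng.integers(1, 7)))
        b = "".join(rng.choice(bases, size=rng.integers(1, 7)))
        got = global_align(b, a).score
        want = brute_force_best_score(a, b, DEFAULT_SCORING)
        assert got == pytest.approx(want), (a, b)


def test_iupac_overlap_scores_as_match():
    # Y = {C,T} intersects both C and T: a heterozygous read never pays a
    # mismatch against either allele
    assert global_align("ACYT", "ACCT").score == pytest.approx(4.0)
    assert global_align("ACYT", "ACTT").score == pytest.approx(4.0)


def test_orientation_detection(coib_ref):
    fwd = SangerRead("f", coib_ref.sequence[10:400], "COI")
    oriented, aln = orient_read(fwd, coib_ref)
    assert aln.orientation == "forward"
    rc = fwd.reverse_complement()
    oriented, aln = orient_read(rc, coib_ref)
    assert aln.orientation == "reverse-complement"
    assert oriented.seq == fwd.seq
    # involution
    assert rc.reverse_complement().seq == fwd.seq


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------


def _mini_ref():
    #           position: 123456789
    return ReferenceAmplicon(
        gene="COI",
        sequence="ACGTACGTA",
        coordinate_offset=1,
        sites=[MarkerSite("p5", "COI", 5, frozenset("ACGT"), "consistency-check")],
    )


def test_call_site_on_identity_returns_ref_base():
    ref = _mini_ref()
    aln = global_align(ref.sequence, ref)
    call = call_site(aln, ref, ref.sites[0])
    assert call.status == "unambiguous"
    assert call.base == "A"


def test_call_site_decodes_ambiguity():
    ref = _mini_ref()
    aln = global_align("ACGTRCGTA", ref)
    call = call_site(aln, ref, ref.sites[0])
    assert call.status == "ambiguous"
    assert call.observed_states == frozenset("AG")


def test_call_site_gap_and_uncovered():
    ref = _mini_ref()
    deleted = global_align("ACGTCGTA", ref)  # position 5 deleted
    assert call_site(deleted, ref, ref.sites[0]).status == "gap"
    truncated = global_align("CGTA", ref)  # read covers only the tail
    assert call_site(truncated, ref, ref.sites[0]).status == "uncovered"


def test_call_site_identity_recovers_every_annotated_site(tpi_ref, coib_ref):
    for ref in (tpi_ref, coib_ref):
        aln = global_align(ref.sequence, ref)
        for site in ref.sites:
            call = call_site(aln, ref, site)
            assert call.status == "unambiguous"
            assert call.base == ref.sequence[ref.site_index(site)]


def test_call_site_rejects_foreign_site(coib_ref, tpi_ref):
    aln = global_align(coib_ref.sequence, coib_ref)
    with pytest.raises(ValueError, match="does not belong"):
        call_site(aln, coib_ref, tpi_ref.sites[0])
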