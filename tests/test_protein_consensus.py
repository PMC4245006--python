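"""Pairwise alignment oracle checks, identity matrices, progressive MSA and
consensus construction rules."""
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from orthostruct import (
    Group,
    MSA,
    SequenceRecord,
    ValidationError,
    build_consensus,
    deletion_tracks,
    global_align,
    identity_matrix,
    progressive_msa,
)

from tests_support_alignment import brute_force_best_score

B62 = substitution_matrices.load("BLOSUM62")


def test_self_alignment_identity():
    a = SequenceRecord(id="a", residues="MKVLQW", alphabet="protein")
    b = SequenceRecord(id="b", residues="MKVLQW", alphabet="protein")
    pw = global_align(a, b)
    assert pw.identity == 1.0
    assert "-" not in pw.aligned_a + pw.aligned_b


def test_single_deletion_column_counting():
    a = SequenceRecord(id="a", residues="ACGT", alphabet="dna")
    b = SequenceRecord(id="b", residues="ACT", alphabet="dna")
    pw = global_align(a, b)
    gap_cols = sum(1 for x, y in zip(pw.aligned_a, pw.aligned_b)
                   if "-" in (x, y))
    match_cols = sum(1 for x, y in zip(pw.aligned_a, pw.aligned_b) if x == y)
    assert gap_cols == 1 and match_cols == 3
    # gap-vs-residue columns count in the identity denominator
    assert pw.identity == pytest.approx(3 / 4)


def test_alphabet_mismatch_errors():
    a = SequenceRecord(id="a", residues="ACGT", alphabet="dna")
    b = SequenceRecord(id="b", residues="MKV", alphabet="protein")
    with pytest.raises(ValidationError):
        global_align(a, b)


@pytest.mark.parametrize("alphabet,letters", [
    ("protein", "ACDEFGHIKLMNPQRSTVWY"),
    ("dna", "ACGT"),
])
def test_score_equals_exhaustive_enumeration(alphabet, letters):
    rng = np.random.default_rng(3)
    for _ in range(25):
        la, lb = int(rng.integers(1, 9)), int(rng.integers(1, 9))
        sa = "".join(rng.choice(list(letters), size=la))
        sb = "".join(rng.choice(list(letters), size=lb))
        pw = global_align(
            SequenceRecord(id="a", residues=sa, alphabet=alphabet),
            SequenceRecord(id="b", residues=sb, alphabet=alphabet))
        assert pw.score == pytest.approx(
            brute_force_best_score(sa, sb, alphabet)), (sa, sb)


def test_identity_matrix_structure(bundle):
    records = [t.protein for t in bundle.taxa[:4]]
    m = identity_matrix(records)
    assert np.allclose(np.diag(m.values), 1.0)
    assert np.allclose(m.values, m.values.T)
    dup = [records[0], SequenceRecord(id="copy",
                                      residues=records[0].residues,
                                      alphabet="protein")]
    m2 = identity_matrix(dup)
    assert m2.values[0, 1] == 1.0


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def test_identical_sequences_align_gap_free():
    recs = [SequenceRecord(id=f"s{i}", residues="MKVLQWERTY" * 4,
                           alphabet="protein") for i in range(4)]
    msa = progressive_msa(recs)
    assert all("-" not in row for row in msa.aligned)


def test_planted_indels_recovered(rng):
    """Sequences derived from a master with known indels: the inferred gap
    pattern restores every row to its source coordinates."""
    master = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
    s1 = master[:40] + master[50:]            # 10-aa deletion at 40
    s2 = master[:80] + "WWWWW" + master[80:]  # 5-aa insertion at 80
    recs = [
        SequenceRecord(id="m", residues=master, alphabet="protein"),
        SequenceRecord(id="d", residues=s1, alphabet="protein"),
        SequenceRecord(id="i", residues=s2, alphabet="protein"),
    ]
    msa = progressive_msa(recs)
    rows = dict(zip(msa.ids, msa.aligned))
    assert rows["m"].replace("-", "") == master
    d_gaps = [c for c, ch in enumerate(rows["d"]) if ch == "-"
              and rows["m"][c] != "-"]
    assert len(d_gaps) == 10
    i_ins = [c for c, ch in enumerate(rows["m"]) if ch == "-"]
    assert len(i_ins) == 5


def _sp_score(rows):
    total = 0.0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            in_gap = False
            for x, y in zip(rows[i], rows[j]):
                if x == "-" and y == "-":
                    continue
                if "-" in (x, y):
                    total += -0.5 if in_gap else -10.0
                    in_gap = True
                else:
                    total += float(B62[x, y])
                    in_gap = False
    return total


def test_sum_of_pairs_beats_stacked_arrangement(bundle):
    recs = [t.protein for t in bundle.taxa[:3]]
    msa = progressive_msa(recs)
    width = max(len(r.residues) for r in recs)
    stacked = [r.residues + "-" * (width - len(r.residues)) for r in recs]
    assert _sp_score(msa.aligned) >= _sp_score(stacked)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def _toy_msa(columns, groups):
    """columns: list of strings, one per row (already aligned)."""
    recs = []
    for i, g in enumerate(groups):
        recs.append(SequenceRecord(
            id=f"t{i}", residues=columns[i].replace("-", ""),
            species=f"t{i}", group=g, alphabet="protein"))
    return MSA(records=recs, aligned=columns)


def test_consensus_unanimity():
    rows = ["AAAA"] * 6 + ["AAAA"] * 2
    groups = [Group.MONOCOT] * 6 + [Group.DICOT] * 2
    msa = _toy_msa(rows, groups)
    prof = build_consensus(msa, "t0")
    assert prof.consensus == "AAAA"
    assert prof.monocot_similarity == [6, 6, 6, 6]
    assert prof.dicot_similarity == [2, 2, 2, 2]


def test_consensus_all_distinct_takes_reference():
    rows = ["M", "K", "V", "W"]
    groups = [Group.MONOCOT] * 2 + [Group.DICOT] * 2
    msa = _toy_msa(rows, groups)
    assert build_consensus(msa, "t0").consensus == "M"
    assert build_consensus(msa, "t2").consensus == "V"


def test_consensus_reference_gapped_all_distinct_takes_lexicographic():
    rows = ["-M", "KM", "VM", "CM"]
    groups = [Group.MONOCOT] * 2 + [Group.DICOT] * 2
    msa = _toy_msa(rows, groups)
    assert build_consensus(msa, "t0").consensus == "CM"


def test_consensus_modal_tie_prefers_reference_mode():
    rows = ["K", "K", "V", "V", "A"]
    groups = [Group.MONOCOT] * 5
    msa = _toy_msa(rows, groups)
    assert build_consensus(msa, "t2").consensus == "V"
    assert build_consensus(msa, "t4").consensus == "K"  # lexicographic


def test_consensus_insertion_columns_retained():
    rows = ["M-K", "MWK", "MWK"]
    groups = [Group.MONOCOT, Group.MONOCOT, Group.DICOT]
    msa = _toy_msa(rows, groups)
    prof = build_consensus(msa, "t0")
    assert prof.consensus == "MWK"


def test_consensus_missing_reference_errors():
    rows = ["MK", "MK"]
    msa = _toy_msa(rows, [Group.MONOCOT, Group.DICOT])
    with pytest.raises(ValidationError):
        build_consensus(msa, "nope")


def test_similarity_scores_match_direct_count(family_msa):
    prof = build_consensus(family_msa, "mono1")
    groups = [r.group for r in family_msa.records]
    for c in range(0, prof.n_columns, 97):  # spot-check a column lattice
        mono = sum(1 for row, g in zip(family_msa.aligned, groups)
                   if g is Group.MONOCOT and row[c] == prof.consensus[c])
        di = sum(1 for row, g in zip(family_msa.aligned, groups)
                 if g is Group.DICOT and row[c] == prof.consensus[c])
        assert prof.monocot_similarity[c] == mono
        assert prof.dicot_similarity[c] == di


# ---------------------------------------------------------------------------
# deletion tracks
# ---------------------------------------------------------------------------

def test_deletion_tracks_planted_and_identity():
    rng = np.random.default_rng(9)
    master = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
    deleted = master[:100] + master[177:]  # 77-aa deletion
    recs = [
        SequenceRecord(id="m1", residues=master, species="m1",
                       group=Group.MONOCOT, alphabet="protein"),
        SequenceRecord(id="m2", residues=master, species="m2",
                       group=Group.MONOCOT, alphabet="protein"),
        SequenceRecord(id="d1", residues=deleted, species="d1",
                       group=Group.DICOT, alphabet="protein"),
    ]
    msa = progressive_msa(recs)
    prof = build_consensus(msa, "m1")
    tracks = deletion_tracks(msa, prof)
    assert tracks["m1"] == [] and tracks["m2"] == []
    assert len(tracks["d1"]) == 1
    start, length = tracks["d1"][0]
    assert length == 77
    # conservation identity: interval lengths sum to consensus length minus
    # the species' non-gap columns
    non_gap = sum(1 for ch in msa.row("d1") if ch != "-")
    assert sum(l for _, l in tracks["d1"]) == prof.n_columns - non_gap
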