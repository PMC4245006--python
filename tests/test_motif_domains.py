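"""TM scan, NBD motif scanning on planted constructs, architecture,
inter-motif distances, NBD comparison and group-specific motifs."""
import numpy as np
import pytest

from orthostruct import (
    ArchitectureError,
    Group,
    MSA,
    NotAnNBDError,
    SequenceRecord,
    annotate_architecture,
    classify_substitution,
    compare_nbd_halves,
    find_conserved_motifs,
    motif_distance_table,
    scan_nbd_motifs,
    tm_scan,
)
from orthostruct.motif_domains import MOTIF_ORDER, MotifHit

from tests_support_motifs import planted_nbd as _planted_nbd
from tests_support_motifs import _bg


def test_planted_motifs_recovered_at_planted_positions(rng):
    for _ in range(20):
        seq, pos = _planted_nbd(rng)
        protein = SequenceRecord(id="nbd", residues=seq, alphabet="protein")
        hits = {h.name: h for h in scan_nbd_motifs(protein)}
        assert set(hits) == set(MOTIF_ORDER)
        for name, start in pos.items():
            assert hits[name].start == start, name
        starts = [hits[n].start for n in MOTIF_ORDER]
        assert starts == sorted(starts)


def test_motif_hits_idempotent_on_rescan(rng):
    seq, _ = _planted_nbd(rng)
    protein = SequenceRecord(id="nbd", residues=seq, alphabet="protein")
    for h in scan_nbd_motifs(protein):
        assert protein.residues[h.start:h.end] == h.matched


def test_walker_a_absent_is_not_an_nbd(rng):
    protein = SequenceRecord(id="bg", residues=_bg(rng, 200),
                             alphabet="protein")
    with pytest.raises(NotAnNBDError):
        scan_nbd_motifs(protein)


# ---------------------------------------------------------------------------
# TM scan
# ---------------------------------------------------------------------------

def test_tm_scan_constructed_positive_and_negative():
    polar = "D" * 60
    seq = polar + "L" * 30 + polar
    protein = SequenceRecord(id="p", residues=seq, alphabet="protein")
    helices = tm_scan(protein)
    assert len(helices) == 1
    s, e = helices[0]
    assert s <= 60 and e >= 90  # spans the leucine run (± window effects)
    negative = SequenceRecord(id="n", residues="D" * 100, alphabet="protein")
    assert tm_scan(negative) == []


def test_tm_scan_matches_independent_running_mean(bundle):
    from orthostruct.motif_domains import _KD
    protein = bundle.taxon("mono1").protein
    window = 19
    seq = protein.residues
    means = [sum(_KD[a] for a in seq[i:i + window]) / window
             for i in range(len(seq) - window + 1)]
    above = [m >= 1.6 for m in means]
    runs = []
    start = None
    for i, f in enumerate(above):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1 + window))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1 + window))
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < 5:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    expected = [(s, e) for s, e in merged if e - s >= 15]
    assert tm_scan(protein) == expected


def test_tm_scan_too_short_errors():
    protein = SequenceRecord(id="p", residues="MKV", alphabet="protein")
    with pytest.raises(Exception):
        tm_scan(protein)


# ---------------------------------------------------------------------------
# architecture
# ---------------------------------------------------------------------------

def test_architecture_order_and_completeness(bundle):
    for t in bundle.taxa:
        arch = annotate_architecture(t.protein)
        spans = [iv for _, iv in arch.spans()]
        flat = [x for iv in spans for x in iv]
        assert flat == sorted(flat), t.protein.species  # ordered, no overlap
        assert arch.complete


def test_single_half_construct_errors(bundle):
    protein = bundle.taxon("mono1").protein
    arch = annotate_architecture(protein)
    half = SequenceRecord(id="half",
                          residues=protein.residues[:arch.linker[0]],
                          alphabet="protein")
    with pytest.raises(ArchitectureError):
        annotate_architecture(half)


def test_linker_located_at_interhalf_junction(bundle):
    """The annotated linker must fall inside the designed inter-half
    segment (between NBD1 and TMD2 of the generator's template)."""
    arch = annotate_architecture(bundle.taxon("dicot1").protein)
    assert arch.nbd1[1] <= arch.linker[0] < arch.linker[1] <= arch.tmd2[0]


# ---------------------------------------------------------------------------
# distance table
# ---------------------------------------------------------------------------

def _hits_fixture(shift_wb=0):
    hits = []
    layout = [("WalkerA", 0, 9), ("Qloop", 40, 41), ("ABCsignature", 90, 95),
              ("WalkerB", 115 + shift_wb, 121 + shift_wb),
              ("Dloop", 130, 134), ("Hloop", 160, 161)]
    for domain in ("NBD1", "NBD2"):
        off = 0 if domain == "NBD1" else 500
        for name, s, e in layout:
            hits.append(MotifHit(name=name, start=s + off, end=e + off,
                                 matched="x", domain=domain))
    return hits


def test_distance_table_identical_layouts_all_conserved():
    table, summary = motif_distance_table(
        {"sp1": _hits_fixture(), "sp2": _hits_fixture()})
    assert (summary["range"] == 0).all()
    assert summary["conserved"].all()


def test_distance_table_perturbation_unflags_gap():
    table, summary = motif_distance_table(
        {"sp1": _hits_fixture(), "sp2": _hits_fixture(shift_wb=5)})
    key = "NBD1:ABCsignature-WalkerB"
    assert summary.loc[key, "range"] == 5
    assert not summary.loc[key, "conserved"]
    assert summary.loc["NBD1:WalkerA-Qloop", "conserved"]


def test_distance_table_missing_motif_is_nan():
    partial = [h for h in _hits_fixture() if h.name != "Dloop"]
    table, _ = motif_distance_table({"sp1": partial})
    assert np.isnan(table.loc["sp1", "NBD1:WalkerB-Dloop"])


# ---------------------------------------------------------------------------
# NBD1 vs NBD2 substitutions
# ---------------------------------------------------------------------------

def test_substitution_classifier_reproduces_printed_calls():
    assert classify_substitution("S", "A") == "conservative"
    assert classify_substitution("S", "P") == "radical"
    assert classify_substitution("S", "C") == "radical"
    assert classify_substitution("S", "S") == "identical"


def test_substitution_classifier_symmetric():
    for a, b in [("S", "A"), ("S", "P"), ("W", "F"), ("K", "R")]:
        assert classify_substitution(a, b) == classify_substitution(b, a)


def test_compare_nbd_halves_finds_planted_walker_change(bundle):
    """The generator plants a Walker A serine→proline difference between
    the halves; the comparison must classify it as radical."""
    protein = bundle.taxon("mono1").protein
    arch = annotate_architecture(protein)
    res = compare_nbd_halves(protein, arch)
    assert 0 < res["identity"] < 1
    planted = [r for r in res["records"]
               if (r.aa1, r.aa2) == ("S", "P")]
    assert planted and all(r.klass == "radical" for r in planted)


# ---------------------------------------------------------------------------
# group-specific motifs
# ---------------------------------------------------------------------------

def test_planted_monocot_motif_found(family_msa):
    motifs = find_conserved_motifs(family_msa, min_len=6, max_mismatch=0,
                                   max_len=15)
    mono = [m for m in motifs if m.group == "monocot"]
    assert any("PELEAFHLPS" in m.consensus for m in mono), motifs


def test_identical_groups_yield_no_motifs():
    rows = ["MKVLQWERTYMKVL"] * 4
    recs = [SequenceRecord(id=f"s{i}", residues=rows[i], species=f"s{i}",
                           group=g, alphabet="protein")
            for i, g in enumerate([Group.MONOCOT, Group.MONOCOT,
                                   Group.DICOT, Group.DICOT])]
    msa = MSA(records=recs, aligned=rows)
    assert find_conserved_motifs(msa, min_len=6) == []


def test_lower_mismatch_budget_does_not_add_motifs(family_msa):
    n0 = len(find_conserved_motifs(family_msa, min_len=8, max_mismatch=0))
    n1 = len(find_conserved_motifs(family_msa, min_len=8, max_mismatch=1))
    assert n0 <= n1
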