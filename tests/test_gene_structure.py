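"""Spliced-alignment inference, phases, protosplice classes, exon
correspondence and phase-spectrum statistics."""
import math

import numpy as np
import pytest

from orthostruct import (
    SequenceRecord,
    ValidationError,
    classify_protosplice,
    compute_phases,
    infer_gene_model,
    map_exon_correspondence,
    phase_spectrum,
    splice,
)
from orthostruct.core_io import GeneModel


def test_intronless_identity():
    rng = np.random.default_rng(1)
    g = SequenceRecord(id="g", residues="".join(
        rng.choice(list("ACGT"), size=240)), alphabet="dna")
    c = SequenceRecord(id="c", residues=g.residues, alphabet="dna")
    model = infer_gene_model(c, g)
    assert model.exons == [(0, len(g.residues))]


def test_exact_recovery_on_truth_bundle(bundle):
    """At zero cDNA/genomic divergence every inferred model equals the
    true model exactly (coordinates and counts)."""
    for t in bundle.taxa:
        model = infer_gene_model(t.cdna, t.genomic)
        truth = bundle.true_models[t.genomic.species]
        assert model.exons == truth.exons
        assert splice(t.genomic, model).residues == t.cdna.residues


def test_unalignable_input_raises():
    rng = np.random.default_rng(0)
    g = SequenceRecord(id="g", residues="".join(
        rng.choice(list("ACGT"), size=500)), alphabet="dna")
    c = SequenceRecord(id="c", residues="".join(
        rng.choice(list("ACGT"), size=300)), alphabet="dna")
    from orthostruct import UnalignableError
    with pytest.raises(UnalignableError):
        infer_gene_model(c, g)


# ---------------------------------------------------------------------------
# phases
# ---------------------------------------------------------------------------

def test_phase_arithmetic():
    # exons of 6 and 9 nt: intron after 6 coding nt -> phase 0
    model = GeneModel(seq_id="g", exons=[(0, 6), (100, 109)])
    assert compute_phases(model) == [0]
    model = GeneModel(seq_id="g", exons=[(0, 7), (100, 108)])
    assert compute_phases(model) == [1]


def _codon_walk_phases(model):
    """Independent recount: walk the spliced transcript codon by codon."""
    phases = []
    codon_pos = 0
    consumed = 0
    junctions = set(model.junctions_cdna())
    for p in range(model.spliced_length):
        if p in junctions:
            phases.append(codon_pos)
        if model.cds_start <= p < model.cds_end:
            codon_pos = (codon_pos + 1) % 3
    return phases


def test_phases_agree_with_codon_walk_oracle(bundle):
    for species, model in bundle.true_models.items():
        assert compute_phases(model) == _codon_walk_phases(model)


def test_phase_invariant_under_intron_length_change(bundle):
    model = bundle.true_models["dicot1"]
    before = compute_phases(model)
    shifted = []
    offset = 0
    for (s, e), intron in zip(model.exons, list(model.introns) + [None]):
        shifted.append((s + offset, e + offset))
        if intron is not None:
            offset += 17  # grow every intron by 17 bp
    grown = GeneModel(seq_id="g", exons=shifted)
    assert compute_phases(grown) == before


# ---------------------------------------------------------------------------
# protosplice classification
# ---------------------------------------------------------------------------

def _single_intron_genomic(flank5: str, flank3: str):
    up = "ATATAT" + flank5
    intron = "GT" + "C" * 20 + "AG"
    down = flank3 + "TATATA" * 3
    g = SequenceRecord(id="g", residues=up + intron + down, alphabet="dna")
    model = GeneModel(seq_id="g", exons=[
        (0, len(up)), (len(up) + len(intron), len(g.residues))])
    return g, model


@pytest.mark.parametrize("flank5,flank3,expected", [
    ("CAG", "G", "PROTOSPLICE"),
    ("AAG", "G", "PROTOSPLICE"),
    ("TTA", "G", "N_G"),
    ("TTG", "A", "G_N"),
    ("TTG", "G", "G_N"),   # upstream G takes precedence over the G downstream
    ("TTA", "A", "N_N"),
])
def test_protosplice_rule_table(flank5, flank3, expected):
    g, model = _single_intron_genomic(flank5, flank3)
    assert classify_protosplice(model, g) == [expected]


def test_protosplice_unclassifiable_short_flank():
    intron = "GT" + "C" * 20 + "AG"
    g = SequenceRecord(id="g", residues="AT" + intron + "GGGGGG",
                       alphabet="dna")
    model = GeneModel(seq_id="g", exons=[(0, 2), (2 + len(intron),
                                                  len(g.residues))])
    assert classify_protosplice(model, g) == [None]


def _expected_class_probs():
    """Enumerate all equally likely (T, Y) contexts and apply the rules."""
    from itertools import product
    counts = {"PROTOSPLICE": 0, "N_G": 0, "G_N": 0, "N_N": 0}
    for t1, t2, t3, y in product("ACGT", repeat=4):
        if t1 in "AC" and t2 == "A" and t3 == "G" and y == "G":
            counts["PROTOSPLICE"] += 1
        elif t3 != "G" and y == "G":
            counts["N_G"] += 1
        elif t3 == "G":
            counts["G_N"] += 1
        else:
            counts["N_N"] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def test_protosplice_frequencies_match_multinomial():
    """1000 introns inserted uniformly at random into uniform-composition
    exons: observed class frequencies within 3 SE of the enumeration."""
    rng = np.random.default_rng(5)
    intron = "GT" + "C" * 10 + "AG"
    observed = {"PROTOSPLICE": 0, "N_G": 0, "G_N": 0, "N_N": 0}
    n = 1000
    for _ in range(n):
        exon = "".join(rng.choice(list("ACGT"), size=40))
        pos = int(rng.integers(4, 36))
        g = SequenceRecord(id="g", residues=exon[:pos] + intron + exon[pos:],
                           alphabet="dna")
        model = GeneModel(seq_id="g", exons=[
            (0, pos), (pos + len(intron), len(g.residues))])
        (cls,) = classify_protosplice(model, g)
        observed[cls] += 1
    for cls, p in _expected_class_probs().items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed[cls] / n - p) <= 3 * se, (cls, observed)


# ---------------------------------------------------------------------------
# exon correspondence
# ---------------------------------------------------------------------------

def test_reference_vs_itself_all_conserved(bundle):
    models = {"dicot1": bundle.true_models["dicot1"]}
    cdnas = {"dicot1": bundle.taxon("dicot1").cdna}
    corr = map_exon_correspondence(models, cdnas, "dicot1")
    assert corr.conserved == set(models["dicot1"].junctions_cdna())
    assert corr.gains == [] and corr.losses == []


def test_losses_match_event_log(bundle):
    """With a dicot (full ancestral structure) as reference, inferred
    losses reproduce the generator's event log exactly."""
    models = dict(bundle.true_models)
    cdnas = {t.cdna.species: t.cdna for t in bundle.taxa}
    corr = map_exon_correspondence(models, cdnas, "dicot1")
    ref_junc = models["dicot1"].junctions_cdna()
    logged = set()
    for species, kind, idx in bundle.event_log:
        logged.add((species, ref_junc[idx]))
    inferred = set()
    for species, pos in corr.losses:
        near = min(ref_junc, key=lambda rp: abs(rp - pos))
        inferred.add((species, near))
    assert inferred == logged
    assert corr.gains == []


def test_conserved_set_symmetric_between_references(bundle):
    models = {s: bundle.true_models[s] for s in ("dicot1", "dicot2")}
    cdnas = {s: bundle.taxon(s).cdna for s in ("dicot1", "dicot2")}
    c1 = map_exon_correspondence(models, cdnas, "dicot1")
    c2 = map_exon_correspondence(models, cdnas, "dicot2")
    assert len(c1.conserved) == len(c2.conserved) == 9


def test_every_species_exon_maps_to_reference_exons(bundle):
    models = dict(bundle.true_models)
    cdnas = {t.cdna.species: t.cdna for t in bundle.taxa}
    corr = map_exon_correspondence(models, cdnas, "dicot1")
    for species, mapping in corr.exon_map.items():
        assert len(mapping) == models[species].n_exons
        assert all(len(covered) >= 1 for covered in mapping.values())


# ---------------------------------------------------------------------------
# phase spectrum
# ---------------------------------------------------------------------------

def _models_with_phase_counts(n0, n1, n2):
    """Single-intron two-exon models engineered to given phase counts."""
    models = []
    specs = [(0, 6)] * n0 + [(1, 7)] * n1 + [(2, 8)] * n2
    for i, (phase, first_len) in enumerate(specs):
        m = GeneModel(seq_id=f"m{i}", exons=[(0, first_len),
                                             (50, 50 + (9 - first_len))])
        models.append(m)
    return models


def test_phase_spectrum_uniform_case():
    res = phase_spectrum(_models_with_phase_counts(10, 10, 10))
    assert res["counts"] == [10, 10, 10]
    assert res["proportions"] == pytest.approx([1 / 3] * 3)
    assert res["chi2_p"] == pytest.approx(1.0)


def test_phase_spectrum_chi2_closed_form():
    res = phase_spectrum(_models_with_phase_counts(30, 0, 0))
    assert res["chi2_stat"] == pytest.approx(60.0)


def test_phase_spectrum_binomial_tail_oracle():
    """Exact one-sided binomial tail computed by direct summation."""
    res = phase_spectrum(_models_with_phase_counts(16, 10, 10))
    n = 36
    tail = sum(math.comb(n, k) * (1 / 3) ** k * (2 / 3) ** (n - k)
               for k in range(16, n + 1))
    assert res["binom_p_phase0"] == pytest.approx(tail, rel=1e-12)


def test_phase_spectrum_empty_errors():
    with pytest.raises(ValidationError):
        phase_spectrum([GeneModel(seq_id="g", exons=[(0, 9)])])
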