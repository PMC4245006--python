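"""Synthetic ABCB1-like gene families with full ground truth.

The generator emulates the evolutionary scenario the downstream analyses
assume: an ancestral multi-exon gene (9 introns, the ancestral angiosperm
state), exact-excision intron loss restricted to monocot lineages, dicot
retention of all ancestral introns, region-heterogeneous protein divergence
(variable N-terminus and inter-half linker, conserved TMD/NBD cores with
invariant nucleotide-binding motifs), canonical GT/AG termini on every
retained intron, and small frame-preserving N-terminal deletions.

The ancestral protein is a designed full-length ABC transporter:
TMD1 (six hydrophobic helices) - NBD1 (Walker A, Q-loop, ABC signature,
Walker B, D-loop, H-loop) - linker - TMD2 - NBD2, with the NBD2 Walker A
carrying a planted serine→proline change relative to NBD1 and monocot
lineages carrying a planted group-specific N-terminal motif.

Every bundle is self-consistent by construction: splicing the genomic
sequence with the true model yields the bundled cDNA, and translating the
cDNA yields the bundled protein.  A single seeded random stream drives the
whole simulation, so identical config ⇒ byte-identical bundle.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .core_io import (
    GeneModel,
    Group,
    SequenceRecord,
    ValidationError,
)

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# region classes (per amino acid / per exonic nucleotide)
CORE, VARIABLE, INVARIANT = 0, 1, 2

# designed ancestral protein segments (lengths in aa); see docs/methods.md
_NTERM = 200          # variable; group-motif slot at aa [80, 90)
_MOTIF_SLOT = (80, 90)
_MONOCOT_MOTIF = "PELEAFHLPS"
_HELIX_LEN, _LOOP_LEN, _N_HELICES = 21, 15, 6
_TMD_LEN = _N_HELICES * _HELIX_LEN + (_N_HELICES - 1) * _LOOP_LEN  # 201
_SPACER = 48
_LINKER = 101         # variable
_CTERM = 100

_WALKER_A1 = "GPSGSGKST"
_WALKER_A2 = "GPPGSGKST"   # planted S→P (the paper-style NBD2 change)
_ABC_SIG = "LSGGQ"
_WALKER_B = "ILLLDE"
_DLOOP = "SALD"

# filler alphabets: NBD filler avoids every residue that could complete a
# spurious motif match (no K/Q/H/D/E/L); helices are strongly hydrophobic.
_NBD_FILLER = "ASTGNRP"
_GENERIC_FILLER = "ADEFGHILMNPQRSTVWY"   # no K (Walker A guard), no C
_HYDROPHOBIC = "LIVFAM"

# NBD internal layout: (kind, payload) with lengths adding to 186 aa
_NBD_LAYOUT = [
    ("filler", 10),
    ("motif", None),        # Walker A (9)
    ("filler", 31),
    ("motif", "Q"),         # Q-loop, 31 aa after Walker A end (window 25-60)
    ("filler", 60),
    ("motif", _ABC_SIG),
    ("filler", 20),
    ("motif", _WALKER_B),
    ("filler", 8),
    ("motif", _DLOOP),
    ("filler", 21),
    ("motif", "H"),         # H-loop, 33 aa after Walker B end (window 25-45)
    ("filler", 10),
]
NBD_LEN = 186

PROTEIN_LENGTH = (_NTERM + _TMD_LEN + _SPACER + NBD_LEN + _LINKER
                  + _TMD_LEN + _SPACER + NBD_LEN + _CTERM)        # 1271 aa
CDS_LENGTH = 3 * (PROTEIN_LENGTH + 1)                             # 3816 nt

# ancestral exon split of the CDS: 10 exons / 9 introns with a phase mix
# (0,1,2,0,0,1,2,0,2) biased toward phase 0 as observed in plant ABCB1
DEFAULT_EXON_LENGTHS = [420, 385, 430, 367, 399, 403, 385, 421, 299, 307]
DEFAULT_INTRON_LENGTHS = [150, 214, 183, 259, 172, 148, 241, 166, 210]
assert sum(DEFAULT_EXON_LENGTHS) == CDS_LENGTH


@dataclass
class EvolutionConfig:
    """Parameters of the simulated gene-family history.

    Defaults follow the eight-species study design: six monocots, two
    dicots, nine ancestral introns totalling 1743 bp, monocot intron-loss
    probability chosen so that monocots retain two–four introns on average,
    and a conserved-core / variable-terminus substitution contrast.
    """

    seed: int = 0
    n_monocots: int = 6
    n_dicots: int = 2
    ancestral_exon_lengths: list[int] = field(
        default_factory=lambda: list(DEFAULT_EXON_LENGTHS))
    ancestral_intron_lengths: list[int] = field(
        default_factory=lambda: list(DEFAULT_INTRON_LENGTHS))
    substitution_rate_core: float = 0.03    # per site, root→tip
    substitution_rate_variable: float = 0.10
    intron_loss_prob_monocot: float = 0.65
    terminal_indel_max: int = 13            # aa, frame-preserving, exon 1
    monocot_motif: str | None = _MONOCOT_MOTIF

    def validate(self) -> None:
        if sum(self.ancestral_exon_lengths) % 3 != 0:
            raise ValidationError("sum of exon lengths must be divisible by 3")
        if sum(self.ancestral_exon_lengths) != CDS_LENGTH:
            raise ValidationError(
                f"exon lengths must re-split the designed CDS of "
                f"{CDS_LENGTH} nt (got {sum(self.ancestral_exon_lengths)})"
            )
        if len(self.ancestral_intron_lengths) != len(self.ancestral_exon_lengths) - 1:
            raise ValidationError("need n_exons - 1 intron lengths")
        for name in ("substitution_rate_core", "substitution_rate_variable",
                     "intron_loss_prob_monocot"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0,1]")
        if self.substitution_rate_variable < self.substitution_rate_core:
            raise ValidationError("variable-region rate must be ≥ core rate")
        if self.n_monocots < 1 or self.n_dicots < 1:
            raise ValidationError("need at least one taxon per group")
        if self.terminal_indel_max < 0:
            raise ValidationError("terminal_indel_max must be ≥ 0")
        if self.monocot_motif is not None and len(self.monocot_motif) != (
                _MOTIF_SLOT[1] - _MOTIF_SLOT[0]):
            raise ValidationError(
                f"monocot_motif must be {_MOTIF_SLOT[1] - _MOTIF_SLOT[0]} aa")


@dataclass
class Taxon:
    """One simulated taxon: genomic, cDNA and protein records."""

    genomic: SequenceRecord
    cdna: SequenceRecord
    protein: SequenceRecord


@dataclass
class TruthBundle:
    """A simulated family plus everything needed to score an analysis."""

    taxa: list[Taxon]
    true_models: dict[str, GeneModel]         # species -> model
    true_tree: str                            # Newick
    event_log: list[tuple[str, str, int]]     # (lineage, kind, intron index)
    config: EvolutionConfig
    aa_classes: dict[str, np.ndarray] = field(default_factory=dict)

    def taxon(self, species: str) -> Taxon:
        for t in self.taxa:
            if t.protein.species == species:
                return t
        raise KeyError(species)

    @property
    def species(self) -> list[str]:
        return [t.protein.species for t in self.taxa]


# ---------------------------------------------------------------------------
# ancestral sequence design
# ---------------------------------------------------------------------------

def _design_protein(rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """Return the ancestral protein and its per-aa region classes."""
    aa: list[str] = []
    cls: list[int] = []

    def emit(s: str, c: int) -> None:
        aa.extend(s)
        cls.extend([c] * len(s))

    def filler(n: int, alphabet: str, c: int) -> None:
        emit("".join(rng.choice(list(alphabet), size=n)), c)

    # N-terminus (variable) with the group-motif slot
    emit("M", INVARIANT)
    filler(_MOTIF_SLOT[0] - 1, _GENERIC_FILLER, VARIABLE)
    filler(_MOTIF_SLOT[1] - _MOTIF_SLOT[0], _GENERIC_FILLER, VARIABLE)
    filler(_NTERM - _MOTIF_SLOT[1], _GENERIC_FILLER, VARIABLE)

    def tmd() -> None:
        for h in range(_N_HELICES):
            filler(_HELIX_LEN, _HYDROPHOBIC, CORE)
            if h < _N_HELICES - 1:
                filler(_LOOP_LEN, _GENERIC_FILLER, CORE)

    def nbd(walker_a: str, template: str | None = None,
            half_divergence: float = 0.45) -> str:
        """Emit one NBD; when a template is given the filler is the
        template's filler partially diverged, emulating the shared descent
        of the two halves (inter-NBD identity near the observed ~60%)."""
        start = len(aa)
        for kind, payload in _NBD_LAYOUT:
            if kind == "filler":
                if template is None:
                    filler(payload, _NBD_FILLER, CORE)
                else:
                    off = len(aa) - start
                    piece = [
                        (str(rng.choice(list(_NBD_FILLER)))
                         if rng.random() < half_divergence else template[off + i])
                        for i in range(payload)
                    ]
                    emit("".join(piece), CORE)
            else:
                emit(payload if payload is not None else walker_a, INVARIANT)
        return "".join(aa[start:])

    tmd()
    filler(_SPACER, _GENERIC_FILLER, CORE)
    nbd1_seq = nbd(_WALKER_A1)
    filler(_LINKER, _GENERIC_FILLER, VARIABLE)
    tmd()
    filler(_SPACER, _GENERIC_FILLER, CORE)
    nbd(_WALKER_A2, template=nbd1_seq)
    filler(_CTERM, _GENERIC_FILLER, CORE)

    assert len(aa) == PROTEIN_LENGTH
    return "".join(aa), np.array(cls, dtype=np.int8)


_CODONS: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    if not _CODONS:
        for b1 in _BASES:
            for b2 in _BASES:
                for b3 in _BASES:
                    codon = b1 + b2 + b3
                    if codon in _STOPS:
                        continue
                    _CODONS.setdefault(str(Seq(codon).translate()), []).append(codon)
    return _CODONS


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    table = _codon_table()
    return "".join(table[a][rng.integers(len(table[a]))] for a in protein)


def _random_intron(length: int, rng: np.random.Generator) -> str:
    if length < 4:
        raise ValidationError("introns must be ≥ 4 bp for GT..AG termini")
    body = "".join(rng.choice(list(_BASES), size=length - 4))
    return "GT" + body + "AG"


# ---------------------------------------------------------------------------
# a mutable per-lineage gene state
# ---------------------------------------------------------------------------

@dataclass
class _GeneState:
    seq: np.ndarray            # uint8 base codes over the genomic sequence
    site_class: np.ndarray     # CORE/VARIABLE/INVARIANT per site; introns CORE
    is_intron: np.ndarray      # bool per site
    exons: list[tuple[int, int]]
    present: list[int]         # ancestral indices of retained introns

    def copy(self) -> "_GeneState":
        return _GeneState(self.seq.copy(), self.site_class.copy(),
                          self.is_intron.copy(), list(self.exons),
                          list(self.present))


_CODE = {b: i for i, b in enumerate(_BASES)}


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8).copy()


def _decode(a: np.ndarray) -> str:
    return a.tobytes().decode()


def _cds_maps(state: _GeneState) -> tuple[np.ndarray, np.ndarray]:
    """genomic position of each CDS index, and CDS index of each genomic
    position (-1 for intronic)."""
    gpos = np.concatenate([np.arange(s, e) for s, e in state.exons])
    cds_of_g = np.full(len(state.seq), -1, dtype=np.int64)
    cds_of_g[gpos] = np.arange(len(gpos))
    return gpos, cds_of_g


def _mutate(state: _GeneState, rate_core: float, rate_variable: float,
            rng: np.random.Generator) -> None:
    """Apply per-site substitutions in place, codon-aware in exons.

    Intronic sites mutate at the variable rate.  A substitution that would
    create an in-frame stop codon is skipped (purifying selection).
    """
    n = len(state.seq)
    rates = np.where(state.is_intron, rate_variable,
                     np.where(state.site_class == VARIABLE, rate_variable,
                              np.where(state.site_class == CORE,
                                       rate_core, 0.0)))
    hits = np.flatnonzero(rng.random(n) < rates)
    if len(hits) == 0:
        return
    gpos, cds_of_g = _cds_maps(state)
    seq_bytes = state.seq
    for pos in hits:
        old = seq_bytes[pos]
        choices = [c for c in (65, 67, 71, 84) if c != old]  # A C G T
        new = choices[rng.integers(3)]
        c = cds_of_g[pos]
        if c >= 0:
            c0 = c - c % 3
            codon_pos = gpos[c0:c0 + 3]
            codon = bytearray(seq_bytes[codon_pos].tobytes())
            codon[c - c0] = new
            if codon.decode() in _STOPS:
                continue
        seq_bytes[pos] = new


def _excise(state: _GeneState, intron_rank: int) -> None:
    """Remove the intron between exon ``intron_rank`` and the next exon
    (rank within currently retained introns); exact exon fusion."""
    s_int = state.exons[intron_rank][1]
    e_int = state.exons[intron_rank + 1][0]
    keep = np.ones(len(state.seq), dtype=bool)
    keep[s_int:e_int] = False
    shift = e_int - s_int
    state.seq = state.seq[keep]
    state.site_class = state.site_class[keep]
    state.is_intron = state.is_intron[keep]
    new_exons = list(state.exons[:intron_rank])
    fused = (state.exons[intron_rank][0], state.exons[intron_rank + 1][1] - shift)
    new_exons.append(fused)
    for s, e in state.exons[intron_rank + 2:]:
        new_exons.append((s - shift, e - shift))
    state.exons = new_exons
    state.present.pop(intron_rank)


def _delete_nterm(state: _GeneState, k_aa: int, at_aa: int = 20) -> None:
    """Frame-preserving deletion of ``k_aa`` codons inside exon 1."""
    if k_aa <= 0:
        return
    s = state.exons[0][0] + 3 * at_aa
    e = s + 3 * k_aa
    keep = np.ones(len(state.seq), dtype=bool)
    keep[s:e] = False
    shift = 3 * k_aa
    state.seq = state.seq[keep]
    state.site_class = state.site_class[keep]
    state.is_intron = state.is_intron[keep]
    state.exons = [(state.exons[0][0], state.exons[0][1] - shift)] + [
        (a - shift, b - shift) for a, b in state.exons[1:]
    ]


def _stamp_gt_ag(state: _GeneState) -> None:
    """Write canonical GT..AG termini at every retained intron (byte codes)."""
    for (_, e1), (s2, _) in zip(state.exons, state.exons[1:]):
        state.seq[e1], state.seq[e1 + 1] = 71, 84      # G T
        state.seq[s2 - 2], state.seq[s2 - 1] = 65, 71  # A G


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def splice(genomic: SequenceRecord, model: GeneModel) -> SequenceRecord:
    """Concatenate the exon substrings of ``genomic`` per ``model``."""
    n = len(genomic.residues)
    for s, e in model.exons:
        if s < 0 or e > n:
            raise ValidationError(
                f"{model.seq_id}: exon [{s},{e}) outside sequence of length {n}"
            )
    residues = "".join(genomic.residues[s:e] for s, e in model.exons)
    return SequenceRecord(
        id=genomic.id + ".spliced", residues=residues,
        species=genomic.species, group=genomic.group, alphabet="dna",
    )


def translate_cds(cdna: SequenceRecord, cds_start: int = 0,
                  cds_end: int | None = None) -> SequenceRecord:
    """Standard-code translation of a CDS span; the trailing stop codon is
    excluded from the output and an internal stop is an error."""
    if cds_end is None:
        cds_end = len(cdna.residues)
    span = cdna.residues[cds_start:cds_end]
    if len(span) % 3 != 0:
        raise ValidationError(
            f"{cdna.id}: CDS span of {len(span)} nt is not a multiple of 3")
    aa = str(Seq(span).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValidationError(
            f"{cdna.id}: internal stop codon at aa {aa.index('*')}")
    return SequenceRecord(
        id=cdna.id + ".protein", residues=aa,
        species=cdna.species, group=cdna.group, alphabet="protein",
    )


def simulate_family(config: EvolutionConfig) -> TruthBundle:
    """Simulate a gene family under the configured history.

    Dicot taxa retain all ancestral introns; each monocot taxon loses each
    intron independently with ``intron_loss_prob_monocot`` by exact
    excision.  Substitutions are applied on a group branch and a terminal
    branch (each carrying half the configured root→tip rate).  Canonical
    GT/AG dinucleotides are guaranteed at every retained intron's termini.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    protein, aa_class = _design_protein(rng)
    cds = _reverse_translate(protein, rng) + "TAA"
    nt_class = np.repeat(aa_class, 3)
    nt_class = np.concatenate([nt_class, np.full(3, INVARIANT, dtype=np.int8)])

    # interleave exons and introns
    exon_bounds, pieces, classes, intron_flags = [], [], [], []
    pos = 0
    cpos = 0
    for i, ex_len in enumerate(config.ancestral_exon_lengths):
        pieces.append(cds[cpos:cpos + ex_len])
        classes.append(nt_class[cpos:cpos + ex_len])
        intron_flags.append(np.zeros(ex_len, dtype=bool))
        exon_bounds.append((pos, pos + ex_len))
        pos += ex_len
        cpos += ex_len
        if i < len(config.ancestral_intron_lengths):
            il = config.ancestral_intron_lengths[i]
            pieces.append(_random_intron(il, rng))
            classes.append(np.full(il, CORE, dtype=np.int8))
            intron_flags.append(np.ones(il, dtype=bool))
            pos += il
    ancestor = _GeneState(
        seq=_encode("".join(pieces)),
        site_class=np.concatenate(classes),
        is_intron=np.concatenate(intron_flags),
        exons=exon_bounds,
        present=list(range(len(config.ancestral_intron_lengths))),
    )
    # protect splice dinucleotides from substitution
    for (_, e1), (s2, _) in zip(ancestor.exons, ancestor.exons[1:]):
        ancestor.site_class[e1:e1 + 2] = INVARIANT
        ancestor.site_class[s2 - 2:s2] = INVARIANT
    _stamp_gt_ag(ancestor)

    half_core = config.substitution_rate_core / 2.0
    half_var = config.substitution_rate_variable / 2.0

    taxa: list[Taxon] = []
    models: dict[str, GeneModel] = {}
    events: list[tuple[str, str, int]] = []
    aa_classes: dict[str, np.ndarray] = {}

    slot_nt = (3 * _MOTIF_SLOT[0], 3 * _MOTIF_SLOT[1])

    for group, n_taxa, prefix in (
        (Group.MONOCOT, config.n_monocots, "mono"),
        (Group.DICOT, config.n_dicots, "dicot"),
    ):
        g_anc = ancestor.copy()
        if group is Group.MONOCOT and config.monocot_motif is not None:
            motif_cds = _reverse_translate(config.monocot_motif, rng)
            g_anc.seq[slot_nt[0]:slot_nt[1]] = _encode(motif_cds)
            g_anc.site_class[slot_nt[0]:slot_nt[1]] = INVARIANT
        _mutate(g_anc, half_core, half_var, rng)
        _stamp_gt_ag(g_anc)

        for t in range(n_taxa):
            species = f"{prefix}{t + 1}"
            state = g_anc.copy()
            _mutate(state, half_core, half_var, rng)
            if group is Group.MONOCOT:
                # iterate over ancestral intron indices; excise by rank
                for anc_idx in list(state.present):
                    if rng.random() < config.intron_loss_prob_monocot:
                        _excise(state, state.present.index(anc_idx))
                        events.append((species, "intron_loss", anc_idx))
            k = int(rng.integers(0, config.terminal_indel_max + 1))
            _delete_nterm(state, k)
            _stamp_gt_ag(state)

            gid = f"{species}_genomic"
            genomic = SequenceRecord(
                id=gid, residues=_decode(state.seq),
                species=species, group=group, alphabet="dna",
            )
            model = GeneModel(seq_id=gid, exons=state.exons)
            cdna = splice(genomic, model)
            cdna.id = f"{species}_cdna"
            prot = translate_cds(cdna)
            prot.id = f"{species}_protein"
            taxa.append(Taxon(genomic=genomic, cdna=cdna, protein=prot))
            models[species] = model
            cls_aa = state.site_class[~state.is_intron][:-3:3]
            aa_classes[species] = cls_aa
    events.sort(key=lambda x: (x[0], x[2]))

    mono = ",".join(
        f"mono{i + 1}:{half_core:.4f}" for i in range(config.n_monocots))
    di = ",".join(
        f"dicot{i + 1}:{half_core:.4f}" for i in range(config.n_dicots))
    tree = f"(({mono}):{half_core:.4f},({di}):{half_core:.4f});"

    return TruthBundle(
        taxa=taxa, true_models=models, true_tree=tree,
        event_log=events, config=config, aa_classes=aa_classes,
    )


# ---------------------------------------------------------------------------
# fixture helpers used by the screen / assembly analyses
# ---------------------------------------------------------------------------

def mutate_record(record: SequenceRecord, rate: float,
                  rng: np.random.Generator) -> SequenceRecord:
    """Return a copy with uniform per-site substitutions at ``rate``.

    Used to degrade inputs (e.g. a cDNA diverged from its genomic locus)
    for robustness tests; no stop-codon awareness.
    """
    seq = _encode(record.residues).copy()
    alphabet = _BASES if record.alphabet == "dna" else "ACDEFGHIKLMNPQRSTVWY"
    codes = _encode(alphabet)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for pos in hits:
        choices = codes[codes != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
    return SequenceRecord(
        id=record.id + ".mut", residues=_decode(seq),
        species=record.species, group=record.group, alphabet=record.alphabet,
    )


def make_decoys(bundle: TruthBundle, n: int,
                rng: np.random.Generator) -> list[SequenceRecord]:
    """Build decoy paralogs by shuffling the core regions of true proteins.

    Each decoy keeps its source taxon's species/group labels and variable
    regions but has its core (TMD/NBD, motifs included) residues permuted,
    which destroys the motif architecture and drops core identity far below
    the screen's decoy ceiling.
    """
    decoys = []
    for i in range(n):
        src = bundle.taxa[int(rng.integers(len(bundle.taxa)))]
        aa = np.array(list(src.protein.residues))
        cls = bundle.aa_classes[src.protein.species]
        core_idx = np.flatnonzero(cls != VARIABLE)
        aa[core_idx] = aa[core_idx[rng.permutation(len(core_idx))]]
        decoys.append(
            SequenceRecord(
                id=f"decoy{i + 1}", residues="".join(aa),
                species=src.protein.species, group=src.protein.group,
                alphabet="protein",
            )
        )
    return decoys


def fragment_into_contigs(record: SequenceRecord, contig_len: int,
                          overlap: int, rng: np.random.Generator
                          ) -> list[SequenceRecord]:
    """Cut a sequence into overlapping exact contigs (shuffled order)."""
    if overlap >= contig_len:
        raise ValidationError("overlap must be smaller than contig length")
    step = contig_len - overlap
    starts = list(range(0, max(len(record.residues) - overlap, 1), step))
    contigs = []
    for i, s in enumerate(starts):
        e = min(s + contig_len, len(record.residues))
        contigs.append(
            SequenceRecord(
                id=f"contig{i + 1}", residues=record.residues[s:e],
                species=record.species, group=record.group, alphabet="dna",
            )
        )
    order = rng.permutation(len(contigs))
    return [contigs[i] for i in order]
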