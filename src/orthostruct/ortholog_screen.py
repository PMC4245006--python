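"""True-ortholog screening and contig walk-assembly.

The screen applies four criteria to a candidate protein against a
reference (query) protein: (1) it is the top-ranked same-species hit by
alignment score with near-full query coverage; (2) it carries every
domain and motif the query carries; (3) searching the candidate back
against the reference species' database retrieves the reference sequence
at rank 1 (reciprocal best hit); (4) the relative sizes and distances
among its motifs and domains match the query's within a tolerance.  A
candidate is a true ortholog iff all four hold.

The database search is an internal semi-global protein alignment
(BLOSUM62, affine gaps, free end gaps), ranking by score with
identity/id tie-breaks — rank, score and coverage stand in for web-BLAST
E-values.  ``walk_assemble`` reproduces iterative sequence walking:
greedy overlap extension of a seed with the best-overlapping contig until
no contig qualifies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .core_io import SequenceRecord, ValidationError
from .motif_domains import (
    MOTIF_ORDER,
    ArchitectureError,
    DomainArchitecture,
    NotAnNBDError,
    annotate_architecture,
)
from .protein_consensus import AlignParams, _matrix

logger = logging.getLogger(__name__)


@dataclass
class CandidateHit:
    query_id: str
    subject_id: str
    coverage: float   # fraction of query residues in aligned pairs
    identity: float   # identical / aligned columns within the paired span
    score: float


@dataclass
class OrthologVerdict:
    candidate_id: str
    c1_rank_ok: bool
    c2_domains_ok: bool
    c3_reciprocal_ok: bool
    c4_spacing_ok: bool
    spacing_deviation: float

    @property
    def is_true_ortholog(self) -> bool:
        return (self.c1_rank_ok and self.c2_domains_ok
                and self.c3_reciprocal_ok and self.c4_spacing_ok)


@dataclass
class ScreenDatabases:
    """Search database, reference-species database and reference id."""

    search_db: list[SequenceRecord]
    reference_db: list[SequenceRecord]
    reference_id: str


def _semiglobal_aligner(params: AlignParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _matrix(params.matrix_name)
    al.open_gap_score = -params.gap_open
    al.extend_gap_score = -params.gap_extend
    # free end gaps on both sequences (overlap/semi-global mode)
    try:
        al.end_insertion_score = 0.0
        al.end_deletion_score = 0.0
    except AttributeError:  # older attribute names
        al.target_end_gap_score = 0.0
        al.query_end_gap_score = 0.0
    return al


def search_db(query: SequenceRecord, db: list[SequenceRecord],
              params: AlignParams | None = None) -> list[CandidateHit]:
    """Score every database sequence against the query; ranked hits.

    Sorted by score descending, ties by identity then id lexicographic.
    """
    if not db:
        raise ValidationError("search_db: empty database")
    params = params or AlignParams()
    al = _semiglobal_aligner(params)
    hits = []
    for subject in db:
        best = al.align(query.residues, subject.residues)[0]
        q_blocks = best.aligned[0]
        paired = int(sum(e - s for s, e in q_blocks))
        coverage = paired / len(query.residues)
        ga, gb = str(best[0]), str(best[1])
        both = [i for i, (x, y) in enumerate(zip(ga, gb))
                if x != "-" and y != "-"]
        if both:
            lo, hi = both[0], both[-1] + 1
            cols = hi - lo
            ident = sum(1 for x, y in zip(ga[lo:hi], gb[lo:hi]) if x == y)
            identity = ident / cols
        else:
            identity = 0.0
        hits.append(CandidateHit(
            query_id=query.id, subject_id=subject.id,
            coverage=coverage, identity=identity, score=float(best.score)))
    hits.sort(key=lambda h: (-h.score, -h.identity, h.subject_id))
    return hits


def reciprocal_best(candidate: SequenceRecord,
                    reference_db: list[SequenceRecord],
                    reference_id: str,
                    params: AlignParams | None = None) -> bool:
    """True iff searching the candidate against the reference database
    retrieves ``reference_id`` at rank 1."""
    if all(r.id != reference_id for r in reference_db):
        raise ValidationError(
            f"reference id {reference_id!r} absent from reference database")
    hits = search_db(candidate, reference_db, params)
    return hits[0].subject_id == reference_id


# ---------------------------------------------------------------------------
# criterion 4: motif/domain spacing
# ---------------------------------------------------------------------------

def _feature_gaps(arch: DomainArchitecture) -> dict[str, int]:
    """Consecutive-feature gaps along TMD1 → NBD1 motifs → TMD2 → NBD2."""
    if not arch.complete:
        raise ValidationError("architecture incomplete: missing motifs")
    by1 = {h.name: h for h in arch.nbd1_hits}
    by2 = {h.name: h for h in arch.nbd2_hits}
    gaps: dict[str, int] = {
        "tmd1-WalkerA1": by1["WalkerA"].start - arch.tmd1[1],
        "Hloop1-tmd2": arch.tmd2[0] - by1["Hloop"].end,
        "tmd2-WalkerA2": by2["WalkerA"].start - arch.tmd2[1],
    }
    for domain, by in (("NBD1", by1), ("NBD2", by2)):
        for a, b in zip(MOTIF_ORDER, MOTIF_ORDER[1:]):
            gaps[f"{domain}:{a}-{b}"] = by[b].start - by[a].end
    return gaps


def motif_spacing_similarity(candidate_arch: DomainArchitecture,
                             reference_arch: DomainArchitecture,
                             tolerance: float = 0.25
                             ) -> tuple[float, bool]:
    """Maximal relative deviation of corresponding inter-feature gaps.

    deviation = max over gaps of |gap_cand − gap_ref| / gap_ref (with a
    floor of 1 aa on the reference gap); ok iff deviation ≤ tolerance.
    """
    gc = _feature_gaps(candidate_arch)
    gr = _feature_gaps(reference_arch)
    deviation = 0.0
    for key, ref_gap in gr.items():
        cand_gap = gc[key]
        deviation = max(deviation,
                        abs(cand_gap - ref_gap) / max(abs(ref_gap), 1))
    return deviation, deviation <= tolerance


def evaluate_candidate(query: SequenceRecord, candidate: SequenceRecord,
                       dbs: ScreenDatabases, tolerance: float = 0.25,
                       min_coverage: float = 0.90,
                       params: AlignParams | None = None
                       ) -> OrthologVerdict:
    """Apply all four true-ortholog criteria to one candidate.

    Criterion 1 ranks the candidate among same-species entries of the
    search database (species-blind when the candidate carries no species
    label) and additionally requires query coverage ≥ ``min_coverage``.
    """
    same_species = [r for r in dbs.search_db
                    if not candidate.species or r.species == candidate.species]
    hits = search_db(query, same_species, params)
    top = hits[0]
    c1 = top.subject_id == candidate.id and top.coverage >= min_coverage

    try:
        query_arch = annotate_architecture(query)
    except (ArchitectureError, NotAnNBDError) as exc:
        raise ValidationError(f"query lacks ABCB architecture: {exc}")
    cand_arch: DomainArchitecture | None
    try:
        cand_arch = annotate_architecture(candidate)
        c2 = cand_arch.complete and query_arch.complete
    except (ArchitectureError, NotAnNBDError):
        cand_arch = None
        c2 = False

    c3 = reciprocal_best(candidate, dbs.reference_db, dbs.reference_id,
                         params)

    if c2 and cand_arch is not None:
        deviation, c4 = motif_spacing_similarity(cand_arch, query_arch,
                                                 tolerance)
    else:
        deviation, c4 = float("nan"), False

    return OrthologVerdict(
        candidate_id=candidate.id,
        c1_rank_ok=c1, c2_domains_ok=c2,
        c3_reciprocal_ok=c3, c4_spacing_ok=c4,
        spacing_deviation=deviation,
    )


# ---------------------------------------------------------------------------
# sequence-walking assembly
# ---------------------------------------------------------------------------

def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def _best_suffix_prefix(A: np.ndarray, C: np.ndarray, min_overlap: int,
                        min_identity: float) -> int:
    """Longest L with identity(A[-L:], C[:L]) ≥ min_identity, else 0."""
    for L in range(min(len(A), len(C)), min_overlap - 1, -1):
        if np.count_nonzero(A[-L:] == C[:L]) / L >= min_identity:
            return L
    return 0


def walk_assemble(seed_seq: SequenceRecord,
                  contig_db: list[SequenceRecord],
                  min_overlap: int = 100,
                  min_identity: float = 0.95) -> SequenceRecord:
    """Greedy iterative overlap extension of a seed sequence.

    Each round merges the contig with the longest qualifying end-overlap
    (both ends attempted; assembly residues win at mismatches; ties break
    to the longer contig, then lexicographic id) until no contig
    qualifies.  Deterministic; assembly length never decreases and each
    round consumes a contig, so the walk terminates.
    """
    if not contig_db:
        raise ValidationError("walk_assemble: empty contig database")
    assembly = _encode(seed_seq.residues).copy()
    pool = {c.id: _encode(c.residues) for c in contig_db}
    extended_once = False
    while pool:
        best = None  # (overlap L, len(contig), id, side)
        for cid, C in pool.items():
            lr = _best_suffix_prefix(assembly, C, min_overlap, min_identity)
            ll = _best_suffix_prefix(C, assembly, min_overlap, min_identity)
            for side, L in (("right", lr), ("left", ll)):
                if L < min_overlap:
                    continue
                better = (
                    best is None
                    or (L, len(C)) > (best[0], best[1])
                    or ((L, len(C)) == (best[0], best[1]) and cid < best[2])
                )
                if better:
                    best = (L, len(C), cid, side)
        if best is None:
            break
        L, _, cid, side = best
        C = pool.pop(cid)
        if side == "right":
            assembly = np.concatenate([assembly, C[L:]])
        else:
            assembly = np.concatenate([C[:len(C) - L], assembly])
        extended_once = True
    if not extended_once:
        logger.warning(
            "walk_assemble: no contig overlaps seed %s; returning seed",
            seed_seq.id)
        return seed_seq
    return SequenceRecord(
        id=seed_seq.id + ".assembly",
        residues=assembly.tobytes().decode(),
        species=seed_seq.species, group=seed_seq.group, alphabet="dna",
    )
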